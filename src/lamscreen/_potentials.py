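"""Numba kernels for the per-substituent 1-D conformational potentials.

Two potential kinds are encoded in fixed-width parameter rows so that the
Langevin integrator can evaluate any substituent without Python dispatch:

``KIND_HARMONIC`` (unfolded ensemble)
    row = [0, offset, k, center, 0, 0, 0, 0]
    U(x) = offset + k/2 (x - center)^2

``KIND_DOUBLE_WELL`` (folded ensemble)
    row = [1, eps_native, k_native, eps_disrupted, k_disrupted,
           disrupted_center, barrier, smoothing, inner_slope]
    U(x) = softmin_s( eps_n + k_n/2 x^2 , eps_d + A(x - d) ) + ridge(x)

The native well is centred at x = 0 by convention.  The disrupted arm
A(t) is an asymmetric Huber shape: quadratic k_d/2 t^2 for
t >= -inner_slope/k_d and the C^1-matched linear ramp
-inner_slope * t - inner_slope^2/(2 k_d) on the native-facing side.  A
large ``inner_slope`` (the default sentinel) recovers a plain parabola;
a small one models a partially unfolded conformation reached downhill
over a long gentle grade, so the return climb is slow.  ``softmin_s`` is
the smooth minimum with smoothing scale s (kcal/mol), which is
C-infinity; the ridge is a compactly supported C^1 cos^2 bump of
amplitude ``barrier`` centred midway between the wells (half-width
0.45|d|), so it vanishes identically at both well minima and
U(0) = eps_native up to an exp(-Delta/s) softmin correction far below
1e-9 for any system the generator emits.
"""

import math

import numpy as np
from numba import njit

KIND_HARMONIC = 0.0
KIND_DOUBLE_WELL = 1.0

#: softmin smoothing scale (kcal/mol) for the folded double well
SOFTMIN_SMOOTHING = 0.25

N_POT_PARAMS = 9

#: inner-slope sentinel that makes the disrupted arm purely quadratic
PURE_QUADRATIC_SLOPE = 1.0e6


@njit
def pot_energy_grad(row, x):
    """Energy and dU/dx of one substituent potential at scalar x."""
    if row[0] == KIND_HARMONIC:
        dx = x - row[3]
        return row[1] + 0.5 * row[2] * dx * dx, row[2] * dx
    eps_n = row[1]
    k_n = row[2]
    eps_d = row[3]
    k_d = row[4]
    d = row[5]
    h = row[6]
    s = row[7]
    slope = row[8]
    u_n = eps_n + 0.5 * k_n * x * x
    dxd = x - d
    t0 = slope / k_d
    if dxd >= -t0:
        u_d = eps_d + 0.5 * k_d * dxd * dxd
        du_d = k_d * dxd
    else:  # gentle linear grade on the native-facing side
        u_d = eps_d - slope * dxd - 0.5 * slope * t0
        du_d = -slope
    if u_n < u_d:
        m = u_n
    else:
        m = u_d
    e_n = math.exp(-(u_n - m) / s)
    e_d = math.exp(-(u_d - m) / s)
    z = e_n + e_d
    u = m - s * math.log(z)
    w_n = e_n / z
    du = w_n * k_n * x + (1.0 - w_n) * du_d
    # C1 cos^2 ridge between the wells
    if h > 0.0 and d != 0.0:
        xm = 0.5 * d
        w = 0.45 * abs(d)
        t = x - xm
        if -w < t < w:
            c = math.cos(0.5 * math.pi * t / w)
            u += h * c * c
            du += -h * (0.5 * math.pi / w) * math.sin(math.pi * t / w)
    return u, du


@njit
def pot_energy(row, x):
    u, _ = pot_energy_grad(row, x)
    return u


@njit
def all_energies_grads(params, x, u_out, du_out):
    """Fill per-substituent U_i(x) and dU_i/dx for an (N, 8) parameter matrix."""
    n = params.shape[0]
    for i in range(n):
        u, du = pot_energy_grad(params[i], x)
        u_out[i] = u
        du_out[i] = du


def harmonic_row(offset, k, center):
    return np.array([KIND_HARMONIC, offset, k, center,
                     0.0, 0.0, 0.0, 0.0, 0.0])


def double_well_row(eps_native, k_native, eps_disrupted, k_disrupted,
                    disrupted_center, barrier, smoothing=SOFTMIN_SMOOTHING,
                    inner_slope=PURE_QUADRATIC_SLOPE):
    return np.array([KIND_DOUBLE_WELL, eps_native, k_native, eps_disrupted,
                     k_disrupted, disrupted_center, barrier, smoothing,
                     inner_slope])
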