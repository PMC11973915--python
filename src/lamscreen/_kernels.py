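"""Numba kernels for the Langevin lambda-dynamics engine.

The default bias family implemented here must stay numerically identical
to :mod:`lamscreen.biasing`'s reference implementation (asserted by unit
tests); the duplication exists only because the integrator inner loop
cannot call back into Python.
"""

import math

import numpy as np
from numba import njit

from ._potentials import all_energies_grads, pot_energy_grad  # noqa: F401

STATUS_OK = 0
STATUS_NONFINITE = 1


@njit
def lam_from_theta_kernel(theta, c_steep, lam):
    n = theta.shape[0]
    m = -1.0e300
    for i in range(n):
        f = c_steep * math.sin(theta[i])
        lam[i] = f
        if f > m:
            m = f
    z = 0.0
    for i in range(n):
        lam[i] = math.exp(lam[i] - m)
        z += lam[i]
    for i in range(n):
        lam[i] /= z


@njit
def bias_energy_grad_kernel(lam, b, c_mat, s_mat, x_mat, alpha, askew, grad):
    """Default-family bias energy; fills grad with dU_bias/dlambda."""
    n = lam.shape[0]
    e = 0.0
    for i in range(n):
        grad[i] = -b[i]
        e -= b[i] * lam[i]
    for i in range(n):
        acc = 0.0
        for j in range(n):
            acc += c_mat[i, j] * lam[j]
        e += 0.5 * lam[i] * acc
        grad[i] += acc
    for i in range(n):
        li = lam[i]
        fi = li / (li + alpha)
        dfi = alpha / ((li + alpha) * (li + alpha))
        exi = math.exp(-li / askew)
        ski = li * exi
        dski = exi * (1.0 - li / askew)
        for j in range(n):
            if i == j:
                continue
            lj = lam[j]
            e += s_mat[i, j] * lj * fi + x_mat[i, j] * ski * lj
            grad[i] += s_mat[i, j] * lj * dfi + x_mat[i, j] * lj * dski
            grad[j] += s_mat[i, j] * fi + x_mat[i, j] * ski
    return e


@njit
def hybrid_force_kernel(theta, x, params, b, c_mat, s_mat, x_mat, alpha,
                        askew, c_steep, ic_height, ic_alpha, lam, u_buf,
                        du_buf, glam, gtheta):
    """Energy, dU/dx and dU/dtheta of the hybrid alchemical potential.

    U(theta, x) = sum_i lam_i(theta) U_i(x) + U_bias(lam) + U_ic(lam),
    with the implicit-constraint restraint
    U_ic = ic_height * sum_i (1 - exp(-lam_i / ic_alpha)),
    a saturating count of alchemically active substituents: it holds
    spectator lambdas near zero and penalizes mixed intermediates while
    adding only a fixed offset at pure end states.  Returns
    (energy, dU/dx); gtheta is filled in place.
    """
    n = theta.shape[0]
    lam_from_theta_kernel(theta, c_steep, lam)
    all_energies_grads(params, x, u_buf, du_buf)
    e = bias_energy_grad_kernel(lam, b, c_mat, s_mat, x_mat, alpha, askew, glam)
    if ic_height > 0.0:
        e -= ic_height * (1.0 - math.exp(-1.0 / ic_alpha))  # vertex offset
        for i in range(n):
            ex = math.exp(-lam[i] / ic_alpha)
            e += ic_height * (1.0 - ex)
            glam[i] += ic_height * ex / ic_alpha
    dux = 0.0
    avg = 0.0
    for i in range(n):
        g = u_buf[i] + glam[i]
        glam[i] = g
        e += lam[i] * u_buf[i]
        dux += lam[i] * du_buf[i]
        avg += lam[i] * g
    for k in range(n):
        gtheta[k] = c_steep * math.cos(theta[k]) * lam[k] * (glam[k] - avg)
    return e, dux


@njit
def baoab_run_kernel(theta, x0, v_theta, v_x0, params, b, c_mat, s_mat,
                     x_mat, alpha, askew, c_steep, ic_height, ic_alpha, dt,
                     gamma, kT, m_theta, m_x, n_steps, stride, seed,
                     lam_frames, x_frames):
    """BAOAB Langevin integration of (theta, x); frames stored every stride.

    Returns (status, failing_step, x, v_x); theta/v_theta updated in place.
    """
    np.random.seed(seed)
    n = theta.shape[0]
    x = x0
    v_x = v_x0
    lam = np.empty(n)
    u_buf = np.empty(n)
    du_buf = np.empty(n)
    glam = np.empty(n)
    gtheta = np.empty(n)
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt(max(0.0, 1.0 - c1 * c1))
    sd_t = math.sqrt(kT / m_theta)
    sd_x = math.sqrt(kT / m_x)
    e, dux = hybrid_force_kernel(theta, x, params, b, c_mat, s_mat, x_mat,
                                 alpha, askew, c_steep, ic_height, ic_alpha,
                                 lam, u_buf, du_buf, glam, gtheta)
    frame = 0
    for step in range(n_steps):
        for i in range(n):
            v_theta[i] -= 0.5 * dt * gtheta[i] / m_theta
        v_x -= 0.5 * dt * dux / m_x
        for i in range(n):
            theta[i] += 0.5 * dt * v_theta[i]
        x += 0.5 * dt * v_x
        if gamma > 0.0:
            for i in range(n):
                v_theta[i] = c1 * v_theta[i] + c2 * sd_t * np.random.normal()
            v_x = c1 * v_x + c2 * sd_x * np.random.normal()
        for i in range(n):
            theta[i] += 0.5 * dt * v_theta[i]
        x += 0.5 * dt * v_x
        e, dux = hybrid_force_kernel(theta, x, params, b, c_mat, s_mat,
                                     x_mat, alpha, askew, c_steep, ic_height,
                                     ic_alpha, lam, u_buf, du_buf, glam,
                                     gtheta)
        if not math.isfinite(e):
            return STATUS_NONFINITE, step, x, v_x
        for i in range(n):
            v_theta[i] -= 0.5 * dt * gtheta[i] / m_theta
        v_x -= 0.5 * dt * dux / m_x
        if (step + 1) % stride == 0:
            for i in range(n):
                lam_frames[frame, i] = lam[i]
            x_frames[frame] = x
            frame += 1
    return STATUS_OK, n_steps, x, v_x
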