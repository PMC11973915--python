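# Methods

`lamscreen` simulates single-site saturation mutagenesis with multisite
λ-dynamics on analytically tractable toy systems, so that the two
bias-training protocols it implements — traditional landscape flattening
(TLF) and competitive screening (CS) — can be compared against exact
ground truth rather than against experiment.

## The model

### Toy alchemical systems

A system is one mutation site carrying N candidate substituents
(N = 22 in the presets: 19 amino acids plus the three protonation
sub-states of histidine).  Each substituent *i* has a one-dimensional
conformational potential per thermodynamic ensemble:

* **unfolded** — a single harmonic well,
  `U_i^u(x) = ε_u + k_u/2 (x − c_u)²`, representing the unfolded peptide
  where every chemistry is conformationally unstrained;
* **folded** — a double well: a native basin at x = 0 and a *disrupted*
  basin at x = d, joined by a smooth minimum (softmin, scale
  0.25 kcal/mol) plus a compactly supported C¹ cos² ridge.  The
  disrupted basin models the partially unfolded conformation a
  destabilising chemistry relaxes into.

Because x is one-dimensional, every ensemble free energy
`G = −kT ln ∫ exp(−U/kT) dx` is available by adaptive quadrature
(absolute tolerance ≤ 1e−8 over `[min center − 8σ, max center + 8σ]`,
σ from the smallest force constant).  Relative unfolding free energies
close the thermodynamic cycle,

    ΔΔG_i = −[(G_f,i − G_f,nat) − (G_u,i − G_u,nat)],

with the convention that **negative ΔΔG destabilises folding**, so
"deleterious beyond −4 kcal/mol" reads ΔΔG ≤ −4.

### The synthetic-data generator

`generate_system` draws shape parameters from a seed and then solves the
folded well offsets so the exact ΔΔG matches a requested target vector
to 1e−6 (free energies shift additively with offsets, so the solve is a
single quadrature pass).  Two preset site classes emulate the behaviour
of surface and buried protein sites:

* **surface-like** — all 21 mutations mild, ΔΔG ~ U[−2, +1] kcal/mol;
* **core-like** — 13 of 21 mutations deleterious with
  ΔΔG ~ U[−9, −5] kcal/mol (beyond the −4 unfolding threshold), the
  rest in [−1, +1].

Deleterious substituents get a deliberately pathological folded
landscape: the disrupted arm is an asymmetric Huber shape whose
native-facing side is a long gentle grade (slope ≈ 2 kcal/mol per x
unit) with a small solved entry barrier (0.4–0.9 kcal/mol above the
native minimum), while the outer side is a stiff parabola
(k ≈ 20–30).  Consequences, by construction:

1. whenever a deleterious chemistry is sampled in the folded ensemble,
   the conformation readily slides into its disrupted basin;
2. the return climb is the full depth of the grade (≥ 5.5 kcal/mol,
   growing with the basin distance), so recovery essentially never
   happens at production length — partial unfolding is irreversible on
   the simulated timescale;
3. disrupted basins of different chemistries are staggered in x
   (0.8 apart) with stiff outer walls, so a disrupted walker cannot hop
   freely between deleterious end states — λ-space biases cannot cancel
   a conformational gap.

More than 90 % of a deleterious substituent's folded Boltzmann weight
sits in the disrupted basin.  The strength of the resulting TLF sampling
pathology varies from one generated core site to another, just as it
varies between real buried sites; the packaged fixtures
(`presets/*.json`) are the canonical seed-1 sites used by the demo and
the acceptance script.

What the generator does *not* emulate: real rotameric multiplicity,
explicit solvent, many-dimensional unfolding pathways, pH-dependent
histidine weighting (sub-state weights are user-supplied probabilities),
and replica exchange.  Passing tests therefore demonstrate correctness
of the estimators and the protocol-level phenomenology (filtering,
trapping, transition enrichment), not force-field-level realism.

## Sampling

λ lives on the probability simplex through implicit constraints,

    λ_i = exp(c sin θ_i) / Σ_j exp(c sin θ_j),     c = 8,

over unbounded θ sampled jointly with x by BAOAB Langevin dynamics
(dt = 0.01, γ = 1, m_θ = 0.1, m_x = 1, kT = 0.593 kcal/mol at
298.15 K).  The hybrid potential is

    U(θ, x) = Σ_i λ_i U_i(x) + U_bias(λ) + U_ic(λ).

`U_ic = h Σ_i (1 − e^{−λ_i/α})` (offset to vanish at pure end states;
h = 1.5 kcal/mol, α = 0.007) is a fixed *activity restraint*: a
saturating count of alchemically active substituents that presses
spectator λ's to zero and penalises mixed intermediates by one `h` per
extra active chemistry.  It plays the role that intrinsically
high-energy partially-coupled chemistries play in all-atom multisite
λ-dynamics; without it, a softmax over 22 θ variables is entropically
dominated by mixed states and pure end states are never reached.  All
engine constants were validated against an exact oracle: for N = 2 the
stationary end-state population ratio from dense θ-space quadrature of
the same hybrid potential, which the sampler reproduces within
statistical error (this is also an acceptance test).

With these defaults a flat 22-substituent landscape yields ≈ 20–25 % of
frames at end states (λ > 0.99) and an alchemical transition every
~650 steps.

## Bias potential

Four coefficient families act on λ (larger linear `b_i` ⇒ substituent
*i* sampled more):

    U_bias = −Σ b_i λ_i + Σ_{i<j} c_ij λ_i λ_j
             + Σ_{i≠j} s_ij λ_j λ_i/(λ_i + α)            (α = 0.017)
             + Σ_{i≠j} x_ij λ_i λ_j e^{−λ_i/α_skew}      (α_skew = 0.18)

The quadratic, endpoint and skew families shape barriers and the
near-end-state region but all vanish at every pure end state, so
end-state free energies are corrected by linear terms alone.  The
estimator nevertheless subtracts the *full* bias evaluated at pure end
states, so it remains exact for any family registered in the pluggable
registry (`lamscreen.biasing.register_family`).

## Adaptive landscape flattening (ALF)

Each iteration runs a trajectory under the current biases and updates:

* **linear terms** by `Δb_i = −kT ln(p_i / (1/N))` with additive
  smoothing 0.5 on end-state counts, capped at ±2 kcal/mol per
  iteration; never-visited substituents get the largest visited
  increment plus `kT ln 2` (same cap) so they are steadily promoted
  until sampled;
* **pairwise terms** by a per-pair least-squares fit of the bias-family
  shapes to the residual profile free energy `−kT ln h(λ_i)` on occupied
  interior bins of pair-dominant frames (λ_i + λ_j ≥ 0.8), under a Huber
  loss with scale 2 kT so sparsely sampled bins cannot dominate;
  increments bounded at ±2 kcal/mol.

The schedule grows geometrically (default 14 iterations, 10 000 →
600 000 steps, ×1.5); convergence is two consecutive iterations with
end-state population max/min ratio ≤ 5.  Because per-iteration count
noise makes the flatness metric bounce, the result carries both the
*final* coefficient set (the controller's latest state — used for
production, since it tracks the visit boundary even for pathological
substituents) and the *best-iteration* set (most substituents visited,
then flattest).  Non-convergence never raises; it is reported through
the `converged` flag, since a folded-ensemble flattening that cannot
converge is precisely the pathology the protocol comparison must
surface rather than hide.

## Protocols and estimation

* **TLF** flattens folded and unfolded independently, then runs 5
  production trials per ensemble (400 000 steps, stride 10, 10 % burn-in
  discarded).
* **CS** flattens the unfolded ensemble only — half the flattening
  budget — transfers the biases bit-identically to the folded ensemble,
  and produces in both.  Transferred biases make folded end-state
  populations ∝ exp(ΔΔG_i/kT): chemistries destabilising beyond a few
  kT are simply never visited.
* **LEGACY** uses supplied reference energies as a primitive linear bias
  with no flattening.

Per trial, `ΔG_i = −kT ln(N_i/N_nat) − [U_bias(e_i) − U_bias(e_nat)]`
over end-state counts (threshold 0.99, minimum 10 frames; both
configurable), the cycle gives ΔΔG, and uncertainties come from
bootstrapping over trials (1000 resamples).  Because five trials is a
very small sample, the reported bootstrap sd is the *expanded*
standard error — raw resample sd times `sqrt(n/(n−1)) ·
t_{0.975,n−1}/z_{0.975}` — so that ±2 sd intervals cover at roughly the
nominal 95 % rate instead of the ~85 % a plain bootstrap achieves at
n = 5.  Substituents with fewer than two finite trials are flagged and
excluded from shared-subset accuracy comparisons.  Histidine sub-states combine by the Boltzmann average
`ΔΔG = +kT ln Σ_s w_s e^{ΔΔG_s/kT}` (most favorable state dominates);
unsampled states are dropped with weight renormalisation.

## Diagnostics

Alchemical transitions reduce a trajectory to its end-state visit
sequence (frames below threshold are ignored, not treated as a state),
collapse repeats, and count identity changes, attributed to the arriving
substituent; both per-trial and pooled counts are reported.
Conformational disruption is tracked as |x − x_native| per frame, with
mean ± SEM across trials.  Accuracy is RMSE and Pearson R over a
declared substituent subset (R only for n ≥ 3), with the shared subset
of two estimates defined as sampled-in-both with bootstrap uncertainties
in both.

## Numerical choices and problem sizes

Default study conditions are desk-scale: 22 substituents, 14 flattening
iterations (~3.3 M steps), 5 × 400 000-step productions per ensemble,
chosen so a full two-protocol comparison on one site completes in a few
minutes on one CPU while leaving estimator noise well below the
interesting effect sizes (surface-site pipeline ΔΔG errors are
~0.05–0.15 kcal/mol in the median against quadrature truth).
Tie-breaks and degenerate inputs: empty trajectories and invalid
thresholds raise; an unsampled native substituent raises (no reference);
flattening with all-zero counts leaves linear terms unchanged; bias
matrices have their diagonals zeroed on construction.

## Known limitations

* The TLF core-site pathology (trapping, transition suppression) is
  site- and run-dependent: because a deleterious substituent's folded
  free energy is dominated by its disrupted basin, there is a dead band
  of linear-bias values in which the chemistry is thermodynamically
  over-favored yet its native basin is never visited at production
  length.  Depending on where the oscillating folded-ensemble flattening
  leaves the biases, TLF either samples the deleterious chemistries and
  disrupts (trapped trajectories, suppressed transitions, large
  deviation) or never reaches them at all (CS-like transition counts
  with poor deleterious accuracy).  Both outcomes are failure modes of
  equal-sampling at pathological sites; which one occurs varies with
  the site and the run seed.
* End-state-population estimation ignores information in intermediate
  frames (no multistate reweighting, by design).
* Protonation sub-state weights are inputs; the package does not derive
  them from pH.
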