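# Methods

This note documents the models, parameter choices, numerical decisions and
limitations behind `saxsbme`. Nothing here reports an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Ensemble model and units

An ensemble is n frames of one bead per residue (Cα by default, residue
centroid optionally), coordinates in Å, with per-frame prior probabilities
w⁰ (uniform 1/n unless a weights file is supplied; always renormalized on
load) and per-bead scattering weights f₀. Residues are numbered from 1 in
all files, matching spin-label site conventions; frames are 0-indexed
internally.

## Forward models

**SAXS (Debye equation).** For one frame,
I(q) = Σ_a Σ_b f_a(q) f_b(q) sin(q r_ab)/(q r_ab), with the a=b limit
f_a(q)². The ensemble curve is the weight-averaged frame curve — exactly
linear in the weights, which BME relies on. No hydration-shell term is
included: the coarse-grained model cannot resolve it, and the global
scale/offset nuisance absorbs most of its low-q effect. Per-bead form
factors default to constant residue electron counts (glycine-normalized
table; unit weights for generic beads); an optional Gaussian bead smearing
f(q) = f₀·exp(−q²R²/2) with R = 3.0 Å mimics finite bead size. Since a
global scale is refitted downstream, only the q-dependence shape matters.

**R_g** is the f₀-weighted RMS distance from the weighted centroid.

**R_h** uses the empirical disordered-chain relation of Nygaard et al.
(2017): R_g/R_h = α₁(R_g − α₂N^0.33)/(N^0.60 − N^0.33) + α₃ with
α₁ = 0.216 Å⁻¹, α₂ = 4.06 Å, α₃ = 0.821, applied per frame and then
weight-averaged (the relation is nonlinear in R_g, so the order matters).

**Guinier fit.** ln I is regressed on q² over the largest low-q window
satisfying q·R_g ≤ 1.1 (iterative shrinking from the full profile;
R_g = √(−3·slope)). 1.1 is a deliberately conservative bound for expanded
chains; the window actually used is reported. A flat profile yields R_g = 0
with a warning; a rising low-q profile is an error (no Guinier regime).

**PRE.** The spin label is a pseudo-atom displaced 6 Å from the labelled
residue's Cα along the local chain normal (the cross product of the two
bond vectors at that residue; an arbitrary perpendicular for collinear or
terminal geometry). Rotamer-library label placement is out of scope at Cα
resolution. Per residue, ⟨r⁻⁶⟩ is the weight-averaged inverse sixth power
of the label–Cα distance (amide proxy), converted via the
Solomon–Bloembergen transverse term
Γ₂ = K·⟨r⁻⁶⟩·(4τ_c + 3τ_c/(1+ω_H²τ_c²)) and
I_para/I_dia = R₂·exp(−Γ₂t)/(R₂+Γ₂). Defaults (all overridable):
τ_c = 1 ns, ω_H/2π = 700 MHz, R₂ = 10 s⁻¹, t = 10 ms,
K = 1.23·10¹⁶ Å⁶s⁻² (the standard nitroxide electron–proton dipolar
constant). These are declared, not fitted; PRE is used for validation, not
as a restraint.

## BME reweighting

Primal: minimize L(w) = ½χ²(w) − θS_rel(w) on the simplex, with
χ² computed after an exact weighted-least-squares fit of a scale a and
optionally an offset b (modes: `none`, `scale`, `scale+offset`).
χ²_red divides by the number of data points m, not m minus fitted
parameters; the convention is recorded in every result.

Dual: with y = (I_exp − b)/a, s = σ/a fixed,
Γ(λ) = θ·log Z(λ) + λ·y + ½Σλ_i²s_i², Z(λ) = Σ_j w⁰_j e^{−(λ·F_j)/θ},
is smooth and convex in the m multipliers. We solve it by damped Newton
(Hessian (1/θ)Cov_w(F) + diag(s²), SPD, m×m) with backtracking line
search, log-sum-exp stabilized weights, λ warm-started at 0 (w = w⁰) and a
gradient max-norm tolerance of 1e-8 relative to the data scale; if the line
search reaches the floating-point noise floor first, gradients within 1e-7
of the data scale still count as converged. Nuisance parameters are
profiled by coordinate descent — exact (a, b) fit, exact dual solve,
repeat until (a, b) are stationary to 1e-7 — each step decreasing the
primal objective. Non-convergence is flagged on the result, never silent.
Reported multipliers are λ/θ, so w_j ∝ w⁰_j·exp(−Σ_i λ̃_i F_ij) holds with
the reported λ̃ directly.

Solving in the dual was chosen because m (≈19 SAXS points) ≪ n (thousands
of frames) and convexity guarantees the unique optimum; the test suite
verifies dual solutions against exhaustive primal grid searches on small
simplices.

## θ selection (L-curve)

A θ ladder (default 20 log-spaced values on [1, 10⁶], bracketing typical
published choices with margin) is scanned from large θ downward,
warm-starting λ/θ along the way; every point is retained with a
convergence flag. χ²_red and φ_eff are non-increasing along decreasing θ
(verified as an invariant). The elbow is operationalized as the maximum
discrete curvature of (log φ_eff, log χ²_red) parametrized by log θ —
visual selection in the literature is a band, not a point, so the selection
method tag is always emitted. Collinear curves fall back to the
χ²-threshold rule (largest θ with χ²_red below a bound) with a warning; a
manual override simply echoes and records the user's value.

## Uncertainties

Frames from trajectories are time-correlated. `block_error` splits the
series into contiguous blocks, computes weighted block means and the
standard error of the weighted mean across blocks
(SE² = K/(K−1)·Σp_k²(m_k−μ)², reducing to std/√K for uniform weights), for
block sizes 16, 32, … up to n/4; the reported estimate is the plateau,
taken as the maximum over the three largest usable sizes. Because the
largest sizes contain few blocks, a single plateau estimate is noisy and
biased upward by roughly a quarter on uncorrelated data; calibration checks
therefore average the plateau over independent replicate series. For
ensembles without time ordering a seeded weighted bootstrap (1000
resamples) replaces blocking. Weighted histogram densities integrate to 1
exactly and carry per-bin block errors computed on bin-indicator series.

## Synthetic ground truth

Chains are self-avoiding walks at Cα resolution: bond length 3.8 Å
(virtual Cα–Cα), hard-sphere diameter 4.0 Å for non-bonded pairs, sampled
with seeded Metropolis pivot and crankshaft moves from a straight initial
chain (30 equilibration sweeps, one sweep = N move attempts, default
stride 1 sweep between recorded frames). A harmonic R_g bias
½k(R_g − target)² (default k = 0.1 kT/Ų) emulates force fields of
different compaction; targets below the globule limit 2.2·N^⅓ Å are
rejected before sampling. Unbiased 50-residue chains average ⟨R_g⟩ ≈ 19 Å
with frames spanning ≈ 12–32 Å — a realistic IDP-like spread.

The "truth" is an exponential tilt w ∝ w⁰·exp(κ·R_g) — exactly the
functional form BME can represent, making recovery a sharp test rather
than an approximation exercise. Default κ = 0.2 shifts ⟨R_g⟩ by ≈ 14% and
retains φ_eff ≈ 0.76 vs uniform, mirroring a realistic good-prior
refinement; tilts collapsing φ_eff below 0.01 are rejected. Synthetic SAXS
data: truth-weighted Debye curve on 19 points, q = 0.01–0.20 Å⁻¹, Gaussian
noise σ(q) = 2%·I(q) + 0.1%·I(q₀) (typical SEC-SAXS quality; both
configurable). Synthetic PRE: truth-weighted forward ratios at five label
sites (24/42/62/87/103 for chains long enough, else evenly spaced) with
Gaussian noise (σ = 0.05) clipped to (0, 1].

Because synthetic data share the forward model's absolute intensity scale
by construction, truth-recovery analyses run with `scale_mode: none`;
floating a scale there is nearly degenerate with compaction over this
narrow q window and only dilutes the information. Real experimental data
are on an arbitrary scale — use `scale+offset` (the default) for them.

What the generator does *not* emulate: residue-specific energetics,
secondary structure, hydration effects, and experimental artifacts
(aggregation, inter-particle interference, buffer mismatch). Passing tests
demonstrate the statistical machinery is correct under the stated noise
model, not that any particular force field or real dataset will behave as
well.

## Toy metainference

Replica-averaged restrained sampling at desk scale: R replicas (default 8)
of the same chain prior evolve by Metropolis pivot/crankshaft moves under
E = Σ_r U_chain(X_r) + Σ_i [(scale·Ī_i − I_i^exp)²/(2σ_tot,i²) + log σ_tot,i],
σ_tot,i² = σ_SEM,i² + σ_b,i², with Ī the replica-mean Debye curve. Moves
always see the current restraint (the moved replica's curve is updated on
acceptance, so the Metropolis criterion is exact for the current nuisance
values). Every 10 sweeps, σ_SEM is re-estimated from the replica spread,
σ_b receives a per-point Metropolis update on log σ_b (the restraint is
separable per point; log-scale proposals correspond to a log-uniform
prior), and the scale takes a random-walk step confined to its flat prior
[0.5, 2.0]. Reported curves (and the final χ²_red, computed with a fitted
scale) use a 200-sweep rolling average of Ī, damping instantaneous
replica-mean fluctuations. An acceptance rate below 1% over the first
tenth of a run aborts with a move-size diagnostic.

This replaces the original multi-replica Langevin-dynamics protocol
(64 replicas, enhanced sampling, implicit solvent) with Monte Carlo on toy
chains; the balance property is checked against direct Boltzmann sampling
of bond angles, and the restraint's effect is assessed by paired
restrained/control runs sharing a seed.

## Problem sizes

Default analysis scales, chosen to make the full pipeline run in minutes
on one CPU while keeping estimates statistically meaningful: 50-residue
chains, 1500–2000 prior frames, 19 SAXS points, 10 paired metainference
repeats of 6 replicas × 150 sweeps on 30-residue chains, 20 replicate
series of 10⁴ samples for block-error calibration. All sizes are function
arguments and scale up trivially.

## Known limitations

- Constant (or Gaussian-smeared) bead form factors: adequate for global
  shape refinement below q ≈ 0.2 Å⁻¹, not for wide-angle features.
- R_h comes from an empirical R_g regression, not hydrodynamic theory
  (no Kirkwood–Riseman double sum); treat small R_h differences with care.
- PRE constants are nominal defaults; absolute ratios depend on them, so
  cross-ensemble comparisons are more meaningful than absolute values.
- The elbow of a discrete L-curve is grid-resolution-dependent; the scan
  grid should bracket the elbow generously.
- χ²_red uses the m convention; comparisons with values normalized by
  m − (fitted parameters) shift by m/(m−k).
- Hard-sphere chains have no attractive interactions: truth tilts emulate
  compaction statistically, not mechanistically.
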