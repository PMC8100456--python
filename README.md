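# saxsbme

Bayesian/Maximum-Entropy (BME) refinement of disordered-protein
conformational ensembles against small-angle X-ray scattering (SAXS) data —
with coarse-grained forward models (Debye-equation SAXS, radius of gyration
R_g, empirical hydrodynamic radius R_h, paramagnetic relaxation enhancement
intensity ratios), L-curve hyperparameter selection, block-averaged
uncertainties, a synthetic ground-truth ensemble generator, and a toy
multi-replica metainference sampler.

## Who this is for

Intrinsically disordered proteins (IDPs) have no single structure; they are
described by conformational ensembles. Molecular simulations provide such
ensembles, but force-field bias often makes them too compact or too
expanded. SAXS measures the ensemble-averaged scattering intensity I(q) and
is highly sensitive to overall compaction, so it is a natural restraint for
*refining* a simulated ensemble. This package is for structural biologists
and simulators who want to (a) reweight an existing ensemble against a SAXS
profile, (b) diagnose whether their prior ensemble is good enough to be
reweighted at all, and (c) validate the result against independent
observables (R_h, PRE).

## The method

Given per-frame observables F_ij (observable i back-calculated for frame j)
and experimental values F_i^exp ± σ_i, BME updates the prior frame weights
w⁰ (usually uniform 1/n) by minimizing

    L(w) = ½ χ²(w) − θ S_rel(w)

over the probability simplex, where

    χ²(w)   = Σ_i ( (a·⟨F_i⟩_w + b − F_i^exp) / σ_i )²,   ⟨F_i⟩_w = Σ_j w_j F_ij
    S_rel(w) = −Σ_j w_j log(w_j / w⁰_j)  ≤ 0.

a and b are optional nuisance scale/offset parameters (profiled by exact
weighted least squares). The hyperparameter θ balances data fit against
prior fidelity; the effective fraction of retained frames is
φ_eff = exp(S_rel) ∈ (0, 1]. A φ_eff collapse toward 0 at acceptable χ²
diagnoses a poor prior: the data-compatible ensemble is not a sub-ensemble
of the prior.

The optimum is computed in the convex dual. With y, s the scale-corrected
data and errors, the dual objective over m Lagrange multipliers λ is

    Γ(λ) = θ·log Σ_j w⁰_j exp(−(1/θ) Σ_i λ_i F_ij) + Σ_i λ_i y_i + ½ Σ_i λ_i² s_i²

minimized by damped Newton iterations (the Hessian (1/θ)Cov_w(F) + diag(s²)
is m×m and SPD), giving weights of exponential-family form
w_j ∝ w⁰_j exp(−Σ_i (λ_i/θ) F_ij). θ is chosen by an L-curve scan: χ²_red
vs φ_eff over a θ ladder, elbow = maximum discrete curvature on log-log
axes (a χ²-threshold rule and manual choice are also provided).

Forward models: Debye-equation SAXS on one bead per residue (no
hydration-shell term), mass-weighted R_g, per-frame R_h from the Nygaard
et al. (2017) empirical R_g→R_h relation, Guinier fits with an iterative
q·R_g-bounded window, and PRE intensity ratios from ensemble-averaged r⁻⁶
label–amide distances through the Solomon–Bloembergen transverse term.
Statistical errors on weighted averages and distributions come from block
averaging. A toy multi-replica Metropolis sampler applies the same SAXS
restraint *during* sampling (metainference), with per-data-point noise
parameters σ_b and a global scale sampled under a flat prior on [0.5, 2.0].

## Worked example

Generate a synthetic ensemble with a known "true" sub-ensemble, refine
against the synthetic SAXS data, and inspect the result:

```bash
saxsbme report --config demo.yaml
```

with `demo.yaml`:

```yaml
seed: 17
output_dir: demo_out
ensemble:
  synthetic: {n_frames: 150, n_residues: 30}
truth: {kappa: 0.2, noise_level: 0.02}
theta_scan: {n: 10, lo: 1.0, hi: 1.0e5}
scale_mode: none
```

This samples 150 self-avoiding Cα chains of 30 residues, tilts them by
exp(κ·R_g) to define a more expanded truth ensemble, synthesizes a 19-point
SAXS curve (q = 0.01–0.20 Å⁻¹, 2% noise) and PRE data from the truth, then
scans θ, picks the elbow and reweights. `demo_out/summary.json` from this
exact run:

```json
{
  "theta": 12.91549665014884,
  "chi2_red_prior": 6.2933821506145335,
  "chi2_red": 0.9359730300236627,
  "phi_eff": 0.943276467456944,
  "rg_prior": 13.194532055075936,
  "rg_reweighted": 13.93375929084052,
  "rg_truth": 14.303616867989028
}
```

Reading it: the uniform prior misfits the data (χ²_red ≈ 6.3); after
reweighting χ²_red ≈ 0.94 (the noise level) while 94% of the prior frames
still contribute (φ_eff = 0.94), and the reweighted average R_g (13.93 Å)
moves most of the way from the prior average (13.19 Å) to the truth
(14.30 Å).
The output directory also contains the L-curve table, posterior weights,
R_g/R_h densities with block-averaged error bands, and a PRE RMSD table
before/after refinement.

The other subcommands (`simulate`, `forward`, `reweight`, `scan-theta`,
`guinier`, `pre`, `metainference`) expose the individual stages; real data
enter as a 3-column SAXS text file (q, I, σ), multi-model PDB or
trajectory+topology ensembles, and PRE CSV tables.

### Metainference estimator

The toy metainference energy per SAXS point i is
(scale·Ī_i − I_i^exp)²/(2(σ_SEM,i² + σ_b,i²)) + log√(σ_SEM,i² + σ_b,i²),
where Ī is the replica-averaged Debye intensity, σ_SEM its standard error
estimated from the replica spread, σ_b a sampled per-point uncertainty
(log-uniform prior), and the scale has a flat prior on [0.5, 2.0].
Coordinate moves always see the current restraint; σ_b, scale and σ_SEM are
refreshed every 10 sweeps, and reported curves are averaged over a rolling
200-sweep window.

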