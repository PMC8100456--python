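"""Synthetic chain ensembles and ground-truth test cases.

Chains are Cα-resolution self-avoiding walks: fixed virtual bond length
3.8 Å, hard-sphere excluded volume 4.0 Å between beads more than one bond
apart, sampled by seeded Metropolis pivot and crankshaft moves. An optional
harmonic bias on R_g steers the ensemble toward a target compaction,
emulating force fields of differing expansion. A "truth" sub-ensemble is an
exponential-family tilt on per-frame R_g, so the target of reweighting lies
exactly in BME's function class and parameter recovery is a sharp test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .ensemble_io import (
    ConformationalEnsemble,
    PREDataset,
    ScatteringProfile,
    save_ensemble,
    save_pre_table,
    save_saxs_profile,
    save_weights,
)
from .forward_models import (
    PREParameters,
    compute_rg,
    ensemble_saxs,
    frame_rg_series,
    pre_ratio_profile,
)

__all__ = [
    "TruthCase",
    "ChainSampler",
    "bond_angles",
    "harmonic_angle_bias",
    "generate_chain_ensemble",
    "make_truth_case",
    "save_truth_case",
    "default_q_grid",
    "BOND_LENGTH",
    "HARD_SPHERE",
]

BOND_LENGTH = 3.8  # Å, Cα–Cα virtual bond
HARD_SPHERE = 4.0  # Å, excluded-volume diameter (non-bonded pairs)
DEFAULT_PRE_SITES = (24, 42, 62, 87, 103)


def default_q_grid(n: int = 19, q_min: float = 0.01, q_max: float = 0.20) -> np.ndarray:
    """The working SAXS grid: 19 points on [0.01, 0.20] Å⁻¹."""
    return np.linspace(q_min, q_max, n)


def _rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _segment_clash(coords: np.ndarray, moved_idx: np.ndarray, fixed_idx: np.ndarray) -> bool:
    """True if any non-bonded moved/fixed pair comes closer than HARD_SPHERE."""
    d = cdist(coords[moved_idx], coords[fixed_idx])
    sep = np.abs(moved_idx[:, None] - fixed_idx[None, :])
    return bool(np.any(d[sep >= 2] < HARD_SPHERE))


class ChainSampler:
    """Metropolis sampler over fixed-bond self-avoiding Cα chains.

    ``bias`` is an optional callable coords→energy (kT units) added to the
    hard-sphere prior; used for the R_g compaction bias and for toy
    potentials in the metainference sampler.
    """

    def __init__(
        self,
        n_residues: int,
        rng: np.random.Generator,
        bias=None,
        max_crank_span: int = 10,
        excluded_volume: bool = True,
    ) -> None:
        if n_residues < 5:
            raise ValueError("n_residues must be ≥ 5")
        self.n = n_residues
        self.rng = rng
        self.bias = bias
        self.max_crank_span = max_crank_span
        self.excluded_volume = excluded_volume
        self.coords = self.straight_chain(n_residues)
        self._bias_energy = self.bias(self.coords) if self.bias else 0.0
        self.n_attempted = 0
        self.n_accepted = 0

    @staticmethod
    def straight_chain(n: int) -> np.ndarray:
        coords = np.zeros((n, 3))
        coords[:, 0] = np.arange(n) * BOND_LENGTH
        return coords

    def _propose(self) -> tuple[np.ndarray, np.ndarray] | None:
        """Return (new_coords, moved_idx) or None for an immediate clash reject."""
        x = self.coords
        n = self.n
        if self.rng.random() < 0.5 and n >= 4:  # crankshaft
            i = int(self.rng.integers(0, n - 2))
            j = int(self.rng.integers(i + 2, min(i + 2 + self.max_crank_span, n)))
            axis = x[j] - x[i]
            if np.linalg.norm(axis) < 1e-9:
                return None
            rot = _rotation_matrix(axis, self.rng.uniform(-np.pi, np.pi))
            moved = np.arange(i + 1, j)
            new = x.copy()
            new[moved] = (x[moved] - x[i]) @ rot.T + x[i]
        else:  # pivot: rotate one tail about a random bead
            p = int(self.rng.integers(1, n - 1))
            axis = self.rng.normal(size=3)
            rot = _rotation_matrix(axis, self.rng.uniform(-np.pi, np.pi))
            moved = np.arange(p + 1, n) if self.rng.random() < 0.5 else np.arange(0, p)
            if len(moved) == 0:
                return None
            new = x.copy()
            new[moved] = (x[moved] - x[p]) @ rot.T + x[p]
        if self.excluded_volume:
            fixed = np.setdiff1d(np.arange(n), moved, assume_unique=True)
            if _segment_clash(new, moved, fixed):
                return None
        return new, moved

    def step(self) -> bool:
        """One move attempt; returns True if accepted."""
        self.n_attempted += 1
        prop = self._propose()
        if prop is None:
            return False
        new, _ = prop
        if self.bias is not None:
            e_new = self.bias(new)
            if e_new - self._bias_energy > 0 and self.rng.random() >= np.exp(
                -(e_new - self._bias_energy)
            ):
                return False
            self._bias_energy = e_new
        self.coords = new
        self.n_accepted += 1
        return True

    def sweep(self, n_moves: int | None = None) -> None:
        for _ in range(n_moves or self.n):
            self.step()


def bond_angles(coords: np.ndarray) -> np.ndarray:
    """Internal bond angles θ_i ∈ (0, π) at each non-terminal bead."""
    v1 = coords[:-2] - coords[1:-1]
    v2 = coords[2:] - coords[1:-1]
    cosang = np.sum(v1 * v2, axis=1) / (
        np.linalg.norm(v1, axis=1) * np.linalg.norm(v2, axis=1)
    )
    return np.arccos(np.clip(cosang, -1.0, 1.0))


def harmonic_angle_bias(k: float, theta0: float):
    """U(x) = ½k Σ_i (θ_i − θ0)² in kT; a toy chain potential."""

    def bias(coords: np.ndarray) -> float:
        ang = bond_angles(coords)
        return float(0.5 * k * np.sum((ang - theta0) ** 2))

    return bias


def generate_chain_ensemble(
    n_frames: int,
    n_residues: int,
    compaction: float | str | None = None,
    seed: int = 0,
    rg_spring: float = 0.1,
    stride: int = 1,
    n_equilibration: int = 30,
) -> ConformationalEnsemble:
    """Sample a Cα chain ensemble by seeded Metropolis pivot/crankshaft moves.

    ``compaction`` is a target ⟨R_g⟩ in Å (or None/'none' for the unbiased
    athermal chain); the bias is ½·rg_spring·(R_g − target)² in kT, with
    rg_spring in kT/Ų. ``stride`` sweeps (one sweep = n_residues attempts)
    separate recorded frames. Bit-reproducible for a given config and seed.
    """
    if n_frames < 10:
        raise ValueError("n_frames must be ≥ 10")
    if n_residues < 5:
        raise ValueError("n_residues must be ≥ 5")
    target = None if compaction in (None, "none") else float(compaction)
    if target is not None:
        globule_limit = 2.2 * n_residues ** (1.0 / 3.0)
        if target < globule_limit:
            raise ValueError(
                f"target Rg {target:.3g} Å below the globule limit "
                f"{globule_limit:.3g} Å for N={n_residues}"
            )
    rng = np.random.default_rng(seed)
    bias = None
    if target is not None:
        bias = lambda x: 0.5 * rg_spring * (compute_rg(x) - target) ** 2  # noqa: E731
    sampler = ChainSampler(n_residues, rng, bias=bias)
    for _ in range(n_equilibration):
        sampler.sweep()
    frames = np.empty((n_frames, n_residues, 3))
    for j in range(n_frames):
        for _ in range(stride):
            sampler.sweep()
        frames[j] = sampler.coords
    return ConformationalEnsemble(coords=frames)


@dataclass
class TruthCase:
    """A prior ensemble plus a known truth tilt and the synthetic data it generates."""

    ensemble: ConformationalEnsemble
    truth_weights: np.ndarray
    synthetic_saxs: ScatteringProfile
    noiseless_saxs: ScatteringProfile
    synthetic_pre: PREDataset
    generator_config: dict = field(default_factory=dict)


def make_truth_case(
    prior: ConformationalEnsemble,
    kappa: float,
    q_grid: np.ndarray | None = None,
    noise_level: float = 0.02,
    noise_floor_frac: float = 1e-3,
    seed: int = 0,
    pre_sites: tuple[int, ...] | None = None,
    pre_error: float = 0.05,
    pre_params: PREParameters | None = None,
) -> TruthCase:
    """Tilt the prior by exp(κ·R_g), then synthesize noisy SAXS and PRE data.

    truth_weights ∝ w⁰·exp(κ·R_g,j); σ(q) = noise_level·I(q) +
    noise_floor_frac·I(q₀); the noisy intensities add N(0, σ) with the given
    seed. PRE ratios are truth-weighted forward values plus N(0, pre_error),
    clipped to (0, 1].
    """
    q = default_q_grid() if q_grid is None else np.asarray(q_grid, dtype=float)
    rng = np.random.default_rng(seed)
    rg = frame_rg_series(prior)
    logw = np.log(prior.prior_weights) + kappa * rg
    logw -= logw.max()
    w_truth = np.exp(logw)
    w_truth /= w_truth.sum()
    eff = float(np.exp(-np.sum(w_truth * np.log(w_truth * len(w_truth)))))
    if eff < 0.01:
        raise ValueError(f"degenerate tilt: phi_eff vs uniform = {eff:.3g} < 0.01")
    ideal = ensemble_saxs(prior, w_truth, q)
    sigma = noise_level * ideal + noise_floor_frac * ideal[0]
    noisy = ideal + rng.normal(size=len(q)) * sigma
    saxs = ScatteringProfile(q=q, intensity=noisy, sigma=sigma)
    noiseless = ScatteringProfile(q=q, intensity=ideal, sigma=sigma)

    if pre_sites is None:
        n = prior.n_residues
        if n >= max(DEFAULT_PRE_SITES):
            pre_sites = DEFAULT_PRE_SITES
        else:
            pre_sites = tuple(int(s) for s in np.linspace(2, n - 1, 5).round())
    params = pre_params or PREParameters()
    site_col, res_col, ratio_col, err_col = [], [], [], []
    for site in pre_sites:
        residues, ratios = pre_ratio_profile(prior, w_truth, int(site), params)
        noisy_ratios = np.clip(ratios + rng.normal(size=len(ratios)) * pre_error, 1e-3, 1.0)
        site_col.extend([int(site)] * len(residues))
        res_col.extend(residues.tolist())
        ratio_col.extend(noisy_ratios.tolist())
        err_col.extend([pre_error] * len(residues))
    pre = PREDataset(
        label_site=np.array(site_col),
        residue=np.array(res_col),
        ratio=np.array(ratio_col),
        error=np.array(err_col),
    )
    config = {
        "kappa": kappa,
        "noise_level": noise_level,
        "noise_floor_frac": noise_floor_frac,
        "seed": seed,
        "pre_sites": [int(s) for s in pre_sites],
        "pre_error": pre_error,
        "q_min": float(q[0]),
        "q_max": float(q[-1]),
        "n_q": int(len(q)),
        "n_frames": prior.n_frames,
        "n_residues": prior.n_residues,
    }
    return TruthCase(
        ensemble=prior,
        truth_weights=w_truth,
        synthetic_saxs=saxs,
        noiseless_saxs=noiseless,
        synthetic_pre=pre,
        generator_config=config,
    )


def save_truth_case(case: TruthCase, directory) -> None:
    """Persist a TruthCase as a directory of plain-text artifacts."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    save_ensemble(case.ensemble, d / "ensemble.dat")
    save_weights(case.truth_weights, d / "truth_weights.dat")
    save_saxs_profile(case.synthetic_saxs, d / "saxs.dat")
    save_saxs_profile(case.noiseless_saxs, d / "saxs_noiseless.dat")
    save_pre_table(case.synthetic_pre, d / "pre.csv")
    with open(d / "config.json", "w") as fh:
        json.dump(case.generator_config, fh, indent=2)
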