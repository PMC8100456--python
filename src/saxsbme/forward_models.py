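"""Forward models: Debye-equation SAXS, radius of gyration, hydrodynamic radius,
Guinier fits and PRE intensity ratios.

All models operate on one-bead-per-residue coordinates in Å. Ensemble
averages are linear in the frame weights throughout: the SAXS intensity and
the PRE ⟨r⁻⁶⟩ are population-weighted arithmetic means of per-frame values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import linregress

from .ensemble_io import ConformationalEnsemble, ScatteringProfile

logger = logging.getLogger(__name__)

__all__ = [
    "ObservableMatrix",
    "GuinierFit",
    "PREParameters",
    "compute_rg",
    "ensemble_rg",
    "compute_rh_from_rg",
    "ensemble_rh",
    "debye_saxs_frame",
    "ensemble_saxs",
    "saxs_observable_matrix",
    "guinier_fit",
    "pre_ratio_profile",
    "pre_distances",
    "mean_inverse_r6",
    "ratios_from_mean_r6",
    "gaussian_bead_form_factor",
    "RESIDUE_ELECTRONS",
]

# Electron counts of the 20 amino-acid residues (residue = amino acid minus
# water), divided by glycine's 30 electrons. Used as constant per-bead
# scattering weights; the global scale is refitted downstream so only
# relative values matter.
_ELECTRONS = {
    "ALA": 38, "ARG": 85, "ASN": 60, "ASP": 59, "CYS": 54, "GLN": 68,
    "GLU": 67, "GLY": 30, "HIS": 72, "ILE": 62, "LEU": 62, "LYS": 71,
    "MET": 70, "PHE": 78, "PRO": 52, "SER": 46, "THR": 54, "TRP": 98,
    "TYR": 86, "VAL": 54,
}
RESIDUE_ELECTRONS = {k: v / _ELECTRONS["GLY"] for k, v in _ELECTRONS.items()}


@dataclass
class ObservableMatrix:
    """Back-calculated observables per frame: values[i, j] = observable i, frame j."""

    values: np.ndarray
    observable_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if not np.all(np.isfinite(self.values)):
            raise ValueError("observable matrix contains non-finite entries")
        if not self.observable_ids:
            self.observable_ids = [f"obs{i}" for i in range(self.values.shape[0])]
        if len(self.observable_ids) != self.values.shape[0]:
            raise ValueError("observable_ids length mismatch")

    @property
    def n_observables(self) -> int:
        return self.values.shape[0]

    @property
    def frame_count(self) -> int:
        return self.values.shape[1]


@dataclass
class GuinierFit:
    rg: float
    i0: float
    q_range_used: tuple[float, float]
    max_qrg: float
    fit_residual: float  # standard error of the slope
    n_points: int


@dataclass
class PREParameters:
    """Constants of the Solomon–Bloembergen transverse PRE term.

    tau_c in ns, larmor_frequency in MHz (protons), r2_diamagnetic in s⁻¹,
    total_evolution_time in s, k_const in Å⁶ s⁻² (1.23e16 Å⁶ s⁻² is the
    standard nitroxide electron–proton dipolar constant, 1.23e-32 cm⁶ s⁻²).
    """

    tau_c: float = 1.0
    larmor_frequency: float = 700.0
    r2_diamagnetic: float = 10.0
    total_evolution_time: float = 0.010
    k_const: float = 1.23e16
    label_displacement: float = 6.0  # Å, pseudo-atom offset from the labelled Cα

    def __post_init__(self) -> None:
        for name in ("tau_c", "larmor_frequency", "r2_diamagnetic",
                     "total_evolution_time", "k_const", "label_displacement"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def gamma2_per_r6(self) -> float:
        """Γ₂ per unit ⟨r⁻⁶⟩ (Å⁶ s⁻¹): K·(4τc + 3τc/(1+ω²τc²))."""
        tau = self.tau_c * 1e-9
        omega = 2 * np.pi * self.larmor_frequency * 1e6
        return self.k_const * (4 * tau + 3 * tau / (1 + (omega * tau) ** 2))


# ---------------------------------------------------------------------------
# size observables

def compute_rg(frame_coords: np.ndarray, bead_weights: np.ndarray | None = None) -> float:
    """Weighted RMS distance from the weighted centroid, in Å."""
    x = np.asarray(frame_coords, dtype=float)
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 1:
        raise ValueError("frame_coords must have shape (n_beads, 3)")
    w = np.ones(x.shape[0]) if bead_weights is None else np.asarray(bead_weights, dtype=float)
    total = w.sum()
    if total <= 0:
        raise ValueError("total bead weight must be positive")
    w = w / total
    center = w @ x
    return float(np.sqrt(np.sum(w * np.sum((x - center) ** 2, axis=1))))


def ensemble_rg(ensemble: ConformationalEnsemble, weights: np.ndarray | None = None) -> float:
    """Weighted ensemble-average R_g (Å)."""
    w = ensemble.prior_weights if weights is None else np.asarray(weights, dtype=float)
    per_frame = frame_rg_series(ensemble)
    return float(w @ per_frame / w.sum())


def frame_rg_series(ensemble: ConformationalEnsemble) -> np.ndarray:
    """Per-frame R_g values (Å)."""
    return np.array([compute_rg(f, ensemble.bead_weights) for f in ensemble.coords])


# Empirical Rg→Rh relation for disordered chains (Nygaard et al. 2017):
# Rg/Rh = α1·(Rg − α2·N^0.33)/(N^0.60 − N^0.33) + α3.
_RH_A1 = 0.216  # Å⁻¹
_RH_A2 = 4.06   # Å
_RH_A3 = 0.821


def compute_rh_from_rg(rg: float, n_residues: int) -> float:
    """Hydrodynamic radius (Å) from R_g via the empirical disordered-chain relation."""
    if rg <= 0:
        raise ValueError("rg must be positive")
    if n_residues < 2:
        raise ValueError("n_residues must be ≥ 2")
    n033 = n_residues ** 0.33
    n060 = n_residues ** 0.60
    ratio = _RH_A1 * (rg - _RH_A2 * n033) / (n060 - n033) + _RH_A3
    if ratio <= 0:
        raise ValueError("non-physical Rg/Rh ratio; rg out of the relation's domain")
    return rg / ratio


def ensemble_rh(ensemble: ConformationalEnsemble, weights: np.ndarray | None = None) -> float:
    """Weighted mean of per-frame R_h (the relation applied frame by frame)."""
    w = ensemble.prior_weights if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    rgs = frame_rg_series(ensemble)
    rhs = np.array([compute_rh_from_rg(r, ensemble.n_residues) for r in rgs])
    return float(w @ rhs)


# ---------------------------------------------------------------------------
# SAXS

def gaussian_bead_form_factor(f0: np.ndarray, r_bead: float = 3.0):
    """Per-bead Gaussian form factor f(q) = f₀·exp(−q²R²/2) as a callable."""
    f0 = np.asarray(f0, dtype=float)

    def f(q: np.ndarray) -> np.ndarray:
        q = np.asarray(q, dtype=float)
        return f0[:, None] * np.exp(-0.5 * (q[None, :] * r_bead) ** 2)

    return f


def _form_factor_table(form_factors, n_beads: int, q: np.ndarray) -> np.ndarray:
    """Resolve form factors to an (n_beads, n_q) array."""
    if form_factors is None:
        return np.ones((n_beads, len(q)))
    if callable(form_factors):
        fq = np.asarray(form_factors(q), dtype=float)
        if fq.shape != (n_beads, len(q)):
            raise ValueError("form factor callable returned wrong shape")
        return fq
    fq = np.asarray(form_factors, dtype=float)
    if fq.ndim == 1:
        if len(fq) != n_beads:
            raise ValueError("form factor vector length mismatch")
        return np.repeat(fq[:, None], len(q), axis=1)
    if fq.shape != (n_beads, len(q)):
        raise ValueError("form factor array shape mismatch")
    return fq


def debye_saxs_frame(frame_coords: np.ndarray, form_factors, q_grid: np.ndarray) -> np.ndarray:
    """Orientation-averaged scattering of one bead frame via the Debye equation.

    I(q) = Σ_a Σ_b f_a(q) f_b(q) sin(q r_ab)/(q r_ab), with the a=b limit
    f_a(q)²; no hydration-shell term.
    """
    x = np.asarray(frame_coords, dtype=float)
    q = np.asarray(q_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("q_grid must be strictly positive")
    if not np.all(np.isfinite(x)):
        raise ValueError("frame coordinates contain NaN/inf")
    n = x.shape[0]
    fq = _form_factor_table(form_factors, n, q)  # (n, m)
    intensity = np.sum(fq * fq, axis=0)  # self terms
    if n > 1:
        d = pdist(x)  # condensed pairwise distances
        iu, ju = np.triu_indices(n, k=1)
        fpair = fq[iu] * fq[ju]  # (n_pairs, m)
        qr = q[None, :] * d[:, None]  # (n_pairs, m)
        with np.errstate(invalid="ignore", divide="ignore"):
            sinc = np.where(qr > 0, np.sin(qr) / np.where(qr > 0, qr, 1.0), 1.0)
        intensity = intensity + 2.0 * np.sum(fpair * sinc, axis=0)
    return intensity


def ensemble_saxs(
    ensemble: ConformationalEnsemble,
    weights: np.ndarray | None = None,
    q_grid: np.ndarray | None = None,
    form_factors=None,
) -> np.ndarray:
    """Weighted arithmetic mean of per-frame Debye intensities on q_grid."""
    if q_grid is None:
        q_grid = np.linspace(0.01, 0.20, 19)
    w = ensemble.prior_weights if weights is None else np.asarray(weights, dtype=float)
    if len(w) != ensemble.n_frames:
        raise ValueError("weights length must equal n_frames")
    w = w / w.sum()
    F = saxs_observable_matrix(ensemble, q_grid, form_factors).values
    return F @ w


def saxs_observable_matrix(
    ensemble: ConformationalEnsemble,
    q_grid: np.ndarray,
    form_factors=None,
) -> ObservableMatrix:
    """Per-frame Debye intensities as an (n_q × n_frames) observable matrix."""
    if form_factors is None:
        form_factors = ensemble.bead_weights
    F = np.empty((len(q_grid), ensemble.n_frames))
    for j, frame in enumerate(ensemble.coords):
        F[:, j] = debye_saxs_frame(frame, form_factors, q_grid)
    return ObservableMatrix(values=F, observable_ids=[f"I(q={q:.5g})" for q in q_grid])


def guinier_fit(profile: ScatteringProfile, max_qrg: float = 1.1) -> GuinierFit:
    """Iterative Guinier fit: ln I vs q² on the largest low-q window with q·R_g ≤ max_qrg.

    Starts from the full profile and drops high-q points until the window
    satisfies the q·R_g bound; R_g = sqrt(−3·slope). A non-negative slope on
    the smallest window means no Guinier regime.
    """
    if np.any(profile.intensity <= 0):
        raise ValueError("Guinier fit requires positive intensities")
    q2 = profile.q**2
    log_i = np.log(profile.intensity)
    hi = len(profile)
    while hi >= 3:
        fit = linregress(q2[:hi], log_i[:hi])
        slope = fit.slope
        if slope > 0:
            if hi == 3:
                raise ValueError("no Guinier regime: positive low-q slope")
            hi -= 1
            continue
        rg = float(np.sqrt(-3.0 * slope))
        if rg == 0.0:
            warnings.warn("flat profile: no Guinier regime, rg = 0 reported")
        if profile.q[hi - 1] * rg <= max_qrg:
            return GuinierFit(
                rg=rg,
                i0=float(np.exp(fit.intercept)),
                q_range_used=(float(profile.q[0]), float(profile.q[hi - 1])),
                max_qrg=max_qrg,
                fit_residual=float(fit.stderr),
                n_points=hi,
            )
        hi -= 1
    raise ValueError("Guinier window shrank below 3 points before q·Rg ≤ max_qrg")


# ---------------------------------------------------------------------------
# PRE

def _label_positions(coords: np.ndarray, site_idx: int, displacement: float) -> np.ndarray:
    """Pseudo spin-label position per frame: site Cα + displacement along the
    local chain normal (cross product of the two bond vectors at the site)."""
    n_frames, n_beads, _ = coords.shape
    i = site_idx
    lo = max(i - 1, 0)
    hi = min(i + 1, n_beads - 1)
    v1 = coords[:, lo] - coords[:, i]
    v2 = coords[:, hi] - coords[:, i]
    normal = np.cross(v1, v2)
    norms = np.linalg.norm(normal, axis=1)
    # collinear (or terminal) fallback: any unit vector perpendicular to v1
    bad = norms < 1e-8
    if np.any(bad):
        ref = np.array([0.0, 0.0, 1.0])
        alt = np.cross(v1[bad], ref)
        alt_norm = np.linalg.norm(alt, axis=1)
        alt[alt_norm < 1e-8] = np.array([1.0, 0.0, 0.0])
        normal[bad] = alt
        norms = np.linalg.norm(normal, axis=1)
    return coords[:, i] + displacement * normal / norms[:, None]


def pre_distances(
    ensemble: ConformationalEnsemble,
    label_site: int,
    params: PREParameters | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame label–residue distances for one spin-label site.

    Returns (residues, d) with 1-based residue numbers and d of shape
    (n_frames, len(residues)); the labelled residue itself and any residue at
    (numerically) zero distance are excluded.
    """
    params = params or PREParameters()
    if not (1 <= label_site <= ensemble.n_residues):
        raise ValueError(f"label_site {label_site} outside chain 1..{ensemble.n_residues}")
    site_idx = label_site - 1
    labels = _label_positions(ensemble.coords, site_idx, params.label_displacement)
    d = np.linalg.norm(ensemble.coords - labels[:, None, :], axis=2)  # (frames, beads)
    keep = []
    for b in range(ensemble.n_beads):
        if b == site_idx:
            logger.info("label residue %d excluded from its own PRE profile", label_site)
            continue
        if np.any(d[:, b] < 1e-6):
            logger.info("residue %d at zero distance from label; excluded", b + 1)
            continue
        keep.append(b)
    keep = np.asarray(keep, dtype=int)
    return keep + 1, d[:, keep]


def mean_inverse_r6(distances: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Population-weighted ⟨r⁻⁶⟩ per residue from (n_frames, n_residues) distances."""
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return w @ np.asarray(distances, dtype=float) ** -6


def ratios_from_mean_r6(mean_r6: np.ndarray, params: PREParameters | None = None) -> np.ndarray:
    """I_para/I_dia from ⟨r⁻⁶⟩: Γ₂ = K·⟨r⁻⁶⟩·(4τc + 3τc/(1+ω²τc²)),
    ratio = R₂·exp(−Γ₂t)/(R₂+Γ₂) ∈ (0, 1]."""
    params = params or PREParameters()
    gamma2 = params.gamma2_per_r6() * np.asarray(mean_r6, dtype=float)
    return params.r2_diamagnetic * np.exp(-gamma2 * params.total_evolution_time) / (
        params.r2_diamagnetic + gamma2
    )


def pre_ratio_profile(
    ensemble: ConformationalEnsemble,
    weights: np.ndarray | None,
    label_site: int,
    params: PREParameters | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Population-weighted PRE intensity ratios for one label site.

    Returns (residues, ratios) with 1-based residue numbers; the labelled
    residue itself is excluded. The PRE averages r⁻⁶ over the ensemble, so
    transiently short label–residue distances dominate even at small weight.
    """
    params = params or PREParameters()
    w = ensemble.prior_weights if weights is None else np.asarray(weights, dtype=float)
    residues, d = pre_distances(ensemble, label_site, params)
    ratios = ratios_from_mean_r6(mean_inverse_r6(d, w), params)
    return residues, ratios
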