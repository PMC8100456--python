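"""Readers, writers and containers for ensembles, SAXS profiles, PRE tables and weights.

Conventions: coordinates in Å, scattering vector q in Å⁻¹. Residues are
numbered from 1 in all files; frames are indexed from 0 internally. Prior
frame weights default to uniform 1/n and are always renormalized on load.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "ConformationalEnsemble",
    "ScatteringProfile",
    "PREDataset",
    "load_ensemble",
    "save_ensemble",
    "load_saxs_profile",
    "save_saxs_profile",
    "rebin_profile",
    "load_pre_table",
    "save_pre_table",
    "load_weights",
    "save_weights",
]


class EnsembleParseError(ValueError):
    """Raised when an ensemble file is malformed (names the offending frame)."""


def _normalize(weights: np.ndarray, what: str = "weights") -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or not np.all(np.isfinite(w)):
        raise ValueError(f"{what} must be finite and non-negative")
    total = w.sum()
    if total <= 0:
        raise ValueError(f"{what} sum to zero")
    if abs(total - 1.0) > 1e-6:
        logger.info("%s renormalized by factor %.12g", what, 1.0 / total)
    return w / total


@dataclass
class ConformationalEnsemble:
    """A weighted set of conformations at one bead per residue.

    coords has shape (n_frames, n_beads, 3) in Å. ``bead_weights`` are the
    per-bead scattering weights f₀ (electrons; dimensionless after
    normalization). ``prior_weights`` w⁰ are per-frame probabilities.
    """

    coords: np.ndarray
    bead_labels: list[str] = field(default_factory=list)
    bead_weights: np.ndarray | None = None
    prior_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_beads, 3)")
        if self.n_frames < 1:
            raise ValueError("ensemble must contain at least one frame")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates contain non-finite values")
        if not self.bead_labels:
            self.bead_labels = [f"RES{i + 1}" for i in range(self.n_beads)]
        if len(self.bead_labels) != self.n_beads:
            raise ValueError("bead_labels length mismatch")
        if self.bead_weights is None:
            self.bead_weights = np.ones(self.n_beads)
        self.bead_weights = np.asarray(self.bead_weights, dtype=float)
        if self.bead_weights.shape != (self.n_beads,):
            raise ValueError("bead_weights length mismatch")
        if self.prior_weights is None:
            self.prior_weights = np.full(self.n_frames, 1.0 / self.n_frames)
        self.prior_weights = _normalize(self.prior_weights, "prior_weights")
        if self.prior_weights.shape != (self.n_frames,):
            raise ValueError("prior_weights length mismatch")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coords.shape[1]

    @property
    def n_residues(self) -> int:
        return self.n_beads


@dataclass
class ScatteringProfile:
    """A SAXS profile: q [Å⁻¹], I(q) (arbitrary units) and σ(q)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        n = len(self.q)
        if n < 2:
            raise ValueError("profile needs at least 2 points")
        if len(self.intensity) != n or len(self.sigma) != n:
            raise ValueError("q, intensity, sigma must have equal length")
        if np.any(self.q <= 0) or np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing and positive")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")
        if not (
            np.all(np.isfinite(self.q))
            and np.all(np.isfinite(self.intensity))
            and np.all(np.isfinite(self.sigma))
        ):
            raise ValueError("profile contains non-finite values")

    def __len__(self) -> int:
        return len(self.q)


@dataclass
class PREDataset:
    """Per-residue paramagnetic relaxation enhancement intensity ratios.

    One row per (label_site, residue) pair; ratio = I_para/I_dia.
    """

    label_site: np.ndarray
    residue: np.ndarray
    ratio: np.ndarray
    error: np.ndarray

    def __post_init__(self) -> None:
        self.label_site = np.asarray(self.label_site, dtype=int)
        self.residue = np.asarray(self.residue, dtype=int)
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.error = np.asarray(self.error, dtype=float)
        n = len(self.label_site)
        if not (len(self.residue) == len(self.ratio) == len(self.error) == n):
            raise ValueError("PRE columns must have equal length")
        if not np.all(np.isfinite(self.ratio)):
            raise ValueError("PRE ratios must be finite")
        pairs = list(zip(self.label_site.tolist(), self.residue.tolist()))
        if len(set(pairs)) != n:
            raise ValueError("duplicate (label_site, residue) rows in PRE table")

    @property
    def sites(self) -> np.ndarray:
        return np.unique(self.label_site)

    def for_site(self, site: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        m = self.label_site == site
        return self.residue[m], self.ratio[m], self.error[m]


# ---------------------------------------------------------------------------
# ensembles

def _load_coordinate_table(path: Path) -> np.ndarray:
    """Parse the plain-text dialect: columns ``frame bead x y z`` ('#' comments).

    Frames and beads are 0- and 1-indexed respectively in the file; beads must
    appear in order and every frame must contain the same bead count.
    """
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            if len(parts) != 5:
                raise EnsembleParseError(f"line {ln}: expected 5 columns, got {len(parts)}")
            rows.append([float(x) for x in parts])
    if not rows:
        raise EnsembleParseError("no frames found in coordinate table")
    arr = np.asarray(rows)
    frames = arr[:, 0].astype(int)
    order = np.argsort(frames, kind="stable")
    arr = arr[order]
    frames = frames[order]
    uniq = np.unique(frames)
    counts = {int(f): int((frames == f).sum()) for f in uniq}
    n_beads = counts[int(uniq[0])]
    for f, c in counts.items():
        if c != n_beads:
            raise EnsembleParseError(
                f"frame {f} has {c} beads, expected {n_beads} (inconsistent frame sizes)"
            )
    return arr[:, 2:5].reshape(len(uniq), n_beads, 3)


def _load_mdtraj(paths, topology, bead: str) -> tuple[np.ndarray, list[str]]:
    import mdtraj as md

    if topology is None:
        traj = md.load(str(paths))
    else:
        traj = md.load(str(paths), top=str(topology))
    if traj.n_frames == 0:
        raise EnsembleParseError("trajectory contains zero frames")
    top = traj.topology
    if bead == "centroid":
        coords = np.stack(
            [traj.xyz[:, [a.index for a in r.atoms], :].mean(axis=1) for r in top.residues],
            axis=1,
        )
        labels = [f"{r.name}{r.resSeq}" for r in top.residues]
    else:  # Cα per residue
        ca = top.select("name CA")
        if len(ca) == 0:
            raise EnsembleParseError("no Cα atoms found in topology")
        coords = traj.xyz[:, ca, :]
        labels = [f"{top.atom(i).residue.name}{top.atom(i).residue.resSeq}" for i in ca]
    return coords * 10.0, labels  # nm → Å


def load_ensemble(
    path,
    format: str = "auto",
    topology=None,
    bead: str = "CA",
    weights_path=None,
) -> ConformationalEnsemble:
    """Load an ensemble from a multi-model PDB, trajectory+topology or coordinate table.

    ``bead`` selects the one-bead-per-residue mapping: ``"CA"`` (default) or
    ``"centroid"``. Prior weights are uniform unless ``weights_path`` is given.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        suffix = path.suffix.lower()
        if suffix in {".pdb", ".xtc", ".dcd", ".trr", ".h5"}:
            format = "trajectory"
        else:
            format = "table"
    if format in {"multi-model-structure", "trajectory", "trajectory+topology"}:
        coords, labels = _load_mdtraj(path, topology, bead)
    elif format in {"table", "raw-coordinate-table"}:
        coords = _load_coordinate_table(path)
        labels = []
    else:
        raise ValueError(f"unknown ensemble format {format!r}")
    prior = load_weights(weights_path) if weights_path is not None else None
    return ConformationalEnsemble(coords=coords, bead_labels=labels, prior_weights=prior)


def save_ensemble(ensemble: ConformationalEnsemble, path) -> None:
    """Write the plain-text coordinate-table dialect (frame bead x y z)."""
    with open(path, "w") as fh:
        fh.write("# frame bead x y z  (Å)\n")
        for j in range(ensemble.n_frames):
            for b in range(ensemble.n_beads):
                x, y, z = ensemble.coords[j, b]
                fh.write(f"{j} {b + 1} {x:.10g} {y:.10g} {z:.10g}\n")


# ---------------------------------------------------------------------------
# SAXS profiles

def load_saxs_profile(path) -> ScatteringProfile:
    """Read a 3-column whitespace SAXS file (q, I, σ); '#' and header lines skipped.

    Rows with non-positive σ are dropped (count reported as a warning); a 4th
    column, if present, is ignored with a warning.
    """
    rows = []
    n_bad_sigma = 0
    warned_extra = False
    with open(path) as fh:
        for line in fh:
            s = line.split("#", 1)[0].strip()
            if not s:
                continue
            parts = s.split()
            try:
                vals = [float(p) for p in parts]
            except ValueError:
                continue  # non-numeric header line
            if len(vals) < 3:
                continue
            if len(vals) > 3 and not warned_extra:
                warnings.warn("SAXS file has >3 columns; extra columns ignored")
                warned_extra = True
            q, i, sig = vals[:3]
            if sig <= 0:
                n_bad_sigma += 1
                continue
            rows.append((q, i, sig))
    if n_bad_sigma:
        warnings.warn(f"dropped {n_bad_sigma} rows with non-positive sigma")
    if len(rows) < 2:
        raise ValueError(f"{path}: fewer than 2 valid data rows")
    arr = np.asarray(rows)
    if np.any(np.diff(arr[:, 0]) <= 0):
        raise ValueError(f"{path}: q values not strictly increasing")
    return ScatteringProfile(q=arr[:, 0], intensity=arr[:, 1], sigma=arr[:, 2])


def save_saxs_profile(profile: ScatteringProfile, path, header: str = "q I sigma") -> None:
    with open(path, "w") as fh:
        fh.write(f"# {header}\n")
        for q, i, s in zip(profile.q, profile.intensity, profile.sigma):
            fh.write(f"{q:.16g} {i:.16g} {s:.16g}\n")


def rebin_profile(
    profile: ScatteringProfile, n_bins: int, q_min: float, q_max: float
) -> ScatteringProfile:
    """Re-bin a profile onto ``n_bins`` equal-width q bins on [q_min, q_max].

    Each bin takes the inverse-variance-weighted mean intensity, the
    propagated σ = 1/sqrt(Σσ⁻²), and the same-weighted mean q.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be ≥ 2")
    if not (q_min < q_max):
        raise ValueError("q_min must be < q_max")
    edges = np.linspace(q_min, q_max, n_bins + 1)
    # left-closed bins; the right edge of the last bin is inclusive
    idx = np.digitize(profile.q, edges) - 1
    idx[profile.q == q_max] = n_bins - 1
    q_out, i_out, s_out = [], [], []
    for b in range(n_bins):
        m = idx == b
        if not np.any(m):
            raise ValueError(
                f"bin {b} ([{edges[b]:.4g}, {edges[b + 1]:.4g}]) is empty; use fewer bins"
            )
        inv_var = 1.0 / profile.sigma[m] ** 2
        w = inv_var / inv_var.sum()
        q_out.append(float(w @ profile.q[m]))
        i_out.append(float(w @ profile.intensity[m]))
        s_out.append(float(1.0 / np.sqrt(inv_var.sum())))
    return ScatteringProfile(q=np.array(q_out), intensity=np.array(i_out), sigma=np.array(s_out))


# ---------------------------------------------------------------------------
# PRE tables and weights

def load_pre_table(path) -> PREDataset:
    """Read a PRE CSV with named columns label_site, residue, ratio, error."""
    import pandas as pd

    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ["label_site", "residue", "ratio", "error"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"PRE table missing column(s): {', '.join(missing)}")
    return PREDataset(
        label_site=df["label_site"].to_numpy(),
        residue=df["residue"].to_numpy(),
        ratio=df["ratio"].to_numpy(),
        error=df["error"].to_numpy(),
    )


def save_pre_table(dataset: PREDataset, path) -> None:
    import pandas as pd

    pd.DataFrame(
        {
            "label_site": dataset.label_site,
            "residue": dataset.residue,
            "ratio": dataset.ratio,
            "error": dataset.error,
        }
    ).to_csv(path, index=False, float_format="%.16g")


def load_weights(path) -> np.ndarray:
    """Read one weight per line ('#'-comments allowed); renormalized to sum 1."""
    vals = []
    with open(path) as fh:
        for line in fh:
            s = line.split("#", 1)[0].strip()
            if s:
                vals.append(float(s))
    if not vals:
        raise ValueError(f"{path}: no weights found")
    return _normalize(np.asarray(vals))


def save_weights(weights: np.ndarray, path) -> None:
    w = _normalize(np.asarray(weights))
    with open(path, "w") as fh:
        fh.write("# per-frame weight\n")
        for v in w:
            fh.write(f"{v:.15g}\n")
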