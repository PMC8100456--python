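"""L-curve scan over the BME hyperparameter θ and elbow selection.

θ trades data fit (χ²_red) against prior fidelity (φ_eff). Scanning a
decreasing θ ladder traces an L-shaped curve in (φ_eff, χ²_red); the elbow —
operationalized here as the point of maximum discrete curvature on log-log
axes — marks the balanced choice.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bme_core import bme_optimize
from .ensemble_io import ScatteringProfile

__all__ = ["LCurve", "lcurve_scan", "select_theta", "default_theta_grid"]


def default_theta_grid(n: int = 20, lo: float = 1.0, hi: float = 1e6) -> np.ndarray:
    """20 log-spaced θ values on [1, 1e6] by default."""
    return np.geomspace(lo, hi, n)


@dataclass
class LCurve:
    """Ordered (θ, χ²_red, φ_eff) points from a scan, with the selected elbow."""

    theta: np.ndarray
    chi2_red: np.ndarray
    phi_eff: np.ndarray
    converged: np.ndarray
    selected_theta: float | None = None
    selection_method: str | None = None
    results: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float)
        d = np.diff(self.theta)
        if len(self.theta) and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("theta values must be strictly monotone with no duplicates")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "theta": self.theta,
                "chi2_red": self.chi2_red,
                "phi_eff": self.phi_eff,
                "converged": self.converged,
            }
        )

    def save(self, table_path, json_path=None) -> None:
        self.to_frame().to_csv(table_path, sep="\t", index=False, float_format="%.10g")
        if json_path is not None:
            with open(json_path, "w") as fh:
                json.dump(
                    {
                        "selected_theta": self.selected_theta,
                        "selection_method": self.selection_method,
                        "n_points": int(len(self.theta)),
                    },
                    fh,
                    indent=2,
                )


def lcurve_scan(
    F,
    exp: ScatteringProfile,
    w0: np.ndarray | None = None,
    theta_grid: np.ndarray | None = None,
    scale_mode: str = "scale+offset",
) -> LCurve:
    """Run BME at each θ of the grid (descending, warm-started) and collect the curve."""
    grid = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, dtype=float)
    if len(grid) < 3:
        raise ValueError("theta grid needs at least 3 values")
    if np.any(grid <= 0):
        raise ValueError("theta values must be > 0")
    order = np.argsort(grid)[::-1]  # scan from large θ (near-prior) downward
    results = {}
    lam_reduced = None  # λ/θ is roughly continuous along the ladder
    for k in order:
        lam = None if lam_reduced is None else lam_reduced * grid[k]
        res = bme_optimize(F, exp, w0=w0, theta=grid[k], scale_mode=scale_mode, lam_init=lam)
        lam_reduced = res.lagrange_multipliers
        results[k] = res
    ordered = [results[k] for k in range(len(grid))]
    conv = np.array([r.converged for r in ordered])
    if not np.any(conv):
        raise RuntimeError("no θ point converged; check data scaling and grid")
    return LCurve(
        theta=grid,
        chi2_red=np.array([r.chi2_red for r in ordered]),
        phi_eff=np.array([r.phi_eff for r in ordered]),
        converged=conv,
        results=ordered,
    )


def _max_curvature_theta(theta, x, y) -> tuple[float, float]:
    """θ at maximum discrete curvature of the parametric curve (x(θ), y(θ))."""
    t = np.log(theta)
    dx, dy = np.gradient(x, t), np.gradient(y, t)
    d2x, d2y = np.gradient(dx, t), np.gradient(dy, t)
    speed2 = dx**2 + dy**2
    with np.errstate(divide="ignore", invalid="ignore"):
        kappa = np.abs(dx * d2y - dy * d2x) / np.power(speed2, 1.5)
    kappa[~np.isfinite(kappa)] = 0.0
    k = int(np.argmax(kappa))
    return float(theta[k]), float(kappa[k])


def select_theta(
    curve: LCurve,
    method: str = "max-curvature",
    chi2_bound: float | None = None,
    manual_value: float | None = None,
    curvature_floor: float = 1e-3,
) -> float:
    """Choose θ from an L-curve.

    'max-curvature': θ maximizing the discrete curvature of
    (log φ_eff, log χ²_red); falls back to 'chi2-threshold' when the curve is
    collinear. 'chi2-threshold': largest θ with χ²_red ≤ bound (default: the
    curve minimum plus 10% of its range). 'manual': echo ``manual_value``.
    The method actually used is recorded on the curve.
    """
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual selection requires manual_value")
        curve.selected_theta = float(manual_value)
        curve.selection_method = "manual"
        return curve.selected_theta

    conv = curve.converged
    theta = curve.theta[conv]
    chi2 = curve.chi2_red[conv]
    phi = curve.phi_eff[conv]

    if method == "max-curvature":
        if conv.sum() < 5:
            raise ValueError("max-curvature selection needs ≥5 converged points")
        order = np.argsort(theta)[::-1]
        t, c, p = theta[order], chi2[order], phi[order]
        x = np.log(np.maximum(p, 1e-300))
        y = np.log(np.maximum(c, 1e-12))
        best_theta, best_kappa = _max_curvature_theta(t, x, y)
        span = max(np.ptp(x), np.ptp(y))
        if best_kappa <= curvature_floor or span < 1e-9:
            warnings.warn("L-curve is collinear; falling back to chi2-threshold selection")
            method = "chi2-threshold"
        else:
            curve.selected_theta = best_theta
            curve.selection_method = "max-curvature"
            return best_theta

    if method == "chi2-threshold":
        bound = chi2_bound
        if bound is None:
            bound = float(chi2.min() + 0.1 * max(np.ptp(chi2), 1e-12))
        ok = chi2 <= bound
        if not np.any(ok):
            warnings.warn("no θ satisfies the χ² bound; choosing the best-fit point")
            sel = float(theta[np.argmin(chi2)])
        else:
            sel = float(theta[ok].max())
        curve.selected_theta = sel
        curve.selection_method = "chi2-threshold"
        return sel

    raise ValueError(f"unknown selection method {method!r}")
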