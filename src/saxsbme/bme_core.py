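"""Bayesian/Maximum-Entropy reweighting.

The primal problem minimizes, over the probability simplex,

    L(w) = ½ χ²(w) − θ S_rel(w),

where χ²(w) = Σ_i ((a·⟨F_i⟩_w + b − F_i^exp)/σ_i)² with nuisance scale a and
offset b, and S_rel(w) = −Σ_j w_j log(w_j/w⁰_j) ≤ 0 penalizes deviation from
the prior weights w⁰. The optimum is found in the dual: for fixed (a, b)

    Γ(λ) = θ·log Σ_j w⁰_j exp(−(1/θ) Σ_i λ_i F_ij) + Σ_i λ_i y_i + ½ Σ_i λ_i² s_i²

is convex in the m Lagrange multipliers λ (y, s are the scale-corrected data
and errors), with w_j ∝ w⁰_j exp(−(1/θ)Σ_i λ_i F_ij). Scale and offset are
profiled by exact coordinate descent between closed-form least squares and
dual solves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .ensemble_io import ScatteringProfile
from .forward_models import ObservableMatrix

__all__ = [
    "ReweightingResult",
    "fit_scale_offset",
    "chi2_reduced",
    "relative_entropy",
    "phi_eff",
    "bme_optimize",
]


@dataclass
class ReweightingResult:
    """Posterior weights and diagnostics of one BME solve at fixed θ."""

    weights: np.ndarray
    theta: float
    chi2_red: float
    chi2_red_prior: float
    s_rel: float
    phi_eff: float
    scale: float
    offset: float
    lagrange_multipliers: np.ndarray
    converged: bool
    n_iterations: int
    objective: float
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "theta": self.theta,
            "chi2_red": self.chi2_red,
            "chi2_red_prior": self.chi2_red_prior,
            "s_rel": self.s_rel,
            "phi_eff": self.phi_eff,
            "scale": self.scale,
            "offset": self.offset,
            "converged": self.converged,
            "n_iterations": self.n_iterations,
            "objective": self.objective,
            "chi2_normalization": "m (data-point count)",
            **self.metadata,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _as_matrix(F) -> np.ndarray:
    if isinstance(F, ObservableMatrix):
        return F.values
    return np.atleast_2d(np.asarray(F, dtype=float))


def fit_scale_offset(
    calc: np.ndarray, exp: ScatteringProfile, fit_offset: bool = True
) -> tuple[float, float]:
    """Closed-form weighted least squares for a·calc + b ≈ exp (offset optional)."""
    c = np.asarray(calc, dtype=float)
    y = exp.intensity
    s = exp.sigma
    if len(c) != len(y):
        raise ValueError("calc and experimental profile must have equal length")
    iv = 1.0 / s**2
    if not fit_offset:
        denom = np.sum(iv * c * c)
        if denom <= 0:
            raise ValueError("degenerate design: calc is identically zero")
        return float(np.sum(iv * c * y) / denom), 0.0
    swx = np.sum(iv * c)
    swy = np.sum(iv * y)
    swxx = np.sum(iv * c * c)
    swxy = np.sum(iv * c * y)
    sw = np.sum(iv)
    det = sw * swxx - swx**2
    if det <= 1e-12 * sw * swxx:
        raise ValueError("degenerate design: calc intensities are constant, cannot fit offset")
    a = (sw * swxy - swx * swy) / det
    b = (swxx * swy - swx * swxy) / det
    return float(a), float(b)


def _fit_nuisance(calc: np.ndarray, exp: ScatteringProfile, scale_mode: str) -> tuple[float, float]:
    if scale_mode == "none":
        return 1.0, 0.0
    if scale_mode == "scale":
        return fit_scale_offset(calc, exp, fit_offset=False)
    if scale_mode in ("scale+offset", "scale_offset"):
        return fit_scale_offset(calc, exp, fit_offset=True)
    raise ValueError(f"unknown scale_mode {scale_mode!r}")


def chi2_reduced(
    calc: np.ndarray,
    exp: ScatteringProfile,
    scale_mode: str = "scale+offset",
) -> float:
    """χ²_red = (1/m)·Σ ((a·calc + b − exp)/σ)² after the requested nuisance fit."""
    c = np.asarray(calc, dtype=float)
    m = len(exp.q)
    if m == 0 or len(c) != m:
        raise ValueError("calc and experimental profile must have equal, non-zero length")
    a, b = _fit_nuisance(c, exp, scale_mode)
    resid = (a * c + b - exp.intensity) / exp.sigma
    return float(np.sum(resid**2) / m)


def relative_entropy(w: np.ndarray, w0: np.ndarray) -> float:
    """S_rel = −Σ w log(w/w⁰) ≤ 0; zero iff w = w⁰ (0·log 0 := 0)."""
    w = np.asarray(w, dtype=float)
    w0 = np.asarray(w0, dtype=float)
    if len(w) != len(w0):
        raise ValueError("weight vectors must have equal length")
    w = w / w.sum()
    w0 = w0 / w0.sum()
    if np.any((w > 0) & (w0 == 0)):
        raise ValueError("posterior mass where prior is zero (absolute continuity violated)")
    m = w > 0
    return float(-np.sum(w[m] * np.log(w[m] / w0[m])))


def phi_eff(w: np.ndarray, w0: np.ndarray) -> float:
    """Effective fraction of prior frames, exp(S_rel) ∈ (0, 1]."""
    return float(np.exp(relative_entropy(w, w0)))


def _dual_solve(
    F: np.ndarray,
    y: np.ndarray,
    s: np.ndarray,
    log_w0: np.ndarray,
    theta: float,
    lam0: np.ndarray,
    grad_tol: float,
    max_iter: int,
):
    """Minimize the convex dual Γ(λ) by damped Newton with backtracking.

    The dual Hessian (1/θ)·Cov_w(F) + diag(s²) is SPD and only m×m, so full
    Newton steps are cheap and drive the gradient to tolerance even when θ
    makes the objective badly scaled. Returns (λ, weights, grad_max, n_iter, ok).
    """

    def weights_of(lam: np.ndarray) -> np.ndarray:
        logw = log_w0 - (lam @ F) / theta
        logw -= logsumexp(logw)
        return np.exp(logw)

    def value_grad(lam: np.ndarray, w: np.ndarray):
        logw = log_w0 - (lam @ F) / theta
        logz = logsumexp(logw)
        val = theta * logz + lam @ y + 0.5 * np.sum(lam**2 * s**2)
        grad = -(F @ w) + y + lam * s**2
        return val, grad

    tol = grad_tol * max(1.0, float(np.max(np.abs(y))))
    lam = lam0.copy()
    w = weights_of(lam)
    val, grad = value_grad(lam, w)
    ok = False
    it = 0
    for it in range(1, max_iter + 1):
        grad_max = float(np.max(np.abs(grad)))
        if grad_max <= tol:
            ok = True
            break
        mean_f = F @ w
        fc = F - mean_f[:, None]
        hess = (fc * w) @ fc.T / theta + np.diag(s**2)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = grad / np.diag(hess)
        t = 1.0
        for _ in range(60):
            lam_new = lam - t * step
            w_new = weights_of(lam_new)
            val_new, grad_new = value_grad(lam_new, w_new)
            if val_new <= val - 1e-4 * t * (grad @ step):
                break
            t *= 0.5
        else:
            # objective at the floating-point noise floor: accept if the
            # gradient is already negligible on the data scale
            break
        lam, w, val, grad = lam_new, w_new, val_new, grad_new
    grad_max = float(np.max(np.abs(grad)))
    ok = ok or grad_max <= max(tol, 1e-7 * max(1.0, float(np.max(np.abs(y)))))
    return lam, w, grad_max, it, ok


def bme_optimize(
    F,
    exp: ScatteringProfile,
    w0: np.ndarray | None = None,
    theta: float = 1000.0,
    scale_mode: str = "scale+offset",
    grad_tol: float = 1e-8,
    max_iterations: int = 5000,
    lam_init: np.ndarray | None = None,
    max_outer: int = 50,
) -> ReweightingResult:
    """Minimize L(w) = ½χ²(w) − θ·S_rel(w) over the simplex at fixed θ.

    ``F`` is the (m observables × n frames) back-calculation matrix. Nuisance
    scale/offset (per ``scale_mode``: 'none', 'scale', 'scale+offset') are
    refitted around every dual solve. Deterministic given its inputs; the
    returned ``lagrange_multipliers`` satisfy w ∝ w⁰·exp(−Σλ_iF_i).
    """
    Fm = _as_matrix(F)
    m, n = Fm.shape
    if len(exp.q) != m:
        raise ValueError("experimental profile length must match observable count")
    if theta <= 0:
        raise ValueError("theta must be > 0")
    w0 = np.full(n, 1.0 / n) if w0 is None else np.asarray(w0, dtype=float)
    w0 = w0 / w0.sum()
    log_w0 = np.where(w0 > 0, np.log(np.where(w0 > 0, w0, 1.0)), -np.inf)

    lam = np.zeros(m) if lam_init is None else np.asarray(lam_init, dtype=float).copy()
    w = w0.copy()
    chi2_prior = chi2_reduced(Fm @ w0, exp, scale_mode)

    a, b = 1.0, 0.0
    a_prev = b_prev = None
    total_iters = 0
    ok = False
    iscale = max(float(np.max(np.abs(exp.intensity))), 1.0)
    for _ in range(max_outer):
        a, b = _fit_nuisance(Fm @ w, exp, scale_mode)
        if (
            a_prev is not None
            and ok
            and abs(a - a_prev) <= 1e-7 * abs(a)
            and abs(b - b_prev) <= 1e-7 * iscale
        ):
            break  # nuisance parameters stationary and dual solved: done
        a_prev, b_prev = a, b
        y = (exp.intensity - b) / a
        s = exp.sigma / abs(a)
        lam, w, grad_max, nit, ok = _dual_solve(
            Fm, y, s, log_w0, theta, lam, grad_tol, max_iterations
        )
        total_iters += max(nit, 1)
        if total_iters >= max_iterations:
            break

    a, b = _fit_nuisance(Fm @ w, exp, scale_mode)
    s_rel = relative_entropy(w, w0)
    chi2 = chi2_reduced(Fm @ w, exp, scale_mode)
    objective = 0.5 * chi2 * m - theta * s_rel
    return ReweightingResult(
        weights=w,
        theta=float(theta),
        chi2_red=chi2,
        chi2_red_prior=chi2_prior,
        s_rel=s_rel,
        phi_eff=float(np.exp(s_rel)),
        scale=a,
        offset=b,
        lagrange_multipliers=lam / theta,
        converged=bool(ok),
        n_iterations=total_iters,
        objective=float(objective),
        metadata={"scale_mode": scale_mode, "n_frames": n, "n_observables": m},
    )
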