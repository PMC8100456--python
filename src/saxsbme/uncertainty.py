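"""Block-averaging error estimation and weighted distribution densities.

Frames from a trajectory are time-correlated, so the naive standard error of
a mean underestimates the true uncertainty. Block averaging groups
contiguous frames into blocks of increasing size; once blocks are longer
than the correlation time the block-mean standard error plateaus at the true
error. For unordered ensembles a seeded weighted bootstrap is provided
instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["BlockErrorResult", "block_error", "weighted_density", "default_block_sizes"]


def default_block_sizes(n: int) -> list[int]:
    """Powers of 2 from 16 up to n/4 (adjusted downward for short series)."""
    lo = 16
    while lo > 1 and n // lo < 4:
        lo //= 2
    sizes = []
    b = lo
    while b <= max(n // 4, lo):
        if n // b >= 2:
            sizes.append(b)
        b *= 2
    return sizes or [1]


@dataclass
class BlockErrorResult:
    error: float
    block_sizes: np.ndarray
    block_errors: np.ndarray  # standard error of the weighted mean at each size

    def curve(self) -> dict[int, float]:
        return dict(zip(self.block_sizes.tolist(), self.block_errors.tolist()))


def _weighted_se(means: np.ndarray, pweights: np.ndarray) -> float:
    """SE of the weighted mean from block means with block probabilities p_k.

    SE² = K/(K−1) · Σ p_k²(m_k − μ)², which reduces to std/√K for uniform p.
    """
    k = len(means)
    mu = float(pweights @ means)
    return float(np.sqrt(k / (k - 1) * np.sum(pweights**2 * (means - mu) ** 2)))


def block_error(
    series: np.ndarray,
    weights: np.ndarray | None = None,
    block_sizes: list[int] | None = None,
    mode: str = "blocks",
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> BlockErrorResult:
    """Standard error of the weighted mean of a (possibly correlated) series.

    mode='blocks' (default) assumes trajectory order and returns, for each
    block size, the standard error across contiguous weighted block means;
    the final estimate is the plateau value (max over the 3 largest usable
    sizes). mode='bootstrap' is for unordered ensembles: seeded weighted
    resampling of frames.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("series must have length ≥ 2")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != n:
        raise ValueError("weights length mismatch")
    w = w / w.sum()

    if mode == "bootstrap":
        rng = np.random.default_rng(seed)
        idx = rng.choice(n, size=(n_bootstrap, n), p=w)
        means = x[idx].mean(axis=1)
        est = float(means.std(ddof=1))
        return BlockErrorResult(error=est, block_sizes=np.array([n]), block_errors=np.array([est]))

    sizes = default_block_sizes(n) if block_sizes is None else list(block_sizes)
    if sizes and n < 2 * max(sizes):
        raise ValueError("series must be at least twice the largest block size")
    used_sizes, errs = [], []
    for b in sizes:
        k = n // b
        if k < 2:
            warnings.warn(f"block size {b} leaves <2 blocks; skipped")
            continue
        xb = x[: k * b].reshape(k, b)
        wb = w[: k * b].reshape(k, b)
        wsum = wb.sum(axis=1)
        if np.any(wsum <= 0):
            warnings.warn(f"block size {b} has zero-weight blocks; skipped")
            continue
        means = (xb * wb).sum(axis=1) / wsum
        errs.append(_weighted_se(means, wsum / wsum.sum()))
        used_sizes.append(b)
    if not errs:
        raise ValueError("no usable block size")
    plateau = float(max(errs[-3:]))
    return BlockErrorResult(
        error=plateau, block_sizes=np.array(used_sizes), block_errors=np.array(errs)
    )


def weighted_density(
    values: np.ndarray,
    weights: np.ndarray | None = None,
    bins: int | np.ndarray = 30,
    block_mode: str = "blocks",
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted histogram density with per-bin block-averaged errors.

    Returns (bin_edges, density, density_errors); Σ density·Δ = 1. Per-bin
    errors come from block_error applied to the bin indicator series.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("empty value set")
    w = np.ones(len(x)) if weights is None else np.asarray(weights, dtype=float)
    w = w / w.sum()
    if np.isscalar(bins):
        if int(bins) < 2:
            raise ValueError("bins must be ≥ 2")
        lo, hi = float(x.min()), float(x.max())
        if lo == hi:  # degenerate: all values equal
            lo, hi = lo - 0.5, hi + 0.5
        edges = np.linspace(lo, hi, int(bins) + 1)
    else:
        edges = np.asarray(bins, dtype=float)
    width = np.diff(edges)
    hist, _ = np.histogram(x, bins=edges, weights=w)
    density = hist / width
    errors = np.zeros_like(density)
    if len(x) >= 4:
        idx = np.clip(np.digitize(x, edges) - 1, 0, len(width) - 1)
        for b in range(len(width)):
            indicator = (idx == b).astype(float) / width[b]
            try:
                errors[b] = block_error(indicator, w, mode=block_mode, seed=seed).error
            except ValueError:
                errors[b] = 0.0
    return edges, density, errors
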