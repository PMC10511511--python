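"""Fold-reduction of mutation rate across structure extremes and the
selection-coefficient model for folding-strengthening mutations.

Within a gene, the antimutator effect size is approximated by
``x`` = (mean mutation rate of the 50-bp window with the highest mean
single-stranded score) / (mean rate of the window with the lowest mean
score): the most-unstructured stretch over the most-structured one.
Division by zero (a mutation-free structured window) is capped at 50.

Assuming no recombination between a folding-altering mutation and its
mutational target, the fitness advantage of a mutation that strengthens
nascent folding is the reduction in the deleterious mutation rate of its
target:

    s = f_del * target_size * (x - 1) * y

with ``f_del`` the deleterious fraction of mutations (0.7),
``target_size`` the nucleotides whose rate one folding change affects
(10), and ``y`` the genomic per-generation per-nucleotide mutation rate
(3.3e-10 in budding yeast).  Selection sees the modifier only when
``s > 1/Ne`` (Ne ~ 1e7), which requires roughly a 44-fold rate reduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "SelectionParams",
    "fold_reduction",
    "selection_coefficient",
    "phase_boundary",
]


@dataclass(frozen=True)
class SelectionParams:
    """Parameters of the fitness-advantage model (defaults for yeast)."""

    f_del: float = 0.7
    target_size: float = 10.0
    y: float = 3.3e-10
    ne: float = 1e7

    def __post_init__(self) -> None:
        if not 0 < self.f_del <= 1:
            raise ValueError("f_del must be in (0, 1]")
        if self.target_size <= 0 or self.y <= 0 or self.ne <= 0:
            raise ValueError("target_size, y and Ne must be positive")


@dataclass
class FoldReduction:
    gene_id: str
    x: float
    capped: bool
    hi_window_start: int  # 1-based start of the max-theta window
    lo_window_start: int


def _window_means(values: np.ndarray, window: int) -> np.ndarray:
    """Mean over each length-``window`` sliding window, NaN-aware:
    positions without data are simply excluded from the window mean."""
    finite = np.isfinite(values)
    vals = np.where(finite, values, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(vals)])
    cnt = np.concatenate([[0], np.cumsum(finite)])
    sums = csum[window:] - csum[:-window]
    counts = cnt[window:] - cnt[:-window]
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)


def fold_reduction(
    theta: np.ndarray,
    rates: np.ndarray,
    gene_id: str = "",
    window: int = 50,
    min_frac: float = 0.05,
    cap: float = 50.0,
) -> FoldReduction | None:
    """Per-gene mutation-rate ratio between structure extremes.

    ``theta`` and ``rates`` are aligned 1-based arrays (index 0 ignored);
    NaN marks missing data.  Genes with fewer than ``min_frac`` of sites
    carrying rate data, or shorter than two windows, are excluded
    (returns None).  Candidate windows slide by 1 bp and must contain at
    least one site with rate data; the max-theta and min-theta windows
    may not overlap.
    """
    th = np.asarray(theta, dtype=float)[1:]
    ra = np.asarray(rates, dtype=float)[1:]
    if th.shape != ra.shape:
        raise ValueError("theta and rates must be aligned")
    n = th.size
    if n < 2 * window:
        return None
    has_rate = np.isfinite(ra)
    if has_rate.sum() < min_frac * n:
        return None

    mean_theta = _window_means(th, window)
    mean_rate = _window_means(ra, window)
    ok = np.isfinite(mean_theta) & np.isfinite(mean_rate)
    if not ok.any():
        return None
    starts = np.flatnonzero(ok)

    hi = starts[np.argmax(mean_theta[starts])]
    non_overlap = starts[np.abs(starts - hi) >= window]
    if non_overlap.size == 0:
        return None
    lo = non_overlap[np.argmin(mean_theta[non_overlap])]

    num, den = mean_rate[hi], mean_rate[lo]
    capped = False
    if den == 0:
        x, capped = cap, True
    else:
        x = num / den
        if x > cap:
            x, capped = cap, True
    return FoldReduction(
        gene_id=gene_id,
        x=float(x),
        capped=capped,
        hi_window_start=int(hi + 1),
        lo_window_start=int(lo + 1),
    )


def selection_coefficient(
    x: float, params: SelectionParams = SelectionParams()
) -> float:
    """Fitness advantage of an x-fold mutation-rate reduction.

    Negative for x < 1 (a folding-weakening change raises the deleterious
    mutation rate of its target).
    """
    return params.f_del * params.target_size * (x - 1.0) * params.y


def phase_boundary(
    x_grid: np.ndarray,
    y_grid: np.ndarray,
    params: SelectionParams = SelectionParams(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Selection-coefficient surface over (x, y) and the s = 1/Ne contour.

    Returns (grid, contour): the grid holds s at every (x, y) pair; the
    contour gives, for each y, the fold reduction x* where s equals the
    drift barrier 1/Ne, i.e. ``x* = 1 + 1/(Ne f_del target_size y)``.
    """
    x_grid = np.asarray(x_grid, dtype=float)
    y_grid = np.asarray(y_grid, dtype=float)
    if x_grid.size == 0 or y_grid.size == 0 or (y_grid <= 0).any():
        raise ValueError("grids must be non-empty and y strictly positive")
    xx, yy = np.meshgrid(x_grid, y_grid, indexing="ij")
    s = params.f_del * params.target_size * (xx - 1.0) * yy
    grid = pd.DataFrame(
        {"x": xx.ravel(), "y": yy.ravel(), "s": s.ravel()}
    )
    x_star = 1.0 + 1.0 / (params.ne * params.f_del * params.target_size * y_grid)
    contour = pd.DataFrame({"y": y_grid, "x_star": x_star})
    return grid, contour
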