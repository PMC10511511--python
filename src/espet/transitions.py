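"""Detection of cotranscriptional structural transitions.

For each nucleotide the longitudinal profile of its winsorized RT-stop
density across transcriptional intermediates is scanned with a sliding
window (default 50 consecutive intermediate lengths, step 1).  The first
and last 25 lengths of a window are compared by a two-sided Wilcoxon
rank-sum test; a window is evaluable only if both halves carry at least
one raw read.  A nucleotide is called transitioning when any window is
significant at ``alpha`` (a Benjamini-Hochberg option is available but
off by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .reads import IntermediateMatrix

__all__ = [
    "scan_profile",
    "detect_transitions",
    "transition_fraction",
    "TransitionFractionResult",
]

DEFAULT_WINDOW = 50
DEFAULT_ALPHA = 0.05


def ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Uses the exact null distribution when the pooled sample is small and
    tie-free, otherwise the normal approximation with tie correction.
    Identical constant halves are trivially non-significant (p = 1).
    """
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0
    exact = pooled.size <= 60 and np.unique(pooled).size == pooled.size
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="exact" if exact else "asymptotic"
    )
    return float(res.pvalue)


def scan_profile(
    density: np.ndarray,
    reads: np.ndarray,
    lengths: np.ndarray | None = None,
    window: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Slide the test window along one nucleotide's longitudinal profile.

    ``density`` and ``reads`` are aligned vectors over ordered
    intermediate lengths (``lengths`` defaults to 0..n-1 labels).  Returns
    one row per window with its start length, evaluability, p-value and
    significance flag; an empty frame if the profile is shorter than the
    window.
    """
    density = np.asarray(density, dtype=float)
    reads = np.asarray(reads, dtype=float)
    if density.shape != reads.shape:
        raise ValueError("density and reads must be aligned")
    n = density.size
    if lengths is None:
        lengths = np.arange(n)
    lengths = np.asarray(lengths)
    if np.any(np.diff(lengths) <= 0):
        raise ValueError("intermediate lengths must be strictly increasing")
    cols = {"start_length": [], "evaluable": [], "p": []}
    half = window // 2
    for j in range(0, n - window + 1):
        first = slice(j, j + half)
        second = slice(j + half, j + window)
        evaluable = reads[first].sum() >= 1 and reads[second].sum() >= 1
        p = ranksum_p(density[first], density[second]) if evaluable else np.nan
        cols["start_length"].append(lengths[j])
        cols["evaluable"].append(evaluable)
        cols["p"].append(p)
    out = pd.DataFrame(cols)
    if bh_correct and out["evaluable"].any():
        adj = np.full(len(out), np.nan)
        mask = out["evaluable"].to_numpy()
        adj[mask] = stats.false_discovery_control(out.loc[mask, "p"])
        out["significant"] = adj < alpha
    else:
        out["significant"] = out["p"] < alpha
    out["significant"] = out["significant"].fillna(False).astype(bool)
    return out


def detect_transitions(
    density: np.ndarray,
    reads: np.ndarray,
    lengths: np.ndarray | None = None,
    window: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> list[tuple[int, float]]:
    """Significant windows of one longitudinal profile as (start L, p)."""
    windows = scan_profile(
        density, reads, lengths, window=window, alpha=alpha, bh_correct=bh_correct
    )
    sig = windows.loc[windows["significant"]]
    return list(zip(sig["start_length"].tolist(), sig["p"].tolist()))


@dataclass
class TransitionFractionResult:
    gene_id: str
    n_informative: int
    n_transitioning: int
    per_site: pd.DataFrame  # pos, informative, best_start_length, min_p, transitioning

    @property
    def fraction(self) -> float:
        """Fraction of informative nucleotides with >= 1 significant window;
        NaN when no nucleotide is informative (gene excluded)."""
        if self.n_informative == 0:
            return float("nan")
        return self.n_transitioning / self.n_informative


def transition_fraction(
    matrix: IntermediateMatrix,
    window: int = DEFAULT_WINDOW,
    alpha: float = DEFAULT_ALPHA,
    bh_correct: bool = False,
) -> TransitionFractionResult:
    """Scan every nucleotide of a gene's intermediate matrix.

    A nucleotide is informative when at least one window is evaluable
    (long enough profile and one read in each half).
    """
    fp = matrix.footprint
    rows = []
    for i in range(1, matrix.length - fp + 1):
        Ls = np.arange(i + fp, matrix.length + 1)
        if Ls.size < window:
            rows.append((i, False, np.nan, np.nan, False))
            continue
        windows = scan_profile(
            matrix.density[Ls, i],
            matrix.raw[Ls, i],
            lengths=Ls,
            window=window,
            alpha=alpha,
            bh_correct=bh_correct,
        )
        informative = bool(windows["evaluable"].any())
        if informative and windows["p"].notna().any():
            best = windows.loc[windows["p"].idxmin()]
            rows.append(
                (
                    i,
                    True,
                    best["start_length"],
                    best["p"],
                    bool(windows["significant"].any()),
                )
            )
        else:
            rows.append((i, informative, np.nan, np.nan, False))
    per_site = pd.DataFrame(
        rows,
        columns=["pos", "informative", "best_start_length", "min_p", "transitioning"],
    )
    return TransitionFractionResult(
        gene_id=matrix.gene_id,
        n_informative=int(per_site["informative"].sum()),
        n_transitioning=int(per_site["transitioning"].sum()),
        per_site=per_site,
    )
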