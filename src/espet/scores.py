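"""Per-nucleotide single-stranded scores and gene-level structure summaries.

The single-stranded score contrasts depth-normalized NAI-N3 RT-stop counts
with the DMSO background:

    k_DMSO = (S_DMSO + S_NAI) / (2 S_DMSO)
    k_NAI  = (S_DMSO + S_NAI) / (2 S_NAI)
    N_t(i) = k_t * n_t(i)
    theta(i) = log2((N_NAI(i) + 1) / (N_DMSO(i) + 1) + 1), capped at 7

where S_t is the library-wide total of retained records in treatment t.
Pseudocounts keep the score strictly positive; higher theta means the
nucleotide is more often unpaired.  Gene-level structure prevalence is
summarized by the negated mean and by the Gini index of theta (a more
structured gene concentrates reactivity on few nucleotides, giving a
higher Gini).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .reads import StopProfile

__all__ = [
    "SSProfile",
    "normalization_constants",
    "single_stranded_score",
    "gini",
    "gene_summary",
    "structural_similarity",
]

DEFAULT_CAP = 7.0


def normalization_constants(s_dmso: float, s_nai: float) -> tuple[float, float]:
    """Depth-normalization constants from the two library totals."""
    if s_dmso <= 0 or s_nai <= 0:
        raise ValueError(
            f"library totals must be positive, got DMSO={s_dmso}, NAI={s_nai}"
        )
    total = s_dmso + s_nai
    return total / (2.0 * s_dmso), total / (2.0 * s_nai)


@dataclass
class SSProfile:
    """Single-stranded scores of one gene.

    ``theta`` is 1-based (index 0 is NaN).  ``low_coverage`` flags
    nucleotides with zero stops in both treatments, whose theta is the
    formula's pseudocount value of 1; gene summaries exclude them by
    default.
    """

    gene_id: str
    theta: np.ndarray
    low_coverage: np.ndarray
    cap: float = DEFAULT_CAP

    @property
    def length(self) -> int:
        return self.theta.size - 1

    def scored_values(self, include_low_coverage: bool = False) -> np.ndarray:
        vals = self.theta[1:]
        if include_low_coverage:
            return vals
        return vals[~self.low_coverage[1:]]


def single_stranded_score(
    nai: StopProfile, dmso: StopProfile, cap: float = DEFAULT_CAP
) -> SSProfile:
    """Score every nucleotide of a gene from its pooled stop profiles."""
    if nai.gene_id != dmso.gene_id:
        raise ValueError(
            f"profiles cover different genes: {nai.gene_id!r} vs {dmso.gene_id!r}"
        )
    if nai.treatment != "NAI" or dmso.treatment != "DMSO":
        raise ValueError("expected an (NAI, DMSO) profile pair, in that order")
    k_dmso, k_nai = normalization_constants(
        dmso.library_total, nai.library_total
    )
    n_nai = k_nai * nai.counts.astype(float)
    n_dmso = k_dmso * dmso.counts.astype(float)
    theta = np.log2((n_nai + 1.0) / (n_dmso + 1.0) + 1.0)
    theta = np.minimum(theta, cap)
    theta[0] = np.nan
    low = (nai.counts == 0) & (dmso.counts == 0)
    return SSProfile(
        gene_id=nai.gene_id, theta=theta, low_coverage=low, cap=cap
    )


def gini(values: np.ndarray) -> float:
    """Gini index by the mean-absolute-difference definition.

    For non-negative values ``x_1..x_n`` this equals
    ``sum_ij |x_i - x_j| / (2 n^2 mean)``, computed via the sorted form.
    """
    x = np.sort(np.asarray(values, dtype=float))
    n = x.size
    if n == 0:
        raise ValueError("gini of an empty vector is undefined")
    total = x.sum()
    if total == 0:
        return 0.0
    ranks = np.arange(1, n + 1)
    return float((2.0 * (ranks * x).sum()) / (n * total) - (n + 1.0) / n)


def gene_summary(
    profile: SSProfile, include_low_coverage: bool = False
) -> tuple[float, float]:
    """Arithmetic mean and Gini index of a gene's scores."""
    vals = profile.scored_values(include_low_coverage)
    if vals.size < 2:
        raise ValueError(
            f"gene {profile.gene_id!r} has fewer than 2 scored nucleotides"
        )
    return float(vals.mean()), gini(vals)


def structural_similarity(a: SSProfile, b: SSProfile) -> float:
    """Pearson correlation of two score profiles over shared positions.

    Positions flagged low-coverage in either profile are excluded; returns
    NaN when either restricted profile has zero variance.
    """
    n = min(a.length, b.length)
    xa = a.theta[1 : n + 1]
    xb = b.theta[1 : n + 1]
    ok = ~(a.low_coverage[1 : n + 1] | b.low_coverage[1 : n + 1])
    xa, xb = xa[ok], xb[ok]
    if xa.size < 3:
        raise ValueError("need at least 3 shared scored positions")
    if np.ptp(xa) == 0 or np.ptp(xb) == 0:
        return float("nan")
    return float(stats.pearsonr(xa, xb).statistic)
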