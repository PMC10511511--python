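"""Statistics linking folding, R-loops and mutation rate.

Among-gene relationships use Spearman rank correlations of gene-level
summaries (structure prevalence as the negated mean or the Gini index of
the single-stranded score).  The R-loop-mediated share of the antimutator
association is ``1 - rho_partial^2 / rho^2``, contrasting the
structure-mutation correlation with its first-order partial controlling
the R-loop score.

Within-gene relationships avoid gene-level confounders: each nucleotide
is dichotomized at its gene's mean for each pair of variables, the 2x2
counts get a +1 pseudocount, per-gene odds ratios are combined by the
Mantel-Haenszel estimator and tested by the Cochran-Mantel-Haenszel
chi-squared statistic (no continuity correction), with a gene-bootstrap
standard deviation.  A permutation null shuffles each variable within
each gene independently and recomputes the mean within-gene Spearman
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "gene_level_correlations",
    "partial_spearman",
    "mediated_fraction",
    "within_gene_or",
    "mh_combine",
    "permutation_null",
    "MHResult",
    "PermutationResult",
    "WITHIN_GENE_PAIRS",
]

# (x, y, expected sign under the competitive-inhibition model); x/y name
# columns of the site table, with "neg_theta" meaning the negated
# single-stranded score (structure prevalence).
WITHIN_GENE_PAIRS = (
    ("neg_theta", "rloop", -1),
    ("rloop", "rate", +1),
    ("neg_theta", "rate", -1),
)


def gene_level_correlations(
    gene_table: pd.DataFrame,
    pairs: tuple[tuple[str, str], ...] = (
        ("neg_mean_theta", "rloop"),
        ("gini_theta", "rloop"),
        ("rloop", "rate"),
        ("neg_mean_theta", "rate"),
        ("gini_theta", "rate"),
    ),
) -> pd.DataFrame:
    """Spearman rho (with two-sided p) across genes for each column pair."""
    if len(gene_table) < 10:
        raise ValueError("need at least 10 genes for among-gene correlations")
    rows = []
    for x, y in pairs:
        sub = gene_table[[x, y]].dropna()
        if sub[x].nunique() <= 1 or sub[y].nunique() <= 1:
            rows.append({"x": x, "y": y, "rho": np.nan, "p": np.nan, "n": len(sub)})
            continue
        res = stats.spearmanr(sub[x], sub[y])
        rows.append(
            {"x": x, "y": y, "rho": float(res.statistic), "p": float(res.pvalue), "n": len(sub)}
        )
    return pd.DataFrame(rows)


def partial_spearman(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial Spearman correlation of x and y controlling z."""
    x, y, z = (np.asarray(v, dtype=float) for v in (x, y, z))
    ok = ~(np.isnan(x) | np.isnan(y) | np.isnan(z))
    x, y, z = x[ok], y[ok], z[ok]
    if x.size < 10:
        raise ValueError("need at least 10 complete triples")
    r_xy = stats.spearmanr(x, y).statistic
    r_xz = stats.spearmanr(x, z).statistic
    r_yz = stats.spearmanr(y, z).statistic
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    if denom <= 0:
        return float("nan")
    return float((r_xy - r_xz * r_yz) / np.sqrt(denom))


def mediated_fraction(rho: float, rho_partial: float) -> float:
    """Fraction of an association removed by controlling the mediator.

    ``1 - rho_partial^2 / rho^2``; lies in [0, 1] whenever
    ``|rho_partial| <= |rho|`` and is reported as-is (negative) otherwise
    so the caller can flag a non-mediating control variable.
    """
    if rho == 0:
        raise ValueError("mediated fraction is undefined for rho = 0")
    return 1.0 - rho_partial**2 / rho**2


def within_gene_or(
    site_table: pd.DataFrame,
    var1: str,
    var2: str,
    pseudocount: float = 1.0,
    min_sites: int = 4,
) -> pd.DataFrame:
    """Per-gene pseudocounted 2x2 tables for two site-level variables.

    Each nucleotide is classified by whether ``var1`` (question i) and
    ``var2`` (question ii) exceed their within-gene means (ties go low):
    a = yes/yes, b = yes/no, c = no/yes, d = no/no, each + pseudocount.
    Genes with fewer than ``min_sites`` complete sites are skipped.
    """
    rows = []
    for gene_id, grp in site_table.groupby("gene_id", sort=True):
        sub = grp[[var1, var2]].dropna()
        if len(sub) < min_sites:
            continue
        hi1 = sub[var1].to_numpy() > sub[var1].mean()
        hi2 = sub[var2].to_numpy() > sub[var2].mean()
        a = float((hi1 & hi2).sum()) + pseudocount
        b = float((hi1 & ~hi2).sum()) + pseudocount
        c = float((~hi1 & hi2).sum()) + pseudocount
        d = float((~hi1 & ~hi2).sum()) + pseudocount
        rows.append(
            {"gene_id": gene_id, "a": a, "b": b, "c": c, "d": d, "or": a * d / (b * c)}
        )
    return pd.DataFrame(rows, columns=["gene_id", "a", "b", "c", "d", "or"])


@dataclass
class MHResult:
    odds_ratio: float
    chi2: float
    p: float
    bootstrap_sd: float
    n_genes: int
    seed: int


def _mh_or(t: pd.DataFrame) -> float:
    n = t["a"] + t["b"] + t["c"] + t["d"]
    return float((t["a"] * t["d"] / n).sum() / (t["b"] * t["c"] / n).sum())


def mh_combine(
    tables: pd.DataFrame, n_boot: int = 1000, seed: int = 0
) -> MHResult:
    """Mantel-Haenszel common odds ratio, CMH test and bootstrap s.d.

    ``tables`` is the output of :func:`within_gene_or` (one stratum per
    gene).  The chi-squared statistic uses no continuity correction; the
    standard deviation comes from resampling genes with replacement
    ``n_boot`` times.
    """
    if len(tables) < 1:
        raise ValueError("need at least one 2x2 table")
    a, b, c, d = (tables[k].to_numpy(dtype=float) for k in "abcd")
    n = a + b + c + d
    expect_a = (a + b) * (a + c) / n
    var_a = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1.0))
    chi2 = (a.sum() - expect_a.sum()) ** 2 / var_a.sum()
    p = float(stats.chi2.sf(chi2, df=1))

    rng = np.random.default_rng(seed)
    n_genes = len(tables)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n_genes, size=n_genes)
        boots[i] = _mh_or(tables.iloc[idx])
    return MHResult(
        odds_ratio=_mh_or(tables),
        chi2=float(chi2),
        p=p,
        bootstrap_sd=float(boots.std(ddof=1)),
        n_genes=n_genes,
        seed=seed,
    )


@dataclass
class PermutationResult:
    observed: dict[str, float]
    null: dict[str, np.ndarray]
    p: dict[str, float]
    n_perm: int
    seed: int


def _rank(v: np.ndarray) -> np.ndarray:
    return stats.rankdata(v)


def permutation_null(
    site_table: pd.DataFrame,
    pairs: tuple[tuple[str, str, int], ...] = WITHIN_GENE_PAIRS,
    n_perm: int = 1000,
    seed: int = 0,
    min_sites: int = 5,
) -> PermutationResult:
    """Within-gene permutation null for mean within-gene correlations.

    The observed statistic for a pair is the mean over genes of the
    within-gene Spearman correlation.  Each permutation independently
    shuffles every involved variable within every gene and recomputes all
    pair means jointly.  Empirical p uses the +1 correction, one-sided in
    the direction of each pair's expected sign.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be positive")
    variables = sorted({v for x, y, _ in pairs for v in (x, y)})
    rng = np.random.default_rng(seed)

    obs_sums = {f"{x}~{y}": 0.0 for x, y, _ in pairs}
    null_sums = {f"{x}~{y}": np.zeros(n_perm) for x, y, _ in pairs}
    n_genes_used = 0
    for _, grp in site_table.groupby("gene_id", sort=True):
        sub = grp[variables].dropna()
        n = len(sub)
        if n < min_sites:
            continue
        n_genes_used += 1
        ranks = {v: _rank(sub[v].to_numpy()) for v in variables}
        # moments of a rank vector are permutation-invariant
        mean = {v: ranks[v].mean() for v in variables}
        sd = {v: ranks[v].std() for v in variables}
        perms = {
            v: ranks[v][np.argsort(rng.random((n_perm, n)), axis=1)]
            for v in variables
        }
        for x, y, _ in pairs:
            key = f"{x}~{y}"
            if sd[x] == 0 or sd[y] == 0:
                continue
            obs = ((ranks[x] * ranks[y]).mean() - mean[x] * mean[y]) / (
                sd[x] * sd[y]
            )
            obs_sums[key] += obs
            null = (
                (perms[x] * perms[y]).mean(axis=1) - mean[x] * mean[y]
            ) / (sd[x] * sd[y])
            null_sums[key] += null
    if n_genes_used == 0:
        raise ValueError("no gene has enough complete sites")

    observed = {k: v / n_genes_used for k, v in obs_sums.items()}
    null = {k: v / n_genes_used for k, v in null_sums.items()}
    pvals = {}
    for x, y, sign in pairs:
        key = f"{x}~{y}"
        if sign >= 0:
            extreme = (null[key] >= observed[key]).sum()
        else:
            extreme = (null[key] <= observed[key]).sum()
        pvals[key] = (1.0 + extreme) / (n_perm + 1.0)
    return PermutationResult(
        observed=observed, null=null, p=pvals, n_perm=n_perm, seed=seed
    )
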