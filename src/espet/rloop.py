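"""R-loop scores from DRIP-style and input coverage.

For a site with ``n`` reads whose 5'-most nucleotide maps to it, out of a
track total of ``m``, define ``x = log2((n + 1) / m)``.  The R-loop score
of the site is ``x`` from the immunoprecipitated (wild-type DRIP) track
minus ``x`` from the input-chromatin track; a positive score marks
R-loop-enriched sites.  Sites with no coverage in either track keep the
formula's value rather than becoming missing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["rloop_score", "rloop_scores_frame", "gene_rloop_scores"]


def rloop_score(
    wt_counts: np.ndarray,
    input_counts: np.ndarray,
    wt_total: float | None = None,
    input_total: float | None = None,
) -> np.ndarray:
    """Per-site R-loop score for aligned coverage vectors.

    Totals default to the sums of the supplied vectors; pass explicit
    (genome-wide) totals when scoring a subset of sites.
    """
    wt = np.asarray(wt_counts, dtype=float)
    inp = np.asarray(input_counts, dtype=float)
    if wt.shape != inp.shape:
        raise ValueError("tracks must cover the same site universe")
    m_wt = float(wt.sum()) if wt_total is None else float(wt_total)
    m_inp = float(inp.sum()) if input_total is None else float(input_total)
    if m_wt <= 0 or m_inp <= 0:
        raise ValueError("both track totals must be positive")
    return np.log2((wt + 1.0) / m_wt) - np.log2((inp + 1.0) / m_inp)


def rloop_scores_frame(counts: pd.DataFrame) -> pd.DataFrame:
    """Score a (gene_id, pos, drip, input) coverage table site by site.

    Track totals are taken over the whole table, mirroring genome-wide
    normalization.
    """
    for col in ("gene_id", "pos", "drip", "input"):
        if col not in counts.columns:
            raise ValueError(f"coverage table is missing column {col!r}")
    out = counts[["gene_id", "pos"]].copy()
    out["rloop"] = rloop_score(
        counts["drip"].to_numpy(), counts["input"].to_numpy()
    )
    return out


def gene_rloop_scores(
    site_scores: pd.DataFrame, aggregator: str = "mean"
) -> pd.DataFrame:
    """Aggregate per-site scores to one score per gene (mean or median)."""
    if aggregator not in ("mean", "median"):
        raise ValueError("aggregator must be 'mean' or 'median'")
    agg = site_scores.groupby("gene_id")["rloop"].agg(aggregator)
    return agg.rename("rloop").reset_index()
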