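"""Read-pair filtering, deduplication and RT-stop counting.

Coordinates are 1-based, inclusive, gene-local sense-strand indices.  A
record's ``fwd5`` is the 5'-most mapped base of the forward read; the RT
stop it implies is the base immediately preceding it (``fwd5 - 1``), so a
record with ``fwd5 == 1`` contributes no stop.  ``txn_site`` is the
transcription site pinned by the reverse read, i.e. the length of the
transcriptional intermediate the pair came from.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "StopProfile",
    "IntermediateMatrix",
    "filter_and_dedup",
    "assign_rt_stops",
    "build_intermediate_matrix",
    "winsorize_row",
]

REQUIRED_COLUMNS = (
    "gene_id",
    "treatment",
    "fwd5",
    "txn_site",
    "umi",
    "mapq",
    "first_base_mismatch",
)

_DEDUP_KEY = ["gene_id", "treatment", "fwd5", "txn_site", "umi"]

MIN_MAPQ = 30


def _check_columns(records: pd.DataFrame) -> None:
    missing = [c for c in REQUIRED_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"pair table is missing columns: {missing}")


def filter_and_dedup(records: pd.DataFrame, min_mapq: int = MIN_MAPQ) -> pd.DataFrame:
    """Drop low-quality records and collapse PCR duplicates.

    Records with mapping quality below ``min_mapq`` or a mismatch at the
    first 5' base are discarded.  Among records sharing
    (gene, treatment, forward 5' position, transcription site, UMI) exactly
    one survives; the result is independent of input row order because the
    table is stably sorted on all columns before duplicates are collapsed.
    """
    _check_columns(records)
    keep = (records["mapq"] >= min_mapq) & (
        ~records["first_base_mismatch"].astype(bool)
    )
    out = records.loc[keep]
    out = out.sort_values(list(out.columns), kind="mergesort")
    out = out.drop_duplicates(subset=_DEDUP_KEY, keep="first")
    return out.reset_index(drop=True)


@dataclass
class StopProfile:
    """Per-gene, per-treatment RT-stop counts.

    ``counts`` is 1-based (index 0 unused).  ``library_total`` is the total
    number of retained records in the whole library for this treatment —
    the normalization denominator shared by all genes.
    """

    gene_id: str
    treatment: str
    counts: np.ndarray
    library_total: int

    @property
    def length(self) -> int:
        return self.counts.size - 1

    def mean_stops_per_nt(self) -> float:
        return float(self.counts[1:].sum()) / self.length


def assign_rt_stops(
    records: pd.DataFrame, gene_lengths: dict[str, int]
) -> dict[tuple[str, str], StopProfile]:
    """Tally RT stops per (gene, treatment) from filtered records.

    Each record increments position ``fwd5 - 1``; records with
    ``fwd5 == 1`` yield no stop but still count toward the library total
    (they are mapped reads).  Genes listed in ``gene_lengths`` but absent
    from the table get zero-count profiles so downstream scoring sees a
    complete gene universe.
    """
    _check_columns(records)
    treatments = ("NAI", "DMSO")
    totals = {
        t: int((records["treatment"] == t).sum()) for t in treatments
    }
    profiles: dict[tuple[str, str], StopProfile] = {
        (g, t): StopProfile(g, t, np.zeros(length + 1, dtype=np.int64), totals[t])
        for g, length in gene_lengths.items()
        for t in treatments
    }
    stops = records.loc[records["fwd5"] > 1]
    for (gene, treatment), grp in stops.groupby(
        ["gene_id", "treatment"], sort=False
    ):
        key = (gene, treatment)
        if key not in profiles:
            raise KeyError(f"gene {gene!r} not present in gene_lengths")
        np.add.at(profiles[key].counts, grp["fwd5"].to_numpy() - 1, 1)
    return profiles


def winsorize_row(
    values: np.ndarray, winsor: float = 0.90, scale: bool = False
) -> np.ndarray:
    """Two-sided winsorization of one intermediate's stop counts.

    Values are clipped at the ``(1 - winsor)/2`` and ``1 - (1 - winsor)/2``
    quantiles (5th/95th percentiles for the default 90% winsorization).
    With ``scale=True`` the clipped row is additionally rescaled so its
    maximum is 1 (a display convenience); longitudinal comparisons keep
    the unscaled values because a per-row scale factor depends on how
    many nucleotides the intermediate exposes and would imprint a
    spurious trend along the intermediate-length axis.
    """
    if not 0.0 < winsor <= 1.0:
        raise ValueError("winsor fraction must be in (0, 1]")
    tail = (1.0 - winsor) / 2.0
    lo, hi = np.quantile(values, [tail, 1.0 - tail])
    clipped = np.clip(values, lo, hi).astype(float)
    if scale:
        top = clipped.max()
        return clipped / top if top > 0 else clipped
    return clipped


@dataclass
class IntermediateMatrix:
    """Per-gene RT-stop densities indexed by (intermediate length, nucleotide).

    ``raw[L, i]`` counts NAI-treatment RT stops at nucleotide ``i`` among
    read pairs whose transcription site is ``L``; ``density`` is the raw
    row winsorized (clipped within the row's winsorization bounds).
    Entries with ``i > L - footprint`` (inside the elongation-complex
    footprint) are NaN in ``density``.
    """

    gene_id: str
    length: int
    footprint: int
    raw: np.ndarray
    density: np.ndarray

    def exposed(self, L: int, i: int) -> bool:
        return 1 <= i <= L - self.footprint <= self.length - self.footprint


def build_intermediate_matrix(
    records: pd.DataFrame,
    gene_id: str,
    gene_length: int,
    footprint: int = 18,
    winsor: float = 0.90,
    winsor_on: str = "counts",
    scale: bool = False,
) -> IntermediateMatrix:
    """Bin NAI RT stops by transcriptional intermediate and winsorize rows.

    ``winsor_on`` selects whether rows are winsorized as raw counts
    (default) or as within-row fractions (counts divided by the row
    total).  ``scale`` additionally max-scales each row to [0, 1] for
    display; it is off by default because the scale factor of a row
    depends on its exposed-position count (see :func:`winsorize_row`).
    """
    _check_columns(records)
    sub = records.loc[
        (records["gene_id"] == gene_id) & (records["treatment"] == "NAI")
    ]
    raw = np.zeros((gene_length + 1, gene_length + 1))
    stops = sub.loc[sub["fwd5"] > 1]
    np.add.at(
        raw,
        (
            stops["txn_site"].astype(np.int64).to_numpy(),
            stops["fwd5"].astype(np.int64).to_numpy() - 1,
        ),
        1.0,
    )

    density = np.full_like(raw, np.nan)
    for L in range(footprint + 1, gene_length + 1):
        row = raw[L, 1 : L - footprint + 1]
        if winsor_on == "fraction":
            total = row.sum()
            row = row / total if total > 0 else row
        elif winsor_on != "counts":
            raise ValueError("winsor_on must be 'counts' or 'fraction'")
        density[L, 1 : L - footprint + 1] = winsorize_row(row, winsor, scale=scale)
    if sub.empty:
        import warnings

        warnings.warn(f"gene {gene_id!r} has no NAI records", stacklevel=2)
    return IntermediateMatrix(
        gene_id=gene_id,
        length=gene_length,
        footprint=footprint,
        raw=raw,
        density=density,
    )
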