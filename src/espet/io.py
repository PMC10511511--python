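"""Readers and writers for the pipeline's plain-text formats.

All tables are tab-separated with a header line; gzip compression is
transparent (pandas infers it from a ``.gz`` suffix).  Trees travel as
Newick, genotype matrices as site-by-tip TSV with A/C/G/T characters.
Malformed rows are reported with their 1-based line numbers.
"""

from __future__ import annotations

import json
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .reads import REQUIRED_COLUMNS

__all__ = [
    "read_pair_table",
    "write_pair_table",
    "read_coverage",
    "write_coverage",
    "read_newick",
    "write_newick",
    "read_genotype_matrix",
    "write_genotype_matrix",
    "read_gene_table",
    "write_gene_table",
    "write_score_track",
    "read_score_track",
    "write_results_json",
]

_PAIR_DTYPES = {
    "gene_id": str,
    "treatment": str,
    "fwd5": np.int64,
    "txn_site": np.int64,
    "umi": str,
    "mapq": np.int64,
    "first_base_mismatch": bool,
}


class ParseError(ValueError):
    """A malformed record, carrying the offending line number."""

    def __init__(self, path: str | Path, line: int, message: str):
        super().__init__(f"{path}:{line}: {message}")
        self.path = str(path)
        self.line = line


def read_pair_table(path: str | Path) -> pd.DataFrame:
    """Read the canonical pair-table TSV and validate every record."""
    df = pd.read_csv(path, sep="\t", dtype={"umi": str, "gene_id": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(path, 1, f"missing columns {missing}")
    df["first_base_mismatch"] = df["first_base_mismatch"].astype(bool)
    bad = ~(
        (df["fwd5"] >= 1)
        & (df["fwd5"] <= df["txn_site"])
        & (df["umi"].str.len() == 3)
        & (df["treatment"].isin(["NAI", "DMSO"]))
    )
    if bad.any():
        line = int(df.index[bad][0]) + 2  # +1 header, +1 one-based
        raise ParseError(path, line, "invalid pair record")
    return df[list(REQUIRED_COLUMNS)]


def write_pair_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(REQUIRED_COLUMNS)].to_csv(path, sep="\t", index=False)


def read_coverage(path: str | Path) -> pd.DataFrame:
    """BED-like per-site DRIP/input coverage: gene_id, pos, drip, input."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "pos", "drip", "input"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing column {col!r}")
    bad = (df["pos"] < 1) | (df["drip"] < 0) | (df["input"] < 0)
    if bad.any():
        raise ParseError(path, int(df.index[bad][0]) + 2, "invalid coverage record")
    return df


def write_coverage(df: pd.DataFrame, path: str | Path) -> None:
    df[["gene_id", "pos", "drip", "input"]].to_csv(path, sep="\t", index=False)


def read_newick(path: str | Path) -> dendropy.Tree:
    """Read a rooted Newick tree, rejecting non-positive branch lengths."""
    tree = dendropy.Tree.get(
        path=str(path), schema="newick", preserve_underscores=True
    )
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            continue
        if nd.edge.length is None or nd.edge.length <= 0:
            raise ValueError(
                f"{path}: branch above {nd.taxon.label if nd.taxon else 'internal node'} "
                f"has non-positive length {nd.edge.length!r}"
            )
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_genotype_matrix(path: str | Path) -> tuple[pd.DataFrame, np.ndarray, list[str]]:
    """Read a site-by-tip genotype TSV.

    Returns (sites, genotypes, tip_labels): identifier columns
    (gene_id, pos), an (n_sites, n_tips) array of A/C/G/T characters and
    the tip labels in column order.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "pos"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing column {col!r}")
    tips = [c for c in df.columns if c not in ("gene_id", "pos")]
    geno = df[tips].to_numpy(dtype="U1")
    valid = np.isin(geno, list("ACGT"))
    if not valid.all():
        row = int(np.flatnonzero(~valid.all(axis=1))[0])
        raise ParseError(path, row + 2, "genotype other than A/C/G/T")
    sites = df[["gene_id", "pos"]].copy()
    sites["pos"] = sites["pos"].astype(int)
    return sites, geno, tips


def write_genotype_matrix(
    sites: pd.DataFrame, genotypes: np.ndarray, tips: list[str], path: str | Path
) -> None:
    out = pd.DataFrame(np.asarray(genotypes, dtype="U1"), columns=tips)
    out.insert(0, "gene_id", sites["gene_id"].to_numpy())
    out.insert(1, "pos", sites["pos"].to_numpy())
    out.to_csv(path, sep="\t", index=False)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Gene annotation: gene_id, length, and optionally strand."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    for col in ("gene_id", "length"):
        if col not in df.columns:
            raise ParseError(path, 1, f"missing column {col!r}")
    if (df["length"] <= 0).any():
        bad = df.index[df["length"] <= 0][0]
        raise ParseError(path, int(bad) + 2, "non-positive gene length")
    return df


def write_gene_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_score_track(df: pd.DataFrame, path: str | Path) -> None:
    """bedGraph-like per-site track (gene_id, pos, value columns)."""
    df.to_csv(path, sep="\t", index=False)


def read_score_track(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gene_id": str})


def write_results_json(results: dict, path: str | Path) -> None:
    def _default(obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        raise TypeError(f"not JSON-serializable: {type(obj)}")

    Path(path).write_text(json.dumps(results, indent=2, default=_default))
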