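"""End-to-end orchestration: stops -> scores -> R-loop -> rates -> statistics.

:func:`analyze` runs the full analysis on in-memory inputs and returns an
:class:`AnalysisResult`; :func:`run_pipeline` is the file-based wrapper
used by the command-line interface, reading the canonical text formats
and writing result tables plus a reproducibility manifest (package
version, parameters, seeds, input checksums).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from . import io as eio
from .correspondence import (
    WITHIN_GENE_PAIRS,
    MHResult,
    PermutationResult,
    gene_level_correlations,
    mediated_fraction,
    mh_combine,
    partial_spearman,
    permutation_null,
    within_gene_or,
)
from .mutation_rate import TreeIndex, site_rates
from .reads import assign_rt_stops, build_intermediate_matrix, filter_and_dedup
from .rloop import gene_rloop_scores, rloop_scores_frame
from .scores import SSProfile, gene_summary, single_stranded_score
from .selection import SelectionParams, fold_reduction, selection_coefficient
from .transitions import transition_fraction

__all__ = ["AnalysisParams", "AnalysisResult", "analyze", "run_pipeline"]


@dataclass(frozen=True)
class AnalysisParams:
    """Tunable thresholds of the analysis stages."""

    footprint: int = 18
    winsor: float = 0.90
    cap: float = 7.0
    window: int = 50
    alpha: float = 0.05
    pseudocount: float = 1.0
    min_stops_per_nt: float = 1.0  # gene coverage filter
    sel_window: int = 50
    sel_min_frac: float = 0.05
    sel_cap: float = 50.0
    n_perm: int = 1000
    n_boot: int = 1000
    seed: int = 0
    run_transitions: bool = False


@dataclass
class AnalysisResult:
    params: AnalysisParams
    ss_profiles: dict[str, SSProfile]
    covered_genes: list[str]
    site_table: pd.DataFrame
    gene_table: pd.DataFrame
    gene_correlations: pd.DataFrame
    mediation: dict[str, dict[str, float]]
    or_tables: dict[str, pd.DataFrame]
    mh: dict[str, MHResult]
    permutation: PermutationResult
    fold_reductions: pd.DataFrame
    transition_fractions: pd.DataFrame | None = None
    selection_params: SelectionParams = field(default_factory=SelectionParams)


def _site_frame(
    profiles: dict[str, SSProfile],
    covered: set[str],
    footprint: int,
) -> pd.DataFrame:
    rows = []
    for gene_id, prof in profiles.items():
        n_scoreable = prof.length - footprint
        pos = np.arange(1, n_scoreable + 1)
        theta = prof.theta[pos].copy()
        theta[prof.low_coverage[pos]] = np.nan
        if gene_id not in covered:
            theta[:] = np.nan
        rows.append(pd.DataFrame({"gene_id": gene_id, "pos": pos, "theta": theta}))
    return pd.concat(rows, ignore_index=True)


def analyze(
    reads: pd.DataFrame,
    rloop_counts: pd.DataFrame,
    tree: dendropy.Tree,
    genotypes: np.ndarray,
    tip_labels: list[str],
    sites: pd.DataFrame,
    gene_lengths: dict[str, int],
    params: AnalysisParams = AnalysisParams(),
) -> AnalysisResult:
    """Run every analysis stage on in-memory inputs.

    ``sites`` aligns the rows of ``genotypes`` with (gene_id, pos).
    Stage order: read filtering and stop assignment; per-gene
    single-stranded scores (genes failing the coverage filter of
    ``min_stops_per_nt`` average RT stops are masked from all
    structure-based statistics); per-site R-loop scores; per-site
    phylogenetic mutation rates; then the among-gene correlations,
    mediation fractions, within-gene odds ratios with Mantel-Haenszel
    combination, the within-gene permutation null, and per-gene
    fold-reduction/selection estimates.
    """
    filtered = filter_and_dedup(reads)
    if filtered.empty:
        raise ValueError("no read pairs survive filtering")
    profiles = assign_rt_stops(filtered, gene_lengths)

    ss: dict[str, SSProfile] = {}
    covered: set[str] = set()
    for gene_id in gene_lengths:
        nai = profiles[(gene_id, "NAI")]
        dmso = profiles[(gene_id, "DMSO")]
        ss[gene_id] = single_stranded_score(nai, dmso, cap=params.cap)
        if nai.mean_stops_per_nt() >= params.min_stops_per_nt:
            covered.add(gene_id)

    site_table = _site_frame(ss, covered, params.footprint)
    site_scores = rloop_scores_frame(rloop_counts)
    site_table = site_table.merge(site_scores, on=["gene_id", "pos"], how="left")

    rates = site_rates(tree, genotypes, tip_labels, sites=sites)
    rate_cols = rates[["gene_id", "pos", "rate", "segregating", "flagged"]]
    site_table = site_table.merge(rate_cols, on=["gene_id", "pos"], how="left")
    site_table["neg_theta"] = -site_table["theta"]

    gene_rows = []
    for gene_id in sorted(gene_lengths):
        row: dict[str, float | str] = {"gene_id": gene_id}
        if gene_id in covered:
            mean_t, gini_t = gene_summary(ss[gene_id])
            row["neg_mean_theta"] = -mean_t
            row["gini_theta"] = gini_t
        else:
            row["neg_mean_theta"] = np.nan
            row["gini_theta"] = np.nan
        gene_rows.append(row)
    gene_table = pd.DataFrame(gene_rows)
    gene_table = gene_table.merge(
        gene_rloop_scores(site_scores), on="gene_id", how="left"
    )
    gene_rates = (
        site_table.groupby("gene_id")["rate"].mean().rename("rate").reset_index()
    )
    gene_table = gene_table.merge(gene_rates, on="gene_id", how="left")

    gene_corr = gene_level_correlations(gene_table)

    mediation: dict[str, dict[str, float]] = {}
    for metric in ("neg_mean_theta", "gini_theta"):
        sub = gene_table[[metric, "rate", "rloop"]].dropna()
        rho = gene_corr.loc[
            (gene_corr["x"] == metric) & (gene_corr["y"] == "rate"), "rho"
        ].iloc[0]
        rho_part = partial_spearman(sub[metric], sub["rate"], sub["rloop"])
        mediation[metric] = {
            "rho": float(rho),
            "rho_partial": float(rho_part),
            "mediated_fraction": mediated_fraction(rho, rho_part),
        }

    or_tables: dict[str, pd.DataFrame] = {}
    mh: dict[str, MHResult] = {}
    for x, y, _ in WITHIN_GENE_PAIRS:
        # within-gene ORs dichotomize the single-stranded score itself
        var1 = "theta" if x == "neg_theta" else x
        key = f"{var1}~{y}"
        tables = within_gene_or(
            site_table, var1, y, pseudocount=params.pseudocount
        )
        or_tables[key] = tables
        mh[key] = mh_combine(tables, n_boot=params.n_boot, seed=params.seed)

    permutation = permutation_null(
        site_table, n_perm=params.n_perm, seed=params.seed
    )

    sel_params = SelectionParams()
    fr_rows = []
    for gene_id in sorted(covered):
        length = gene_lengths[gene_id]
        theta = ss[gene_id].theta.copy()
        theta[ss[gene_id].low_coverage] = np.nan
        rate_vec = np.full(length + 1, np.nan)
        sub = site_table.loc[site_table["gene_id"] == gene_id]
        rate_vec[sub["pos"].to_numpy()] = sub["rate"].to_numpy()
        fr = fold_reduction(
            theta,
            rate_vec,
            gene_id=gene_id,
            window=params.sel_window,
            min_frac=params.sel_min_frac,
            cap=params.sel_cap,
        )
        if fr is not None:
            fr_rows.append(
                {
                    "gene_id": gene_id,
                    "x": fr.x,
                    "capped": fr.capped,
                    "s": selection_coefficient(fr.x, sel_params),
                }
            )
    fold_reductions = pd.DataFrame(fr_rows, columns=["gene_id", "x", "capped", "s"])

    trans_frac = None
    if params.run_transitions:
        tf_rows = []
        for gene_id in sorted(covered):
            matrix = build_intermediate_matrix(
                filtered,
                gene_id,
                gene_lengths[gene_id],
                footprint=params.footprint,
                winsor=params.winsor,
            )
            res = transition_fraction(
                matrix, window=params.window, alpha=params.alpha
            )
            tf_rows.append(
                {
                    "gene_id": gene_id,
                    "fraction": res.fraction,
                    "n_informative": res.n_informative,
                }
            )
        trans_frac = pd.DataFrame(tf_rows)

    return AnalysisResult(
        params=params,
        ss_profiles=ss,
        covered_genes=sorted(covered),
        site_table=site_table,
        gene_table=gene_table,
        gene_correlations=gene_corr,
        mediation=mediation,
        or_tables=or_tables,
        mh=mh,
        permutation=permutation,
        fold_reductions=fold_reductions,
        transition_fractions=trans_frac,
        selection_params=sel_params,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(
    pair_table: str | Path,
    coverage: str | Path,
    newick: str | Path,
    genotype_matrix: str | Path,
    gene_table: str | Path,
    outdir: str | Path,
    params: AnalysisParams = AnalysisParams(),
) -> AnalysisResult:
    """File-based pipeline: read canonical inputs, analyze, write results."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    inputs = {
        "pair_table": Path(pair_table),
        "coverage": Path(coverage),
        "newick": Path(newick),
        "genotype_matrix": Path(genotype_matrix),
        "gene_table": Path(gene_table),
    }
    for name, path in inputs.items():
        if not path.exists():
            raise FileNotFoundError(f"{name} input does not exist: {path}")
        if path.stat().st_size == 0:
            raise ValueError(f"{name} input is empty: {path}")

    reads = eio.read_pair_table(inputs["pair_table"])
    if reads.empty:
        raise ValueError(f"pair table has no records: {inputs['pair_table']}")
    cov = eio.read_coverage(inputs["coverage"])
    tree = eio.read_newick(inputs["newick"])
    sites, geno, tips = eio.read_genotype_matrix(inputs["genotype_matrix"])
    genes = eio.read_gene_table(inputs["gene_table"])
    gene_lengths = dict(zip(genes["gene_id"], genes["length"].astype(int)))

    result = analyze(
        reads, cov, tree, geno, tips, sites, gene_lengths, params=params
    )

    eio.write_score_track(result.site_table, outdir / "site_table.tsv")
    eio.write_gene_table(result.gene_table, outdir / "gene_table.tsv")
    result.gene_correlations.to_csv(
        outdir / "gene_correlations.tsv", sep="\t", index=False
    )
    result.fold_reductions.to_csv(
        outdir / "fold_reductions.tsv", sep="\t", index=False
    )
    if result.transition_fractions is not None:
        result.transition_fractions.to_csv(
            outdir / "transition_fractions.tsv", sep="\t", index=False
        )
    summary = {
        "mediation": result.mediation,
        "mantel_haenszel": {
            k: {
                "odds_ratio": v.odds_ratio,
                "chi2": v.chi2,
                "p": v.p,
                "bootstrap_sd": v.bootstrap_sd,
                "n_genes": v.n_genes,
                "seed": v.seed,
            }
            for k, v in result.mh.items()
        },
        "permutation": {
            "observed": result.permutation.observed,
            "p": result.permutation.p,
            "n_perm": result.permutation.n_perm,
            "seed": result.permutation.seed,
        },
    }
    eio.write_results_json(summary, outdir / "results.json")

    from . import __version__

    manifest = {
        "version": __version__,
        "params": asdict(params),
        "inputs": {k: {"path": str(v), "sha256": _sha256(v)} for k, v in inputs.items()},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return result
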