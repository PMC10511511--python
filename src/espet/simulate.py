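"""Synthetic data generator with planted ground truth.

Emulates the full input bundle of the analysis pipeline: per-nucleotide
unpairedness trajectories across transcript intermediates (with planted
cotranscriptional structural transitions), paired-end structure-probing
read tables (NAI-N3 treatment versus DMSO background), DRIP-style R-loop
coverage anticorrelated with folding, and a phylogeny on which per-site
Poisson mutation counts are planted with rates coupled to folding and
R-loop propensity.

Every stochastic draw flows through a single :class:`numpy.random.Generator`
so that a configuration plus a seed fixes the whole bundle bit-for-bit.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

__all__ = [
    "SimConfig",
    "FoldingTruth",
    "PhyloSim",
    "simulate_genes",
    "simulate_espet_reads",
    "planted_site_table",
    "simulate_rloop_counts",
    "simulate_phylogeny_and_mutations",
    "simulate_bundle",
    "SimulationBundle",
]

BASES = np.array(["A", "C", "G", "T"])

NAI = "NAI"
DMSO = "DMSO"


class ConfigurationError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic bundle.

    Parameters
    ----------
    n_genes:
        Number of simulated genes.
    gene_length_range:
        Inclusive (min, max) gene length in nucleotides.
    depth:
        Sequenced read pairs per nucleotide per treatment; the number of
        records per gene and treatment is exactly ``round(depth * length)``.
    background_stop_rate:
        Per-nucleotide weight of chemistry-independent RT stops (the DMSO
        control samples only this component).
    nai_multiplier:
        Weight added per unit of unpairedness in the NAI-N3 treatment, so
        the stop weight at an exposed nucleotide is
        ``background_stop_rate + nai_multiplier * unpaired``.
    footprint:
        Number of 3'-terminal nucleotides hidden inside the elongation
        complex; no RT stop can be sampled there (default 18).
    transition_fraction / transitions_per_gene:
        How many nucleotides per gene carry a planted step change in
        unpairedness along the intermediate-length axis.
        ``transitions_per_gene`` overrides the fraction when set.
    transition_effect:
        Minimum absolute difference in unpairedness before/after a planted
        transition.
    rloop_coupling:
        Slope of the natural-log DRIP intensity on per-site foldedness
        (1 - mean unpairedness); negative means folded sites form fewer
        R-loops, the direction of the competitive-inhibition model.
    drip_depth / input_depth:
        Mean Poisson counts per site in the DRIP and input tracks.
    mu_mean:
        Mean planted per-site mutation count over the whole phylogeny.
    mu_fold_coupling / mu_rloop_coupling:
        Slopes of the log mutation rate on centred foldedness and on the
        centred planted R-loop log-intensity.  The defaults plant the
        antimutator model: folded sites mutate less, R-loop-rich sites
        mutate more.
    n_tips:
        Number of strains (tree tips); the published analysis used a
        190-strain population phylogeny.
    birth_rate:
        Yule (pure-birth) speciation rate for the simulated phylogeny.
    contaminant_fraction:
        Fraction of records given a mapping quality below 30.
    mismatch_fraction:
        Fraction of records flagged as having a first-base mismatch.
    seed:
        Seed for all stochastic draws.
    """

    n_genes: int = 200
    gene_length_range: tuple[int, int] = (100, 160)
    depth: float = 30.0
    background_stop_rate: float = 0.05
    nai_multiplier: float = 1.0
    footprint: int = 18
    transition_fraction: float = 0.2
    transitions_per_gene: int | None = None
    transition_effect: float = 0.8
    rloop_coupling: float = -2.0
    drip_depth: float = 8.0
    input_depth: float = 8.0
    mu_mean: float = 1.0
    mu_fold_coupling: float = -1.5
    mu_rloop_coupling: float = 1.0
    n_tips: int = 190
    birth_rate: float = 1.0
    contaminant_fraction: float = 0.02
    mismatch_fraction: float = 0.01
    intermediate_length_dist: str = "weight"
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.gene_length_range
        if self.n_genes < 0:
            raise ConfigurationError("n_genes must be non-negative")
        if lo <= 0 or hi < lo:
            raise ConfigurationError(
                f"invalid gene_length_range {self.gene_length_range!r}"
            )
        if lo <= self.footprint:
            raise ConfigurationError(
                "gene length must exceed the footprint; got "
                f"min length {lo} with footprint {self.footprint}"
            )
        for name in (
            "depth",
            "background_stop_rate",
            "nai_multiplier",
            "drip_depth",
            "input_depth",
            "mu_mean",
            "birth_rate",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if not 0.0 <= self.transition_fraction <= 1.0:
            raise ConfigurationError("transition_fraction must be in [0, 1]")
        if not 0.0 < self.transition_effect <= 1.0:
            raise ConfigurationError("transition_effect must be in (0, 1]")
        if self.intermediate_length_dist not in ("weight", "uniform"):
            raise ConfigurationError(
                "intermediate_length_dist must be 'weight' or 'uniform'"
            )

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass
class FoldingTruth:
    """Planted folding state of one gene across transcript intermediates.

    ``unpaired[L, i]`` is the probability that nucleotide ``i`` (1-based)
    is unpaired when the intermediate has length ``L``; it is defined only
    for ``1 <= i <= L - footprint`` and is NaN elsewhere (row/column 0 are
    padding so indices match gene coordinates).
    """

    gene_id: str
    length: int
    footprint: int
    unpaired: np.ndarray
    transition_sites: list[tuple[int, int]] = field(default_factory=list)

    @property
    def n_scoreable(self) -> int:
        """Nucleotides ever exposed outside the polymerase footprint."""
        return self.length - self.footprint

    def mean_unpaired(self) -> np.ndarray:
        """Per-site unpairedness averaged over the intermediates exposing it.

        Returns a 1-based array of length ``length + 1``; positions inside
        the terminal footprint (never exposed) are NaN.
        """
        defined = ~np.isnan(self.unpaired)
        counts = defined.sum(axis=0)
        sums = np.where(defined, self.unpaired, 0.0).sum(axis=0)
        out = np.divide(
            sums, counts, out=np.full(counts.shape, np.nan), where=counts > 0
        )
        out[0] = np.nan
        return out


def _smooth_unpaired_profile(
    rng: np.random.Generator, length: int, window: int = 15, gain: float = 2.0
) -> np.ndarray:
    """Autocorrelated base unpairedness: a moving-average Gaussian field
    squashed through a sigmoid, mimicking alternating stems and loops."""
    z = rng.normal(size=length + window - 1)
    s = np.convolve(z, np.ones(window) / window, mode="valid")
    s = (s - s.mean()) / (s.std() + 1e-12)
    return 1.0 / (1.0 + np.exp(-gain * s))


def simulate_genes(
    config: SimConfig, rng: np.random.Generator | None = None
) -> list[FoldingTruth]:
    """Draw per-gene folding truths with planted structural transitions."""
    config.validate()
    if rng is None:
        rng = config.rng()
    lo, hi = config.gene_length_range
    fp = config.footprint
    truths: list[FoldingTruth] = []
    for g in range(config.n_genes):
        length = int(rng.integers(lo, hi + 1))
        base = _smooth_unpaired_profile(rng, length)

        # how many planted transitions, and where they can go: both the
        # before- and after-change regimes need >= 25 observable
        # intermediate lengths so a 50-length window can straddle them
        n_scoreable = length - fp
        if config.transitions_per_gene is not None:
            n_trans = config.transitions_per_gene
        else:
            n_trans = int(round(config.transition_fraction * n_scoreable))
        eligible = np.arange(1, max(length - fp - 50, 0) + 1)
        n_trans = min(n_trans, eligible.size)
        trans_idx = (
            rng.choice(eligible, size=n_trans, replace=False)
            if n_trans
            else np.array([], dtype=int)
        )

        unpaired = np.full((length + 1, length + 1), np.nan)
        for L in range(fp + 1, length + 1):
            unpaired[L, 1 : L - fp + 1] = base[: L - fp]

        transitions: list[tuple[int, int]] = []
        for i in sorted(int(i) for i in trans_idx):
            L_star = int(rng.integers(i + fp + 25, length - 25 + 1))
            low = rng.uniform(0.05, min(0.15, 1.0 - config.transition_effect))
            high = low + config.transition_effect
            before, after = (low, high) if rng.random() < 0.5 else (high, low)
            Ls = np.arange(i + fp, length + 1)
            unpaired[Ls, i] = np.where(Ls < L_star, before, after)
            transitions.append((i, L_star))

        truths.append(
            FoldingTruth(
                gene_id=f"g{g + 1:04d}",
                length=length,
                footprint=fp,
                unpaired=unpaired,
                transition_sites=transitions,
            )
        )
    return truths


def _sample_stops(
    rng: np.random.Generator,
    weights: np.ndarray,
    intermediate_lengths: np.ndarray,
) -> np.ndarray:
    """Draw one stop position per read from per-intermediate weight rows.

    ``weights`` is a (length+1, length+1) matrix whose row ``L`` holds the
    stop weight for each exposed nucleotide of the intermediate of length
    ``L`` (zero where the nucleotide is hidden or out of range).
    """
    cum = np.cumsum(weights, axis=1)
    totals = cum[intermediate_lengths, -1]
    if np.any(totals <= 0):
        raise ConfigurationError(
            "an intermediate has zero total stop weight; "
            "increase background_stop_rate or unpairedness"
        )
    u = rng.random(intermediate_lengths.size) * totals
    # first column whose cumulative weight reaches u (column 0 has weight 0)
    return (cum[intermediate_lengths] < u[:, None]).sum(axis=1)


def _sample_cells(
    rng: np.random.Generator, weights: np.ndarray, n_reads: int
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (intermediate length, stop) pairs jointly ∝ cell weight."""
    total = weights.sum()
    if total <= 0:
        raise ConfigurationError(
            "total stop weight is zero; "
            "increase background_stop_rate or unpairedness"
        )
    flat = weights.ravel()
    cells = rng.choice(flat.size, size=n_reads, p=flat / total)
    L, stop = np.unravel_index(cells, weights.shape)
    return L, stop


def _random_umis(rng: np.random.Generator, n: int) -> np.ndarray:
    codes = rng.integers(0, 64, size=n)
    lut = np.array(
        ["".join((BASES[a], BASES[b], BASES[c]))
         for a in range(4) for b in range(4) for c in range(4)]
    )
    return lut[codes]


def simulate_espet_reads(
    truths: list[FoldingTruth],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    treatments: tuple[str, ...] = (NAI, DMSO),
) -> pd.DataFrame:
    """Sample a paired-read table for both treatments.

    Every record carries a transcription site (the intermediate length
    ``L``, pinned by the reverse read) and an RT stop whose forward-read
    5' end is one base 3' of it.  NAI-N3 stop weight at an exposed
    nucleotide is ``background + multiplier * unpaired``; DMSO records
    sample the background component only.

    Under the default ``intermediate_length_dist="weight"`` the (L, stop)
    pair is drawn from the joint distribution proportional to the cell
    weight, i.e. each intermediate yields reads in proportion to its
    total stop propensity — the way a sequenced library samples reads.
    ``"uniform"`` instead draws L uniformly over all intermediate lengths
    and then the stop within it.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    fp = config.footprint
    frames: list[pd.DataFrame] = []
    for truth in truths:
        n_reads = int(round(config.depth * truth.length))
        if n_reads == 0:
            continue
        exposed = ~np.isnan(truth.unpaired)
        w_nai = (
            np.nan_to_num(truth.unpaired) * config.nai_multiplier
            + exposed * config.background_stop_rate
        )
        w_dmso = exposed * config.background_stop_rate
        for treatment, w in ((NAI, w_nai), (DMSO, w_dmso)):
            if treatment not in treatments:
                continue
            if config.intermediate_length_dist == "weight":
                L, stop = _sample_cells(rng, w, n_reads)
            else:
                L = rng.integers(fp + 1, truth.length + 1, size=n_reads)
                stop = _sample_stops(rng, w, L)
            mapq = np.full(n_reads, 42)
            contam = rng.random(n_reads) < config.contaminant_fraction
            mapq[contam] = rng.integers(0, 30, size=int(contam.sum()))
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": truth.gene_id,
                        "treatment": treatment,
                        "fwd5": stop + 1,
                        "txn_site": L,
                        "umi": _random_umis(rng, n_reads),
                        "mapq": mapq,
                        "first_base_mismatch": rng.random(n_reads)
                        < config.mismatch_fraction,
                    }
                )
            )
    if not frames:
        return pd.DataFrame(
            columns=[
                "gene_id",
                "treatment",
                "fwd5",
                "txn_site",
                "umi",
                "mapq",
                "first_base_mismatch",
            ]
        )
    return pd.concat(frames, ignore_index=True)


def planted_site_table(truths: list[FoldingTruth], config: SimConfig) -> pd.DataFrame:
    """Deterministic per-site ground truth used by the count samplers.

    Columns: gene_id, pos, unpaired (mean over intermediates), foldedness,
    drip_rate (Poisson mean of the DRIP track), rloop_lograte (centred log
    intensity, the latent R-loop propensity) and k_true (planted expected
    mutation count over the whole phylogeny).
    """
    config.validate()
    rows = []
    for truth in truths:
        u = truth.mean_unpaired()
        pos = np.arange(1, truth.n_scoreable + 1)
        rows.append(
            pd.DataFrame(
                {"gene_id": truth.gene_id, "pos": pos, "unpaired": u[pos]}
            )
        )
    table = pd.concat(rows, ignore_index=True)
    table["foldedness"] = 1.0 - table["unpaired"]

    log_g = config.rloop_coupling * table["foldedness"].to_numpy()
    log_g_c = log_g - log_g.mean()
    g = np.exp(log_g_c)
    table["drip_rate"] = config.drip_depth * g / g.mean()
    table["rloop_lograte"] = log_g_c

    fold_c = table["foldedness"] - table["foldedness"].mean()
    log_h = (
        config.mu_fold_coupling * fold_c.to_numpy()
        + config.mu_rloop_coupling * log_g_c
    )
    h = np.exp(log_h - log_h.mean())
    table["k_true"] = config.mu_mean * h / h.mean()
    return table


def simulate_rloop_counts(
    truths: list[FoldingTruth],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    planted: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Poisson DRIP and input counts per scoreable site.

    DRIP intensity decreases with gene foldedness through
    ``rloop_coupling``; the input track is uniform.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    if planted is None:
        planted = planted_site_table(truths, config)
    out = planted[["gene_id", "pos"]].copy()
    out["drip"] = rng.poisson(planted["drip_rate"].to_numpy())
    out["input"] = rng.poisson(config.input_depth, size=len(planted))
    return out


@dataclass
class PhyloSim:
    """Planted phylogeny, tip genotypes and per-site mutation truth."""

    tree: dendropy.Tree
    tip_labels: list[str]
    sites: pd.DataFrame  # gene_id, pos, k_true, n_mutations
    genotypes: np.ndarray  # (n_sites, n_tips) uint8 codes into BASES

    def genotype_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            BASES[self.genotypes], columns=self.tip_labels, copy=False
        )
        df.insert(0, "gene_id", self.sites["gene_id"].to_numpy())
        df.insert(1, "pos", self.sites["pos"].to_numpy())
        return df


def _yule_tree(config: SimConfig, rng: np.random.Generator) -> dendropy.Tree:
    if config.n_tips < 3:
        raise ConfigurationError("n_tips must be >= 3")
    pyrng = _pyrandom.Random(int(rng.integers(0, 2**31 - 1)))
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate,
        death_rate=0.0,
        num_extant_tips=config.n_tips,
        rng=pyrng,
    )
    # pure-birth simulators occasionally emit a zero-length edge; clamp to
    # a small positive floor so branch lengths stay strictly positive
    lengths = [
        nd.edge.length
        for nd in tree.preorder_node_iter()
        if nd.parent_node is not None and nd.edge.length
    ]
    floor = 1e-3 * float(np.mean(lengths))
    for nd in tree.preorder_node_iter():
        if nd.parent_node is None:
            nd.edge.length = None
        elif nd.edge.length is None or nd.edge.length < floor:
            nd.edge.length = floor
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon.label = f"t{i + 1}"
    return tree


def simulate_phylogeny_and_mutations(
    truths: list[FoldingTruth],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    planted: pd.DataFrame | None = None,
) -> PhyloSim:
    """Plant Poisson mutation counts on a Yule tree and drop genotypes.

    For site ``s`` with planted rate ``k_true`` the count on branch ``i``
    of length ``b_i`` is Poisson(``k_true * b_i / B``); any positive count
    flips the genotype to a uniformly chosen different base, so multiple
    hits on one branch surface as a single observable change.
    """
    config.validate()
    if rng is None:
        rng = config.rng()
    if planted is None:
        planted = planted_site_table(truths, config)
    tree = _yule_tree(config, rng)

    nodes = list(tree.preorder_node_iter())
    node_index = {id(nd): j for j, nd in enumerate(nodes)}
    edges = [nd for nd in nodes if nd.parent_node is not None]
    b = np.array([nd.edge.length for nd in edges])
    B = b.sum()

    k_true = planted["k_true"].to_numpy()
    n_sites = k_true.size
    counts = rng.poisson(np.outer(k_true, b / B))  # (n_sites, n_edges)

    states = np.empty((len(nodes), n_sites), dtype=np.uint8)
    states[0] = rng.integers(0, 4, size=n_sites)
    for e, nd in enumerate(edges):
        parent = states[node_index[id(nd.parent_node)]]
        child = parent.copy()
        hit = counts[:, e] > 0
        n_hit = int(hit.sum())
        if n_hit:
            child[hit] = (parent[hit] + rng.integers(1, 4, size=n_hit)) % 4
        states[node_index[id(nd)]] = child

    tips = [nd for nd in tree.leaf_node_iter()]
    tip_labels = [nd.taxon.label for nd in tips]
    genotypes = np.stack(
        [states[node_index[id(nd)]] for nd in tips], axis=1
    )

    sites = planted[["gene_id", "pos"]].copy()
    sites["k_true"] = k_true
    sites["n_mutations"] = counts.sum(axis=1)
    return PhyloSim(
        tree=tree, tip_labels=tip_labels, sites=sites, genotypes=genotypes
    )


@dataclass
class SimulationBundle:
    """Everything the pipeline consumes, plus the planted truth."""

    config: SimConfig
    truths: list[FoldingTruth]
    reads: pd.DataFrame
    rloop_counts: pd.DataFrame
    phylo: PhyloSim
    planted: pd.DataFrame

    @property
    def gene_lengths(self) -> dict[str, int]:
        return {t.gene_id: t.length for t in self.truths}


def simulate_bundle(config: SimConfig) -> SimulationBundle:
    """Generate the full input bundle from one seed."""
    config.validate()
    rng = config.rng()
    truths = simulate_genes(config, rng)
    reads = simulate_espet_reads(truths, config, rng)
    planted = planted_site_table(truths, config)
    rloop_counts = simulate_rloop_counts(truths, config, rng, planted=planted)
    phylo = simulate_phylogeny_and_mutations(truths, config, rng, planted=planted)
    return SimulationBundle(
        config=config,
        truths=truths,
        reads=reads,
        rloop_counts=rloop_counts,
        phylo=phylo,
        planted=planted,
    )
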