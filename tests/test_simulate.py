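"""Generator contracts: determinism, planted structure, sampling laws."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from espet.rloop import gene_rloop_scores, rloop_scores_frame
from espet.simulate import (
    ConfigurationError,
    FoldingTruth,
    SimConfig,
    planted_site_table,
    simulate_bundle,
    simulate_espet_reads,
    simulate_genes,
    simulate_phylogeny_and_mutations,
    simulate_rloop_counts,
)


def tiny(**kw) -> SimConfig:
    base = dict(
        n_genes=5, gene_length_range=(80, 100), depth=5.0, n_tips=5, seed=7
    )
    base.update(kw)
    return SimConfig(**base)


class TestSimulateGenes:
    def test_zero_genes_is_empty(self):
        assert simulate_genes(tiny(n_genes=0)) == []

    def test_same_seed_is_bit_identical(self):
        a = simulate_genes(tiny())
        b = simulate_genes(tiny())
        for ta, tb in zip(a, b):
            assert ta.gene_id == tb.gene_id and ta.length == tb.length
            np.testing.assert_array_equal(ta.unpaired, tb.unpaired)
            assert ta.transition_sites == tb.transition_sites

    def test_one_planted_transition_per_gene(self):
        truths = simulate_genes(tiny(transitions_per_gene=1))
        for t in truths:
            assert len(t.transition_sites) == 1
            i, L_star = t.transition_sites[0]
            before = t.unpaired[L_star - 1, i]
            after = t.unpaired[L_star, i]
            assert abs(before - after) >= 0.8

    def test_transition_effect_size_respected(self):
        truths = simulate_genes(tiny(transition_effect=0.5, seed=3))
        for t in truths:
            for i, L_star in t.transition_sites:
                assert (
                    abs(t.unpaired[L_star, i] - t.unpaired[L_star - 1, i])
                    >= 0.5 - 1e-9
                )

    def test_unpaired_defined_only_outside_footprint(self):
        (t,) = simulate_genes(tiny(n_genes=1))
        defined = ~np.isnan(t.unpaired)
        L_idx, i_idx = np.nonzero(defined)
        assert (i_idx <= L_idx - t.footprint).all()
        assert (defined[t.footprint + 1 :, 1]).all()  # pos 1 exposed everywhere
        assert t.unpaired[~np.isnan(t.unpaired)].min() >= 0
        assert t.unpaired[~np.isnan(t.unpaired)].max() <= 1

    def test_invalid_config_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_genes(tiny(gene_length_range=(0, 10)))
        with pytest.raises(ConfigurationError):
            simulate_genes(tiny(gene_length_range=(10, 5)))


class TestSimulateReads:
    def test_zero_depth_gives_empty_table(self):
        truths = simulate_genes(tiny())
        reads = simulate_espet_reads(truths, tiny(depth=0.0))
        assert reads.empty

    def test_record_count_matches_depth_exactly(self):
        config = tiny()
        truths = simulate_genes(config)
        reads = simulate_espet_reads(truths, config)
        for t in truths:
            expected = int(round(config.depth * t.length))
            sub = reads[reads.gene_id == t.gene_id]
            assert (sub.treatment == "NAI").sum() == expected
            assert (sub.treatment == "DMSO").sum() == expected

    def test_all_stops_at_single_unpaired_site(self):
        # degenerate sampler: one fully unpaired nucleotide, no background
        length, fp = 60, 18
        unpaired = np.full((length + 1, length + 1), np.nan)
        for L in range(fp + 1, length + 1):
            unpaired[L, 1 : L - fp + 1] = 0.0
        unpaired[fp + 1 :, 1] = 1.0  # position 1, exposed in every intermediate
        truth = FoldingTruth("g1", length, fp, unpaired)
        config = tiny(background_stop_rate=0.0, depth=10.0)
        reads = simulate_espet_reads([truth], config, treatments=("NAI",))
        assert (reads.fwd5 == 2).all()  # stop at 1 -> forward 5' end at 2

    def test_reads_respect_footprint_and_order(self):
        config = tiny()
        truths = simulate_genes(config)
        reads = simulate_espet_reads(truths, config)
        lengths = {t.gene_id: t.length for t in truths}
        stop = reads.fwd5 - 1
        assert (stop >= 1).all()
        assert (stop <= reads.txn_site - config.footprint).all()
        assert (reads.txn_site <= reads.gene_id.map(lengths)).all()
        assert (reads.umi.str.len() == 3).all()

    def test_null_background_indistinguishable_between_treatments(self):
        # with unpairedness identically 0 both treatments sample pure
        # background: per-seed rank-test p-values should look uniform
        length, fp = 70, 18
        unpaired = np.full((length + 1, length + 1), np.nan)
        for L in range(fp + 1, length + 1):
            unpaired[L, 1 : L - fp + 1] = 0.0
        truth = FoldingTruth("g1", length, fp, unpaired)
        pvals = []
        for seed in range(25):
            config = tiny(depth=8.0, seed=100 + seed)
            reads = simulate_espet_reads([truth], config)
            nai = reads.loc[reads.treatment == "NAI", "fwd5"]
            dmso = reads.loc[reads.treatment == "DMSO", "fwd5"]
            pvals.append(
                stats.mannwhitneyu(nai, dmso, alternative="two-sided").pvalue
            )
        assert stats.kstest(pvals, "uniform").pvalue > 0.01


class TestSimulateRloop:
    def test_zero_coupling_plants_uniform_enrichment(self):
        config = tiny(rloop_coupling=0.0)
        truths = simulate_genes(config)
        planted = planted_site_table(truths, config)
        assert planted.drip_rate.nunique() == 1

    def test_negative_coupling_recovered_in_scores(self):
        config = SimConfig(
            n_genes=120,
            gene_length_range=(80, 120),
            depth=0.0,
            rloop_coupling=-3.0,
            n_tips=5,
            seed=5,
        )
        truths = simulate_genes(config)
        planted = planted_site_table(truths, config)
        counts = simulate_rloop_counts(truths, config, planted=planted)
        gene_scores = gene_rloop_scores(rloop_scores_frame(counts))
        gene_fold = (
            planted.groupby("gene_id")["foldedness"].mean().reset_index()
        )
        merged = gene_scores.merge(gene_fold, on="gene_id")
        res = stats.spearmanr(merged.rloop, merged.foldedness)
        assert res.statistic < 0 and res.pvalue < 0.01

    def test_zero_depth_gives_zero_counts(self):
        config = tiny(drip_depth=0.0, input_depth=0.0)
        truths = simulate_genes(config)
        counts = simulate_rloop_counts(truths, config)
        assert (counts.drip == 0).all() and (counts["input"] == 0).all()


class TestSimulatePhylogeny:
    def test_zero_rate_keeps_all_tips_identical(self):
        config = tiny(mu_mean=0.0)
        truths = simulate_genes(config)
        sim = simulate_phylogeny_and_mutations(truths, config)
        assert (sim.genotypes == sim.genotypes[:, [0]]).all()

    def test_total_mutations_match_planted_rates(self):
        config = tiny(n_genes=30, mu_mean=2.0, seed=9)
        truths = simulate_genes(config)
        planted = planted_site_table(truths, config)
        sim = simulate_phylogeny_and_mutations(truths, config, planted=planted)
        total = sim.sites.n_mutations.sum()
        expected = planted.k_true.sum()
        assert abs(total - expected) < 4 * np.sqrt(expected)

    def test_same_seed_gives_identical_tree_and_genotypes(self):
        config = tiny()
        truths = simulate_genes(config)
        a = simulate_phylogeny_and_mutations(truths, config)
        b = simulate_phylogeny_and_mutations(truths, config)
        assert a.tree.as_string(schema="newick") == b.tree.as_string(
            schema="newick"
        )
        np.testing.assert_array_equal(a.genotypes, b.genotypes)

    def test_branch_lengths_strictly_positive(self):
        config = tiny(n_tips=40)
        truths = simulate_genes(config)
        sim = simulate_phylogeny_and_mutations(truths, config)
        for nd in sim.tree.preorder_node_iter():
            if nd.parent_node is not None:
                assert nd.edge.length > 0

    def test_too_few_tips_rejected(self):
        config = tiny(n_tips=2)
        truths = simulate_genes(config)
        with pytest.raises(ConfigurationError):
            simulate_phylogeny_and_mutations(truths, config)


def test_bundle_is_deterministic():
    a = simulate_bundle(tiny())
    b = simulate_bundle(tiny())
    pd.testing.assert_frame_equal(a.reads, b.reads)
    pd.testing.assert_frame_equal(a.rloop_counts, b.rloop_counts)
    pd.testing.assert_frame_equal(a.planted, b.planted)
    np.testing.assert_array_equal(a.phylo.genotypes, b.phylo.genotypes)


def test_null_couplings_center_recovered_correlation_on_zero():
    # with every coupling switched off the gene-level folding/R-loop
    # correlation should be centered on zero across replicate seeds
    rhos = []
    for seed in range(30):
        config = SimConfig(
            n_genes=40,
            gene_length_range=(60, 80),
            depth=0.0,
            rloop_coupling=0.0,
            mu_fold_coupling=0.0,
            mu_rloop_coupling=0.0,
            n_tips=5,
            seed=seed,
        )
        truths = simulate_genes(config)
        planted = planted_site_table(truths, config)
        counts = simulate_rloop_counts(truths, config, planted=planted)
        merged = gene_rloop_scores(rloop_scores_frame(counts)).merge(
            planted.groupby("gene_id")["foldedness"].mean().reset_index()
        )
        rhos.append(stats.spearmanr(merged.rloop, merged.foldedness).statistic)
    assert abs(np.mean(rhos)) < 0.1
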