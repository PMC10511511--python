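"""Correlations, mediation, odds ratios, MH combining, permutation null."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from espet.correspondence import (
    gene_level_correlations,
    mediated_fraction,
    mh_combine,
    partial_spearman,
    permutation_null,
    within_gene_or,
)


def gene_table_from(x, y):
    return pd.DataFrame({"a": x, "b": y})


class TestGeneLevelCorrelations:
    def test_perfect_and_reversed_rankings(self):
        x = np.arange(20.0)
        out = gene_level_correlations(
            gene_table_from(x, x), pairs=(("a", "b"),)
        )
        assert out.rho.iloc[0] == pytest.approx(1.0)
        out = gene_level_correlations(
            gene_table_from(x, -x), pairs=(("a", "b"),)
        )
        assert out.rho.iloc[0] == pytest.approx(-1.0)

    def test_constant_vector_flagged(self):
        out = gene_level_correlations(
            gene_table_from(np.ones(15), np.arange(15.0)), pairs=(("a", "b"),)
        )
        assert np.isnan(out.rho.iloc[0])

    def test_too_few_genes_rejected(self):
        with pytest.raises(ValueError):
            gene_level_correlations(gene_table_from(np.ones(5), np.ones(5)))


class TestPartialSpearman:
    def test_reduces_to_plain_rho_for_unrelated_control(self):
        rng = np.random.default_rng(0)
        x = rng.random(2000)
        y = x + 0.5 * rng.random(2000)
        z = rng.random(2000)
        rho = stats.spearmanr(x, y).statistic
        assert partial_spearman(x, y, z) == pytest.approx(rho, abs=0.03)

    def test_degenerate_control_is_nan(self):
        x = np.arange(30.0)
        y = np.arange(30.0)[::-1]
        assert np.isnan(partial_spearman(x, y, x))

    def test_full_mediation_drives_partial_to_zero(self):
        rng = np.random.default_rng(1)
        z = rng.random(3000)
        y = z + 0.3 * rng.random(3000)
        values = []
        for noise in (0.3, 0.1, 0.02):
            x = z + noise * rng.random(3000)
            values.append(abs(partial_spearman(x, y, z)))
        assert values[-1] < 0.1  # association vanishes once z is controlled


class TestMediatedFraction:
    def test_published_style_values(self):
        assert mediated_fraction(-0.219, -0.177) == pytest.approx(0.347, abs=5e-4)
        assert mediated_fraction(-0.156, -0.086) == pytest.approx(0.696, abs=5e-4)

    def test_no_mediation(self):
        assert mediated_fraction(-0.3, -0.3) == pytest.approx(0.0)

    def test_zero_rho_rejected(self):
        with pytest.raises(ValueError):
            mediated_fraction(0.0, 0.1)

    def test_bounded_when_partial_is_smaller(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            rho = rng.uniform(-1, 1)
            if abs(rho) < 1e-3:
                continue
            part = rho * rng.uniform(0, 1)
            assert 0.0 <= mediated_fraction(rho, part) <= 1.0


def site_frame(gene_id, v1, v2, name1="theta", name2="rloop"):
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "pos": np.arange(1, len(v1) + 1),
            name1: v1,
            name2: v2,
        }
    )


class TestWithinGeneOR:
    def test_concordant_extreme_table(self):
        n = 40
        v1 = np.concatenate([np.ones(n // 2), np.zeros(n // 2)])
        tables = within_gene_or(site_frame("g1", v1, v1), "theta", "rloop")
        row = tables.iloc[0]
        assert (row.a, row.b, row.c, row.d) == (n / 2 + 1, 1, 1, n / 2 + 1)
        assert row["or"] == pytest.approx((n / 2 + 1) ** 2)

    def test_pseudocount_keeps_or_finite(self):
        v1 = np.array([1.0, 1.0, 0.0, 0.0])
        v2 = np.array([1.0, 1.0, 0.0, 0.0])
        tables = within_gene_or(site_frame("g1", v1, v2), "theta", "rloop")
        assert np.isfinite(tables["or"]).all()

    def test_independent_fields_give_null_or(self):
        rng = np.random.default_rng(3)
        inside = 0
        for _ in range(40):
            v1, v2 = rng.random(1000), rng.random(1000)
            tables = within_gene_or(site_frame("g1", v1, v2), "theta", "rloop")
            inside += 0.8 <= tables["or"].iloc[0] <= 1.25
        assert inside >= 34  # ~95% of seeds

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(4)
        v1, v2 = rng.random(200), rng.random(200)
        base = within_gene_or(site_frame("g1", v1, v2), "theta", "rloop")
        moved = within_gene_or(
            site_frame("g1", 3.0 * v1 - 1.0, 0.5 * v2 + 2.0), "theta", "rloop"
        )
        assert base["or"].iloc[0] == pytest.approx(moved["or"].iloc[0])

    def test_small_genes_skipped(self):
        tables = within_gene_or(
            site_frame("g1", np.ones(3), np.ones(3)), "theta", "rloop"
        )
        assert tables.empty


class TestMHCombine:
    def _random_tables(self, rng, n):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(n)],
                "a": rng.integers(1, 40, n).astype(float),
                "b": rng.integers(1, 40, n).astype(float),
                "c": rng.integers(1, 40, n).astype(float),
                "d": rng.integers(1, 40, n).astype(float),
            }
        )

    def test_single_table_equals_its_or(self):
        t = pd.DataFrame({"gene_id": ["g1"], "a": [9.0], "b": [3.0], "c": [2.0], "d": [6.0]})
        res = mh_combine(t, n_boot=10)
        assert res.odds_ratio == pytest.approx(9 * 6 / (3 * 2))

    def test_balanced_tables_are_null(self):
        t = pd.DataFrame(
            {"gene_id": ["g1", "g2"], "a": [5.0, 8.0], "b": [5.0, 8.0],
             "c": [5.0, 8.0], "d": [5.0, 8.0]}
        )
        res = mh_combine(t, n_boot=10)
        assert res.odds_ratio == pytest.approx(1.0)
        assert res.p > 0.9

    def test_matches_reference_stratified_implementation(self):
        sm = pytest.importorskip("statsmodels.stats.contingency_tables")
        rng = np.random.default_rng(5)
        for _ in range(50):
            tables = self._random_tables(rng, int(rng.integers(2, 12)))
            res = mh_combine(tables, n_boot=2)
            strata = np.stack(
                [
                    tables[["a", "b"]].to_numpy().T,
                    tables[["c", "d"]].to_numpy().T,
                ],
                axis=0,
            )
            # statsmodels wants 2x2xk
            arr = np.stack(
                [np.array([[r.a, r.b], [r.c, r.d]]) for r in tables.itertuples()],
                axis=2,
            )
            ref = sm.StratifiedTable(arr)
            assert res.odds_ratio == pytest.approx(
                ref.oddsratio_pooled, rel=1e-10
            )
            assert res.chi2 == pytest.approx(
                ref.test_null_odds(correction=False).statistic, rel=1e-8
            )

    def test_combined_or_between_stratum_extremes(self):
        rng = np.random.default_rng(6)
        tables = self._random_tables(rng, 8)
        ors = tables.a * tables.d / (tables.b * tables.c)
        res = mh_combine(tables, n_boot=2)
        assert ors.min() <= res.odds_ratio <= ors.max()

    def test_bootstrap_is_seeded(self):
        rng = np.random.default_rng(7)
        tables = self._random_tables(rng, 6)
        a = mh_combine(tables, n_boot=50, seed=3)
        b = mh_combine(tables, n_boot=50, seed=3)
        assert a.bootstrap_sd == b.bootstrap_sd


def null_site_table(rng, n_genes=10, n_sites=40):
    frames = []
    for g in range(n_genes):
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": f"g{g}",
                    "pos": np.arange(1, n_sites + 1),
                    "neg_theta": rng.random(n_sites),
                    "rloop": rng.random(n_sites),
                    "rate": rng.random(n_sites),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


class TestPermutationNull:
    def test_zero_permutations_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            permutation_null(null_site_table(rng), n_perm=0)

    def test_observed_matches_direct_mean_spearman(self):
        rng = np.random.default_rng(1)
        table = null_site_table(rng)
        res = permutation_null(table, n_perm=10, seed=0)
        direct = np.mean(
            [
                stats.spearmanr(g.neg_theta, g.rloop).statistic
                for _, g in table.groupby("gene_id")
            ]
        )
        assert res.observed["neg_theta~rloop"] == pytest.approx(direct)

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for seed in range(30):
            rng = np.random.default_rng(100 + seed)
            res = permutation_null(
                null_site_table(rng, n_genes=6, n_sites=25),
                n_perm=99,
                seed=seed,
            )
            pvals.append(res.p["neg_theta~rloop"])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_planted_association_is_detected(self):
        rng = np.random.default_rng(2)
        frames = []
        for g in range(8):
            base = rng.random(30)
            frames.append(
                pd.DataFrame(
                    {
                        "gene_id": f"g{g}",
                        "pos": np.arange(1, 31),
                        "neg_theta": -base + 0.2 * rng.random(30),
                        "rloop": base + 0.2 * rng.random(30),
                        "rate": base + 0.2 * rng.random(30),
                    }
                )
            )
        res = permutation_null(pd.concat(frames), n_perm=200, seed=1)
        assert res.p["neg_theta~rloop"] < 0.05
        assert res.p["rloop~rate"] < 0.05
        assert res.p["neg_theta~rate"] < 0.05
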