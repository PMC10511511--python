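import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from espet.pipeline import AnalysisParams, analyze
from espet.simulate import SimConfig, simulate_bundle

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_pairs(rows) -> pd.DataFrame:
    """Build a pair table from (gene, treatment, fwd5, txn, umi, mapq, mm) rows."""
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "treatment",
            "fwd5",
            "txn_site",
            "umi",
            "mapq",
            "first_base_mismatch",
        ],
    )


@pytest.fixture(scope="session")
def small_bundle():
    """A modest synthetic bundle shared by fast integration tests."""
    config = SimConfig(
        n_genes=15, gene_length_range=(100, 130), depth=20.0, n_tips=20, seed=11
    )
    return simulate_bundle(config)


@pytest.fixture(scope="session")
def study_bundle():
    """The study-scale bundle: 200 genes, 190 strains, 30 stops/nt."""
    return simulate_bundle(SimConfig(seed=20260923))


@pytest.fixture(scope="session")
def study_result(study_bundle):
    b = study_bundle
    return analyze(
        b.reads,
        b.rloop_counts,
        b.phylo.tree,
        b.phylo.genotypes,
        b.phylo.tip_labels,
        b.phylo.sites[["gene_id", "pos"]],
        b.gene_lengths,
        AnalysisParams(n_perm=1000, n_boot=1000, seed=1),
    )
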