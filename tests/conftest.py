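import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from pombechip.annotation_io import FeatureCatalog, GenomicFeature
from pombechip.matrix import EnrichmentMatrix
from pombechip import synthetic

settings.register_profile(
    "ci",
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow, HealthCheck.function_scoped_fixture],
    deadline=None,
)
settings.load_profile("ci")


@pytest.fixture
def toy_catalog() -> FeatureCatalog:
    """Six features on two chromosomes, one island overlapping a gene."""
    return FeatureCatalog(
        features=[
            GenomicFeature("mei4", "chr2", 100, 700, "+", "mRNA"),
            GenomicFeature("ssm4", "chr2", 1000, 1600, "-", "mRNA"),
            GenomicFeature("island_mei4", "chr2", 50, 800, ".", "island"),
            GenomicFeature("act1", "chr1", 200, 900, "+", "mRNA"),
            GenomicFeature("tlh1", "chr1", 0, 150, ".", "subtelomere"),
            GenomicFeature("ncrna_394", "chr1", 1200, 1500, ".", "ncRNA"),
        ],
        chrom_sizes={"chr1": 2000, "chr2": 2000},
    )


@pytest.fixture
def small_matrix() -> EnrichmentMatrix:
    return EnrichmentMatrix(
        values=pd.DataFrame(
            {"rep1": [1.0, 2.0, 3.0], "rep2": [2.0, 0.0, 4.0]},
            index=["g1", "g2", "g3"],
        ),
        channel="rip",
    )


@pytest.fixture(scope="session")
def default_config() -> synthetic.SynthConfig:
    return synthetic.SynthConfig(seed=11)


@pytest.fixture(scope="session")
def default_study(default_config):
    """One generated study shared by read-only tests: (config, catalog, truth)."""
    catalog = synthetic.make_genome(default_config)
    truth = synthetic.make_truth(default_config, catalog)
    return default_config, catalog, truth
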