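import pytest
from hypothesis import HealthCheck, settings

from flmeta.flscore import classify_genes, score_collection
from flmeta.preprocess import filter_datasets, preprocess_dataset
from flmeta.synthetic import SimulationConfig, simulate_collection

settings.register_profile(
    "package", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("package")


@pytest.fixture(scope="session")
def small_config():
    """A small but fully featured collection: 2 probes/gene, planted
    enrichment and positive annotation couplings."""
    return SimulationConfig(
        n_genes=400, n_datasets=6, samples_per_dataset=8,
        probes_per_gene=2, n_mirnas=20, targets_per_mirna=40,
        target_enrichment_odds=3.0, utr_coupling=1.0, tfbs_coupling=1.0,
        seed=11)


@pytest.fixture(scope="session")
def collection(small_config):
    return simulate_collection(small_config)


@pytest.fixture(scope="session")
def scored(collection):
    """(ranked matrix, FL scores) of the preprocessed session collection."""
    processed = [preprocess_dataset(ds, collection.truth.probe_map)
                 for ds in filter_datasets(collection.datasets)]
    return score_collection(processed)


@pytest.fixture(scope="session")
def scores(scored):
    return scored[1]["fl_score"]


@pytest.fixture(scope="session")
def classification(scores):
    return classify_genes(scores, q=0.05)
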