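import pytest

from adrmine.datamodel import PipelineConfig
from adrmine.ingest import Vocabulary
from adrmine.datamodel import AdrTerm
from adrmine.synthetic import GeneratorParams, emit_fixture, load_ground_truth


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def small_vocab():
    """Hand-written vocabulary exercising kept, excluded and psychiatric SOCs."""
    terms = [
        AdrTerm("P001", "nausea", "nausea symptoms", "gi motility",
                "Gastrointestinal disorders"),
        AdrTerm("P002", "blood sodium decreased", "electrolyte analyses",
                "hlgt investigations", "Investigations"),
        AdrTerm("P003", "anorexia nervosa", "eating disorders",
                "eating disorders and disturbances", "Psychiatric disorders"),
        AdrTerm("P004", "insomnia", "sleep disturbances",
                "sleep disorders and disturbances", "Psychiatric disorders"),
        AdrTerm("P005", "headache", "headaches", "neuro hlgt",
                "Nervous system disorders"),
    ]
    return Vocabulary(terms)


SMALL_PARAMS = dict(
    n_drugs=60, n_targets=12, n_families=3, n_adrs=60, n_socs=15,
    n_reports=2000, planted_link_count=3, n_adr_only_drugs=4,
    n_target_only_drugs=3, n_conflict_drugs=2, idio_pool_size=30,
    idio_pool_excluded_socs=8, idio_adr_mean=15, seed=7,
)


@pytest.fixture(scope="session")
def small_fixture_dir(tmp_path_factory):
    """A small emitted synthetic fixture shared across tests."""
    out = tmp_path_factory.mktemp("fixture_small")
    emit_fixture(GeneratorParams(**SMALL_PARAMS), out)
    return out


@pytest.fixture(scope="session")
def small_ground_truth(small_fixture_dir):
    return load_ground_truth(small_fixture_dir / "ground_truth.json")
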