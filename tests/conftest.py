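import pytest

from phenonorm import embedding, ontology, testkit


@pytest.fixture(scope="session")
def toy_fixture(tmp_path_factory):
    """50-concept deterministic toy ontology with gold irregular queries."""
    out = tmp_path_factory.mktemp("toy")
    return testkit.generate_toy_ontology(
        testkit.ToyOntologySpec(n_concepts=50, synonyms_per_concept=(1, 2), seed=7), out
    )


@pytest.fixture(scope="session")
def toy_index(toy_fixture):
    return ontology.load_ontology(toy_fixture.ontology_csv)


@pytest.fixture(scope="session")
def test_backend():
    return embedding.deterministic_test_embedder(dim=128, seed=0)


@pytest.fixture(scope="session")
def toy_cache(toy_index, test_backend):
    return embedding.build_cache(toy_index, test_backend)


@pytest.fixture()
def tiny_csv(tmp_path):
    """Three concepts, one with two synonyms (5 expanded records)."""
    p = tmp_path / "tiny.csv"
    p.write_text(
        "Class ID,Preferred Label,Synonyms\n"
        "http://purl.obolibrary.org/obo/HP_0001265,Hyporeflexia,Decreased reflexes|Reduced tendon reflexes\n"
        "HP:0009027,Foot drop,\n"
        "HP:0001337,Tremor,\n"
    )
    return p


@pytest.fixture()
def tiny_index(tiny_csv):
    return ontology.load_ontology(tiny_csv)
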