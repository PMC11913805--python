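"""Build a synonym-expanded term index and its embedding cache.

Generates a small deterministic toy ontology (stand-in for an HPO CSV
export), loads it with synonym expansion, embeds every expanded term with
the deterministic test backend, and persists the vector cache.
"""

from tempfile import TemporaryDirectory

from phenonorm import build_cache, deterministic_test_embedder, load_ontology
from phenonorm.testkit import ToyOntologySpec, generate_toy_ontology

with TemporaryDirectory() as tmp:
    fixture = generate_toy_ontology(ToyOntologySpec(n_concepts=25, seed=4), tmp)
    index = load_ontology(fixture.ontology_csv)
    print(f"concepts (canonical labels): {index.n_canonical}")
    print(f"searchable terms after synonym expansion: {index.n_expanded}")

    backend = deterministic_test_embedder(dim=128, seed=0)
    cache = build_cache(index, backend)
    path = cache.save(tmp + "/index")
    print(f"embedded {len(cache)} terms at dim {cache.dim} -> {path.name}")

# The expanded count exceeds the canonical count because every synonym
# becomes its own searchable record, all pointing back to one HPO ID.
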