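"""Retrieve the top-k candidate HPO entries for an irregular term.

The query is embedded once and scored against every cached term vector by
cosine similarity; rank 1 is what the pure-embedding baseline would answer.
"""

from tempfile import TemporaryDirectory

from phenonorm import build_cache, deterministic_test_embedder, load_ontology, top_k
from phenonorm.testkit import ToyOntologySpec, generate_toy_ontology

with TemporaryDirectory() as tmp:
    fixture = generate_toy_ontology(ToyOntologySpec(n_concepts=25, seed=4), tmp)
    index = load_ontology(fixture.ontology_csv)
    backend = deterministic_test_embedder(dim=128, seed=0)
    cache = build_cache(index, backend)

    query = sorted(fixture.gold)[0]  # an irregular paraphrase of one concept
    print(f"query: {query!r}  (gold concept: {fixture.gold[query]})")
    for c in top_k(query, cache, k=5, backend=backend):
        print(f"  rank {c.rank}: {c.record.surface_label!r} "
              f"({c.record.hpo_id}) cosine={c.score:.3f}")

# Higher cosine = closer in the embedding space. Whether rank 1 is the
# right concept is exactly what the LLM selection step improves on.
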