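"""Run the three normalization regimes on one term.

embedding-argmax needs no LLM; llm-direct asks the model alone; llm-rag
shows the model the top-k retrieved candidates.  A scripted mock client
stands in for a hosted model so the example runs offline.
"""

from tempfile import TemporaryDirectory

from phenonorm import build_cache, deterministic_test_embedder, load_ontology
from phenonorm.normalize import NormalizationResources, normalize_term
from phenonorm.testkit import ToyOntologySpec, generate_toy_ontology, perfect_oracle_client

with TemporaryDirectory() as tmp:
    fixture = generate_toy_ontology(ToyOntologySpec(n_concepts=25, seed=4), tmp)
    index = load_ontology(fixture.ontology_csv)
    backend = deterministic_test_embedder(dim=128, seed=0)
    cache = build_cache(index, backend)

    query = sorted(fixture.gold)[0]
    res = NormalizationResources(cache=cache, backend=backend,
                                 client=perfect_oracle_client(fixture.gold))

    for mode in ("embedding-argmax", "llm-rag"):
        r = normalize_term(query, mode, res)
        print(f"{mode:18s} -> {r.chosen_label!r} ({r.chosen_hpo_id}) "
              f"flags={sorted(r.flags) or 'none'}")
    print(f"gold: {fixture.gold[query]}")

# llm-rag can only answer from the candidates it was shown; when the
# retriever misses the gold concept, the result records why (flags).
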