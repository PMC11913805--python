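"""Compare two methods' choices term by term (the Δ table).

Where the embedding-argmax baseline and the retrieval-augmented selector
pick different concepts, Δ = cs_a − cs_b measures how much cosine
similarity the selector gave up; a small positive Δ with a semantically
better choice is the signature of the LLM overriding raw similarity.
"""

from tempfile import TemporaryDirectory

from phenonorm import build_cache, deterministic_test_embedder, load_ontology
from phenonorm.evaluate import delta_table
from phenonorm.normalize import NormalizationResources, normalize_batch
from phenonorm.testkit import ToyOntologySpec, generate_toy_ontology, perfect_oracle_client

with TemporaryDirectory() as tmp:
    fixture = generate_toy_ontology(ToyOntologySpec(n_concepts=50, seed=7), tmp)
    index = load_ontology(fixture.ontology_csv)
    backend = deterministic_test_embedder(dim=128, seed=0)
    cache = build_cache(index, backend)
    terms = sorted(fixture.gold)

    res = NormalizationResources(cache=cache, backend=backend,
                                 client=perfect_oracle_client(fixture.gold))
    argmax_results, _ = normalize_batch(terms, "embedding-argmax", res)
    rag_results, _ = normalize_batch(terms, "llm-rag", res)

    df = delta_table(argmax_results, rag_results, backend)
    print(f"{len(df)} of {len(terms)} queries resolved to different concepts\n")
    print(df.head(8).to_string(index=False))

# cs_a is the cosine of the argmax choice (the highest available by
# construction), cs_b that of the selector's choice; Δ >= 0 rows show the
# selector trading similarity for semantic fit.
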