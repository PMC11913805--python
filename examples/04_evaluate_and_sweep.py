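"""Score a normalization run and sweep the candidate count k.

Confusion conventions: a true positive is an equivalent answer with the
correct HPO ID; a wrong answer is a false positive; an unanswered term a
false negative; there are no true negatives.  The sweep shows accuracy
rising with k until the retriever's containment ceiling flattens it.
"""

from tempfile import TemporaryDirectory

from phenonorm import build_cache, deterministic_test_embedder, load_ontology
from phenonorm.evaluate import compute_metrics, judgments_from_gold, k_sweep, tally
from phenonorm.normalize import NormalizationResources, normalize_batch
from phenonorm.retrieve import gold_containment
from phenonorm.testkit import ToyOntologySpec, generate_toy_ontology, perfect_oracle_client

with TemporaryDirectory() as tmp:
    fixture = generate_toy_ontology(ToyOntologySpec(n_concepts=50, seed=7), tmp)
    index = load_ontology(fixture.ontology_csv)
    backend = deterministic_test_embedder(dim=128, seed=0)
    cache = build_cache(index, backend)
    terms = sorted(fixture.gold)

    res = NormalizationResources(cache=cache, backend=backend,
                                 client=perfect_oracle_client(fixture.gold))
    results, _ = normalize_batch(terms, "llm-rag", res)
    judgments = judgments_from_gold(results, fixture.gold)
    report = compute_metrics(tally(results, judgments, gold=fixture.gold))
    print("llm-rag at k=20:", report.rounded())

    ks = [1, 2, 5, 10, 20]
    df = k_sweep(terms, fixture.gold, ks, res)
    containment = gold_containment(terms, fixture.gold, cache, backend, ks)
    print("\n   k  accuracy  top-k contains gold")
    for k in ks:
        acc = float(df.loc[df.k == k, "accuracy"].iloc[0])
        print(f"  {k:2d}   {acc:.2f}      {containment[k]:.2f}")

# With a perfect selector the two columns are identical: candidate count
# only helps until the gold concept is reliably inside the shown list.
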