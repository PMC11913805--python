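"""Equivalence adjudication, confusion tally, metrics and the k-sweep."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenonorm import evaluate, normalize, testkit
from phenonorm.evaluate import (
    EQUIVALENT,
    NOT_EQUIVALENT,
    UNAVAILABLE,
    ConfusionCounts,
    adjudicate,
    build_delta_rows,
    compute_metrics,
    delta_table,
    f1_from_precision_recall,
    judge_cosine,
    judge_llm,
    judgments_from_gold,
    k_sweep,
    tally,
)
from phenonorm.normalize import NormalizationResources, NormalizationResult
from phenonorm.retrieve import gold_containment, top_k


def _cand(label, hpo_id):
    from phenonorm.ontology import TermRecord
    from phenonorm.retrieve import CandidateMatch

    return CandidateMatch(TermRecord(label, label, hpo_id, False), 0.9, 1)


def _result(term, label, hpo_id, answered=True):
    flags = frozenset() if answered else frozenset({"no_answer"})
    cands = (_cand(label or "x", hpo_id or "HP:0000001"),)
    return NormalizationResult(term, "llm-rag",
                               label if answered else None,
                               hpo_id if answered else None,
                               cands, "", flags)


# -- judgments -----------------------------------------------------------


def test_judge_cosine_identity_pair(test_backend):
    score, verdict = judge_cosine("gait ataxia", "gait ataxia", test_backend, 0.9)
    assert score == pytest.approx(1.0)
    assert verdict == EQUIVALENT


def test_judge_cosine_dissimilar_pair(test_backend):
    score, verdict = judge_cosine("gait ataxia", "ocular tremor", test_backend, 0.9)
    assert score < 0.9
    assert verdict == NOT_EQUIVALENT


def test_judge_cosine_threshold_bounds(test_backend):
    with pytest.raises(ValueError):
        judge_cosine("a b", "a b", test_backend, 1.5)


def test_judge_llm_scripted_verdicts():
    yes = testkit.ScriptedLLMClient(default_reply="yes")
    no = testkit.ScriptedLLMClient(default_reply="No.")
    garbage = testkit.ScriptedLLMClient(default_reply="perhaps, hard to say")
    assert judge_llm("a", "b", yes) == EQUIVALENT
    assert judge_llm("a", "b", no) == NOT_EQUIVALENT
    assert judge_llm("a", "b", garbage) == UNAVAILABLE


def test_judge_llm_batch_order():
    pairs = [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h"), ("i", "j")]
    script = [(f"Term A: {q}", "yes" if i % 2 == 0 else "no")
              for i, (q, _) in enumerate(pairs)]
    client = testkit.scripted_llm(script)
    verdicts = [judge_llm(q, p, client) for q, p in pairs]
    assert verdicts == [EQUIVALENT, NOT_EQUIVALENT] * 2 + [EQUIVALENT]
    assert len(client.transcript) == 5


def test_adjudication_precedence():
    # expert outranks LLM outranks cosine
    assert adjudicate(NOT_EQUIVALENT, EQUIVALENT, EQUIVALENT) == NOT_EQUIVALENT
    assert adjudicate(UNAVAILABLE, EQUIVALENT, NOT_EQUIVALENT) == EQUIVALENT
    assert adjudicate(UNAVAILABLE, UNAVAILABLE, EQUIVALENT) == EQUIVALENT
    with pytest.raises(ValueError):
        adjudicate(UNAVAILABLE, UNAVAILABLE, UNAVAILABLE)


# -- tally and metrics ---------------------------------------------------


def test_tally_hand_counted_fixture():
    gold = {"q1": "HP:0000001", "q2": "HP:0000002", "q3": "HP:0000003", "q4": "HP:0000004"}
    results = [
        _result("q1", "Right label", "HP:0000001"),
        _result("q2", "Right label", "HP:0000002"),
        _result("q3", "Wrong id", "HP:0009999"),
        _result("q4", None, None, answered=False),
    ]
    judgments = {"q1": EQUIVALENT, "q2": EQUIVALENT, "q3": EQUIVALENT}
    counts = tally(results, judgments, gold=gold)
    assert (counts.tp, counts.fp, counts.fn, counts.tn) == (2, 1, 1, 0)


def test_tally_all_correct_means_no_errors():
    gold = {"q1": "HP:0000001", "q2": "HP:0000002"}
    results = [_result("q1", "A", "HP:0000001"), _result("q2", "B", "HP:0000002")]
    counts = tally(results, {"q1": EQUIVALENT, "q2": EQUIVALENT}, gold=gold)
    assert counts.fp == counts.fn == 0 and counts.tp == 2


def test_tally_semantic_miss_is_fp():
    gold = {"q1": "HP:0000001"}
    results = [_result("q1", "A", "HP:0000001")]
    counts = tally(results, {"q1": NOT_EQUIVALENT}, gold=gold)
    assert counts.fp == 1 and counts.tp == 0


def test_tally_requires_judgment_for_answered():
    gold = {"q1": "HP:0000001"}
    with pytest.raises(ValueError, match="judgment"):
        tally([_result("q1", "A", "HP:0000001")], {}, gold=gold)


def test_empty_tally_is_an_error():
    with pytest.raises(ValueError):
        tally([], {}, gold={})
    with pytest.raises(ValueError):
        compute_metrics(ConfusionCounts(0, 0, 0, 0))


def test_tally_is_permutation_invariant():
    gold = {f"q{i}": f"HP:{i:07d}" for i in range(1, 9)}
    results = [_result(f"q{i}", "L", f"HP:{i:07d}" if i % 2 else "HP:0009999")
               for i in range(1, 9)]
    judgments = {f"q{i}": EQUIVALENT for i in range(1, 9)}
    rng = random.Random(0)
    shuffled = results[:]
    rng.shuffle(shuffled)
    assert tally(results, judgments, gold=gold) == tally(shuffled, judgments, gold=gold)


def test_metrics_from_spacy_style_counts():
    # precision 1.00 / recall 0.46 must yield F1 0.63
    counts = ConfusionCounts(tp=837, fp=0, fn=983, tn=0)
    report = compute_metrics(counts).rounded()
    assert report == {"accuracy": 0.46, "precision": 1.0, "recall": 0.46,
                      "f1": 0.63, "n": 1820}


def test_f1_harmonic_mean_values():
    assert round(f1_from_precision_recall(1.00, 0.46), 2) == 0.63
    assert round(f1_from_precision_recall(0.91, 0.96), 2) == 0.93
    assert f1_from_precision_recall(0.0, 0.0) == 0.0


def test_zero_division_conventions():
    with pytest.warns(UserWarning):
        report = compute_metrics(ConfusionCounts(tp=0, fp=0, fn=5, tn=0))
    assert report.precision == 0.0 and report.recall == 0.0 and report.f1 == 0.0


@settings(max_examples=1000, derandomize=True)
@given(
    tp=st.integers(0, 10_000), fp=st.integers(0, 10_000), fn=st.integers(0, 10_000)
)
def test_metric_identities_on_random_counts(tp, fp, fn):
    if tp + fp + fn == 0:
        return
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        r = compute_metrics(ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0))
    assert 0.0 <= r.accuracy <= 1.0
    assert 0.0 <= r.precision <= 1.0
    assert 0.0 <= r.recall <= 1.0
    assert r.f1 <= min(2 * r.precision, 2 * r.recall) + 1e-12
    assert (r.f1 == 0.0) == (r.precision * r.recall == 0.0)
    if fn == 0:  # with tn = 0 and fn = 0, accuracy equals precision
        assert r.accuracy == pytest.approx(r.precision)


# -- k-sweep and pipeline identity ---------------------------------------


@pytest.fixture(scope="module")
def sweep_setup(toy_cache, test_backend, toy_fixture):
    res = NormalizationResources(
        cache=toy_cache, backend=test_backend,
        client=testkit.perfect_oracle_client(toy_fixture.gold),
    )
    return sorted(toy_fixture.gold), toy_fixture.gold, res


def test_rag_accuracy_equals_topk_containment(sweep_setup, toy_cache, test_backend):
    terms, gold, res = sweep_setup
    ks = [1, 5, 10, 20]
    containment = gold_containment(terms, gold, toy_cache, test_backend, ks)
    df = k_sweep(terms, gold, ks, res)
    for k in ks:
        acc = float(df.loc[df.k == k, "accuracy"].iloc[0])
        assert acc == pytest.approx(containment[k])


def test_sweep_accuracy_monotone_non_decreasing(sweep_setup):
    terms, gold, res = sweep_setup
    df = k_sweep(terms, gold, [1, 2, 5, 10, 20, 50], res)
    acc = df["accuracy"].tolist()
    assert all(a <= b + 1e-12 for a, b in zip(acc, acc[1:]))


def test_sweep_k1_with_rank1_mock_collapses_to_argmax(toy_cache, test_backend,
                                                      toy_fixture):
    terms = sorted(toy_fixture.gold)
    gold = toy_fixture.gold
    res = NormalizationResources(cache=toy_cache, backend=test_backend,
                                 client=testkit.rank1_client())
    df = k_sweep(terms, gold, [1], res)
    argmax_results = [normalize.normalize_term(t, "embedding-argmax", res) for t in terms]
    judgments = judgments_from_gold(argmax_results, gold)
    argmax_acc = compute_metrics(tally(argmax_results, judgments, gold=gold)).accuracy
    assert float(df["accuracy"].iloc[0]) == pytest.approx(argmax_acc)


def test_sweep_emits_one_row_per_k(sweep_setup, tmp_path):
    terms, gold, res = sweep_setup
    out = tmp_path / "sweep.csv"
    df = k_sweep(terms[:10], gold, [1, 5, 10, 20, 50], res, out_csv=out)
    assert len(df) == 5
    assert out.read_text().count("\n") == 6  # header + 5 rows


# -- delta comparison ----------------------------------------------------


def test_delta_rows_from_printed_similarities():
    rows = build_delta_rows([
        ("Absent ankle jerks", "Absent knee jerk reflex", 0.96,
         "Absent ankle reflexes", 0.95),
        ("Bilateral foot drop", "Bilateral clubfoot", 0.94, "Foot drop", 0.93),
    ])
    assert rows["delta"].tolist() == [0.01, 0.01]


def test_delta_rows_omit_identical_choices():
    rows = build_delta_rows([("q", "Same choice", 0.95, "same choice", 0.95)])
    assert len(rows) == 0


def test_delta_table_pipeline(test_backend):
    a = [_result("proximal leg weakness", "Proximal leg weakness", "HP:0000001"),
         _result("gait ataxia", "Gait ataxia", "HP:0000002")]
    b = [_result("proximal leg weakness", "Proximal arm weakness", "HP:0000003"),
         _result("gait ataxia", "Gait ataxia", "HP:0000002")]
    df = delta_table(a, b, test_backend)
    assert len(df) == 1  # identical second choice omitted
    row = df.iloc[0]
    assert row["query"] == "proximal leg weakness"
    assert row["delta"] == pytest.approx(round(row["cs_a"] - row["cs_b"], 2))
    assert row["cs_a"] > row["cs_b"]  # exact surface beats the arm variant


def test_delta_table_requires_same_queries(test_backend):
    a = [_result("q1", "A", "HP:0000001")]
    b = [_result("q2", "B", "HP:0000002")]
    with pytest.raises(ValueError, match="different queries"):
        delta_table(a, b, test_backend)
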