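"""Prompt rendering, reply parsing and the three normalization regimes."""

import json

import pytest

from phenonorm import normalize, testkit
from phenonorm.normalize import (
    FLAG_ID_INVALID,
    FLAG_ID_LABEL_MISMATCH,
    FLAG_LABEL_NOT_IN_CANDIDATES,
    FLAG_NO_ANSWER,
    FLAG_PARSE_FAILED,
    NormalizationResources,
    NormalizationResult,
    ParseError,
    build_direct_prompt,
    build_rag_prompt,
    load_prompt_asset,
    normalize_batch,
    normalize_term,
    parse_candidate_block,
    parse_reply,
    read_results_jsonl,
    render_candidates,
)
from phenonorm.ontology import TermRecord
from phenonorm.retrieve import CandidateMatch, top_k


def _cands(pairs):
    return [
        CandidateMatch(TermRecord(lab, lab, hid, False), 1.0 - 0.01 * i, i + 1)
        for i, (lab, hid) in enumerate(pairs)
    ]


# -- prompts -------------------------------------------------------------


def test_direct_prompt_substitutes_term():
    p = build_direct_prompt("hyporeflexia")
    assert "Term: hyporeflexia" in p
    assert p.count('{"best_match"') == 1  # reply schema appears exactly once


def test_direct_prompt_matches_stored_template():
    tpl = load_prompt_asset("direct.txt")
    assert build_direct_prompt("X").replace("X", "{term}") == tpl


def test_rag_prompt_lists_candidates_in_order():
    cands = _cands([("Foot drop", "HP:0009027"), ("Tremor", "HP:0001337"),
                    ("Hyporeflexia", "HP:0001265")])
    p = build_rag_prompt("foot drop", cands)
    parsed = parse_candidate_block(p)
    assert parsed == [(c.record.surface_label, c.record.hpo_id) for c in cands]
    assert "Possible matches:" in p and "Term: foot drop" in p


def test_candidate_rendering_is_delimiter_safe():
    awkward = _cands([('Pain, "burning" type', "HP:0000001"),
                      ("Weakness, distal", "HP:0000002")])
    block = render_candidates(awkward)
    prompt = build_rag_prompt("pain", awkward)
    assert parse_candidate_block(prompt) == [
        ('Pain, "burning" type', "HP:0000001"),
        ("Weakness, distal", "HP:0000002"),
    ]
    assert len(block.strip().splitlines()) == 4  # [ + one line per candidate + ]


def test_rag_prompt_rejects_empty_candidates():
    with pytest.raises(ValueError):
        build_rag_prompt("x", [])


def test_rag_prompt_with_20_candidates_shape():
    cands = _cands([(f"Finding {i}", f"HP:{i:07d}") for i in range(1, 21)])
    p = build_rag_prompt("finding", cands)
    assert len(parse_candidate_block(p)) == 20
    # term line, matches block, instruction, schema all present
    assert "Term: finding" in p
    assert "Pick the best one from the above matches" in p
    assert '"best_match"' in p


# -- reply parsing -------------------------------------------------------


@pytest.mark.parametrize(
    "raw,expected",
    [
        ('{"best_match": "Hyporeflexia", "hpo_id": "HP:0001265"}',
         ("Hyporeflexia", "HP:0001265")),
        ('{"best_match": "Hyporeflexia", "HPO ID": "HP:0001265"}',
         ("Hyporeflexia", "HP:0001265")),
        ('{"best_match": "Hyporeflexia", "HPO_ID": "HP:0001265"}',
         ("Hyporeflexia", "HP:0001265")),
        ('Sure! Here is the answer: {"best_match": "Foot drop", "HPO ID": "HP:0009027"} ',
         ("Foot drop", "HP:0009027")),
        ('{"best_match": "  padded  ", "hpo_id": " HP:0000001 "}',
         ("padded", "HP:0000001")),
    ],
)
def test_parse_reply_accepted_spellings(raw, expected):
    assert parse_reply(raw) == expected


@pytest.mark.parametrize(
    "raw",
    [
        "I cannot determine a match.",
        '{"best_match": "X"}',  # missing ID key
        '{"hpo_id": "HP:0000001"}',  # missing label key
        '{"best_match": unquoted}',  # malformed JSON
        "",
    ],
)
def test_parse_reply_failures(raw):
    with pytest.raises(ParseError):
        parse_reply(raw)


def test_parse_of_rendered_reply_is_identity():
    for label, hid in [("Foot drop", "HP:0009027"), ('Odd "label", here', "HP:0000042")]:
        raw = json.dumps({"best_match": label, "hpo_id": hid})
        assert parse_reply(raw) == (label, hid)


# -- regimes -------------------------------------------------------------


@pytest.fixture()
def rag_resources(toy_cache, test_backend):
    def make(client, **kw):
        return NormalizationResources(cache=toy_cache, backend=test_backend,
                                      client=client, **kw)

    return make


def test_rank1_mock_equals_embedding_argmax(rag_resources, toy_cache, test_backend,
                                            toy_fixture):
    res = rag_resources(testkit.rank1_client())
    for q in sorted(toy_fixture.gold)[:5]:
        rag = normalize_term(q, "llm-rag", res)
        argmax = normalize_term(q, "embedding-argmax", res)
        assert rag.chosen_hpo_id == argmax.chosen_hpo_id
        assert rag.flags == frozenset()


def test_hallucinated_label_strict_vs_permissive(toy_cache, test_backend, toy_fixture):
    q = sorted(toy_fixture.gold)[0]
    off_list = '{"best_match": "Completely invented concept", "hpo_id": "HP:9999999"}'
    strict = NormalizationResources(cache=toy_cache, backend=test_backend,
                                    client=testkit.scripted_llm([("Possible", off_list)]),
                                    hallucination_policy="strict")
    r = normalize_term(q, "llm-rag", strict)
    assert FLAG_LABEL_NOT_IN_CANDIDATES in r.flags
    assert r.chosen_label == r.candidates_shown[0].record.surface_label  # rank-1 fallback

    permissive = NormalizationResources(cache=toy_cache, backend=test_backend,
                                        client=testkit.scripted_llm([("Possible", off_list)]),
                                        hallucination_policy="permissive")
    r2 = normalize_term(q, "llm-rag", permissive)
    assert FLAG_LABEL_NOT_IN_CANDIDATES in r2.flags
    assert r2.chosen_label == "Completely invented concept"


def test_malformed_replies_exhaust_retries_to_no_answer(rag_resources, toy_fixture):
    client = testkit.ScriptedLLMClient(default_reply="garbage, not JSON")
    res = rag_resources(client)
    r = normalize_term(sorted(toy_fixture.gold)[0], "llm-rag", res)
    assert FLAG_NO_ANSWER in r.flags and FLAG_PARSE_FAILED in r.flags
    assert r.chosen_label is None and r.chosen_hpo_id is None
    assert len(client.transcript) == 3  # default max_retries


def test_transport_errors_are_contained(rag_resources, toy_fixture):
    class FlakyClient:
        identity = "flaky"

        def complete(self, prompt, temperature=0.0, max_tokens=256):
            raise ConnectionError("boom")

    r = normalize_term(sorted(toy_fixture.gold)[0], "llm-rag", rag_resources(FlakyClient()))
    assert FLAG_NO_ANSWER in r.flags
    assert "transport error" in r.raw_reply


def test_invalid_reply_id_flagged(toy_cache, test_backend, toy_fixture):
    q = sorted(toy_fixture.gold)[0]
    res = NormalizationResources(cache=toy_cache, backend=test_backend,
                                 client=None, hallucination_policy="permissive")

    def reply(prompt):
        label, _ = parse_candidate_block(prompt)[0]
        return json.dumps({"best_match": label, "hpo_id": "HP:12"})

    res.client = testkit.ScriptedLLMClient([("Possible", reply)])
    r = normalize_term(q, "llm-rag", res)
    assert FLAG_ID_INVALID in r.flags
    assert FLAG_ID_LABEL_MISMATCH in r.flags  # label maps to a different, valid ID


def test_repair_ids_uses_candidate_mapping(toy_cache, test_backend, toy_fixture):
    q = sorted(toy_fixture.gold)[0]

    def reply(prompt):
        label, _ = parse_candidate_block(prompt)[0]
        return json.dumps({"best_match": label, "hpo_id": "HP:7777777"})

    res = NormalizationResources(cache=toy_cache, backend=test_backend,
                                 client=testkit.ScriptedLLMClient([("Possible", reply)]),
                                 repair_ids=True)
    r = normalize_term(q, "llm-rag", res)
    assert FLAG_ID_LABEL_MISMATCH in r.flags  # evidence retained
    assert r.chosen_hpo_id == r.candidates_shown[0].record.hpo_id  # mapping wins


def test_llm_direct_has_no_candidates(toy_fixture):
    client = testkit.scripted_llm(
        [("Term:", '{"best_match": "Tremor", "HPO ID": "HP:0001337"}')]
    )
    r = normalize_term("tremors", "llm-direct", NormalizationResources(client=client))
    assert r.method == "llm-direct"
    assert r.candidates_shown == ()
    assert r.chosen_hpo_id == "HP:0001337"


def test_result_invariant_no_answer_means_absent():
    with pytest.raises(ValueError):
        NormalizationResult("q", "llm-rag", "label", "HP:0000001", (), "",
                            frozenset({FLAG_NO_ANSWER}))


def test_result_invariant_invalid_id_requires_flag():
    with pytest.raises(ValueError):
        NormalizationResult("q", "llm-direct", "label", "HP:1", (), "", frozenset())


# -- batch ---------------------------------------------------------------


def test_batch_preserves_input_order(rag_resources, toy_fixture, tmp_path):
    terms = sorted(toy_fixture.gold)[:10]
    res = rag_resources(testkit.perfect_oracle_client(toy_fixture.gold))
    results, manifest = normalize_batch(terms, "llm-rag", res,
                                        out_path=tmp_path / "out.jsonl")
    assert [r.query_term for r in results] == terms
    assert manifest["n_terms"] == 10
    assert manifest["client_identity"] == "perfect-oracle-mock"


def test_batch_rerun_with_mock_is_byte_identical(rag_resources, toy_fixture, tmp_path):
    terms = sorted(toy_fixture.gold)[:8]
    a, b = tmp_path / "a.jsonl", tmp_path / "b.jsonl"
    for path in (a, b):
        res = rag_resources(testkit.perfect_oracle_client(toy_fixture.gold))
        normalize_batch(terms, "llm-rag", res, out_path=path)
    assert a.read_bytes() == b.read_bytes()


def test_interrupted_batch_resumes_without_reprocessing(rag_resources, toy_fixture,
                                                        tmp_path):
    terms = sorted(toy_fixture.gold)[:10]
    out = tmp_path / "run.jsonl"
    res_first = rag_resources(testkit.perfect_oracle_client(toy_fixture.gold))
    normalize_batch(terms[:4], "llm-rag", res_first, out_path=out)  # simulated interruption

    client = testkit.perfect_oracle_client(toy_fixture.gold)
    res = rag_resources(client)
    results, manifest = normalize_batch(terms, "llm-rag", res, out_path=out, resume=True)
    assert [r.query_term for r in results] == terms
    assert manifest["n_resumed"] == 4
    assert len(client.transcript) == 6  # only the remaining terms hit the client
    assert [r.query_term for r in read_results_jsonl(out)] == terms


def test_resume_rejects_mismatched_term_list(rag_resources, toy_fixture, tmp_path):
    terms = sorted(toy_fixture.gold)[:5]
    out = tmp_path / "run.jsonl"
    res = rag_resources(testkit.perfect_oracle_client(toy_fixture.gold))
    normalize_batch(terms, "llm-rag", res, out_path=out)
    with pytest.raises(ValueError, match="does not match"):
        normalize_batch(list(reversed(terms)), "llm-rag", res, out_path=out, resume=True)
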