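"""Prompt construction, LLM reply parsing, and the three normalization regimes.

A term is normalized in one of three ways:

``embedding-argmax``
    take the ontology entry with the highest cosine similarity (no LLM);
``llm-direct``
    ask a language model for the best HPO match and ID from its own
    pre-training, with no candidates supplied;
``llm-rag``
    retrieve the top-k (default 20) candidate entries by cosine similarity
    and ask the model to pick one — retrieval-augmented normalization.

The model is reached through a minimal chat-completion contract
(:class:`LLMClient`), so a scripted mock is a drop-in replacement for a
hosted API.  Replies are expected as a JSON object with ``best_match`` and
an HPO-ID key; several key spellings are accepted because model output
varies.  Every result records the raw reply and validation flags, so
downstream scoring can distinguish a clean answer from a repaired or
hallucinated one.

The two prompt templates are stored as text assets under
``phenonorm/prompts/`` rather than inlined, so the exact wording used is
auditable; ``{term}``-style placeholders are substituted verbatim.
"""

from __future__ import annotations

import json
import re
import time
from dataclasses import dataclass, field
from importlib import resources as importlib_resources
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, runtime_checkable

from .embedding import EmbeddingBackend, EmbeddingCache
from .ontology import TermIndex, TermRecord, canonicalize_hpo_id, normalize_surface, validate_hpo_id
from .retrieve import DEFAULT_K, CandidateMatch, top_k

__all__ = [
    "LLMClient",
    "OpenAIChatClient",
    "NormalizationResult",
    "NormalizationResources",
    "ParseError",
    "load_prompt_asset",
    "build_direct_prompt",
    "build_rag_prompt",
    "render_candidates",
    "parse_candidate_block",
    "parse_reply",
    "normalize_term",
    "normalize_with_candidates",
    "normalize_batch",
    "write_results_jsonl",
    "read_results_jsonl",
]

MODES = ("embedding-argmax", "llm-direct", "llm-rag")

FLAG_ID_INVALID = "id_invalid"
FLAG_LABEL_NOT_IN_CANDIDATES = "label_not_in_candidates"
FLAG_ID_LABEL_MISMATCH = "id_label_mismatch"
FLAG_PARSE_FAILED = "parse_failed"
FLAG_NO_ANSWER = "no_answer"


class ParseError(ValueError):
    """Raised when no (label, HPO ID) pair can be extracted from a reply."""


@runtime_checkable
class LLMClient(Protocol):
    """Narrow chat-completion contract; mocks implement the same surface."""

    identity: str

    def complete(self, prompt: str, temperature: float = 0.0, max_tokens: int = 256) -> str:
        ...


class OpenAIChatClient:
    """Chat-completion client for any OpenAI-compatible HTTP endpoint.

    Uses only the standard library, reads the API key from an environment
    variable, and is deliberately thin: one prompt in, one reply string
    out.  Not exercised by the offline test suite.
    """

    def __init__(
        self,
        model: str,
        endpoint: str = "https://api.openai.com/v1/chat/completions",
        api_key_env: str = "OPENAI_API_KEY",
        timeout: float = 60.0,
    ):
        self.model = model
        self.endpoint = endpoint
        self.api_key_env = api_key_env
        self.timeout = timeout
        self.identity = f"openai-chat/{model}"

    def complete(self, prompt: str, temperature: float = 0.0, max_tokens: int = 256) -> str:  # pragma: no cover
        import os
        import urllib.request

        key = os.environ.get(self.api_key_env, "")
        payload = json.dumps(
            {
                "model": self.model,
                "temperature": temperature,
                "max_tokens": max_tokens,
                "messages": [{"role": "user", "content": prompt}],
            }
        ).encode()
        req = urllib.request.Request(
            self.endpoint,
            data=payload,
            headers={"Content-Type": "application/json", "Authorization": f"Bearer {key}"},
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            body = json.loads(resp.read().decode())
        return body["choices"][0]["message"]["content"]


@dataclass(frozen=True)
class NormalizationResult:
    """The chosen (label, HPO ID) with full provenance for one query term."""

    query_term: str
    method: str
    chosen_label: Optional[str]
    chosen_hpo_id: Optional[str]
    candidates_shown: tuple[CandidateMatch, ...] | list[CandidateMatch]
    raw_reply: str
    flags: frozenset[str]

    def __post_init__(self) -> None:
        if self.method not in MODES:
            raise ValueError(f"unknown method {self.method!r}")
        if FLAG_NO_ANSWER in self.flags and (
            self.chosen_label is not None or self.chosen_hpo_id is not None
        ):
            raise ValueError("no_answer results must carry no chosen label/ID")
        if (
            self.chosen_hpo_id is not None
            and FLAG_ID_INVALID not in self.flags
            and not validate_hpo_id(self.chosen_hpo_id)
        ):
            raise ValueError("invalid chosen_hpo_id without id_invalid flag")

    @property
    def answered(self) -> bool:
        return FLAG_NO_ANSWER not in self.flags

    def to_dict(self) -> dict:
        return {
            "query_term": self.query_term,
            "method": self.method,
            "chosen_label": self.chosen_label,
            "chosen_hpo_id": self.chosen_hpo_id,
            "candidates_shown": [
                {
                    "surface_label": c.record.surface_label,
                    "canonical_label": c.record.canonical_label,
                    "hpo_id": c.record.hpo_id,
                    "is_synonym": c.record.is_synonym,
                    "score": c.score,
                    "rank": c.rank,
                }
                for c in self.candidates_shown
            ],
            "raw_reply": self.raw_reply,
            "flags": sorted(self.flags),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationResult":
        cands = tuple(
            CandidateMatch(
                TermRecord(
                    c["surface_label"], c["canonical_label"], c["hpo_id"], c["is_synonym"]
                ),
                c["score"],
                c["rank"],
            )
            for c in d.get("candidates_shown", [])
        )
        return cls(
            query_term=d["query_term"],
            method=d["method"],
            chosen_label=d.get("chosen_label"),
            chosen_hpo_id=d.get("chosen_hpo_id"),
            candidates_shown=cands,
            raw_reply=d.get("raw_reply", ""),
            flags=frozenset(d.get("flags", [])),
        )


# -- prompt construction -------------------------------------------------


def load_prompt_asset(name: str) -> str:
    """Read a prompt template shipped under ``phenonorm/prompts/``."""
    return (
        importlib_resources.files("phenonorm").joinpath("prompts", name).read_text()
    )


def build_direct_prompt(term: str) -> str:
    """Render the direct-normalization prompt for one term."""
    if not term or not term.strip():
        raise ValueError("term must be non-empty")
    return load_prompt_asset("direct.txt").replace("{term}", term.strip())


def render_candidates(candidates: Sequence[CandidateMatch]) -> str:
    """Render the candidate list as a JSON array, one object per line.

    JSON escaping keeps labels containing commas or quotes unambiguous, so
    the block can be parsed back losslessly (see
    :func:`parse_candidate_block`).
    """
    lines = []
    for c in candidates:
        obj = {"term": c.record.surface_label, "hpo_id": c.record.hpo_id}
        lines.append(json.dumps(obj))
    return "[\n" + ",\n".join(lines) + "\n]"


def build_rag_prompt(term: str, candidates: Sequence[CandidateMatch]) -> str:
    """Render the retrieval-augmented prompt: term, ranked candidates, schema."""
    if not term or not term.strip():
        raise ValueError("term must be non-empty")
    if not candidates:
        raise ValueError("candidate list must be non-empty")
    ranks = [c.rank for c in candidates]
    if ranks != sorted(ranks):
        raise ValueError("candidates must be rank-ordered")
    tpl = load_prompt_asset("rag.txt")
    return tpl.replace("{term}", term.strip()).replace(
        "{matches}", render_candidates(candidates)
    )


def _first_balanced(text: str, open_ch: str, close_ch: str) -> Optional[str]:
    """Extract the first balanced {...} or [...] span, string-aware."""
    start = text.find(open_ch)
    while start != -1:
        depth = 0
        in_str = False
        esc = False
        for i in range(start, len(text)):
            ch = text[i]
            if in_str:
                if esc:
                    esc = False
                elif ch == "\\":
                    esc = True
                elif ch == '"':
                    in_str = False
                continue
            if ch == '"':
                in_str = True
            elif ch == open_ch:
                depth += 1
            elif ch == close_ch:
                depth -= 1
                if depth == 0:
                    return text[start : i + 1]
        start = text.find(open_ch, start + 1)
    return None


def parse_candidate_block(prompt: str) -> list[tuple[str, str]]:
    """Recover the (term, hpo_id) candidate list from a rendered RAG prompt."""
    anchor = prompt.find("Possible matches:")
    if anchor == -1:
        raise ParseError("no candidate block found")
    block = _first_balanced(prompt[anchor:], "[", "]")
    if block is None:
        raise ParseError("unbalanced candidate block")
    items = json.loads(block)
    return [(d["term"], d["hpo_id"]) for d in items]


def _normalize_key(key: str) -> str:
    return re.sub(r"[\s\-]+", "_", key.strip().casefold())


def parse_reply(raw: str) -> tuple[str, str]:
    """Extract (best-match label, HPO ID) from a model reply.

    Takes the first balanced JSON object in the reply (models often wrap
    the object in prose), and accepts the key spellings ``HPO ID``,
    ``HPO_ID`` and ``hpo_id`` for the identifier.  Raises
    :class:`ParseError` when no parseable object with both keys exists.
    """
    obj_text = _first_balanced(raw, "{", "}")
    if obj_text is None:
        raise ParseError("no JSON object in reply")
    try:
        obj = json.loads(obj_text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON object: {exc}") from exc
    if not isinstance(obj, dict):
        raise ParseError("reply JSON is not an object")
    by_key = {_normalize_key(k): v for k, v in obj.items()}
    label = by_key.get("best_match")
    hpo_id = by_key.get("hpo_id")
    if not isinstance(label, str) or not isinstance(hpo_id, str):
        raise ParseError("reply object lacks best_match / HPO ID keys")
    return label.strip(), hpo_id.strip()


# -- regimes -------------------------------------------------------------


@dataclass
class NormalizationResources:
    """Everything a regime may need; each mode checks for what it uses.

    ``hallucination_policy`` governs RAG replies whose label is not among
    the shown candidates: ``strict`` replaces the answer with the rank-1
    candidate (keeping the flag as evidence), ``permissive`` keeps the
    model's answer.  ``repair_ids`` lets the candidate/index label→ID
    mapping override a disagreeing reply ID.  ``lenient_ids`` upcases
    ill-cased identifiers before validation.
    """

    cache: Optional[EmbeddingCache] = None
    backend: Optional[EmbeddingBackend] = None
    client: Optional[LLMClient] = None
    index: Optional[TermIndex] = None
    k: int = DEFAULT_K
    dedupe_ids: bool = False
    hallucination_policy: str = "strict"
    repair_ids: bool = False
    lenient_ids: bool = False
    max_retries: int = 3
    retry_backoff: float = 0.0  # seconds; exponential, 0 disables sleeping
    temperature: float = 0.0
    max_tokens: int = 256


def _call_with_retries(res: NormalizationResources, prompt: str):
    """Return (parsed or None, raw_reply, flags) after up to max_retries tries."""
    last_raw = ""
    for attempt in range(res.max_retries):
        try:
            last_raw = res.client.complete(
                prompt, temperature=res.temperature, max_tokens=res.max_tokens
            )
        except Exception as exc:  # transport failure: retry, then give up
            last_raw = f"<transport error: {exc}>"
            if res.retry_backoff:
                time.sleep(res.retry_backoff * (2**attempt))
            continue
        try:
            return parse_reply(last_raw), last_raw, set()
        except ParseError:
            if res.retry_backoff:
                time.sleep(res.retry_backoff * (2**attempt))
    return None, last_raw, {FLAG_PARSE_FAILED}


def _no_answer(term: str, method: str, cands, raw: str, flags: set[str]) -> NormalizationResult:
    return NormalizationResult(
        query_term=term,
        method=method,
        chosen_label=None,
        chosen_hpo_id=None,
        candidates_shown=tuple(cands),
        raw_reply=raw,
        flags=frozenset(flags | {FLAG_NO_ANSWER}),
    )


def _validate_id(hpo_id: str, res: NormalizationResources, flags: set[str]) -> Optional[str]:
    if validate_hpo_id(hpo_id):
        return hpo_id
    if res.lenient_ids:
        fixed = canonicalize_hpo_id(hpo_id)
        if fixed is not None:
            return fixed
    flags.add(FLAG_ID_INVALID)
    return hpo_id


def normalize_term(
    term: str, mode: str, resources: NormalizationResources
) -> NormalizationResult:
    """Run one regime end-to-end for one term; never raises past transport.

    Reply validation: the ID must be well-formed (else ``id_invalid``); in
    RAG mode the chosen label must appear among the shown candidates under
    case-insensitive comparison (else ``label_not_in_candidates``, handled
    per the hallucination policy); a label whose reply ID disagrees with
    the candidate/index mapping gets ``id_label_mismatch``.  Parse failure
    after the configured retries yields a ``no_answer`` result, which the
    evaluation stage scores as a false negative.
    """
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "embedding-argmax":
        from .retrieve import best_match

        if resources.cache is None or resources.backend is None:
            raise ValueError("embedding-argmax needs cache and backend")
        return best_match(term, resources.cache, resources.backend)

    if resources.client is None:
        raise ValueError(f"{mode} needs an LLM client")

    if mode == "llm-direct":
        prompt = build_direct_prompt(term)
        parsed, raw, flags = _call_with_retries(resources, prompt)
        if parsed is None:
            return _no_answer(term, mode, (), raw, flags)
        label, hpo_id = parsed
        hpo_id = _validate_id(hpo_id, resources, flags)
        if resources.index is not None:
            from .ontology import exact_match

            hit = exact_match(label, resources.index)
            if hit is not None and hit.hpo_id != hpo_id:
                flags.add(FLAG_ID_LABEL_MISMATCH)
                if resources.repair_ids:
                    hpo_id = hit.hpo_id
                    flags.discard(FLAG_ID_INVALID)
        return NormalizationResult(
            query_term=term,
            method=mode,
            chosen_label=label,
            chosen_hpo_id=hpo_id,
            candidates_shown=(),
            raw_reply=raw,
            flags=frozenset(flags),
        )

    # llm-rag
    if resources.cache is None or resources.backend is None:
        raise ValueError("llm-rag needs cache and backend")
    cands = tuple(
        top_k(
            term,
            resources.cache,
            k=resources.k,
            backend=resources.backend,
            dedupe_ids=resources.dedupe_ids,
        )
    )
    return normalize_with_candidates(term, cands, resources)


def normalize_with_candidates(
    term: str,
    candidates: Sequence[CandidateMatch],
    resources: NormalizationResources,
) -> NormalizationResult:
    """RAG regime over an already-retrieved candidate list.

    Lets a candidate-count sweep reuse a single top-max(k) retrieval pass,
    truncating per k, instead of re-embedding the query for every k.
    """
    if resources.client is None:
        raise ValueError("llm-rag needs an LLM client")
    cands = tuple(candidates)
    prompt = build_rag_prompt(term, cands)
    parsed, raw, flags = _call_with_retries(resources, prompt)
    if parsed is None:
        return _no_answer(term, "llm-rag", cands, raw, flags)
    label, hpo_id = parsed
    hpo_id = _validate_id(hpo_id, resources, flags)

    by_label: dict[str, str] = {}
    for c in cands:
        by_label.setdefault(normalize_surface(c.record.surface_label), c.record.hpo_id)
    key = normalize_surface(label)
    if key not in by_label:
        flags.add(FLAG_LABEL_NOT_IN_CANDIDATES)
        if resources.hallucination_policy == "strict":
            label = cands[0].record.surface_label
            hpo_id = cands[0].record.hpo_id
            key = normalize_surface(label)
    if key in by_label and by_label[key] != hpo_id:
        flags.add(FLAG_ID_LABEL_MISMATCH)
        if resources.repair_ids:
            hpo_id = by_label[key]
            flags.discard(FLAG_ID_INVALID)

    return NormalizationResult(
        query_term=term,
        method="llm-rag",
        chosen_label=label,
        chosen_hpo_id=hpo_id,
        candidates_shown=cands,
        raw_reply=raw,
        flags=frozenset(flags),
    )


# -- batch driver --------------------------------------------------------


def write_results_jsonl(results: Iterable[NormalizationResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in results:
            fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")


def read_results_jsonl(path: str | Path) -> list[NormalizationResult]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(NormalizationResult.from_dict(json.loads(line)))
    return out


def normalize_batch(
    terms: Sequence[str],
    mode: str,
    resources: NormalizationResources,
    out_path: str | Path | None = None,
    resume: bool = False,
) -> tuple[list[NormalizationResult], dict]:
    """Normalize a list of terms; results are returned in input order.

    When ``out_path`` is given, results are appended to a JSONL file as
    they are produced, and a sidecar ``<out>.manifest.json`` records the
    run configuration.  ``resume=True`` skips terms already present in an
    existing output file, so an interrupted run never processes a term
    twice.  Per-term failures are isolated: the batch always completes.
    """
    if not terms:
        raise ValueError("terms must be non-empty")
    done: list[NormalizationResult] = []
    out_file = Path(out_path) if out_path is not None else None
    if resume and out_file is not None and out_file.exists():
        done = read_results_jsonl(out_file)
        if [r.query_term for r in done] != list(terms[: len(done)]):
            raise ValueError("existing output does not match the input term list")
    started = time.time()
    results = list(done)
    fh = open(out_file, "a" if resume else "w") if out_file is not None else None
    try:
        for term in terms[len(done):]:
            try:
                r = normalize_term(term, mode, resources)
            except Exception as exc:  # isolate per-term failures
                r = _no_answer(term, mode, (), f"<error: {exc}>", {FLAG_PARSE_FAILED})
            results.append(r)
            if fh is not None:
                fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")
                fh.flush()
    finally:
        if fh is not None:
            fh.close()
    manifest = {
        "mode": mode,
        "k": resources.k,
        "n_terms": len(terms),
        "n_resumed": len(done),
        "backend_id": resources.backend.backend_id if resources.backend else None,
        "client_identity": resources.client.identity if resources.client else None,
        "decoding": {
            "temperature": resources.temperature,
            "max_tokens": resources.max_tokens,
            "max_retries": resources.max_retries,
        },
        "hallucination_policy": resources.hallucination_policy,
        "repair_ids": resources.repair_ids,
        "started_unix": started,
        "finished_unix": time.time(),
    }
    if out_file is not None:
        Path(str(out_file) + ".manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True)
        )
    return results, manifest
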