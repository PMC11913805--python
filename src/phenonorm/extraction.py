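"""Sign/symptom extraction from clinical-feature texts, and term exclusion.

Free-text clinical synopses (e.g. OMIM *Clinical Features* sections) are
turned into candidate phenotype terms by prompting a language model to list
the bedside-observable signs and symptoms as a JSON array under the key
``"Signs"``.  Because such extraction yields some malformed phrases (vague,
contradictory, verbose or ambiguous), a curated exclusion list — a data
file of human judgments, one term per line, never an algorithm — filters
the extracted terms before normalization is attempted.

Fetching source texts from licensed databases is out of scope; this module
consumes already-downloaded text.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .normalize import LLMClient, ParseError, _first_balanced, load_prompt_asset
from .ontology import normalize_surface

__all__ = [
    "ExtractionRecord",
    "build_extraction_prompt",
    "parse_signs",
    "extract_signs",
    "apply_exclusion_list",
    "read_exclusion_list",
    "read_extraction_jsonl",
    "write_extraction_jsonl",
]

logger = logging.getLogger(__name__)


def _dedupe(signs: Iterable[str]) -> list[str]:
    """Trim, drop empties, dedupe case-insensitively keeping first occurrence."""
    out: list[str] = []
    seen: set[str] = set()
    for s in signs:
        t = str(s).strip()
        key = normalize_surface(t)
        if t and key not in seen:
            seen.add(key)
            out.append(t)
    return out


@dataclass(frozen=True)
class ExtractionRecord:
    """Signs extracted from one disease's clinical-feature text."""

    disease_id: str  # opaque catalogue number, e.g. an OMIM entry
    source_text: str
    signs: tuple[str, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "signs", tuple(_dedupe(self.signs)))

    def to_dict(self) -> dict:
        return {
            "disease_id": self.disease_id,
            "source_text": self.source_text,
            "signs": list(self.signs),
        }


def build_extraction_prompt(clinical_text: str) -> str:
    """Render the extraction prompt with the text embedded as a JSON object.

    The input is serialized as ``{"clinical Features": <text>}`` so quotes
    and newlines inside the source text cannot break the prompt structure.
    """
    if not clinical_text or not clinical_text.strip():
        raise ValueError("clinical text must be non-empty")
    payload = json.dumps({"clinical Features": clinical_text}, ensure_ascii=False)
    return load_prompt_asset("extraction.txt").replace("{input}", payload)


def parse_signs(raw: str) -> list[str]:
    """Extract the ``"Signs"`` array from a model reply.

    Trims entries and deduplicates them case-insensitively (first
    occurrence kept); an empty list is a valid result.  A key differing
    only in case (``"signs"``) is accepted and logged.  Missing key or
    malformed JSON raises :class:`~phenonorm.normalize.ParseError`.
    """
    obj_text = _first_balanced(raw, "{", "}")
    if obj_text is None:
        raise ParseError("no JSON object in extraction reply")
    try:
        obj = json.loads(obj_text)
    except json.JSONDecodeError as exc:
        raise ParseError(f"malformed JSON in extraction reply: {exc}") from exc
    if not isinstance(obj, dict):
        raise ParseError("extraction reply is not a JSON object")
    if "Signs" in obj:
        signs = obj["Signs"]
    else:
        lower = {k.casefold(): (k, v) for k, v in obj.items()}
        if "signs" not in lower:
            raise ParseError('extraction reply lacks the "Signs" key')
        key, signs = lower["signs"]
        logger.info("accepted non-canonical key %r for Signs", key)
    if not isinstance(signs, list):
        raise ParseError('"Signs" is not a list')
    return _dedupe(signs)


def extract_signs(disease_id: str, clinical_text: str, client: LLMClient) -> ExtractionRecord:
    """Prompt the model on one text and parse its reply into a record."""
    raw = client.complete(build_extraction_prompt(clinical_text))
    return ExtractionRecord(disease_id, clinical_text, tuple(parse_signs(raw)))


def apply_exclusion_list(
    signs: Sequence[str], exclusions: Sequence[str]
) -> tuple[list[str], list[str]]:
    """Partition signs into (kept, removed) against a curated exclusion list.

    Matching is case-insensitive with collapsed whitespace.  The two
    partitions always reassemble the input, and the operation is
    idempotent — re-filtering the kept list removes nothing further.
    """
    keys = set()
    for e in exclusions:
        if not str(e).strip():
            raise ValueError("exclusion entries must be non-empty")
        keys.add(normalize_surface(e))
    kept, removed = [], []
    for s in signs:
        (removed if normalize_surface(s) in keys else kept).append(s)
    return kept, removed


def read_exclusion_list(path: str | Path) -> list[str]:
    """One excluded term per line; blank lines and '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        t = line.strip()
        if t and not t.startswith("#"):
            out.append(t)
    return out


def write_extraction_jsonl(records: Iterable[ExtractionRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(json.dumps(r.to_dict(), sort_keys=True) + "\n")


def read_extraction_jsonl(path: str | Path) -> list[ExtractionRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                d = json.loads(line)
                out.append(ExtractionRecord(d["disease_id"], d["source_text"], tuple(d["signs"])))
    return out
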