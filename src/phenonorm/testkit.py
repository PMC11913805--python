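"""Synthetic fixtures: toy ontologies, gold mappings, scripted LLM clients.

Everything the pipeline needs can be generated deterministically from a
seed, so retrieval, prompting, selection and scoring are exercisable
end-to-end with no downloads, no model weights and no API keys.

The toy ontology mimics the structure that matters for normalization: a
set of concepts with canonical labels built from a small clinical
vocabulary (qualifier + body part + finding), zero-padded HP-style IDs,
and rule-generated synonyms (pluralization, word reorder, adjective
insertion).  Each concept also gets an *irregular query form* — a
paraphrase using qualifier substitutions that is deliberately further from
the canonical label than the synonyms are — so that n-gram retrieval
places the gold concept in the top k most of the time but not always.
That gap is what gives the evaluation suite true positives, false
positives and retrieval misses by construction.
"""

from __future__ import annotations

import csv
import json
import random
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

from .normalize import parse_candidate_block

__all__ = [
    "ToyOntologySpec",
    "ToyFixture",
    "generate_toy_ontology",
    "ScriptedLLMClient",
    "scripted_llm",
    "perfect_oracle_client",
    "rank1_client",
    "DEFAULT_VOCABULARY",
]

# qualifier stems, body parts, findings — enough for 10*10*15 unique labels
DEFAULT_VOCABULARY: dict[str, list[str]] = {
    "qualifiers": [
        "Absent", "Reduced", "Increased", "Mild", "Severe",
        "Progressive", "Bilateral", "Proximal", "Distal", "Episodic",
    ],
    "parts": [
        "hand", "foot", "leg", "arm", "facial",
        "ocular", "truncal", "gait", "speech", "limb",
    ],
    "findings": [
        "reflexes", "weakness", "tremor", "ataxia", "spasticity",
        "seizures", "atrophy", "numbness", "rigidity", "dystonia",
        "nystagmus", "dysarthria", "hypotonia", "clonus", "myoclonus",
    ],
}

# paraphrase table used only for the irregular query forms
_QUALIFIER_PARAPHRASE = {
    "Absent": "missing",
    "Reduced": "diminished",
    "Increased": "heightened",
    "Mild": "slight",
    "Severe": "marked",
    "Progressive": "worsening",
    "Bilateral": "two-sided",
    "Proximal": "near",
    "Distal": "far",
    "Episodic": "intermittent",
}


@dataclass(frozen=True)
class ToyOntologySpec:
    """Recipe for one deterministic toy ontology."""

    n_concepts: int = 50
    synonyms_per_concept: tuple[int, int] = (1, 2)
    label_vocabulary: Optional[Mapping[str, Sequence[str]]] = None
    seed: int = 0


@dataclass(frozen=True)
class ToyFixture:
    """Paths and in-memory gold mapping of one generated fixture set."""

    ontology_csv: Path
    gold_csv: Path
    queries_txt: Path
    gold: dict[str, str] = field(default_factory=dict)  # irregular query -> HP ID
    canonical: dict[str, str] = field(default_factory=dict)  # HP ID -> label


def _pluralize(label: str) -> str:
    return label[:-1] if label.endswith("s") else label + "s"


def _synonym_variants(qual: str, part: str, find: str, rng: random.Random) -> list[str]:
    """Candidate synonym surface forms, in a fixed enumeration order."""
    base = f"{qual} {part} {find}"
    return [
        _pluralize(base),                       # inflection
        f"{part.capitalize()} {find}, {qual.casefold()}",  # token reorder
        f"{qual} notable {part} {find}",        # adjective insertion
        f"{qual} {find} of the {part}",         # prepositional rephrase
    ]


def generate_toy_ontology(spec: ToyOntologySpec, out_dir: str | Path) -> ToyFixture:
    """Write a BioPortal-dialect ontology CSV, a gold CSV and a query list.

    Outputs are byte-identical for identical (spec, seed).  Raises when the
    vocabulary cannot supply ``n_concepts`` unique labels.
    """
    if spec.n_concepts < 1:
        raise ValueError("n_concepts must be >= 1")
    lo, hi = spec.synonyms_per_concept
    if not (0 <= lo <= hi):
        raise ValueError("invalid synonyms_per_concept range")
    vocab = dict(spec.label_vocabulary or DEFAULT_VOCABULARY)
    combos = [
        (q, p, f)
        for q in vocab["qualifiers"]
        for p in vocab["parts"]
        for f in vocab["findings"]
    ]
    if spec.n_concepts > len(combos):
        raise ValueError(
            f"vocabulary supports at most {len(combos)} unique concepts, "
            f"{spec.n_concepts} requested"
        )
    rng = random.Random(spec.seed)
    chosen = rng.sample(combos, spec.n_concepts)
    id_numbers = sorted(rng.sample(range(1, 10_000_000), spec.n_concepts))

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ontology_csv = out / "ontology.csv"
    gold_csv = out / "gold.csv"
    queries_txt = out / "queries.txt"

    gold: dict[str, str] = {}
    canonical: dict[str, str] = {}
    with open(ontology_csv, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["Class ID", "Preferred Label", "Synonyms"])
        for (q, p, f), num in zip(chosen, id_numbers):
            hpo_id = f"HP:{num:07d}"
            label = f"{q} {p} {f}"
            n_syn = rng.randint(lo, hi)
            variants = _synonym_variants(q, p, f, rng)
            syns = rng.sample(variants, min(n_syn, len(variants)))
            w.writerow(
                [f"http://purl.obolibrary.org/obo/HP_{num:07d}", label, "|".join(syns)]
            )
            canonical[hpo_id] = label
            # irregular query: paraphrased qualifier, occasional inflection
            quals = dict(_QUALIFIER_PARAPHRASE)
            para = quals.get(q, q.casefold())
            query = f"{para} {p} {f}"
            if rng.random() < 0.5:
                query = _pluralize(query)
            gold[query] = hpo_id

    with open(gold_csv, "w", newline="") as fh:
        w = csv.writer(fh, lineterminator="\n")
        w.writerow(["term", "hpo_id"])
        for term in sorted(gold):
            w.writerow([term, gold[term]])
    queries_txt.write_text("\n".join(sorted(gold)) + "\n")

    return ToyFixture(ontology_csv, gold_csv, queries_txt, gold, canonical)


# -- scripted language-model clients -------------------------------------

Matcher = Callable[[str], bool]


class ScriptedLLMClient:
    """Chat client whose replies are scripted per prompt.

    The script is an ordered list of (matcher, reply); a matcher is either
    a substring or a predicate over the prompt, and the first match wins.
    Unmatched prompts get the default reply.  Every call is recorded in
    ``transcript`` for assertions.  A reply may itself be a callable
    (prompt → str) for computed responses.
    """

    def __init__(
        self,
        script: Sequence[tuple[str | Matcher, str | Callable[[str], str]]] = (),
        default_reply: str = "I cannot determine a match.",
        identity: str = "scripted-mock",
    ):
        self.script = list(script)
        self.default_reply = default_reply
        self.identity = identity
        self.transcript: list[tuple[str, str]] = []  # (prompt, reply)

    def complete(self, prompt: str, temperature: float = 0.0, max_tokens: int = 256) -> str:
        reply = self.default_reply
        for matcher, scripted in self.script:
            hit = matcher in prompt if isinstance(matcher, str) else matcher(prompt)
            if hit:
                reply = scripted
                break
        if callable(reply):
            reply = reply(prompt)
        self.transcript.append((prompt, reply))
        return reply


def scripted_llm(
    script: Sequence[tuple[str | Matcher, str | Callable[[str], str]]],
    default_reply: str = "I cannot determine a match.",
) -> ScriptedLLMClient:
    """Build a scripted mock client (see :class:`ScriptedLLMClient`)."""
    return ScriptedLLMClient(script, default_reply)


_TERM_RE = re.compile(r"^\"?Term: (.*?)\"?$", re.MULTILINE)


def _query_term(prompt: str) -> str:
    m = _TERM_RE.search(prompt)
    if m is None:
        raise ValueError("prompt has no 'Term:' line")
    return m.group(1).strip()


def perfect_oracle_client(gold: Mapping[str, str]) -> ScriptedLLMClient:
    """Client that selects the gold candidate whenever the retriever shows it.

    Parses the query term and the candidate block out of the prompt; if a
    candidate carries the query's gold HPO ID, it replies with exactly that
    candidate, otherwise it declines (an unparseable reply, scored as a
    false negative).  With this client, retrieval-augmented accuracy
    equals the retriever's top-k gold-containment rate — the ceiling that
    makes accuracy-vs-k curves plateau.
    """

    def _reply(prompt: str) -> str:
        term = _query_term(prompt)
        target = gold.get(term)
        for label, hpo_id in parse_candidate_block(prompt):
            if hpo_id == target:
                return json.dumps({"best_match": label, "hpo_id": hpo_id})
        return "No suitable match among the candidates."

    return ScriptedLLMClient(
        [(lambda p: "Possible matches:" in p, _reply)],
        identity="perfect-oracle-mock",
    )


def rank1_client() -> ScriptedLLMClient:
    """Client that always selects the first (rank-1) candidate shown.

    Equivalent to the embedding-argmax baseline routed through the RAG
    prompt; useful for generating false positives on purpose.
    """

    def _reply(prompt: str) -> str:
        label, hpo_id = parse_candidate_block(prompt)[0]
        return json.dumps({"best_match": label, "hpo_id": hpo_id})

    return ScriptedLLMClient(
        [(lambda p: "Possible matches:" in p, _reply)],
        identity="rank1-mock",
    )
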