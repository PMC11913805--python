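"""Scoring of normalization output: equivalence judgments, confusion
tally, metrics, candidate-count sweep, and method comparison.

A proposed normalization is scored in two steps.  First, *semantic
equivalence* between the query term and the proposed label is adjudicated
from up to three sources in increasing order of authority: a cosine
similarity threshold, a binary language-model judgment, and an expert
verdict read from a review file (expert review is data, never computed).
Second, the confusion tally applies the study conventions:

* true positive — the answer is semantically equivalent *and* carries the
  correct HPO ID;
* false positive — the method answered, but the answer is semantically
  wrong or its HPO ID is wrong;
* false negative — the method returned no normalization at all;
* true negatives — none by construction: malformed terms are excluded
  before normalization is attempted and are never counted.

Accuracy, precision, recall and F1 then follow the standard formulas,
reported to two decimals.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd

from .embedding import EmbeddingBackend, embed_term
from .normalize import (
    FLAG_NO_ANSWER,
    NormalizationResources,
    NormalizationResult,
    load_prompt_asset,
    normalize_with_candidates,
)
from .ontology import TermIndex, normalize_surface
from .retrieve import cosine_similarity, top_k

__all__ = [
    "EQUIVALENT",
    "NOT_EQUIVALENT",
    "UNAVAILABLE",
    "EquivalenceJudgment",
    "ConfusionCounts",
    "MetricsReport",
    "judge_cosine",
    "judge_llm",
    "adjudicate",
    "judgments_from_gold",
    "read_expert_reviews",
    "read_gold",
    "tally",
    "compute_metrics",
    "f1_from_precision_recall",
    "k_sweep",
    "build_delta_rows",
    "delta_table",
    "DEFAULT_COSINE_THRESHOLD",
]

EQUIVALENT = "equivalent"
NOT_EQUIVALENT = "not_equivalent"
UNAVAILABLE = "unavailable"

# Unstated in the source procedure; equivalent pairs in practice score >= ~0.91,
# so 0.90 is the default decision threshold. Always reported with raw scores.
DEFAULT_COSINE_THRESHOLD = 0.90


@dataclass(frozen=True)
class EquivalenceJudgment:
    """One adjudicated equivalence decision with its evidence trail."""

    query_term: str
    proposed_label: str
    cosine_score: Optional[float] = None
    llm_verdict: str = UNAVAILABLE
    expert_verdict: str = UNAVAILABLE
    cosine_verdict: str = UNAVAILABLE

    @property
    def final(self) -> str:
        return adjudicate(self.expert_verdict, self.llm_verdict, self.cosine_verdict)


def judge_cosine(
    query: str,
    proposed: str,
    backend: EmbeddingBackend,
    threshold: float = DEFAULT_COSINE_THRESHOLD,
) -> tuple[float, str]:
    """Equivalent iff cosine(query, proposed) >= threshold; score always kept."""
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    score = cosine_similarity(embed_term(query, backend), embed_term(proposed, backend))
    return score, (EQUIVALENT if score >= threshold else NOT_EQUIVALENT)


_YES = {"yes", "equivalent", "true", "y"}
_NO = {"no", "not equivalent", "not_equivalent", "false", "n"}


def judge_llm(query: str, proposed: str, client) -> str:
    """Binary semantic-equivalence judgment from a language model.

    The prompt template (``prompts/equivalence.reconstructed.txt``) is a
    reconstruction — the study does not print its judgment prompt — and is
    marked as such in the asset name.  Unparseable or failed replies yield
    ``unavailable`` rather than a guess.
    """
    tpl = load_prompt_asset("equivalence.reconstructed.txt")
    prompt = tpl.replace("{query}", query.strip()).replace("{proposed}", proposed.strip())
    try:
        raw = client.complete(prompt, temperature=0.0, max_tokens=8)
    except Exception:
        return UNAVAILABLE
    token = raw.strip().strip('."’').casefold()
    first = token.split()[0] if token.split() else ""
    if token in _YES or first in _YES:
        return EQUIVALENT
    if token in _NO or first in _NO:
        return NOT_EQUIVALENT
    return UNAVAILABLE


def adjudicate(expert: str, llm: str, cosine: str) -> str:
    """Resolve the final verdict: expert > LLM > cosine threshold."""
    for verdict in (expert, llm, cosine):
        if verdict in (EQUIVALENT, NOT_EQUIVALENT):
            return verdict
        if verdict != UNAVAILABLE:
            raise ValueError(f"unknown verdict {verdict!r}")
    raise ValueError("no equivalence judgment available from any source")


def judgments_from_gold(
    results: Sequence[NormalizationResult], gold: Mapping[str, str]
) -> dict[str, str]:
    """Synthetic-benchmark judgment: equivalent iff the chosen ID is gold.

    On generated fixtures the gold mapping *defines* semantic equivalence,
    so no cosine/LLM/expert adjudication is needed.
    """
    out = {}
    for r in results:
        if not r.answered:
            continue
        out[r.query_term] = (
            EQUIVALENT if r.chosen_hpo_id == gold.get(r.query_term) else NOT_EQUIVALENT
        )
    return out


def read_expert_reviews(path: str | Path) -> dict[tuple[str, str], str]:
    """Read an expert-review CSV (query, proposed, verdict) into a lookup."""
    out: dict[tuple[str, str], str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            v = row["verdict"].strip().casefold()
            verdict = EQUIVALENT if v in _YES | {EQUIVALENT} else NOT_EQUIVALENT
            out[(normalize_surface(row["query"]), normalize_surface(row["proposed"]))] = verdict
    return out


def read_gold(path: str | Path) -> dict[str, str]:
    """Read a gold CSV with columns term, hpo_id."""
    out: dict[str, str] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out[row["term"]] = row["hpo_id"]
    return out


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def tally(
    results: Sequence[NormalizationResult],
    judgments: Mapping[str, str],
    gold: Optional[Mapping[str, str]] = None,
    index: Optional[TermIndex] = None,
) -> ConfusionCounts:
    """Apply the TP/FP/FN conventions to a batch of results.

    ``judgments`` maps each answered query term to its final equivalence
    verdict.  The correct ID for a query comes from ``gold`` when given,
    otherwise from the ontology index mapping of the chosen label.  A
    result that answered but has no judgment is an error — silence must
    never default to a verdict.  TN stays 0 by convention.
    """
    if gold is None and index is None:
        raise ValueError("tally needs a gold mapping or an ontology index")
    if not results:
        raise ValueError("no results to tally (all terms excluded?)")
    tp = fp = fn = 0
    for r in results:
        if not r.answered:
            fn += 1
            continue
        if r.query_term not in judgments:
            raise ValueError(f"answered result without judgment: {r.query_term!r}")
        verdict = judgments[r.query_term]
        if gold is not None:
            correct_id = gold.get(r.query_term)
        else:
            from .ontology import exact_match

            hit = exact_match(r.chosen_label or "", index)
            correct_id = hit.hpo_id if hit is not None else None
        if verdict == EQUIVALENT and correct_id is not None and r.chosen_hpo_id == correct_id:
            tp += 1
        else:
            fp += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=0)


@dataclass(frozen=True)
class MetricsReport:
    counts: ConfusionCounts
    accuracy: float
    precision: float
    recall: float
    f1: float
    n: int

    def rounded(self, ndigits: int = 2) -> dict:
        """The report as printed: metrics to two decimals."""
        return {
            "accuracy": round(self.accuracy, ndigits),
            "precision": round(self.precision, ndigits),
            "recall": round(self.recall, ndigits),
            "f1": round(self.f1, ndigits),
            "n": self.n,
        }


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        warnings.warn(f"{what}: zero denominator, defined as 0", stacklevel=3)
        return 0.0
    return num / den


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """F1 = 2PR / (P + R); 0 when both are 0."""
    if precision == 0 and recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def compute_metrics(counts: ConfusionCounts) -> MetricsReport:
    """Accuracy, precision, recall and F1 from the confusion counts.

    accuracy = (TP+TN)/(TP+TN+FP+FN); precision = TP/(TP+FP);
    recall = TP/(TP+FN); F1 = 2PR/(P+R).  Degenerate zero denominators are
    defined as 0 with a warning; an empty tally is an error, never NaN.
    """
    c = counts
    if c.total == 0:
        raise ValueError("metrics undefined for an empty tally")
    precision = _safe_div(c.tp, c.tp + c.fp, "precision")
    recall = _safe_div(c.tp, c.tp + c.fn, "recall")
    return MetricsReport(
        counts=c,
        accuracy=(c.tp + c.tn) / c.total,
        precision=precision,
        recall=recall,
        f1=f1_from_precision_recall(precision, recall),
        n=c.total,
    )


def k_sweep(
    terms: Sequence[str],
    gold: Mapping[str, str],
    k_values: Sequence[int],
    resources: NormalizationResources,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Accuracy (and the other metrics) as a function of candidate count.

    Retrieval runs once per term at max(k); each smaller k truncates that
    list before prompting, so the sweep isolates the effect of candidate
    count from retrieval noise.  Returns one row per k; writes a CSV when
    asked.
    """
    ks = sorted(k_values)
    if list(k_values) != ks:
        raise ValueError("k values must be sorted ascending")
    kmax = ks[-1]
    retrieved = {
        t: top_k(t, resources.cache, k=kmax, backend=resources.backend,
                 dedupe_ids=resources.dedupe_ids)
        for t in terms
    }
    rows = []
    for k in ks:
        results = []
        for t in terms:
            cands = [c for c in retrieved[t][:k]]
            try:
                results.append(normalize_with_candidates(t, cands, resources))
            except Exception as exc:  # isolate per-term failures
                from .normalize import _no_answer, FLAG_PARSE_FAILED

                results.append(_no_answer(t, "llm-rag", cands, f"<error: {exc}>",
                                          {FLAG_PARSE_FAILED}))
        judgments = judgments_from_gold(results, gold)
        report = compute_metrics(tally(results, judgments, gold=gold))
        rows.append({"k": k, **report.rounded(6), **{
            "tp": report.counts.tp, "fp": report.counts.fp, "fn": report.counts.fn}})
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df


def build_delta_rows(
    entries: Sequence[tuple[str, str, float, str, float]], ndigits: int = 2
) -> pd.DataFrame:
    """Δ table from explicit scores: (query, choice_a, cs_a, choice_b, cs_b).

    Scores are rounded to the reporting precision first, and Δ is the
    difference of the rounded similarities, matching how the comparison is
    printed.  Rows where both methods chose the same term are omitted.
    """
    rows = []
    for query, choice_a, cs_a, choice_b, cs_b in entries:
        if normalize_surface(choice_a) == normalize_surface(choice_b):
            continue
        ra, rb = round(cs_a, ndigits), round(cs_b, ndigits)
        rows.append(
            {
                "query": query,
                "choice_a": choice_a,
                "cs_a": ra,
                "choice_b": choice_b,
                "cs_b": rb,
                "delta": round(ra - rb, ndigits),
            }
        )
    return pd.DataFrame(rows, columns=["query", "choice_a", "cs_a", "choice_b", "cs_b", "delta"])


def delta_table(
    results_a: Sequence[NormalizationResult],
    results_b: Sequence[NormalizationResult],
    backend: EmbeddingBackend,
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Compare two methods' choices query by query.

    For every query where the two result sets chose different concepts,
    computes the cosine similarity of each choice to the query and the
    difference Δ = cs_a − cs_b (2 d.p.).  Queries with identical choices
    are omitted.  Both result sets must cover the same queries.
    """
    by_query_b = {r.query_term: r for r in results_b}
    missing = [r.query_term for r in results_a if r.query_term not in by_query_b]
    if missing:
        raise ValueError(f"result sets cover different queries, e.g. {missing[0]!r}")
    entries = []
    for ra in results_a:
        rb = by_query_b[ra.query_term]
        if not (ra.answered and rb.answered):
            continue
        if ra.chosen_hpo_id == rb.chosen_hpo_id:
            continue
        q = embed_term(ra.query_term, backend)
        cs_a = cosine_similarity(q, embed_term(ra.chosen_label, backend))
        cs_b = cosine_similarity(q, embed_term(rb.chosen_label, backend))
        entries.append((ra.query_term, ra.chosen_label, cs_a, rb.chosen_label, cs_b))
    df = build_delta_rows(entries)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
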