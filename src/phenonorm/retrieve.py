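"""Cosine-similarity retrieval of candidate HPO terms.

A query term is embedded once, scored against every precomputed ontology
vector, and the highest-scoring entries are returned in rank order.  Rank 1
alone is the standalone embedding baseline ("pick the nearest HPO term");
the top k (default 20) feed the retrieval-augmented language-model
selector.  Ties are broken deterministically by ascending HPO ID, then
ascending surface label.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .embedding import EmbeddingBackend, EmbeddingCache, EmbeddingVector, embed_term
from .ontology import TermRecord

__all__ = ["CandidateMatch", "cosine_similarity", "top_k", "best_match", "gold_containment"]

DEFAULT_K = 20


@dataclass(frozen=True)
class CandidateMatch:
    """One retrieved ontology entry: (record, cosine score, 1-based rank)."""

    record: TermRecord
    score: float
    rank: int


def cosine_similarity(a: EmbeddingVector | np.ndarray, b: EmbeddingVector | np.ndarray) -> float:
    """dot(a, b) / (‖a‖·‖b‖), in [-1, 1] up to rounding.

    Raises on dimension mismatch or a zero-norm vector (a zero vector
    signals a degenerate embedding, not "no similarity").
    """
    va = a.values if isinstance(a, EmbeddingVector) else np.asarray(a, dtype=np.float64)
    vb = b.values if isinstance(b, EmbeddingVector) else np.asarray(b, dtype=np.float64)
    if va.shape != vb.shape:
        raise ValueError(f"dimension mismatch: {va.shape} vs {vb.shape}")
    na, nb = np.linalg.norm(va), np.linalg.norm(vb)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for zero-norm vector")
    return float(np.dot(va, vb) / (na * nb))


def _record_for(cache: EmbeddingCache, i: int) -> TermRecord:
    # The cache stores surface forms only; canonical resolution is done by
    # callers holding the index.  Surface==canonical here marks "as stored".
    return TermRecord(
        surface_label=cache.labels[i],
        canonical_label=cache.labels[i],
        hpo_id=cache.hpo_ids[i],
        is_synonym=False,
    )


def top_k(
    query: str,
    cache: EmbeddingCache,
    k: int = DEFAULT_K,
    backend: EmbeddingBackend = None,
    dedupe_ids: bool = False,
) -> list[CandidateMatch]:
    """Return the min(k, cache size) best-scoring entries, rank-ordered.

    Candidates are distinct cache records, so two synonyms of one concept
    may both appear; ``dedupe_ids=True`` keeps only the best-scoring record
    per HPO ID before truncation.
    """
    if backend is None:
        raise ValueError("an embedding backend is required")
    if backend.backend_id != cache.backend_id:
        raise ValueError(
            f"backend {backend.backend_id!r} does not match cache {cache.backend_id!r}"
        )
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(cache) == 0:
        raise ValueError("empty cache")
    q = embed_term(query, backend).values
    qn = np.linalg.norm(q)
    if qn == 0.0:
        raise ValueError("query embedded to a zero vector")
    norms = np.linalg.norm(cache.matrix, axis=1)
    if np.any(norms == 0.0):
        raise ValueError("cache contains a zero-norm vector")
    scores = (cache.matrix @ q) / (norms * qn)

    order = sorted(
        range(len(cache)),
        key=lambda i: (-scores[i], cache.hpo_ids[i], cache.labels[i]),
    )
    if dedupe_ids:
        seen: set[str] = set()
        filtered = []
        for i in order:
            if cache.hpo_ids[i] not in seen:
                seen.add(cache.hpo_ids[i])
                filtered.append(i)
        order = filtered
    out = []
    for rank, i in enumerate(order[:k], start=1):
        out.append(CandidateMatch(_record_for(cache, i), float(scores[i]), rank))
    return out


def best_match(query: str, cache: EmbeddingCache, backend: EmbeddingBackend):
    """Standalone embedding baseline: the argmax-cosine HPO entry.

    Returns a :class:`~phenonorm.normalize.NormalizationResult` with
    method ``embedding-argmax``.
    """
    from .normalize import NormalizationResult

    cands = top_k(query, cache, k=1, backend=backend)
    best = cands[0]
    return NormalizationResult(
        query_term=query,
        method="embedding-argmax",
        chosen_label=best.record.surface_label,
        chosen_hpo_id=best.record.hpo_id,
        candidates_shown=cands,
        raw_reply="",
        flags=frozenset(),
    )


def gold_containment(
    queries: Sequence[str],
    gold: Mapping[str, str],
    cache: EmbeddingCache,
    backend: EmbeddingBackend,
    ks: Sequence[int],
) -> dict[int, float]:
    """Fraction of queries whose gold HPO ID appears in the top-k candidates.

    This is the ceiling on retrieval-augmented accuracy: a selector can
    only pick the right concept when the retriever surfaced it.
    """
    ks = sorted(ks)
    hits = {k: 0 for k in ks}
    kmax = ks[-1]
    for q in queries:
        cands = top_k(q, cache, k=kmax, backend=backend)
        ids = [c.record.hpo_id for c in cands]
        for k in ks:
            if gold[q] in ids[:k]:
                hits[k] += 1
    n = len(queries)
    return {k: hits[k] / n for k in ks}
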