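"""Term embeddings: backend contract, contextual mean pooling, vector cache.

Every ontology entry and every query term is mapped to one fixed-length
real vector.  The contextual backend tokenizes a term with a cased
biomedical BERT tokenizer (truncation at 128 tokens) and averages the
final-layer hidden states over all token positions — special tokens
included — to form a single "global" term vector.  Vectors are stored
unnormalized; length normalization happens inside cosine similarity.

Because a transformer backend needs model weights, the module also ships a
fully deterministic hashed character n-gram embedder for testing: strings
sharing more n-grams land closer in cosine, and the mapping depends only on
(dim, seed), never on process or platform.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .ontology import TermIndex

__all__ = [
    "EmbeddingVector",
    "EmbeddingBackend",
    "HashedNGramEmbedder",
    "BioBertEmbedder",
    "EmbeddingCache",
    "embed_term",
    "build_cache",
    "deterministic_test_embedder",
    "DEFAULT_CONTEXTUAL_MODEL",
]

DEFAULT_CONTEXTUAL_MODEL = "dmis-lab/biobert-base-cased-v1.1"


@dataclass(frozen=True)
class EmbeddingVector:
    """One term vector together with the backend that produced it."""

    values: np.ndarray
    backend_id: str
    source_text: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        object.__setattr__(self, "values", v)
        if v.ndim != 1 or v.size == 0:
            raise ValueError("embedding must be a non-empty 1-D vector")
        if not np.isfinite(v).any():
            raise ValueError("embedding has no finite components")

    @property
    def dim(self) -> int:
        return int(self.values.size)


@runtime_checkable
class EmbeddingBackend(Protocol):
    """Anything that maps strings to fixed-dim vectors.

    ``backend_id`` identifies model + revision + pooling options; caches
    refuse to mix vectors from different backend ids.
    """

    backend_id: str
    dim: int

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # (n, dim)
        ...


def embed_term(text: str, backend: EmbeddingBackend) -> EmbeddingVector:
    """Embed a single term; deterministic for a fixed backend revision."""
    if not text or not text.strip():
        raise ValueError("cannot embed empty text")
    text = text.strip()
    mat = backend.embed([text])
    return EmbeddingVector(np.asarray(mat)[0], backend.backend_id, text)


class HashedNGramEmbedder:
    """Deterministic test backend: seeded hashing of character n-grams.

    Each padded character n-gram of the casefolded text is hashed (BLAKE2b,
    keyed by the seed) to a coordinate and a sign; the vector is the sum of
    those one-hot signed contributions.  Strings sharing more n-grams get a
    larger expected dot product, so near-duplicate strings are near in
    cosine — a small-scale stand-in for the geometry of contextual
    embeddings, adequate for exercising retrieval and evaluation logic.
    """

    def __init__(self, dim: int = 128, seed: int = 0, ngram: int = 3):
        if dim < 2:
            raise ValueError("dim must be >= 2")
        self.dim = int(dim)
        self.seed = int(seed)
        self.ngram = int(ngram)
        self.backend_id = f"hashed-ngram/n{self.ngram}-d{self.dim}-s{self.seed}"
        self._key = str(self.seed).encode()

    def _grams(self, text: str) -> list[str]:
        s = "\x02" + " ".join(text.split()).casefold() + "\x03"
        n = self.ngram
        if len(s) <= n:
            return [s]
        return [s[i : i + n] for i in range(len(s) - n + 1)]

    def _one(self, text: str) -> np.ndarray:
        v = np.zeros(self.dim, dtype=np.float64)
        for g in self._grams(text):
            h = hashlib.blake2b(g.encode(), key=self._key, digest_size=8).digest()
            x = int.from_bytes(h, "big")
            v[x % self.dim] += 1.0 if (x >> 32) & 1 else -1.0
        if not v.any():  # cannot happen for non-empty text, but stay total
            v[0] = 1.0
        return v

    def embed(self, texts: Sequence[str]) -> np.ndarray:
        return np.stack([self._one(t) for t in texts])


def deterministic_test_embedder(dim: int = 128, seed: int = 0) -> HashedNGramEmbedder:
    """Factory for the seeded test backend (see :class:`HashedNGramEmbedder`)."""
    return HashedNGramEmbedder(dim=dim, seed=seed)


class BioBertEmbedder:
    """Contextual backend: mean-pooled final hidden states of a cased
    biomedical BERT encoder (default ``dmis-lab/biobert-base-cased-v1.1``).

    The mean is taken over every token position the tokenizer emits,
    special start/end tokens included (set ``include_special_tokens=False``
    to pool over content tokens only).  Batched calls mask padding
    positions out of the mean so batch composition cannot change a vector.

    Requires the optional ``transformers`` + ``torch`` dependencies and
    model weights; import is deferred so the rest of the package works
    without them.
    """

    def __init__(
        self,
        model_name: str = DEFAULT_CONTEXTUAL_MODEL,
        max_length: int = 128,
        include_special_tokens: bool = True,
        device: str = "cpu",
    ):
        try:
            import torch  # noqa: F401
            from transformers import AutoModel, AutoTokenizer
        except ImportError as exc:  # pragma: no cover - optional dependency
            raise ImportError(
                "BioBertEmbedder needs the 'biobert' extra (transformers + torch)"
            ) from exc
        self._torch = torch
        self.tokenizer = AutoTokenizer.from_pretrained(model_name)
        self.model = AutoModel.from_pretrained(model_name).to(device).eval()
        self.max_length = max_length
        self.include_special_tokens = include_special_tokens
        self.dim = int(self.model.config.hidden_size)
        pooling = "all-tokens" if include_special_tokens else "content-tokens"
        self.backend_id = f"{model_name}@{pooling}-L{max_length}"
        self._device = device

    def embed(self, texts: Sequence[str]) -> np.ndarray:  # pragma: no cover
        torch = self._torch
        enc = self.tokenizer(
            list(texts),
            return_tensors="pt",
            truncation=True,
            padding=True,
            max_length=self.max_length,
        ).to(self._device)
        with torch.no_grad():
            hidden = self.model(**enc).last_hidden_state  # (b, t, d)
        mask = enc["attention_mask"].unsqueeze(-1).float()
        if not self.include_special_tokens and "special_tokens_mask" not in enc:
            special = torch.zeros_like(enc["attention_mask"])
            for i, ids in enumerate(enc["input_ids"]):
                sm = self.tokenizer.get_special_tokens_mask(
                    ids.tolist(), already_has_special_tokens=True
                )
                special[i] = torch.tensor(sm)
            mask = mask * (1 - special).unsqueeze(-1).float()
        summed = (hidden * mask).sum(dim=1)
        counts = mask.sum(dim=1).clamp(min=1)
        return (summed / counts).cpu().numpy().astype(np.float64)


class EmbeddingCache:
    """Precomputed vectors for every index record, persisted as CSV.

    The CSV has columns ``surface_label, hpo_id, v0 … v{dim-1}``; a JSON
    sidecar manifest records backend id and dimension so that caches built
    with different backends can never be silently mixed.
    """

    def __init__(
        self,
        labels: Sequence[str],
        hpo_ids: Sequence[str],
        matrix: np.ndarray,
        backend_id: str,
    ):
        matrix = np.asarray(matrix, dtype=np.float64)
        if matrix.ndim != 2 or len(labels) != matrix.shape[0] or len(hpo_ids) != len(labels):
            raise ValueError("labels, hpo_ids and matrix rows must align")
        self.labels = list(labels)
        self.hpo_ids = list(hpo_ids)
        self.matrix = matrix
        self.backend_id = backend_id
        self._keys = {(l, h): i for i, (l, h) in enumerate(zip(self.labels, self.hpo_ids))}

    @property
    def dim(self) -> int:
        return int(self.matrix.shape[1])

    def __len__(self) -> int:
        return len(self.labels)

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self._keys

    def vector(self, surface_label: str, hpo_id: str) -> np.ndarray:
        return self.matrix[self._keys[(surface_label, hpo_id)]]

    # -- persistence ---------------------------------------------------

    @staticmethod
    def _paths(path: str | Path) -> tuple[Path, Path]:
        p = Path(path)
        if p.suffix != ".csv":
            p = p / "embeddings.csv"
        return p, p.with_suffix(".manifest.json")

    def save(self, path: str | Path, **options) -> Path:
        csv_path, man_path = self._paths(path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        cols = {"surface_label": self.labels, "hpo_id": self.hpo_ids}
        for j in range(self.dim):
            cols[f"v{j}"] = self.matrix[:, j]
        pd.DataFrame(cols).to_csv(csv_path, index=False, float_format="%.10g")
        manifest = {
            "backend_id": self.backend_id,
            "dim": self.dim,
            "n_entries": len(self),
            "options": options,
        }
        man_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return csv_path

    @classmethod
    def load(cls, path: str | Path) -> "EmbeddingCache":
        csv_path, man_path = cls._paths(path)
        manifest = json.loads(man_path.read_text())
        df = pd.read_csv(csv_path, dtype={"surface_label": str, "hpo_id": str})
        vcols = [f"v{j}" for j in range(int(manifest["dim"]))]
        cache = cls(
            df["surface_label"].tolist(),
            df["hpo_id"].tolist(),
            df[vcols].to_numpy(dtype=np.float64),
            manifest["backend_id"],
        )
        return cache


def build_cache(
    index: TermIndex,
    backend: EmbeddingBackend,
    existing: Optional[EmbeddingCache] = None,
    batch_size: int = 64,
    progress: bool = False,
) -> EmbeddingCache:
    """Embed every index record, reusing entries from ``existing``.

    Rebuilding over an identical cache computes zero new embeddings; an
    ``existing`` cache from a different backend raises rather than mixing
    vector spaces.
    """
    if len(index) == 0:
        raise ValueError("cannot build a cache from an empty index")
    if existing is not None and existing.backend_id != backend.backend_id:
        raise ValueError(
            f"cache backend {existing.backend_id!r} != requested {backend.backend_id!r}"
        )
    labels, ids, rows = [], [], []
    todo: list[tuple[str, str]] = []
    for rec in index:
        key = (rec.surface_label, rec.hpo_id)
        labels.append(rec.surface_label)
        ids.append(rec.hpo_id)
        if existing is not None and key in existing:
            rows.append(existing.vector(*key))
        else:
            rows.append(None)
            todo.append(key)
    if todo:
        it = range(0, len(todo), batch_size)
        if progress:
            from tqdm import tqdm  # pragma: no cover

            it = tqdm(it, desc="embedding")  # pragma: no cover
        fresh: list[np.ndarray] = []
        for start in it:
            chunk = [t[0] for t in todo[start : start + batch_size]]
            fresh.extend(np.asarray(backend.embed(chunk)))
        fi = iter(fresh)
        rows = [r if r is not None else next(fi) for r in rows]
    return EmbeddingCache(labels, ids, np.stack(rows), backend.backend_id)
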