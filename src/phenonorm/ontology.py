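"""Human Phenotype Ontology term index with synonym expansion.

The HPO assigns every phenotypic abnormality a canonical label (e.g.
``Hyporeflexia``) and an identifier of the form ``HP:`` followed by exactly
seven digits (``HP:0001265``).  Normalization pipelines search not only the
canonical labels but every recorded synonym, each pointing back to its
canonical concept; this module loads an ontology file (BioPortal CSV export
or OBO), performs that synonym expansion, and offers exact-match lookup and
enumeration over the expanded term list.
"""

from __future__ import annotations

import csv
import hashlib
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Optional

import pandas as pd

__all__ = [
    "TermRecord",
    "TermIndex",
    "CsvDialect",
    "LoadReport",
    "load_ontology",
    "validate_hpo_id",
    "canonicalize_hpo_id",
    "exact_match",
    "normalize_surface",
]

_HPO_ID_RE = re.compile(r"^HP:\d{7}$")
# BioPortal "Class ID" columns carry purl URLs such as
# http://purl.obolibrary.org/obo/HP_0001265
_PURL_RE = re.compile(r"(HP)[_:](\d{7})$", re.IGNORECASE)


def validate_hpo_id(candidate: str, strict: bool = True) -> bool:
    """Check that a string is a well-formed HPO identifier.

    A valid ID is the prefix ``HP:`` followed by exactly seven decimal
    digits.  In strict mode (default) the prefix must be upper-case; in
    lenient mode the prefix is matched case-insensitively (callers should
    then upcase via :func:`canonicalize_hpo_id`).
    """
    if not isinstance(candidate, str):
        return False
    if strict:
        return bool(_HPO_ID_RE.match(candidate))
    return bool(_HPO_ID_RE.match(candidate.strip().upper()))


def canonicalize_hpo_id(candidate: str) -> Optional[str]:
    """Return the canonical ``HP:nnnnnnn`` form, or None if unsalvageable.

    Accepts lenient casing (``hp:0001265``) and BioPortal purl URLs.
    """
    s = candidate.strip()
    if validate_hpo_id(s):
        return s
    up = s.upper()
    if validate_hpo_id(up):
        return up
    m = _PURL_RE.search(s)
    if m:
        return f"HP:{m.group(2)}"
    return None


def normalize_surface(text: str) -> str:
    """Matching key: trim, collapse internal whitespace, casefold."""
    return " ".join(text.split()).casefold()


@dataclass(frozen=True)
class TermRecord:
    """One searchable ontology entry: a canonical label or a synonym.

    ``surface_label`` is the matchable text; ``canonical_label`` and
    ``hpo_id`` always identify the concept the surface form resolves to,
    so a synonym hit still yields the (canonical label, HPO ID) answer.
    """

    surface_label: str
    canonical_label: str
    hpo_id: str
    is_synonym: bool

    def __post_init__(self) -> None:
        if not self.surface_label.strip():
            raise ValueError("surface_label must be non-empty after trimming")
        if not validate_hpo_id(self.hpo_id):
            raise ValueError(f"malformed HPO ID: {self.hpo_id!r}")
        if not self.is_synonym and self.surface_label != self.canonical_label:
            raise ValueError("canonical record must have surface_label == canonical_label")


@dataclass
class LoadReport:
    """Rejected input rows (malformed IDs etc.), never silently dropped."""

    rejects: list[tuple[int, str]] = field(default_factory=list)  # (line no., reason)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["line", "reason"])
            w.writerows(self.rejects)


class TermIndex:
    """Ordered, synonym-expanded term list with exact-match lookup.

    Duplicate (surface form, HPO ID) pairs — compared case-insensitively
    with collapsed whitespace — are deduplicated at construction, the first
    occurrence winning, so a synonym that restates its canonical label does
    not inflate the expanded count.
    """

    def __init__(self, records: Iterable[TermRecord]):
        self._records: list[TermRecord] = []
        self._by_surface: dict[str, list[TermRecord]] = {}
        seen: set[tuple[str, str]] = set()
        canonical_ids: dict[str, str] = {}
        for rec in records:
            key = (normalize_surface(rec.surface_label), rec.hpo_id)
            if key in seen:
                continue
            seen.add(key)
            self._records.append(rec)
            self._by_surface.setdefault(key[0], []).append(rec)
            if not rec.is_synonym:
                if rec.hpo_id in canonical_ids:
                    raise ValueError(f"two canonical records for {rec.hpo_id}")
                canonical_ids[rec.hpo_id] = rec.canonical_label
        if not self._records:
            raise ValueError("ontology contains no valid records")
        self._canonical_ids = canonical_ids
        orphans = {r.hpo_id for r in self._records if r.is_synonym} - set(canonical_ids)
        if orphans:
            raise ValueError(f"synonym records with no canonical record: {sorted(orphans)[:5]}")

    @property
    def records(self) -> list[TermRecord]:
        return list(self._records)

    @property
    def n_canonical(self) -> int:
        return len(self._canonical_ids)

    @property
    def n_expanded(self) -> int:
        return len(self._records)

    def canonical_label_for(self, hpo_id: str) -> Optional[str]:
        return self._canonical_ids.get(hpo_id)

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TermRecord]:
        return iter(self._records)

    def manifest(self, source: str | Path | None = None, **options) -> dict:
        m = {
            "n_canonical": self.n_canonical,
            "n_expanded": self.n_expanded,
            "options": options,
        }
        if source is not None:
            p = Path(source)
            m["source"] = str(p)
            if p.exists():
                m["source_sha256"] = hashlib.sha256(p.read_bytes()).hexdigest()
        return m

    def write_manifest(self, path: str | Path, **kwargs) -> None:
        Path(path).write_text(json.dumps(self.manifest(**kwargs), indent=2, sort_keys=True))


def exact_match(term: str, index: TermIndex) -> Optional[TermRecord]:
    """Look up a term under case-insensitive, whitespace-collapsed equality.

    Used for reporting exact-hit rates; the retrieval pipeline does not
    shortcut through it by default.  If one surface form maps to several
    concepts, the record with the smallest HPO ID is returned (canonical
    records preferred) for determinism.
    """
    hits = index._by_surface.get(normalize_surface(term))
    if not hits:
        return None
    return min(hits, key=lambda r: (r.hpo_id, r.is_synonym, r.surface_label))


@dataclass(frozen=True)
class CsvDialect:
    """Column names of the BioPortal HPO CSV export."""

    label: str = "Preferred Label"
    class_id: str = "Class ID"
    synonyms: str = "Synonyms"
    synonym_sep: str = "|"


def _iter_csv(path: Path, dialect: CsvDialect, report: LoadReport):
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in (dialect.label, dialect.class_id):
        if col not in df.columns:
            raise ValueError(f"CSV is missing required column {col!r}")
    has_syn = dialect.synonyms in df.columns
    for i in range(len(df)):  # CSV line = i + 2 (line 1 is the header)
        raw = df.iloc[i]
        line_no = i + 2
        label = str(raw[dialect.label]).strip()
        hpo_id = canonicalize_hpo_id(str(raw[dialect.class_id]))
        if hpo_id is None:
            report.rejects.append((line_no, f"malformed id {raw[dialect.class_id]!r}"))
            continue
        if not label:
            report.rejects.append((line_no, "empty label"))
            continue
        syns: list[str] = []
        if has_syn and str(raw[dialect.synonyms]).strip():
            syns = [s.strip() for s in str(raw[dialect.synonyms]).split(dialect.synonym_sep)]
        yield label, hpo_id, [s for s in syns if s]


_OBO_SYN_RE = re.compile(r'"(.*)"')


def _iter_obo(path: Path, report: LoadReport):
    import obonet

    graph = obonet.read_obo(path, ignore_obsolete=True)
    for node, data in sorted(graph.nodes(data=True)):
        hpo_id = canonicalize_hpo_id(str(node))
        if hpo_id is None:
            report.rejects.append((0, f"non-HPO or malformed id {node!r}"))
            continue
        label = str(data.get("name", "")).strip()
        if not label:
            report.rejects.append((0, f"{hpo_id}: no name"))
            continue
        syns = []
        for raw in data.get("synonym", []):
            m = _OBO_SYN_RE.search(raw)
            if m and m.group(1).strip():
                syns.append(m.group(1).strip())
        yield label, hpo_id, syns


def load_ontology(
    path: str | Path,
    format: str = "csv",
    dialect: CsvDialect | None = None,
    rejects_path: str | Path | None = None,
) -> TermIndex:
    """Load an ontology file and expand every entry with its synonyms.

    Returns a :class:`TermIndex` with one canonical record per class plus
    one record per distinct synonym.  Rows with malformed identifiers are
    collected into a rejects report (written to ``rejects_path`` when
    given) rather than silently dropped; a file with zero valid records
    raises ``ValueError``.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(p)
    report = LoadReport()
    if format == "csv":
        rows = _iter_csv(p, dialect or CsvDialect(), report)
    elif format == "obo":
        rows = _iter_obo(p, report)
    else:
        raise ValueError(f"unknown ontology format {format!r}")

    records: list[TermRecord] = []
    for label, hpo_id, syns in rows:
        records.append(TermRecord(label, label, hpo_id, is_synonym=False))
        for s in syns:
            records.append(TermRecord(s, label, hpo_id, is_synonym=True))
    if rejects_path is not None:
        report.write_csv(rejects_path)
    if not records:
        raise ValueError(f"no valid records in {p}")
    index = TermIndex(records)
    index.load_report = report  # type: ignore[attr-defined]
    return index
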