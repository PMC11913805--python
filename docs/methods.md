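# Methods

## Model of the task

Term normalization is treated as entity linking into a fixed vocabulary:
an irregular term *q* must be resolved to one ontology concept, reported
as the pair (canonical label, HP ID). The pipeline factorizes into a
*retriever*, which proposes candidates by embedding similarity, and a
*selector* (a language model), which judges semantic equivalence among
them. The retriever requires no term definitions and no training: it
relies entirely on the geometry of contextual embeddings of the surface
forms.

Key assumption: for the selector to answer correctly, the correct concept
must be among the k candidates shown. Retrieval containment is therefore
a hard ceiling on retrieval-augmented accuracy, and the accuracy-vs-k
curve must rise toward and then plateau at that ceiling. The package
asserts this identity exactly under a perfect-selection mock.

## Ontology index

The loader accepts a BioPortal-style CSV (columns configurable; defaults
`Preferred Label`, `Class ID` with purl URLs accepted, `Synonyms`
pipe-separated) or OBO via `obonet`. Every synonym becomes its own
searchable record carrying its canonical label and ID, so a synonym hit
still produces the canonical answer. Matching for exact lookup and
deduplication trims, collapses internal whitespace and casefolds;
embeddings are computed on the raw trimmed surface form because cased
biomedical tokenizers distinguish case. IDs must match `HP:` + 7 digits;
a lenient mode upcases ill-cased prefixes. Malformed rows go to a rejects
report, never silently dropped. Graph structure (parents/children,
obsoletes) is out of scope.

## Embeddings

The contextual backend (`dmis-lab/biobert-base-cased-v1.1` by default,
behind the optional `biobert` extra) tokenizes with truncation at
max_length 128 and averages the final hidden layer over **all** token
positions, special tokens included; a flag pools over content tokens only.
Batched calls mask padding out of the mean so batch composition cannot
change a vector. Vectors are stored unnormalized; normalization happens
inside the cosine. The cache is a CSV (`surface_label, hpo_id, v0…`) plus
a JSON manifest recording backend id and dimension — caches from
different backends cannot be mixed, by construction.

The deterministic test embedder hashes padded character trigrams of the
casefolded string (BLAKE2b keyed by the seed) to signed coordinates.
Strings sharing more n-grams have larger expected dot products, so
near-paraphrases are near in cosine. Default dim 128: small enough to be
fast, large enough that hash collisions rarely disturb orderings. It
reproduces the *geometry* that retrieval needs, not the semantics of
contextual embeddings — passing tests show the pipeline's logic is
correct, not that any particular encoder is accurate on clinical text.

## Retrieval

Scores are full-precision cosines; candidates are sorted by descending
score with ties broken by ascending HP ID then surface label, so results
are identical across platforms and entry orderings. By default candidates
are distinct index records, so two synonyms of one concept can co-occupy
the top-k (the literal procedure); `dedupe_ids` keeps only the best
record per concept. k defaults to 20.

## Prompts, parsing, validation

The direct and retrieval-augmented prompt templates live as text assets
under `phenonorm/prompts/`; candidates are rendered as a JSON array (one
object per line) so labels containing commas or quotes survive a
round-trip. Replies must contain a JSON object with `best_match` and an
ID key; `HPO ID`, `HPO_ID` and `hpo_id` spellings are all accepted, and
the first balanced JSON object is extracted from surrounding prose.
Decoding is temperature 0, bounded reply length, 3 retries (exponential
backoff available); exhausted retries yield a `no_answer` result, scored
as a false negative.

Validation policy was genuinely open, so both options ship: a RAG answer
outside the candidate list is flagged `label_not_in_candidates` and, under
the default `strict` policy, replaced by the rank-1 candidate (the
`permissive` policy keeps it); a label whose reply ID disagrees with the
candidate/index mapping is flagged `id_label_mismatch`, and `repair_ids`
(off by default) lets the mapping win. Raw replies are always retained.

## Evaluation

Equivalence is adjudicated expert > LLM > cosine threshold; an
all-unavailable judgment is an error, never a silent default. Expert
verdicts are consumed from a review CSV — they are data, not code. The
cosine threshold default is 0.90 (configurable; raw scores are always
reported alongside), chosen because clearly-equivalent pairs in practice
score ≈0.91 and above. The equivalence-judgment prompt asset is a
reconstruction (marked `reconstructed` in its filename) since no original
wording is available. Zero-denominator metrics are defined as 0 with a
warning; an empty tally raises rather than returning NaN.

The k-sweep retrieves once at max(k) per term and truncates per k, so the
curve isolates candidate count from retrieval noise. The Δ table compares
two methods per query: where their chosen concepts differ, it reports the
cosine of each choice to the query (rounded to 2 d.p. first) and
Δ = cs_a − cs_b of the rounded values, matching reporting precision.

## Synthetic data

The toy ontology generator composes canonical labels from a clinical
vocabulary (10 qualifiers × 10 body parts × 15 findings), draws unique
zero-padded HP-style IDs, and adds 1–2 rule-generated synonyms per
concept (pluralization, token reorder, adjective insertion, prepositional
rephrase). Each concept also yields one *irregular query form* built by
paraphrasing the qualifier (Absent→missing, Reduced→diminished, …) with
occasional inflection — deliberately further from the canonical label
than the synonyms, so n-gram retrieval places gold at rank 1 only ~80% of
the time and inside the top-5 nearly always. That spread produces true
positives, false positives (via the rank-1 mock) and retrieval misses by
construction. Defaults: 50 concepts, synonym range (1, 2), all outputs
byte-identical given (spec, seed).

What the generator does **not** emulate: real clinical language (typos,
abbreviations, multi-finding phrases), the scale of the full HPO
(~18k entries → ~30k after expansion), contextual-encoder semantics, or
the behaviour of hosted language models. Green tests certify the
machinery — counting, ranking, prompting, parsing, scoring — not clinical
accuracy.

## Problem sizes and determinism

Tests and the acceptance script run at desk scale: 50-concept ontologies,
a 500-entry cache with 200 random queries for the retrieval oracle check,
sweeps over k ∈ {1, 2, 5, 10, 20, 50}. Every random draw flows from an
explicit seed (`random.Random`, keyed hashing); mock clients are
deterministic, so batch reruns are byte-identical.

## Known limitations

- The OBO loader takes the quoted text of each synonym line and ignores
  synonym scope (EXACT vs RELATED).
- `normalize_batch` is sequential; bounded concurrency is contracted
  (results in input order) but not implemented.
- The HTTP chat client and the contextual encoder backend are thin,
  unbenchmarked adapters; only their contracts are tested, via mocks.
- Exclusion of malformed terms is a curated data file by design —
  automating "malformedness" would be invented science.
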