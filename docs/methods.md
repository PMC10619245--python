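# Methods

## Co-occurrence model and the exact test

The unit of evidence is the abstract: two terms co-occur when both appear
in the same document, regardless of distance. For a pair (x, y) over N
eligible documents the 2×2 table (a, b, c, d) counts both / x-only /
y-only / neither, and significance is the one-sided Fisher's Exact Test in
the enrichment direction: p = P(X ≥ a) for X ~ Hypergeometric(N, n_x, n_y),
*including* the observed table — the standard over-representation tail.
Two-sided and depletion tests are out of scope, and no multiple-testing
correction is applied: the pipeline filters on raw p at a strict 10⁻⁵,
which is the algorithm's operating convention rather than a familywise
error guarantee.

Numerics: the tail is summed in log space. Each log-pmf term is assembled
from log-gamma (math.lgamma for tails up to 64 terms, vectorized
scipy gammaln + logsumexp beyond), summed with the usual max-shift trick.
Exhaustive comparison against exact rational summation over all 39,711
tables with N = 60 gives a maximum relative error of ~1.3 × 10⁻¹³. A
p-value whose exponent is below the subnormal range maps deterministically
to 0.0; the display convention renders anything below 2.2 × 10⁻³⁰⁸ (the
smallest normal double) as the string "0", and otherwise uses
one-significant-figure scientific notation.

Degenerate inputs: if either term matches no eligible document, p = 1 and
the pair is flagged `absent`. A Pearson chi-square (1 df, no continuity
correction) is available as an alternative measure; it is documented as
unreliable for small expected counts, and any zero margin returns p = 1
with a `degenerate` flag. The ratio reported per pair is a/n_y, in [0, 1].

## Text normalization and the index

One tokenizer is used for indexing, query matching, and knowledge-graph
entity names, so all three are consistent by construction: NFC-normalize,
lowercase, split on maximal runs of non-word characters (Unicode letters,
digits, underscore). Punctuation is ignored; there is no stemming or
lemmatization — "seizure" and "seizures" are distinct tokens, and synonym
lists are the intended mechanism for covering variants.

The index is a positional inverted index: token → (pmid → sorted
positions), plus pmid → publication year and the document count N
(documents whose text yields no tokens still count toward N). Title tokens
are indexed first, then abstract tokens after one unused position, so a
phrase can never match across the title/abstract boundary. Phrase matching
requires consecutive positions; a term matches a document if any synonym's
phrase does, and the document counts once.

Cutoff semantics: a cutoff year Y restricts every count — matches *and*
N — to documents with a *known* year ≤ Y. Documents with unknown year are
excluded under any active cutoff (conservative for historical rediscovery:
an undatable abstract can never leak post-discovery information) but
included when no cutoff is set. Sub-year granularity is not modelled.

Persistence is a versioned JSON container (format stamp, version, n_docs
header, then doc_meta and postings). The contract is query-result
equivalence after a round trip, not byte-identity of the file; a version
or format mismatch refuses to load. Duplicate PMIDs in corpus input
(record revisions) resolve last-wins with a warning at read time.

## The serial search

Open discovery runs in two stages with the defaults p < 10⁻⁵ (strict) and
a 300-pair cap. The threshold is applied first, then the cap keeps the
smallest surviving p-values; ties break by larger overlap count, then
labels, making every result list a total deterministic order (identical
inputs produce byte-identical output files). Each surviving B is paired
with every C; the chain (A, B, C) gets the prediction score

score = a_BC / n_C if p_BC < 10⁻⁵ else 0,

the significance-gated fraction of C's literature that B covers. This
gated-ratio form is this package's canonical instantiation of a score
defined elsewhere only by its ingredients (the B–C p-value and the
B∩C/C count ratio); it is a documented reconstruction, chosen because it
is monotone in the evidence, bounded in [0, 1], and zero exactly when the
link is not significant. Hits are ranked descending by score with
ascending B–C p-value and labels as tie-breaks; B = C self-links are
suppressed. Multiple A terms run as independent searches (the cap applies
per A term) whose outputs are concatenated.

Closed discovery computes, for each B, the A–B and B–C results through
the same code path as open discovery (so shared pairs agree bit-exactly)
and reports B terms significant on both sides, ordered by the weaker
p-value.

## Knowledge-graph annotation

A triples file (subject, subject type, relation, object, object type,
evidence PMIDs) loads into a directed multigraph over 5 entity types and
10 relation labels; rows with labels outside the closed sets, or with no
evidence, are skipped with warnings, and duplicate triples merge evidence.
Entity names are normalized with the corpus tokenizer and matched exactly
against a term's synonyms — no fuzzy matching, mirroring the engine's
exact-match philosophy. Annotation reports the stored edge direction
(COREF, POS_ASSOCIATION and NEG_ASSOCIATION are flagged symmetric for
display) and is a pure decoration: scores, p-values, and ranks are
unchanged, and a pair without a matching edge simply lacks annotations.

## Synthetic corpora

Real abstract corpora are too large to ship, so all statistical behaviour
is verified on generated pseudo-abstracts. Background tokens are drawn
i.i.d. from a Zipf-weighted vocabulary (exponent 1.1, mimicking
natural-language frequency skew); years are uniform over the configured
range; planted pairs put both terms in a document with probability
p_joint, one alone with p_x_only / p_y_only; planted phrases are inserted
at distinct random gaps so insertions never become adjacent. The manifest
records every placement, and contingency tables derived from it must equal
tables the index computes, exactly.

The documented planted-chain configuration — 400 documents, chain joint
rates 0.12, solo rates 0.03, distractor B/C terms at 0.05, plus
never-occurring decoys — is the condition under which open discovery is
required to rank the planted C first and pass the A–B threshold in ≥95%
of seeds. The null battery plants pairs whose joint probability factorizes
(p_xy = p_x·p_y, marginals 0.05) in 2,000 documents; because the exact
test is conservative, the fraction of null p-values below 0.05 stays under
0.08. The cap stress corpus is deterministic: one anchor term co-occurring
with 400 B terms in 5–14 documents each inside a 100,000-document corpus
(padded with empty documents, which count toward N), making all 400 pairs
significant so the cap alone decides survival.

What the generator does *not* emulate: real linguistic structure, MeSH
indexing, temporal publication trends, correlated vocabulary between
documents, or term ambiguity (a real "IF" gene symbol collides with
ordinary prose; synthetic terms never collide). Passing tests therefore
demonstrate the statistics, the filtering contracts, and the plumbing —
not retrieval quality on real PubMed text.

## Problem sizes and determinism

The default verification runs use: the full 39,711-table N = 60
enumeration for oracle agreement; 200 null pairs × 2,000 documents for
calibration; 50 seeds of the chain configuration for recovery; and the
400-pair / 100,000-document stress corpus for the cap. These sizes give
stable pass/fail behaviour across seeds while keeping a full run in
seconds. All randomness flows from numpy's `default_rng` seeded from the
corpus spec; identical spec + seed yields byte-identical corpora and
result files.

## Known limitations

Single-token background vocabulary makes synthetic phrase matching easier
than real text; the index is held in memory and serialized as JSON, which
is fine at fixture scale but would need a compact memory-mapped layout for
tens of millions of abstracts; the chi-square alternative is provided for
completeness, not recommended; and the prediction score is a
reconstruction (see above), so rankings on real corpora may differ from
other implementations of the same two ingredients.
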