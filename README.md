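# skimlbd — serial literature-based discovery over abstract corpora

`skimlbd` implements the Serial KinderMiner (SKiM) algorithm for
literature-based discovery (LBD): finding implicit A–B–C relationships in a
corpus of abstracts, where a source concept A (say, a disease) is connected
to candidate target concepts C (say, drugs) through intermediate concepts B
(say, phenotypes) that co-occur with both. It is aimed at researchers doing
hypothesis generation — drug repurposing, mechanism hunting — who want a
transparent, statistics-first alternative to black-box relation extraction.

## The model

For a term pair (x, y) over an N-abstract corpus, form the 2×2 table of
abstract counts

|              | y present | y absent |
|--------------|-----------|----------|
| **x present**| a         | b        |
| **x absent** | c         | d        |

with margins n_x = a + b and n_y = a + c. The association measure is the
one-sided Fisher's Exact Test in the enrichment direction,

p = P(X ≥ a),  X ~ Hypergeometric(N, n_x, n_y),

summed in log space so p-values far below double precision remain exact in
ordering; any p below 2.2 × 10⁻³⁰⁸ is displayed as "0". A pair is
*significant* when p < 10⁻⁵ (strict).

**Open discovery** (A → B → C): test A against every B; keep significant
A–B pairs, at most 300 (the smallest by p); pair each surviving B with
every C; rank the resulting (A, B, C) chains by a **prediction score** —
the significance-gated B–C ratio a/n_c, i.e. the fraction of C's abstracts
that also mention B when the B–C pair is significant, and 0 otherwise.

**Closed discovery** (A → B ← C): given A and C, report the B terms
significant against both, ordered by the weaker of the two p-values.

Terms are labels with synonym sets; matching is exact, case-insensitive,
phrase-level, and punctuation-insensitive (text is lowercased and split on
non-word characters; no stemming). Queries can be restricted to abstracts
published at or before a cutoff year, which is what makes historical
rediscovery experiments honest. Significant pairs can additionally be
labelled with typed relations (TREATS, POS_ASSOCIATION, …) from a
precomputed knowledge-graph triples file, with PMID evidence attached.

## Worked example

The package ships a synthetic-corpus generator, so the full pipeline runs
without any download. Generate a 400-abstract corpus with one planted
A–B–C chain (`srcterm` → `linkterm` → `targetterm`) plus distractor terms,
index it, and search:

```bash
skimlbd simulate -o fixtures --seed 11
skimlbd index fixtures/corpus.jsonl -o corpus.idx
skimlbd skim --mode open --index corpus.idx \
    --a-terms fixtures/a_terms.tsv --b-terms fixtures/b_terms.tsv \
    --c-terms fixtures/c_terms.tsv -o hits.tsv --top-n 3
```

`hits.tsv` (columns 1–10):

```
a_label  b_label   c_label       ab_p                    ab_p_display  bc_p                   bc_p_display  bc_ratio  prediction_score  rank
srcterm  linkterm  targetterm    2.8256142902784496e-21  3e-21         4.681865396860633e-26  5e-26         0.815385  0.815385          1
srcterm  linkterm  targetdecoy2  2.8256142902784496e-21  3e-21         0.4456274937727184     0.4           0.294118  0                 2
srcterm  linkterm  targetdecoy1  2.8256142902784496e-21  3e-21         0.49761351328879017    0.5           0.285714  0                 3
```

Reading rank 1: `srcterm` and `linkterm` co-occur far more often than
chance (p ≈ 3 × 10⁻²¹), `linkterm` appears in 81.5% of the abstracts that
mention `targetterm` (ratio 0.815) with p ≈ 5 × 10⁻²⁶, so the planted
target is ranked first with prediction score 0.815. The decoy C terms
co-occur with `linkterm` only at chance level (p ≈ 0.45), score 0, and sink.

Annotating against the generated triples file labels the B–C link:

```bash
skimlbd annotate hits.tsv fixtures/relations.tsv -o annotated.json
```

adds, to the rank-1 hit, `"bc_annotations": [{"direction": "reverse",
"label": "TREATS", "pmids": [1000007, 1000019, ...]}]` — `targetterm`
TREATS `linkterm`, with the PMIDs the relation was recorded from.

The same library surface is available in Python (`build_index`,
`km_query`, `skim_open`, `skim_closed`, `annotate_hits`, `generate_corpus`).

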