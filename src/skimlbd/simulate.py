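"""Synthetic abstract corpora with planted co-occurrence structure.

Real abstract corpora are too large (and too encumbered) to ship, so every
statistical property of the search engine is exercised on generated
pseudo-abstracts instead.  A corpus spec controls the background
vocabulary (Zipf-like token frequencies, mimicking natural-language skew),
document lengths, publication years, and the planted structure:

* planted *pairs* — two terms co-inserted into each document with a given
  joint probability, plus solo rates, giving a known 2x2 table in
  expectation and an exact per-document ground truth in the manifest;
* a planted *chain* — an A-B pair and a B-C pair sharing the B term, the
  configuration an open-discovery search should recover at rank 1;
* planted *singles* and absent *decoys* — realistic distractor terms.

Everything is a pure function of the spec, including its seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from skimlbd.corpus import Document, write_jsonl_corpus, write_pubmed_xml
from skimlbd.index import build_index
from skimlbd.stats import ContingencyTable, fisher_one_sided
from skimlbd.terms import TermSpec, write_term_list
from skimlbd.textnorm import normalize_and_tokenize

logger = logging.getLogger(__name__)

#: Zipf exponent for background token frequencies.
ZIPF_EXPONENT = 1.1

#: Background vocabulary tokens are w0000, w0001, ... — planted terms must
#: not collide with this namespace.
_BG_PREFIX = "w"


@dataclass(frozen=True)
class PlantedPair:
    """Co-insert ``term_x`` and ``term_y`` with controlled document rates."""

    term_x: str
    term_y: str
    p_joint: float
    p_x_only: float = 0.0
    p_y_only: float = 0.0

    def __post_init__(self) -> None:
        probs = (self.p_joint, self.p_x_only, self.p_y_only)
        if any(p < 0 or p > 1 for p in probs) or sum(probs) > 1 + 1e-12:
            raise ValueError(f"invalid pair probabilities {probs}")


@dataclass(frozen=True)
class PlantedChain:
    """An A-B and a B-C planted pair sharing the intermediate B term."""

    a: str
    b: str
    c: str
    p_ab: float = 0.12
    p_bc: float = 0.12
    p_a_only: float = 0.03
    p_b_only: float = 0.03
    p_c_only: float = 0.03

    def as_pairs(self) -> tuple[PlantedPair, PlantedPair]:
        return (
            PlantedPair(self.a, self.b, self.p_ab, self.p_a_only, self.p_b_only),
            PlantedPair(self.b, self.c, self.p_bc, 0.0, self.p_c_only),
        )


@dataclass(frozen=True)
class PlantedSingle:
    """A term inserted independently at a fixed per-document rate."""

    term: str
    p_occur: float
    role: str = "b"  # which term list the fixture writer places it in


@dataclass(frozen=True)
class CorpusSpec:
    n_docs: int = 500
    vocab_size: int = 200
    tokens_per_doc: tuple[int, int] = (20, 60)
    year_range: tuple[int, int] = (1980, 2000)
    planted_pairs: tuple[PlantedPair, ...] = ()
    planted_chain: PlantedChain | None = None
    planted_singles: tuple[PlantedSingle, ...] = ()
    decoys: tuple[tuple[str, str], ...] = ()  # (label, role); never inserted
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_docs < 0:
            raise ValueError("n_docs must be >= 0")
        if self.vocab_size < 1:
            raise ValueError("vocab_size must be >= 1")
        lo, hi = self.tokens_per_doc
        if not (0 <= lo <= hi):
            raise ValueError("tokens_per_doc must satisfy 0 <= min <= max")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must satisfy min <= max")
        for term in self.all_planted_terms():
            for tok in normalize_and_tokenize(term):
                if tok.startswith(_BG_PREFIX) and tok[1:].isdigit():
                    raise ValueError(
                        f"planted term {term!r} collides with background vocabulary"
                    )

    def effective_pairs(self) -> tuple[PlantedPair, ...]:
        pairs = tuple(self.planted_pairs)
        if self.planted_chain is not None:
            pairs = self.planted_chain.as_pairs() + pairs
        return pairs

    def all_planted_terms(self) -> list[str]:
        terms: list[str] = []
        for pair in self.effective_pairs():
            terms.extend([pair.term_x, pair.term_y])
        terms.extend(s.term for s in self.planted_singles)
        # preserve order, drop duplicates (chain B appears in both its pairs)
        seen: set[str] = set()
        return [t for t in terms if not (t in seen or seen.add(t))]


@dataclass
class Manifest:
    """Exact ground truth of a generated corpus.

    ``placements`` maps pmid -> term -> start positions of each insertion
    within the document's abstract token stream (title tokens precede the
    abstract in the index, so these are relative positions).  Contingency
    tables derived from the manifest must agree exactly with tables the
    index computes.
    """

    spec: CorpusSpec
    placements: dict[int, dict[str, list[int]]]
    years: dict[int, int | None]

    def docs_with(self, term: str, cutoff_year: int | None = None) -> set[int]:
        hits = {pmid for pmid, terms in self.placements.items() if term in terms}
        if cutoff_year is None:
            return hits
        return {
            pmid for pmid in hits
            if self.years[pmid] is not None and self.years[pmid] <= cutoff_year
        }

    def contingency(
        self, term_x: str, term_y: str, cutoff_year: int | None = None
    ) -> ContingencyTable:
        hits_x = self.docs_with(term_x, cutoff_year)
        hits_y = self.docs_with(term_y, cutoff_year)
        if cutoff_year is None:
            n_total = len(self.years)
        else:
            n_total = sum(
                1 for y in self.years.values() if y is not None and y <= cutoff_year
            )
        a = len(hits_x & hits_y)
        return ContingencyTable(
            a, len(hits_x) - a, len(hits_y) - a, n_total - len(hits_x | hits_y)
        )


def _zipf_weights(vocab_size: int) -> np.ndarray:
    ranks = np.arange(1, vocab_size + 1, dtype=float)
    weights = ranks ** (-ZIPF_EXPONENT)
    return weights / weights.sum()


def generate_corpus(spec: CorpusSpec) -> tuple[list[Document], Manifest]:
    """Generate pseudo-abstracts with the spec's planted structure.

    Per document: the publication year is uniform over ``year_range``;
    background tokens are drawn i.i.d. from the Zipf-weighted background
    vocabulary; each planted pair independently contributes both terms
    (``p_joint``), only x, only y, or neither; each planted single
    contributes with its rate.  Planted terms are inserted at distinct
    random gaps of the background stream, so two insertions are always
    separated by at least one background token and multi-token phrases
    stay intact but never merge.
    """
    rng = np.random.default_rng(spec.seed)
    vocab = np.array([f"{_BG_PREFIX}{i:04d}" for i in range(spec.vocab_size)])
    weights = _zipf_weights(spec.vocab_size)
    pairs = spec.effective_pairs()

    docs: list[Document] = []
    placements: dict[int, dict[str, list[int]]] = {}
    years: dict[int, int | None] = {}
    lo, hi = spec.tokens_per_doc
    for i in range(spec.n_docs):
        pmid = 1_000_001 + i
        year = int(rng.integers(spec.year_range[0], spec.year_range[1] + 1))
        n_background = int(rng.integers(lo, hi + 1))
        background = list(rng.choice(vocab, size=n_background, p=weights))

        present: list[str] = []
        for pair in pairs:
            u = rng.random()
            if u < pair.p_joint:
                present += [pair.term_x, pair.term_y]
            elif u < pair.p_joint + pair.p_x_only:
                present.append(pair.term_x)
            elif u < pair.p_joint + pair.p_x_only + pair.p_y_only:
                present.append(pair.term_y)
        for single in spec.planted_singles:
            if rng.random() < single.p_occur:
                present.append(single.term)

        doc_placements: dict[str, list[int]] = {}
        title = background[:3]
        abstract = background[3:]
        if present:
            n_gaps = len(abstract) + 1
            if len(present) > n_gaps:
                # pad so every insertion gets its own gap
                extra = rng.choice(vocab, size=len(present) - n_gaps + 1, p=weights)
                abstract += list(extra)
                n_gaps = len(abstract) + 1
            gaps = sorted(rng.choice(n_gaps, size=len(present), replace=False))
            order = rng.permutation(len(present))
            # insert right-to-left so earlier gap offsets stay valid
            inserted: list[tuple[int, str]] = []
            for gap, term_idx in zip(reversed(gaps), reversed(list(order))):
                term = present[int(term_idx)]
                tokens = normalize_and_tokenize(term)
                abstract[gap:gap] = tokens
                inserted.append((int(gap), term))
            # recompute final start positions left-to-right
            shift = 0
            for gap, term in sorted(inserted):
                start = gap + shift
                doc_placements.setdefault(term, []).append(start)
                shift += len(normalize_and_tokenize(term))
        docs.append(
            Document(
                pmid=pmid,
                title=" ".join(title),
                abstract=" ".join(abstract),
                pub_year=year,
            )
        )
        placements[pmid] = doc_placements
        years[pmid] = year
    return docs, Manifest(spec=spec, placements=placements, years=years)


# ---------------------------------------------------------------------------
# Fixture emission: the exact file dialects the other modules consume
# ---------------------------------------------------------------------------


def _term_lists(spec: CorpusSpec) -> dict[str, list[TermSpec]]:
    lists: dict[str, list[TermSpec]] = {"a": [], "b": [], "c": []}
    chain = spec.planted_chain
    if chain is not None:
        lists["a"].append(TermSpec(chain.a))
        lists["b"].append(TermSpec(chain.b))
        lists["c"].append(TermSpec(chain.c))
    for pair in spec.planted_pairs:
        lists["a"].append(TermSpec(pair.term_x))
        lists["b"].append(TermSpec(pair.term_y))
    for single in spec.planted_singles:
        lists[single.role].append(TermSpec(single.term))
    for label, role in spec.decoys:
        lists[role].append(TermSpec(label))
    return lists


def emit_fixtures(
    docs: list[Document], manifest: Manifest, out_dir: str | Path
) -> dict[str, Path]:
    """Write a generated corpus as the full fixture file set.

    Emits the corpus in both MEDLINE-style XML and JSONL (exercising both
    readers), term-list TSVs per role (planted terms plus decoys), and a
    relations TSV linking the planted chain's terms for annotation tests.
    Returns the path of each file written.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    spec = manifest.spec
    paths = {
        "xml": out_dir / "corpus.xml",
        "jsonl": out_dir / "corpus.jsonl",
        "a_terms": out_dir / "a_terms.tsv",
        "b_terms": out_dir / "b_terms.tsv",
        "c_terms": out_dir / "c_terms.tsv",
        "relations": out_dir / "relations.tsv",
    }
    write_pubmed_xml(docs, paths["xml"])
    write_jsonl_corpus(docs, paths["jsonl"])
    lists = _term_lists(spec)
    write_term_list(lists["a"], paths["a_terms"])
    write_term_list(lists["b"], paths["b_terms"])
    write_term_list(lists["c"], paths["c_terms"])

    with open(paths["relations"], "w", encoding="utf-8") as handle:
        handle.write("subject\tsubject_type\trelation\tobject\tobject_type\tpmids\n")
        chain = spec.planted_chain
        if chain is not None:
            ab_evidence = sorted(
                manifest.docs_with(chain.a) & manifest.docs_with(chain.b)
            )
            bc_evidence = sorted(
                manifest.docs_with(chain.b) & manifest.docs_with(chain.c)
            )
            if ab_evidence:
                handle.write(
                    f"{chain.a}\tCONDITION\tPOS_ASSOCIATION\t{chain.b}\tCONDITION\t"
                    + ",".join(map(str, ab_evidence)) + "\n"
                )
            if bc_evidence:
                handle.write(
                    f"{chain.c}\tDRUG\tTREATS\t{chain.b}\tCONDITION\t"
                    + ",".join(map(str, bc_evidence)) + "\n"
                )
    return paths


def default_chain_spec(seed: int = 0) -> CorpusSpec:
    """The documented planted-chain study configuration.

    One A-B-C chain planted in 400 documents (joint rates 0.12, solo rates
    0.03) among Zipf background text, with independent distractor B and C
    terms at rate 0.05 and decoy terms that never occur.  Under this
    configuration the chain's A-B pair is overwhelmingly significant at
    p < 1e-5 and the planted C term should take rank 1 by prediction score.
    """
    return CorpusSpec(
        n_docs=400,
        vocab_size=150,
        tokens_per_doc=(20, 40),
        year_range=(1980, 2000),
        planted_chain=PlantedChain(a="srcterm", b="linkterm", c="targetterm"),
        planted_singles=(
            PlantedSingle("linkdecoy1", 0.05, "b"),
            PlantedSingle("linkdecoy2", 0.05, "b"),
            PlantedSingle("linkdecoy3", 0.05, "b"),
            PlantedSingle("targetdecoy1", 0.05, "c"),
            PlantedSingle("targetdecoy2", 0.05, "c"),
            PlantedSingle("targetdecoy3", 0.05, "c"),
            PlantedSingle("targetdecoy4", 0.05, "c"),
        ),
        decoys=(("ghostlink", "b"), ("ghosttarget", "c")),
        seed=seed,
    )


def cap_stress_corpus(
    n_b_terms: int = 400, n_total_docs: int = 100_000
) -> tuple[list[Document], str, list[str]]:
    """Deterministic corpus where every A-B pair is strongly significant.

    One anchor A term co-occurs with each of ``n_b_terms`` B terms in 5-14
    joint documents (no solo occurrences); the rest of the corpus is padded
    with empty-text documents, which count toward N.  Every pair then has
    an exact-test p-value far below 1e-5, so the stage-one cap — not the
    threshold — decides which pairs survive.  Returns the documents, the A
    label and the B labels.
    """
    a_label = "anchorterm"
    b_labels = [f"linkb{i:03d}" for i in range(n_b_terms)]
    docs: list[Document] = []
    pmid = 1
    for i, b_label in enumerate(b_labels):
        for _ in range(5 + i % 10):
            docs.append(Document(pmid, f"{a_label} {b_label}", "", 1990))
            pmid += 1
    while len(docs) < n_total_docs:
        docs.append(Document(pmid, "", "", 1990))
        pmid += 1
    return docs, a_label, b_labels


def null_pair_battery(
    n_pairs: int = 200,
    n_docs: int = 2000,
    seed: int = 0,
    p_x: float = 0.05,
    p_y: float = 0.05,
) -> list[float]:
    """Exact-test p-values for independently planted term pairs.

    Each pair's joint probability is the product of its marginals, so every
    pair satisfies the null hypothesis of independence; the returned
    p-values calibrate the one-sided exact test (which is conservative:
    their distribution stochastically dominates uniform).
    """
    pairs = tuple(
        PlantedPair(
            f"nullx{i:03d}", f"nully{i:03d}",
            p_joint=p_x * p_y,
            p_x_only=p_x * (1 - p_y),
            p_y_only=(1 - p_x) * p_y,
        )
        for i in range(n_pairs)
    )
    spec = CorpusSpec(
        n_docs=n_docs,
        vocab_size=300,
        tokens_per_doc=(30, 60),
        planted_pairs=pairs,
        seed=seed,
    )
    docs, _manifest = generate_corpus(spec)
    index = build_index(docs)
    p_values: list[float] = []
    for pair in pairs:
        hits_x = index.match_term(pair.term_x)
        hits_y = index.match_term(pair.term_y)
        a = len(hits_x & hits_y)
        table = ContingencyTable(
            a, len(hits_x) - a, len(hits_y) - a, index.n_docs - len(hits_x | hits_y)
        )
        p_values.append(fisher_one_sided(table))
    return p_values
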