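"""Positional inverted index over tokenized abstracts.

Each token maps to the documents it occurs in and its integer positions
within each document, enabling consecutive-position phrase queries.  Title
tokens are indexed first, then abstract tokens after a one-position gap, so
a phrase can never spuriously match across the title/abstract boundary.
Per-document publication years support date-cutoff queries for historical
rediscovery experiments.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from skimlbd.corpus import Document
from skimlbd.terms import TermSpec
from skimlbd.textnorm import normalize_and_tokenize

logger = logging.getLogger(__name__)

INDEX_FORMAT = "skimlbd-index"
INDEX_VERSION = 1


class IndexFormatError(Exception):
    """Raised when an on-disk index file cannot be understood."""


@dataclass
class CorpusIndex:
    """Positional inverted index plus per-document year metadata.

    ``postings``: token -> (pmid -> sorted ascending unique positions).
    ``doc_meta``: pmid -> publication year (``None`` when unknown); its size
    is the corpus document count N, which includes documents whose text
    produced no tokens.
    """

    postings: dict[str, dict[int, list[int]]] = field(default_factory=dict)
    doc_meta: dict[int, int | None] = field(default_factory=dict)

    @property
    def n_docs(self) -> int:
        return len(self.doc_meta)

    # -- cutoff handling ----------------------------------------------------

    def eligible_pmids(self, cutoff_year: int | None) -> set[int]:
        """PMIDs countable under a cutoff.

        With no cutoff every document is eligible.  With a cutoff, only
        documents with a *known* year <= cutoff are eligible; unknown-year
        documents are excluded (conservative for rediscovery tests).
        """
        if cutoff_year is None:
            return set(self.doc_meta)
        return {
            pmid
            for pmid, year in self.doc_meta.items()
            if year is not None and year <= cutoff_year
        }

    def n_eligible(self, cutoff_year: int | None) -> int:
        if cutoff_year is None:
            return self.n_docs
        return sum(
            1 for year in self.doc_meta.values() if year is not None and year <= cutoff_year
        )

    # -- queries ------------------------------------------------------------

    def match_phrase(self, phrase: str, cutoff_year: int | None = None) -> set[int]:
        """PMIDs whose token stream contains the phrase at consecutive positions."""
        tokens = normalize_and_tokenize(phrase)
        if not tokens:
            raise ValueError(f"phrase {phrase!r} normalizes to zero tokens")
        first = self.postings.get(tokens[0])
        if first is None:
            return set()
        # candidate docs must contain every token of the phrase
        candidates = set(first)
        for tok in tokens[1:]:
            entry = self.postings.get(tok)
            if entry is None:
                return set()
            candidates &= entry.keys()
            if not candidates:
                return set()
        if len(tokens) == 1:
            hits = candidates
        else:
            hits = set()
            for pmid in candidates:
                starts = self.postings[tokens[0]][pmid]
                later = [set(self.postings[tok][pmid]) for tok in tokens[1:]]
                for start in starts:
                    if all(start + offset + 1 in later[offset] for offset in range(len(later))):
                        hits.add(pmid)
                        break
        if cutoff_year is None:
            return set(hits)
        return {
            pmid
            for pmid in hits
            if self.doc_meta.get(pmid) is not None and self.doc_meta[pmid] <= cutoff_year
        }

    def match_term(self, term: TermSpec | str, cutoff_year: int | None = None) -> set[int]:
        """Union of phrase matches over a term's synonyms (document-level OR)."""
        term = TermSpec.coerce(term)
        hits: set[int] = set()
        for synonym in term.synonyms:
            hits |= self.match_phrase(synonym, cutoff_year=cutoff_year)
        return hits


def tokenize_document(doc: Document) -> tuple[list[str], int]:
    """Token stream of a document and the boundary position of the abstract.

    Title tokens occupy positions ``0..t-1``; abstract tokens start at
    ``t+1``, leaving position ``t`` unused as the phrase-blocking gap.
    """
    title_tokens = normalize_and_tokenize(doc.title)
    return title_tokens, len(title_tokens) + 1


def build_index(docs: Iterable[Document]) -> CorpusIndex:
    """Build the positional inverted index for a corpus.

    PMIDs must be unique (the corpus readers resolve duplicates).  Documents
    with no tokens still count toward N.
    """
    index = CorpusIndex()
    postings = index.postings
    for doc in docs:
        if doc.pmid in index.doc_meta:
            raise ValueError(f"duplicate PMID {doc.pmid} passed to build_index")
        index.doc_meta[doc.pmid] = doc.pub_year
        title_tokens, boundary = tokenize_document(doc)
        abstract_tokens = normalize_and_tokenize(doc.abstract)
        for pos, tok in enumerate(title_tokens):
            postings.setdefault(tok, {}).setdefault(doc.pmid, []).append(pos)
        for offset, tok in enumerate(abstract_tokens):
            postings.setdefault(tok, {}).setdefault(doc.pmid, []).append(boundary + offset)
    return index


# ---------------------------------------------------------------------------
# Persistence: a versioned JSON container.  Layout (format v1):
#   {"format": "skimlbd-index", "version": 1, "n_docs": N,
#    "doc_meta": {"<pmid>": year-or-null, ...},
#    "postings": {"<token>": {"<pmid>": [pos, ...], ...}, ...}}
# Bit-exactness of the file is not promised across versions, only
# query-result equivalence after a round trip.
# ---------------------------------------------------------------------------


def save_index(index: CorpusIndex, path: str | Path) -> None:
    payload = {
        "format": INDEX_FORMAT,
        "version": INDEX_VERSION,
        "n_docs": index.n_docs,
        "doc_meta": {str(pmid): year for pmid, year in index.doc_meta.items()},
        "postings": {
            tok: {str(pmid): positions for pmid, positions in entry.items()}
            for tok, entry in index.postings.items()
        },
    }
    with open(path, "w", encoding="utf-8") as handle:
        json.dump(payload, handle)


def load_index(path: str | Path) -> CorpusIndex:
    try:
        with open(path, "r", encoding="utf-8") as handle:
            payload = json.load(handle)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise IndexFormatError(f"{path}: not a readable index file ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("format") != INDEX_FORMAT:
        raise IndexFormatError(f"{path}: missing or wrong format stamp")
    if payload.get("version") != INDEX_VERSION:
        raise IndexFormatError(
            f"{path}: index format version {payload.get('version')!r} "
            f"not supported (expected {INDEX_VERSION})"
        )
    index = CorpusIndex(
        postings={
            tok: {int(pmid): list(map(int, positions)) for pmid, positions in entry.items()}
            for tok, entry in payload["postings"].items()
        },
        doc_meta={int(pmid): year for pmid, year in payload["doc_meta"].items()},
    )
    if payload["n_docs"] != index.n_docs:
        raise IndexFormatError(f"{path}: header n_docs disagrees with document table")
    return index


def index_summary(index: CorpusIndex) -> str:
    years = [y for y in index.doc_meta.values() if y is not None]
    n_tokens = sum(
        len(positions) for entry in index.postings.values() for positions in entry.values()
    )
    if years:
        coverage = f"{min(years)}-{max(years)} ({len(years)}/{index.n_docs} dated)"
    else:
        coverage = "none dated"
    return (
        f"indexed n_docs={index.n_docs} n_tokens={n_tokens} "
        f"vocab={len(index.postings)} years={coverage}"
    )
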