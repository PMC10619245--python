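"""Abstract corpus I/O: MEDLINE-style citation XML and a JSONL dialect.

Both readers produce :class:`Document` sequences.  Duplicate PMIDs (PubMed
revisions) are resolved last-record-wins with a logged warning, so that
downstream indexing sees unique PMIDs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Sequence

from lxml import etree

logger = logging.getLogger(__name__)

#: Publication years outside this range are treated as unknown.
YEAR_MIN, YEAR_MAX = 1500, 2100


@dataclass(frozen=True)
class Document:
    """One abstract record: PMID, title, abstract text, publication year.

    ``pub_year`` is ``None`` when the year is missing or unparseable.
    """

    pmid: int
    title: str
    abstract: str = ""
    pub_year: int | None = None

    def __post_init__(self) -> None:
        if self.pmid <= 0:
            raise ValueError(f"pmid must be a positive integer, got {self.pmid}")
        if self.pub_year is not None and not (YEAR_MIN <= self.pub_year <= YEAR_MAX):
            raise ValueError(
                f"pub_year {self.pub_year} outside plausible range "
                f"[{YEAR_MIN}, {YEAR_MAX}]; use None for unknown"
            )


def dedupe_documents(docs: Iterable[Document]) -> list[Document]:
    """Resolve duplicate PMIDs: the later record replaces the earlier one."""
    by_pmid: dict[int, Document] = {}
    for doc in docs:
        if doc.pmid in by_pmid:
            logger.warning("duplicate PMID %d: later record replaces earlier", doc.pmid)
        by_pmid[doc.pmid] = doc
    return list(by_pmid.values())


# ---------------------------------------------------------------------------
# MEDLINE-style citation XML
# ---------------------------------------------------------------------------


def _element_text(elem: etree._Element | None) -> str:
    if elem is None:
        return ""
    return "".join(elem.itertext()).strip()


def _parse_year(citation: etree._Element) -> int | None:
    year_elem = citation.find(".//PubDate/Year")
    text = _element_text(year_elem)
    if not text:
        # MedlineDate fallback: take the leading 4-digit year, e.g. "1984 Jul-Aug"
        medline_date = _element_text(citation.find(".//PubDate/MedlineDate"))
        text = medline_date[:4]
    try:
        year = int(text)
    except (TypeError, ValueError):
        return None
    if not (YEAR_MIN <= year <= YEAR_MAX):
        logger.warning("implausible publication year %r treated as unknown", text)
        return None
    return year


def parse_pubmed_xml(source: str | Path | IO[bytes]) -> list[Document]:
    """Parse citations from a MEDLINE/PubMed XML stream.

    One :class:`Document` per ``MedlineCitation``.  Multiple ``AbstractText``
    sections are concatenated in order with a single space; a missing
    abstract yields an empty string; a missing or unparseable year yields an
    unknown (``None``) year.  A citation lacking a PMID is skipped with a
    logged warning.  Malformed XML raises ``lxml.etree.XMLSyntaxError``,
    which reports the offending position.
    """
    docs: list[Document] = []
    for _event, citation in etree.iterparse(source, events=("end",), tag="MedlineCitation"):
        pmid_text = _element_text(citation.find("PMID"))
        if not pmid_text or not pmid_text.isdigit():
            logger.warning("citation without a valid PMID skipped (%r)", pmid_text)
        else:
            title = _element_text(citation.find(".//ArticleTitle"))
            sections = [
                _element_text(sec) for sec in citation.findall(".//Abstract/AbstractText")
            ]
            abstract = " ".join(sec for sec in sections if sec)
            docs.append(
                Document(
                    pmid=int(pmid_text),
                    title=title,
                    abstract=abstract,
                    pub_year=_parse_year(citation),
                )
            )
        citation.clear(keep_tail=True)
    return dedupe_documents(docs)


def write_pubmed_xml(docs: Sequence[Document], dest: str | Path | IO[bytes]) -> None:
    """Write documents as MEDLINE-style citation XML (inverse of the parser)."""
    root = etree.Element("PubmedArticleSet")
    for doc in docs:
        article = etree.SubElement(root, "PubmedArticle")
        citation = etree.SubElement(article, "MedlineCitation")
        etree.SubElement(citation, "PMID").text = str(doc.pmid)
        art = etree.SubElement(citation, "Article")
        journal = etree.SubElement(art, "Journal")
        issue = etree.SubElement(journal, "JournalIssue")
        pubdate = etree.SubElement(issue, "PubDate")
        if doc.pub_year is not None:
            etree.SubElement(pubdate, "Year").text = str(doc.pub_year)
        etree.SubElement(art, "ArticleTitle").text = doc.title
        if doc.abstract:
            abstract = etree.SubElement(art, "Abstract")
            etree.SubElement(abstract, "AbstractText").text = doc.abstract
    tree = etree.ElementTree(root)
    tree.write(str(dest) if isinstance(dest, (str, Path)) else dest,
               xml_declaration=True, encoding="utf-8", pretty_print=True)


# ---------------------------------------------------------------------------
# JSONL dialect: one record per line with pmid, title, abstract, year
# ---------------------------------------------------------------------------


def read_jsonl_corpus(source: str | Path | IO[str]) -> list[Document]:
    """Read the JSONL corpus dialect.

    Each line is an object with integer ``pmid``, string ``title`` and
    ``abstract``, and ``year`` (integer or null).  A record without a pmid
    is a record-level error.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        handle = source
    try:
        docs: list[Document] = []
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            record = json.loads(line)
            if "pmid" not in record or record["pmid"] is None:
                raise ValueError(f"JSONL line {lineno}: missing required field 'pmid'")
            docs.append(
                Document(
                    pmid=int(record["pmid"]),
                    title=record.get("title", ""),
                    abstract=record.get("abstract") or "",
                    pub_year=record.get("year"),
                )
            )
        return dedupe_documents(docs)
    finally:
        if close:
            handle.close()


def write_jsonl_corpus(docs: Sequence[Document], dest: str | Path | IO[str]) -> None:
    """Write documents as JSONL; ``read_jsonl_corpus`` is its inverse."""
    close = False
    if isinstance(dest, (str, Path)):
        handle: IO[str] = open(dest, "w", encoding="utf-8")
        close = True
    else:
        handle = dest
    try:
        for doc in docs:
            handle.write(
                json.dumps(
                    {
                        "pmid": doc.pmid,
                        "title": doc.title,
                        "abstract": doc.abstract,
                        "year": doc.pub_year,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )
    finally:
        if close:
            handle.close()
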