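"""Query terms: a labelled concept with a synonym set.

A term can be a word, a phrase, or a set of words/phrases (synonyms).  A
document matches a term if it contains any synonym as a consecutive token
phrase; a document counts once no matter how many synonyms hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Sequence

from skimlbd.textnorm import normalize_and_tokenize


@dataclass(frozen=True)
class TermSpec:
    """A named concept with a non-empty set of synonym phrases."""

    label: str
    synonyms: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        syns = self.synonyms or (self.label,)
        object.__setattr__(self, "synonyms", tuple(syns))
        if not self.synonyms:
            raise ValueError(f"term {self.label!r} has no synonyms")
        for syn in self.synonyms:
            if not normalize_and_tokenize(syn):
                raise ValueError(
                    f"term {self.label!r}: synonym {syn!r} normalizes to zero tokens"
                )

    @classmethod
    def coerce(cls, value: "TermSpec | str") -> "TermSpec":
        """Accept a bare string as a term whose only synonym is itself."""
        if isinstance(value, TermSpec):
            return value
        return cls(label=value)


def read_term_list(source: str | Path | IO[str]) -> list[TermSpec]:
    """Read a term-list TSV: ``label<TAB>syn1|syn2|...``.

    A line with a single column is a term whose only synonym is itself.
    Blank lines and ``#`` comment lines are skipped.
    """
    close = False
    if isinstance(source, (str, Path)):
        handle: IO[str] = open(source, "r", encoding="utf-8")
        close = True
    else:
        handle = source
    try:
        terms: list[TermSpec] = []
        for line in handle:
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            label = parts[0].strip()
            if len(parts) > 1 and parts[1].strip():
                synonyms = tuple(s.strip() for s in parts[1].split("|") if s.strip())
            else:
                synonyms = (label,)
            terms.append(TermSpec(label=label, synonyms=synonyms))
        return terms
    finally:
        if close:
            handle.close()


def write_term_list(terms: Sequence[TermSpec], dest: str | Path | IO[str]) -> None:
    close = False
    if isinstance(dest, (str, Path)):
        handle: IO[str] = open(dest, "w", encoding="utf-8")
        close = True
    else:
        handle = dest
    try:
        for term in terms:
            handle.write(f"{term.label}\t{'|'.join(term.synonyms)}\n")
    finally:
        if close:
            handle.close()


def coerce_terms(values: Iterable["TermSpec | str"]) -> list[TermSpec]:
    return [TermSpec.coerce(v) for v in values]
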