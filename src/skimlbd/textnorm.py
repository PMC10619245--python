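"""Text normalization and tokenization.

A single rule is used everywhere — indexing, query-term matching, and
knowledge-graph entity names — so that the three are provably consistent:
NFC-normalize, lowercase, then split on maximal runs of non-word characters
(word = Unicode letters, digits, underscore).  Punctuation is thereby
ignored and matching is exact, case-insensitive, and phrase-level.  No
stemming or lemmatization is performed.
"""

from __future__ import annotations

import re
import unicodedata

_NONWORD = re.compile(r"\W+", re.UNICODE)


def normalize_and_tokenize(text: str) -> list[str]:
    """Lowercase ``text`` and split it into word tokens.

    Unicode is NFC-normalized first so composed and decomposed forms of the
    same character match.  Empty tokens are discarded; an empty input yields
    an empty list.

    >>> normalize_and_tokenize("Raynaud's Disease")
    ['raynaud', 's', 'disease']
    """
    text = unicodedata.normalize("NFC", text).lower()
    return [tok for tok in _NONWORD.split(text) if tok]


def normalize_phrase(text: str) -> str:
    """Canonical single-space-joined form of a phrase.

    Idempotent: normalizing the output again is a no-op.  Used as the key
    for knowledge-graph entity names.
    """
    return " ".join(normalize_and_tokenize(text))
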