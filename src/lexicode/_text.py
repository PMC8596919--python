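"""Text canonicalization shared by every module.

All cross-module string comparisons go through :func:`normalize`; all token
set operations go through :func:`tokenize`.  Keeping these in one place is
what makes dictionary lookup, deduplication and the scorers agree on what
counts as "the same term".
"""

from __future__ import annotations

import re
import unicodedata

_WS_RE = re.compile(r"\s+")
# split on anything that is not a word character (covers CJK, keeps digits)
_TOKEN_RE = re.compile(r"[^\w]+", re.UNICODE)


def _is_punct(ch: str) -> bool:
    return unicodedata.category(ch).startswith("P")


def normalize(s: str) -> str:
    """Canonical form of a term: lowercase, collapsed whitespace,
    surrounding punctuation stripped."""
    s = _WS_RE.sub(" ", s.strip().lower())
    start, end = 0, len(s)
    while start < end and _is_punct(s[start]):
        start += 1
    while end > start and _is_punct(s[end - 1]):
        end -= 1
    return s[start:end].strip()


def tokenize(s: str) -> list[str]:
    """Lowercase word tokens, split on whitespace and punctuation.

    No stemming: inflectional variation is handled upstream by fuzzy
    dictionary extraction, not by the tokenizer.
    """
    return [t for t in _TOKEN_RE.split(s.lower()) if t]


def token_set(s: str) -> frozenset[str]:
    return frozenset(tokenize(s))
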