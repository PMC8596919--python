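"""Hybrid source-to-target translation.

Two backends run in parallel for every phrase: exact lookup in the
bilingual domain dictionary, and an external machine-translation service
behind a small interface.  When the two agree the shared result is a
single candidate tagged ``both``; when they differ (partly or completely)
every distinct result is kept in the union set, because a wrong discard
here silently loses the only translation the scorers could have matched.
A deterministic table-driven backend stands in for the external service in
tests and fixtures; adapters to a real service plug in through the same
interface.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

from ._text import normalize
from .lexicon import BilingualDictionary

logger = logging.getLogger(__name__)


@dataclass
class TranslationSet:
    """Union of translation candidates for one source phrase.

    ``candidates`` holds ``(text, origin)`` with origin one of
    ``dictionary``, ``external`` or ``both``; texts are distinct after
    normalization.  ``failed`` is true iff no backend produced anything.
    """

    source: str
    candidates: list[tuple[str, str]] = field(default_factory=list)

    @property
    def failed(self) -> bool:
        return not self.candidates

    def texts(self) -> list[str]:
        return [text for text, _ in self.candidates]


@runtime_checkable
class TranslatorBackend(Protocol):
    """Anything with a name and a phrase -> list-of-translations callable."""

    name: str

    def translate(self, phrase: str) -> list[str]: ...


class TableTranslator:
    """Deterministic mock backend that echoes a fixed lookup table.

    The table maps normalized source phrases to translation lists; unknown
    phrases translate to nothing.
    """

    def __init__(self, table: dict[str, list[str]], name: str = "mock"):
        self.name = name
        self._table = {normalize(k): list(v) for k, v in table.items()}

    def translate(self, phrase: str) -> list[str]:
        return list(self._table.get(normalize(phrase), []))

    @classmethod
    def from_tsv(cls, path: str | Path, name: str = "mock") -> "TableTranslator":
        """Load ``source<TAB>translation`` rows; repeated sources accumulate."""
        table: dict[str, list[str]] = {}
        with Path(path).open(encoding="utf-8", newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if len(row) < 2 or not row[0].strip() or not row[1].strip():
                    continue
                table.setdefault(normalize(row[0]), []).append(row[1].strip())
        return cls(table, name=name)


class DictionaryBackend:
    """Dictionary lookup exposed through the backend interface."""

    def __init__(self, dictionary: BilingualDictionary):
        self.name = "dictionary"
        self._dictionary = dictionary

    def translate(self, phrase: str) -> list[str]:
        return dictionary_lookup(self._dictionary, phrase)


def dictionary_lookup(dictionary: BilingualDictionary, phrase: str) -> list[str]:
    """Exact-match lookup of the normalized phrase; all stored targets in
    order, empty list on a miss."""
    if not phrase or not normalize(phrase):
        raise ValueError("phrase must be non-empty")
    return dictionary.lookup(phrase)


def hybrid_translate(
    phrase: str,
    dictionary: BilingualDictionary,
    external: TranslatorBackend,
) -> TranslationSet:
    """Deduplicated union of dictionary and external translations.

    An external backend that raises is logged and treated as returning
    nothing, so coding degrades to dictionary-only rather than aborting.
    """
    dict_results = dictionary_lookup(dictionary, phrase)
    try:
        ext_results = external.translate(phrase)
    except Exception:  # noqa: BLE001 - any backend failure degrades gracefully
        logger.warning(
            "external backend %r failed on %r; using dictionary only",
            getattr(external, "name", "?"),
            phrase,
            exc_info=True,
        )
        ext_results = []

    dict_set = {}
    for text in dict_results:
        key = normalize(text)
        if key and key not in dict_set:
            dict_set[key] = text
    ext_set = {}
    for text in ext_results:
        key = normalize(text)
        if key and key not in ext_set:
            ext_set[key] = text

    candidates: list[tuple[str, str]] = []
    for key in dict_set:
        origin = "both" if key in ext_set else "dictionary"
        candidates.append((key, origin))
    for key in ext_set:
        if key not in dict_set:
            candidates.append((key, "external"))
    return TranslationSet(source=phrase, candidates=candidates)
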