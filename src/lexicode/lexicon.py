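"""Target-lexicon and bilingual-glossary I/O, merging and fuzzy extraction.

The target lexicon is any controlled vocabulary in the shape
``code<TAB>preferred name<TAB>synonym|synonym|...`` (RadLex-style "RID"
codes in the fixtures).  Bilingual glossaries are two-column TSV files
mapping source-language terms to target-language terms.  The domain
dictionary is obtained by keeping only glossary entries whose target is an
exact or fuzzy (edit distance <= ``max_dist``) match of some lexicon term;
single-word targets must match exactly, because for one-word terms a small
edit distance routinely crosses concept boundaries.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

from ._text import normalize, tokenize
from .similarity import levenshtein_distance

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LexiconConcept:
    """One lexicon entry: an opaque code, a preferred name and synonyms."""

    code: str
    preferred_name: str
    synonyms: tuple[str, ...] = ()

    def terms(self) -> tuple[str, ...]:
        """Preferred name followed by synonyms."""
        return (self.preferred_name, *self.synonyms)


@dataclass
class BilingualEntry:
    source: str
    targets: list[str]
    provenance: set[str] = field(default_factory=set)


class BilingualDictionary:
    """Deduplicated source -> target-terms map with provenance.

    Lookups are exact-match on the normalized source term.
    """

    def __init__(self, entries: dict[str, BilingualEntry] | None = None):
        self.entries: dict[str, BilingualEntry] = entries if entries is not None else {}

    @property
    def size(self) -> int:
        return len(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, phrase: str) -> bool:
        return normalize(phrase) in self.entries

    def add(self, source: str, target: str, provenance: str | None = None) -> None:
        src = normalize(source)
        tgt = normalize(target)
        if not src or not tgt:
            raise ValueError("source and target must be non-empty after normalization")
        entry = self.entries.get(src)
        if entry is None:
            entry = BilingualEntry(source=src, targets=[])
            self.entries[src] = entry
        if tgt not in entry.targets:
            entry.targets.append(tgt)
        if provenance is not None:
            entry.provenance.add(provenance)

    def lookup(self, phrase: str) -> list[str]:
        """All stored targets for the normalized phrase, order preserved;
        empty list on a miss."""
        entry = self.entries.get(normalize(phrase))
        return list(entry.targets) if entry is not None else []

    def items(self):
        return self.entries.items()


def load_lexicon(path: str | Path, *, header: bool = False) -> list[LexiconConcept]:
    """Read a lexicon TSV (code, preferred name, optional ``|``-separated
    synonyms), preserving row order.

    Raises ``ValueError`` on a duplicate code (naming the code) or an empty
    preferred name (naming the row).
    """
    path = Path(path)
    concepts: list[LexiconConcept] = []
    seen: set[str] = set()
    with path.open(encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for rownum, row in enumerate(reader, start=1):
            if header and rownum == 1:
                continue
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) < 2:
                raise ValueError(f"{path}:{rownum}: expected >=2 columns, got {len(row)}")
            code = row[0].strip()
            preferred = normalize(row[1])
            if not code:
                raise ValueError(f"{path}:{rownum}: empty code")
            if not preferred:
                raise ValueError(f"{path}:{rownum}: empty preferred name")
            if code in seen:
                raise ValueError(f"duplicate lexicon code {code!r}")
            seen.add(code)
            synonyms: list[str] = []
            if len(row) >= 3 and row[2].strip():
                for raw in row[2].split("|"):
                    syn = normalize(raw)
                    if syn and syn != preferred and syn not in synonyms:
                        synonyms.append(syn)
            concepts.append(LexiconConcept(code, preferred, tuple(synonyms)))
    if not concepts:
        logger.warning("lexicon file %s is empty", path)
    return concepts


def write_lexicon(concepts: Sequence[LexiconConcept], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for c in concepts:
            writer.writerow([c.code, c.preferred_name, "|".join(c.synonyms)])


def merge_glossaries(paths: Sequence[str | Path]) -> BilingualDictionary:
    """Union of two-column (source, target) TSV glossaries.

    Identical (source, target) pairs collapse to one entry with merged
    provenance; the same source with different targets accumulates targets.
    Malformed rows are skipped with a logged count.
    """
    if not paths:
        raise ValueError("merge_glossaries requires at least one glossary path")
    d = BilingualDictionary()
    for path in paths:
        path = Path(path)
        skipped = 0
        with path.open(encoding="utf-8", newline="") as fh:
            reader = csv.reader(fh, delimiter="\t")
            for row in reader:
                if not row or (len(row) == 1 and not row[0].strip()):
                    continue
                if len(row) < 2 or not row[0].strip() or not row[1].strip():
                    skipped += 1
                    continue
                d.add(row[0], row[1], provenance=path.name)
        if skipped:
            logger.warning("%s: skipped %d malformed rows", path, skipped)
    return d


def write_glossary(d: BilingualDictionary, path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        for src in sorted(d.entries):
            for tgt in d.entries[src].targets:
                writer.writerow([src, tgt])


def _target_matches(
    target: str,
    lexicon_terms: Sequence[str],
    terms_by_len: dict[int, list[str]] | None,
    max_dist: int,
    token_filter: Callable[[str, str], bool] | None,
) -> bool:
    multi_word = len(tokenize(target)) > 1
    if not multi_word:
        # single-word targets: exact match only
        return target in lexicon_terms if terms_by_len is None else (
            target in terms_by_len.get(len(target), ())
        )
    if terms_by_len is not None:
        # length-window prefilter: |len(a)-len(b)| <= max_dist is a lower
        # bound on edit distance, so the filter is lossless
        candidates: Iterable[str] = (
            t
            for length in range(len(target) - max_dist, len(target) + max_dist + 1)
            for t in terms_by_len.get(length, ())
        )
    else:
        candidates = lexicon_terms
    for term in candidates:
        if levenshtein_distance(target, term) <= max_dist:
            if token_filter is None or token_filter(target, term):
                return True
    return False


def extract_domain_dictionary(
    d: BilingualDictionary,
    lexicon: Sequence[LexiconConcept],
    max_dist: int = 3,
    *,
    prefilter: bool = False,
    token_filter: Callable[[str, str], bool] | None = None,
) -> BilingualDictionary:
    """Keep entries with at least one target fuzzy-matching a lexicon term.

    Multi-word targets match when their Levenshtein distance to some lexicon
    term (preferred name or synonym) is at most ``max_dist``; single-word
    targets only on an exact match.  Retained entries keep *all* their
    targets.  ``token_filter(target, term)`` is an optional extra predicate
    applied to fuzzy matches (off by default).
    """
    if max_dist < 0:
        raise ValueError("max_dist must be >= 0")
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    terms: list[str] = []
    seen: set[str] = set()
    for concept in lexicon:
        for term in concept.terms():
            t = normalize(term)
            if t not in seen:
                seen.add(t)
                terms.append(t)
    terms_by_len: dict[int, list[str]] | None = None
    if prefilter:
        terms_by_len = {}
        for t in terms:
            terms_by_len.setdefault(len(t), []).append(t)
    kept: dict[str, BilingualEntry] = {}
    for src, entry in d.items():
        if any(
            _target_matches(tgt, terms, terms_by_len, max_dist, token_filter)
            for tgt in entry.targets
        ):
            kept[src] = BilingualEntry(
                source=entry.source,
                targets=list(entry.targets),
                provenance=set(entry.provenance),
            )
    return BilingualDictionary(kept)
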