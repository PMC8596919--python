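"""String-level similarity scores: Levenshtein and Jaccard.

Both scorers are symmetric and mapped into [0, 1].  Levenshtein similarity
normalizes the raw edit distance by the longer string's length; Jaccard
works on token *sets* (duplicates collapsed) from the shared tokenizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._text import token_set


def levenshtein_distance(a: str, b: str) -> int:
    """Minimum number of single-character insertions, deletions or
    substitutions converting ``a`` into ``b``."""
    if a == b:
        return 0
    if not a:
        return len(b)
    if not b:
        return len(a)
    if len(a) < len(b):  # keep the inner row short
        a, b = b, a
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, start=1):
        cur = [i]
        for j, cb in enumerate(b, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def levenshtein_similarity(a: str, b: str) -> float:
    """1 - d(a, b) / max(|a|, |b|); two empty strings score 1.0."""
    longest = max(len(a), len(b))
    if longest == 0:
        return 1.0
    return 1.0 - levenshtein_distance(a, b) / longest


def jaccard_similarity(a: str, b: str) -> float:
    """|A & B| / |A | B| over token sets; two empty sets score 1.0."""
    ta, tb = token_set(a), token_set(b)
    if not ta and not tb:
        return 1.0
    return len(ta & tb) / len(ta | tb)


@dataclass
class SimilarityVector:
    """The four per-pair scores fed to the synonym classifier.

    ``flags`` records components imputed to zero for lack of resource
    coverage (out-of-vocabulary phrases, unresolvable taxonomy tokens,
    missing resources).
    """

    lev: float
    jac: float
    cbow: float
    wup: float
    flags: frozenset[str] = field(default_factory=frozenset)

    def as_tuple(self) -> tuple[float, float, float, float]:
        return (self.lev, self.jac, self.cbow, self.wup)

    def __post_init__(self) -> None:
        for name, value in zip(("lev", "jac", "cbow", "wup"), self.as_tuple()):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} score {value} outside [0, 1]")


def similarity_vector(a, b, *, embedding=None, taxonomy=None, word_map=None):
    """Score a candidate pair with all four similarity algorithms.

    ``embedding`` is a fitted :class:`~lexicode.embedding.CbowEmbedding`;
    ``taxonomy``/``word_map`` feed the Wu-Palmer scorer.  A component whose
    resource is absent or lacks coverage for the pair is imputed 0 and
    flagged.
    """
    from .taxonomy import wup_phrase_similarity  # deferred: avoids cycle

    flags: set[str] = set()
    lev = levenshtein_similarity(a, b)
    jac = jaccard_similarity(a, b)
    if embedding is None:
        cbow, oov = 0.0, True
        flags.add("cbow_missing")
    else:
        cbow, oov = embedding.phrase_similarity(a, b)
        if oov:
            flags.add("cbow_oov")
    if taxonomy is None or word_map is None:
        wup = 0.0
        flags.add("wup_missing")
    else:
        wup, unresolved = wup_phrase_similarity(taxonomy, word_map, a, b)
        if unresolved:
            flags.add("wup_unresolved")
    return SimilarityVector(lev, jac, cbow, wup, frozenset(flags))


class SimilarityScorer:
    """Bundle of scoring resources with a single ``vector(a, b)`` entry point."""

    def __init__(self, embedding=None, taxonomy=None, word_map=None):
        self.embedding = embedding
        self.taxonomy = taxonomy
        self.word_map = word_map

    def vector(self, a: str, b: str) -> SimilarityVector:
        return similarity_vector(
            a,
            b,
            embedding=self.embedding,
            taxonomy=self.taxonomy,
            word_map=self.word_map,
        )
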