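"""End-to-end phrase coding and gold-standard evaluation.

Coding a phrase: translate it (hybrid union), pair every translation with
every lexicon term, score each pair with the four similarity algorithms,
classify each pair with the synonym network, and assign the code of the
highest-probability synonym pair (ties: higher Wu-Palmer score, then
lexicographically smallest code).  A phrase with no synonym-labeled pair
gets ``NO_MATCH``.

Evaluation follows the counting scheme in which a phrase with the correct
code is a true positive, a gold-coded phrase that received a wrong code or
no code is a false negative, and a gold-NO_MATCH phrase that received any
code is a false positive.  Note this differs from conventional retrieval
counting, where a wrongly coded phrase is also a false positive; the
conventional variant is available via ``standard_metrics=True``.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from sklearn.base import BaseEstimator

from ._text import normalize, token_set
from .lexicon import BilingualDictionary, LexiconConcept
from .mlp import SynonymMLP
from .similarity import SimilarityScorer
from .translation import TranslationSet, TranslatorBackend, hybrid_translate

logger = logging.getLogger(__name__)

NO_MATCH = "NO_MATCH"


@dataclass
class CodingResult:
    phrase: str
    translations: TranslationSet
    assigned: str  # lexicon code or NO_MATCH
    score: float | None = None  # winning synonym probability
    alternatives: list[tuple[str, float]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "phrase": self.phrase,
            "candidates": [
                {"text": t, "origin": o} for t, o in self.translations.candidates
            ],
            "assigned": self.assigned,
            "score": self.score,
            "alternatives": [[c, p] for c, p in self.alternatives],
        }


def generate_candidates(
    translations: TranslationSet,
    lexicon: Sequence[LexiconConcept],
    prefilter: str = "none",
) -> list[tuple[str, str, str]]:
    """Cross product of translation candidates and lexicon terms.

    Returns ``(candidate translation, lexicon term, concept code)`` triples.
    ``prefilter="token-overlap"`` drops pairs whose token sets are disjoint
    (a cheap blocking step); an empty translation set yields no candidates,
    which downstream becomes NO_MATCH.
    """
    if not lexicon:
        raise ValueError("lexicon must be non-empty")
    if prefilter not in ("none", "token-overlap"):
        raise ValueError(f"unknown prefilter {prefilter!r}")
    pairs: list[tuple[str, str, str]] = []
    for cand in translations.texts():
        cand_tokens = token_set(cand) if prefilter == "token-overlap" else None
        for concept in lexicon:
            for term in concept.terms():
                if cand_tokens is not None and cand_tokens.isdisjoint(token_set(term)):
                    continue
                pairs.append((cand, term, concept.code))
    return pairs


def code_phrase(
    phrase: str,
    *,
    dictionary: BilingualDictionary,
    external: TranslatorBackend,
    lexicon: Sequence[LexiconConcept],
    scorer: SimilarityScorer,
    mlp: SynonymMLP,
    prefilter: str = "none",
    top_k: int = 3,
) -> CodingResult:
    """Assign a lexicon code (or NO_MATCH) to one source phrase."""
    translations = hybrid_translate(phrase, dictionary, external)
    candidates = (
        generate_candidates(translations, lexicon, prefilter=prefilter)
        if not translations.failed
        else []
    )
    scored: list[tuple[float, float, str]] = []  # (prob, wup, code)
    for cand, term, code in candidates:
        v = scorer.vector(cand, term)
        prob, label = mlp.predict_pair(v)
        if label == 1:
            scored.append((prob, v.wup, code))
    if not scored:
        return CodingResult(phrase, translations, NO_MATCH)
    # higher probability, then higher wup, then smaller code
    scored.sort(key=lambda t: (-t[0], -t[1], t[2]))
    best_prob, _, best_code = scored[0]
    alternatives: list[tuple[str, float]] = []
    seen = {best_code}
    for prob, _, code in scored:
        if code not in seen:
            seen.add(code)
            alternatives.append((code, prob))
        if len(alternatives) >= top_k:
            break
    return CodingResult(phrase, translations, best_code, best_prob, alternatives)


class LexiconCoder(BaseEstimator):
    """End-to-end coder bundling all fitted resources.

    ``predict(phrases)`` returns assigned codes; ``code(phrase)`` and
    ``code_all(phrases)`` return full :class:`CodingResult` objects.
    """

    def __init__(
        self,
        dictionary: BilingualDictionary,
        external: TranslatorBackend,
        lexicon: Sequence[LexiconConcept],
        scorer: SimilarityScorer,
        mlp: SynonymMLP,
        prefilter: str = "none",
        top_k: int = 3,
    ):
        self.dictionary = dictionary
        self.external = external
        self.lexicon = lexicon
        self.scorer = scorer
        self.mlp = mlp
        self.prefilter = prefilter
        self.top_k = top_k

    def code(self, phrase: str) -> CodingResult:
        return code_phrase(
            phrase,
            dictionary=self.dictionary,
            external=self.external,
            lexicon=self.lexicon,
            scorer=self.scorer,
            mlp=self.mlp,
            prefilter=self.prefilter,
            top_k=self.top_k,
        )

    def code_all(self, phrases: Sequence[str]) -> list[CodingResult]:
        return [self.code(p) for p in phrases]

    def predict(self, phrases: Sequence[str]) -> list[str]:
        return [r.assigned for r in self.code_all(phrases)]


# ------------------------------------------------------------------ metrics
@dataclass
class EvalReport:
    tp: int
    fn: int
    fp: int
    precision: float
    recall: float
    f1: float
    undefined: frozenset[str] = field(default_factory=frozenset)
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "fp": self.fp,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "undefined": sorted(self.undefined),
            "n_excluded": self.n_excluded,
        }


def harmonic_f1(precision: float, recall: float) -> float:
    """F1 = 2 * precision * recall / (precision + recall); 0 when both are 0."""
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def report_from_counts(tp: int, fn: int, fp: int, n_excluded: int = 0) -> EvalReport:
    undefined = set()
    if tp + fp > 0:
        precision = tp / (tp + fp)
    else:
        precision = 0.0
        undefined.add("precision")
    if tp + fn > 0:
        recall = tp / (tp + fn)
    else:
        recall = 0.0
        undefined.add("recall")
    if precision + recall == 0:
        undefined.add("f1")
    return EvalReport(
        tp, fn, fp, precision, recall, harmonic_f1(precision, recall),
        frozenset(undefined), n_excluded,
    )


def evaluate(
    results: Sequence[CodingResult],
    gold: Mapping[str, str],
    *,
    standard_metrics: bool = False,
    missing: str = "error",
) -> EvalReport:
    """Score coding results against a gold phrase -> code map.

    ``gold`` values are lexicon codes or ``NO_MATCH``.  With the default
    counting scheme: TP = correct code; FN = gold-coded phrase given a
    wrong code or NO_MATCH; FP = gold-NO_MATCH phrase given any code.
    ``standard_metrics=True`` additionally counts wrongly coded phrases as
    false positives (conventional retrieval counting).  ``missing`` is
    ``"error"`` (raise on a phrase absent from gold) or ``"exclude"``
    (skip with a logged count — gold files often omit NO_MATCH rows).
    """
    if missing not in ("error", "exclude"):
        raise ValueError("missing must be 'error' or 'exclude'")
    norm_gold = {normalize(k): v for k, v in gold.items()}
    tp = fn = fp = 0
    n_excluded = 0
    for result in results:
        key = normalize(result.phrase)
        if key not in norm_gold:
            if missing == "error":
                raise KeyError(f"phrase {result.phrase!r} missing from gold standard")
            n_excluded += 1
            continue
        truth = norm_gold[key]
        got = result.assigned
        if truth == NO_MATCH:
            if got != NO_MATCH:
                fp += 1
        else:
            if got == truth:
                tp += 1
            else:
                fn += 1
                if standard_metrics and got != NO_MATCH:
                    fp += 1
    if n_excluded:
        logger.warning("evaluate: excluded %d phrases absent from gold", n_excluded)
    return report_from_counts(tp, fn, fp, n_excluded=n_excluded)


# ---------------------------------------------------------------------- I/O
def load_gold(path: str | Path) -> dict[str, str]:
    """Read a gold TSV of ``phrase<TAB>code-or-NO_MATCH`` rows."""
    gold: dict[str, str] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"malformed gold row: {line!r}")
            gold[parts[0].strip()] = parts[1].strip()
    return gold


def write_results(results: Sequence[CodingResult], path: str | Path) -> None:
    with Path(path).open("w", encoding="utf-8") as fh:
        for r in results:
            fh.write(json.dumps(r.to_dict()) + "\n")


def read_results(path: str | Path) -> list[CodingResult]:
    out: list[CodingResult] = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if not line.strip():
            continue
        d = json.loads(line)
        ts = TranslationSet(
            source=d["phrase"],
            candidates=[(c["text"], c["origin"]) for c in d["candidates"]],
        )
        out.append(
            CodingResult(
                phrase=d["phrase"],
                translations=ts,
                assigned=d["assigned"],
                score=d["score"],
                alternatives=[(c, p) for c, p in d["alternatives"]],
            )
        )
    return out
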