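"""Candidate generation, phrase coding, and gold-standard evaluation."""

from __future__ import annotations

import numpy as np
import pytest

from lexicode.coder import (
    NO_MATCH,
    CodingResult,
    evaluate,
    generate_candidates,
    harmonic_f1,
    report_from_counts,
)
from lexicode.lexicon import LexiconConcept
from lexicode.synthetic import make_gold, source_phrase
from lexicode.translation import TranslationSet


LEX3 = [
    LexiconConcept("RID1", "lung", ("pulmo",)),
    LexiconConcept("RID2", "nodule", ("tubercle",)),
    LexiconConcept("RID3", "pleura", ("pleural membrane",)),
]


def ts(*texts):
    return TranslationSet("src", [(t, "dictionary") for t in texts])


# ---------------------------------------------------- generate_candidates
def test_candidate_product_arithmetic():
    pairs = generate_candidates(ts("a b", "c d"), LEX3, prefilter="none")
    assert len(pairs) == 2 * 6  # 2 translations x (3 preferred + 3 synonyms)
    assert {code for _, _, code in pairs} == {"RID1", "RID2", "RID3"}


def test_token_overlap_prefilter_is_a_subset():
    full = set(generate_candidates(ts("pleural nodule"), LEX3, prefilter="none"))
    filtered = set(
        generate_candidates(ts("pleural nodule"), LEX3, prefilter="token-overlap")
    )
    assert filtered <= full
    assert all("pleural" in term or "nodule" in term for _, term, _ in filtered)


def test_failed_translation_yields_no_candidates():
    assert generate_candidates(TranslationSet("src", []), LEX3) == []


def test_empty_lexicon_rejected():
    with pytest.raises(ValueError):
        generate_candidates(ts("x"), [])


# ------------------------------------------------------------ code_phrase
def test_exact_dictionary_match_gets_correct_code(pipeline_coder, lexicon):
    """A phrase whose translation equals the lexicon preferred name exactly
    must be coded with that concept, at a score above threshold."""
    concept = lexicon[0]
    result = pipeline_coder.code(source_phrase(concept.code))
    assert result.assigned == concept.code
    assert result.score is not None and result.score >= pipeline_coder.mlp.threshold


def test_untranslatable_phrase_is_no_match(pipeline_coder):
    result = pipeline_coder.code("zh_never_seen_phrase")
    assert result.translations.failed
    assert result.assigned == NO_MATCH and result.score is None


def test_probability_tie_breaks_to_smaller_code(scorer, benchmark_split):
    # two concepts expose an identical term -> identical probabilities
    from lexicode.coder import code_phrase
    from lexicode.lexicon import BilingualDictionary
    from lexicode.translation import TableTranslator

    lex = [
        LexiconConcept("RID9", "lobe of lung"),
        LexiconConcept("RID2", "lobe of lung2"),  # distinct but same tokens
        LexiconConcept("RID5", "lobe of lung"),
    ]
    d = BilingualDictionary()
    d.add("zh1", "lobe of lung")
    result = code_phrase(
        "zh1",
        dictionary=d,
        external=TableTranslator({}),
        lexicon=lex,
        scorer=scorer,
        mlp=benchmark_split["mlp"],
    )
    assert result.assigned == "RID5"  # min("RID9", "RID5") among the tie


def test_raising_threshold_never_adds_matches(pipeline_coder, cfg, lexicon):
    phrases = [source_phrase(c.code) for c in lexicon[:8]] + ["zh_nomatch_0"]
    mlp = pipeline_coder.mlp
    original = mlp.threshold
    counts = []
    try:
        for t in (0.3, 0.5, 0.7, 0.9, 0.99):
            mlp.threshold = t
            counts.append(
                sum(r.assigned != NO_MATCH for r in pipeline_coder.code_all(phrases))
            )
    finally:
        mlp.threshold = original
    assert counts == sorted(counts, reverse=True)


def test_coding_is_deterministic(pipeline_coder, lexicon):
    phrase = source_phrase(lexicon[3].code)
    r1, r2 = pipeline_coder.code(phrase), pipeline_coder.code(phrase)
    assert r1.to_dict() == r2.to_dict()


def test_end_to_end_f1_on_synthetic_gold(pipeline_coder, cfg, lexicon):
    """Regression guard: full coverage, 10% typo corruption, default seed."""
    gold = make_gold(cfg, lexicon)
    results = pipeline_coder.code_all(list(gold))
    report = evaluate(results, gold)
    assert report.f1 > 0.8


# --------------------------------------------------------------- evaluate
def res(phrase, assigned):
    return CodingResult(phrase, TranslationSet(phrase, []), assigned)


def test_reported_metric_arithmetic():
    # precision 0.9178, recall 0.8859 combine to F1 0.9015
    assert harmonic_f1(0.9178, 0.8859) == pytest.approx(0.9015, abs=1e-4)


def test_perfect_coding_scores_one():
    gold = {"p1": "RID1", "p2": "RID2", "p3": NO_MATCH}
    results = [res("p1", "RID1"), res("p2", "RID2"), res("p3", NO_MATCH)]
    report = evaluate(results, gold)
    assert (report.precision, report.recall, report.f1) == (1.0, 1.0, 1.0)


def test_unit_counts_give_half_metrics():
    report = report_from_counts(tp=1, fn=1, fp=1)
    assert (report.precision, report.recall, report.f1) == (0.5, 0.5, 0.5)


def test_counting_definitions():
    gold = {"a": "RID1", "b": "RID2", "c": NO_MATCH, "d": NO_MATCH, "e": "RID3"}
    results = [
        res("a", "RID1"),     # correct code -> TP
        res("b", "RID9"),     # wrong code -> FN
        res("c", "RID1"),     # gold NO_MATCH coded -> FP
        res("d", NO_MATCH),   # true negative, uncounted
        res("e", NO_MATCH),   # missed code -> FN
    ]
    report = evaluate(results, gold)
    assert (report.tp, report.fn, report.fp) == (1, 2, 1)
    standard = evaluate(results, gold, standard_metrics=True)
    assert (standard.tp, standard.fn, standard.fp) == (1, 2, 2)


def test_count_identities_on_random_tables():
    rng = np.random.default_rng(17)
    codes = ["RID1", "RID2", "RID3", NO_MATCH]
    for _ in range(50):
        n = int(rng.integers(1, 40))
        gold = {f"p{i}": codes[rng.integers(4)] for i in range(n)}
        results = [res(f"p{i}", codes[rng.integers(4)]) for i in range(n)]
        report = evaluate(results, gold)
        n_coded = sum(1 for v in gold.values() if v != NO_MATCH)
        n_nomatch = n - n_coded
        assert report.tp + report.fn == n_coded
        assert report.fp <= n_nomatch
        if report.precision > 0 and report.recall > 0:
            assert (
                min(report.precision, report.recall)
                <= report.f1
                <= max(report.precision, report.recall)
            )


def test_missing_phrase_raises_or_excludes(caplog):
    gold = {"a": "RID1"}
    results = [res("a", "RID1"), res("ghost", "RID1")]
    with pytest.raises(KeyError, match="ghost"):
        evaluate(results, gold)
    with caplog.at_level("WARNING"):
        report = evaluate(results, gold, missing="exclude")
    assert report.tp == 1 and report.n_excluded == 1


def test_undefined_ratios_reported_as_zero_with_flag():
    report = report_from_counts(tp=0, fn=0, fp=0)
    assert report.precision == 0.0 and report.recall == 0.0 and report.f1 == 0.0
    assert {"precision", "recall", "f1"} <= set(report.undefined)
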