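"""Synthetic generator: determinism, constructed properties, oracles."""

from __future__ import annotations

import filecmp
from collections import Counter

import pytest

from lexicode.lexicon import extract_domain_dictionary, merge_glossaries
from lexicode.similarity import levenshtein_distance, levenshtein_similarity
from lexicode.synthetic import (
    SynthConfig,
    corrupt_phrase,
    distributional_aliases,
    make_corpus,
    make_glossaries,
    make_labeled_pairs,
    make_lexicon,
    make_taxonomy,
    source_phrase,
    write_fixtures,
)


def test_complete_tree_node_count():
    tax = make_taxonomy(SynthConfig(taxonomy_branching=2, taxonomy_depth=3, n_concepts=4))
    assert len(tax) == 7  # 1 + 2 + 4
    assert tax.depth(tax.root) == 1
    assert len(tax.leaves()) == 4


def test_taxonomy_regenerates_identically(cfg):
    t1, t2 = make_taxonomy(cfg), make_taxonomy(cfg)
    assert t1.edges() == t2.edges()


def test_lexicon_counts_and_distinct_codes(cfg, tax, lexicon):
    assert len(lexicon) == cfg.n_concepts
    assert len({c.code for c in lexicon}) == cfg.n_concepts
    again = make_lexicon(cfg, tax)
    assert again == lexicon


def test_n_concepts_bounded_by_leaves(tax):
    with pytest.raises(ValueError):
        make_lexicon(SynthConfig(n_concepts=1000), tax)


def test_glyph_synonyms_within_distance_three(lexicon):
    """Oracle check: every generated glyph synonym is a small-edit variant."""
    checked = 0
    for c in lexicon:
        for syn in c.synonyms:
            if len(syn.split()) == len(c.preferred_name.split()):  # glyph variant
                assert 1 <= levenshtein_distance(syn, c.preferred_name) <= 3
                checked += 1
    assert checked > 0


def test_corpus_size_and_determinism(cfg, lexicon, corpus):
    assert len(corpus) == cfg.corpus_sentences
    assert make_corpus(cfg, lexicon) == corpus


def test_aliases_share_templates_with_their_words(cfg, lexicon, corpus):
    """A word and its alias must occur with overlapping context vocabularies."""
    aliases = distributional_aliases(lexicon)
    word, alias = next(iter(aliases.items()))
    ctx_word = {t for s in corpus if word in s for t in s}
    ctx_alias = {t for s in corpus if alias in s for t in s}
    assert len(ctx_word & ctx_alias) >= 5


def test_labeled_pair_counts_and_balance(cfg, labeled_pairs):
    labels = Counter(p.label for p in labeled_pairs)
    assert labels[1] == cfg.n_pairs
    assert labels[0] == round(cfg.n_pairs * cfg.negative_ratio)
    regimes = Counter(p.regime for p in labeled_pairs if p.label == 1)
    for regime, prop in cfg.regime_mix.items():
        assert regimes[regime] == pytest.approx(cfg.n_pairs * prop, abs=1)


def test_glyph_positives_similarity_floor(labeled_pairs):
    for p in labeled_pairs:
        if p.regime == "glyph":
            assert levenshtein_similarity(p.a, p.b) >= 0.5


def test_adversarial_negatives_are_close_but_negative(labeled_pairs):
    adversarial = [p for p in labeled_pairs if p.regime == "adversarial"]
    assert adversarial, "benchmark must include adversarial negatives"
    for p in adversarial:
        assert p.label == 0
        assert levenshtein_distance(p.a, p.b) <= 3


def test_bad_regime_mix_rejected():
    with pytest.raises(ValueError):
        SynthConfig(regime_mix={"glyph": 0.5, "token_subset": 0.5,
                                "distributional": 0.25, "taxonomic": 0.25})
    with pytest.raises(ValueError):
        SynthConfig(regime_mix={"glyph": 1.0})


def test_full_coverage_no_typos_gives_exact_lookup(tax):
    cfg = SynthConfig(glossary_coverage=1.0, typo_rate=0.0)
    lexicon = make_lexicon(cfg, tax)
    rows = [r for f in make_glossaries(cfg, lexicon) for r in f]
    by_source = {}
    for src, tgt in rows:
        by_source.setdefault(src, set()).add(tgt)
    terms = {t for c in lexicon for t in c.terms()}
    for c in lexicon:
        targets = by_source[source_phrase(c.code)]
        assert c.preferred_name in targets or targets <= terms


def test_corrupted_targets_survive_fuzzy_extraction(cfg, tax, tmp_path):
    """Multi-word typo corruption stays within distance 3 of a lexicon term,
    so extraction retains every generated entry."""
    lexicon = make_lexicon(cfg, tax)
    files = make_glossaries(cfg, lexicon)
    paths = []
    for i, rows in enumerate(files):
        p = tmp_path / f"g{i}.tsv"
        p.write_text("".join(f"{s}\t{t}\n" for s, t in rows), encoding="utf-8")
        paths.append(p)
    merged = merge_glossaries(paths)
    kept = extract_domain_dictionary(merged, lexicon)
    assert set(kept.entries) == set(merged.entries)


def test_glossary_overlap_deduplicates(cfg, lexicon):
    f1, f2 = make_glossaries(cfg, lexicon)
    overlap = set(f1) & set(f2)
    assert overlap, "glossary files must share deliberate duplicate pairs"


def test_corrupt_phrase_never_deletes_tokens():
    import numpy as np

    rng = np.random.default_rng(0)
    for _ in range(100):
        out = corrupt_phrase("superior lobe of lung", rng, int(rng.integers(1, 4)))
        assert len(out.split()) == 4
        assert "of" in out.split()


def test_write_fixtures_byte_identical(tmp_path):
    cfg = SynthConfig(corpus_sentences=50, n_pairs=40)
    d1, d2 = tmp_path / "run1", tmp_path / "run2"
    p1, p2 = write_fixtures(cfg, d1), write_fixtures(cfg, d2)
    assert set(p1) == set(p2)
    for name in p1:
        assert filecmp.cmp(p1[name], p2[name], shallow=False), name
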