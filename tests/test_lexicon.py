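"""Lexicon/glossary I/O, merging, and fuzzy domain-dictionary extraction."""

from __future__ import annotations

import pytest

from lexicode.lexicon import (
    BilingualDictionary,
    extract_domain_dictionary,
    load_lexicon,
    merge_glossaries,
)
from lexicode.similarity import levenshtein_distance


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


# ----------------------------------------------------------- load_lexicon
def test_load_lexicon_parses_rows_and_synonyms(tmp_path):
    p = write(tmp_path / "lex.tsv", "RID1\tlung\nRID2\tnodule\tnodules|tubercle\n")
    concepts = load_lexicon(p)
    assert [c.code for c in concepts] == ["RID1", "RID2"]
    assert concepts[0].synonyms == ()
    assert concepts[1].synonyms == ("nodules", "tubercle")


def test_load_lexicon_duplicate_code_raises(tmp_path):
    p = write(tmp_path / "lex.tsv", "RID1\tlung\nRID1\tliver\n")
    with pytest.raises(ValueError, match="RID1"):
        load_lexicon(p)


def test_load_lexicon_empty_preferred_name_raises(tmp_path):
    p = write(tmp_path / "lex.tsv", "RID1\tlung\nRID2\t  \n")
    with pytest.raises(ValueError, match="2"):
        load_lexicon(p)


def test_load_lexicon_empty_file_warns(tmp_path, caplog):
    p = write(tmp_path / "lex.tsv", "")
    with caplog.at_level("WARNING"):
        assert load_lexicon(p) == []
    assert any("empty" in r.message for r in caplog.records)


# ------------------------------------------------------- merge_glossaries
def test_merge_union_arithmetic(tmp_path):
    a = write(tmp_path / "a.tsv", "s1\tlung\ns2\tnodule\ns3\tliver\n")
    b = write(tmp_path / "b.tsv", "s2\tnodule\ns4\tpleura\n")
    d = merge_glossaries([a, b])
    assert d.size == 4
    assert d.entries["s2"].provenance == {"a.tsv", "b.tsv"}


def test_merge_same_source_accumulates_targets(tmp_path):
    a = write(tmp_path / "a.tsv", "s1\tnodule\n")
    b = write(tmp_path / "b.tsv", "s1\ttubercle\n")
    d = merge_glossaries([a, b])
    assert d.size == 1
    assert d.lookup("s1") == ["nodule", "tubercle"]


def test_merge_with_empty_file_is_identity(tmp_path):
    empty = write(tmp_path / "e.tsv", "")
    five = write(
        tmp_path / "f.tsv", "".join(f"s{i}\tt{i}\n" for i in range(5))
    )
    assert merge_glossaries([empty, five]).size == 5


def test_merge_is_order_insensitive(tmp_path):
    a = write(tmp_path / "a.tsv", "s1\tlung\ns2\tnodule\n")
    b = write(tmp_path / "b.tsv", "s2\ttubercle\ns3\tpleura\n")
    d1, d2 = merge_glossaries([a, b]), merge_glossaries([b, a])
    assert set(d1.entries) == set(d2.entries)
    for src in d1.entries:
        assert set(d1.lookup(src)) == set(d2.lookup(src))


def test_merge_requires_at_least_one_path():
    with pytest.raises(ValueError):
        merge_glossaries([])


def test_merge_skips_malformed_rows(tmp_path, caplog):
    a = write(tmp_path / "a.tsv", "s1\tlung\nmalformed-no-tab\ns2\tnodule\n")
    with caplog.at_level("WARNING"):
        d = merge_glossaries([a])
    assert d.size == 2
    assert any("skipped 1" in r.message for r in caplog.records)


def test_lookup_normalizes_whitespace_and_case(tmp_path):
    a = write(tmp_path / "a.tsv", "Some  Term\tLung Nodule\n")
    d = merge_glossaries([a])
    assert d.lookup("  some term ") == ["lung nodule"]


# ---------------------------------------------- extract_domain_dictionary
def make_dict(pairs):
    d = BilingualDictionary()
    for i, tgt in enumerate(pairs):
        d.add(f"s{i}", tgt)
    return d


def test_extract_fuzzy_multi_word_within_three(lexicon_3concepts):
    d = make_dict(["lobes of lung"])  # distance 1 from "lobe of lung"
    kept = extract_domain_dictionary(d, lexicon_3concepts)
    assert kept.size == 1


def test_extract_single_word_requires_exact_match(lexicon_3concepts):
    # "nodule" is distance 1 from lexicon term "nodules" but single-word
    d = make_dict(["nodule"])
    assert extract_domain_dictionary(d, lexicon_3concepts).size == 0
    d = make_dict(["nodules"])  # exact match against a synonym
    assert extract_domain_dictionary(d, lexicon_3concepts).size == 1


def test_extract_exact_synonym_match_retained(lexicon_3concepts):
    d = make_dict(["pulmonary lobe"])  # equals a synonym exactly
    assert extract_domain_dictionary(d, lexicon_3concepts).size == 1


def test_extract_is_subset_and_idempotent(lexicon_3concepts):
    d = make_dict(["lobes of lung", "totally unrelated phrase", "nodules"])
    once = extract_domain_dictionary(d, lexicon_3concepts)
    assert set(once.entries) <= set(d.entries)
    twice = extract_domain_dictionary(once, lexicon_3concepts)
    assert set(twice.entries) == set(once.entries)


def test_extract_monotone_in_max_dist(lexicon_3concepts):
    d = make_dict(
        ["lobe of lung", "lobes of lungs", "lobez of lungz", "qqq www eee"]
    )
    sizes = [
        extract_domain_dictionary(d, lexicon_3concepts, max_dist=k).size
        for k in range(0, 6)
    ]
    assert sizes == sorted(sizes)


def test_extract_prefilter_is_lossless(lexicon_3concepts):
    d = make_dict(
        ["lobes of lung", "nodule", "nodules", "lobe lung", "random stuff here"]
    )
    full = extract_domain_dictionary(d, lexicon_3concepts, prefilter=False)
    fast = extract_domain_dictionary(d, lexicon_3concepts, prefilter=True)
    assert set(full.entries) == set(fast.entries)


def test_extract_exactness_against_distance_oracle(lexicon_3concepts):
    """On a constructed glossary with known distances, exactly the
    multi-word targets within distance 3 plus exact single-word matches
    survive."""
    targets = [
        "lobe of lung",      # distance 0
        "lobes of lung",     # 1
        "lobus off lung",    # 3
        "lobus offf lungs",  # 5 (out)
        "nodules",           # single word, exact
        "nodule",            # single word, distance 1 (out)
        "completely different wording",  # far (out)
    ]
    lex_terms = [
        t
        for c in lexicon_3concepts
        for t in (c.preferred_name, *c.synonyms)
    ]
    expected = set()
    for i, tgt in enumerate(targets):
        best = min(levenshtein_distance(tgt, t) for t in lex_terms)
        if len(tgt.split()) > 1:
            if best <= 3:
                expected.add(f"s{i}")
        elif best == 0:
            expected.add(f"s{i}")
    d = make_dict(targets)
    kept = extract_domain_dictionary(d, lexicon_3concepts)
    assert set(kept.entries) == expected
    assert "s3" not in kept.entries and "s5" not in kept.entries


def test_extract_requires_nonempty_lexicon():
    with pytest.raises(ValueError):
        extract_domain_dictionary(make_dict(["x y"]), [])


@pytest.fixture()
def lexicon_3concepts(tmp_path):
    p = tmp_path / "lex.tsv"
    p.write_text(
        "RID1\tlobe of lung\tpulmonary lobe\n"
        "RID2\tnodules\n"
        "RID3\tpleural margin\n",
        encoding="utf-8",
    )
    return load_lexicon(p)
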