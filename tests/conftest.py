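"""Shared fixtures: one synthetic study, generated and trained once.

The default :class:`SynthConfig` defines the reference conditions; the
embedding and the benchmark featurization are expensive enough that every
test shares the session-scoped instances.
"""

from __future__ import annotations

import numpy as np
import pytest
from sklearn.model_selection import train_test_split

from lexicode.benchmark import featurize_pairs
from lexicode.embedding import CbowEmbedding
from lexicode.mlp import SynonymMLP
from lexicode.similarity import SimilarityScorer
from lexicode.synthetic import (
    SynthConfig,
    make_corpus,
    make_labeled_pairs,
    make_lexicon,
    make_taxonomy,
)
from lexicode.taxonomy import word_map_from_labels


@pytest.fixture(scope="session")
def cfg() -> SynthConfig:
    return SynthConfig()


@pytest.fixture(scope="session")
def tax(cfg):
    return make_taxonomy(cfg)


@pytest.fixture(scope="session")
def lexicon(cfg, tax):
    return make_lexicon(cfg, tax)


@pytest.fixture(scope="session")
def corpus(cfg, lexicon):
    return make_corpus(cfg, lexicon)


@pytest.fixture(scope="session")
def embedding(cfg, corpus):
    return CbowEmbedding(random_state=cfg.seed).fit(corpus)


@pytest.fixture(scope="session")
def word_map(tax):
    return word_map_from_labels(tax)


@pytest.fixture(scope="session")
def scorer(embedding, tax, word_map):
    return SimilarityScorer(embedding, tax, word_map)


@pytest.fixture(scope="session")
def labeled_pairs(cfg, lexicon, tax):
    return make_labeled_pairs(cfg, lexicon, tax)


@pytest.fixture(scope="session")
def benchmark_split(cfg, labeled_pairs, scorer):
    """Featurized benchmark with a stratified 70/30 split and a trained MLP."""
    X, y = featurize_pairs(labeled_pairs, scorer)
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, random_state=cfg.seed, stratify=y
    )
    mlp = SynonymMLP(random_state=cfg.seed).fit(X_tr, y_tr)
    return {
        "X_train": X_tr, "X_test": X_te,
        "y_train": y_tr, "y_test": y_te,
        "mlp": mlp,
    }


@pytest.fixture(scope="session")
def pipeline_coder(cfg, lexicon, tax, scorer, benchmark_split, tmp_path_factory):
    """Fully wired end-to-end coder over the synthetic study."""
    import csv

    from lexicode.coder import LexiconCoder
    from lexicode.lexicon import extract_domain_dictionary, merge_glossaries
    from lexicode.synthetic import make_glossaries, make_mock_translations
    from lexicode.translation import TableTranslator

    tmp = tmp_path_factory.mktemp("glossaries")
    paths = []
    for i, rows in enumerate(make_glossaries(cfg, lexicon)):
        p = tmp / f"glossary_{i + 1}.tsv"
        with p.open("w", encoding="utf-8", newline="") as fh:
            csv.writer(fh, delimiter="\t", lineterminator="\n").writerows(rows)
        paths.append(p)
    merged = merge_glossaries(paths)
    domain = extract_domain_dictionary(merged, lexicon)
    external = TableTranslator(make_mock_translations(cfg, lexicon))
    return LexiconCoder(domain, external, lexicon, scorer, benchmark_split["mlp"])


@pytest.fixture(scope="session")
def cli_chain(tmp_path_factory):
    """The full command-line pipeline executed twice with identical seeds.

    simulate -> build-dict -> train-embeddings -> score -> train -> code ->
    evaluate, each run in its own directory; returns both directories.
    """
    import json

    from click.testing import CliRunner

    from lexicode.cli import main

    runner = CliRunner()
    dirs = []
    for run in ("run1", "run2"):
        base = tmp_path_factory.mktemp(run)
        fx = base / "fx"

        def invoke(*args):
            result = runner.invoke(main, [str(a) for a in args], catch_exceptions=False)
            assert result.exit_code == 0, result.output
            return result

        invoke("simulate", "--seed", 7, "--outdir", fx)
        invoke("build-dict", "--glossary", fx / "glossary_1.tsv",
               "--glossary", fx / "glossary_2.tsv", "--lexicon", fx / "lexicon.tsv",
               "--max-dist", 3, "--out", base / "domain.tsv")
        invoke("train-embeddings", "--corpus", fx / "corpus.txt", "--seed", 7,
               "--out", base / "embeddings.json")
        invoke("score", "--pairs", fx / "pairs.csv", "--model", base / "embeddings.json",
               "--taxonomy", fx / "taxonomy.tsv", "--out", base / "scores.csv")
        invoke("train", "--features", base / "scores.csv", "--seed", 7,
               "--out", base / "mlp.json")
        invoke("code", "--phrases", fx / "phrases.txt", "--dict", base / "domain.tsv",
               "--lexicon", fx / "lexicon.tsv", "--model", base / "mlp.json",
               "--embeddings", base / "embeddings.json",
               "--taxonomy", fx / "taxonomy.tsv",
               "--mock-table", fx / "mock_translation.tsv", "--seed", 7,
               "--out", base / "results.jsonl")
        invoke("evaluate", "--results", base / "results.jsonl",
               "--gold", fx / "gold.tsv", "--out", base / "report.json")
        dirs.append(base)
    report = json.loads((dirs[0] / "report.json").read_text(encoding="utf-8"))
    return {"dirs": dirs, "report": report}


@pytest.fixture(scope="session")
def planted_rule():
    """Planted-rule dataset: label = [mean of 4 features > 0.5], 2% noise."""
    rng = np.random.default_rng(7)
    X = rng.random((2000, 4))
    y = (X.mean(axis=1) > 0.5).astype(int)
    flip = rng.random(2000) < 0.02
    y[flip] = 1 - y[flip]
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.3, random_state=7, stratify=y
    )
    mlp = SynonymMLP(random_state=7).fit(X_tr, y_tr)
    return {
        "X_train": X_tr, "X_test": X_te,
        "y_train": y_tr, "y_test": y_te,
        "mlp": mlp,
    }
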