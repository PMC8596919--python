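"""Benchmark utilities: featurize labeled pairs and compare the trained
ensemble against thresholded single-score baselines.

The single-score baselines (and the equal-weight linear combination) are
the reference points the fused classifier is expected to beat: each
synthetic regime is constructed to defeat at least one individual score,
so no single thresholded score should reach the ensemble's F1 on the
mixed benchmark.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.metrics import f1_score

from .similarity import SimilarityScorer
from .synthetic import PairExample

SCORE_NAMES = ("lev", "jac", "cbow", "wup")


def featurize_pairs(
    pairs: Sequence[PairExample], scorer: SimilarityScorer
) -> tuple[np.ndarray, np.ndarray]:
    """Similarity-vector features and labels for a labeled pair set."""
    X = np.array([scorer.vector(p.a, p.b).as_tuple() for p in pairs], dtype=float)
    y = np.array([p.label for p in pairs], dtype=int)
    return X, y


def threshold_f1(scores: np.ndarray, y: np.ndarray, grid: np.ndarray | None = None
                 ) -> tuple[float, float]:
    """Best F1 over a threshold grid for one score column; returns
    ``(f1, threshold)``."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 101)
    best_f1, best_t = 0.0, 0.0
    for t in grid:
        f1 = f1_score(y, (scores >= t).astype(int), zero_division=0)
        if f1 > best_f1:
            best_f1, best_t = float(f1), float(t)
    return best_f1, best_t


def single_score_f1s(X: np.ndarray, y: np.ndarray,
                     grid: np.ndarray | None = None) -> dict[str, float]:
    """Grid-swept best F1 of each individual similarity score."""
    return {
        name: threshold_f1(X[:, j], y, grid)[0] for j, name in enumerate(SCORE_NAMES)
    }


def single_score_holdout_f1s(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    grid: np.ndarray | None = None,
) -> dict[str, float]:
    """Held-out F1 of each single-score threshold classifier.

    Each baseline picks its threshold by grid search on the training split
    (the same data the ensemble trains on) and is evaluated on the test
    split — the protocol any classifier comparison uses.
    """
    out = {}
    for j, name in enumerate(SCORE_NAMES):
        _, t = threshold_f1(X_train[:, j], y_train, grid)
        out[name] = float(
            f1_score(y_test, (X_test[:, j] >= t).astype(int), zero_division=0)
        )
    return out


def equal_weight_f1(X: np.ndarray, y: np.ndarray,
                    grid: np.ndarray | None = None) -> float:
    """Grid-swept best F1 of the unweighted mean of the four scores (the
    linear-weighting baseline)."""
    return threshold_f1(X.mean(axis=1), y, grid)[0]
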