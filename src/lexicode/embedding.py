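"""Continuous bag-of-words (CBOW) word embeddings, trained from scratch.

The model follows the classic three-layer word2vec CBOW architecture: the
input layer holds the context words of a symmetric window of size ``c``,
the projection layer averages their vectors, and the output layer scores
the centre word; training maximizes the average log-probability of each
centre word given its context, optimized here with negative sampling and
per-position stochastic gradient updates.  Everything is driven by a single
seeded generator and a single worker, so a fixed seed gives bit-identical
vectors across runs.

Phrase similarity is the cosine of mean in-vocabulary token vectors,
clamped at 0; a phrase that is entirely out of vocabulary scores 0 and is
flagged, mirroring the treatment of unknown words as UNK.
"""

from __future__ import annotations

import json
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from ._text import tokenize


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


class CbowEmbedding(BaseEstimator):
    """CBOW word-embedding model with negative sampling.

    Parameters
    ----------
    dim : embedding dimension (d >= 2).
    window : context half-width c; the context of position t is the up to
        2c surrounding in-vocabulary tokens.
    min_count : minimum corpus frequency for a token to enter the
        vocabulary.
    epochs : full passes over the corpus.
    negative : negative samples per centre word, drawn from the unigram
        distribution raised to 3/4.
    learning_rate : constant SGD step size.
    random_state : seed for initialization, epoch shuffling and negative
        sampling.

    Attributes
    ----------
    vocabulary_ : token -> row index.
    index2word_ : inverse of ``vocabulary_``.
    vectors_ : (V, dim) input-side embedding matrix.
    counts_ : per-token corpus frequencies aligned with ``index2word_``.
    """

    def __init__(
        self,
        dim: int = 100,
        window: int = 5,
        min_count: int = 1,
        epochs: int = 20,
        negative: int = 5,
        learning_rate: float = 0.025,
        random_state: int | None = None,
    ):
        self.dim = dim
        self.window = window
        self.min_count = min_count
        self.epochs = epochs
        self.negative = negative
        self.learning_rate = learning_rate
        self.random_state = random_state

    # ------------------------------------------------------------------ fit
    def fit(self, X: Iterable[Sequence[str]], y=None) -> "CbowEmbedding":
        """Train on a corpus given as an iterable of token sequences."""
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if self.window < 1:
            raise ValueError("window must be >= 1")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        sentences = [list(s) for s in X]
        if not sentences or all(not s for s in sentences):
            raise ValueError("corpus is empty")
        counts = Counter(t for s in sentences for t in s)
        vocab_items = sorted(
            ((t, c) for t, c in counts.items() if c >= self.min_count),
            key=lambda tc: (-tc[1], tc[0]),
        )
        if not vocab_items:
            raise ValueError("vocabulary empty after min_count filtering")
        self.index2word_ = [t for t, _ in vocab_items]
        self.vocabulary_ = {t: i for i, t in enumerate(self.index2word_)}
        self.counts_ = np.array([c for _, c in vocab_items], dtype=np.int64)

        rng = np.random.default_rng(self.random_state)
        v, d = len(self.index2word_), self.dim
        w_in = (rng.random((v, d)) - 0.5) / d  # projection vectors
        w_out = np.zeros((v, d))  # output-layer weights

        noise = self.counts_.astype(float) ** 0.75
        noise_cdf = np.cumsum(noise / noise.sum())

        encoded = [
            np.array([self.vocabulary_[t] for t in s if t in self.vocabulary_], dtype=np.int64)
            for s in sentences
        ]
        encoded = [s for s in encoded if len(s) >= 2]
        if not encoded:
            raise ValueError("no sentence has two in-vocabulary tokens")

        lr, c, k = self.learning_rate, self.window, self.negative
        for _ in range(self.epochs):
            order = rng.permutation(len(encoded))
            # one batch of negative draws per epoch keeps the rng stream cheap
            for si in order:
                sent = encoded[si]
                n = len(sent)
                negs = np.searchsorted(noise_cdf, rng.random((n, k)))
                for t in range(n):
                    lo, hi = max(0, t - c), min(n, t + c + 1)
                    ctx = np.concatenate([sent[lo:t], sent[t + 1 : hi]])
                    if ctx.size == 0:
                        continue
                    h = w_in[ctx].mean(axis=0)
                    targets = np.concatenate(([sent[t]], negs[t]))
                    labels = np.zeros(targets.size)
                    labels[0] = 1.0
                    # drop negative draws that collide with the centre word
                    keep = np.ones(targets.size, dtype=bool)
                    keep[1:] = targets[1:] != sent[t]
                    targets, labels = targets[keep], labels[keep]
                    out = w_out[targets]
                    g = lr * (labels - _sigmoid(out @ h))
                    grad_h = g @ out
                    w_out[targets] += np.outer(g, h)
                    w_in[ctx] += grad_h / ctx.size
        self.vectors_ = w_in
        self.syn1_ = w_out
        return self

    # -------------------------------------------------------------- queries
    def _check_fitted(self) -> None:
        if not hasattr(self, "vectors_"):
            raise RuntimeError("CbowEmbedding is not fitted")

    def word_vector(self, token: str) -> np.ndarray | None:
        self._check_fitted()
        idx = self.vocabulary_.get(token)
        return None if idx is None else self.vectors_[idx]

    def word_similarity(self, a: str, b: str) -> float:
        """Cosine similarity of two in-vocabulary tokens (raises otherwise)."""
        va, vb = self.word_vector(a), self.word_vector(b)
        if va is None or vb is None:
            raise KeyError("token out of vocabulary")
        return float(va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb)))

    def phrase_vector(self, phrase: str) -> np.ndarray | None:
        """Mean of in-vocabulary token vectors; None if all tokens are OOV."""
        self._check_fitted()
        rows = [
            self.vectors_[self.vocabulary_[t]]
            for t in tokenize(phrase)
            if t in self.vocabulary_
        ]
        if not rows:
            return None
        return np.mean(rows, axis=0)

    def phrase_similarity(self, a: str, b: str) -> tuple[float, bool]:
        """``(max(0, cosine), oov_flag)`` of the two phrase vectors.

        The flag is set (and the score is 0) when either phrase has no
        in-vocabulary token.
        """
        va, vb = self.phrase_vector(a), self.phrase_vector(b)
        if va is None or vb is None:
            return 0.0, True
        denom = float(np.linalg.norm(va) * np.linalg.norm(vb))
        if denom == 0.0:
            return 0.0, False
        return min(1.0, max(0.0, float(va @ vb) / denom)), False

    def transform(self, phrases: Sequence[str]) -> np.ndarray:
        """Phrase vectors as a (n, dim) matrix; all-OOV rows are zero."""
        self._check_fitted()
        out = np.zeros((len(phrases), self.dim))
        for i, p in enumerate(phrases):
            v = self.phrase_vector(p)
            if v is not None:
                out[i] = v
        return out

    # ---------------------------------------------------------- persistence
    def save(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "params": self.get_params(),
            "vocab": [
                [t, int(c)] for t, c in zip(self.index2word_, self.counts_.tolist())
            ],
            "vectors": [[float(x) for x in row] for row in self.vectors_],
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CbowEmbedding":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        model = cls(**payload["params"])
        model.index2word_ = [t for t, _ in payload["vocab"]]
        model.vocabulary_ = {t: i for i, t in enumerate(model.index2word_)}
        model.counts_ = np.array([c for _, c in payload["vocab"]], dtype=np.int64)
        model.vectors_ = np.array(payload["vectors"], dtype=float)
        return model


def train_cbow(corpus: Iterable[Sequence[str]], **config) -> CbowEmbedding:
    """Convenience wrapper: ``CbowEmbedding(**config).fit(corpus)``."""
    return CbowEmbedding(**config).fit(corpus)
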