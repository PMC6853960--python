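"""Heterogeneous skip-gram embeddings trained with typed negative sampling.

Walk corpora are turned into (center, context) pairs by a sliding window;
the context likelihood is stratified by node type, so each observed pair is
contrasted against M noise nodes drawn from a *type-specific* unigram
distribution (counts raised to a sub-unit exponent, word2vec-style).  For a
pair (v, c) of context type f with negatives u_1..u_M the per-pair
objective is

    O = log sigma(x_c . x_v) + sum_m log sigma(-x_{u_m} . x_v)

maximized by stochastic gradient ascent: every target node u in
{c, u_1..u_M} with indicator I[u = c] receives

    x_u += lr * (I - sigma(x_u . x_v)) * x_v

and the center accumulates the matching sum over targets.  One shared
embedding table is used for centers and contexts.  Logits are clamped to
+-logit_max before the sigmoid so the updates stay finite.

The inner loop is a scalar kernel compiled with numba when available (a
numpy per-pair fallback keeps the module importable without it).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
from scipy.special import expit

from .graph_io import NodeType
from .walker import WalkCorpus

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False


@dataclass(frozen=True)
class SkipgramConfig:
    """Training hyperparameters.

    dimension
        Embedding width (default 128, the customary size for skip-gram
        node embeddings).
    window
        Context radius in walk positions (default 5 each side).
    negatives
        Noise nodes M per observed pair (default 5).
    epochs
        Passes over the pair stream.
    learning_rate / min_learning_rate
        Initial step size, decayed linearly over all updates down to the
        floor.
    noise_exponent
        Exponent applied to typed unigram counts for the noise
        distribution; must lie in (0, 1].  0.75 is the word2vec default.
    logit_max
        Clamp on |x_u . x_v| inside the sigmoid.
    """

    dimension: int = 128
    window: int = 5
    negatives: int = 5
    epochs: int = 5
    learning_rate: float = 0.025
    min_learning_rate: float = 1e-4
    noise_exponent: float = 0.75
    logit_max: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dimension <= 0:
            raise ValueError("dimension must be positive")
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.negatives <= 0:
            raise ValueError("negatives must be positive")
        if self.epochs < 0:
            raise ValueError("epochs must be non-negative")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if not (0.0 < self.noise_exponent <= 1.0):
            raise ValueError("noise_exponent must be in (0, 1]")


@dataclass
class EmbeddingMatrix:
    """Dense node embeddings with per-type vocabularies."""

    ids: list[str]
    vectors: np.ndarray
    node_types: dict[str, NodeType] | None = None
    index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        if self.vectors.ndim != 2 or self.vectors.shape[0] != len(self.ids):
            raise ValueError("vectors must be (n_ids, dimension)")
        if not np.isfinite(self.vectors).all():
            raise ValueError("embedding contains non-finite entries")
        self.index = {n: i for i, n in enumerate(self.ids)}
        if len(self.index) != len(self.ids):
            raise ValueError("duplicate node IDs in embedding")

    @property
    def dimension(self) -> int:
        return self.vectors.shape[1]

    def __contains__(self, node: str) -> bool:
        return node in self.index

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, node: str) -> np.ndarray | None:
        i = self.index.get(node)
        return None if i is None else self.vectors[i]

    def type_vocab(self) -> dict[NodeType, list[str]]:
        if self.node_types is None:
            raise ValueError("embedding carries no node-type information")
        vocab: dict[NodeType, list[str]] = {}
        for n in self.ids:
            vocab.setdefault(self.node_types[n], []).append(n)
        return {t: sorted(v) for t, v in vocab.items()}

    def ids_of_type(self, node_type: NodeType) -> list[str]:
        return self.type_vocab().get(node_type, [])

    def to_tsv(self, path: str | Path) -> None:
        """TSV: header ``#dim=<d>``, then node-ID plus d float columns."""
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"#dim={self.dimension}\n")
            for n in self.ids:
                vec = self.vectors[self.index[n]]
                fh.write(n + "\t" + "\t".join(repr(float(x)) for x in vec) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EmbeddingMatrix":
        ids: list[str] = []
        rows: list[list[float]] = []
        dim = None
        with open(path, encoding="utf-8") as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("#dim="):
                        dim = int(line[5:])
                    continue
                cols = line.split("\t")
                ids.append(cols[0])
                rows.append([float(x) for x in cols[1:]])
        vectors = np.array(rows, dtype=np.float64)
        if dim is not None and vectors.size and vectors.shape[1] != dim:
            raise ValueError(f"{path}: header dim {dim} != row width {vectors.shape[1]}")
        return cls(ids, vectors)


# ---------------------------------------------------------------------------
# context extraction


def extract_contexts(
    corpus: WalkCorpus, window: int
) -> Iterator[tuple[str, str, NodeType]]:
    """Yield (center, context, context_type) pairs from walk windows.

    Every node within ``window`` positions of the center (both sides)
    contributes one pair; the context's type follows from its position in
    the meta-path's cyclic pattern.  Walks shorter than the window simply
    yield their in-bounds pairs.
    """
    if window <= 0:
        raise ValueError("window must be positive")
    mp = corpus.metapath
    for w in corpus.walks:
        length = len(w)
        for i in range(length):
            lo = max(0, i - window)
            hi = min(length, i + window + 1)
            for j in range(lo, hi):
                if j != i:
                    yield w[i], w[j], mp.type_at(j)


# ---------------------------------------------------------------------------
# noise distribution / negative sampling


class NoiseDistribution:
    """Typed noise distribution: P_f(u) proportional to count(u)^exponent.

    One cumulative table per node type; sampling is inverse-CDF on a
    uniform draw, restricted to the context node's type.
    """

    def __init__(
        self,
        type_vocab: Mapping[NodeType, Sequence[str]],
        counts: Mapping[str, int],
        exponent: float = 0.75,
    ) -> None:
        if not (0.0 < exponent <= 1.0):
            raise ValueError("noise exponent must be in (0, 1]")
        self.exponent = exponent
        self._ids: dict[NodeType, list[str]] = {}
        self._cdf: dict[NodeType, np.ndarray] = {}
        for t, vocab in type_vocab.items():
            ids = sorted(vocab)
            if not ids:
                continue
            w = np.array(
                [float(counts.get(n, 0)) ** exponent for n in ids], dtype=np.float64
            )
            total = w.sum()
            if total <= 0:  # no observed counts: uniform
                w = np.ones(len(ids))
                total = w.sum()
            self._ids[t] = ids
            self._cdf[t] = np.cumsum(w / total)

    def ids(self, node_type: NodeType) -> list[str]:
        return self._ids.get(node_type, [])

    def sample(
        self, node_type: NodeType, rng: np.random.Generator, size: int | None = None
    ):
        """Draw node IDs of ``node_type``; scalar when ``size`` is None."""
        if node_type not in self._ids:
            raise ValueError(f"empty vocabulary for type {node_type.value!r}")
        cdf = self._cdf[node_type]
        ids = self._ids[node_type]
        r = rng.random(size if size is not None else 1)
        idx = np.minimum(np.searchsorted(cdf, r, side="right"), len(ids) - 1)
        picks = [ids[i] for i in idx]
        return picks[0] if size is None else picks


def negative_sample(
    type_vocab: Mapping[NodeType, Sequence[str]],
    context_type: NodeType,
    counts: Mapping[str, int],
    config: SkipgramConfig,
    rng: np.random.Generator,
) -> str:
    """Draw one noise node of the context's type (convenience wrapper)."""
    dist = NoiseDistribution(type_vocab, counts, config.noise_exponent)
    return dist.sample(context_type, rng)


# ---------------------------------------------------------------------------
# per-pair objective / gradients (reference path, used by tests and sgd_step)


def _clamped_logit(x: float, logit_max: float) -> float:
    return max(-logit_max, min(logit_max, x))


def pair_objective(
    W: np.ndarray,
    center: int,
    context: int,
    negatives: Sequence[int],
    logit_max: float = 6.0,
) -> float:
    """Negative-sampling objective O for one (center, context) pair."""
    v = W[center]
    o = math.log(expit(_clamped_logit(float(W[context] @ v), logit_max)))
    for u in negatives:
        o += math.log(expit(-_clamped_logit(float(W[u] @ v), logit_max)))
    return o


def pair_gradients(
    W: np.ndarray,
    center: int,
    context: int,
    negatives: Sequence[int],
    logit_max: float = 6.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Analytic gradients of O.

    Returns ``(grad_center, targets, grad_targets)`` where ``targets`` is
    the int array [context, *negatives] and row m of ``grad_targets`` is
    dO/dx_{targets[m]} ignoring any second role the same row may play
    (duplicates are accumulated by the caller).  For target u with
    indicator I: dO/dx_u = (I - sigma(x_u . x_v)) x_v, and
    dO/dx_v = sum_u (I - sigma(x_u . x_v)) x_u.
    """
    v = W[center]
    targets = np.array([context, *negatives], dtype=np.int64)
    labels = np.zeros(len(targets))
    labels[0] = 1.0
    grad_v = np.zeros_like(v)
    grad_t = np.zeros((len(targets), W.shape[1]))
    for m, (u, label) in enumerate(zip(targets, labels)):
        g = label - expit(_clamped_logit(float(W[u] @ v), logit_max))
        grad_t[m] = g * v
        grad_v += g * W[u]
    return grad_v, targets, grad_t


def sgd_step(
    W: np.ndarray,
    center: int,
    context: int,
    negatives: Sequence[int],
    learning_rate: float,
    logit_max: float = 6.0,
) -> np.ndarray:
    """One in-place stochastic gradient-ascent update on ``W``.

    All gradients are computed from the pre-update vectors, then applied;
    a negative drawn equal to the context simply contributes its own
    (label 0) term.
    """
    grad_v, targets, grad_t = pair_gradients(W, center, context, negatives, logit_max)
    np.add.at(W, targets, learning_rate * grad_t)
    W[center] += learning_rate * grad_v
    return W


# ---------------------------------------------------------------------------
# training kernel


def _epoch_kernel_py(W, centers, contexts, negatives, t0, total, lr0, lr_min, logit_max):
    n_pairs, n_neg = negatives.shape
    d = W.shape[1]
    gv = np.zeros(d)
    for i in range(n_pairs):
        lr = lr0 * (1.0 - (t0 + i) / total)
        if lr < lr_min:
            lr = lr_min
        v = centers[i]
        for k in range(d):
            gv[k] = 0.0
        for m in range(n_neg + 1):
            if m == 0:
                u = contexts[i]
                label = 1.0
            else:
                u = negatives[i, m - 1]
                label = 0.0
            x = 0.0
            for k in range(d):
                x += W[u, k] * W[v, k]
            if x > logit_max:
                x = logit_max
            elif x < -logit_max:
                x = -logit_max
            g = label - 1.0 / (1.0 + math.exp(-x))
            for k in range(d):
                gv[k] += g * W[u, k]
                W[u, k] += lr * g * W[v, k]
        for k in range(d):
            W[v, k] += lr * gv[k]


if _HAVE_NUMBA:
    _epoch_kernel = njit(cache=False)(_epoch_kernel_py)
else:  # pragma: no cover
    _epoch_kernel = _epoch_kernel_py


# ---------------------------------------------------------------------------
# training


def _pairs_as_arrays(
    corpus: WalkCorpus, window: int, index: dict[str, int]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized window enumeration -> (centers, contexts, context positions)."""
    mp = corpus.metapath
    centers: list[np.ndarray] = []
    contexts: list[np.ndarray] = []
    ctx_pos: list[np.ndarray] = []
    for w in corpus.walks:
        a = np.fromiter((index[n] for n in w), count=len(w), dtype=np.int64)
        pos = np.arange(len(w), dtype=np.int64)
        for off in range(1, window + 1):
            if off >= len(w):
                break
            # context precedes center ...
            centers.append(a[off:])
            contexts.append(a[:-off])
            ctx_pos.append(pos[:-off])
            # ... and context follows center
            centers.append(a[:-off])
            contexts.append(a[off:])
            ctx_pos.append(pos[off:])
    if not centers:
        return (
            np.empty(0, np.int64),
            np.empty(0, np.int64),
            np.empty(0, np.int64),
        )
    return (
        np.concatenate(centers),
        np.concatenate(contexts),
        np.concatenate(ctx_pos) % mp.period,
    )


def train(corpus: WalkCorpus, config: SkipgramConfig) -> EmbeddingMatrix:
    """Train embeddings on one walk corpus.

    Deterministic given ``config.seed``: vocabulary order, initialization,
    per-epoch pair shuffling and negative draws all flow from one seeded
    generator.  ``epochs=0`` returns the initialization unchanged.
    """
    if not corpus.walks:
        raise ValueError("empty corpus")
    mp = corpus.metapath

    counts: Counter[str] = Counter()
    node_types: dict[str, NodeType] = {}
    for w in corpus.walks:
        counts.update(w)
        for i, n in enumerate(w):
            t = mp.type_at(i)
            prev = node_types.setdefault(n, t)
            if prev is not t:
                raise ValueError(
                    f"node {n!r} appears at positions of two types "
                    f"({prev.value}, {t.value}); corpus is inconsistent"
                )

    ids = sorted(counts)
    index = {n: i for i, n in enumerate(ids)}
    n_nodes, d = len(ids), config.dimension

    rng = np.random.default_rng(config.seed)
    W = (rng.random((n_nodes, d)) - 0.5) / d

    if config.epochs == 0:
        return EmbeddingMatrix(ids, W, node_types)

    centers, contexts, ctx_pos = _pairs_as_arrays(corpus, config.window, index)
    n_pairs = len(centers)
    if n_pairs == 0:
        return EmbeddingMatrix(ids, W, node_types)

    # map each meta-path position class to its typed vocabulary (row ids + CDF)
    pos_types = [mp.type_at(p) for p in range(mp.period)]
    type_rows: dict[NodeType, np.ndarray] = {}
    type_cdf: dict[NodeType, np.ndarray] = {}
    for t in set(pos_types):
        rows = np.array([index[n] for n in ids if node_types[n] is t], dtype=np.int64)
        w = np.array(
            [counts[ids[r]] ** config.noise_exponent for r in rows], dtype=np.float64
        )
        type_rows[t] = rows
        type_cdf[t] = np.cumsum(w / w.sum())

    total = config.epochs * n_pairs
    M = config.negatives
    t0 = 0
    for _ in range(config.epochs):
        perm = rng.permutation(n_pairs)
        c = centers[perm]
        x = contexts[perm]
        p = ctx_pos[perm]
        negs = np.empty((n_pairs, M), dtype=np.int64)
        for pos in range(mp.period):
            mask = p == pos
            k = int(mask.sum())
            if k == 0:
                continue
            t = pos_types[pos]
            rows, cdf = type_rows[t], type_cdf[t]
            draw = rows[
                np.minimum(
                    np.searchsorted(cdf, rng.random((k, M)), side="right"),
                    len(rows) - 1,
                )
            ]
            # a negative equal to its own context is redrawn once, then kept
            clash = draw == x[mask][:, None]
            n_clash = int(clash.sum())
            if n_clash:
                redraw = rows[
                    np.minimum(
                        np.searchsorted(cdf, rng.random(n_clash), side="right"),
                        len(rows) - 1,
                    )
                ]
                draw[clash] = redraw
            negs[mask] = draw
        _epoch_kernel(
            W,
            c,
            x,
            negs,
            t0,
            total,
            config.learning_rate,
            config.min_learning_rate,
            config.logit_max,
        )
        t0 += n_pairs

    if not np.isfinite(W).all():  # defensive; clamp should prevent this
        raise FloatingPointError("training produced non-finite embeddings")
    return EmbeddingMatrix(ids, W, node_types)


def mean_objective(
    emb_or_W,
    pairs: Sequence[tuple[int, int]],
    negatives: Sequence[Sequence[int]],
    logit_max: float = 6.0,
) -> float:
    """Mean per-pair objective O over a fixed evaluation sample."""
    W = emb_or_W.vectors if isinstance(emb_or_W, EmbeddingMatrix) else emb_or_W
    vals = [
        pair_objective(W, v, c, negs, logit_max)
        for (v, c), negs in zip(pairs, negatives)
    ]
    return float(np.mean(vals))
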