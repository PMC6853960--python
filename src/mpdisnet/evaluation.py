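"""Scoring predicted disease–disease similarities against labeled pairs.

AUROC is computed with the tie-corrected Mann–Whitney rank statistic (the
probability that a random positive outscores a random negative, ties
counting one half); ROC points come from scikit-learn and agree with the
rank statistic by construction.  AUPR is the non-interpolated step
estimator (average precision).  The negative class is never invented
silently: callers either supply labeled negatives or ask
:func:`sample_negative_pairs` for a seeded 1:1 draw and keep the seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.manifold import TSNE
from sklearn.metrics import average_precision_score, precision_recall_curve, roc_curve

from .skipgram import EmbeddingMatrix
from .graph_io import NodeType

logger = logging.getLogger(__name__)

LABEL_COLUMNS = ["disease_a", "disease_b", "label"]

_POSITIVE = {"1", "positive", "pos", "true"}
_NEGATIVE = {"0", "negative", "neg", "false"}


def read_labels(path: str | Path) -> pd.DataFrame:
    """Read a (disease_a, disease_b, label) TSV; labels may be 0/1 or
    positive/negative words."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, names=LABEL_COLUMNS, header=None
    )
    if list(df.iloc[0]) == LABEL_COLUMNS:  # header row present
        df = df.iloc[1:].reset_index(drop=True)

    def parse(x: str) -> int:
        s = str(x).strip().lower()
        if s in _POSITIVE:
            return 1
        if s in _NEGATIVE:
            return 0
        raise ValueError(f"unparseable label {x!r}")

    df["label"] = df["label"].map(parse)
    return df


def _canonical(df: pd.DataFrame) -> pd.DataFrame:
    a = df["disease_a"].astype(str)
    b = df["disease_b"].astype(str)
    swap = a > b
    out = df.copy()
    out["disease_a"] = a.where(~swap, b)
    out["disease_b"] = b.where(~swap, a)
    return out


@dataclass
class CurveResult:
    """ROC/PR summary for one similarity table against one label set."""

    auroc: float
    aupr: float
    fpr: np.ndarray
    tpr: np.ndarray
    roc_thresholds: np.ndarray
    precision: np.ndarray
    recall: np.ndarray
    n_pos: int
    n_neg: int
    n_dropped: int = 0
    aupr_estimator: str = "step"

    def to_json(self, path: str | Path, extra: Mapping | None = None) -> None:
        payload = {
            "auroc": self.auroc,
            "aupr": self.aupr,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
            "n_dropped": self.n_dropped,
            "aupr_estimator": self.aupr_estimator,
        }
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2) + "\n", encoding="utf-8")

    def roc_points(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"fpr": self.fpr, "tpr": self.tpr, "threshold": self.roc_thresholds}
        )

    def pr_points(self) -> pd.DataFrame:
        return pd.DataFrame({"recall": self.recall, "precision": self.precision})


def rank_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Tie-corrected Mann–Whitney AUROC."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(labels.sum())
    n_neg = int(len(labels) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes are required to compute AUROC")
    ranks = rankdata(scores)
    r_pos = ranks[labels == 1].sum()
    return float((r_pos - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def evaluate(sims: pd.DataFrame, labels: pd.DataFrame) -> CurveResult:
    """Score a similarity table against labeled disease pairs.

    Labeled pairs naming a disease absent from the similarity table's
    universe are dropped (count logged and reported); known pairs missing
    a score fall back to 0, the similarity module's missing-signal value.
    """
    sims = _canonical(sims)
    labels = _canonical(labels)
    universe = set(sims["disease_a"]) | set(sims["disease_b"])
    known = labels["disease_a"].isin(universe) & labels["disease_b"].isin(universe)
    n_dropped = int((~known).sum())
    if n_dropped:
        logger.info("dropping %d labeled pair(s) with unknown diseases", n_dropped)
    labels = labels[known]
    if labels.empty:
        raise ValueError("no labeled pair references known diseases")

    score_map = {
        (a, b): s
        for a, b, s in zip(sims["disease_a"], sims["disease_b"], sims["score"])
    }
    scores = np.array(
        [
            score_map.get((a, b), 0.0)
            for a, b in zip(labels["disease_a"], labels["disease_b"])
        ],
        dtype=np.float64,
    )
    y = labels["label"].to_numpy(dtype=np.int64)
    if len(np.unique(y)) < 2:
        raise ValueError("label set contains a single class; AUROC/AUPR undefined")

    auroc = rank_auroc(scores, y)
    fpr, tpr, thr = roc_curve(y, scores)
    precision, recall, _ = precision_recall_curve(y, scores)
    aupr = float(average_precision_score(y, scores))
    return CurveResult(
        auroc=auroc,
        aupr=aupr,
        fpr=fpr,
        tpr=tpr,
        roc_thresholds=thr,
        precision=precision,
        recall=recall,
        n_pos=int(y.sum()),
        n_neg=int(len(y) - y.sum()),
        n_dropped=n_dropped,
    )


def sample_negative_pairs(
    diseases: Sequence[str],
    positive_pairs: Iterable[tuple[str, str]],
    n: int | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Seeded draw of non-positive disease pairs, labeled 0.

    ``n`` defaults to the number of positives (1:1 matching).  The draw is
    without replacement from the sorted complement, so it is deterministic
    given the seed; if fewer non-positive pairs exist than requested, all
    of them are returned.
    """
    diseases = sorted(set(diseases))
    pos = {tuple(sorted(p)) for p in positive_pairs}
    candidates = [p for p in combinations(diseases, 2) if p not in pos]
    if n is None:
        n = len(pos)
    rng = np.random.default_rng(seed)
    take = min(n, len(candidates))
    idx = rng.choice(len(candidates), size=take, replace=False)
    chosen = sorted(candidates[i] for i in idx)
    return pd.DataFrame(
        [(a, b, 0) for a, b in chosen], columns=LABEL_COLUMNS
    )


def export_network(
    pairs: pd.DataFrame,
    gexf_path: str | Path | None = None,
    tsv_path: str | Path | None = None,
    annotations: Mapping[str, str] | None = None,
) -> nx.Graph:
    """Write a top-k disease–disease network as GEXF (Gephi) and/or TSV.

    Edge weight is the similarity score; the optional ``annotations`` map
    attaches a ``category`` attribute to each disease node.
    """
    g = nx.Graph()
    for a, b, s in zip(pairs["disease_a"], pairs["disease_b"], pairs["score"]):
        g.add_edge(str(a), str(b), weight=float(s))
    if annotations:
        for node in g.nodes:
            if node in annotations:
                g.nodes[node]["category"] = annotations[node]
    if gexf_path is not None:
        nx.write_gexf(g, gexf_path)
    if tsv_path is not None:
        pairs.loc[:, ["disease_a", "disease_b", "score"]].to_csv(
            tsv_path, sep="\t", index=False
        )
    return g


def project_2d(
    emb: EmbeddingMatrix,
    node_ids: Sequence[str] | None = None,
    seed: int = 0,
    perplexity: float | None = None,
) -> pd.DataFrame:
    """Seeded t-SNE layout of (by default) the disease vectors.

    Visualization plumbing only — the coordinates carry no quantitative
    claim.  Fewer than 3 points is an error.
    """
    if node_ids is None:
        if emb.node_types is not None:
            node_ids = emb.ids_of_type(NodeType.DISEASE) or list(emb.ids)
        else:
            node_ids = list(emb.ids)
    node_ids = [n for n in node_ids if n in emb]
    n = len(node_ids)
    if n < 3:
        raise ValueError(f"t-SNE needs at least 3 points, got {n}")
    X = np.stack([emb.get(nid) for nid in node_ids])
    if perplexity is None:
        perplexity = min(30.0, max(1.0, (n - 1) / 3.0))
    tsne = TSNE(
        n_components=2,
        random_state=seed,
        init="pca",
        perplexity=perplexity,
        max_iter=500,
    )
    coords = tsne.fit_transform(X)
    return pd.DataFrame(
        {"node": node_ids, "x": coords[:, 0], "y": coords[:, 1]}
    )
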