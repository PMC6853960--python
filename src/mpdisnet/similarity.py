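"""Disease–disease similarity: embedding cosine and the miRNA-overlap baseline.

Similarities live in a tidy table of unordered disease pairs
(``disease_a < disease_b`` lexicographically) with a score, a method label
and the meta-path provenance.  Multiple meta-path embeddings are fused by
plain vector concatenation before the cosine; a disease missing from one
meta-path's embedding contributes a zero block of that block's width,
which keeps it rankable without inventing signal.
"""

from __future__ import annotations

from itertools import combinations
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph_io import HeteroNetwork, NodeType
from .skipgram import EmbeddingMatrix

PAIR_COLUMNS = ["disease_a", "disease_b", "score", "method", "metapaths"]


def overlap_similarity(a_mirnas: Iterable[str], b_mirnas: Iterable[str]) -> float:
    """Jaccard index of two diseases' miRNA sets: |A∩B| / |A∪B|.

    Two empty sets score 0 (absence of evidence, not identity).
    """
    a, b = set(a_mirnas), set(b_mirnas)
    union = a | b
    if not union:
        return 0.0
    return len(a & b) / len(union)


def cosine_similarity(x: Sequence[float], y: Sequence[float]) -> float:
    """Cosine of two equal-length vectors; either zero vector scores 0."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape:
        raise ValueError(f"dimension mismatch: {x.shape} vs {y.shape}")
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0.0 or ny == 0.0:
        return 0.0
    return float(x @ y / (nx * ny))


def concatenate_embeddings(
    matrices: Sequence[EmbeddingMatrix],
    node_ids: Sequence[str] | None = None,
) -> EmbeddingMatrix:
    """Concatenate per-meta-path embeddings in the given order.

    ``node_ids`` restricts/augments the output rows (default: union of all
    input vocabularies, sorted).  A node absent from one matrix gets a
    zero block of that matrix's dimension; output dimension is the sum of
    input dimensions.
    """
    if not matrices:
        raise ValueError("need at least one embedding matrix")
    if node_ids is None:
        universe: set[str] = set()
        for m in matrices:
            universe.update(m.ids)
        node_ids = sorted(universe)
    dims = [m.dimension for m in matrices]
    out = np.zeros((len(node_ids), sum(dims)), dtype=np.float64)
    offset = 0
    for m, d in zip(matrices, dims):
        for i, n in enumerate(node_ids):
            vec = m.get(n)
            if vec is not None:
                out[i, offset : offset + d] = vec
        offset += d
    node_types = None
    typed = [m.node_types for m in matrices if m.node_types is not None]
    if typed:
        node_types = {}
        for t in typed:
            node_types.update(t)
        node_types = {n: node_types[n] for n in node_ids if n in node_types}
        if len(node_types) != len(node_ids):
            node_types = None  # incomplete typing: drop rather than guess
    return EmbeddingMatrix(list(node_ids), out, node_types)


def _canonical_pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


def cosine_table(
    emb: EmbeddingMatrix,
    diseases: Sequence[str] | None = None,
    metapaths: str = "",
) -> pd.DataFrame:
    """All unordered disease-pair cosine similarities from an embedding.

    ``diseases`` defaults to the embedding's disease-typed vocabulary.
    """
    if diseases is None:
        if emb.node_types is None:
            raise ValueError("embedding has no types; pass `diseases` explicitly")
        diseases = emb.ids_of_type(NodeType.DISEASE)
    diseases = sorted(set(diseases))
    if len(diseases) < 2:
        raise ValueError("need at least two diseases to score pairs")
    X = np.zeros((len(diseases), emb.dimension))
    for i, d in enumerate(diseases):
        vec = emb.get(d)
        if vec is not None:
            X[i] = vec
    norms = np.linalg.norm(X, axis=1)
    safe = np.where(norms == 0.0, 1.0, norms)
    S = (X / safe[:, None]) @ (X / safe[:, None]).T
    rows = []
    for i, j in combinations(range(len(diseases)), 2):
        score = 0.0 if (norms[i] == 0.0 or norms[j] == 0.0) else float(S[i, j])
        rows.append((diseases[i], diseases[j], score, "cosine", metapaths))
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def overlap_table(
    network: HeteroNetwork, diseases: Sequence[str] | None = None
) -> pd.DataFrame:
    """miRNA-overlap (Jaccard) similarity for all unordered disease pairs."""
    if diseases is None:
        diseases = network.nodes_of_type(NodeType.DISEASE)
    diseases = sorted(set(diseases))
    if len(diseases) < 2:
        raise ValueError("need at least two diseases to score pairs")
    mirna_sets = {d: set(network.neighbors(d, NodeType.MIRNA)) for d in diseases}
    rows = [
        (a, b, overlap_similarity(mirna_sets[a], mirna_sets[b]), "overlap", "")
        for a, b in combinations(diseases, 2)
    ]
    return pd.DataFrame(rows, columns=PAIR_COLUMNS)


def rank_pairs(table: pd.DataFrame, k: int | None = None) -> pd.DataFrame:
    """Top-``k`` pairs, descending by score, ties broken lexicographically
    by (disease_a, disease_b). Deterministic."""
    if k is None:
        k = len(table)
    if k > len(table):
        raise ValueError(f"k={k} exceeds the {len(table)} available pairs")
    out = table.sort_values(
        ["score", "disease_a", "disease_b"],
        ascending=[False, True, True],
        kind="mergesort",
    ).head(k)
    return out.reset_index(drop=True)


def write_similarity_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_similarity_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"disease_a": str, "disease_b": str})
    missing = [c for c in ("disease_a", "disease_b", "score") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if "metapaths" in df.columns:
        df["metapaths"] = df["metapaths"].fillna("")
    return df
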