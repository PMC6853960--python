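"""Synthetic heterogeneous networks with planted comorbidity structure.

The generator emulates the *structure* of the real four-layer data —
diseases, miRNAs and genes wired through disease–miRNA, miRNA–gene,
disease–gene and PPI (gene–gene) layers — at desk scale, not its size or
degree distributions.  Diseases are grouped into clusters; each cluster
owns a private pool of genes and (depending on the signal channel) of
miRNAs, and within-cluster attachment probabilities exceed cross-cluster
ones (a planted-partition design).  Same-cluster disease pairs are the
planted positives.

Channels
--------
``mirna-mediated``
    Same-cluster diseases share a cluster-private miRNA pool; the
    disease–gene layer is unclustered background.  Both the miRNA-overlap
    baseline and walk embeddings can recover the clusters.
``gene-mediated``
    Every disease gets its own *private* miRNAs (no two diseases ever
    share one, so the overlap baseline is uniformly zero), but those
    miRNAs target the cluster's gene pool and the disease–gene layer is
    clustered.  Only methods that walk through the gene layer can recover
    the clusters — the comparative setting the embedding approach is
    built for.
``both``
    Clustered attachment in both layers.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .evaluation import LABEL_COLUMNS
from .graph_io import HeteroNetwork, NodeType, TypedEdge, build_network, read_edge_list

CHANNELS = ("mirna-mediated", "gene-mediated", "both")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the planted-partition generator.

    Probabilities are per-potential-edge Bernoulli rates; ``within``
    applies to disease/miRNA/gene entities of the same cluster, ``cross``
    otherwise.  Defaults give a small two-cluster benchmark whose planted
    structure is recoverable in seconds.
    """

    n_disease_clusters: int = 2
    diseases_per_cluster: int = 5
    n_mirnas: int = 40
    n_genes: int = 60
    p_disease_mirna_within: float = 0.8
    p_disease_mirna_cross: float = 0.02
    p_mirna_gene_within: float = 0.5
    p_mirna_gene_cross: float = 0.02
    p_disease_gene_within: float = 0.6
    p_disease_gene_cross: float = 0.02
    ppi_edge_probability: float = 0.3
    ppi_cross_probability: float = 0.02
    channel: str = "both"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "p_disease_mirna_within",
            "p_disease_mirna_cross",
            "p_mirna_gene_within",
            "p_mirna_gene_cross",
            "p_disease_gene_within",
            "p_disease_gene_cross",
            "ppi_edge_probability",
            "ppi_cross_probability",
        ):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name}={p} outside [0, 1]")
        for name in (
            "n_disease_clusters",
            "diseases_per_cluster",
            "n_mirnas",
            "n_genes",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.channel not in CHANNELS:
            raise ValueError(f"channel must be one of {CHANNELS}")


def _bernoulli_edges(rng, left, right, p, layer):
    """Seeded Bernoulli edges between two sorted node lists."""
    if p <= 0.0 or not left or not right:
        return []
    draw = rng.random((len(left), len(right))) < p
    return [
        TypedEdge(left[i], right[j], layer)
        for i, j in zip(*np.nonzero(draw))
    ]


def generate(spec: SyntheticSpec) -> tuple[HeteroNetwork, pd.DataFrame]:
    """Generate (network, labeled pair set) from a :class:`SyntheticSpec`.

    Fully deterministic given ``spec.seed``.  Positives are all
    same-cluster disease pairs; negatives are a seeded 1:1 sample of
    cross-cluster pairs.
    """
    rng = np.random.default_rng(spec.seed)
    K = spec.n_disease_clusters
    diseases = [
        [f"D{c}_{i}" for i in range(spec.diseases_per_cluster)] for c in range(K)
    ]
    all_diseases = [d for cluster in diseases for d in cluster]
    genes = [f"g{j:03d}" for j in range(spec.n_genes)]
    gene_pools = [list(a) for a in np.array_split(genes, K)]
    mirnas = [f"mir{j:03d}" for j in range(spec.n_mirnas)]

    edges: dict[str, list[TypedEdge]] = {
        "disease-mirna": [],
        "mirna-gene": [],
        "disease-gene": [],
        "gene-gene": [],
    }

    # ---- miRNA ownership and the disease-miRNA layer
    mirna_cluster: dict[str, int] = {}
    if spec.channel == "gene-mediated":
        # private per-disease pools: no disease pair ever shares a miRNA
        pools = [list(a) for a in np.array_split(mirnas, len(all_diseases))]
        for d, pool in zip(all_diseases, pools):
            c = all_diseases.index(d) // spec.diseases_per_cluster
            for m in pool:
                mirna_cluster[m] = c
            edges["disease-mirna"].extend(
                _bernoulli_edges(
                    rng, [d], pool, spec.p_disease_mirna_within, "disease-mirna"
                )
            )
    else:
        pools = [list(a) for a in np.array_split(mirnas, K)]
        for c, pool in enumerate(pools):
            for m in pool:
                mirna_cluster[m] = c
        for c in range(K):
            for c2, pool in enumerate(pools):
                p = (
                    spec.p_disease_mirna_within
                    if c2 == c
                    else spec.p_disease_mirna_cross
                )
                edges["disease-mirna"].extend(
                    _bernoulli_edges(rng, diseases[c], pool, p, "disease-mirna")
                )

    # ---- miRNA-gene layer: miRNAs target their cluster's gene pool
    for c2, gene_pool in enumerate(gene_pools):
        own = [m for m in mirnas if mirna_cluster.get(m) == c2]
        other = [m for m in mirnas if mirna_cluster.get(m, c2) != c2]
        edges["mirna-gene"].extend(
            _bernoulli_edges(rng, own, gene_pool, spec.p_mirna_gene_within, "mirna-gene")
        )
        edges["mirna-gene"].extend(
            _bernoulli_edges(
                rng, other, gene_pool, spec.p_mirna_gene_cross, "mirna-gene"
            )
        )

    # ---- disease-gene layer
    clustered_dg = spec.channel in ("gene-mediated", "both")
    for c in range(K):
        for c2, gene_pool in enumerate(gene_pools):
            p = (
                spec.p_disease_gene_within
                if (clustered_dg and c2 == c)
                else spec.p_disease_gene_cross
            )
            edges["disease-gene"].extend(
                _bernoulli_edges(rng, diseases[c], gene_pool, p, "disease-gene")
            )

    # ---- PPI (gene-gene) layer, upper triangle only
    gene_cluster = {g: c for c, pool in enumerate(gene_pools) for g in pool}
    n_g = len(genes)
    draw = rng.random((n_g, n_g))
    for i in range(n_g):
        for j in range(i + 1, n_g):
            p = (
                spec.ppi_edge_probability
                if gene_cluster[genes[i]] == gene_cluster[genes[j]]
                else spec.ppi_cross_probability
            )
            if draw[i, j] < p:
                edges["gene-gene"].append(TypedEdge(genes[i], genes[j], "gene-gene"))

    isolated = (
        [(d, NodeType.DISEASE) for d in all_diseases]
        + [(m, NodeType.MIRNA) for m in mirnas]
        + [(g, NodeType.GENE) for g in genes]
    )
    network = build_network(edges, isolated_nodes=isolated)

    positives = []
    for cluster in diseases:
        for i in range(len(cluster)):
            for j in range(i + 1, len(cluster)):
                a, b = sorted((cluster[i], cluster[j]))
                positives.append((a, b))
    positives.sort()

    cross = []
    for c1 in range(K):
        for c2 in range(c1 + 1, K):
            for a in diseases[c1]:
                for b in diseases[c2]:
                    cross.append(tuple(sorted((a, b))))
    cross.sort()
    neg_rng = np.random.default_rng(spec.seed + 1)
    take = min(len(positives), len(cross))
    idx = sorted(neg_rng.choice(len(cross), size=take, replace=False))
    negatives = [cross[i] for i in idx]

    labels = pd.DataFrame(
        [(a, b, 1) for a, b in positives] + [(a, b, 0) for a, b in negatives],
        columns=LABEL_COLUMNS,
    )
    return network, labels


def write_dataset(
    spec: SyntheticSpec, outdir: str | Path
) -> tuple[HeteroNetwork, pd.DataFrame]:
    """Generate and write the four layer TSVs plus ``labels.tsv``."""
    outdir = Path(outdir)
    network, labels = generate(spec)
    network.write_layers(outdir)
    labels.to_csv(outdir / "labels.tsv", sep="\t", index=False)
    return network, labels


# ---------------------------------------------------------------------------
# packaged desk-scale fixtures

FIXTURE_NAMES = ("chain_m1", "chain_m3", "mirna_star", "dense_toy", "two_cliques")


def load_fixture(name: str) -> HeteroNetwork:
    """Load one of the packaged hand-written fixture networks."""
    if name not in FIXTURE_NAMES:
        raise ValueError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
    root = resources.files("mpdisnet") / "fixtures" / name
    edges = {}
    for entry in sorted(root.iterdir(), key=lambda e: e.name):
        if entry.name.endswith(".tsv"):
            layer = entry.name[: -len(".tsv")]
            with resources.as_file(entry) as path:
                edges[layer] = read_edge_list(path, layer)
    return build_network(edges)


def fixture_suite() -> dict[str, HeteroNetwork]:
    """All packaged fixtures, keyed by name.

    ``chain_m3``: the 4-node D1–g1–g2–D2 chain (unique M3 instance).
    ``chain_m1``: the 6-node chain realizing exactly one M1 instance.
    ``mirna_star``: one disease with three miRNA neighbors (uniform
    transition checks).
    ``dense_toy``: complete inter-type layers, so no walk ever dead-ends.
    ``two_cliques``: 2x5 diseases with cluster-private miRNA and gene
    pools and no cross-cluster edges.
    """
    return {name: load_fixture(name) for name in FIXTURE_NAMES}
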