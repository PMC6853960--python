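"""Mechanistic explanation: concrete meta-path instances between diseases.

Where the walker *samples* paths, this module *enumerates* them: a
deterministic depth-first search lists every concrete node chain that
realizes a meta-path between two named diseases (e.g. every
disease–miRNA–gene–gene–miRNA–disease chain linking lung cancer and
asthma), in lexicographic order, optionally capped.  Enumeration is a
superset of anything walk sampling can discover, which makes the output
reproducible subnetwork evidence rather than a stochastic sketch.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .graph_io import HeteroNetwork, NodeType
from .walker import M1, MetaPath


@dataclass(frozen=True)
class PathInstance:
    """One concrete realization of a meta-path between two diseases."""

    nodes: tuple[str, ...]
    metapath: MetaPath

    @property
    def endpoints(self) -> tuple[str, str]:
        return self.nodes[0], self.nodes[-1]

    def validate(self, network: HeteroNetwork) -> None:
        """Re-check types and adjacency against the network; raises on
        any violation."""
        if len(self.nodes) != len(self.metapath.types):
            raise ValueError("instance length does not match the meta-path")
        for node, t in zip(self.nodes, self.metapath.types):
            if network.node_type(node) is not t:
                raise ValueError(f"node {node!r} is not of type {t.value}")
        for u, v in zip(self.nodes, self.nodes[1:]):
            if not network.has_edge(u, v):
                raise ValueError(f"({u!r}, {v!r}) is not a network edge")


def enumerate_instances(
    network: HeteroNetwork,
    disease_a: str,
    disease_b: str,
    metapath: MetaPath = M1,
    limit: int | None = None,
) -> list[PathInstance]:
    """Exhaustive DFS enumeration of meta-path instances from
    ``disease_a`` to ``disease_b``.

    Order is lexicographic by node sequence (neighbor lists are sorted),
    truncated after ``limit`` instances.  Node revisits within an
    instance are allowed except where adjacency forbids them (no
    self-loops exist, so consecutive nodes are always distinct).  Each
    returned instance is re-validated against the network.
    """
    if metapath.types[0] is not NodeType.DISEASE or metapath.types[-1] is not NodeType.DISEASE:
        raise ValueError(
            f"meta-path {metapath.name!r} does not start and end at disease nodes"
        )
    for d in (disease_a, disease_b):
        if network.node_type(d) is not NodeType.DISEASE:
            raise ValueError(f"{d!r} is not a disease node")
    if limit is not None and limit <= 0:
        return []

    L = len(metapath.types)
    results: list[PathInstance] = []
    path = [disease_a]

    def dfs() -> bool:
        """Returns True when the limit is reached and search must stop."""
        pos = len(path)
        if pos == L:
            inst = PathInstance(tuple(path), metapath)
            inst.validate(network)
            results.append(inst)
            return limit is not None and len(results) >= limit
        want = metapath.types[pos]
        last = pos == L - 1
        for nb in network.neighbors(path[-1], want):
            if last and nb != disease_b:
                continue
            path.append(nb)
            stop = dfs()
            path.pop()
            if stop:
                return True
        return False

    dfs()
    return results


def shared_mirnas(
    network: HeteroNetwork, disease_a: str, disease_b: str
) -> set[str]:
    """miRNAs associated with both diseases (neighbor-set intersection)."""
    a = set(network.neighbors(disease_a, NodeType.MIRNA))
    b = set(network.neighbors(disease_b, NodeType.MIRNA))
    return a & b


def write_instances(
    instances: Iterable[PathInstance], path: str | Path
) -> None:
    """One instance per line: tab-separated node chain, preceded by a
    header naming the meta-path."""
    instances = list(instances)
    with open(path, "w", encoding="utf-8") as fh:
        if instances:
            fh.write(f"# metapath={instances[0].metapath.name}\n")
        for inst in instances:
            fh.write("\t".join(inst.nodes) + "\n")
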