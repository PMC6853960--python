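"""Meta-path-constrained random walks over the heterogeneous network.

A meta-path is an ordered node-type sequence, e.g.
``M1 = disease–miRNA–gene–gene–miRNA–disease``.  A walk starting at a node
of the first type repeatedly traverses the pattern; at each step the next
node is drawn uniformly from the current node's neighbors of the type the
pattern requires (all other neighbors get probability zero).  Symmetric
meta-paths (first type == last type) recurse, so a walk of ``s`` pattern
traversals visits ``s * (L - 1) + 1`` nodes when it never dead-ends — 251
nodes for M1 at 50 traversals.

A walk that reaches a node with no neighbor of the required type is
truncated there and flagged incomplete; truncated walks of length >= 2 are
kept in the corpus (they are still observed context), bare starts are
dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .graph_io import HeteroNetwork, NodeType


@dataclass(frozen=True)
class MetaPath:
    """Ordered node-type sequence constraining each walk step."""

    name: str
    types: tuple[NodeType, ...]

    def __post_init__(self) -> None:
        if len(self.types) < 2:
            raise ValueError("a meta-path needs at least two node types")

    @property
    def symmetric(self) -> bool:
        return self.types[0] is self.types[-1]

    @property
    def period(self) -> int:
        """Steps per pattern traversal (L - 1)."""
        return len(self.types) - 1

    def type_at(self, position: int) -> NodeType:
        """Node type at walk position ``position`` under cyclic repetition."""
        return self.types[position % self.period]

    def expected_length(self, steps_per_walk: int) -> int:
        """Node count of a never-stuck walk: steps * (L - 1) + 1."""
        return steps_per_walk * self.period + 1


_D, _M, _G = NodeType.DISEASE, NodeType.MIRNA, NodeType.GENE

#: The three meta-paths used for disease-disease inference.
M1 = MetaPath("M1", (_D, _M, _G, _G, _M, _D))
M2 = MetaPath("M2", (_D, _M, _G, _G, _G, _M, _D))
M3 = MetaPath("M3", (_D, _G, _G, _D))

BUILTIN_METAPATHS: dict[str, MetaPath] = {"M1": M1, "M2": M2, "M3": M3}


def get_metapath(name: str) -> MetaPath:
    try:
        return BUILTIN_METAPATHS[name.upper()]
    except KeyError:
        raise ValueError(
            f"unknown meta-path {name!r}; built-ins are {sorted(BUILTIN_METAPATHS)}"
        ) from None


@dataclass(frozen=True)
class WalkConfig:
    """Walk generation parameters.

    ``steps_per_walk`` counts full meta-path traversals (50 in the
    reference configuration, giving 251-node M1 walks);
    ``walks_per_node`` is the number of walks attempted from every node of
    the start type (reference: 1000 per disease).
    """

    steps_per_walk: int = 50
    walks_per_node: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps_per_walk < 1:
            raise ValueError("steps_per_walk must be positive")
        if self.walks_per_node < 0:
            raise ValueError("walks_per_node must be non-negative")


@dataclass
class WalkCorpus:
    """Walk sequences generated under one meta-path."""

    walks: list[list[str]]
    completed: list[bool]
    metapath: MetaPath
    steps_per_walk: int

    def __len__(self) -> int:
        return len(self.walks)

    def __iter__(self) -> Iterator[list[str]]:
        return iter(self.walks)

    def walk_counts_by_start(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for w in self.walks:
            counts[w[0]] = counts.get(w[0], 0) + 1
        return counts


def transition_candidates(
    network: HeteroNetwork, current: str, next_type: NodeType
) -> list[str]:
    """Eligible next nodes: the type-``next_type`` neighbors of ``current``.

    Drawing uniformly from the returned list realizes the walk's
    transition law: probability 1/|N| for each eligible neighbor, 0 for
    every other node.  An empty list means the walk is stuck.
    """
    return network.neighbors(current, next_type)


def walk(
    network: HeteroNetwork,
    start: str,
    metapath: MetaPath,
    steps_per_walk: int,
    rng: np.random.Generator,
) -> tuple[list[str], bool]:
    """One meta-path-constrained walk from ``start``.

    Returns the node sequence and a completion flag (False when truncated
    at a dead end).  ``start`` must carry the meta-path's first type, and
    the meta-path must be symmetric so the pattern can recurse.
    """
    if not metapath.symmetric:
        raise ValueError(f"meta-path {metapath.name!r} is not symmetric")
    if network.node_type(start) is not metapath.types[0]:
        raise ValueError(
            f"start node {start!r} has type {network.node_type(start).value}, "
            f"but meta-path {metapath.name!r} starts at {metapath.types[0].value}"
        )
    total_steps = steps_per_walk * metapath.period
    sequence = [start]
    current = start
    for i in range(1, total_steps + 1):
        candidates = transition_candidates(network, current, metapath.type_at(i))
        if not candidates:
            return sequence, False
        current = candidates[int(rng.integers(len(candidates)))]
        sequence.append(current)
    return sequence, True


def generate_corpus(
    network: HeteroNetwork, metapath: MetaPath, config: WalkConfig
) -> WalkCorpus:
    """Attempt ``walks_per_node`` walks from every node of the start type.

    Start nodes are visited in sorted order and one seeded generator is
    consumed in node-then-walk order, so the corpus is deterministic given
    the seed.  Truncated walks shorter than 2 nodes are dropped.
    """
    start_nodes = network.nodes_of_type(metapath.types[0])
    if not start_nodes:
        raise ValueError(
            f"network has no node of start type {metapath.types[0].value!r}"
        )
    rng = np.random.default_rng(config.seed)
    walks: list[list[str]] = []
    completed: list[bool] = []
    for node in start_nodes:
        for _ in range(config.walks_per_node):
            seq, ok = walk(network, node, metapath, config.steps_per_walk, rng)
            if len(seq) >= 2:
                walks.append(seq)
                completed.append(ok)
    return WalkCorpus(walks, completed, metapath, config.steps_per_walk)


def write_corpus(corpus: WalkCorpus, path: str | Path, seed: int | None = None) -> None:
    """One walk per line, space-separated node IDs, with a header comment
    recording the meta-path, its type pattern and steps-per-walk."""
    mp = corpus.metapath
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# metapath={mp.name}\n")
        fh.write(f"# types={','.join(t.value for t in mp.types)}\n")
        fh.write(f"# steps_per_walk={corpus.steps_per_walk}\n")
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        for w in corpus.walks:
            fh.write(" ".join(w) + "\n")


def read_corpus(path: str | Path) -> WalkCorpus:
    """Read a corpus written by :func:`write_corpus`."""
    meta: dict[str, str] = {}
    walks: list[list[str]] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    k, v = body.split("=", 1)
                    meta[k.strip()] = v.strip()
                continue
            walks.append(line.split())
    if "types" not in meta or "steps_per_walk" not in meta:
        raise ValueError(f"{path}: missing corpus header (types/steps_per_walk)")
    types = tuple(NodeType(t) for t in meta["types"].split(","))
    mp = MetaPath(meta.get("metapath", "custom"), types)
    steps = int(meta["steps_per_walk"])
    expected = mp.expected_length(steps)
    completed = [len(w) == expected for w in walks]
    return WalkCorpus(walks, completed, mp, steps)
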