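"""Typed edge-list I/O and assembly of the heterogeneous network.

The network couples four association layers over three node types —
``disease``, ``mirna`` and ``gene`` — where proteins of the interactome are
identified with their coding genes, so protein–protein interactions are
stored as gene–gene edges.  Edges are undirected and unweighted; duplicate
lines (in either orientation) collapse to a single edge, matching the
uniform transition law of the walker.

Node identifiers are opaque strings: no vocabulary normalization is
attempted.  Each identifier must resolve to exactly one node type across
all layers; a violation is a hard error naming the offending node.
"""

from __future__ import annotations

import enum
import logging
from collections.abc import Iterable, Mapping, Sequence
from pathlib import Path
from typing import NamedTuple

logger = logging.getLogger(__name__)


class NodeType(str, enum.Enum):
    """The three node types of the heterogeneous network."""

    DISEASE = "disease"
    MIRNA = "mirna"
    GENE = "gene"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Layer label -> (type of first column, type of second column).
LAYER_TYPES: dict[str, tuple[NodeType, NodeType]] = {
    "disease-mirna": (NodeType.DISEASE, NodeType.MIRNA),
    "mirna-gene": (NodeType.MIRNA, NodeType.GENE),
    "disease-gene": (NodeType.DISEASE, NodeType.GENE),
    "gene-gene": (NodeType.GENE, NodeType.GENE),
}

LAYERS: tuple[str, ...] = tuple(LAYER_TYPES)


def normalize_layer(label: str) -> str:
    """Canonicalize a layer label (en-dash and underscore tolerated)."""
    key = label.strip().lower().replace("–", "-").replace("_", "-")
    if key not in LAYER_TYPES:
        raise ValueError(
            f"unknown layer {label!r}; expected one of {sorted(LAYER_TYPES)}"
        )
    return key


class TypedEdge(NamedTuple):
    """An undirected edge within one layer; orientation is incidental."""

    source: str
    target: str
    layer: str

    @property
    def key(self) -> tuple[str, str, str]:
        """Orientation-free identity used for deduplication."""
        a, b = sorted((self.source, self.target))
        return (self.layer, a, b)


def read_edge_list(path: str | Path, layer: str) -> list[TypedEdge]:
    """Read a two-column tab-separated edge list.

    Lines starting with ``#`` and blank lines are skipped; extra columns
    beyond the first two are ignored.  Undirected duplicates collapse to
    the first-seen orientation.  Self-loops are dropped with a warning.

    Raises
    ------
    ValueError
        On a line with fewer than two non-empty columns (reported with its
        line number).
    """
    layer = normalize_layer(layer)
    edges: list[TypedEdge] = []
    seen: set[tuple[str, str, str]] = set()
    n_self = 0
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            cols = [c.strip() for c in line.split("\t")]
            if len(cols) < 2 or not cols[0] or not cols[1]:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected at least two "
                    f"tab-separated columns, got {line!r}"
                )
            u, v = cols[0], cols[1]
            if u == v:
                n_self += 1
                continue
            edge = TypedEdge(u, v, layer)
            if edge.key in seen:
                continue
            seen.add(edge.key)
            edges.append(edge)
    if n_self:
        logger.warning("%s: dropped %d self-loop line(s)", path, n_self)
    return edges


def write_edge_list(edges: Iterable[TypedEdge], path: str | Path) -> None:
    """Write edges in the canonical order: each row (a, b) with a <= b,
    rows sorted lexicographically. Reproducible byte-for-byte."""
    rows = sorted({tuple(sorted((e.source, e.target))) for e in edges})
    with open(path, "w", encoding="utf-8") as fh:
        for a, b in rows:
            fh.write(f"{a}\t{b}\n")


class HeteroNetwork:
    """Typed node registry plus per-type adjacency for the 4-layer graph.

    ``neighbors(v, t)`` returns the lexicographically sorted list of
    type-``t`` neighbors of ``v`` pooled over all layers — the neighbor
    set the walker samples from uniformly.
    """

    def __init__(self) -> None:
        self._types: dict[str, NodeType] = {}
        self._adj: dict[str, dict[NodeType, list[str]]] = {}
        self._layer_edges: dict[str, set[tuple[str, str]]] = {
            layer: set() for layer in LAYER_TYPES
        }
        self._frozen = False

    # -- registration -----------------------------------------------------

    def _assign_type(self, node: str, node_type: NodeType) -> None:
        prev = self._types.setdefault(node, node_type)
        if prev is not node_type:
            raise ValueError(
                f"node {node!r} appears with two types: {prev.value} and "
                f"{node_type.value}"
            )
        self._adj.setdefault(node, {})

    def add_node(self, node: str, node_type: NodeType) -> None:
        """Explicitly register a (possibly isolated) node."""
        self._assign_type(node, node_type)

    def _add_typed_edge(self, u: str, v: str, layer: str) -> None:
        a, b = sorted((u, v))
        if (a, b) in self._layer_edges[layer]:
            return
        self._layer_edges[layer].add((a, b))
        self._adj[u].setdefault(self._types[v], []).append(v)
        self._adj[v].setdefault(self._types[u], []).append(u)

    def _finalize(self) -> None:
        for per_type in self._adj.values():
            for t in per_type:
                per_type[t] = sorted(set(per_type[t]))
        self._frozen = True

    # -- queries ----------------------------------------------------------

    @property
    def nodes(self) -> list[str]:
        return sorted(self._types)

    @property
    def n_nodes(self) -> int:
        return len(self._types)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self._layer_edges.values())

    @property
    def layer_edge_counts(self) -> dict[str, int]:
        return {layer: len(s) for layer, s in self._layer_edges.items()}

    def __contains__(self, node: str) -> bool:
        return node in self._types

    def node_type(self, node: str) -> NodeType:
        try:
            return self._types[node]
        except KeyError:
            raise KeyError(f"unknown node {node!r}") from None

    def nodes_of_type(self, node_type: NodeType) -> list[str]:
        return sorted(n for n, t in self._types.items() if t is node_type)

    def neighbors(self, node: str, node_type: NodeType) -> list[str]:
        """Sorted type-``node_type`` neighbors of ``node`` (empty if none)."""
        if node not in self._types:
            raise KeyError(f"unknown node {node!r}")
        return self._adj[node].get(node_type, [])

    def degree(self, node: str) -> int:
        return sum(len(v) for v in self._adj[node].values())

    def has_edge(self, u: str, v: str, layer: str | None = None) -> bool:
        a, b = sorted((u, v))
        layers = [normalize_layer(layer)] if layer else LAYERS
        return any((a, b) in self._layer_edges[l] for l in layers)

    def edges(self, layer: str) -> list[tuple[str, str]]:
        return sorted(self._layer_edges[normalize_layer(layer)])

    def write_layer(self, layer: str, path: str | Path) -> None:
        layer = normalize_layer(layer)
        write_edge_list(
            [TypedEdge(a, b, layer) for a, b in self.edges(layer)], path
        )

    def write_layers(self, outdir: str | Path) -> dict[str, Path]:
        """Write every non-empty layer as ``<layer>.tsv`` under ``outdir``."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for layer, edge_set in self._layer_edges.items():
            if edge_set:
                p = outdir / f"{layer}.tsv"
                self.write_layer(layer, p)
                paths[layer] = p
        return paths


def _orient(
    edge: TypedEdge, types: dict[str, NodeType]
) -> tuple[str, str] | None:
    """Resolve which endpoint carries the layer's first type.

    Returns (first-type node, second-type node), or None when neither
    endpoint is typed yet. Raises on contradiction.
    """
    ta, tb = LAYER_TYPES[edge.layer]
    tu = types.get(edge.source)
    tv = types.get(edge.target)
    if tu is None and tv is None:
        return None
    forward = tu in (None, ta) and tv in (None, tb)
    backward = tu in (None, tb) and tv in (None, ta)
    if forward:
        return edge.source, edge.target
    if backward:
        return edge.target, edge.source
    bad = edge.source if tu not in (None, ta, tb) else edge.target
    raise ValueError(
        f"node {bad!r} has type {types[bad].value}, incompatible with "
        f"layer {edge.layer!r} edge ({edge.source!r}, {edge.target!r})"
    )


def build_network(
    edges: Mapping[str, Iterable[TypedEdge]] | Iterable[TypedEdge],
    isolated_nodes: Iterable[tuple[str, NodeType]] = (),
) -> HeteroNetwork:
    """Assemble a :class:`HeteroNetwork` from per-layer edge lists.

    Endpoint types are inferred from the layer type pairs.  Because input
    files need not order their columns consistently, orientation of each
    heterogeneous edge is fixed by constraint propagation against already
    typed endpoints; only when no endpoint can be resolved is the declared
    column order assumed.  A node required to take two different types is
    a hard error.

    ``isolated_nodes`` registers nodes with no edges (they are otherwise
    not permitted to exist).
    """
    if isinstance(edges, Mapping):
        flat: list[TypedEdge] = []
        for layer, layer_edges in edges.items():
            layer = normalize_layer(layer)
            flat.extend(TypedEdge(e.source, e.target, layer) for e in layer_edges)
    else:
        flat = [TypedEdge(e.source, e.target, normalize_layer(e.layer)) for e in edges]

    net = HeteroNetwork()
    types = net._types

    homo: list[TypedEdge] = []
    hetero: list[TypedEdge] = []
    for e in flat:
        if e.source == e.target:
            raise ValueError(f"self-loop ({e.source!r}) in layer {e.layer!r}")
        ta, tb = LAYER_TYPES[e.layer]
        (homo if ta is tb else hetero).append(e)

    oriented: list[tuple[str, str, str]] = []
    for e in homo:
        ta, _ = LAYER_TYPES[e.layer]
        net._assign_type(e.source, ta)
        net._assign_type(e.target, ta)
        oriented.append((e.source, e.target, e.layer))

    unresolved = list(hetero)
    while unresolved:
        progressed = False
        remaining: list[TypedEdge] = []
        for e in unresolved:
            pair = _orient(e, types)
            if pair is None:
                remaining.append(e)
                continue
            ta, tb = LAYER_TYPES[e.layer]
            net._assign_type(pair[0], ta)
            net._assign_type(pair[1], tb)
            oriented.append((e.source, e.target, e.layer))
            progressed = True
        if not progressed and remaining:
            # No endpoint typed anywhere: fall back to declared column order
            # for the first pending edge, then keep propagating.
            e = remaining.pop(0)
            ta, tb = LAYER_TYPES[e.layer]
            net._assign_type(e.source, ta)
            net._assign_type(e.target, tb)
            oriented.append((e.source, e.target, e.layer))
        unresolved = remaining

    for node, node_type in isolated_nodes:
        net._assign_type(node, node_type)

    for u, v, layer in oriented:
        net._add_typed_edge(u, v, layer)
    net._finalize()
    return net


def read_network(
    layer_paths: Mapping[str, str | Path],
    isolated_nodes: Iterable[tuple[str, NodeType]] = (),
) -> HeteroNetwork:
    """Read the layers named in ``layer_paths`` and assemble the network."""
    edges = {
        normalize_layer(layer): read_edge_list(path, layer)
        for layer, path in layer_paths.items()
    }
    return build_network(edges, isolated_nodes=isolated_nodes)
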