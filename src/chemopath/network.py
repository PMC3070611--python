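"""Network integration and cycle condensation.

Interaction records are merged into one deduplicated directed network whose
vertices are official gene symbols and whose arcs carry interaction-kind
labels.  Because transcription factors may regulate each other (and
themselves), the raw network contains cycles that make simple-shortest-path
semantics awkward; groups of mutually cyclic vertices are therefore merged
into supernodes before path mining, and a merge map records which genes each
supernode stands for so that scoring can later consider every gene
separately.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import networkx as nx

from chemopath.io import InteractionRecord

logger = logging.getLogger("chemopath")

CONDENSE_MODES = ("none", "two_cycle", "scc")

#: Kinds that count as regulation for two-cycle merging.
_REGULATION_KINDS = ("regulation_positive", "regulation_negative")

#: Separator for flattened supernode labels ("AR+DDIT3").
SUPERNODE_SEP = "+"


class BioNetwork:
    """Directed labeled interaction network.

    Backed by a :class:`networkx.MultiDiGraph` keyed by interaction kind, so
    parallel arcs of different kinds are kept distinct while duplicate
    ``(source, target, kind)`` arcs collapse to one.  Undirected records are
    expanded to two arcs that share a single interaction identity, so the
    interaction count does not double-count them.
    """

    def __init__(self) -> None:
        self.graph = nx.MultiDiGraph()
        self._next_interaction = 0

    # -- construction -------------------------------------------------------

    def add_vertex(self, symbol: str, **attrs) -> None:
        self.graph.add_node(symbol, **attrs)

    def add_arc(self, source: str, target: str, kind: str = "unspecified",
                interaction_id: int | None = None, provenance: str = "",
                directed: bool = True) -> None:
        if interaction_id is None:
            interaction_id = self._next_interaction
            self._next_interaction += 1
        self.graph.add_edge(source, target, key=kind,
                            interaction_id=interaction_id,
                            provenance=provenance, directed=directed)
        self._next_interaction = max(self._next_interaction, interaction_id + 1)

    def add_record(self, record: InteractionRecord) -> None:
        interaction_id = self._find_interaction_id(record)
        if record.directed:
            self.add_arc(record.source, record.target, record.kind,
                         interaction_id, record.provenance, directed=True)
        else:
            # one interaction, two arcs sharing one identity
            if interaction_id is None:
                interaction_id = self._next_interaction
            self.add_arc(record.source, record.target, record.kind,
                         interaction_id, record.provenance, directed=False)
            self.add_arc(record.target, record.source, record.kind,
                         interaction_id, record.provenance, directed=False)

    def _find_interaction_id(self, record: InteractionRecord) -> int | None:
        """Reuse the identity of an equivalent existing arc (deduplication)."""
        data = self.graph.get_edge_data(record.source, record.target)
        if data and record.kind in data:
            return data[record.kind]["interaction_id"]
        if not record.directed:
            data = self.graph.get_edge_data(record.target, record.source)
            if data and record.kind in data:
                return data[record.kind]["interaction_id"]
        return None

    # -- queries ------------------------------------------------------------

    def vertices(self) -> list[str]:
        return list(self.graph.nodes)

    def arcs(self) -> Iterator[tuple[str, str, str]]:
        """Iterate ``(source, target, kind)`` triples."""
        for source, target, kind in self.graph.edges(keys=True):
            yield source, target, kind

    def has_arc(self, source: str, target: str, kind: str | None = None) -> bool:
        data = self.graph.get_edge_data(source, target)
        if data is None:
            return False
        return kind is None or kind in data

    def arc_kinds(self, source: str, target: str) -> list[str]:
        data = self.graph.get_edge_data(source, target) or {}
        return sorted(data)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_arcs(self) -> int:
        return self.graph.number_of_edges()

    @property
    def n_interactions(self) -> int:
        """Distinct interactions (an undirected pair of arcs counts once)."""
        ids = {d["interaction_id"] for _, _, d in self.graph.edges(data=True)}
        return len(ids)

    def undirected_projection(self) -> nx.Graph:
        """Simple undirected view (parallel kinds and directions collapsed)."""
        simple = nx.Graph()
        simple.add_nodes_from(self.graph.nodes)
        simple.add_edges_from((u, v) for u, v, _ in self.arcs() if u != v)
        return simple

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        return _network_to_dict(self)

    def __eq__(self, other) -> bool:
        if not isinstance(other, BioNetwork):
            return NotImplemented
        return (set(self.graph.nodes) == set(other.graph.nodes)
                and set(self.arcs()) == set(other.arcs()))


def _network_to_dict(net: BioNetwork) -> dict:
    arcs = [
        {"source": u, "target": v, "kind": k,
         "interaction_id": d["interaction_id"],
         "provenance": d.get("provenance", ""),
         "directed": bool(d.get("directed", True))}
        for u, v, k, d in net.graph.edges(keys=True, data=True)
    ]
    arcs.sort(key=lambda a: (a["source"], a["target"], a["kind"]))
    return {"vertices": sorted(net.graph.nodes), "arcs": arcs}


def _network_from_dict(payload: dict) -> BioNetwork:
    net = BioNetwork()
    for vertex in payload["vertices"]:
        net.add_vertex(vertex)
    for arc in payload["arcs"]:
        net.add_arc(arc["source"], arc["target"], arc["kind"],
                    arc["interaction_id"], arc.get("provenance", ""),
                    arc.get("directed", True))
    return net



@dataclass
class CondensedNetwork:
    """Cycle-merged network plus the supernode -> member-gene partition."""

    network: BioNetwork
    merge_map: dict[str, frozenset[str]]
    mode: str = "scc"

    def members(self, vertex: str) -> frozenset[str]:
        """Constituent genes of a condensed vertex (singleton if unmerged)."""
        if vertex in self.merge_map:
            return self.merge_map[vertex]
        if vertex not in self.network.graph:
            raise KeyError(f"vertex {vertex!r} not in condensed network")
        return frozenset([vertex])

    def image_of(self, gene: str) -> str | None:
        """Condensed vertex that a raw gene maps to, or None if absent."""
        for supernode, genes in self.merge_map.items():
            if gene in genes:
                return supernode
        return gene if gene in self.network.graph else None

    def to_dict(self) -> dict:
        payload = _network_to_dict(self.network)
        payload["merge_map"] = {k: sorted(v) for k, v in sorted(self.merge_map.items())}
        payload["mode"] = self.mode
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "CondensedNetwork":
        return cls(
            network=_network_from_dict(payload),
            merge_map={k: frozenset(v) for k, v in payload.get("merge_map", {}).items()},
            mode=payload.get("mode", "scc"),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "CondensedNetwork":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def build_network(records: Iterable[InteractionRecord]) -> BioNetwork:
    """Integrate alias-resolved interaction records into one network.

    Duplicate ``(source, target, kind)`` arcs collapse to a single arc;
    undirected records expand to two arcs sharing one interaction identity.
    An empty record list yields an empty network.
    """
    net = BioNetwork()
    for record in records:
        net.add_vertex(record.source)
        net.add_vertex(record.target)
        net.add_record(record)
    return net


def _mutual_regulation_pairs(net: BioNetwork) -> list[tuple[str, str]]:
    pairs = []
    for u, v, kind in net.arcs():
        if u >= v or kind not in _REGULATION_KINDS:
            continue
        if any(k in _REGULATION_KINDS for k in net.arc_kinds(v, u)):
            pairs.append((u, v))
    return pairs


def _supernode_label(genes: Iterable[str]) -> str:
    return SUPERNODE_SEP.join(sorted(genes))


def condense(network: BioNetwork, mode: str = "scc") -> CondensedNetwork:
    """Merge cyclically regulating vertices into supernodes.

    Modes: ``none`` removes self-loops only; ``two_cycle`` merges maximal
    groups connected by mutual-regulation arc pairs; ``scc`` (default)
    merges every strongly connected component with two or more vertices,
    which guarantees the quotient over merged components is acyclic for
    arbitrary cyclic regulation.  Arcs are re-attached to supernodes with
    duplicates collapsed, and self-loops created by merging are dropped.
    """
    if mode not in CONDENSE_MODES:
        raise ValueError(f"unknown condensation mode {mode!r}; expected {CONDENSE_MODES}")

    groups: list[set[str]] = []
    if mode == "scc":
        groups = [set(c) for c in nx.strongly_connected_components(network.graph)
                  if len(c) >= 2]
    elif mode == "two_cycle":
        union = nx.utils.UnionFind(network.vertices())
        for u, v in _mutual_regulation_pairs(network):
            union.union(u, v)
        groups = [set(c) for c in union.to_sets() if len(c) >= 2]

    image: dict[str, str] = {}
    merge_map: dict[str, frozenset[str]] = {}
    for group in groups:
        label = _supernode_label(group)
        merge_map[label] = frozenset(group)
        for gene in group:
            image[gene] = label

    condensed = BioNetwork()
    for vertex in network.vertices():
        condensed.add_vertex(image.get(vertex, vertex))
    for u, v, kind in network.arcs():
        cu, cv = image.get(u, u), image.get(v, v)
        if cu == cv:
            continue  # self-loop (original or merge-induced)
        if not condensed.has_arc(cu, cv, kind):
            data = network.graph.get_edge_data(u, v)[kind]
            condensed.add_arc(cu, cv, kind, data["interaction_id"],
                              data.get("provenance", ""),
                              data.get("directed", True))
    if merge_map:
        logger.info("condense(mode=%s): %d supernode(s) covering %d gene(s)",
                    mode, len(merge_map), sum(len(g) for g in merge_map.values()))
    return CondensedNetwork(network=condensed, merge_map=merge_map, mode=mode)


def expand_path(path, merge_map: dict[str, frozenset[str]],
                network: BioNetwork | None = None) -> set[str]:
    """Union of the constituent genes of every vertex on a path.

    Supernodes expand to all their member genes so that scoring can weight
    each gene individually.  ``path`` may be a Pathway or a vertex sequence.
    """
    vertices = getattr(path, "vertices", path)
    genes: set[str] = set()
    for vertex in vertices:
        if network is not None and vertex not in network.graph:
            raise KeyError(f"vertex {vertex!r} not in network")
        genes.update(merge_map.get(vertex, frozenset([vertex])))
    return genes
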