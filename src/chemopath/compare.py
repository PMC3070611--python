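"""Label-driven intersection of pathways between two conditions.

General graph comparison is NP-hard; here, as in label-correspondence
pathway analysis, vertices correspond exactly when their official gene
symbols match, which reduces intersection to set operations.  Supernodes
correspond through their member genes (matched individually), so inputs
are first flattened to the gene-symbol level: a supernode expands to its
members and each of its arcs is replicated between member pairs.  In
``strict`` mode an edge survives only if an edge with the same endpoints,
kind label and direction exists in the other input; in ``relaxed`` mode an
edge survives whenever both endpoints have corresponding vertices,
regardless of the other input's edges.  Strict-mode edges are therefore
always a subset of relaxed-mode edges.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

from chemopath.network import BioNetwork
from chemopath.pathfind import Pathway

logger = logging.getLogger("chemopath")

INTERSECT_MODES = ("strict", "relaxed")

Edge = tuple[str, str, str]  # (source gene, target gene, kind)


@dataclass(frozen=True)
class IntersectionResult:
    """Common subgraph of two pathways/networks at the gene-symbol level."""

    vertices: frozenset[str]
    edges: frozenset[Edge]
    provenance: tuple[tuple[str, str], ...] = ()

    def __bool__(self) -> bool:
        return bool(self.vertices)

    def to_dict(self) -> dict:
        return {
            "vertices": sorted(self.vertices),
            "edges": sorted(list(e) for e in self.edges),
            "provenance": [list(p) for p in self.provenance],
        }

    def write_sif(self, path) -> None:
        from pathlib import Path

        lines = sorted(f"{s}\t{k}\t{t}" for s, t, k in self.edges)
        Path(path).write_text("".join(line + "\n" for line in lines))


def _flatten(obj) -> tuple[set[str], set[Edge]]:
    """Reduce a Pathway, BioNetwork or IntersectionResult to gene level.

    Supernode vertices expand to their member genes, and a condensed arc is
    replicated between every member pair of its endpoints.
    """
    if isinstance(obj, IntersectionResult):
        return set(obj.vertices), set(obj.edges)
    if isinstance(obj, BioNetwork):
        return set(obj.vertices()), set(obj.arcs())
    if isinstance(obj, Pathway):
        members = obj.member_map()
        vertices: set[str] = set()
        for vtx in obj.vertices:
            vertices.update(members.get(vtx, (vtx,)))
        edges: set[Edge] = set()
        for u, v, kind in obj.arcs:
            for gu in members.get(u, (u,)):
                for gv in members.get(v, (v,)):
                    edges.add((gu, gv, kind))
        return vertices, edges
    # scored pathways delegate to their underlying pathway
    inner = getattr(obj, "pathway", None)
    if inner is not None:
        return _flatten(inner)
    raise TypeError(f"cannot interpret {type(obj).__name__} as a pathway or network")


def correspond(a, b) -> list[tuple[str, str]]:
    """Vertex correspondences between two inputs by official-symbol match.

    At the flattened gene level a correspondence is simply an equal-symbol
    pair; supernodes of the original networks correspond exactly when their
    member sets share at least one symbol, which this member-level matching
    realises.  The relation is symmetric and may be many-to-many upstream.
    """
    va, _ = _flatten(a)
    vb, _ = _flatten(b)
    return [(g, g) for g in sorted(va & vb)]


def intersect(a, b, mode: str = "strict") -> IntersectionResult:
    """Intersection of two pathways or networks by label correspondence.

    Vertices: all label-matched pairs.  Edges in ``strict`` mode: an edge
    of either input survives iff both endpoints correspond and the other
    input has an edge with the same corresponding endpoints, direction and
    kind label.  ``relaxed`` mode keeps any edge whose two endpoints
    correspond.
    """
    if mode not in INTERSECT_MODES:
        raise ValueError(f"unknown mode {mode!r}; expected {INTERSECT_MODES}")
    va, ea = _flatten(a)
    vb, eb = _flatten(b)
    common = va & vb
    if mode == "strict":
        edges = {e for e in ea & eb if e[0] in common and e[1] in common}
    else:
        edges = {e for e in ea | eb if e[0] in common and e[1] in common}
    return IntersectionResult(vertices=frozenset(common), edges=frozenset(edges))


def intersect_sets(set_a, set_b, mode: str = "strict") -> list[IntersectionResult]:
    """Pairwise intersection of two pathway sets.

    All pairs of the Cartesian product are intersected; empty results are
    discarded and duplicates (identical vertex and edge sets) collapsed,
    with every contributing pair recorded in the result's provenance.
    """
    if not set_a or not set_b:
        raise ValueError("both pathway sets must be nonempty")
    merged: dict[tuple[frozenset, frozenset], list[tuple[str, str]]] = {}
    for i, a in enumerate(set_a):
        for j, b in enumerate(set_b):
            result = intersect(a, b, mode)
            if not result:
                continue
            merged.setdefault((result.vertices, result.edges), []).append(
                (f"a{i}", f"b{j}"))
    results = [
        IntersectionResult(vertices=v, edges=e, provenance=tuple(pairs))
        for (v, e), pairs in merged.items()
    ]
    results.sort(key=lambda r: (-len(r.vertices), sorted(r.vertices)))
    logger.info("intersected %d x %d pathways -> %d distinct non-empty result(s)",
                len(set_a), len(set_b), len(results))
    return results
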