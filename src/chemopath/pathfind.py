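"""Seed selection and k-shortest simple-path mining.

Candidate pathways are extracted from the condensed network as the k
lowest-weight simple paths between every ordered pair of seed genes, using
Yen's algorithm.  The search phase uses unit arc weights by default (hop
count); differential expression enters only at the scoring stage.  Ties
between equal-weight paths are broken by the lexicographic order of the
vertex-label sequence so that runs are reproducible.
"""

from __future__ import annotations

import heapq
import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

from chemopath.network import BioNetwork, CondensedNetwork

logger = logging.getLogger("chemopath")

SEED_PROVENANCES = ("user_interest", "resistance", "dna_damage", "de_selected")

WeightFn = Callable[[str, str, str], float]


def _unit_weight(source: str, target: str, kind: str) -> float:
    return 1.0


@dataclass
class SeedSet:
    """Seed genes with the criterion that selected each of them.

    Provenance is one of: ``user_interest`` (genes supplied by the analyst),
    ``dna_damage`` (DNA damage/repair functional annotation), ``resistance``
    (known drug-resistance transcription factors), or ``de_selected``
    (significantly differentially expressed between the two conditions).
    Seeds absent from the network are kept aside in ``missing``.
    """

    provenance: dict[str, str] = field(default_factory=dict)
    missing: list[str] = field(default_factory=list)

    @property
    def symbols(self) -> list[str]:
        return sorted(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.provenance


@dataclass(frozen=True)
class Pathway:
    """A simple path on the condensed network.

    ``arcs[i]`` joins ``vertices[i]`` to ``vertices[i+1]`` and carries the
    (lexicographically first) interaction kind of the condensed arc.
    ``members`` maps each vertex to its constituent genes so that supernodes
    can be expanded during scoring and comparison.
    """

    vertices: tuple[str, ...]
    arcs: tuple[tuple[str, str, str], ...]
    source_seed: str
    target_seed: str
    weight: float = 0.0
    members: tuple[tuple[str, tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        if len(set(self.vertices)) != len(self.vertices):
            raise ValueError("a pathway must be a simple path (no repeated vertex)")
        if len(self.arcs) != max(len(self.vertices) - 1, 0):
            raise ValueError("arc list must connect consecutive vertices")
        for i, (u, v, _) in enumerate(self.arcs):
            if (u, v) != (self.vertices[i], self.vertices[i + 1]):
                raise ValueError(f"arc {i} does not join vertices {i} and {i + 1}")

    @property
    def length(self) -> int:
        """Hop length (number of arcs)."""
        return len(self.arcs)

    def member_map(self) -> dict[str, tuple[str, ...]]:
        return dict(self.members)

    def gene_set(self) -> set[str]:
        """All constituent genes, with supernodes expanded."""
        mapping = self.member_map()
        genes: set[str] = set()
        for vertex in self.vertices:
            genes.update(mapping.get(vertex, (vertex,)))
        return genes


# ---------------------------------------------------------------------------
# Seed selection
# ---------------------------------------------------------------------------

def select_seeds(network: BioNetwork,
                 user_genes: Iterable[str] = (),
                 annotation_genes: Iterable[str] = (),
                 tf_genes: Iterable[str] = (),
                 gene_scores=None,
                 p_threshold: float = 0.05) -> SeedSet:
    """Assemble the seed set from the four selection criteria.

    Later criteria do not overwrite earlier provenance; precedence is
    user_interest > dna_damage > resistance > de_selected, so a gene that is
    both user-supplied and differentially expressed is reported once as
    user_interest.  Candidates absent from the network are listed in
    ``missing`` (reported, not fatal); an entirely empty seed set is an
    error.
    """
    if not (0.0 < p_threshold < 1.0):
        raise ValueError("p_threshold must lie in (0, 1)")
    candidates: list[tuple[str, str]] = []
    candidates += [(g, "user_interest") for g in user_genes]
    candidates += [(g, "dna_damage") for g in annotation_genes]
    candidates += [(g, "resistance") for g in tf_genes]
    if gene_scores is not None:
        candidates += [(g, "de_selected")
                       for g in gene_scores.significant_genes(p_threshold)]
    if not candidates:
        raise ValueError("no seed candidates supplied by any criterion")

    seeds = SeedSet()
    present = set(network.vertices())
    for symbol, provenance in candidates:
        if symbol in seeds.provenance:
            continue
        if symbol in present:
            seeds.provenance[symbol] = provenance
        elif symbol not in seeds.missing:
            seeds.missing.append(symbol)
    if seeds.missing:
        logger.warning("%d seed candidate(s) absent from the network: %s",
                       len(seeds.missing), ", ".join(seeds.missing[:10]))
    if not seeds.provenance:
        raise ValueError("all seed candidates are absent from the network")
    return seeds


# ---------------------------------------------------------------------------
# Shortest simple paths
# ---------------------------------------------------------------------------

def _resolve_weight(weights: WeightFn | None) -> WeightFn:
    return weights if weights is not None else _unit_weight


def _min_arc(net: BioNetwork, u: str, v: str,
             weight_fn: WeightFn) -> tuple[float, str]:
    """Cheapest (then lexicographically first) parallel arc u -> v."""
    best: tuple[float, str] | None = None
    for kind in net.arc_kinds(u, v):
        w = weight_fn(u, v, kind)
        if w < 0:
            raise ValueError(f"negative arc weight on ({u}, {v}, {kind})")
        if best is None or (w, kind) < best:
            best = (w, kind)
    assert best is not None
    return best


def _lex_dijkstra(net: BioNetwork, source: str, target: str,
                  weight_fn: WeightFn,
                  banned_vertices: frozenset[str] = frozenset(),
                  banned_arcs: frozenset[tuple[str, str]] = frozenset(),
                  ) -> tuple[float, tuple[str, ...]] | None:
    """Minimum-weight path, tie-broken by lexicographic vertex sequence.

    Dijkstra whose heap entries carry the full vertex sequence, so equal
    weights are ordered by label sequence.  With strictly positive weights
    the first finalized entry per vertex is the (weight, lex)-minimal path.
    """
    if source in banned_vertices or target in banned_vertices:
        return None
    graph = net.graph
    if source not in graph or target not in graph:
        return None
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (source,))]
    done: set[str] = set()
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in done:
            continue
        done.add(node)
        if node == target:
            return cost, path
        for succ in graph.successors(node):
            if succ in done or succ in banned_vertices or (node, succ) in banned_arcs:
                continue
            w, _ = _min_arc(net, node, succ, weight_fn)
            heapq.heappush(heap, (cost + w, path + (succ,)))
    return None


def _make_pathway(net: BioNetwork, vertex_seq: Sequence[str], weight: float,
                  source_seed: str, target_seed: str, weight_fn: WeightFn,
                  merge_map: dict[str, frozenset[str]] | None = None) -> Pathway:
    arcs = []
    for u, v in zip(vertex_seq, vertex_seq[1:]):
        _, kind = _min_arc(net, u, v, weight_fn)
        arcs.append((u, v, kind))
    members = ()
    if merge_map:
        members = tuple(
            (vtx, tuple(sorted(merge_map[vtx])))
            for vtx in vertex_seq if vtx in merge_map
        )
    return Pathway(vertices=tuple(vertex_seq), arcs=tuple(arcs),
                   source_seed=source_seed, target_seed=target_seed,
                   weight=weight, members=members)


def shortest_path(network: CondensedNetwork, source: str, target: str,
                  weights: WeightFn | None = None) -> Pathway | None:
    """Minimum-total-weight simple path, or None if the target is unreachable.

    ``source == target`` yields the zero-length path of one vertex.
    """
    weight_fn = _resolve_weight(weights)
    net = network.network
    if source == target:
        if source not in net.graph:
            return None
        return _make_pathway(net, (source,), 0.0, source, target, weight_fn,
                             network.merge_map)
    found = _lex_dijkstra(net, source, target, weight_fn)
    if found is None:
        return None
    cost, path = found
    return _make_pathway(net, path, cost, source, target, weight_fn,
                         network.merge_map)


def yen_ksp(network: CondensedNetwork, source: str, target: str, k: int,
            weights: WeightFn | None = None) -> list[Pathway]:
    """Up to k shortest simple paths in (weight, lexicographic) order.

    Classic Yen construction: the i-th path is found by spurring off every
    prefix of the (i-1)-th path with the shared root excluded, keeping a
    candidate heap ordered by (total weight, vertex sequence).  The first
    returned path equals :func:`shortest_path`'s result; an unreachable
    target yields an empty list.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    weight_fn = _resolve_weight(weights)
    net = network.network
    first = _lex_dijkstra(net, source, target, weight_fn)
    if first is None:
        return []

    selected: list[tuple[float, tuple[str, ...]]] = [first]
    candidates: list[tuple[float, tuple[str, ...]]] = []
    seen: set[tuple[str, ...]] = {first[1]}

    while len(selected) < k:
        prev_cost, prev_path = selected[-1]
        prefix_cost = 0.0
        for i in range(len(prev_path) - 1):
            spur = prev_path[i]
            root = prev_path[: i + 1]
            # arcs leaving the spur node along any already-selected path
            # sharing this root must not be reused
            banned_arcs = {
                (p[i], p[i + 1])
                for _, p in selected
                if len(p) > i + 1 and p[: i + 1] == root
            }
            banned_vertices = frozenset(root[:-1])
            found = _lex_dijkstra(net, spur, target, weight_fn,
                                  banned_vertices, frozenset(banned_arcs))
            if found is not None:
                spur_cost, spur_path = found
                total = root[:-1] + spur_path
                if total not in seen:
                    heapq.heappush(candidates, (prefix_cost + spur_cost, total))
                    seen.add(total)
            if i + 1 < len(prev_path):
                w, _ = _min_arc(net, prev_path[i], prev_path[i + 1], weight_fn)
                prefix_cost += w
        if not candidates:
            break
        selected.append(heapq.heappop(candidates))

    return [
        _make_pathway(net, path, cost, source, target, weight_fn,
                      network.merge_map)
        for cost, path in selected
    ]


def mine_pathways(network: CondensedNetwork, seeds: SeedSet, k: int = 5,
                  weights: WeightFn | None = None,
                  ordered_pairs: bool = True) -> list[Pathway]:
    """Pool the k shortest simple paths over every pair of seed genes.

    Seeds are first mapped to their condensed vertices; pairs that fall in
    the same supernode are skipped (their genes are inseparable on the
    condensed network).  Duplicate vertex sequences arising from different
    seed pairs are removed; the pool is ordered by (weight, vertex
    sequence) for reproducibility.  With ``ordered_pairs=False`` only one
    direction per unordered pair is searched.
    """
    if len(seeds) < 2:
        raise ValueError("at least two seeds are required to mine pathways")
    images: dict[str, str] = {}
    for symbol in seeds.symbols:
        image = network.image_of(symbol)
        if image is None:
            logger.warning("seed %s not present in condensed network", symbol)
        else:
            images[symbol] = image

    pairs = (itertools.permutations(sorted(images), 2) if ordered_pairs
             else itertools.combinations(sorted(images), 2))
    pooled: dict[tuple[str, ...], Pathway] = {}
    for a, b in pairs:
        if images[a] == images[b]:
            logger.info("seeds %s and %s share supernode %s; pair skipped",
                        a, b, images[a])
            continue
        for pathway in yen_ksp(network, images[a], images[b], k, weights):
            pooled.setdefault(pathway.vertices, pathway)
    ordered = sorted(pooled.values(), key=lambda p: (p.weight, p.vertices))
    logger.info("mined %d distinct pathway(s) from %d seed(s) at k=%d",
                len(ordered), len(images), k)
    return ordered
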