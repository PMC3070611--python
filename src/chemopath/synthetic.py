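"""Synthetic networks and expression matrices with known ground truth.

The generator emulates the study design the pipeline targets: a directed
labeled interaction network containing a planted simple path of
differentially expressed genes between two designated seed genes, plus a
requested number of planted mutual-regulation 2-cycles to exercise
condensation, and a two-group expression matrix (chemosensitive vs
chemoresistant, 3 + 3 samples by default) in which the planted-path genes
are shifted by an effect of ``effect`` noise units in the resistant group.

Background arcs are drawn Erdős–Rényi-style but oriented along a random
gene ordering, so the background is acyclic — regulatory networks are
predominantly acyclic, and planting the only cycles explicitly keeps the
condensation ground truth exact (each planted pair is exactly one
supernode in both ``two_cycle`` and ``scc`` modes).  Cycle-pair genes take
no background arcs, so no larger strongly connected component can form.

All randomness flows from the single integer seed in the spec; identical
specs produce byte-identical fixture files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from chemopath.io import (
    AliasTable,
    ExpressionMatrix,
    InteractionRecord,
    write_aliases,
    write_expression,
    write_interactions,
    write_seeds,
)
from chemopath.network import BioNetwork, build_network

logger = logging.getLogger("chemopath")

_BACKGROUND_KINDS = ("protein_binding", "regulation_positive",
                     "regulation_negative", "metabolic", "unspecified")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of one synthetic study.

    ``effect`` is the planted expression shift in units of the noise
    standard deviation ``sigma``; ``path_len`` counts genes on the planted
    path (so the path has ``path_len - 1`` arcs).
    """

    n_genes: int = 80
    n_arcs: int = 100
    cycle_pairs: int = 2
    path_len: int = 5
    effect: float = 2.0
    sigma: float = 1.0
    n_per_group: int = 3
    baseline: float = 8.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.path_len < 2 or self.path_len > self.n_genes:
            raise ValueError("planted path length must be in [2, n_genes]")
        if self.path_len + 2 * self.cycle_pairs > self.n_genes:
            raise ValueError("planted path and cycle pairs need disjoint genes")
        if self.n_arcs < self.n_genes - 1:
            raise ValueError("need at least n_genes - 1 arcs")
        if self.n_per_group < 2:
            raise ValueError("each group needs at least 2 samples")
        if self.sigma < 0 or self.effect < 0:
            raise ValueError("sigma and effect must be nonnegative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one generated network."""

    path: tuple[str, ...]
    cycle_pairs: tuple[tuple[str, str], ...]
    records: tuple[InteractionRecord, ...]

    @property
    def source(self) -> str:
        return self.path[0]

    @property
    def target(self) -> str:
        return self.path[-1]


def _gene_names(n: int) -> list[str]:
    width = max(3, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(spec: SyntheticSpec) -> tuple[BioNetwork, SyntheticTruth]:
    """Random directed network with a planted path and planted 2-cycles.

    The planted path is laid along a random increasing subsequence of a
    random gene ordering and all background arcs respect that ordering, so
    the planted 2-cycles are the only cycles in the network.
    """
    rng = np.random.default_rng([spec.seed, 0])
    genes = _gene_names(spec.n_genes)
    order = [genes[i] for i in rng.permutation(spec.n_genes)]
    rank = {g: i for i, g in enumerate(order)}

    # planted path: random increasing subsequence of the ordering,
    # skipping none of the first/last constraint
    positions = np.sort(rng.choice(spec.n_genes, size=spec.path_len, replace=False))
    path = tuple(order[p] for p in positions)

    # planted mutual-regulation pairs: adjacent in the ordering, disjoint
    # from the path and from each other
    blocked = set(path)
    pairs: list[tuple[str, str]] = []
    adjacent = [i for i in range(spec.n_genes - 1)
                if order[i] not in blocked and order[i + 1] not in blocked]
    rng.shuffle(adjacent)
    for i in adjacent:
        if len(pairs) == spec.cycle_pairs:
            break
        a, b = order[i], order[i + 1]
        if a in blocked or b in blocked:
            continue
        pairs.append((a, b))
        blocked.update((a, b))
    if len(pairs) < spec.cycle_pairs:
        raise ValueError("could not place the requested cycle pairs disjointly")

    records: list[InteractionRecord] = []
    for u, v in zip(path, path[1:]):
        records.append(InteractionRecord(u, v, "regulation_positive",
                                         directed=True, provenance="planted_path"))
    for a, b in pairs:
        records.append(InteractionRecord(a, b, "regulation_positive",
                                         directed=True, provenance="planted_cycle"))
        records.append(InteractionRecord(b, a, "regulation_positive",
                                         directed=True, provenance="planted_cycle"))

    cycle_genes = {g for p in pairs for g in p}
    planted_arcs = {(u, v) for u, v in zip(path, path[1:])}
    candidates = [
        (u, v)
        for u in genes if u not in cycle_genes
        for v in genes if v not in cycle_genes
        if rank[u] < rank[v] and (u, v) not in planted_arcs
    ]
    n_background = spec.n_arcs - len(records)
    if n_background > len(candidates):
        raise ValueError("arc count too large for the acyclic background")
    if n_background > 0:
        chosen = rng.choice(len(candidates), size=n_background, replace=False)
        kinds = rng.choice(len(_BACKGROUND_KINDS), size=n_background)
        for idx, kind_idx in zip(chosen, kinds):
            u, v = candidates[idx]
            records.append(InteractionRecord(
                u, v, _BACKGROUND_KINDS[kind_idx],
                directed=True, provenance="background"))

    network = build_network(records)
    for gene in genes:  # isolated genes still belong to the vertex set
        network.add_vertex(gene)
    truth = SyntheticTruth(path=path, cycle_pairs=tuple(pairs),
                           records=tuple(records))
    return network, truth


def generate_expression(network: BioNetwork, truth: SyntheticTruth,
                        spec: SyntheticSpec) -> ExpressionMatrix:
    """Two-group Gaussian expression with the planted path shifted.

    Background genes are N(baseline, sigma^2) in both groups; planted-path
    genes get an additive shift of ``effect * sigma`` in the resistant
    group (an absolute shift of ``effect`` in the noise-free sigma = 0
    case, which exercises the degenerate zero-variance branch of the
    t-test).  Equal variances across groups match the pooled t-test
    assumption, which keeps power analytically checkable.
    """
    missing = set(truth.path) - set(network.vertices())
    if missing:
        raise ValueError(f"truth genes absent from the network: {sorted(missing)}")
    rng = np.random.default_rng([spec.seed, 1])
    genes = sorted(network.vertices())
    n = spec.n_per_group
    samples = [f"sens_{i + 1}" for i in range(n)] + [f"res_{i + 1}" for i in range(n)]
    values = spec.baseline + spec.sigma * rng.standard_normal((len(genes), 2 * n))
    planted = {g: i for i, g in enumerate(genes) if g in set(truth.path)}
    shift = spec.effect * spec.sigma if spec.sigma > 0 else spec.effect
    for row in planted.values():
        values[row, n:] += shift
    frame = pd.DataFrame(values, index=pd.Index(genes, name="gene"),
                         columns=samples)
    groups = pd.Series(["sensitive"] * n + ["resistant"] * n, index=samples)
    return ExpressionMatrix(values=frame, groups=groups)


@dataclass
class FixtureBundle:
    """Everything an end-to-end pipeline run needs, on disk and in memory."""

    spec: SyntheticSpec
    truth: SyntheticTruth
    network: BioNetwork
    expression: ExpressionMatrix
    files: dict[str, Path] = field(default_factory=dict)


def _write_bundle(spec: SyntheticSpec, network: BioNetwork,
                  truth: SyntheticTruth, outdir: Path) -> FixtureBundle:
    outdir.mkdir(parents=True, exist_ok=True)
    expression = generate_expression(network, truth, spec)

    # a synthetic <gene>_ALT alias per planted gene exercises resolution
    aliases = AliasTable()
    for gene in truth.path:
        aliases.add(f"{gene}_ALT", gene)

    files = {
        "interactions": outdir / "interactions.tsv",
        "aliases": outdir / "aliases.tsv",
        "expression": outdir / "expression.tsv",
        "groups": outdir / "groups.tsv",
        "seeds": outdir / "seeds.txt",
    }
    write_interactions(truth.records, files["interactions"])
    write_aliases(aliases, files["aliases"])
    write_expression(expression, files["expression"], files["groups"])
    write_seeds([truth.source, truth.target], files["seeds"])
    logger.info("fixture written to %s (planted path %s)", outdir,
                "->".join(truth.path))
    return FixtureBundle(spec=spec, truth=truth, network=network,
                         expression=expression, files=files)


def end_to_end_fixture(spec: SyntheticSpec, outdir: str | Path) -> FixtureBundle:
    """Write a complete input set for the full pipeline.

    Produces interactions.tsv, aliases.tsv, expression.tsv, groups.tsv and
    seeds.txt under ``outdir`` (the two planted-path endpoints are the
    seeds) and returns the bundle with the ground truth for assertions.
    """
    network, truth = generate_network(spec)
    return _write_bundle(spec, network, truth, Path(outdir))


def paired_fixtures(spec: SyntheticSpec, outdir_a: str | Path,
                    outdir_b: str | Path,
                    n_shared: int | None = None
                    ) -> tuple[FixtureBundle, FixtureBundle]:
    """Two studies whose planted paths share a prefix of genes.

    Emulates profiling the same resistance mechanism in two conditions
    (e.g. two cancers): the second study is generated independently
    (seed + 1) and then relabeled by a gene-name permutation so that the
    first ``n_shared`` genes of its planted path carry the same symbols —
    and hence the same regulatory arcs — as the first study's.  Pathway
    intersection between the two scored sets must therefore recover at
    least that shared sub-path.  Defaults to sharing half the planted
    genes (rounded up).
    """
    if n_shared is None:
        n_shared = (spec.path_len + 1) // 2
    if not (0 < n_shared <= spec.path_len):
        raise ValueError("n_shared must be in [1, path_len]")

    bundle_a = end_to_end_fixture(spec, outdir_a)
    spec_b = replace(spec, seed=spec.seed + 1)
    network_b, truth_b = generate_network(spec_b)

    # permutation of B's gene labels aligning its planted prefix with A's
    mapping = {g: g for g in network_b.vertices()}
    for i in range(n_shared):
        want, have = bundle_a.truth.path[i], truth_b.path[i]
        inverse = {v: k for k, v in mapping.items()}
        cur_at = inverse[want]  # gene currently labeled `want`
        mapping[cur_at], mapping[have] = mapping[have], mapping[cur_at]

    records_b = tuple(
        InteractionRecord(mapping[r.source], mapping[r.target], r.kind,
                          r.directed, r.provenance)
        for r in truth_b.records
    )
    truth_b = SyntheticTruth(
        path=tuple(mapping[g] for g in truth_b.path),
        cycle_pairs=tuple(tuple(sorted((mapping[a], mapping[b])))
                          for a, b in truth_b.cycle_pairs),
        records=records_b,
    )
    network_b = build_network(records_b)
    for gene in _gene_names(spec.n_genes):
        network_b.add_vertex(gene)
    bundle_b = _write_bundle(spec_b, network_b, truth_b, Path(outdir_b))
    return bundle_a, bundle_b
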