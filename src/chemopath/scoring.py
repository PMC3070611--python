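"""Differential-expression scoring of mined pathways.

Per-gene two-sample t-tests between the sensitive and resistant groups give
p-values p_m; these are converted to z-scores z_m = Phi^-1(1 - p_m), where
Phi^-1 is the inverse standard normal CDF, so that under the null
(uniform p) the z-scores are standard normal and smaller p-values map to
larger z-scores.  A pathway's activity score aggregates the z-scores of its
constituent genes; the default size-corrected form (sum z)/sqrt(k) keeps the
null mean 0 and variance 1 for any gene count k, so pathways of all sizes
are comparable.  A line-graph transform is provided so that interactions
become vertices and shared genes become expression-weighted edges.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from chemopath.io import ExpressionMatrix
from chemopath.network import BioNetwork, expand_path
from chemopath.pathfind import Pathway

logger = logging.getLogger("chemopath")

TEST_VARIANTS = ("pooled", "welch")
NORMALIZATIONS = ("sqrt_k", "sum")

#: p-values are clamped into [P_FLOOR, 1] before the normal inversion,
#: which diverges at 0.
P_FLOOR = 1e-16


@dataclass
class GeneScoreTable:
    """Per-gene differential-expression p-values and z-scores.

    ``table`` has columns ``p``, ``z``, ``statistic``, ``degenerate`` (True
    where a zero-variance branch fired) and optionally ``q``
    (Benjamini-Hochberg adjusted p, reporting only — never used in scoring).
    """

    table: pd.DataFrame
    n_sensitive: int = 0
    n_resistant: int = 0
    variant: str = "pooled"

    def p(self, gene: str) -> float:
        return float(self.table.at[gene, "p"])

    def z(self, gene: str) -> float:
        return float(self.table.at[gene, "z"])

    def __contains__(self, gene: str) -> bool:
        return gene in self.table.index

    def __len__(self) -> int:
        return len(self.table)

    def significant_genes(self, p_threshold: float = 0.05) -> list[str]:
        return sorted(self.table.index[self.table["p"] < p_threshold])

    @classmethod
    def from_pvalues(cls, pvalues: dict[str, float]) -> "GeneScoreTable":
        """Build a table from precomputed p-values (e.g. a published list)."""
        genes = sorted(pvalues)
        p = np.clip([pvalues[g] for g in genes], P_FLOOR, 1.0)
        frame = pd.DataFrame(
            {"p": p, "z": stats.norm.isf(p), "statistic": np.nan,
             "degenerate": False},
            index=pd.Index(genes, name="gene"),
        )
        return cls(table=frame)


@dataclass(frozen=True)
class ScoredPathway:
    """A mined pathway with its expanded gene set and aggregate score."""

    pathway: Pathway
    genes: frozenset[str]
    gene_z: tuple[tuple[str, float], ...]
    score: float
    normalization: str = "sqrt_k"

    @property
    def k(self) -> int:
        """Number of genes contributing to the score."""
        return len(self.gene_z)

    def to_dict(self) -> dict:
        return {
            "vertices": list(self.pathway.vertices),
            "arcs": [list(a) for a in self.pathway.arcs],
            "source_seed": self.pathway.source_seed,
            "target_seed": self.pathway.target_seed,
            "weight": self.pathway.weight,
            "members": {v: list(m) for v, m in self.pathway.members},
            "genes": sorted(self.genes),
            "gene_z": {g: z for g, z in self.gene_z},
            "score": self.score,
            "normalization": self.normalization,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "ScoredPathway":
        pathway = Pathway(
            vertices=tuple(payload["vertices"]),
            arcs=tuple(tuple(a) for a in payload["arcs"]),
            source_seed=payload["source_seed"],
            target_seed=payload["target_seed"],
            weight=payload["weight"],
            members=tuple((v, tuple(m))
                          for v, m in sorted(payload.get("members", {}).items())),
        )
        return cls(
            pathway=pathway,
            genes=frozenset(payload["genes"]),
            gene_z=tuple(sorted(payload["gene_z"].items())),
            score=payload["score"],
            normalization=payload.get("normalization", "sqrt_k"),
        )


# ---------------------------------------------------------------------------
# Per-gene tests and the p -> z conversion
# ---------------------------------------------------------------------------

def gene_pvalues(expr: ExpressionMatrix, variant: str = "pooled",
                 p_floor: float = P_FLOOR,
                 bh_column: bool = False) -> GeneScoreTable:
    """Two-sided two-sample t-test per gene between the two groups.

    ``pooled`` is the classic equal-variance Student test; ``welch`` drops
    the equal-variance assumption.  Degenerate rows (zero variance in both
    groups) get p = 1 when the group means are equal and p = ``p_floor``
    otherwise, with the ``degenerate`` flag set.  No multiple-testing
    correction enters the scores; ``bh_column=True`` adds a
    Benjamini-Hochberg ``q`` column for reporting.
    """
    if variant not in TEST_VARIANTS:
        raise ValueError(f"unknown test variant {variant!r}; expected {TEST_VARIANTS}")
    sens = expr.group_values("sensitive").to_numpy(float)
    resi = expr.group_values("resistant").to_numpy(float)
    import warnings

    with warnings.catch_warnings():
        # zero-variance rows trip scipy's precision warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        result = stats.ttest_ind(sens, resi, axis=1,
                                 equal_var=(variant == "pooled"))
    statistic = np.asarray(result.statistic, float)
    p = np.asarray(result.pvalue, float)

    zero_var = (sens.var(axis=1) == 0) & (resi.var(axis=1) == 0)
    equal_means = np.isclose(sens.mean(axis=1), resi.mean(axis=1))
    degenerate = zero_var | ~np.isfinite(p)
    p = np.where(degenerate & equal_means, 1.0, p)
    p = np.where(degenerate & ~equal_means, p_floor, p)
    if degenerate.any():
        logger.warning("%d gene(s) hit the zero-variance degenerate branch",
                       int(degenerate.sum()))
    p = np.clip(p, p_floor, 1.0)

    frame = pd.DataFrame(
        {"p": p, "z": stats.norm.isf(np.clip(p, P_FLOOR, 1 - P_FLOOR)),
         "statistic": statistic, "degenerate": degenerate},
        index=expr.values.index.rename("gene"),
    )
    if bh_column:
        from statsmodels.stats.multitest import multipletests

        frame["q"] = multipletests(frame["p"], method="fdr_bh")[1]
    return GeneScoreTable(table=frame, n_sensitive=sens.shape[1],
                          n_resistant=resi.shape[1], variant=variant)


def p_to_z(p: float) -> float:
    """z = Phi^-1(1 - p): map a p-value to a standard-normal z-score.

    Strictly decreasing in p; inputs outside (0, 1) are clamped to
    [P_FLOOR, 1 - P_FLOOR] because the inversion diverges at the ends.
    """
    p = float(p)
    if math.isnan(p):
        raise ValueError("p-value must be a number")
    p = min(max(p, P_FLOOR), 1.0 - P_FLOOR)
    return float(stats.norm.isf(p))


# ---------------------------------------------------------------------------
# Aggregation, scoring, filtering
# ---------------------------------------------------------------------------

def aggregate_score(genes, scores: GeneScoreTable,
                    normalization: str = "sqrt_k") -> float:
    """Aggregate the z-scores of a gene set into one pathway activity score.

    ``sqrt_k`` returns (sum z)/sqrt(k) with k the number of scored genes
    (null mean 0, variance 1 for any k); ``sum`` returns the raw sum.
    Genes without an expression measurement are excluded from both the sum
    and k.
    """
    if normalization not in NORMALIZATIONS:
        raise ValueError(
            f"unknown normalization {normalization!r}; expected {NORMALIZATIONS}")
    genes = list(genes)
    if not genes:
        raise ValueError("cannot score an empty gene set")
    measured = [g for g in genes if g in scores]
    if not measured:
        raise ValueError("none of the genes has an expression score")
    total = sum(scores.z(g) for g in measured)
    if normalization == "sum":
        return float(total)
    return float(total / math.sqrt(len(measured)))


def score_pathways(pathways: list[Pathway],
                   merge_map: dict[str, frozenset[str]],
                   scores: GeneScoreTable,
                   normalization: str = "sqrt_k") -> list[ScoredPathway]:
    """Expand each pathway's supernodes and score its gene set.

    Every member gene of a supernode contributes its own z-score.  Genes
    absent from the expression data are dropped from the score with a
    logged count.  Results are sorted by score descending, ties broken by
    the lexicographic vertex sequence.
    """
    scored: list[ScoredPathway] = []
    n_unmeasured = 0
    for pathway in pathways:
        genes = expand_path(pathway, merge_map)
        measured = sorted(g for g in genes if g in scores)
        n_unmeasured += len(genes) - len(measured)
        if not measured:
            logger.warning("pathway %s has no measured gene; skipped",
                           "->".join(pathway.vertices))
            continue
        gene_z = tuple((g, scores.z(g)) for g in measured)
        score = aggregate_score(measured, scores, normalization)
        scored.append(ScoredPathway(pathway=pathway, genes=frozenset(genes),
                                    gene_z=gene_z, score=score,
                                    normalization=normalization))
    if n_unmeasured:
        logger.info("%d pathway gene slot(s) lacked expression data and were "
                    "excluded from scoring", n_unmeasured)
    scored.sort(key=lambda s: (-s.score, s.pathway.vertices))
    return scored


def filter_pathways(scored: list[ScoredPathway], threshold: float = -math.inf,
                    top_n: int | None = None) -> list[ScoredPathway]:
    """Keep pathways with score >= threshold, then truncate to the top n."""
    if top_n is not None and top_n < 1:
        raise ValueError("top_n must be a positive integer")
    kept = [s for s in scored if s.score >= threshold]
    kept.sort(key=lambda s: (-s.score, s.pathway.vertices))
    if top_n is not None:
        kept = kept[:top_n]
    return kept


# ---------------------------------------------------------------------------
# Line graph
# ---------------------------------------------------------------------------

@dataclass
class LineGraph:
    """Interaction-centric view of a network.

    Vertices are the arcs of the source network; two are adjacent when the
    arcs share an endpoint (on the undirected projection).  Each line-graph
    edge is labeled with the shared gene, which lets gene-level expression
    z-scores sit directly on edges.
    """

    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def n_vertices(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def to_line_graph(network, scores: GeneScoreTable | None = None) -> LineGraph:
    """Line graph of a network or pathway: arcs become vertices.

    Line-graph edges carry ``label`` (the shared gene — the smallest shared
    symbol if the two arcs share both endpoints) and, when ``scores`` is
    given, ``weight`` = that gene's z-score.  An arc-free input is an error.
    """
    if isinstance(network, Pathway):
        arcs = list(network.arcs)
    elif isinstance(network, BioNetwork):
        arcs = list(network.arcs())
    else:
        arcs = list(network)
    if not arcs:
        raise ValueError("line graph of an arc-free input is undefined")

    line = nx.Graph()
    line.add_nodes_from(arcs)
    for i, a in enumerate(arcs):
        for b in arcs[i + 1:]:
            shared = {a[0], a[1]} & {b[0], b[1]}
            if not shared:
                continue
            label = min(shared)
            weight = scores.z(label) if scores is not None and label in scores else None
            if weight is None:
                line.add_edge(a, b, label=label)
            else:
                line.add_edge(a, b, label=label, weight=weight)
    return LineGraph(graph=line)
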