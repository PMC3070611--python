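"""Scaled betweenness and degree centrality on a reference network.

Both measures are computed on the undirected projection of the reference
interaction network.  Scaled betweenness of node i is the sum over node
pairs (s, t) of the fraction of s-t shortest paths passing through i,
normalized by 2/((n-1)(n-2)) so it lies in [0, 1]; degree centrality is
deg(i)/(n-1).  Genes of interest (e.g. those appearing in filtered
pathways) are flagged when both of their centralities exceed the
network-wide means, the signal for hub-node candidates.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import pandas as pd

from chemopath.io import AliasTable
from chemopath.network import BioNetwork

logger = logging.getLogger("chemopath")


@dataclass
class CentralityReport:
    """Per-gene centralities plus the network-wide context.

    ``rows`` has columns ``betweenness``, ``degree_centrality`` and
    ``above_both_means``; the means are arithmetic means over *all* nodes
    of the reference network, not just the genes of interest.
    """

    rows: pd.DataFrame
    n_nodes: int
    mean_betweenness: float
    mean_degree: float

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene", "betweenness", "degree_centrality",
                            "above_both_means"])
            for gene, row in self.rows.iterrows():
                writer.writerow([
                    gene, "%.10g" % row["betweenness"],
                    "%.10g" % row["degree_centrality"],
                    "true" if row["above_both_means"] else "false",
                ])


def betweenness(network: BioNetwork) -> dict[str, float]:
    """Scaled betweenness centrality per gene, on the undirected projection.

    Endpoint pairs with no connecting path contribute zero.  Networks with
    fewer than three nodes have no interior pairs, so every value is zero.
    """
    if network.n_vertices == 0:
        raise ValueError("cannot compute centrality on an empty network")
    simple = network.undirected_projection()
    values = nx.betweenness_centrality(simple, normalized=True)
    return {node: float(v) for node, v in values.items()}


def degree_centrality(network: BioNetwork) -> dict[str, float]:
    """deg(i)/(n-1) on the undirected projection; requires n >= 2."""
    if network.n_vertices < 2:
        raise ValueError("degree centrality needs at least two nodes")
    simple = network.undirected_projection()
    return {node: float(v) for node, v in nx.degree_centrality(simple).items()}


def centrality_report(reference: BioNetwork, genes_of_interest,
                      alias_table: AliasTable | None = None) -> CentralityReport:
    """Centralities of the genes of interest in a reference network.

    Genes absent from the reference yield no row (an empty report is a
    warning, not an error); the means are always reported.  Aliases are
    resolved before lookup when a table is supplied.
    """
    b = betweenness(reference)
    d = degree_centrality(reference)
    mean_b = sum(b.values()) / len(b)
    mean_d = sum(d.values()) / len(d)

    alias_table = alias_table or AliasTable()
    wanted = sorted({alias_table.resolve(g) for g in genes_of_interest})
    present = [g for g in wanted if g in b]
    if not present:
        logger.warning("none of the %d gene(s) of interest is present in the "
                       "reference network", len(wanted))
    rows = pd.DataFrame(
        {
            "betweenness": [b[g] for g in present],
            "degree_centrality": [d[g] for g in present],
        },
        index=pd.Index(present, name="gene"),
    )
    rows["above_both_means"] = (
        (rows["betweenness"] > mean_b) & (rows["degree_centrality"] > mean_d)
    )
    return CentralityReport(rows=rows, n_nodes=reference.n_vertices,
                            mean_betweenness=mean_b, mean_degree=mean_d)
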