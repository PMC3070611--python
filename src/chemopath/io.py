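"""Readers and writers for every on-disk format the toolkit touches.

All tabular formats are TSV with a mandatory header row; lines starting
with ``#`` are comments.  Interaction tables are a generic flat abstraction
of parsed pathway databases (source, target, kind, directed, provenance);
alias tables map alternative gene symbols to official ones; expression
matrices are genes x samples with a companion sample->group file; pathway
sets round-trip through JSON.  Networks are additionally exportable as SIF
(``source TAB kind TAB target``) for interoperability with graph viewers.
"""

from __future__ import annotations

import csv
import io as _stdio
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd

logger = logging.getLogger("chemopath")

#: Closed enumeration of interaction kinds.
INTERACTION_KINDS = (
    "protein_binding",
    "regulation_positive",
    "regulation_negative",
    "metabolic",
    "unspecified",
)

#: Valid sample-group labels for two-condition expression data.
GROUP_LABELS = ("sensitive", "resistant")


class FormatError(ValueError):
    """A file does not conform to its declared dialect."""


class ValidationError(ValueError):
    """Contents are well-formed but violate a domain invariant."""


# ---------------------------------------------------------------------------
# Interaction records and alias tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InteractionRecord:
    """One gene/protein interaction: a labeled, optionally directed arc.

    ``regulation_positive`` / ``regulation_negative`` records are always
    directed (a regulator acts on its target); binding and metabolic
    records may be undirected, in which case network construction expands
    them to two arcs sharing a single interaction identity.
    """

    source: str
    target: str
    kind: str = "unspecified"
    directed: bool = True
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.source or not self.target:
            raise ValidationError("interaction endpoints must be non-empty symbols")
        if self.kind not in INTERACTION_KINDS:
            raise ValidationError(
                f"unknown interaction kind {self.kind!r}; "
                f"expected one of {INTERACTION_KINDS}"
            )
        if self.kind.startswith("regulation_") and not self.directed:
            raise ValidationError(f"{self.kind} interactions must be directed")


class AliasTable:
    """Single-valued mapping from alias symbols to official gene symbols.

    Official symbols always resolve to themselves, which makes resolution
    idempotent: ``resolve(resolve(s)) == resolve(s)``.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self._map: dict[str, str] = {}
        for alias, official in (mapping or {}).items():
            self.add(alias, official)

    def add(self, alias: str, official: str) -> None:
        if not alias or not official:
            raise ValidationError("alias and official symbols must be non-empty")
        existing = self._map.get(alias)
        if existing is not None and existing != official:
            raise ValidationError(
                f"conflicting alias mapping for {alias!r}: "
                f"{existing!r} vs {official!r}"
            )
        self._map[alias] = official
        # Official symbols map to themselves so resolution is idempotent.
        self._map.setdefault(official, official)

    def resolve(self, symbol: str) -> str:
        """Return the official symbol, or ``symbol`` unchanged if unknown."""
        return self._map.get(symbol, symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self._map

    def __len__(self) -> int:
        return len(self._map)

    def items(self) -> Iterator[tuple[str, str]]:
        return iter(sorted(self._map.items()))


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a two-group sample assignment.

    ``values`` is indexed by gene symbol with one column per sample;
    ``groups`` maps every sample to ``sensitive`` or ``resistant``.
    """

    values: pd.DataFrame
    groups: pd.Series

    def __post_init__(self) -> None:
        self.groups = self.groups.astype(str)
        unknown = set(self.groups.unique()) - set(GROUP_LABELS)
        if unknown:
            raise ValidationError(f"unknown group labels: {sorted(unknown)}")
        unlabeled = [s for s in self.values.columns if s not in self.groups.index]
        if unlabeled:
            raise ValidationError(f"samples missing a group label: {unlabeled}")
        counts = self.groups.loc[list(self.values.columns)].value_counts()
        for label in GROUP_LABELS:
            if counts.get(label, 0) < 2:
                raise ValidationError(
                    f"group {label!r} has {counts.get(label, 0)} samples; "
                    "at least 2 are required for a t-test"
                )
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate gene rows after collapsing")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_values(self, label: str) -> pd.DataFrame:
        """Sub-matrix of the samples assigned to ``label``."""
        cols = [s for s in self.values.columns if self.groups[s] == label]
        return self.values[cols]


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------

def _read_tsv(path: str | Path, required: Iterable[str]) -> pd.DataFrame:
    """Read a commented TSV and check that required header columns exist."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(required))
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return frame


def read_interactions(
    path: str | Path, alias_table: AliasTable | None = None
) -> list[InteractionRecord]:
    """Read an interaction TSV, resolving symbols through ``alias_table``.

    Unknown symbols pass through unchanged with a logged warning; an empty
    file yields an empty list.
    """
    frame = _read_tsv(path, ("source", "target", "kind", "directed", "provenance"))
    alias_table = alias_table or AliasTable()
    records: list[InteractionRecord] = []
    unknown: set[str] = set()
    for row in frame.itertuples(index=False):
        source, target = str(row.source), str(row.target)
        for symbol in (source, target):
            if symbol not in alias_table and len(alias_table):
                unknown.add(symbol)
        directed = str(row.directed).strip().lower() in ("true", "1", "yes", "directed")
        records.append(
            InteractionRecord(
                source=alias_table.resolve(source),
                target=alias_table.resolve(target),
                kind=str(row.kind),
                directed=directed,
                provenance="" if pd.isna(row.provenance) else str(row.provenance),
            )
        )
    if unknown:
        logger.warning(
            "%d symbol(s) not in the alias table passed through unchanged: %s",
            len(unknown),
            ", ".join(sorted(unknown)[:10]),
        )
    return records


def write_interactions(records: Iterable[InteractionRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["source", "target", "kind", "directed", "provenance"])
        for rec in records:
            writer.writerow(
                [rec.source, rec.target, rec.kind,
                 "true" if rec.directed else "false", rec.provenance]
            )


def read_aliases(path: str | Path) -> AliasTable:
    """Read an ``alias TAB official`` TSV into an :class:`AliasTable`."""
    frame = _read_tsv(path, ("alias", "official"))
    table = AliasTable()
    for row in frame.itertuples(index=False):
        table.add(str(row.alias), str(row.official))
    return table


def write_aliases(table: AliasTable, path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["alias", "official"])
        for alias, official in table.items():
            writer.writerow([alias, official])


def read_expression(
    matrix_path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    """Read a genes x samples TSV plus a ``sample TAB group`` file.

    Duplicate gene rows are collapsed by their mean with a logged warning;
    a sample without a group label, or a group with fewer than two samples,
    raises :class:`ValidationError`.
    """
    matrix_path = Path(matrix_path)
    frame = pd.read_csv(matrix_path, sep="\t", comment="#", index_col=0)
    frame.index = frame.index.astype(str)
    if frame.index.duplicated().any():
        dupes = sorted(set(frame.index[frame.index.duplicated()]))
        logger.warning(
            "%s: %d duplicated gene row(s) collapsed by mean: %s",
            matrix_path, len(dupes), ", ".join(dupes[:10]),
        )
        frame = frame.groupby(level=0, sort=False).mean()
    gframe = _read_tsv(groups_path, ("sample", "group"))
    groups = pd.Series(
        gframe["group"].values, index=gframe["sample"].astype(str), dtype=str
    )
    return ExpressionMatrix(values=frame.astype(float), groups=groups)


def write_expression(expr: ExpressionMatrix, matrix_path: str | Path,
                     groups_path: str | Path) -> None:
    with open(matrix_path, "w", newline="") as handle:
        buffer = _stdio.StringIO()
        expr.values.to_csv(buffer, sep="\t", index_label="gene",
                           lineterminator="\n", float_format="%.10g")
        handle.write(buffer.getvalue())
    with open(groups_path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(["sample", "group"])
        for sample in expr.samples:
            writer.writerow([sample, expr.groups[sample]])


def read_pvalues(path: str | Path) -> dict[str, float]:
    """Read a precomputed per-gene p-value table (columns: gene, p)."""
    frame = _read_tsv(path, ("gene", "p"))
    return {str(row.gene): float(row.p) for row in frame.itertuples(index=False)}


def read_seeds(path: str | Path) -> list[str]:
    """Read a seed list: one gene symbol per line, ``#`` comments allowed."""
    seeds: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            seeds.append(line)
    return seeds


def write_seeds(seeds: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{s}\n" for s in seeds))


# ---------------------------------------------------------------------------
# Pathway sets (JSON) and SIF export
# ---------------------------------------------------------------------------

def write_pathways(pathways: list, path: str | Path) -> None:
    """Serialize scored pathways to JSON; round-trips via :func:`read_pathways`."""
    payload = {"pathways": [p.to_dict() for p in pathways]}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")


def read_pathways(path: str | Path) -> list:
    from chemopath.scoring import ScoredPathway  # local import: avoids a cycle

    payload = json.loads(Path(path).read_text())
    if "pathways" not in payload:
        raise FormatError(f"{path}: not a pathway-set JSON document")
    return [ScoredPathway.from_dict(d) for d in payload["pathways"]]


def write_sif(network, path: str | Path) -> None:
    """Export a network as SIF lines ``source TAB kind TAB target``.

    Supernodes are flattened to a ``A+B`` joined label.
    """
    lines = sorted(
        f"{source}\t{kind}\t{target}" for source, target, kind in network.arcs()
    )
    Path(path).write_text("".join(line + "\n" for line in lines))
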