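"""Readers and writers for the external formats the pipeline touches.

Gene set collections travel as GMT (one set per line: identifier,
description, member symbols, tab-delimited).  Expression data is a
tab-delimited genes x samples matrix with a header row of sample
identifiers, paired with a two-column sample -> group annotation table.
GO term relationships come in as an OBO file reduced to its ``is_a``
backbone.

Sample profiles containing any missing or non-numeric value are dropped
on ingest (the whole profile is abandoned, not individual genes), and
duplicate gene rows — typically multiple probes for one symbol — are
collapsed by per-sample maximum.  Gene symbols are matched by exact,
case-sensitive string equality.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import networkx as nx
import obonet
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "GeneSetCollection",
    "ExpressionMatrix",
    "GmtParseError",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_groups",
    "write_groups",
    "read_obo",
    "write_table",
]


class GmtParseError(ValueError):
    """Raised when a GMT line cannot be parsed into a gene set."""


@dataclass(frozen=True)
class GeneSet:
    """A named gene set: identifier, display name, ordered unique members."""

    id: str
    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.id!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.id!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)


class GeneSetCollection:
    """Ordered mapping of set identifier -> :class:`GeneSet`.

    Iteration order is insertion (file) order and is deterministic.
    Identifiers are unique; a duplicate raises ``ValueError``.
    """

    def __init__(self, sets: Iterable[GeneSet]):
        self._sets: dict[str, GeneSet] = {}
        for gs in sets:
            if gs.id in self._sets:
                raise ValueError(f"duplicate gene set identifier {gs.id!r}")
            self._sets[gs.id] = gs

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self) -> Iterator[str]:
        return iter(self._sets)

    def __contains__(self, set_id: object) -> bool:
        return set_id in self._sets

    def __getitem__(self, set_id: str) -> GeneSet:
        return self._sets[set_id]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeneSetCollection):
            return NotImplemented
        return list(self.items()) == list(other.items())

    def items(self) -> Iterable[tuple[str, GeneSet]]:
        return self._sets.items()

    def values(self) -> Iterable[GeneSet]:
        return self._sets.values()

    def __repr__(self) -> str:
        return f"GeneSetCollection({len(self)} sets)"


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity table with per-sample group labels.

    ``values`` is indexed by gene symbol with sample identifiers as
    columns; ``groups`` maps every sample to exactly one group label.
    The matrix is validated on construction: no missing values, unique
    genes and samples, complete group annotation.
    """

    values: pd.DataFrame
    groups: pd.Series = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene symbols in expression matrix")
        if self.values.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in expression matrix")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if self.groups is None:
            raise ValueError("group labels are required")
        missing = [s for s in self.values.columns if s not in self.groups.index]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        self.groups = self.groups.loc[self.values.columns]

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, label: str) -> list[str]:
        """Sample identifiers annotated with ``label``, in matrix order."""
        return [s for s in self.values.columns if self.groups[s] == label]

    def subset_samples(self, samples: Iterable[str]) -> "ExpressionMatrix":
        samples = list(samples)
        return ExpressionMatrix(self.values[samples], self.groups.loc[samples])


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file into a :class:`GeneSetCollection`.

    Each line must carry at least three tab-separated fields: set
    identifier, description, and one or more member symbols.  Members
    are deduplicated preserving first occurrence.
    """
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GmtParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, name = fields[0], fields[1]
            members = tuple(dict.fromkeys(m for m in fields[2:] if m))
            if not members:
                raise GmtParseError(f"{path}: line {lineno}: set {set_id!r} has no members")
            sets.append(GeneSet(set_id, name, members))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for _, gs in collection.items():
            fh.write("\t".join([gs.id, gs.name, *gs.members]) + "\n")


def read_groups(path: str | Path) -> pd.Series:
    """Read a two-column sample -> group annotation table (with header)."""
    table = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if table.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (sample, group)")
    series = pd.Series(table.iloc[:, 1].values, index=table.iloc[:, 0].values)
    if series.index.has_duplicates:
        raise ValueError(f"{path}: duplicate sample identifiers")
    series.index.name = "sample"
    series.name = "group"
    return series


def write_groups(groups: pd.Series, path: str | Path) -> None:
    frame = groups.rename("group").rename_axis("sample").reset_index()
    frame.to_csv(path, sep="\t", index=False)


def read_expression(matrix_path: str | Path, groups_path: str | Path) -> ExpressionMatrix:
    """Read an expression matrix and its group annotation.

    Samples whose profile contains any missing or non-numeric cell are
    dropped with a warning — the profile is abandoned whole rather than
    patched.  Duplicate gene symbols are collapsed by per-sample
    maximum.  A sample surviving the filter but absent from the groups
    file is an error, as is an empty matrix after filtering.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str, comment="#")
    values = raw.apply(pd.to_numeric, errors="coerce")

    bad = values.columns[values.isna().any(axis=0)]
    for sample in bad:
        logger.warning("dropping sample %r: profile contains missing data", sample)
    values = values.drop(columns=bad)
    if values.shape[1] == 0:
        raise ValueError(f"{matrix_path}: no complete sample profiles remain")

    if values.index.has_duplicates:
        order = list(dict.fromkeys(values.index))
        values = values.groupby(level=0, sort=False).max().loc[order]

    groups = read_groups(groups_path)
    unlabelled = [s for s in values.columns if s not in groups.index]
    if unlabelled:
        raise ValueError(f"samples missing from group annotation: {unlabelled}")
    return ExpressionMatrix(values, groups.loc[values.columns])


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.rename_axis("gene").to_csv(path, sep="\t")


def read_obo(path: str | Path) -> nx.DiGraph:
    """Read an OBO file into a directed ``is_a`` graph (child -> parent).

    Obsolete terms are skipped; relationship types other than ``is_a``
    are ignored.  A cyclic ``is_a`` structure is an error.
    """
    multi = obonet.read_obo(path, ignore_obsolete=True)
    graph = nx.DiGraph()
    graph.add_nodes_from((n, {"name": d.get("name", "")}) for n, d in multi.nodes(data=True))
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            graph.add_edge(child, parent)
    if not nx.is_directed_acyclic_graph(graph):
        raise ValueError(f"{path}: cyclic is_a relations")
    return graph


def write_table(frame: pd.DataFrame, path: str | Path, *, config: Mapping | None = None,
                index: bool = True) -> None:
    """Write a result table with a commented provenance header line."""
    from gsreg import __version__

    digest = ""
    if config is not None:
        payload = repr(sorted(config.items())).encode()
        digest = " config_sha=" + hashlib.sha256(payload).hexdigest()[:12]
    with open(path, "w") as fh:
        fh.write(f"# gsreg v{__version__}{digest}\n")
        frame.to_csv(fh, sep="\t", index=index)
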