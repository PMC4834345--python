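"""Shared data model and I/O for interaction matrices and attribute tables.

The two on-disk formats are deliberately plain:

* **Interaction matrix** — square CSV, first row and first column hold the
  individual ids, integer cells; cell (i, j) is the number of times i
  directed the behavior at j.  The diagonal is structurally zero.
* **Attribute table** — CSV with header ``id,gender,age,matriline,hierarchy``;
  an empty field means missing.  ``matriline`` is an ordinal code with
  larger integers denoting higher-ranking matrilines; ``hierarchy`` is a
  real-valued rank covariate, usually filled in downstream from the
  agonistic matrix.

Missing matriline is kept as an explicit NA, never coerced to 0, so it
can never silently enter a regression as a real level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import ConsistencyError, StructureError

VALID_BEHAVIORS = ("agonistic", "allogrooming", "other")
ATTRIBUTE_COLUMNS = ("gender", "age", "matriline", "hierarchy")


@dataclass
class InteractionMatrix:
    """Directed, weighted behavior-count matrix over named individuals.

    Parameters
    ----------
    ids
        Ordered unique individual identifiers.
    counts
        ``(n, n)`` array of nonnegative integers; entry ``(i, j)`` is the
        frequency of the behavior directed from individual ``i`` to ``j``.
    behavior
        One of ``{"agonistic", "allogrooming", "other"}``.
    """

    ids: list[str]
    counts: np.ndarray
    behavior: str = "other"

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.counts = np.asarray(self.counts)
        if self.behavior not in VALID_BEHAVIORS:
            raise ValueError(f"unknown behavior label {self.behavior!r}")
        n = len(self.ids)
        if len(set(self.ids)) != n:
            raise ValueError("duplicate individual ids in interaction matrix")
        if self.counts.ndim != 2 or self.counts.shape != (n, n):
            raise StructureError(
                f"counts must be {n}x{n} to match ids, got {self.counts.shape}"
            )
        if not np.issubdtype(self.counts.dtype, np.number):
            raise ValueError("interaction counts must be numeric")
        if np.any(~np.isfinite(self.counts.astype(float))):
            raise ValueError("interaction counts must be finite")
        if np.any(self.counts < 0):
            raise ValueError("interaction counts must be nonnegative")
        if np.any(np.diagonal(self.counts) != 0):
            raise ValueError("self-interaction on the diagonal is not allowed")
        self.counts = self.counts.astype(np.int64)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.ids, columns=self.ids)

    def reorder(self, ids: Sequence[str]) -> "InteractionMatrix":
        """Return a copy with rows/columns permuted to the given id order."""
        if set(ids) != set(self.ids) or len(ids) != self.n:
            raise ConsistencyError("reorder ids must be a permutation of matrix ids")
        idx = [self.ids.index(i) for i in ids]
        return InteractionMatrix(list(ids), self.counts[np.ix_(idx, idx)], self.behavior)

    def induced(self, ids: Sequence[str]) -> "InteractionMatrix":
        """Return the submatrix induced by a subset of ids (given order)."""
        missing = [i for i in ids if i not in self.ids]
        if missing:
            raise ConsistencyError(f"ids not in matrix: {missing}")
        idx = [self.ids.index(i) for i in ids]
        return InteractionMatrix(list(ids), self.counts[np.ix_(idx, idx)], self.behavior)

    @property
    def total_weight(self) -> int:
        return int(self.counts.sum())


@dataclass
class AttributeTable:
    """Per-individual covariates: gender, age, matriline, hierarchy.

    Stored as a DataFrame indexed by id.  ``matriline`` and ``hierarchy``
    are float columns where NaN encodes missing.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        if df.index.name != "id":
            if "id" in df.columns:
                df = df.set_index("id")
            else:
                df.index.name = "id"
        df.index = df.index.astype(str)
        if df.index.duplicated().any():
            raise ValueError("duplicate ids in attribute table")
        for col in ("gender", "age"):
            if col not in df.columns:
                raise ValueError(f"attribute table missing required column {col!r}")
        df["gender"] = df["gender"].astype(str).str.strip().str.upper().str[0]
        bad = ~df["gender"].isin(["F", "M"])
        if bad.any():
            raise ValueError(
                f"unknown gender token(s) for ids {list(df.index[bad])}; expected F or M"
            )
        df["age"] = pd.to_numeric(df["age"], errors="raise").astype(float)
        if (df["age"] <= 0).any() or df["age"].isna().any():
            raise ValueError("ages must be positive")
        for col in ("matriline", "hierarchy"):
            if col not in df.columns:
                df[col] = np.nan
            df[col] = pd.to_numeric(df[col], errors="coerce").astype(float)
        self.data = df[list(ATTRIBUTE_COLUMNS)]

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n(self) -> int:
        return len(self.data)

    def __getitem__(self, col: str) -> pd.Series:
        return self.data[col]

    @property
    def has_hierarchy(self) -> bool:
        return self.data["hierarchy"].notna().all() and len(self.data) > 0

    def with_hierarchy(self, ranks: pd.Series) -> "AttributeTable":
        df = self.data.copy()
        df["hierarchy"] = ranks.reindex(df.index).astype(float)
        return AttributeTable(df)

    def subset(self, ids: Iterable[str]) -> "AttributeTable":
        return AttributeTable(self.data.loc[list(ids)].copy())

    def check_covers(self, m: InteractionMatrix) -> None:
        """Raise ConsistencyError unless every matrix id has attributes."""
        missing = set(m.ids) - set(self.ids)
        if missing:
            raise ConsistencyError(
                f"matrix ids without attribute rows: {sorted(missing)}"
            )


def read_interaction_matrix(path: str | Path, behavior: str = "other") -> InteractionMatrix:
    """Read a square named-count CSV into an :class:`InteractionMatrix`.

    Columns whose order is a permutation of the row order are realigned to
    the row order.  A nonzero diagonal or a negative cell is an input
    error, not silently repaired.
    """
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if len(set(df.index)) != len(df.index):
        raise ValueError(f"{path}: duplicate row ids")
    if len(set(df.columns)) != len(df.columns):
        raise ValueError(f"{path}: duplicate column ids")
    if set(df.index) != set(df.columns):
        raise StructureError(
            f"{path}: row and column id sets differ; matrix must be square over one id set"
        )
    df = df[df.index]  # realign columns to row order
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell in interaction matrix") from exc
    if np.any(~np.isfinite(values)):
        raise ValueError(f"{path}: missing or non-finite cell in interaction matrix")
    return InteractionMatrix(list(df.index), values, behavior)


def write_interaction_matrix(m: InteractionMatrix, path: str | Path) -> None:
    m.to_frame().to_csv(path, index_label="")


def read_attribute_table(path: str | Path) -> AttributeTable:
    """Read an ``id,gender,age,matriline,hierarchy`` CSV.

    Blank matriline/hierarchy fields parse as missing; gender tokens are
    normalized to ``{F, M}``.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: attribute table must have an 'id' column")
    return AttributeTable(df.set_index("id"))


def write_attribute_table(attrs: AttributeTable, path: str | Path) -> None:
    attrs.data.to_csv(path, index_label="id")


def to_graph(m: InteractionMatrix, attrs: AttributeTable | None = None) -> nx.DiGraph:
    """Build a networkx DiGraph with weight edges and node attributes."""
    g = nx.DiGraph()
    for i, ident in enumerate(m.ids):
        node_attrs: dict = {}
        if attrs is not None:
            row = attrs.data.loc[ident]
            node_attrs["gender"] = row["gender"]
            node_attrs["age"] = float(row["age"])
            # GraphML has no NaN literal; missing values become empty strings
            node_attrs["matriline"] = "" if pd.isna(row["matriline"]) else float(row["matriline"])
            node_attrs["hierarchy"] = "" if pd.isna(row["hierarchy"]) else float(row["hierarchy"])
        g.add_node(ident, **node_attrs)
    rows, cols = np.nonzero(m.counts)
    for r, c in zip(rows, cols):
        g.add_edge(m.ids[r], m.ids[c], weight=int(m.counts[r, c]))
    return g


def export_network(
    m: InteractionMatrix,
    attrs: AttributeTable | None,
    path: str | Path,
    format: str = "graphml",
) -> None:
    """Export the network as GraphML or a 3-column ``src,dst,weight`` CSV."""
    if attrs is not None:
        attrs.check_covers(m)
    if format == "graphml":
        nx.write_graphml(to_graph(m, attrs), path)
    elif format == "edge-list":
        rows, cols = np.nonzero(m.counts)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("src,dst,weight\n")
            for r, c in zip(rows, cols):
                fh.write(f"{m.ids[r]},{m.ids[c]},{int(m.counts[r, c])}\n")
    else:
        raise ValueError(f"unknown export format {format!r}")


def read_edge_list(
    path: str | Path, ids: Sequence[str] | None = None, behavior: str = "other"
) -> InteractionMatrix:
    """Rebuild an :class:`InteractionMatrix` from an exported edge list.

    Isolated individuals do not appear in an edge list, so callers that
    need them back must pass the full id universe explicitly.
    """
    df = pd.read_csv(path, dtype={"src": str, "dst": str})
    universe = list(ids) if ids is not None else sorted(set(df["src"]) | set(df["dst"]))
    index = {ident: k for k, ident in enumerate(universe)}
    counts = np.zeros((len(universe), len(universe)), dtype=np.int64)
    for src, dst, w in df.itertuples(index=False):
        counts[index[src], index[dst]] = int(w)
    return InteractionMatrix(universe, counts, behavior)
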