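"""Pedigree container: animal/sire/dam triples with herd, sex and birth date.

The pedigree is the backbone of the numerator relationship matrix A and its
inverse.  Animals are integer ids; the sentinel ``0`` (or NA on file) marks an
unknown parent.  On construction the table is validated (unique ids, parents
present, no cycles) and stored in a topological order with parents before
offspring, which is the order every relationship-matrix recursion needs.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components

from .errors import PedigreeError

UNKNOWN = 0

REQUIRED_COLUMNS = ("animal", "sire", "dam")
METADATA_COLUMNS = ("herd", "sex", "birth_date")


@dataclass
class PedigreeTable:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns ``animal, sire, dam`` plus optional ``herd, sex, birth_date``
        (and any extra metadata), one row per animal, parents before
        offspring.
    meta : dict
        Free-form provenance (e.g. the per-generation offspring log written
        by the simulator).
    """

    df: pd.DataFrame
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ #
    # construction
    # ------------------------------------------------------------------ #
    @classmethod
    def from_frame(cls, df: pd.DataFrame, meta: dict | None = None) -> "PedigreeTable":
        """Validate and topologically sort a raw pedigree frame."""
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise PedigreeError(f"pedigree frame lacks required column {col!r}")
        df = df.copy()
        for col in REQUIRED_COLUMNS:
            df[col] = (
                pd.to_numeric(df[col], errors="raise")
                .fillna(UNKNOWN)
                .astype(np.int64)
            )
        animals = df["animal"].to_numpy()
        if (animals == UNKNOWN).any():
            raise PedigreeError(f"animal id {UNKNOWN} is reserved for unknown parents")
        if len(np.unique(animals)) != len(animals):
            dup = df["animal"][df["animal"].duplicated()].iloc[0]
            raise PedigreeError(f"duplicate animal id {dup}")
        known = set(animals.tolist())
        for col in ("sire", "dam"):
            parents = df[col].to_numpy()
            bad = set(parents[parents != UNKNOWN].tolist()) - known
            if bad:
                raise PedigreeError(f"{col} ids absent from pedigree: {sorted(bad)[:5]}")
        order = _topological_order(df)
        df = df.iloc[order].reset_index(drop=True)
        if "birth_date" in df.columns:
            df["birth_date"] = pd.to_datetime(df["birth_date"])
        return cls(df=df, meta=dict(meta or {}))

    # ------------------------------------------------------------------ #
    # basic accessors
    # ------------------------------------------------------------------ #
    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        """Animal ids in topological (parents-first) order."""
        return self.df["animal"].to_numpy()

    @property
    def positions(self) -> dict[int, int]:
        """Map animal id -> row position in topological order."""
        return {int(a): i for i, a in enumerate(self.ids)}

    def parent_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Sire and dam row positions (-1 for unknown), topological order."""
        pos = self.positions
        sire = np.array([pos.get(int(s), -1) for s in self.df["sire"]], dtype=np.int64)
        dam = np.array([pos.get(int(d), -1) for d in self.df["dam"]], dtype=np.int64)
        return sire, dam

    def is_founder(self) -> np.ndarray:
        """Boolean mask: animal has both parents unknown."""
        return ((self.df["sire"] == UNKNOWN) & (self.df["dam"] == UNKNOWN)).to_numpy()

    # ------------------------------------------------------------------ #
    # graph utilities
    # ------------------------------------------------------------------ #
    def connected_component_labels(self) -> np.ndarray:
        """Label each animal by its undirected family-graph component.

        Edges join every animal to each known parent; two animals share a
        label iff a chain of parent-offspring links connects them, which is
        exactly the condition for a nonzero entry in the additive
        relationship matrix A.
        """
        n = len(self)
        sire, dam = self.parent_indices()
        rows, cols = [], []
        for parent in (sire, dam):
            child = np.nonzero(parent >= 0)[0]
            rows.extend(child.tolist())
            cols.extend(parent[child].tolist())
        graph = coo_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(n, n)
        )
        _, labels = connected_components(graph, directed=False)
        return labels

    def related_to(self, anchor_ids) -> np.ndarray:
        """Ids of animals sharing a pedigree component with any anchor."""
        pos = self.positions
        anchor_pos = [pos[int(a)] for a in anchor_ids if int(a) in pos]
        if not anchor_pos:
            return np.array([], dtype=np.int64)
        labels = self.connected_component_labels()
        keep = np.isin(labels, labels[anchor_pos])
        return self.ids[keep]


def _topological_order(df: pd.DataFrame) -> np.ndarray:
    """Kahn's algorithm over parent->offspring edges; raises on cycles."""
    n = len(df)
    animals = df["animal"].to_numpy()
    pos = {int(a): i for i, a in enumerate(animals)}
    sire = np.array([pos.get(int(s), -1) for s in df["sire"]], dtype=np.int64)
    dam = np.array([pos.get(int(d), -1) for d in df["dam"]], dtype=np.int64)
    indeg = np.zeros(n, dtype=np.int64)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for p in (sire[i], dam[i]):
            if p >= 0:
                indeg[i] += 1
                children[p].append(i)
    # stable queue: founders in input order first
    queue = [i for i in range(n) if indeg[i] == 0]
    order: list[int] = []
    head = 0
    while head < len(queue):
        i = queue[head]
        head += 1
        order.append(i)
        for c in children[i]:
            indeg[c] -= 1
            if indeg[c] == 0:
                queue.append(c)
    if len(order) != n:
        cyclic = sorted(int(animals[i]) for i in range(n) if indeg[i] > 0)
        raise PedigreeError(f"pedigree contains a cycle involving ids {cyclic[:5]}")
    return np.array(order, dtype=np.int64)
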