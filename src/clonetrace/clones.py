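"""Clone calling by barcode-set similarity and clone-level statistics.

Cells sharing barcode content are grouped into clones: presence of each
barcode is binarized, the Jaccard similarity of every cell pair's barcode
sets is computed, pairs at or above the cutoff (default 0.7) are linked,
and connected components with at least two members are called clones.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp

logger = logging.getLogger(__name__)

__all__ = [
    "Clone",
    "CloneStats",
    "jaccard_similarity",
    "call_clones",
    "clones_to_frame",
    "clone_statistics",
    "cross_lineage_error",
]


@dataclass(frozen=True)
class Clone:
    """A called clone: >= 2 member cells and the union of their barcodes."""

    index: int
    cells: tuple[str, ...]
    cloneids: frozenset[str]

    @property
    def size(self) -> int:
        return len(self.cells)


def jaccard_similarity(a: set[str], b: set[str]) -> float:
    """|A n B| / |A u B| for two non-empty barcode sets."""
    if not a or not b:
        raise ValueError("barcode sets must be non-empty")
    return len(a & b) / len(a | b)


def call_clones(
    matrix: pd.DataFrame, threshold: float = 0.7
) -> tuple[list[Clone], list[str]]:
    """Group barcode-expressing cells into clones.

    ``matrix`` is the cells x barcodes UMI count table; presence is
    binarized at count >= 1.  Cells are linked when the Jaccard similarity
    of their barcode sets reaches ``threshold``; connected components of
    size >= 2 become clones (singletons are returned separately).
    """
    if not (0.0 < threshold <= 1.0):
        raise ValueError("threshold must lie in (0, 1]")
    if matrix.empty:
        return [], []
    b = sp.csr_matrix((matrix.values > 0).astype(np.int32))
    sizes = np.asarray(b.sum(axis=1)).ravel()
    keep = sizes > 0
    cells = list(matrix.index[keep])
    b = b[keep]
    sizes = sizes[keep]
    inter = (b @ b.T).tocoo()
    g = nx.Graph()
    g.add_nodes_from(range(len(cells)))
    for i, j, n_ab in zip(inter.row, inter.col, inter.data):
        if i >= j or n_ab == 0:
            continue
        union = sizes[i] + sizes[j] - n_ab
        if n_ab / union >= threshold:
            g.add_edge(int(i), int(j))
    clones: list[Clone] = []
    singletons: list[str] = []
    comps = sorted(nx.connected_components(g), key=lambda c: min(c))
    for comp in comps:
        members = sorted(cells[i] for i in comp)
        if len(members) < 2:
            singletons.extend(members)
            continue
        ids = frozenset(
            col for col in matrix.columns if matrix.loc[members, col].gt(0).any()
        )
        clones.append(Clone(len(clones), tuple(members), ids))
    return clones, sorted(singletons)


def clones_to_frame(clones: list[Clone]) -> pd.DataFrame:
    """Long-form clone table: one row per member cell."""
    rows = [
        (c.index, cell, ",".join(sorted(c.cloneids)))
        for c in clones
        for cell in c.cells
    ]
    return pd.DataFrame(rows, columns=["clone_id", "cellID", "cloneids"])


@dataclass
class CloneStats:
    """Summary of a clone set: size moments overall and per stratum, plus
    group membership counts and the per-cell barcode multiplicity split."""

    n_clones: int
    n_cells: int
    mean_size: float
    sem_size: float
    per_stratum: pd.DataFrame  # index stratum value; columns n_clones, mean, sem
    cells_per_group: pd.DataFrame  # counts of cells in clones by metadata column
    sem_defined: bool = True


def _mean_sem(sizes: np.ndarray) -> tuple[float, float, bool]:
    mean = float(sizes.mean())
    if sizes.size < 2:
        return mean, 0.0, False
    return mean, float(sizes.std(ddof=1) / np.sqrt(sizes.size)), True


def clone_statistics(
    clones: list[Clone],
    metadata: pd.DataFrame | None = None,
    stratify_by: str = "cell_type",
) -> CloneStats:
    """Clone-size mean and s.e.m. (sample s.d. with n-1 over sqrt(n clones)),
    overall and per metadata stratum, plus cells-in-clones counts per cell
    type and region.  Cells missing from ``metadata`` fall in "unknown"."""
    if not clones:
        logger.warning("no clones; empty statistics")
        empty = pd.DataFrame()
        return CloneStats(0, 0, 0.0, 0.0, empty, empty, False)
    sizes = np.array([c.size for c in clones], dtype=float)
    mean, sem, defined = _mean_sem(sizes)

    def lookup(cell: str, col: str) -> str:
        if metadata is not None and cell in metadata.index and col in metadata.columns:
            return str(metadata.at[cell, col])
        return "unknown"

    strata: dict[str, list[int]] = {}
    group_counts: Counter[tuple[str, str]] = Counter()
    for c in clones:
        labels = {lookup(cell, stratify_by) for cell in c.cells}
        for lab in labels:
            strata.setdefault(lab, []).append(c.size)
        for cell in c.cells:
            for col in ("cell_type", "region"):
                group_counts[(col, lookup(cell, col))] += 1
    per_stratum = pd.DataFrame(
        [
            (lab, len(v), *_mean_sem(np.array(v, dtype=float))[:2])
            for lab, v in sorted(strata.items())
        ],
        columns=[stratify_by, "n_clones", "mean_size", "sem_size"],
    ).set_index(stratify_by)
    cells_per_group = pd.DataFrame(
        [(col, val, n) for (col, val), n in sorted(group_counts.items())],
        columns=["group", "value", "n_cells"],
    )
    return CloneStats(
        len(clones), int(sizes.sum()), mean, sem, per_stratum, cells_per_group, defined
    )


def multiplicity_fractions(matrix: pd.DataFrame) -> tuple[float, float]:
    """Fractions of barcode-positive cells with exactly one vs >= 2 distinct
    barcodes."""
    if matrix.empty:
        raise ValueError("matrix must be non-empty")
    per_cell = (matrix.values > 0).sum(axis=1)
    per_cell = per_cell[per_cell > 0]
    single = float((per_cell == 1).mean())
    return single, 1.0 - single


def cross_lineage_error(
    clones: list[Clone],
    metadata: pd.DataFrame,
    incompatible: tuple[set[str], set[str]],
    type_column: str = "cell_type",
) -> dict:
    """Rate at which clones mix developmentally incompatible lineages.

    For each clone with a strict majority of members on one side of the
    incompatible pair, members from the other side are counted as
    offenders.  The error rate is offenders over all cells in
    majority-assigned clones; evenly split clones are flagged unresolvable
    and excluded from the denominator.
    """
    side_a, side_b = incompatible
    offenders: list[str] = []
    denom = 0
    unresolvable: list[int] = []
    for c in clones:
        types = [str(metadata.at[cell, type_column]) if cell in metadata.index else "unknown"
                 for cell in c.cells]
        n_a = sum(t in side_a for t in types)
        n_b = sum(t in side_b for t in types)
        if n_a == 0 and n_b == 0:
            continue
        if n_a == n_b:
            unresolvable.append(c.index)
            continue
        # denominator counts the dominant side's cells in qualifying clones
        denom += max(n_a, n_b)
        minority = side_b if n_a > n_b else side_a
        offenders.extend(cell for cell, t in zip(c.cells, types) if t in minority)
    rate = len(offenders) / denom if denom else 0.0
    return {
        "error_rate": rate,
        "n_offending": len(offenders),
        "n_cells_considered": denom,
        "offending_cells": offenders,
        "unresolvable_clones": unresolvable,
    }
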