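"""Clonal coupling: which cell-type pairs share clones more than chance.

Clones with at least three cells are summarized as a binary clone x
cell-type incidence matrix.  The null model randomizes clone-type
associations while preserving both marginals (the number of types per
clone and the number of clones per type) using checkerboard-swap MCMC.
For every type pair the observed number of shared clones is compared with
the randomized ensemble, yielding a z-score and an empirical P value.
Across samples, z-score profiles are correlated per type pair, Fisher
z-transformed, averaged, and ordered by complete-linkage clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingResult",
    "build_incidence",
    "randomize_incidence",
    "coupling_scores",
    "summarize_couplings",
]


@dataclass
class CouplingResult:
    """Per-sample coupling output: symmetric type x type tables of the
    observed shared-clone counts, null mean/sd, z-scores and empirical
    (add-one) enrichment P values."""

    observed: pd.DataFrame
    null_mean: pd.DataFrame
    null_sd: pd.DataFrame
    z: pd.DataFrame
    p: pd.DataFrame


def build_incidence(
    clone_cells: pd.DataFrame,
    metadata: pd.DataFrame,
    min_cells_per_clone: int = 3,
    type_column: str = "cell_type",
) -> pd.DataFrame:
    """Binary clones x cell-types incidence matrix.

    ``clone_cells`` is the long-form clone table (columns clone_id, cellID).
    Clones with fewer than ``min_cells_per_clone`` cells are excluded; an
    entry is 1 iff the clone contains at least one cell of the type.
    """
    if clone_cells.empty:
        logger.warning("no clones; empty incidence matrix")
        return pd.DataFrame(dtype=int)
    types = clone_cells["cellID"].map(
        lambda c: str(metadata.at[c, type_column]) if c in metadata.index else "unknown"
    )
    df = clone_cells.assign(_type=types)
    sizes = df.groupby("clone_id").size()
    keep = sizes[sizes >= min_cells_per_clone].index
    df = df[df["clone_id"].isin(keep)]
    if df.empty:
        logger.warning("no clones pass the size floor; empty incidence matrix")
        return pd.DataFrame(dtype=int)
    inc = pd.crosstab(df["clone_id"], df["_type"])
    inc = (inc > 0).astype(int)
    inc.columns.name = None
    inc.index.name = "clone_id"
    return inc.sort_index().sort_index(axis=1)


def _checkerboard_sweep(m: np.ndarray, rng: np.random.Generator, n_steps: int) -> None:
    """Attempt ``n_steps`` in-place 2x2 checkerboard swaps preserving margins."""
    ones = np.argwhere(m == 1)
    if len(ones) < 2:
        return
    for _ in range(n_steps):
        a, b = rng.integers(len(ones), size=2)
        r1, c1 = ones[a]
        r2, c2 = ones[b]
        if r1 == r2 or c1 == c2:
            continue
        if m[r1, c2] == 0 and m[r2, c1] == 0:
            m[r1, c1] = m[r2, c2] = 0
            m[r1, c2] = m[r2, c1] = 1
            ones[a] = (r1, c2)
            ones[b] = (r2, c1)


def randomize_incidence(
    incidence: pd.DataFrame,
    n_reps: int = 1000,
    seed: int | None = None,
    burn_in_factor: int = 10,
    thin_factor: int = 5,
) -> Iterator[np.ndarray]:
    """Stream of randomized incidence matrices with the observed marginals.

    A checkerboard-swap Markov chain is burned in for
    ``burn_in_factor * #ones`` attempted swaps and thinned by
    ``thin_factor * #ones`` attempts between replicates.  Degenerate
    matrices without any swappable checkerboard simply reproduce the input
    (logged once).
    """
    m = incidence.values.astype(np.int8).copy()
    rng = np.random.default_rng(seed)
    n_ones = int(m.sum())
    before = m.copy()
    _checkerboard_sweep(m, rng, burn_in_factor * max(n_ones, 1))
    if np.array_equal(before, m):
        logger.info("incidence matrix may be degenerate: burn-in produced no change")
    for _ in range(n_reps):
        _checkerboard_sweep(m, rng, thin_factor * max(n_ones, 1))
        yield m.copy()


def _pair_counts(m: np.ndarray) -> np.ndarray:
    """Type x type matrix of clones containing both types."""
    return m.T @ m


def coupling_scores(
    incidence: pd.DataFrame,
    replicates: Iterator[np.ndarray] | Sequence[np.ndarray],
) -> CouplingResult:
    """Observed shared-clone counts per type pair against the randomized
    null: z = (obs - mean)/sd (0 where sd = 0) and empirical enrichment
    P = (1 + #{null >= obs}) / (1 + n_reps)."""
    types = list(incidence.columns)
    obs = _pair_counts(incidence.values.astype(np.int64))
    n_rep = 0
    s1 = np.zeros_like(obs, dtype=float)
    s2 = np.zeros_like(obs, dtype=float)
    n_ge = np.zeros_like(obs, dtype=np.int64)
    for rep in replicates:
        c = _pair_counts(rep.astype(np.int64))
        s1 += c
        s2 += c.astype(float) ** 2
        n_ge += c >= obs
        n_rep += 1
    if n_rep == 0:
        raise ValueError("at least one replicate required")
    mean = s1 / n_rep
    var = np.maximum(s2 / n_rep - mean**2, 0.0)
    sd = np.sqrt(var)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    p = (1.0 + n_ge) / (1.0 + n_rep)
    p = np.where(sd > 0, p, 1.0)
    wrap = lambda a: pd.DataFrame(a, index=types, columns=types)
    return CouplingResult(wrap(obs), wrap(mean), wrap(sd), wrap(z), wrap(p))


def summarize_couplings(
    z_matrices: dict[str, pd.DataFrame],
) -> tuple[pd.DataFrame, list[str]]:
    """Cross-sample coupling summary.

    Restricts to the cell types present in every sample's z matrix, then per
    sample correlates the z-score profiles of each type pair (Pearson), maps
    through atanh, averages across samples, maps back through tanh, and
    orders the types by complete-linkage clustering on 1 - correlation.
    Returns the averaged correlation matrix and the clustered leaf order.
    """
    if len(z_matrices) < 2:
        raise ValueError("need z matrices from at least two samples")
    shared = None
    for zm in z_matrices.values():
        cols = set(zm.columns)
        shared = cols if shared is None else shared & cols
    types = sorted(shared)
    if len(types) < 2:
        raise ValueError("fewer than two cell types shared across samples")
    k = len(types)
    acc = np.zeros((k, k))
    cnt = np.zeros((k, k))
    for zm in z_matrices.values():
        z = zm.loc[types, types].values
        with np.errstate(invalid="ignore"):
            r = np.corrcoef(z)
        r = np.clip(r, -0.999999, 0.999999)
        ok = np.isfinite(r)
        if not ok.all():
            logger.info("constant z profile in a sample; affected pairs dropped")
        acc += np.where(ok, np.arctanh(np.where(ok, r, 0.0)), 0.0)
        cnt += ok
    with np.errstate(invalid="ignore"):
        avg = np.tanh(acc / np.where(cnt > 0, cnt, 1.0))
    avg[cnt == 0] = np.nan
    np.fill_diagonal(avg, 1.0)
    corr = pd.DataFrame(avg, index=types, columns=types)
    dist = 1.0 - np.nan_to_num(avg, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    condensed = dist[np.triu_indices(k, 1)]
    order = sch.leaves_list(sch.linkage(condensed, method="complete"))
    return corr, [types[i] for i in order]
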