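"""Closed-form experiment-design and library-QC mathematics.

Covers the planning arithmetic of an expressed-barcode lineage-tracing
experiment: back-calculating the number of transduced progenitors from a
later cell count, the fraction of uniquely labeled progenitors for a given
library size, the viral copy-number distribution under a Poisson
multiplicity-of-infection model, the power to detect every cell type of a
clone under sparse sampling, extrapolation of true clone size through a
multi-stage recovery chain, and two library-diversity metrics (Gini index
of barcode abundance and sampled pairwise Hamming distance).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LabelingDesign",
    "GrowthParams",
    "CloneComposition",
    "RecoveryChain",
    "back_calculate_progenitors",
    "unique_fraction_uniform",
    "expected_non_unique",
    "copy_number_distribution",
    "detection_probability_single",
    "detection_probability_multi",
    "recovery_extrapolation",
    "gini_index",
    "hamming_distance",
    "hamming_diversity",
]


@dataclass(frozen=True)
class LabelingDesign:
    """Library size ``n_barcodes``, number of transduced progenitors ``k``
    and an optional barcode-abundance vector ``p`` (uniform if omitted)."""

    n_barcodes: int
    k: int
    p: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.n_barcodes < 1:
            raise ValueError("n_barcodes must be >= 1")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.p is not None:
            p = np.asarray(self.p, dtype=float)
            if p.shape != (self.n_barcodes,):
                raise ValueError("p must have length n_barcodes")
            if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
                raise ValueError("p must be non-negative and sum to 1")
            object.__setattr__(self, "p", p)


@dataclass(frozen=True)
class GrowthParams:
    """Exponential-expansion parameters: ``n_t1`` labeled cells observed
    after ``dt`` days at ``f`` symmetric divisions per day."""

    n_t1: float
    dt: float
    f: float

    def __post_init__(self) -> None:
        if self.n_t1 <= 0 or self.dt <= 0 or self.f <= 0:
            raise ValueError("all growth parameters must be positive")


@dataclass(frozen=True)
class CloneComposition:
    """Cell-type counts of one clone and the number ``s`` of cells sampled
    from it without replacement."""

    cell_type_counts: tuple[int, ...]
    s: int

    def __post_init__(self) -> None:
        if not self.cell_type_counts or any(c < 1 for c in self.cell_type_counts):
            raise ValueError("each listed cell type needs >= 1 cell")
        if not (1 <= self.s <= self.total):
            raise ValueError("s must be in [1, clone size]")

    @property
    def total(self) -> int:
        return sum(self.cell_type_counts)


@dataclass(frozen=True)
class RecoveryChain:
    """Ordered per-stage recovery rates (dissociation, sorting, droplet
    capture, barcode detection, ...), each in (0, 1]."""

    rates: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.rates:
            raise ValueError("at least one stage rate required")
        if any(not (0.0 < r <= 1.0) for r in self.rates):
            raise ValueError("stage rates must lie in (0, 1]")

    @property
    def overall(self) -> float:
        return math.prod(self.rates)


def back_calculate_progenitors(growth: GrowthParams) -> int:
    """Number of labeled progenitors at time 0 implied by exponential
    expansion: N_t0 = N_t1 / 2^(dt * f), rounded to the nearest integer.
    """
    return round(growth.n_t1 / 2.0 ** (growth.dt * growth.f))


def unique_fraction_uniform(n_barcodes: int, k: int) -> float:
    """Fraction of uniquely labeled progenitors for a uniform library:
    F = (1 - 1/N)^(k-1), the chance that none of the other k-1 progenitors
    picked a focal progenitor's barcode."""
    if n_barcodes < 1 or k < 1:
        raise ValueError("n_barcodes and k must be >= 1")
    return (1.0 - 1.0 / n_barcodes) ** (k - 1)


def expected_non_unique(design: LabelingDesign) -> tuple[float, float]:
    """Expected number of non-uniquely labeled progenitors,

        E(X) = k * sum_i p_i * (1 - (1 - p_i)^(k-1)),

    for an arbitrary abundance vector p (uniform by default).  Returns
    ``(E(X), percent_unique)`` with percent_unique = 100 * (1 - E(X)/k).
    """
    if design.p is None:
        p = np.full(design.n_barcodes, 1.0 / design.n_barcodes)
    else:
        p = design.p
    ex = design.k * float(np.sum(p * (1.0 - (1.0 - p) ** (design.k - 1))))
    return ex, 100.0 * (1.0 - ex / design.k)


def copy_number_distribution(rate: float, k_max: int = 10) -> dict:
    """Integration copy-number distribution among labeled cells.

    The number of integrations per exposed cell is modeled as
    K ~ Poisson(lambda) with lambda = -ln(1 - rate), so that ``rate`` is the
    fraction of cells with at least one integration.  Returns the
    zero-truncated probabilities P(K = k | K >= 1) for k = 1..k_max together
    with ``lambda`` and P(K >= 2 | K >= 1).
    """
    if not (0.0 < rate < 1.0):
        raise ValueError("rate must lie strictly in (0, 1)")
    from scipy.stats import poisson

    lam = -math.log1p(-rate)
    ks = np.arange(1, k_max + 1)
    pmf = poisson.pmf(ks, lam) / (1.0 - math.exp(-lam))
    p1 = float(pmf[0])
    return {
        "lambda": lam,
        "k": ks,
        "pmf": pmf,
        "p_single": p1,
        "p_multi": 1.0 - p1,
    }


def detection_probability_single(comp: CloneComposition) -> float:
    """Probability that a without-replacement sample of ``s`` cells from a
    clone contains at least one cell of every type present in the clone.

    The sampled type counts follow a multivariate hypergeometric
    distribution; the all-types-present probability is evaluated exactly by
    inclusion-exclusion over the type subsets that could be missed:

        P = sum_{S subset of types} (-1)^|S| C(T - n_S, s) / C(T, s)

    with T the clone size and n_S the number of cells in the excluded types.
    """
    counts = comp.cell_type_counts
    total = comp.total
    s = comp.s
    denom = math.comb(total, s)
    p = 0.0
    for r in range(len(counts) + 1):
        for subset in itertools.combinations(counts, r):
            rem = total - sum(subset)
            if rem >= s:
                p += (-1) ** r * math.comb(rem, s) / denom
    return p


def detection_probability_multi(comp: CloneComposition, n_clones: int) -> float:
    """Probability of seeing every cell type in at least one of ``n_clones``
    independent clones of identical composition: 1 - (1 - p)^N with p the
    single-clone detection probability (the binomial tail from n = 1..N)."""
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    p = detection_probability_single(comp)
    return 1.0 - (1.0 - p) ** n_clones


def recovery_extrapolation(
    chain: RecoveryChain,
    observed_mean_clone_size: float,
    round_to: int | None = None,
) -> dict:
    """Extrapolate true clone size through the recovery chain.

    The overall recovery rate is the product of the stage rates; the true
    mean clone size is the observed mean divided by that rate, optionally
    rounded to the nearest multiple of ``round_to``.
    """
    if observed_mean_clone_size <= 0:
        raise ValueError("observed mean clone size must be positive")
    overall = chain.overall
    true_size = observed_mean_clone_size / overall
    out = {"overall_rate": overall, "fold": 1.0 / overall, "true_size": true_size}
    if round_to:
        out["true_size_rounded"] = round(true_size / round_to) * round_to
    return out


def gini_index(counts: Sequence[float] | np.ndarray) -> float:
    """Gini index of an abundance vector: mean absolute difference between
    all ordered pairs divided by twice the mean, G = sum|x_i - x_j|/(2 n^2 mu).
    0 for a perfectly uniform library, approaching 1 as a single barcode
    dominates."""
    x = np.sort(np.asarray(counts, dtype=float))
    if x.size == 0 or np.any(x < 0):
        raise ValueError("counts must be non-negative and non-empty")
    total = x.sum()
    if total == 0:
        raise ValueError("counts must not all be zero")
    n = x.size
    # identity: G = (2 * sum_i i*x_(i) - (n+1) * sum x) / (n * sum x), 1-based ranks
    ranks = np.arange(1, n + 1)
    return float((2.0 * np.sum(ranks * x) - (n + 1) * total) / (n * total))


def hamming_distance(a: str, b: str) -> int:
    """Number of mismatching positions between two equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(ca != cb for ca, cb in zip(a, b))


def hamming_diversity(
    sequences: Sequence[str], n_pairs: int = 10_000, seed: int | None = None
) -> tuple[float, float]:
    """Mean and sample s.d. of the Hamming distance over ``n_pairs`` pairs of
    distinct sequences drawn uniformly at random from ``sequences``.

    For i.i.d. uniform random barcodes of length L over a 4-letter alphabet
    the expectation is 3L/4 with s.d. sqrt(3L/16).
    """
    if len(sequences) < 2:
        raise ValueError("need at least two sequences")
    rng = np.random.default_rng(seed)
    arr = np.frombuffer("".join(sequences).encode(), dtype=np.uint8)
    L = len(sequences[0])
    arr = arr.reshape(len(sequences), L)
    i = rng.integers(0, len(sequences), size=n_pairs)
    j = rng.integers(0, len(sequences) - 1, size=n_pairs)
    j = np.where(j >= i, j + 1, j)  # uniform over distinct pairs
    d = (arr[i] != arr[j]).sum(axis=1)
    return float(d.mean()), float(d.std(ddof=1))
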