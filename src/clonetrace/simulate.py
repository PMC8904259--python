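"""Synthetic barcoding experiments with known ground truth.

Emulates the full chain of an expressed-barcode lineage-tracing study:

1. a lentiviral barcode library with skewed abundances,
2. transduction of a progenitor pool at a target labeling rate
   (Poisson multiplicity of infection),
3. clonal expansion by symmetric division with per-progenitor fate
   profiles (cell type, anatomical region),
4. multi-stage sampling loss (dissociation, sorting, encapsulation,
   barcode dropout),
5. sequencing reads of barcode molecules with per-base substitution
   errors and ambient (cross-cell) contamination, emitted as tagged
   alignment records against an N-masked transgene reference,
6. a spatial-transcriptomics section binning barcoded cells into
   capture spots on a regular grid.

Every stage is seeded and deterministic, and every emitted molecule and
cell traces back to its generating progenitor through :class:`TruthTables`,
so the downstream extraction / clone-calling / coupling / spatial modules
can be validated against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .design import gini_index

__all__ = [
    "CLONEID_LENGTH",
    "ALPHABET",
    "REFERENCE_NAME",
    "REGION_START",
    "REGION_END",
    "reference_sequence",
    "LibraryProfile",
    "Transduction",
    "FateProfile",
    "TruthTables",
    "ReadSimConfig",
    "SpatialConfig",
    "SpatialSection",
    "random_barcodes",
    "simulate_library",
    "calibrate_concentration",
    "simulate_transduction",
    "simulate_lineage",
    "simulate_sampling",
    "simulate_reads",
    "simulate_spatial_section",
]

CLONEID_LENGTH = 30
ALPHABET = "ACGT"

# Synthetic transgene reference: the 30-bp variable barcode region is masked
# with 'N' so any barcode aligns; fixed 20-bp flanks on both sides.
_LEFT_FLANK = "ATGGTGAGCAAGGGCGAGGA"
_RIGHT_FLANK = "CTGTTCACCGGGGTGGTGCC"
REFERENCE_NAME = "transgene"
REGION_START = len(_LEFT_FLANK) + 1  # 1-based, closed interval
REGION_END = REGION_START + CLONEID_LENGTH - 1


def reference_sequence() -> str:
    """N-masked transgene reference used by the simulator and aligner stubs."""
    return _LEFT_FLANK + "N" * CLONEID_LENGTH + _RIGHT_FLANK


def _seqs_from_codes(codes: np.ndarray) -> list[str]:
    lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    return [bytes(lut[row]).decode() for row in codes]


def random_barcodes(n: int, seed: int | None = None, length: int = CLONEID_LENGTH) -> list[str]:
    """``n`` i.i.d. uniform random barcode sequences (not deduplicated)."""
    rng = np.random.default_rng(seed)
    return _seqs_from_codes(rng.integers(0, 4, size=(n, length)))


@dataclass(frozen=True)
class LibraryProfile:
    """A barcode library: unique sequences and their abundance probabilities."""

    sequences: tuple[str, ...]
    probabilities: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if len(self.sequences) != p.size:
            raise ValueError("sequences and probabilities differ in length")
        if np.any(p < 0) or abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("probabilities must be >= 0 and sum to 1")
        if len(set(self.sequences)) != len(self.sequences):
            raise ValueError("library sequences must be unique")
        for s in self.sequences:
            if len(s) != CLONEID_LENGTH or any(c not in ALPHABET for c in s):
                raise ValueError("sequences must be length-30 over ACGT")
        object.__setattr__(self, "probabilities", p)

    def __len__(self) -> int:
        return len(self.sequences)

    def gini(self) -> float:
        return gini_index(self.probabilities)


def simulate_library(
    n_barcodes: int, concentration: float = 8.0, seed: int | None = None
) -> LibraryProfile:
    """Random barcode library with Dirichlet-distributed abundances.

    Abundances are drawn from a symmetric Dirichlet with the given
    ``concentration``; larger concentration gives a more uniform library
    (lower Gini index).  The default of 8 puts the Gini index near 0.2,
    typical of a well-made lentiviral preparation, via the large-N identity
    Gini(Gamma(a)) = Gamma(a + 1/2) / (Gamma(a + 1) * sqrt(pi)).
    """
    if n_barcodes < 1:
        raise ValueError("n_barcodes must be >= 1")
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    rng = np.random.default_rng(seed)
    seqs: list[str] = []
    seen: set[str] = set()
    while len(seqs) < n_barcodes:  # rejection keeps sequences unique
        for s in random_barcodes(n_barcodes - len(seqs), rng.integers(2**31)):
            if s not in seen:
                seen.add(s)
                seqs.append(s)
    p = rng.dirichlet(np.full(n_barcodes, concentration)) if n_barcodes > 1 else np.ones(1)
    return LibraryProfile(tuple(seqs), p)


def calibrate_concentration(
    target_gini: float,
    n_barcodes: int = 1000,
    seed: int | None = None,
    tol: float = 5e-3,
    max_iter: int = 40,
) -> float:
    """Bisect the Dirichlet concentration so a library drawn with it has the
    requested Gini index (evaluated on one seeded draw)."""
    if not (0.0 < target_gini < 1.0):
        raise ValueError("target_gini must be in (0, 1)")

    def g(conc: float) -> float:
        return simulate_library(n_barcodes, conc, seed).gini()

    lo, hi = 1e-3, 1e4  # Gini decreases with concentration
    for _ in range(max_iter):
        mid = math.sqrt(lo * hi)
        if abs(g(mid) - target_gini) < tol:
            return mid
        if g(mid) > target_gini:
            lo = mid
        else:
            hi = mid
    return math.sqrt(lo * hi)


@dataclass(frozen=True)
class Transduction:
    """Outcome of exposing ``n_cells`` cells to the library: a map from each
    labeled progenitor index to the multiset of barcode sequences it
    integrated (cells with zero integrations are omitted)."""

    n_cells: int
    rate: float
    lam: float
    assignments: dict[int, tuple[str, ...]]

    @property
    def n_labeled(self) -> int:
        return len(self.assignments)

    @property
    def multi_integration_fraction(self) -> float:
        """Fraction of labeled cells carrying >= 2 integrations."""
        if not self.assignments:
            return 0.0
        multi = sum(1 for v in self.assignments.values() if len(v) >= 2)
        return multi / len(self.assignments)


def simulate_transduction(
    n_cells: int, rate: float, library: LibraryProfile, seed: int | None = None
) -> Transduction:
    """Poisson-MOI transduction at a target labeling rate.

    Each cell receives K ~ Poisson(lambda) integrations with
    lambda = -ln(1 - rate), so ``rate`` is the expected fraction of cells
    with at least one integration.  Each integration draws a barcode from
    the library with its abundance probability, with replacement.
    """
    if not (0.0 <= rate < 1.0):
        raise ValueError("rate must lie in [0, 1)")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    rng = np.random.default_rng(seed)
    lam = -math.log1p(-rate) if rate > 0 else 0.0
    ks = rng.poisson(lam, size=n_cells)
    labeled = np.nonzero(ks)[0]
    total = int(ks[labeled].sum())
    draws = rng.choice(len(library), size=total, p=library.probabilities)
    assignments: dict[int, tuple[str, ...]] = {}
    off = 0
    for idx in labeled:
        k = int(ks[idx])
        assignments[int(idx)] = tuple(library.sequences[d] for d in draws[off : off + k])
        off += k
    return Transduction(n_cells, rate, lam, assignments)


@dataclass(frozen=True)
class FateProfile:
    """A progenitor fate program: the distribution of cell types and regions
    its descendants adopt.  ``weight`` is the chance a progenitor follows
    this program; ``mean_size`` optionally overrides the global expected
    clone size for progenitors on this program (e.g. a highly proliferative
    myeloid-like pool next to smaller neuroectodermal clones)."""

    name: str
    type_probs: Mapping[str, float]
    region_probs: Mapping[str, float] = field(default_factory=lambda: {"CX": 1.0})
    weight: float = 1.0
    mean_size: float | None = None


@dataclass
class TruthTables:
    """Ground truth linking every simulated cell to its progenitor.

    ``progenitor_cloneids`` maps progenitor id -> integrated barcode multiset;
    ``cells`` is indexed by cell id with columns
    progenitor, cell_type, region, sample.
    """

    progenitor_cloneids: dict[str, tuple[str, ...]]
    cells: pd.DataFrame

    def __post_init__(self) -> None:
        if any(len(v) == 0 for v in self.progenitor_cloneids.values()):
            raise ValueError("every progenitor must carry >= 1 barcode")
        missing = set(self.cells["progenitor"]) - set(self.progenitor_cloneids)
        if missing:
            raise ValueError(f"cells reference unknown progenitors: {sorted(missing)[:3]}")

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def cloneids_of_cell(self, cell_id: str) -> tuple[str, ...]:
        return self.progenitor_cloneids[self.cells.at[cell_id, "progenitor"]]

    def partition(self, cell_ids: Sequence[str] | None = None) -> pd.Series:
        """Progenitor label per cell (the true clone partition)."""
        s = self.cells["progenitor"]
        return s if cell_ids is None else s.loc[list(cell_ids)]


def simulate_lineage(
    transduction: Transduction | Mapping[int, tuple[str, ...]],
    f: float = 2.0,
    dt: float = 2.0,
    fate_profiles: Sequence[FateProfile] | None = None,
    sample: str = "S1",
    deterministic: bool = False,
    seed: int | None = None,
) -> TruthTables:
    """Expand labeled progenitors into clones of descendant cells.

    Symmetric division for ``dt`` days at ``f`` divisions per day gives an
    expected clone size of 2**(dt * f); each progenitor's descendant count
    is drawn as max(1, Poisson(2**(dt * f))), preserving that expectation
    (or set exactly to round(2**(dt * f)) when ``deterministic``).  All
    descendants inherit the progenitor's barcode multiset.  Each progenitor
    commits to one fate profile (chosen by profile weight, optionally with
    its own mean clone size), and each descendant's cell type and region
    are drawn from that profile — planting fate-biased progenitor pools or
    always-coupled type pairs is a matter of the profile list passed in.
    """
    if f * dt < 0:
        raise ValueError("f * dt must be >= 0")
    assignments = (
        transduction.assignments if isinstance(transduction, Transduction) else dict(transduction)
    )
    if fate_profiles is None:
        fate_profiles = [FateProfile("default", {"typeA": 1.0})]
    weights = np.array([p.weight for p in fate_profiles], dtype=float)
    weights = weights / weights.sum()
    rng = np.random.default_rng(seed)

    prog_cloneids: dict[str, tuple[str, ...]] = {}
    rows: list[tuple[str, str, str, str, str]] = []
    cell_no = 0
    base_mean = 2.0 ** (dt * f)
    for orig_idx in sorted(assignments):
        pid = f"{sample}_P{orig_idx:07d}"
        prog_cloneids[pid] = tuple(assignments[orig_idx])
        profile = fate_profiles[int(rng.choice(len(fate_profiles), p=weights))]
        mean_size = profile.mean_size if profile.mean_size is not None else base_mean
        if deterministic:
            n_desc = max(1, round(mean_size))
        else:
            n_desc = max(1, int(rng.poisson(mean_size)))
        tnames = list(profile.type_probs)
        tp = np.array([profile.type_probs[t] for t in tnames], dtype=float)
        tp = tp / tp.sum()
        rnames = list(profile.region_probs)
        rp = np.array([profile.region_probs[r] for r in rnames], dtype=float)
        rp = rp / rp.sum()
        types = rng.choice(len(tnames), size=n_desc, p=tp)
        regions = rng.choice(len(rnames), size=n_desc, p=rp)
        for t_i, r_i in zip(types, regions):
            rows.append(
                (f"{sample}_c{cell_no:07d}", pid, tnames[t_i], rnames[r_i], sample)
            )
            cell_no += 1
    cells = pd.DataFrame(
        rows, columns=["cell", "progenitor", "cell_type", "region", "sample"]
    ).set_index("cell")
    return TruthTables(prog_cloneids, cells)


def simulate_sampling(
    truth: TruthTables, stage_rates: Sequence[float], seed: int | None = None
) -> tuple[list[str], float]:
    """Retain each cell independently with probability equal to the product
    of the stage rates.  Returns the retained cell ids (input order) and the
    realized overall retention rate."""
    rates = list(stage_rates)
    if not rates:
        raise ValueError("stage_rates must not be empty")
    if any(not (0.0 < r <= 1.0) for r in rates):
        raise ValueError("each stage rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    p = math.prod(rates)
    keep = rng.random(truth.n_cells) < p
    retained = [cid for cid, k in zip(truth.cells.index, keep) if k]
    realized = len(retained) / truth.n_cells if truth.n_cells else 0.0
    return retained, realized


@dataclass(frozen=True)
class ReadSimConfig:
    """Read-simulation parameters.

    UMIs per integrated barcode copy: 1 + Poisson(mean_umis - 1).
    Reads per UMI: negative binomial (given mean and dispersion = shape)
    truncated at 1.  ``error_rate`` is the per-base substitution rate;
    ``contamination_rate`` the fraction of molecules re-tagged with another
    cell's identifier (ambient capture).  ``frac_softclip`` of reads align
    only to the left flank with the barcode bases soft-clipped;
    ``frac_partial`` cover only a prefix of the barcode region.
    """

    mean_umis: float = 3.0
    reads_per_umi_mean: float = 3.0
    reads_per_umi_dispersion: float = 1.0
    error_rate: float = 0.0
    contamination_rate: float = 0.0
    frac_softclip: float = 0.15
    frac_partial: float = 0.10
    umi_length: int = 12

    def __post_init__(self) -> None:
        if not (0.0 <= self.error_rate < 0.25):
            raise ValueError("error_rate must lie in [0, 0.25)")
        if not (0.0 <= self.contamination_rate < 1.0):
            raise ValueError("contamination_rate must lie in [0, 1)")
        if self.mean_umis < 1 or self.reads_per_umi_mean < 1:
            raise ValueError("means must be >= 1")
        if self.frac_softclip + self.frac_partial > 1.0:
            raise ValueError("layout fractions must sum to <= 1")


def _truncated_nb(rng: np.random.Generator, mean: float, disp: float, size: int) -> np.ndarray:
    """Negative binomial truncated at 1 (resampling zeros)."""
    p = disp / (disp + mean)
    out = rng.negative_binomial(disp, p, size=size)
    while True:
        zero = out == 0
        if not zero.any():
            return out
        out[zero] = rng.negative_binomial(disp, p, size=int(zero.sum()))


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate == 0.0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < error_rate)[0]
    for i in hit:
        choices = [b for b in b"ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(3)]
    return bytes(arr).decode()


def simulate_reads(
    truth: TruthTables,
    retained_cells: Sequence[str],
    config: ReadSimConfig = ReadSimConfig(),
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Emit tagged alignment records for every barcode molecule of the
    retained cells, plus the molecule-level truth table.

    Returns ``(reads, molecules)``.  ``reads`` has columns
    read_id, cellID, UMI, reference, pos (1-based), cigar, sequence;
    ``molecules`` has columns
    molecule_id, cellID, true_cell, UMI, true_cloneid, n_reads, contaminated.

    Molecule structure (UMIs, read counts, contamination) and read
    rendering (layout, substitution errors) consume independent seeded
    streams, so two configs differing only in layout fractions produce the
    identical molecule truth.
    """
    rng, rng_read = [
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    ]
    retained = list(retained_cells)
    read_rows: list[tuple] = []
    mol_rows: list[tuple] = []
    mol_no = 0
    read_no = 0
    ref = reference_sequence()
    left = _LEFT_FLANK
    right = _RIGHT_FLANK
    for cell_id in retained:
        for cloneid in truth.cloneids_of_cell(cell_id):
            n_umis = 1 + rng.poisson(config.mean_umis - 1.0)
            for _ in range(n_umis):
                umi = _seqs_from_codes(
                    rng.integers(0, 4, size=(1, config.umi_length))
                )[0]
                n_reads = int(
                    _truncated_nb(
                        rng, config.reads_per_umi_mean, config.reads_per_umi_dispersion, 1
                    )[0]
                )
                tagged_cell = cell_id
                contaminated = False
                if config.contamination_rate > 0 and rng.random() < config.contamination_rate:
                    others = [c for c in retained if c != cell_id]
                    if others:
                        tagged_cell = others[rng.integers(len(others))]
                        contaminated = True
                mol_id = f"m{mol_no:08d}"
                mol_rows.append(
                    (mol_id, tagged_cell, cell_id, umi, cloneid, n_reads, contaminated)
                )
                mol_no += 1
                for _ in range(n_reads):
                    u = rng_read.random()
                    if u < config.frac_softclip:
                        # aligned to the left flank only, barcode soft-clipped
                        seq = _mutate(rng_read, left + cloneid, config.error_rate)
                        pos, cigar = 1, f"{len(left)}M{CLONEID_LENGTH}S"
                    elif u < config.frac_softclip + config.frac_partial:
                        # covers only a prefix of the barcode region
                        k = int(rng_read.integers(12, CLONEID_LENGTH))
                        seq = _mutate(rng_read, left + cloneid[:k], config.error_rate)
                        pos, cigar = 1, f"{len(left) + k}M"
                    else:
                        seq = _mutate(rng_read, left + cloneid + right, config.error_rate)
                        pos, cigar = 1, f"{len(ref)}M"
                    read_rows.append(
                        (f"r{read_no:09d}", tagged_cell, umi, REFERENCE_NAME, pos, cigar, seq)
                    )
                    read_no += 1
    reads = pd.DataFrame(
        read_rows,
        columns=["read_id", "cellID", "UMI", "reference", "pos", "cigar", "sequence"],
    )
    molecules = pd.DataFrame(
        mol_rows,
        columns=[
            "molecule_id",
            "cellID",
            "true_cell",
            "UMI",
            "true_cloneid",
            "n_reads",
            "contaminated",
        ],
    )
    return reads, molecules


@dataclass(frozen=True)
class SpatialConfig:
    """Geometry of a synthetic spatial-transcriptomics section: a grid of
    capture spots at 100-um pitch with 55-um spot diameter, partitioned into
    three rectangular anatomical regions along x."""

    n_rows: int = 20
    n_cols: int = 20
    pitch_um: float = 100.0
    spot_diameter_um: float = 55.0
    cells_per_spot: float = 4.0
    regions: tuple[str, ...] = ("CX", "STR", "HC")
    section: int = 1
    umis_per_copy: float = 2.0


@dataclass
class SpatialSection:
    """One simulated section: spot table (Visium tissue-position dialect plus
    region), spot x barcode UMI counts (long form) and true cell centroids."""

    spots: pd.DataFrame
    spot_counts: pd.DataFrame
    cell_positions: pd.DataFrame

    def mean_cells_per_occupied_spot(self) -> float:
        occ = self.cell_positions.groupby("spot_id").size()
        return float(occ.mean()) if len(occ) else 0.0


def simulate_spatial_section(
    truth: TruthTables,
    barcoded_cells: Sequence[str] | None = None,
    config: SpatialConfig = SpatialConfig(),
    seed: int | None = None,
) -> SpatialSection:
    """Bin barcoded cells into capture spots on a regular grid.

    Each spot receives Poisson(cells_per_spot) cells drawn without
    replacement from the barcoded-cell pool until the pool is exhausted;
    cells are jittered inside the spot, the spot inherits the region of its
    x-band, and each barcode copy of a placed cell contributes
    1 + Poisson(umis_per_copy - 1) UMIs to the spot's count.
    """
    rng = np.random.default_rng(seed)
    pool = list(barcoded_cells) if barcoded_cells is not None else list(truth.cells.index)
    rng.shuffle(pool)
    width = config.n_cols * config.pitch_um
    band = width / len(config.regions)
    spot_rows = []
    count_rows: dict[tuple[str, str], int] = {}
    cell_rows = []
    pool_pos = 0
    for r in range(config.n_rows):
        for c in range(config.n_cols):
            sid = f"spot_{r:03d}_{c:03d}"
            x = (c + 0.5) * config.pitch_um
            y = (r + 0.5) * config.pitch_um
            region = config.regions[min(int(x // band), len(config.regions) - 1)]
            n_here = int(rng.poisson(config.cells_per_spot))
            placed = pool[pool_pos : pool_pos + n_here]
            pool_pos += len(placed)
            for cid in placed:
                ang = rng.random() * 2 * math.pi
                rad = math.sqrt(rng.random()) * config.spot_diameter_um * 0.45
                cell_rows.append(
                    (
                        cid,
                        x + rad * math.cos(ang),
                        y + rad * math.sin(ang),
                        sid,
                        config.section,
                        region,
                    )
                )
                for cloneid in truth.cloneids_of_cell(cid):
                    u = 1 + int(rng.poisson(config.umis_per_copy - 1.0))
                    count_rows[(sid, cloneid)] = count_rows.get((sid, cloneid), 0) + u
            spot_rows.append((sid, 1, r, c, x, y, region))
    spots = pd.DataFrame(
        spot_rows,
        columns=["barcode", "in_tissue", "array_row", "array_col", "x_um", "y_um", "region"],
    )
    spot_counts = pd.DataFrame(
        [(s, cid, n) for (s, cid), n in sorted(count_rows.items())],
        columns=["spot_id", "cloneid", "umis"],
    )
    cell_positions = pd.DataFrame(
        cell_rows, columns=["cell_id", "x_um", "y_um", "spot_id", "section", "region"]
    )
    return SpatialSection(spots, spot_counts, cell_positions)
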