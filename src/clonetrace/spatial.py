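"""Spot-level spatial clone mapping and dispersion statistics.

Barcodes captured on spatial-transcriptomics spots (55-um capture areas on
a 100-um-pitch grid) are assembled into a spot x barcode matrix, clones
are called on spot barcode sets with the same machinery used for cells,
and clonal dispersion is quantified: per-clone region proportions (row
scaled), region-set Venn classes (one, two or three regions), nearest-
nucleus cell-type assignment for barcode-positive spots, and clone spatial
extent in-plane and across serial sections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "CloneDispersion",
    "build_spot_matrix",
    "region_proportions",
    "classify_dispersion",
    "overlap_score",
    "assign_spot_to_nucleus",
    "clone_extent",
]


@dataclass
class CloneDispersion:
    """Per-clone regional dispersion: raw counts, row-scaled proportions and
    the set of occupied regions."""

    counts: pd.DataFrame  # clones x regions, member counts
    proportions: pd.DataFrame  # rows sum to 1
    region_sets: pd.Series  # frozenset of occupied regions per clone


def build_spot_matrix(
    spot_counts: pd.DataFrame, all_spots: list[str] | None = None
) -> pd.DataFrame:
    """Spots x barcodes UMI matrix from a long-form table (columns spot_id,
    cloneid, umis).  Spots listed in ``all_spots`` but lacking barcodes are
    kept as zero rows so denominators over all spots stay honest."""
    if spot_counts.empty:
        mat = pd.DataFrame(dtype=int)
    else:
        dup = spot_counts.duplicated(subset=["spot_id", "cloneid"])
        if dup.any():
            raise ValueError("duplicate (spot, barcode) entries")
        mat = spot_counts.pivot(index="spot_id", columns="cloneid", values="umis").fillna(0)
        mat = mat.astype(int)
        mat.columns.name = None
        mat.index.name = None
    if all_spots is not None:
        if len(set(all_spots)) != len(all_spots):
            raise ValueError("duplicate spot ids")
        mat = mat.reindex(all_spots, fill_value=0)
        if mat.columns.empty:
            mat = pd.DataFrame(index=all_spots, dtype=int)
    return mat


def region_proportions(
    members: pd.DataFrame,
    min_region_members: int = 0,
    clone_column: str = "clone_id",
    region_column: str = "region",
) -> CloneDispersion:
    """Row-scaled per-clone region proportions.

    ``members`` is long-form with one row per clone member (cell or
    barcode-positive spot) carrying a region label ("unassigned" where
    unknown).  Regions with fewer than ``min_region_members`` total members
    are excluded from the column set before scaling — the floor used when
    only well-covered regions are comparable (e.g. > 20 barcodes).
    """
    if members.empty:
        logger.warning("no members; empty dispersion table")
        empty = pd.DataFrame()
        return CloneDispersion(empty, empty, pd.Series(dtype=object))
    counts = pd.crosstab(members[clone_column], members[region_column])
    if min_region_members > 0:
        keep = counts.sum(axis=0) > min_region_members
        dropped = list(counts.columns[~keep])
        if dropped:
            logger.info("regions below the member floor excluded: %s", dropped)
        counts = counts.loc[:, keep]
        counts = counts[counts.sum(axis=1) > 0]
    row_sums = counts.sum(axis=1)
    proportions = counts.div(row_sums, axis=0)
    region_sets = counts.apply(
        lambda row: frozenset(row.index[row > 0]), axis=1
    )
    counts.columns.name = None
    proportions.columns.name = None
    return CloneDispersion(counts, proportions, region_sets)


def classify_dispersion(dispersion: CloneDispersion) -> pd.DataFrame:
    """Venn-class tabulation: for each occupied region set, the number and
    fraction of clones confined to exactly that set."""
    if dispersion.region_sets.empty:
        logger.warning("no clones to classify")
        return pd.DataFrame(columns=["regions", "n_regions", "n_clones", "fraction"])
    counts = dispersion.region_sets.value_counts()
    total = int(counts.sum())
    rows = [
        ("/".join(sorted(rs)), len(rs), int(n), n / total)
        for rs, n in counts.items()
    ]
    rows.sort(key=lambda r: (r[1], r[0]))
    return pd.DataFrame(rows, columns=["regions", "n_regions", "n_clones", "fraction"])


def overlap_score(pixels_a: set, pixels_b: set, colocal_threshold: float = 0.5) -> tuple[float, bool]:
    """Nuclei co-localization score across imaging channels:
    |A n B| / min(|A|, |B|), flagged co-localized at >= ``colocal_threshold``."""
    if not pixels_a or not pixels_b:
        raise ValueError("pixel sets must be non-empty")
    score = len(pixels_a & pixels_b) / min(len(pixels_a), len(pixels_b))
    return score, score >= colocal_threshold


def assign_spot_to_nucleus(
    spots: pd.DataFrame,
    nuclei: pd.DataFrame,
    max_radius_um: float = 50.0,
) -> pd.DataFrame:
    """Assign each barcode-positive spot the nearest segmented nucleus.

    ``spots`` needs columns spot_id, x_um, y_um; ``nuclei`` needs
    nucleus_id, x_um, y_um, channel (the cell-type label).  Euclidean
    distance decides; ties go to the smaller nucleus id (logged); spots
    with no nucleus within ``max_radius_um`` are "undetermined".
    """
    if nuclei.empty:
        raise ValueError("at least one nucleus required")
    nuc = nuclei.sort_values("nucleus_id").reset_index(drop=True)
    nxy = nuc[["x_um", "y_um"]].values
    rows = []
    for t in spots.itertuples(index=False):
        d = np.hypot(nxy[:, 0] - t.x_um, nxy[:, 1] - t.y_um)
        best = float(d.min())
        if best > max_radius_um:
            rows.append((t.spot_id, None, None, np.nan))
            continue
        hits = np.nonzero(d == best)[0]
        if len(hits) > 1:
            logger.info("spot %s equidistant to %d nuclei; tie broken by id", t.spot_id, len(hits))
        i = int(hits[0])
        rows.append((t.spot_id, nuc.at[i, "nucleus_id"], nuc.at[i, "channel"], best))
    return pd.DataFrame(rows, columns=["spot_id", "nucleus_id", "cell_type", "distance_um"])


def clone_extent(
    members: pd.DataFrame, section_thickness_um: float = 10.0
) -> dict:
    """Spatial extent of one clone's members.

    ``members`` needs columns x_um, y_um, section.  Returns the in-plane
    bounding-box width/height and the anteroposterior span under the
    inclusive convention (number of spanned sections x thickness, so
    members confined to one section span one thickness).
    """
    if section_thickness_um <= 0:
        raise ValueError("section thickness must be positive")
    x = members["x_um"].values
    y = members["y_um"].values
    sec = members["section"].astype(int).values
    return {
        "width_um": float(x.max() - x.min()),
        "height_um": float(y.max() - y.min()),
        "n_sections": int(sec.max() - sec.min() + 1),
        "ap_span_um": float((sec.max() - sec.min() + 1) * section_thickness_um),
    }
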