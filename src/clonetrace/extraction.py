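"""Barcode recovery from tagged alignments and error correction.

Reads aligned to an N-masked transgene reference carry a 30-bp expressed
barcode in the masked window.  This module recovers the barcode bases each
read contributes (including bases soft-clipped at the window boundary,
projected ungapped into it), collapses reads sharing a (cell, UMI) tag to a
per-position plurality consensus, error-corrects barcode sequences by
single-linkage clustering at Hamming distance <= 5, applies the
single-UMI-single-read and ambient-contamination filters, and builds the
cell x barcode UMI count matrix that clone calling consumes.

Unknown positions are written as '0'; they are ignored in Hamming
distances and treated as wildcards when partial sequences are matched to
fully known ones.
"""

from __future__ import annotations

import logging
import re
from collections import Counter, defaultdict
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import CLONEID_LENGTH, REFERENCE_NAME, REGION_END, REGION_START

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentRecord",
    "MoleculeRecord",
    "locate_cloneid_bases",
    "extract_reads",
    "collapse_molecules",
    "hamming_partial",
    "correct_cloneids",
    "filter_molecules",
    "build_matrix",
]

_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


@dataclass(frozen=True)
class AlignmentRecord:
    """One tagged alignment: read id, cell and UMI tags, reference name,
    1-based start and CIGAR segments."""

    read_id: str
    cell_id: str
    umi: str
    reference: str
    pos: int  # 1-based leftmost aligned reference position
    cigar: str
    sequence: str


@dataclass(frozen=True)
class MoleculeRecord:
    """One consensus molecule: the barcode sequence supported by all reads
    sharing a (cell, UMI) tag, with its read count."""

    cell_id: str
    umi: str
    cloneid: str
    n_reads: int


def _parse_cigar(cigar: str) -> list[tuple[str, int]]:
    if not re.fullmatch(r"(?:\d+[MIDNSHP=X])+", cigar):
        raise ValueError(f"malformed CIGAR: {cigar!r}")
    return [(m.group(2), int(m.group(1))) for m in _CIGAR_RE.finditer(cigar)]


def locate_cloneid_bases(
    record: AlignmentRecord,
    region_start: int = REGION_START,
    region_end: int = REGION_END,
    min_known: int = 10,
    reference_name: str = REFERENCE_NAME,
) -> str | None:
    """Recover the barcode bases a single read contributes.

    Walks the alignment segments; read bases aligned inside the 1-based
    closed interval [region_start, region_end] are recorded at their
    reference position.  A soft clip abutting the region (the alignment
    ends at the region boundary or inside the region) is projected ungapped
    into it, since the reference is 'N'-masked there and the aligner had
    nothing to anchor.  Uncovered positions become '0'.  Returns ``None``
    for reads on other references, reads not touching the region, or
    recoveries with fewer than ``min_known`` known bases.
    """
    if record.reference != reference_name:
        return None
    try:
        ops = _parse_cigar(record.cigar)
    except ValueError:
        logger.warning("rejecting read %s: malformed CIGAR", record.read_id)
        return None
    n = region_end - region_start + 1
    out = ["0"] * n
    seq = record.sequence
    ref_pos = record.pos  # next reference position to consume (1-based)
    read_pos = 0  # next read index to consume (0-based)

    def fill(ref_at: int, base: str) -> None:
        if region_start <= ref_at <= region_end:
            out[ref_at - region_start] = base

    for i, (op, length) in enumerate(ops):
        if op in ("M", "=", "X"):
            for j in range(length):
                if read_pos + j < len(seq):
                    fill(ref_pos + j, seq[read_pos + j])
            ref_pos += length
            read_pos += length
        elif op == "I":
            read_pos += length
        elif op in ("D", "N"):
            ref_pos += length
        elif op == "S":
            if i == 0:
                # leading clip projected backwards, ending at pos - 1; abuts
                # the region iff the alignment starts inside it or at the
                # base just after it
                if region_start + 1 <= record.pos <= region_end + 1:
                    start_ref = ref_pos - length
                    for j in range(length):
                        fill(start_ref + j, seq[j])
                read_pos += length
            else:
                # trailing clip projected forwards from the first unaligned
                # reference position; abuts the region iff the alignment
                # ended inside it or at the base just before it
                if region_start <= ref_pos <= region_end:
                    for j in range(length):
                        if read_pos + j < len(seq):
                            fill(ref_pos + j, seq[read_pos + j])
                read_pos += length
        # H and P consume nothing we track
    known = n - out.count("0")
    if known < min_known:
        return None
    return "".join(out)


def extract_reads(
    reads: pd.DataFrame,
    region_start: int = REGION_START,
    region_end: int = REGION_END,
    min_known: int = 10,
    reference_name: str = REFERENCE_NAME,
) -> pd.DataFrame:
    """Apply :func:`locate_cloneid_bases` to a table of tagged alignments
    (columns read_id, cellID, UMI, reference, pos, cigar, sequence); returns
    rows with a recovered barcode (columns cellID, UMI, cloneid)."""
    rows = []
    for t in reads.itertuples(index=False):
        rec = AlignmentRecord(
            t.read_id, t.cellID, t.UMI, t.reference, int(t.pos), t.cigar, t.sequence
        )
        if not rec.cell_id or not rec.umi:
            continue
        got = locate_cloneid_bases(rec, region_start, region_end, min_known, reference_name)
        if got is not None:
            rows.append((rec.cell_id, rec.umi, got))
    return pd.DataFrame(rows, columns=["cellID", "UMI", "cloneid"])


def collapse_molecules(extracted: pd.DataFrame) -> list[MoleculeRecord]:
    """Collapse reads sharing a (cellID, UMI) tag to one consensus molecule.

    Per position, the plurality base among reads covering it wins; a tie
    between bases, or no coverage, yields '0'.  Read support is the group
    size.
    """
    if extracted.empty:
        return []
    out: list[MoleculeRecord] = []
    for (cell, umi), grp in extracted.groupby(["cellID", "UMI"], sort=True):
        seqs = list(grp["cloneid"])
        if len(seqs) == 1:
            out.append(MoleculeRecord(cell, umi, seqs[0], 1))
            continue
        consensus = []
        for i in range(CLONEID_LENGTH):
            votes = Counter(s[i] for s in seqs if s[i] != "0")
            if not votes:
                consensus.append("0")
                continue
            best = votes.most_common()
            if len(best) > 1 and best[0][1] == best[1][1]:
                consensus.append("0")
            else:
                consensus.append(best[0][0])
        out.append(MoleculeRecord(cell, umi, "".join(consensus), len(seqs)))
    return out


def hamming_partial(a: str, b: str) -> int:
    """Hamming distance over positions known ('0'-free) in both sequences."""
    return sum(1 for x, y in zip(a, b) if x != "0" and y != "0" and x != y)


def _linked(a: str, b: str, max_hamming: int) -> bool:
    """Linking rule for error correction.

    Full-length sequences link at Hamming distance <= max_hamming.  When
    unknown positions shrink the comparable overlap, the threshold scales
    with it (constant per-base tolerance): mismatches <= max_hamming *
    overlap / length.  A fixed threshold over a short overlap would link
    unrelated barcodes by chance and let single linkage bridge distinct
    clones.
    """
    overlap = mism = 0
    for x, y in zip(a, b):
        if x != "0" and y != "0":
            overlap += 1
            if x != y:
                mism += 1
    if overlap == 0:
        return False
    return mism * len(a) <= max_hamming * overlap


def correct_cloneids(
    molecules: list[MoleculeRecord], max_hamming: int = 5
) -> list[MoleculeRecord]:
    """Error-correct barcode sequences by single-linkage clustering.

    Distinct sequences are linked when their (partial-aware) Hamming
    distance is at most ``max_hamming``; within each connected component
    every molecule's barcode is replaced by the component's most frequent
    fully known sequence (frequency = UMI count, ties broken
    lexicographically).  Components with no fully known member are dropped.
    """
    if max_hamming < 0:
        raise ValueError("max_hamming must be >= 0")
    if not molecules:
        return []
    counts: Counter[str] = Counter(m.cloneid for m in molecules)
    seqs = sorted(counts)
    g = nx.Graph()
    g.add_nodes_from(seqs)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if _linked(seqs[i], seqs[j], max_hamming):
                g.add_edge(seqs[i], seqs[j])
    representative: dict[str, str | None] = {}
    for comp in nx.connected_components(g):
        full = [s for s in comp if "0" not in s]
        if not full:
            logger.info("dropping cluster with no fully known sequence (%d members)", len(comp))
            rep = None
        else:
            rep = max(full, key=lambda s: (counts[s], [-ord(c) for c in s]))
        for s in comp:
            representative[s] = rep
    out = []
    for m in molecules:
        rep = representative[m.cloneid]
        if rep is not None:
            out.append(MoleculeRecord(m.cell_id, m.umi, rep, m.n_reads))
    return out


def filter_molecules(
    molecules: list[MoleculeRecord],
    single_umi_read_min: int = 2,
    contamination_umi_threshold: int = 5,
) -> tuple[list[MoleculeRecord], pd.DataFrame]:
    """Remove weakly supported and likely-contaminant combinations.

    A (cell, barcode) combination supported by exactly one UMI whose
    consensus had exactly one read is discarded; a single-UMI combination is
    also discarded when the same barcode reaches
    ``contamination_umi_threshold`` UMIs in some other cell (ambient
    capture).  Returns the retained molecules and a log of removals with
    reason codes.
    """
    if single_umi_read_min < 1 or contamination_umi_threshold < 1:
        raise ValueError("thresholds must be >= 1")
    per_combo: dict[tuple[str, str], list[MoleculeRecord]] = defaultdict(list)
    for m in molecules:
        per_combo[(m.cell_id, m.cloneid)].append(m)
    umis_per_cell: dict[str, Counter] = defaultdict(Counter)
    for (cell, cid), ms in per_combo.items():
        umis_per_cell[cid][cell] = len(ms)
    kept: list[MoleculeRecord] = []
    log_rows = []
    for (cell, cid), ms in per_combo.items():
        if len(ms) == 1:
            if ms[0].n_reads < single_umi_read_min:
                log_rows.append((cell, cid, "single_umi_single_read"))
                continue
            others = umis_per_cell[cid]
            if any(
                c != cell and n >= contamination_umi_threshold for c, n in others.items()
            ):
                log_rows.append((cell, cid, "contamination"))
                continue
        kept.extend(ms)
    log = pd.DataFrame(log_rows, columns=["cellID", "cloneid", "reason"])
    return kept, log


def _wildcard_match(partial: str, full: str) -> bool:
    return all(p == "0" or p == f for p, f in zip(partial, full))


def build_matrix(
    molecules: list[MoleculeRecord], allowed_cells: set[str] | list[str]
) -> pd.DataFrame:
    """UMI count matrix (cells x barcodes) restricted to the filtered cell
    list.  Partial barcodes compatible with exactly one fully known column
    are merged into it; ambiguous or unmatched partials are dropped."""
    allowed = set(allowed_cells)
    if not allowed:
        raise ValueError("allowed cell list must not be empty")
    mols = [m for m in molecules if m.cell_id in allowed]
    if not mols:
        logger.warning("no molecules from allowed cells; empty matrix")
        return pd.DataFrame(dtype=int)
    full_seqs = sorted({m.cloneid for m in mols if "0" not in m.cloneid})
    counts: Counter[tuple[str, str]] = Counter()
    for m in mols:
        cid = m.cloneid
        if "0" in cid:
            hits = [f for f in full_seqs if _wildcard_match(cid, f)]
            if len(hits) != 1:
                logger.info(
                    "dropping partial barcode %s (%d compatible columns)", cid, len(hits)
                )
                continue
            cid = hits[0]
        counts[(m.cell_id, cid)] += 1
    if not counts:
        return pd.DataFrame(dtype=int)
    cells = sorted({c for c, _ in counts})
    cols = sorted({s for _, s in counts})
    mat = pd.DataFrame(0, index=cells, columns=cols, dtype=int)
    for (c, s), n in counts.items():
        mat.at[c, s] = n
    return mat
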