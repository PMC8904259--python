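"""Readers and writers for the tool's interchange formats.

Tagged alignment records travel either as a TSV dialect (read_id, cellID,
UMI, reference, pos, cigar, sequence) or as genuine BAM with CB/UB tags;
count matrices as MatrixMarket triplets with row/column label files (and
TSV for small cases); cell lists as plain text compatible with 10x
"barcodes.tsv" (a trailing "-1" suffix is tolerated); spot positions as a
Visium-style tissue-positions CSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import scipy.io
import scipy.sparse as sp

from .simulate import REFERENCE_NAME, reference_sequence

READ_COLUMNS = ["read_id", "cellID", "UMI", "reference", "pos", "cigar", "sequence"]

__all__ = [
    "read_cell_list",
    "write_cell_list",
    "read_reads_tsv",
    "write_reads_tsv",
    "read_bam",
    "write_bam",
    "write_matrix",
    "read_matrix",
    "read_spot_positions",
    "write_spot_positions",
]


def read_cell_list(path: str | Path) -> list[str]:
    """One cell identifier per line; an optional 10x-style "-1" suffix is
    stripped."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line:
            out.append(line[:-2] if line.endswith("-1") else line)
    return out


def write_cell_list(cells: list[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{c}\n" for c in cells))


def read_reads_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"pos": int})
    missing = set(READ_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"reads table missing columns: {sorted(missing)}")
    return df[READ_COLUMNS]


def write_reads_tsv(reads: pd.DataFrame, path: str | Path) -> None:
    reads[READ_COLUMNS].to_csv(path, sep="\t", index=False)


def read_bam(path: str | Path, reference_name: str = REFERENCE_NAME) -> pd.DataFrame:
    """Tagged alignments from a BAM with CB (cell) and UB (UMI) tags, as the
    TSV-dialect DataFrame.  Unmapped reads and reads lacking either tag are
    skipped."""
    import pysam

    rows = []
    with pysam.AlignmentFile(str(path), "rb") as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_unmapped or not rec.has_tag("CB") or not rec.has_tag("UB"):
                continue
            cb = str(rec.get_tag("CB"))
            cb = cb[:-2] if cb.endswith("-1") else cb
            rows.append(
                (
                    rec.query_name,
                    cb,
                    str(rec.get_tag("UB")),
                    rec.reference_name,
                    rec.reference_start + 1,
                    rec.cigarstring,
                    rec.query_sequence,
                )
            )
    return pd.DataFrame(rows, columns=READ_COLUMNS)


def write_bam(reads: pd.DataFrame, path: str | Path) -> None:
    """Write the TSV-dialect reads as a coordinate-unsorted BAM with CB/UB
    tags against the synthetic transgene reference."""
    import pysam

    header = {
        "HD": {"VN": "1.6"},
        "SQ": [{"SN": REFERENCE_NAME, "LN": len(reference_sequence())}],
    }
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for t in reads.itertuples(index=False):
            a = pysam.AlignedSegment(bam.header)
            a.query_name = t.read_id
            a.query_sequence = t.sequence
            a.reference_id = 0
            a.reference_start = int(t.pos) - 1
            a.cigarstring = t.cigar
            a.mapping_quality = 60
            a.flag = 0
            a.set_tag("CB", t.cellID)
            a.set_tag("UB", t.UMI)
            bam.write(a)


def write_matrix(matrix: pd.DataFrame, outdir: str | Path, also_tsv: bool = True) -> None:
    """MTX triplet plus row (cells) and column (barcodes) label files; a TSV
    copy for desk-scale inspection unless disabled."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), sp.csr_matrix(matrix.values))
    (outdir / "cells.txt").write_text("".join(f"{c}\n" for c in matrix.index))
    (outdir / "cloneids.txt").write_text("".join(f"{c}\n" for c in matrix.columns))
    if also_tsv:
        matrix.to_csv(outdir / "matrix.tsv", sep="\t")


def read_matrix(indir: str | Path) -> pd.DataFrame:
    indir = Path(indir)
    m = scipy.io.mmread(str(indir / "matrix.mtx")).toarray().astype(int)
    cells = [l for l in (indir / "cells.txt").read_text().splitlines() if l]
    ids = [l for l in (indir / "cloneids.txt").read_text().splitlines() if l]
    return pd.DataFrame(m, index=cells, columns=ids)


def write_spot_positions(spots: pd.DataFrame, path: str | Path) -> None:
    """Visium tissue-positions dialect: barcode, in_tissue, array_row,
    array_col, pixel row/col (micrometre coordinates reused as pixels)."""
    out = spots.rename(
        columns={"y_um": "pxl_row_in_fullres", "x_um": "pxl_col_in_fullres"}
    )[
        ["barcode", "in_tissue", "array_row", "array_col", "pxl_row_in_fullres", "pxl_col_in_fullres"]
    ]
    out.to_csv(path, index=False)


def read_spot_positions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return df.rename(
        columns={"pxl_row_in_fullres": "y_um", "pxl_col_in_fullres": "x_um"}
    )
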