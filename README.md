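# clonetrace

Clonal lineage tracing with expressed lentiviral barcodes, from raw tagged
alignments to clone-level biology — plus a full synthetic-experiment
generator so every stage can be validated against known ground truth.

## The problem

A diverse lentiviral library delivers random 30-bp expressed barcodes
("cloneIDs") into progenitor cells; every descendant inherits and expresses
its progenitor's barcode(s). Single-cell RNA-seq (or spatial
transcriptomics) then reads both the transcriptome and the barcode of each
cell, so cells sharing barcode content can be grouped into clones and
cross-referenced with cell type and anatomy. Turning sequencing reads into
trustworthy clones requires dedicated machinery:

- **Barcode recovery.** Reads are aligned to a transgene reference whose
  barcode region is masked with `N`. Barcode bases are recovered from
  alignments covering the masked window; soft clips abutting the window are
  projected ungapped into it, and partially covered positions are tracked
  as unknown (`0`).
- **Denoising.** Reads sharing a (cell, UMI) tag are collapsed to a
  per-position plurality consensus. Distinct barcode sequences are then
  single-linkage clustered at Hamming distance ≤ 5 and each cluster is
  replaced by its most frequent member. Weakly supported barcode–cell
  combinations (one UMI, one read) and ambient contaminants (one UMI here,
  abundant in another cell) are removed.
- **Clone calling.** Cells become nodes, edges join pairs with Jaccard
  similarity of barcode sets ≥ 0.7, and connected components with ≥ 2
  members are clones.
- **Clonal coupling.** For clones with ≥ 3 cells, a binary clone × cell-type
  incidence matrix is compared against 1,000 randomizations that preserve
  both marginals (checkerboard-swap MCMC), giving a z-score and empirical P
  per type pair; z-profiles are correlated across samples, Fisher
  z-averaged, and ordered by complete-linkage clustering.
- **Design math.** Closed forms for progenitor back-calculation
  (N_t0 = N_t1 / 2^(Δt·f)), unique-labeling fractions
  (F = (1 − 1/N)^(k−1) and E(X) = k·Σ pᵢ(1 − (1 − pᵢ)^(k−1))), the
  zero-truncated-Poisson copy-number model with λ = −ln(1 − rate),
  multivariate-hypergeometric detection power, recovery-chain clone-size
  extrapolation, and library QC (Gini index, pairwise Hamming diversity).
- **Spatial clone mapping.** Spot × barcode matrices from Visium-style
  sections, row-scaled per-clone region proportions and region-set Venn
  classes, nucleus overlap scores (|A∩B|/min(|A|,|B|)), nearest-nucleus
  cell-type assignment of barcode-positive spots, and clone extent in-plane
  and across serial sections.

The `simulate` module generates complete experiments — skewed-abundance
library, Poisson-MOI transduction, clonal expansion with fate profiles,
multi-stage sampling loss, reads with substitution errors and ambient
contamination, and spatial sections — with truth tables linking every
molecule and cell to its progenitor.

## Worked example

Experiment-design arithmetic from the command line:

```bash
clonetrace design --n-t1 41450 --n-barcodes 940000 --rate 0.018 \
    --stage-rates 0.106,0.35,0.5,0.24 --observed-size 4.9
```

```json
{
  "n_progenitors": 2591,
  "unique_fraction_uniform": 0.9972484717973358,
  "expected_non_unique": 7.129209573102999,
  "percent_unique": 99.72484717973357,
  "copy_number": {
    "lambda": 0.018163970627671163,
    "p_single": 0.9909455086873931,
    "p_multi": 0.009054491312606938
  },
  "overall_recovery": 0.004451999999999999,
  ...
}
```

41,450 labeled cells observed after two days at two divisions per day imply
2,591 transduced progenitors; with 0.94 million injected barcodes 99.7% of
them carry a unique label; at a 1.8% transduction rate 99.1% of labeled
cells carry exactly one barcode; and the four-stage recovery chain
(dissociation, sorting, encapsulation, barcode detection) retains 0.45% of
barcoded cells.

A full simulated experiment through extraction and clone calling:

```python
from clonetrace import pipeline, simulate

cfg = pipeline.PipelineConfig(
    seed=1, n_barcodes=20_000, n_cells_exposed=2_000,
    transduction_rate=0.03, stage_rates=(1.0,),
    read_config=simulate.ReadSimConfig(mean_umis=4.0, reads_per_umi_mean=4.0),
)
res = pipeline.run_pipeline(cfg, outdir="demo")
print(res.report)
```

prints (abridged)

```json
{
  "n_clones": 59,
  "n_cells_in_clones": 953,
  "mean_clone_size": 16.15,
  "sem_clone_size": 0.66,
  "library_gini": 0.197,
  "single_fraction": 0.973,
  "multi_fraction": 0.027
}
```

59 clones of 16.2 ± 0.7 cells (the expected 2^(Δt·f) = 16 for two days at
two divisions per day), a library Gini index near the 0.2 of a well-made
preparation, and a single-barcode fraction consistent with the Poisson
copy-number model at this transduction rate. The run directory contains
the molecule table, the MTX count matrix, the clone table and a manifest
with per-stage record counts.

## Layout

- `src/clonetrace/simulate.py` — synthetic experiments with ground truth
- `src/clonetrace/extraction.py` — barcode recovery, consensus, error
  correction, filtering, count matrix
- `src/clonetrace/clones.py` — Jaccard clone calling and clone statistics
- `src/clonetrace/coupling.py` — marginal-preserving coupling statistics
- `src/clonetrace/design.py` — closed-form design and QC mathematics
- `src/clonetrace/spatial.py` — spot-level clone mapping and dispersion
- `src/clonetrace/pipeline.py`, `cli.py`, `io.py` — orchestration, CLI,
  interchange formats (TSV/BAM/MTX/Visium positions)

See `docs/methods.md` for models, assumptions and numerical choices.
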