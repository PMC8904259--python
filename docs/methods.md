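# Methods

This note documents the models behind `clonetrace`, the parameters that
matter, what the synthetic-data generator does and does not emulate, and
the numerical decisions taken where the design was genuinely open.

## Barcode recovery from alignments

Reads are assumed pre-aligned to a transgene reference whose 30-bp barcode
window is `N`-masked (so any barcode aligns through it). For each read the
window bases are reconstructed by walking the CIGAR: aligned bases map to
their reference positions, insertions consume read bases only, deletions
and skips consume reference only. Because the masked window gives the
aligner nothing to anchor, alignments frequently end at its boundary with
the barcode soft-clipped; a clip whose alignment ends inside the window or
at the base immediately adjacent is projected ungapped into it (leading
clips symmetrically, backwards). Positions never covered become `0`
(unknown). A recovery with fewer than `min_known` known bases (default 10)
is discarded — the floor is ours; partial alignments are legitimate input
but ten bases is the least that still identifies a barcode against a
desk-scale library with comfortable margin.

Indels *inside* the masked window cannot be placed reliably (the reference
is wildcards); bases after an in-window indel stay at their nominal
reference offsets. This is the same simplification an aligner makes when
it soft-clips instead.

## Consensus, error correction, filtering

Reads sharing a (cell, UMI) tag collapse to a per-position plurality
consensus; a position tied between bases, or covered by no read, becomes
`0`. Distinct sequences are then single-linkage clustered and every
molecule in a cluster is relabeled with the cluster's most frequent fully
known sequence (frequency = UMI count; ties broken lexicographically;
clusters with no fully known member are dropped and logged).

The linking rule is Hamming distance ≤ 5 for fully known pairs. When
unknown positions shrink the comparable overlap, the threshold scales with
it: link iff mismatches ≤ 5 × overlap / 30, i.e. a constant per-base
tolerance. A fixed threshold of 5 over a 12-base overlap would accept
unrelated barcodes with probability ≈ 8% per comparison
(P[Binom(12, 3/4) ≤ 5]), and single linkage would then bridge entire
clones through one stray partial sequence; with the scaled rule a
noise-free simulation is recovered exactly. For fully known sequences the
two rules coincide.

Two filters follow, both targeting artifacts rather than biology: a
(cell, barcode) combination supported by a single UMI whose consensus had
a single read is removed (PCR/sequencing noise), and a single-UMI
combination whose barcode reaches ≥ 5 UMIs in some other cell is removed
as ambient contamination. The contamination threshold of 5 UMIs
quantifies "high frequency in another cell"; it is configurable because
the right value scales with sequencing depth.

In the count matrix, a partial (`0`-containing) barcode compatible with
exactly one fully known column is merged into it; ambiguous or unmatched
partials are dropped and logged.

## Clone calling

Presence of a barcode in a cell is binarized at ≥ 1 UMI. Cells are linked
when the Jaccard similarity of their barcode sets is ≥ 0.7 and clones are
the connected components with ≥ 2 members. Components (single linkage)
rather than all-pairs cliques: the choice is deterministic, scales, and
respects the fact that multi-integration cells make barcode sets
combinatorially diverse, so a shared sub-signature is strong evidence. At
threshold 1.0 only identical sets link. Clone-size s.e.m. uses the sample
standard deviation (n − 1) over √(number of clones).

The cross-lineage error rate takes declared incompatible lineage pairs
(e.g. mesoderm-derived immune cells vs neuroectoderm derivatives), finds
clones with a strict majority on one side, and counts minority members as
offenders; the denominator is the dominant side's cells in those clones.
Evenly split clones are unresolvable and excluded.

## Clonal coupling

Clones with ≥ 3 cells form a binary clone × type incidence matrix (entry 1
iff the clone contains ≥ 1 cell of the type). The null preserves both
marginals — types per clone and clones per type — via checkerboard-swap
MCMC: pick two 1-cells in distinct rows and columns, swap to the opposite
diagonal when it is free. Burn-in is 10 × (number of ones) attempted
swaps and replicates are taken every 5 × (number of ones) attempts;
degenerate matrices with no swappable checkerboard reproduce the input and
are flagged. For each type pair, z = (observed − null mean)/null sd (0
when sd = 0, e.g. on the diagonal where the marginals fix the count) and
the empirical enrichment P uses the add-one estimator
(1 + #{null ≥ obs})/(1 + reps), never exactly zero. One-sided enrichment
is the default reading; the randomized ensemble also supports depletion if
the caller inverts the comparison.

Across samples, z-profiles of the types present everywhere are correlated
per pair (Pearson), mapped through atanh, averaged, mapped back through
tanh, and ordered by complete-linkage clustering on 1 − correlation.
Constant z-profiles have undefined correlations; those pairs are dropped
from the average and logged.

## Design mathematics

- Progenitor back-calculation: N_t0 = N_t1 / 2^(Δt·f), rounded.
- Unique labeling: F = (1 − 1/N)^(k−1) for a uniform library;
  E(X) = k·Σ pᵢ(1 − (1 − pᵢ)^(k−1)) for an arbitrary abundance vector.
  For uniform p these obey E(X)/k = 1 − F, asserted numerically in tests.
- Copy number: integrations per exposed cell K ~ Poisson(λ) with
  λ = −ln(1 − rate), so the stated transduction rate is P(K ≥ 1); the
  distribution among labeled cells is the zero-truncated Poisson. At a
  1.8% rate this gives 99.09% single-copy — an idealized model; real
  tissue shows position- and receptor-dependent local rates that push the
  multi-copy fraction well above it.
- Detection power: the probability that s cells sampled without
  replacement from a clone include every type, computed exactly by
  inclusion–exclusion over missed-type subsets,
  P = Σ_S (−1)^|S| C(T − n_S, s)/C(T, s); the enumeration over the
  multivariate hypergeometric support is kept as the test oracle. Across
  N same-composition clones the detect-in-at-least-one probability is
  1 − (1 − p)^N.
- Recovery extrapolation: the overall recovery rate is the product of the
  stage rates and the true clone size is the observed mean divided by it,
  with caller-chosen rounding granularity.
- Library QC: Gini index via the sorted-rank identity (equivalent to the
  mean-absolute-difference double sum), and mean ± sd Hamming distance
  over uniformly sampled distinct sequence pairs (for i.i.d. uniform
  30-mers: mean 22.5, sd 2.37).

## Spatial clone mapping

Spot × barcode matrices keep zero rows so per-spot denominators are
honest. Clone calling on spots reuses the cell machinery unchanged.
Per-clone region proportions are row-scaled counts; a configurable member
floor can drop sparsely covered regions from the column set before
scaling (the CLI applies > 20 by default, the library function none).
Region-set Venn classes are the sets of regions with nonzero proportion.
Nucleus co-localization across imaging channels uses
|A∩B|/min(|A|,|B|) with a 0.5 inclusive cutoff. Barcode-positive spots
take the cell type of the nearest segmented nucleus (Euclidean distance;
ties to the smaller nucleus id, logged); nuclei farther than 50 µm —
spot radius 27.5 µm plus registration slack — leave the spot
"undetermined". Anteroposterior clone extent uses the inclusive
convention: (max − min section + 1) × thickness, so eight 10-µm sections
span 80 µm and a single-section clone spans one thickness.

## The synthetic-data generator

What it emulates, stage by stage:

- **Library**: unique random 30-mers with symmetric-Dirichlet abundances.
  The default concentration 8 targets a Gini index of 0.2 — for large N
  the Gini of Dirichlet weights approaches that of a Gamma(α) sample,
  Γ(α+½)/(Γ(α+1)√π), which crosses 0.2 at α ≈ 8. A bisection helper
  calibrates the concentration to any target Gini.
- **Transduction**: K ~ Poisson(−ln(1 − rate)) integrations per cell,
  barcodes drawn with their abundance probabilities, with replacement.
- **Lineage**: each progenitor's clone size is max(1, Poisson(2^(Δt·f)))
  — the Poisson is on the *size*, not the division count, so the
  exponential-growth expectation N_t1 = N_t0·2^(Δt·f) holds exactly
  (a Poisson division count D would give E[2^D] = e^(Δt·f) ≫ 2^(Δt·f)).
  Fate profiles assign cell types and regions per progenitor and can
  plant fate-biased pools, coupled type pairs, or pools with their own
  mean clone size (large myeloid-like vs small neuroectodermal clones).
- **Sampling**: independent retention with probability equal to the
  product of the stage rates; defaults mirror a realistic chain
  (10.6% dissociation survival, 35% sorting, 50% encapsulation, 24%
  barcode detection → 0.45% overall).
- **Reads**: per barcode copy 1 + Poisson(mean − 1) UMIs (default mean
  3), per UMI a negative binomial (mean 3, dispersion 1) truncated at 1
  reads; i.i.d. per-base substitutions; a contamination fraction of
  molecules re-tagged with another cell's identifier (the exact shape the
  contamination filter targets); a mix of full-span, soft-clipped and
  partial-prefix read layouts. Molecule structure and read rendering use
  separate seeded streams, so layout mixes can vary with the molecule
  truth held fixed.
- **Spatial**: a 100-µm-pitch grid of 55-µm spots split into three
  rectangular regions (CX/STR/HC — arbitrary geometry, sufficient for the
  dispersion analyses); each spot draws Poisson(4) cells from the
  barcoded pool, jittered inside the spot.

What it does not emulate: transcriptomes or expression counts beyond
barcode molecules, histology images, doublets as a distinct droplet
artifact, position-dependent local transduction rates, PCR chimeras, or
indel sequencing errors. Passing tests therefore demonstrate correctness
of the computational chain under the stated noise model, not robustness
to every artifact of real data.

## Problem sizes and tolerances

Tests run desk-scale experiments: libraries of 2×10⁴–10⁵ barcodes,
10³–4×10³ exposed cells (10⁶ only for the copy-number model check, where
the quantity is a single fraction), and 400–4,000 null replicates. These
sizes give Monte-Carlo standard errors small enough for 3-SE assertions
while keeping the suite quick. Stochastic assertions use closed-form
binomial/Poisson SEs; exact assertions (worked examples, enumeration
oracles) use printed precision or 1e-12. The noise-free recovery check
asserts ARI = 1 exactly; its conditions (unique labeling, full retention,
error-free reads) make the pipeline lossless by construction.

## Known limitations

- Single-linkage error correction is exact over the distinct-sequence
  set and quadratic in it; far beyond desk scale an indexed
  neighbor search would be needed.
- The checkerboard chain's mixing is adequate for desk-scale incidence
  matrices (verified against exhaustive enumeration); very large, very
  dense matrices would need longer thinning.
- The coupling empirical P is one-sided (enrichment); depletion is only
  reflected in negative z.
- The idealized copy-number model has no local-rate heterogeneity, so
  real multi-barcode fractions exceed its prediction; the simulator
  reproduces the model, not the heterogeneity.
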