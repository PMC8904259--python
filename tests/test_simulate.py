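"""Generator behavior: determinism, calibrated library skew, Poisson-MOI
labeling, expansion expectations, sampling-loss binomials, read errors and
spot geometry."""

import math

import numpy as np
import pandas as pd
import pytest

from clonetrace import simulate as sim
from clonetrace.design import gini_index
from clonetrace.simulate import (
    FateProfile,
    LibraryProfile,
    ReadSimConfig,
    SpatialConfig,
    calibrate_concentration,
    simulate_library,
    simulate_lineage,
    simulate_reads,
    simulate_sampling,
    simulate_spatial_section,
    simulate_transduction,
)


class TestLibrary:
    def test_seed_reproducibility(self):
        a = simulate_library(500, 8.0, seed=3)
        b = simulate_library(500, 8.0, seed=3)
        assert a.sequences == b.sequences
        assert np.array_equal(a.probabilities, b.probabilities)

    def test_validity(self):
        lib = simulate_library(200, seed=0)
        assert len(set(lib.sequences)) == 200
        assert lib.probabilities.sum() == pytest.approx(1.0, abs=1e-9)
        assert all(len(s) == 30 and set(s) <= set("ACGT") for s in lib.sequences)

    def test_high_concentration_approaches_uniform(self):
        assert simulate_library(1000, 1e6, seed=1).gini() < 0.01

    def test_concentration_calibrates_to_study_skew(self):
        conc = calibrate_concentration(0.2, n_barcodes=1000, seed=5)
        assert abs(simulate_library(1000, conc, seed=5).gini() - 0.2) < 0.02

    def test_default_concentration_near_study_skew(self):
        assert simulate_library(2000, seed=9).gini() == pytest.approx(0.2, abs=0.03)

    def test_rejects_bad_arguments(self):
        with pytest.raises(ValueError):
            simulate_library(0)
        with pytest.raises(ValueError):
            LibraryProfile(("A" * 30, "A" * 30), np.array([0.5, 0.5]))


class TestTransduction:
    def test_zero_rate_labels_nobody(self):
        lib = simulate_library(10, seed=0)
        assert simulate_transduction(1000, 0.0, lib, seed=1).n_labeled == 0

    def test_rate_one_rejected(self):
        lib = simulate_library(10, seed=0)
        with pytest.raises(ValueError):
            simulate_transduction(1000, 1.0, lib, seed=1)

    def test_labeled_fraction_matches_target_rate(self):
        lib = simulate_library(1000, seed=2)
        tr = simulate_transduction(100_000, 0.018, lib, seed=3)
        se = math.sqrt(0.018 * 0.982 / 100_000)
        assert tr.n_labeled / tr.n_cells == pytest.approx(0.018, abs=3 * se)

    def test_multi_integration_matches_truncated_poisson(self):
        lib = simulate_library(1000, seed=4)
        tr = simulate_transduction(1_000_000, 0.018, lib, seed=5)
        lam = -math.log(0.982)
        expected = (1 - math.exp(-lam) - lam * math.exp(-lam)) / (1 - math.exp(-lam))
        se = math.sqrt(expected * (1 - expected) / tr.n_labeled)
        assert tr.multi_integration_fraction == pytest.approx(expected, abs=3 * se)


class TestLineage:
    def test_deterministic_expansion(self):
        truth = simulate_lineage({0: ("A" * 30,)}, f=2, dt=2, deterministic=True, seed=0)
        assert truth.n_cells == 16

    def test_expected_descendants_at_study_parameters(self):
        assignments = {i: ("A" * 30,) for i in range(2591)}
        truth = simulate_lineage(assignments, f=2, dt=2, seed=1)
        # mean clone size 2^4 = 16; Poisson sd 4 per clone
        se = 4.0 * math.sqrt(2591)
        assert truth.n_cells == pytest.approx(41_450, abs=3 * se)

    def test_descendants_inherit_barcode_multiset(self):
        ids = ("A" * 30, "C" * 30)
        truth = simulate_lineage({5: ids}, deterministic=True, seed=2)
        for cell in truth.cells.index:
            assert truth.cloneids_of_cell(cell) == ids

    def test_fate_profile_law_of_large_numbers(self):
        profile = FateProfile("ab", {"typeA": 0.5, "typeB": 0.5})
        assignments = {i: ("A" * 30,) for i in range(500)}
        truth = simulate_lineage(assignments, fate_profiles=[profile], seed=3)
        frac = (truth.cells["cell_type"] == "typeA").mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_per_profile_mean_size(self):
        big = FateProfile("immune", {"I": 1.0}, weight=0.2, mean_size=30.0)
        small = FateProfile("neuro", {"N": 1.0}, weight=0.8, mean_size=4.0)
        assignments = {i: ("A" * 30,) for i in range(400)}
        truth = simulate_lineage(assignments, fate_profiles=[big, small], seed=4)
        sizes = truth.cells.groupby("progenitor").size()
        types = truth.cells.groupby("progenitor")["cell_type"].first()
        assert sizes[types == "I"].mean() == pytest.approx(30.0, rel=0.1)
        assert sizes[types == "N"].mean() == pytest.approx(4.0, rel=0.1)


class TestSampling:
    def test_keep_everything(self):
        truth = simulate_lineage({0: ("A" * 30,)}, deterministic=True, seed=0)
        retained, rate = simulate_sampling(truth, [1.0], seed=1)
        assert retained == list(truth.cells.index) and rate == 1.0

    def test_empty_rate_list_rejected(self):
        truth = simulate_lineage({0: ("A" * 30,)}, deterministic=True, seed=0)
        with pytest.raises(ValueError):
            simulate_sampling(truth, [], seed=1)

    def test_binomial_retention(self):
        assignments = {i: ("A" * 30,) for i in range(6250)}
        truth = simulate_lineage(assignments, f=2, dt=2, deterministic=True, seed=2)
        assert truth.n_cells == 100_000
        retained, _ = simulate_sampling(truth, [0.1, 0.051], seed=3)
        se = math.sqrt(100_000 * 0.0051 * (1 - 0.0051))
        assert len(retained) == pytest.approx(510, abs=3 * se)


@pytest.fixture(scope="module")
def tiny_truth():
    assignments = {0: ("A" * 30,), 1: ("C" * 30, "G" * 30)}
    return simulate_lineage(assignments, f=1, dt=2, deterministic=True, seed=0)


class TestReads:
    def test_error_free_reads_carry_true_barcode(self, tiny_truth):
        reads, mols = simulate_reads(
            tiny_truth, list(tiny_truth.cells.index), ReadSimConfig(), seed=1
        )
        from clonetrace.extraction import extract_reads

        rec = extract_reads(reads)
        truth_sets = {
            c: set(tiny_truth.cloneids_of_cell(c)) for c in tiny_truth.cells.index
        }
        for t in rec.itertuples(index=False):
            known = t.cloneid.replace("0", "")
            assert any(
                all(p == "0" or p == f for p, f in zip(t.cloneid, full))
                for full in truth_sets[t.cellID]
            ), known

    def test_substitution_rate_realized(self):
        assignments = {i: ("ACGT"[i % 4] * 30,) for i in range(30)}
        truth = simulate_lineage(assignments, f=1, dt=2, deterministic=True, seed=0)
        cfg = ReadSimConfig(error_rate=0.005, frac_softclip=0.0, frac_partial=0.0)
        reads, _ = simulate_reads(truth, list(truth.cells.index), cfg, seed=2)
        ref_by_cell = {c: truth.cloneids_of_cell(c) for c in truth.cells.index}
        mism = total = 0
        for t in reads.itertuples(index=False):
            body = t.sequence[20:50]
            best = min(
                sum(a != b for a, b in zip(body, cid)) for cid in ref_by_cell[t.cellID]
            )
            mism += best
            total += 30
        assert total > 20_000
        se = math.sqrt(0.005 * 0.995 / total)
        assert mism / total == pytest.approx(0.005, abs=3 * se)

    def test_no_contamination_means_tags_match_truth(self, tiny_truth):
        _, mols = simulate_reads(tiny_truth, list(tiny_truth.cells.index), seed=3)
        assert (mols["cellID"] == mols["true_cell"]).all()
        assert not mols["contaminated"].any()

    def test_contamination_retags_fraction(self, tiny_truth):
        cfg = ReadSimConfig(contamination_rate=0.3)
        _, mols = simulate_reads(tiny_truth, list(tiny_truth.cells.index), cfg, seed=4)
        frac = mols["contaminated"].mean()
        assert 0.1 < frac < 0.5
        bad = mols[mols["contaminated"]]
        assert (bad["cellID"] != bad["true_cell"]).all()

    def test_seed_determinism(self, tiny_truth):
        cells = list(tiny_truth.cells.index)
        r1, m1 = simulate_reads(tiny_truth, cells, ReadSimConfig(error_rate=0.01), seed=5)
        r2, m2 = simulate_reads(tiny_truth, cells, ReadSimConfig(error_rate=0.01), seed=5)
        pd.testing.assert_frame_equal(r1, r2)
        pd.testing.assert_frame_equal(m1, m2)

    def test_molecule_truth_invariant_to_read_layout(self, tiny_truth):
        cells = list(tiny_truth.cells.index)
        _, m1 = simulate_reads(tiny_truth, cells, ReadSimConfig(frac_softclip=0.0), seed=6)
        _, m2 = simulate_reads(tiny_truth, cells, ReadSimConfig(frac_softclip=0.5), seed=6)
        pd.testing.assert_frame_equal(m1, m2)


class TestSpatial:
    def _truth(self, n_prog=150, seed=0):
        assignments = {i: (f"{'ACGT'[i % 4]}" * 30,) for i in range(n_prog)}
        return simulate_lineage(assignments, f=1.5, dt=2, seed=seed)

    def test_mean_cells_per_occupied_spot(self):
        truth = self._truth(300, seed=1)
        sec = simulate_spatial_section(truth, config=SpatialConfig(), seed=2)
        assert sec.mean_cells_per_occupied_spot() == pytest.approx(
            4.0 / (1 - math.exp(-4.0)), rel=0.1
        )

    def test_no_barcoded_cells_gives_empty_table(self):
        truth = self._truth(5, seed=3)
        sec = simulate_spatial_section(truth, barcoded_cells=[], seed=4)
        assert sec.spot_counts.empty and sec.cell_positions.empty

    def test_single_cell_spots_carry_that_cells_barcodes(self):
        truth = self._truth(60, seed=5)
        sec = simulate_spatial_section(
            truth, config=SpatialConfig(cells_per_spot=0.3), seed=6
        )
        per_spot = sec.cell_positions.groupby("spot_id")
        counts = sec.spot_counts.groupby("spot_id")["cloneid"].apply(set)
        for sid, grp in per_spot:
            if len(grp) == 1:
                expected = set(truth.cloneids_of_cell(grp["cell_id"].iloc[0]))
                assert counts.loc[sid] == expected

    def test_conservation_every_placed_cell_has_one_spot(self):
        truth = self._truth(40, seed=7)
        sec = simulate_spatial_section(truth, seed=8)
        assert sec.cell_positions["cell_id"].is_unique
        assert set(sec.cell_positions["spot_id"]) <= set(sec.spots["barcode"])
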