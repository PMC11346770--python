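"""The direct simulator: clone trees, truth matrices, count/BAF generation."""

import numpy as np
import pytest

from ascna.synthetic_data import (
    load_truth,
    make_bin_table,
    simulate_dataset,
    simulate_matrices,
    simulate_truth,
    write_truth,
)


class TestSimulateTruth:
    def test_exact_normal_cell_count(self):
        truth = simulate_truth(100, 200, 2, 4, normal_fraction=0.25, seed=0)
        assert int(truth.is_normal.sum()) == 25
        normal = truth.cell_minor[truth.is_normal]
        assert (normal == 1).all()
        assert (truth.cell_major[truth.is_normal] == 1).all()
        np.testing.assert_allclose(truth.ploidy[truth.is_normal], 2.0)

    def test_zero_events_reproduce_base_genomes(self):
        for mode, total in [("diploid", 2), ("tetraploid", 4), ("triploid", 3)]:
            truth = simulate_truth(
                10, 60, 2, 3, cna_events_per_clone=0, ploidy_mode=mode, seed=1
            )
            tumor = ~truth.is_normal
            assert (truth.cell_total[tumor] == total).all()

    def test_hypodiploid_mode_loses_genome(self):
        truth = simulate_truth(
            20, 100, 2, 2, cna_events_per_clone=0,
            ploidy_mode="hypodiploid", seed=2,
        )
        tumor_p = truth.ploidy[~truth.is_normal]
        assert (tumor_p < 2.0).all()
        assert tumor_p.mean() == pytest.approx(1.65, abs=0.35)

    def test_seeded_determinism(self):
        a = simulate_truth(30, 80, 2, 3, seed=42)
        b = simulate_truth(30, 80, 2, 3, seed=42)
        np.testing.assert_array_equal(a.cell_minor, b.cell_minor)
        np.testing.assert_array_equal(a.cell_clone, b.cell_clone)
        for x, y in zip(a.breakpoints, b.breakpoints):
            np.testing.assert_array_equal(x, y)

    def test_allele_cap_respected(self):
        truth = simulate_truth(
            20, 100, 2, 4, cna_events_per_clone=20, seed=3, max_allele_copies=4
        )
        assert truth.cell_major.max() <= 4

    def test_breakpoints_match_state_changes(self):
        truth = simulate_truth(15, 90, 3, 3, seed=4)
        spans = truth.chrom_spans
        for i in range(truth.n_cells):
            expected = []
            for lo, hi in spans:
                for j in range(lo, hi - 1):
                    if (
                        truth.cell_minor[i, j] != truth.cell_minor[i, j + 1]
                        or truth.cell_major[i, j] != truth.cell_major[i, j + 1]
                    ):
                        expected.append(j)
            np.testing.assert_array_equal(truth.breakpoints[i], expected)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            simulate_truth(10, 50, 2, 2, ploidy_mode="pentaploid")
        with pytest.raises(ValueError):
            simulate_truth(10, 50, 2, 2, normal_fraction=1.0)


class TestSimulateMatrices:
    def test_zero_noise_is_deterministic_and_exact(self):
        truth = simulate_truth(12, 60, 2, 2, normal_fraction=0.5, seed=5)
        R, baf = simulate_matrices(truth, coverage_scale=1000, seed=0)
        R2, baf2 = simulate_matrices(truth, coverage_scale=1000, seed=99)
        np.testing.assert_array_equal(R, R2)  # counts carry no randomness
        mbaf = np.minimum(baf, 1 - baf)
        normal = truth.is_normal
        assert (R[normal] == 1000).all()
        np.testing.assert_allclose(mbaf[normal], 0.5)
        # mirrored BAF equals minor fraction everywhere (guard totals > 0)
        tot = truth.cell_total
        ok = tot > 0
        np.testing.assert_allclose(
            mbaf[ok], truth.cell_minor[ok] / tot[ok], atol=1e-12
        )

    def test_loh_bins_have_zero_mbaf(self):
        truth = simulate_truth(
            30, 100, 2, 4, cna_events_per_clone=8, seed=6
        )
        R, baf = simulate_matrices(truth, seed=0)
        mbaf = np.minimum(baf, 1 - baf)
        loh = (truth.cell_minor == 0) & (truth.cell_major > 0)
        assert loh.any()
        np.testing.assert_allclose(mbaf[loh], 0.0, atol=1e-12)

    def test_poisson_sampling_mean(self):
        # 10^4 draws at mean 50: CLT bound on the sample mean
        truth = simulate_truth(
            100, 100, 2, 1, cna_events_per_clone=0, normal_fraction=0.0, seed=7
        )
        R, _ = simulate_matrices(
            truth, coverage_scale=50, rdr_noise_sd=1e-9, seed=8
        )
        assert R.mean() == pytest.approx(50, abs=3 * np.sqrt(50 / R.size))

    def test_rdr_noise_increases_dispersion(self):
        truth = simulate_truth(20, 80, 2, 2, seed=9)
        R_lo, _ = simulate_matrices(truth, rdr_noise_sd=0.01, seed=1)
        R_hi, _ = simulate_matrices(truth, rdr_noise_sd=0.2, seed=1)
        normal = truth.is_normal
        assert R_hi[normal].std() > R_lo[normal].std() * 2


class TestTruthPersistence:
    def test_round_trip(self, tmp_path):
        bt = make_bin_table(60, 2, seed=0)
        truth = simulate_truth(10, 60, 2, 2, seed=11)
        ids = [f"cell_{i}" for i in range(10)]
        write_truth(tmp_path, truth, bt, ids)
        back = load_truth(tmp_path)
        np.testing.assert_array_equal(back.cell_minor, truth.cell_minor)
        np.testing.assert_array_equal(back.cell_major, truth.cell_major)
        np.testing.assert_allclose(back.ploidy, truth.ploidy)
        for a, b in zip(back.breakpoints, truth.breakpoints):
            np.testing.assert_array_equal(a, b)


class TestSimulateDataset:
    def test_shapes_and_determinism(self):
        bt, R, baf, truth = simulate_dataset(8, 40, 2, 2, seed=12)
        assert R.shape == (8, 40) and baf.shape == (8, 40)
        assert bt.n_bins == 40
        bt2, R2, baf2, _ = simulate_dataset(8, 40, 2, 2, seed=12)
        np.testing.assert_array_equal(R, R2)
        np.testing.assert_array_equal(baf, baf2)
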