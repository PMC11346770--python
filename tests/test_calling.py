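"""Segment assignment, candidate ploidies, state likelihood, ploidy selection."""

import numpy as np
import pytest

from ascna.calling import (
    assign_segments,
    call_cells,
    candidate_ploidies,
    folded_mbaf_mean,
    rounding_sse,
    select_ploidy,
    state_likelihood,
)
from ascna.data_model import CopyState, StateSpace, expected_state_mean
from ascna.ensemble import Segment, SegmentSet, build_segments
from ascna.gmm_segmentation import BreakpointSets

from conftest import make_bins, make_features
from test_gmm import simple_model


def seg(rdr, mbaf, bins):
    bins = np.asarray(bins, dtype=int)
    return Segment("chr1", int(bins[0]), int(bins[-1]) + 1, bins, rdr, mbaf)


class TestAssignSegments:
    def test_zero_distance_wins(self):
        model = simple_model([[1.0, 0.5], [2.0, 0.25]])
        s = [seg(1.0, 0.5, [0, 1])]
        assert assign_segments(s, model)[0] == 0

    def test_tie_goes_to_heavier_component(self):
        model = simple_model([[0.9, 0.5], [1.1, 0.5]], weights=[0.3, 0.7])
        s = [seg(1.0, 0.5, [0])]
        assert assign_segments(s, model)[0] == 1

    def test_euclidean_distance_arithmetic(self):
        model = simple_model([[1.0, 0.5], [1.5, 0.33]])
        s = [seg(1.4, 0.33, [0])]
        # distances 0.435 vs 0.1
        assert assign_segments(s, model)[0] == 1


class TestCandidatePloidies:
    def test_balanced_anchor_at_unit_rdr(self):
        model = simple_model([[1.0, 0.5], [1.5, 0.33]], weights=[0.7, 0.3])
        cands, r = candidate_ploidies(model, max_wgd=2)
        np.testing.assert_allclose(cands, [2.0, 4.0, 8.0])
        assert r == 1.0

    def test_balanced_anchor_at_half_rdr_implies_tetraploid_base(self):
        model = simple_model([[0.5, 0.5]], weights=[1.0])
        cands, _ = candidate_ploidies(model, max_wgd=1)
        np.testing.assert_allclose(cands, [4.0, 8.0])
        # consistency: a {1,1} state in a tetraploid cell sits at RDR 0.5
        assert expected_state_mean(CopyState(1, 1), 4.0)[0] == pytest.approx(0.5)

    def test_max_wgd_zero_gives_single_candidate(self):
        model = simple_model([[1.0, 0.5]])
        cands, _ = candidate_ploidies(model, max_wgd=0)
        assert len(cands) == 1

    def test_fallback_warns_and_uses_mbaf_consistent_total(self):
        # densest component is a pure {1,2} signature (mBAF 1/3) at RDR 1
        model = simple_model([[1.0, 1 / 3]], weights=[1.0])
        with pytest.warns(UserWarning, match="mBAF"):
            cands, _ = candidate_ploidies(model, max_wgd=1)
        np.testing.assert_allclose(cands, [3.0, 6.0])

    def test_per_cell_density_overrides_global_weights(self):
        model = simple_model(
            [[1.0, 0.5], [0.5, 0.5]], weights=[0.9, 0.1]
        )
        cands, r = candidate_ploidies(
            model, max_wgd=0, density=np.array([0.0, 1.0])
        )
        assert r == 0.5
        np.testing.assert_allclose(cands, [4.0])


class TestFoldedMbaf:
    def test_no_noise_is_identity(self):
        q = np.array([0.0, 0.25, 0.5])
        np.testing.assert_array_equal(folded_mbaf_mean(q, 0.0), q)

    def test_boundary_shifts(self):
        s = 0.05
        shift = s * np.sqrt(2 / np.pi)
        assert folded_mbaf_mean(0.5, s) == pytest.approx(0.5 - shift)
        assert folded_mbaf_mean(0.0, s) == pytest.approx(shift)
        # mid-range ratios are essentially unaffected
        assert folded_mbaf_mean(0.25, s) == pytest.approx(0.25, abs=1e-6)

    def test_matches_monte_carlo_fold(self, rng):
        s = 0.06
        for q in (0.0, 0.1, 0.45, 0.5):
            y = q + rng.normal(0, s, 200_000)
            y = np.abs(y)
            y = 1 - np.abs(1 - y)
            sim = np.minimum(y, 1 - y).mean()
            assert folded_mbaf_mean(q, s) == pytest.approx(sim, abs=2e-3)


def brute_force_state(pts, cov, ploidy, omega):
    """Independent enumeration of Eq-7's per-component maximization."""
    from scipy.stats import multivariate_normal

    best, best_ll = None, -np.inf
    for st in omega.states:
        mu = expected_state_mean(st, ploidy)
        ll = multivariate_normal.logpdf(pts, mean=mu, cov=cov).sum()
        if ll > best_ll:
            best, best_ll = st, ll
    return best, best_ll


class TestStateLikelihood:
    def make_single_comp(self, pts, cov=1e-4):
        feats = make_features(pts[None, :, 0].reshape(1, -1), pts[None, :, 1].reshape(1, -1))
        model = simple_model([[float(pts[:, 0].mean()), float(pts[:, 1].mean())]], cov=cov)
        segments = [seg(pts[:, 0].mean(), pts[:, 1].mean(), np.arange(len(pts)))]
        return feats, model, segments

    @pytest.mark.parametrize(
        "point,ploidy,expected",
        [
            ((1.0, 0.5), 2.0, (1, 1)),
            ((1.5, 0.0), 2.0, (0, 3)),
            ((1.5, 1 / 3), 2.0, (1, 2)),
        ],
    )
    def test_noiseless_points_recover_state(self, point, ploidy, expected):
        pts = np.tile(point, (6, 1))
        feats, model, segments = self.make_single_comp(pts)
        states, _ = state_likelihood(
            ploidy, segments, np.array([0]), model, StateSpace(6), feats, 0
        )
        assert tuple(states[0]) == expected

    def test_matches_brute_force_enumeration(self, rng):
        omega = StateSpace(8)
        for _ in range(25):
            pts = np.column_stack(
                [rng.uniform(0.2, 3.0, 8), rng.uniform(0.0, 0.5, 8)]
            )
            cov = np.diag([0.02, 0.005])
            feats, model, segments = self.make_single_comp(pts)
            model.covariances[0] = cov
            ploidy = float(rng.uniform(1.5, 4.5))
            states, ll = state_likelihood(
                ploidy, segments, np.array([0]), model, omega, feats, 0
            )
            ref_state, ref_ll = brute_force_state(pts, cov, ploidy, omega)
            assert tuple(states[0]) == tuple(ref_state)
            assert ll == pytest.approx(ref_ll, rel=1e-9)


class TestRoundingSse:
    def test_zero_when_scaled_values_are_integral(self):
        rdr = np.array([0.5, 1.0, 1.5, 2.5])
        assert rounding_sse(2.0, rdr) == 0.0

    def test_half_offsets_score_quarter_each(self):
        assert rounding_sse(1.0, np.array([0.5, 1.5])) == pytest.approx(0.5)

    def test_weights_scale_contributions(self):
        assert rounding_sse(
            1.0, np.array([0.4]), np.array([10.0])
        ) == pytest.approx(10 * 0.16, rel=1e-12)


class TestSelectPloidy:
    def build(self, seg_specs, model):
        """seg_specs: list of (rdr, mbaf, n_bins).  Returns features/segments."""
        rdrs = np.concatenate([[r] * n for r, b, n in seg_specs])
        mbafs = np.concatenate([[b] * n for r, b, n in seg_specs])
        feats = make_features(rdrs[None, :], mbafs[None, :])
        bins_used = 0
        segments = []
        for r, b, n in seg_specs:
            segments.append(seg(r, b, np.arange(bins_used, bins_used + n)))
            bins_used += n
        return feats, segments

    def test_clean_diploid_prefers_two(self):
        model = simple_model(
            [[0.5, 0.0], [1.0, 0.5], [1.5, 1 / 3]], cov=1e-4
        )
        feats, segments = self.build(
            [(1.0, 0.5, 30), (0.5, 0.0, 10), (1.5, 1 / 3, 10)], model
        )
        assignment = assign_segments(segments, model)
        p, states, trace = select_ploidy(
            0, np.array([2.0, 4.0, 8.0]), segments, assignment, model,
            StateSpace(10), feats,
        )
        assert p == pytest.approx(2.0)
        assert tuple(states[1]) == (1, 1)

    def test_imbalanced_tetraploid_beats_diploid(self):
        # {2,2} bins at RDR 1 plus a {2,3} component at 1.25/0.4: only the
        # WGD candidate explains the imbalance-consistent states
        model = simple_model([[1.0, 0.5], [1.25, 0.4]], cov=1e-4)
        feats, segments = self.build(
            [(1.0, 0.5, 30), (1.25, 0.4, 20)], model
        )
        assignment = assign_segments(segments, model)
        p, states, trace = select_ploidy(
            0, np.array([2.0, 4.0]), segments, assignment, model,
            StateSpace(10), feats,
        )
        assert p == pytest.approx(4.0)
        assert tuple(states[0]) == (2, 2)
        assert tuple(states[1]) == (2, 3)
        assert trace[4.0] < trace[2.0]

    def test_single_balanced_segment_ties_to_smallest_candidate(self):
        model = simple_model([[1.0, 0.5]], cov=1e-4)
        feats, segments = self.build([(1.0, 0.5, 20)], model)
        assignment = assign_segments(segments, model)
        p, _, _ = select_ploidy(
            0, np.array([2.0, 4.0, 8.0]), segments, assignment, model,
            StateSpace(10), feats, refine=False,
        )
        assert p == pytest.approx(2.0)


class TestCallCells:
    def noiseless_setup(self, rng):
        from ascna.config import SimulationConfig
        from ascna.pipeline import run_simulated

        sim = SimulationConfig(
            n_cells=16, m_bins=80, n_chroms=2, n_clones=2, normal_fraction=0.25
        )
        from ascna.config import PipelineConfig

        return run_simulated(sim, PipelineConfig(seed=7, cbs_n_perm=100))

    def test_noiseless_recovery_and_candidate_membership(self, rng):
        res = self.noiseless_setup(rng)
        np.testing.assert_array_equal(res.calls.c_minor, res.truth.cell_minor)
        np.testing.assert_array_equal(res.calls.c_major, res.truth.cell_major)
        np.testing.assert_allclose(res.calls.ploidy, res.truth.ploidy, atol=1e-9)
        # every state within the bounded space
        totals = res.calls.total_cn[res.calls.total_cn >= 0]
        assert totals.max() <= res.calls.state_space.max_total

    def test_output_invariant_under_baf_mirroring(self):
        from ascna.config import PipelineConfig, SimulationConfig
        from ascna.pipeline import derive_stage_seeds, run_pipeline
        from ascna.synthetic_data import simulate_dataset

        seeds = derive_stage_seeds(3)
        bt, R, baf, truth = simulate_dataset(
            n_cells=10, m_bins=60, n_chroms=2, n_clones=2, seed=seeds["simulate"]
        )
        cfg = PipelineConfig(seed=3, cbs_n_perm=100)
        a = run_pipeline(R, baf, bt, cfg)
        b = run_pipeline(R, 1.0 - baf, bt, cfg)
        np.testing.assert_array_equal(a.calls.c_minor, b.calls.c_minor)
        np.testing.assert_array_equal(a.calls.c_major, b.calls.c_major)

    def test_known_ploidy_bypasses_selection(self):
        model = simple_model([[1.0, 0.5]], cov=1e-4)
        feats = make_features(np.full((1, 10), 1.0), np.full((1, 10), 0.5))
        segset = SegmentSet([[seg(1.0, 0.5, np.arange(10))]])
        calls = call_cells(feats, segset, model, known_ploidies=np.array([4.0]))
        assert calls.candidate_ploidy[0] == pytest.approx(4.0)
        assert (calls.c_minor[0] == 2).all() and (calls.c_major[0] == 2).all()
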