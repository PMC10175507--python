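"""Linearity-index maps: LI arithmetic, gating, smoothing, nonlinearity
testing, timing classification and asymmetry."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spectint import process_dataset
from spectint.interaction import (FACILITATIVE, NONE, SUPPRESSIVE,
                                  aggregate_population_map,
                                  asymmetry_from_matrix,
                                  build_interaction_map,
                                  classify_from_matrix,
                                  compute_linearity_index,
                                  map_two_tone_to_fm_rate,
                                  normalized_magnitude_profile, smooth_map)
from spectint.interaction import test_nonlinearity as nonlinearity_verdict
from spectint.interaction import InteractionMap
from spectint.protocol import DF_GRID, DT_GRID
from spectint.synth import simulate_population


class TestLinearityIndex:
    @pytest.mark.parametrize("t,l,expected", [
        (2.0, 2.0, 0.0),        # linear summation
        (1.5, 0.0, 1.0),        # pure combination response
        (1.0, 2.0, -1.0 / 3.0),
        (0.0, 1.0, -1.0),
        (-0.5, 1.0, -1.0),      # negative amplitudes clamp to 0 first
    ])
    def test_values(self, t, l, expected):
        assert compute_linearity_index(t, l) == pytest.approx(expected)

    def test_undefined_when_both_zero(self):
        assert np.isnan(compute_linearity_index(0.0, 0.0))
        assert np.isnan(compute_linearity_index(-1.0, -2.0))

    @settings(max_examples=50, deadline=None)
    @given(t=st.floats(-5, 5), l=st.floats(-5, 5))
    def test_range_invariant(self, t, l):
        li = compute_linearity_index(t, l)
        assert np.isnan(li) or -1.0 <= li <= 1.0


class TestNonlinearityTest:
    def test_null_set_size_is_trial_product(self):
        """5 center x 5 dF trials combine into 25 pairwise sums."""
        c = np.arange(5, dtype=float)
        d = np.arange(5, dtype=float)
        assert len(np.add.outer(c, d).ravel()) == 25

    def test_identical_distributions_give_none(self):
        tt = np.full(5, 2.0)
        c = np.full(5, 1.0)
        d = np.full(5, 1.0)
        assert nonlinearity_verdict(tt, c, d) == NONE

    def test_fully_separated_facilitative(self):
        """Two-tone strictly above every pairwise sum: exact rank-sum
        two-sided p = 2 / C(30, 5) = 1.403e-5."""
        rng = np.random.default_rng(0)
        c = rng.uniform(0, 1, 5)
        d = rng.uniform(0, 1, 5)
        tt = np.full(5, 3.0)  # above max possible sum of 2
        assert nonlinearity_verdict(tt, c, d, alpha=0.1) == FACILITATIVE
        from scipy import stats
        p = stats.mannwhitneyu(tt, np.add.outer(c, d).ravel(),
                               alternative="two-sided", method="exact").pvalue
        assert p == pytest.approx(1.4034496793117482e-05, rel=1e-9)

    def test_fully_separated_suppressive(self):
        c = np.full(5, 1.0) + np.arange(5) * 0.01
        d = np.full(5, 1.0) + np.arange(5) * 0.01
        tt = np.full(5, 0.1) + np.arange(5) * 0.01
        assert nonlinearity_verdict(tt, c, d, alpha=0.1) == SUPPRESSIVE

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            nonlinearity_verdict([1.0], [1.0, 2.0], [1.0, 2.0])


class TestSmoothing:
    def test_constant_map_preserved(self):
        li = np.full((9, 9), 0.37)
        out = smooth_map(li, np.ones((9, 9), bool))
        np.testing.assert_allclose(out, 0.37)

    def test_single_valid_cell_keeps_its_value(self):
        li = np.full((9, 9), np.nan)
        valid = np.zeros((9, 9), bool)
        li[4, 4] = -0.6
        valid[4, 4] = True
        out = smooth_map(li, valid)
        assert out[4, 4] == pytest.approx(-0.6)
        assert np.isnan(out[0, 0])  # beyond kernel support

    def test_delta_map_neighbor_weights(self):
        """Neighbor of a delta on an all-valid grid gets the normalized
        Gaussian weight computed by an explicit double loop."""
        sigma = 0.4
        li = np.zeros((9, 9))
        li[4, 4] = 1.0
        valid = np.ones((9, 9), bool)
        out = smooth_map(li, valid, sigma_grid=sigma)
        radius = int(np.ceil(4 * sigma))
        num = den = 0.0
        for a in range(9):
            for b in range(9):
                d2 = (a - 4) ** 2 + (b - 5) ** 2
                if d2 <= radius ** 2:
                    w = np.exp(-d2 / (2 * sigma ** 2))
                    den += w
                    num += w * li[a, b]
        assert out[4, 5] == pytest.approx(num / den)

    def test_sigma_unit_conversion(self):
        """0.4 grid units correspond to 0.1 oct and 10 ms at the
        0.25-oct / 25-ms grid spacing."""
        from spectint.interaction import DF_SPACING_OCT, DT_SPACING_MS
        assert 0.4 * DF_SPACING_OCT == pytest.approx(0.1)
        assert 0.4 * DT_SPACING_MS == pytest.approx(10.0)


class TestInteractionMapGating:
    def test_noise_free_map_recovers_kernel(self, noise_free_dataset,
                                            noise_free_cell):
        """Full-pipeline LI equals the generating kernel at valid cells."""
        _, rt = noise_free_dataset
        m = build_interaction_map(rt, 0, run_significance=False)
        assert m.valid.any()
        diff = np.abs(m.li[m.valid] - noise_free_cell.li_kernel[m.valid])
        assert diff.max() < 1e-6

    def test_unresponsive_roi_all_invalid(self, protocol_nofm):
        from spectint.synth import make_null_cell
        ts = simulate_population([make_null_cell()], protocol_nofm, seed=1)
        rt = process_dataset(ts)
        m = build_interaction_map(rt, 0, run_significance=False)
        assert not m.valid.any()
        assert np.isnan(m.li).all()

    def test_fac_and_supp_flags_exclusive(self, noise_free_dataset):
        _, rt = noise_free_dataset
        m = build_interaction_map(rt, 0, run_significance=True)
        assert not np.any(m.fac_sig & m.supp_sig)

    def test_conflicting_flags_rejected(self):
        flag = np.ones((9, 9), bool)
        with pytest.raises(ValueError):
            InteractionMap(li=np.zeros((9, 9)), valid=flag,
                           li_smoothed=np.zeros((9, 9)), fac_sig=flag,
                           supp_sig=flag)


class TestAggregation:
    def _map(self, li, valid):
        return InteractionMap(li=li, valid=valid, li_smoothed=li,
                              fac_sig=np.zeros((9, 9), bool),
                              supp_sig=np.zeros((9, 9), bool))

    def test_single_map_is_identity(self):
        li = np.random.default_rng(0).uniform(-1, 1, (9, 9))
        mean, n = aggregate_population_map([self._map(li, np.ones((9, 9),
                                                                  bool))])
        np.testing.assert_allclose(mean, li)
        assert (n == 1).all()

    def test_disjoint_valid_cells_union(self):
        a = np.full((9, 9), np.nan)
        b = np.full((9, 9), np.nan)
        a[0, 0] = 0.5
        b[8, 8] = -0.5
        mean, n = aggregate_population_map(
            [self._map(a, ~np.isnan(a)), self._map(b, ~np.isnan(b))])
        assert mean[0, 0] == pytest.approx(0.5)
        assert mean[8, 8] == pytest.approx(-0.5)
        assert n[0, 0] == n[8, 8] == 1
        assert n[4, 4] == 0 and np.isnan(mean[4, 4])

    def test_opposite_maps_cancel(self):
        a = np.full((9, 9), 0.5)
        b = np.full((9, 9), -0.5)
        ones = np.ones((9, 9), bool)
        mean, n = aggregate_population_map([self._map(a, ones),
                                            self._map(b, ones)])
        np.testing.assert_allclose(mean, 0.0)
        assert (n == 2).all()


class TestTimingClassification:
    def _matrix(self, coincident, shifted, neg=None, pos=None):
        m = np.full((9, 9), shifted, dtype=float)
        if neg is not None:
            m[:, DT_GRID < 0] = neg
        if pos is not None:
            m[:, DT_GRID > 0] = pos
        m[:, np.isclose(DT_GRID, 0.0)] = coincident
        return m

    def test_coincident_preferring(self):
        tp = classify_from_matrix(self._matrix(1.6, 1.0))
        assert tp.label == "coincident_preferring"

    def test_symmetric_shift_preferring(self):
        tp = classify_from_matrix(self._matrix(1.0, 1.6))
        assert tp.label == "symmetric_shift_preferring"

    def test_negative_dt_preferring(self):
        """Shift-preferring with negative-dT amplitudes more than 1.5x the
        positive-dT ones subdivides to negative-dT-preferring."""
        tp = classify_from_matrix(self._matrix(1.0, 1.6, neg=2.2, pos=1.0))
        assert tp.shifted_amp > 1.5 * tp.coincident_amp
        assert tp.neg_amp > 1.5 * tp.pos_amp
        assert tp.label == "negative_dT_preferring"

    def test_boundary_ratio_unclassified(self):
        """Exactly 1.5x is not 'more than 1.5 times larger'."""
        tp = classify_from_matrix(self._matrix(1.5, 1.0))
        assert tp.label == "unclassified"

    def test_ratio_near_one_leaves_only_ties_unclassified(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            m = rng.uniform(0, 2, (9, 9))
            tp = classify_from_matrix(m, ratio=1.0 + 1e-12)
            assert tp.label != "unclassified"


class TestAsymmetryIndex:
    def test_balanced_map_zero(self):
        assert asymmetry_from_matrix(np.ones((9, 9))) == pytest.approx(0.0)

    def test_one_sided_map_is_one(self):
        m = np.zeros((9, 9))
        m[:, DT_GRID > 0] = 1.0
        assert asymmetry_from_matrix(m) == pytest.approx(1.0)

    def test_three_to_one_ratio(self):
        """P = 3, N = 1 gives |(3-1)/(3+1)| = 0.5."""
        m = np.zeros((9, 9))
        m[0, DT_GRID > 0] = 3.0 / 4.0
        m[0, DT_GRID < 0] = 1.0 / 4.0
        assert asymmetry_from_matrix(m) == pytest.approx(0.5)

    def test_undefined_for_silent_map(self):
        assert np.isnan(asymmetry_from_matrix(np.zeros((9, 9))))


class TestNormalizedProfile:
    def test_flat_amplitudes_profile_of_ones(self, noise_free_dataset):
        _, rt = noise_free_dataset
        prof = normalized_magnitude_profile(rt, [0])
        assert prof.shape == (9,)
        assert prof.max() <= 1.0 + 1e-12
        assert np.isclose(prof.max(), 1.0)


class TestFmRateMapping:
    @pytest.mark.parametrize("dF,dT,expected", [
        (0.25, 100.0, 2.5),
        (1.0, 25.0, 40.0),
        (-0.5, -50.0, 10.0),
        (0.0, 50.0, 0.0),
    ])
    def test_conversion(self, dF, dT, expected):
        assert map_two_tone_to_fm_rate(dF, dT) == pytest.approx(expected)

    def test_coincident_undefined(self):
        with pytest.raises(ValueError):
            map_two_tone_to_fm_rate(0.5, 0.0)
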