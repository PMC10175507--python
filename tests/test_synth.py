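"""Generator correctness: kernel inversion, recovery, determinism,
pixel-level contamination model."""

import numpy as np
import pytest

from spectint import process_dataset
from spectint.interaction import classify_timing_preference
from spectint.protocol import DF_GRID, DT_GRID
from spectint.synth import (GroundTruthCell, kernel_a1_asymmetric,
                            kernel_a2_coincident, kernel_linear,
                            kernel_sublinear_uniform, make_cell,
                            make_population, simulate_population,
                            subtract_background, synthesize_pixel_traces,
                            synthesize_trial_traces,
                            two_tone_amplitude_from_kernel)
from spectint.traces import exclude_contaminated_pixels


def _cell_with_kernel(kern, base=1.0, df_amp=1.0, **kw):
    return GroundTruthCell(base_amp_center=base,
                           amp_df={float(d): df_amp for d in DF_GRID},
                           li_kernel=kern, **kw)


class TestKernelInversion:
    def test_linear_case(self):
        """LI* = 0 leaves T equal to L."""
        cell = _cell_with_kernel(kernel_linear(), base=1.0, df_amp=1.0)
        assert two_tone_amplitude_from_kernel(cell, 0.5, 50.0) == pytest.approx(2.0)

    def test_known_supralinear_amplitude(self):
        """(T - L)/(T + L) = 1/3 with L = 1 solves to T = 2."""
        kern = np.full((9, 9), 1.0 / 3.0)
        cell = _cell_with_kernel(kern, base=0.5, df_amp=0.5)
        assert two_tone_amplitude_from_kernel(cell, 0.25, 25.0) == pytest.approx(2.0)

    def test_full_suppression_gives_zero(self):
        cell = _cell_with_kernel(np.full((9, 9), -1.0))
        assert two_tone_amplitude_from_kernel(cell, 0.0, 0.0) == 0.0

    def test_li_one_unrepresentable(self):
        cell = _cell_with_kernel(np.full((9, 9), 1.0))
        with pytest.raises(ValueError):
            two_tone_amplitude_from_kernel(cell, 0.0, 0.0)

    def test_round_trip_li(self):
        """Recomputing LI from (T, L) returns the kernel value exactly."""
        rng = np.random.default_rng(0)
        kern = rng.uniform(-0.95, 0.95, size=(9, 9))
        cell = _cell_with_kernel(kern, base=0.7, df_amp=0.4)
        for i, dF in enumerate(DF_GRID):
            for j, dT in enumerate(DT_GRID):
                t = two_tone_amplitude_from_kernel(cell, dF, dT)
                l = 1.1
                assert (t - l) / (t + l) == pytest.approx(kern[i, j], abs=1e-12)


class TestCellInvariants:
    def test_kernel_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            _cell_with_kernel(np.full((9, 9), 1.5))

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            _cell_with_kernel(kernel_linear(), base=-0.1)

    def test_bad_kinetics_rejected(self):
        with pytest.raises(ValueError):
            _cell_with_kernel(kernel_linear(), tau_rise=0.0)
        with pytest.raises(ValueError):
            _cell_with_kernel(kernel_linear(), tau_rise=2.0, tau_decay=1.0)


class TestTemplates:
    def test_a2_coincident_structure(self):
        """Max LI sits in the dT = 0 column; off-coincidence is sublinear."""
        k = kernel_a2_coincident()
        j0 = int(np.argmin(np.abs(DT_GRID)))
        assert np.unravel_index(np.argmax(k), k.shape)[1] == j0
        off = np.delete(k, j0, axis=1)
        assert (off < 0).all()
        # overlapping identical tones are just a louder single tone
        assert k[int(np.argmin(np.abs(DF_GRID))), j0] == 0.0

    def test_a1_asymmetric_region_imbalance(self):
        """Summed LI differs between Upward and Downward regions."""
        k = kernel_a1_asymmetric()
        df = DF_GRID[:, None]
        dt = DT_GRID[None, :]
        up = ((df > 0) & (dt > 0)) | ((df < 0) & (dt < 0))
        down = ((df > 0) & (dt < 0)) | ((df < 0) & (dt > 0))
        assert k[up].sum() != pytest.approx(k[down].sum())

    def test_sublinear_uniform_range(self):
        k = kernel_sublinear_uniform(-0.3)
        assert (k == -0.3).all()


class TestTraceSynthesis:
    def test_noise_free_amplitude_recovery(self, protocol_nofm):
        """With no noise, the window mean recovers the ground-truth
        amplitude after dividing out the transient shape factor."""
        from spectint.synth import kernel_window_mean
        cell = _cell_with_kernel(kernel_linear(), base=0.8, df_amp=0.3,
                                 trial_noise_cv=0.0, baseline_sd=0.0)
        tr = synthesize_trial_traces(cell, protocol_nofm, seed=0)
        proto = protocol_nofm
        center_id = proto.condition_id("tone", role="center")
        idx = proto.trials.index[proto.trials["condition_id"] == center_id]
        shape = kernel_window_mean(cell, 30, proto.frame_rate)
        for t in idx:
            window = tr[t, proto.onset_frame: proto.onset_frame + 30]
            assert window.mean() / shape == pytest.approx(0.8, rel=1e-9)

    def test_seeded_traces_bit_reproducible(self, protocol_nofm):
        cell = make_cell("a2_coincident", seed=[0, 0, 0])
        a = synthesize_trial_traces(cell, protocol_nofm, seed=123)
        b = synthesize_trial_traces(cell, protocol_nofm, seed=123)
        np.testing.assert_array_equal(a, b)

    def test_zero_amplitude_is_pure_noise(self, protocol_nofm):
        cell = _cell_with_kernel(kernel_linear(), base=0.0, df_amp=0.0,
                                 baseline_sd=0.05, trial_noise_cv=0.0)
        tr = synthesize_trial_traces(cell, protocol_nofm, seed=5)
        assert abs(tr.mean()) < 0.01
        assert tr.std() == pytest.approx(0.05, rel=0.05)

    def test_substreams_stable_under_population_growth(self):
        """Adding cells never reshuffles the earlier cells' parameters."""
        small = make_population("a1_asymmetric", 3, seed=21)
        big = make_population("a1_asymmetric", 6, seed=21)
        for a, b in zip(small, big):
            np.testing.assert_array_equal(a.li_kernel, b.li_kernel)
            assert a.base_amp_center == b.base_amp_center


class TestPixelModel:
    def test_alpha_zero_identity(self):
        cell = np.sin(np.linspace(0, 10, 500)) + 100
        measured, pixels, true, _ = synthesize_pixel_traces(
            cell, contamination_alpha=0.0, seed=1)
        np.testing.assert_allclose(measured, true)

    def test_subtraction_recovers_truth_with_clean_background(self):
        """With noiseless clean ring pixels, measured - 0.9 x background
        equals the true trace exactly (alpha = 0.9 by construction)."""
        cell = np.zeros(400) + 50
        measured, pixels, true, _ = synthesize_pixel_traces(
            cell, contamination_alpha=0.9, n_contaminated=0,
            pixel_noise_sd=0.0, seed=2)
        rec = subtract_background(measured, pixels.mean(axis=0), coeff=0.9)
        np.testing.assert_allclose(rec, true, atol=1e-9)

    def test_exclusion_reduces_subtraction_error(self):
        """Dropping the injected contaminated pixels shrinks the RMSE of
        the recovered trace."""
        rng = np.random.default_rng(3)
        cell = 60 + 5 * rng.standard_normal(600)
        measured, pixels, true, bad = synthesize_pixel_traces(
            cell, contamination_alpha=0.9, n_contaminated=3, seed=3)
        keep, bg_clean = exclude_contaminated_pixels(pixels, cell)
        assert not keep[bad].any()
        rec_naive = subtract_background(measured, pixels.mean(axis=0))
        rec_clean = subtract_background(measured, bg_clean)
        rmse = lambda x: np.sqrt(np.mean((x - true) ** 2))
        assert rmse(rec_clean) < rmse(rec_naive)


def test_population_recovery_coincidence_preference(protocol_nofm):
    """Most cells drawn from the coincidence template classify as
    coincidence-preferring at low noise."""
    cells = make_population("a2_coincident", 15, seed=4,
                            trial_noise_cv=0.05, baseline_sd=0.02,
                            include_fm=False)
    ts = simulate_population(cells, protocol_nofm, seed=4)
    rt = process_dataset(ts)
    labels = [classify_timing_preference(rt, r).label
              for r in rt.roi_ids if rt.twotone_sig_matrix(r).any()]
    assert len(labels) > 0
    frac = np.mean([lab == "coincident_preferring" for lab in labels])
    assert frac > 0.5
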