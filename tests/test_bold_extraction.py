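import numpy as np
import pandas as pd
import pytest

from nbacklight import (
    Bold4D,
    SimulationSpec,
    VoxelGrid,
    brain_mask,
    extract_trial_patterns,
    fit_first_level,
    make_contrast,
    simulate_subject,
    smooth_gaussian,
    valid_trials,
)
from nbacklight.bold_extraction import TrialPatternSet
from nbacklight.task_design import NBackDesign, generate_design

from _oracles import gaussian_kernel_1d

GRID = VoxelGrid((8, 8, 8))


def noiseless_spec(**kw):
    defaults = dict(
        grid=GRID, n_treated=0, n_control=2, noise_sd=0.0, pattern_sd=0.0, seed=9,
        amplitudes={0: 1.0, 1: 1.5, 2: 2.0},
    )
    defaults.update(kw)
    return SimulationSpec(**defaults)


class TestSmoothing:
    def test_zero_fwhm_is_identity(self):
        vol = np.random.default_rng(0).standard_normal(GRID.shape)
        out = smooth_gaussian(vol, 0.0, grid=GRID)
        assert np.array_equal(out, vol)

    def test_constant_volume_preserved(self):
        vol = np.full(GRID.shape, 3.25)
        out = smooth_gaussian(vol, 8.0, grid=GRID)
        assert np.allclose(out, 3.25)

    def test_delta_peak_matches_kernel_oracle(self):
        """Peak of a smoothed delta equals the product of the per-axis
        discrete kernel centre weights (separable convolution)."""
        vol = np.zeros((15, 15, 15))
        vol[7, 7, 7] = 1.0
        fwhm = 8.0
        out = smooth_gaussian(vol, fwhm, grid=VoxelGrid((15, 15, 15)))
        sigma_vox = fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0
        k0 = gaussian_kernel_1d(sigma_vox)[len(gaussian_kernel_1d(sigma_vox)) // 2]
        assert out[7, 7, 7] == pytest.approx(k0**3, rel=1e-10)
        assert out.sum() == pytest.approx(1.0, rel=1e-10)

    def test_negative_fwhm_raises(self):
        with pytest.raises(ValueError):
            smooth_gaussian(np.zeros(GRID.shape), -1.0, grid=GRID)


class TestFirstLevel:
    def test_noiseless_amplitude_recovery(self):
        spec = noiseless_spec()
        bold, _ = simulate_subject(spec, "control_00", "baseline")
        effects = fit_first_level(bold, spec.design)
        mask = brain_mask(spec)
        for level, amp in spec.amplitudes.items():
            vals = effects.effects[level][mask]
            assert np.allclose(vals, amp, atol=1e-3)  # float32 storage of the session

    def test_all_zero_signal_gives_zero_coefficients(self, session_design):
        data = np.zeros(GRID.shape + (184,), dtype=np.float32)
        bold = Bold4D(GRID, 2.0, data, "p0", "control", "baseline")
        effects = fit_first_level(bold, session_design, mask=np.ones(GRID.shape, bool))
        for vol in effects.effects.values():
            assert np.allclose(vol, 0.0)

    def test_rank_deficient_design_names_columns(self):
        # two levels sharing identical onsets -> identical regressors
        base = generate_design(levels=(0,), blocks_per_level=1, stimuli_per_block=8, targets_per_block=2, seed=0)
        t0 = base.table.assign(level=0)
        t1 = base.table.assign(level=1)
        table = (
            pd.concat([t0, t1]).sort_values(["block", "index", "level"]).reset_index(drop=True)
        )
        twisted = NBackDesign(
            levels=(0, 1),
            blocks_per_level=1,
            stimuli_per_block=8,
            targets_per_block=2,
            stimulus_duration=0.5,
            isi=1.5,
            instruction_duration=2.0,
            rest_duration=5.0,
            block_order=[(0, 0), (1, 0)],
            table=table,
        )
        data = np.random.default_rng(0).standard_normal(GRID.shape + (40,)).astype(np.float32)
        bold = Bold4D(GRID, 2.0, data, "p0", "control", "baseline")
        with pytest.raises(ValueError, match="level_1"):
            fit_first_level(bold, twisted)

    def test_time_axis_too_short_raises(self, session_design):
        data = np.zeros(GRID.shape + (10,), dtype=np.float32)
        bold = Bold4D(GRID, 2.0, data, "p0", "control", "baseline")
        with pytest.raises(ValueError, match="cover"):
            fit_first_level(bold, session_design)


class TestContrasts:
    @pytest.fixture()
    def effects(self):
        spec = noiseless_spec()
        bold, _ = simulate_subject(spec, "control_00", "baseline")
        return fit_first_level(bold, spec.design), spec

    def test_two_gt_zero_is_difference(self, effects):
        eff, spec = effects
        c = make_contrast(eff, "2>0")
        mask = brain_mask(spec)
        assert np.allclose(c.values[mask], spec.amplitudes[2] - spec.amplitudes[0], atol=1e-3)

    def test_two_gt_rest_recovers_amplitude(self, effects):
        eff, spec = effects
        c = make_contrast(eff, "2>rest")
        assert np.allclose(c.values[brain_mask(spec)], spec.amplitudes[2], atol=1e-3)

    def test_contrast_linearity(self, effects):
        eff, _ = effects
        lhs = make_contrast(eff, "2>1").values
        rhs = make_contrast(eff, "2>0").values - make_contrast(eff, "1>0").values
        assert np.allclose(lhs, rhs, atol=1e-12)

    def test_equal_effects_cancel(self, effects):
        eff, spec = effects
        eff.effects[0] = eff.effects[2].copy()
        c = make_contrast(eff, "2>0")
        assert np.allclose(c.values, 0.0)

    def test_unknown_contrast_raises(self, effects):
        with pytest.raises(ValueError, match="unknown contrast"):
            make_contrast(effects[0], "3>0")

    def test_task_contrast_weights_sum_to_zero(self):
        from nbacklight import CONTRAST_WEIGHTS

        for name, weights in CONTRAST_WEIGHTS.items():
            if name != "2>rest":
                assert sum(weights.values()) == 0


class TestTrialPatterns:
    def test_row_counts_match_valid_trials(self):
        spec = noiseless_spec()
        base, _ = simulate_subject(spec, "control_00", "baseline")
        fu, _ = simulate_subject(spec, "control_00", "followup")
        ps = extract_trial_patterns(base, fu, spec.design)
        assert ps.data.shape[0] == 2 * valid_trials(spec.design, 2) == 84
        assert (ps.labels["time_point"] == "baseline").sum() == 42

    def test_identical_sessions_classify_at_chance(self):
        """Same constant signal at both time points -> all rows identical."""
        data = np.full(GRID.shape + (184,), 7.0, dtype=np.float32)
        mask = np.ones(GRID.shape, bool)
        base = Bold4D(GRID, 2.0, data, "p0", "control", "baseline")
        fu = Bold4D(GRID, 2.0, data.copy(), "p0", "control", "followup")
        ps = extract_trial_patterns(base, fu, generate_design(seed=1), mask=mask)
        assert np.allclose(ps.data, ps.data[0][None, :])
        assert np.allclose(ps.data, 0.0)  # 0-back reference cancels exactly

    def test_equal_level_responses_carry_no_information(self):
        """Equal 0- and 2-back amplitudes: the 0-back reference removes all
        multivoxel and time-point structure.  (Per-trial values retain a
        small deterministic HRF ramp/sampling-phase residual, so rows are
        spatially flat and identical across time points rather than
        literally zero.)"""
        spec = noiseless_spec(amplitudes={0: 1.2, 1: 1.2, 2: 1.2})
        base, _ = simulate_subject(spec, "control_00", "baseline")
        fu, _ = simulate_subject(spec, "control_00", "followup")
        ps = extract_trial_patterns(base, fu, spec.design)
        # spatially uniform: no voxel pattern at all
        assert np.allclose(ps.data.std(axis=1), 0.0, atol=1e-5)
        # identical between time points: nothing for a classifier to find
        is_base = (ps.labels["time_point"] == "baseline").to_numpy()
        assert np.allclose(ps.data[is_base], ps.data[~is_base], atol=1e-5)
        # and bounded: residuals are a small fraction of the amplitude
        assert np.abs(ps.data).max() < 0.5 * 1.2

    def test_voxel_permutation_equivariance(self):
        spec = noiseless_spec(noise_sd=0.5)
        base, _ = simulate_subject(spec, "control_00", "baseline")
        fu, _ = simulate_subject(spec, "control_00", "followup")
        ps = extract_trial_patterns(base, fu, spec.design)

        perm = (2, 0, 1)  # rotate the spatial axes: a voxel permutation
        def permute(bold):
            return Bold4D(
                VoxelGrid(tuple(GRID.shape[a] for a in perm)),
                bold.tr,
                np.transpose(bold.data, perm + (3,)).copy(),
                bold.participant,
                bold.group,
                bold.time_point,
            )

        ps_perm = extract_trial_patterns(permute(base), permute(fu), spec.design)
        # map mask columns of the permuted volume back to original columns
        col_of = np.full(GRID.shape, -1)
        col_of[ps.mask] = np.arange(ps.mask.sum())
        reordered = col_of.transpose(perm)[ps_perm.mask]
        assert np.allclose(ps_perm.data, ps.data[:, reordered])

    def test_lag_window_beyond_series_raises(self):
        spec = noiseless_spec()
        base, _ = simulate_subject(spec, "control_00", "baseline")
        fu, _ = simulate_subject(spec, "control_00", "followup")
        with pytest.raises(ValueError, match="lag window"):
            extract_trial_patterns(base, fu, spec.design, lag_window=(50, 60))

    def test_mismatched_grids_raise(self):
        a = Bold4D(GRID, 2.0, np.ones(GRID.shape + (5,), np.float32), "p", "control", "baseline")
        other = VoxelGrid((6, 6, 6))
        b = Bold4D(other, 2.0, np.ones(other.shape + (5,), np.float32), "p", "control", "followup")
        with pytest.raises(ValueError, match="grid"):
            extract_trial_patterns(a, b, generate_design(seed=1))

    def test_save_load_round_trip(self, tmp_path):
        spec = noiseless_spec(noise_sd=0.3)
        base, _ = simulate_subject(spec, "control_00", "baseline")
        fu, _ = simulate_subject(spec, "control_00", "followup")
        ps = extract_trial_patterns(base, fu, spec.design)
        ps.save(tmp_path / "p0")
        back = TrialPatternSet.load(tmp_path / "p0")
        assert np.allclose(back.data, ps.data, atol=1e-6)
        assert back.participant == ps.participant
        assert back.group == ps.group
        assert np.array_equal(back.mask, ps.mask)
        pd.testing.assert_frame_equal(back.labels, ps.labels)
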