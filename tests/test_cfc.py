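import numpy as np
import pytest

import wmcoupling as w
from wmcoupling import cfc
from wmcoupling.signal_core import AnalysisWindowSet, Band, PhaseAmpSeries, TrialWindow


def brute_force_mi(phase, amp, n_bins=18):
    """Independent single-pass oracle: per-sample binning, then Eq.-style MI."""
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for ph, a in zip(phase, amp):
        j = int((ph + np.pi) / (2 * np.pi) * n_bins)
        if j == n_bins:
            j = 0
        sums[j] += a
        counts[j] += 1
    means = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    total = sum(means)
    p = [m / total for m in means]
    h = -sum(q * np.log(q) for q in p if q > 0)
    return (np.log(n_bins) - h) / np.log(n_bins), p


class TestBinning:
    def test_uniform_phases_constant_amplitude_give_flat_distribution(self):
        phase = np.linspace(-np.pi, np.pi, 18 * 100, endpoint=False)
        dist = cfc.bin_by_phase((phase, np.ones_like(phase)))
        np.testing.assert_allclose(dist.p, 1 / 18, atol=1e-12)
        assert dist.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_amplitude_concentrated_in_one_bin_gives_point_mass(self):
        rng = np.random.default_rng(0)
        phase = rng.uniform(-np.pi, np.pi, 5000)
        idx = cfc.phase_bin_indices(phase)
        amp = np.where(idx == 5, 1.0, 0.0)
        dist = cfc.bin_by_phase((phase, amp))
        assert dist.p[5] == pytest.approx(1.0)
        assert np.all(dist.p[np.arange(18) != 5] == 0.0)

    def test_boundary_phase_pi_wraps_to_first_bin(self):
        idx = cfc.phase_bin_indices(np.array([-np.pi, np.pi - 1e-9, np.pi]))
        assert idx[0] == 0 and idx[1] == 17 and idx[2] == 0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(1)
        phase = rng.uniform(-np.pi, np.pi, 1000)
        amp = rng.random(1000)
        dist = cfc.bin_by_phase((phase, amp))
        mi = cfc.modulation_index(dist).mi
        mi_oracle, p_oracle = brute_force_mi(phase, amp)
        np.testing.assert_allclose(dist.p, p_oracle, atol=1e-12)
        assert mi == pytest.approx(mi_oracle, abs=1e-12)

    def test_empty_series_and_degenerate_input_raise(self):
        with pytest.raises(ValueError):
            cfc.bin_by_phase((np.array([]), np.array([])))
        with pytest.raises(ValueError):
            cfc.bin_by_phase((np.zeros(10), np.zeros(10)))
        with pytest.raises(ValueError):
            cfc.bin_by_phase((np.zeros(10), np.ones(10)), n_bins=1)

    def test_empty_bins_warn(self):
        phase = np.zeros(100)  # all in one bin
        with pytest.warns(UserWarning, match="no samples"):
            cfc.bin_by_phase((phase, np.ones(100)))


class TestModulationIndex:
    def _dist(self, p):
        p = np.asarray(p, dtype=float)
        return cfc.PhaseAmpDistribution(
            n_bins=p.size, mean_amp_per_bin=p.copy(), p=p,
            bin_edges=np.linspace(-np.pi, np.pi, p.size + 1), n_samples=1000,
        )

    def test_uniform_distribution_has_zero_mi(self):
        assert cfc.modulation_index(self._dist(np.full(18, 1 / 18))).mi == pytest.approx(0.0, abs=1e-15)

    def test_point_mass_has_unit_mi(self):
        p = np.zeros(18)
        p[3] = 1.0
        assert cfc.modulation_index(self._dist(p)).mi == pytest.approx(1.0)

    def test_von_mises_shaped_distribution_matches_entropy_oracle(self):
        """p proportional to exp(cos(theta_j)) over the 18 bin centers: MI must
        equal the directly evaluated (log N - H)/log N."""
        centers = -np.pi + (np.arange(18) + 0.5) * (2 * np.pi / 18)
        p = np.exp(np.cos(centers))
        p /= p.sum()
        expected = (np.log(18) + np.sum(p * np.log(p))) / np.log(18)
        assert cfc.modulation_index(self._dist(p)).mi == pytest.approx(expected, abs=1e-14)

    def test_mi_bounded_on_random_distributions(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            p = rng.dirichlet(np.full(18, rng.uniform(0.05, 5.0)))
            mi = cfc.modulation_index(self._dist(p)).mi
            assert 0.0 <= mi <= 1.0

    def test_amplitude_scale_invariance(self):
        rng = np.random.default_rng(3)
        phase = rng.uniform(-np.pi, np.pi, 4000)
        amp = rng.random(4000)
        base = cfc.mi_from_series((phase, amp)).mi
        for c in (1e-6, 3.7, 1e6):
            assert cfc.mi_from_series((phase, c * amp)).mi == pytest.approx(base, abs=1e-12)


class TestRecordingMI:
    def test_cross_equals_within_when_channels_coincide(self, coupled_recording):
        within = w.mi_within(coupled_recording, "Cz")
        cross = w.mi_cross(coupled_recording, "Cz", "Cz")
        assert cross.mi == pytest.approx(within.mi, abs=1e-15)

    def test_on_band_mi_exceeds_off_band_mi(self, coupled_recording):
        on = w.mi_within(coupled_recording, "Cz", Band(4, 8), Band(40, 80)).mi
        off = w.mi_within(coupled_recording, "Cz", Band(8, 9), Band(30, 40)).mi
        assert on > 5 * off

    def test_determinism(self, coupled_recording):
        a = w.mi_within(coupled_recording, "Cz").mi
        b = w.mi_within(coupled_recording, "Cz").mi
        assert a == b

    def test_directionality_of_planted_cross_coupling(self, cross_coupled_recording):
        fwd = w.mi_cross(cross_coupled_recording, "FT9", "Cz").mi
        rev = w.mi_cross(cross_coupled_recording, "Cz", "FT9").mi
        assert fwd > 10 * rev


class TestTimeBinnedMI:
    def _series(self, duration_s, fs=250.0, seed=0):
        rng = np.random.default_rng(seed)
        n = int(duration_s * fs)
        return PhaseAmpSeries(
            phase_rad=rng.uniform(-np.pi, np.pi, n), amplitude=rng.random(n), fs_hz=fs
        )

    def test_three_10s_segments_average_two_5s_bins_each(self):
        series = self._series(30.0)
        out = cfc.mi_time_binned(series)
        assert out.shape == (3,)
        fs = int(series.fs_hz)
        for s in range(3):
            seg = slice(s * 10 * fs, (s + 1) * 10 * fs)
            ph, am = series.phase_rad[seg], series.amplitude[seg]
            manual = np.mean([
                cfc.mi_from_series((ph[: 5 * fs], am[: 5 * fs])).mi,
                cfc.mi_from_series((ph[5 * fs :], am[5 * fs :])).mi,
            ])
            assert out[s] == pytest.approx(manual, abs=1e-15)

    def test_partial_final_bin_is_discarded(self):
        """12-s segments: bins [0,5) and [5,10) used, trailing 2 s dropped."""
        series = self._series(36.0)
        out = cfc.mi_time_binned(series)
        fs = int(series.fs_hz)
        seg0 = slice(0, 12 * fs)
        ph, am = series.phase_rad[seg0], series.amplitude[seg0]
        manual = np.mean([
            cfc.mi_from_series((ph[: 5 * fs], am[: 5 * fs])).mi,
            cfc.mi_from_series((ph[5 * fs : 10 * fs], am[5 * fs : 10 * fs])).mi,
        ])
        assert out[0] == pytest.approx(manual, abs=1e-15)

    def test_segment_without_full_bin_flagged_nan(self):
        series = self._series(9.0)  # 3-s segments < one 5-s bin
        with pytest.warns(UserWarning, match="indicator undefined"):
            out = cfc.mi_time_binned(series)
        assert np.isnan(out).all()

    def test_indicators_mutually_correlate_under_stationary_coupling(self):
        """Per-segment MI indicators agree across simulated participants."""
        vals = []
        for seed in range(30):
            rec = w.generate_recording(
                montage=["Cz"], duration_s=40.0, fs_hz=250.0,
                couplings=[w.CouplingSpec("Cz", "Cz",
                                          strength_chi=0.3 + 0.02 * (seed % 20),
                                          noise_sd=0.5)],
                seed=seed,
            )
            series, n_edge = w.signal_core.phase_amp_series(rec, "Cz", "Cz")
            windows = w.signal_core.whole_recording_windows(rec, n_edge)
            concat = w.concatenate_windows(series, windows)
            vals.append(cfc.mi_time_binned(concat))
        vals = np.array(vals)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            assert np.corrcoef(vals[:, a], vals[:, b])[0, 1] > 0.5


class TestComodulogram:
    def test_mask_is_deterministic_given_seed(self, uncoupled_recording):
        a = cfc.comodulogram(uncoupled_recording, "Cz", n_perm=150, seed=3)
        b = cfc.comodulogram(uncoupled_recording, "Cz", n_perm=150, seed=3)
        np.testing.assert_array_equal(a.significance_mask, b.significance_mask)
        np.testing.assert_array_equal(a.mi_grid, b.mi_grid)

    def test_grid_geometry_matches_default_band_grids(self, coupled_recording):
        com = cfc.comodulogram(coupled_recording, "Cz", n_perm=120, seed=0)
        assert com.mi_grid.shape == (7, 5)
        np.testing.assert_allclose(com.phase_centers_hz, np.arange(3.5, 10.5))
        np.testing.assert_allclose(com.amp_centers_hz, np.arange(35.0, 85.0, 10.0))

    def test_planted_coupling_cell_is_masked(self, coupled_recording):
        com = cfc.comodulogram(coupled_recording, "Cz", n_perm=300, seed=1)
        hit = [
            com.significance_mask[i, j]
            for i, pb in enumerate(com.phase_bands)
            for j, ab in enumerate(com.amp_bands)
            if pb.low_hz <= 6.0 <= pb.high_hz and ab.low_hz <= 60.0 <= ab.high_hz
        ]
        assert any(hit)

    def test_small_n_perm_warns(self, uncoupled_recording):
        with pytest.warns(UserWarning, match="n_perm"):
            cfc.comodulogram_null([np.random.default_rng(0).random((7, 5))], n_perm=10)


class TestMotorContrast:
    def test_masks_partition_window_sample_counts(self):
        rng = np.random.default_rng(6)
        series = PhaseAmpSeries(rng.uniform(-np.pi, np.pi, 5000), rng.random(5000), 250.0)
        win = TrialWindow(2.0, 10.0, motor_masks=((3.0, 3.4), (7.0, 7.4)))
        ws = AnalysisWindowSet([win])
        n_m = len(w.concatenate_windows(series, ws, motor=True))
        n_nm = len(w.concatenate_windows(series, ws, motor=False))
        assert n_m + n_nm == len(w.concatenate_windows(series, ws))
        assert n_m == 200

    def test_windows_without_masks_rejected(self, coupled_recording):
        ws = AnalysisWindowSet([TrialWindow(5.0, 15.0)])
        with pytest.raises(ValueError, match="motor masks"):
            cfc.motor_nonmotor_mi(coupled_recording, "Cz", ws)

    def test_fully_masked_window_leaves_no_nonmotor_samples(self, coupled_recording):
        ws = AnalysisWindowSet([TrialWindow(5.0, 6.0, motor_masks=((5.0, 6.0),))])
        with pytest.raises(ValueError):
            cfc.motor_nonmotor_mi(coupled_recording, "Cz", ws)
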