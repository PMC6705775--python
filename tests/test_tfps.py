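import numpy as np
import pytest
from scipy.signal import hilbert

from netsig import TrialSet, build_fcn, plv, rid_rihaczek, synth_coupled_trials
from netsig.tfps import ambiguity_function, phase_difference


def _tone(f0: float, fs: float, t_len: int, phase: float = 0.0) -> np.ndarray:
    t = np.arange(t_len) / fs
    return np.cos(2 * np.pi * f0 * t + phase)


class TestTrialSet:
    def test_valid_construction(self):
        ts = TrialSet(np.zeros((3, 2, 16)), fs=128.0, t0=-100.0)
        assert ts.n_trials == 3 and ts.n_channels == 2 and ts.n_samples == 16
        assert ts.times_ms()[0] == -100.0

    @pytest.mark.parametrize(
        "shape,fs",
        [((0, 2, 16), 128.0), ((3, 1, 16), 128.0), ((3, 2, 4), 128.0),
         ((3, 2, 16), 0.0)],
    )
    def test_invalid_rejected(self, shape, fs):
        with pytest.raises(ValueError):
            TrialSet(np.zeros(shape), fs=fs)

    def test_nonfinite_rejected(self):
        data = np.zeros((2, 2, 16))
        data[0, 0, 0] = np.nan
        with pytest.raises(ValueError):
            TrialSet(data, fs=128.0)


class TestAmbiguityFunction:
    def test_origin_carries_total_energy(self):
        a = ambiguity_function(np.ones(32))
        assert abs(abs(a[0, 0]) - 32.0) < 1e-10

    def test_impulse_concentrated_at_zero_lag(self):
        x = np.zeros(32)
        x[10] = 1.0
        a = ambiguity_function(x)
        assert np.abs(a[:, 1:]).max() < 1e-12
        assert np.abs(a[:, 0]).max() == pytest.approx(1.0)

    def test_tone_concentrated_on_zero_doppler_ridge(self):
        n = np.arange(64)
        a = ambiguity_function(np.exp(2j * np.pi * 5 * n / 64))
        energy = np.abs(a) ** 2
        assert energy[0].sum() / energy.sum() > 1 - 1e-10

    def test_hermitian_symmetry_away_from_nyquist(self):
        t = 32
        a = ambiguity_function(np.random.default_rng(0).standard_normal(t) + 0j)
        for p in range(1, t):
            for m in range(t):
                if p == t // 2 or m == t // 2:
                    continue
                assert abs(a[(-p) % t, (-m) % t] - np.conj(a[p, m])) < 1e-10

    def test_nonfinite_input_rejected(self):
        x = np.zeros(16)
        x[0] = np.inf
        with pytest.raises(ValueError):
            ambiguity_function(x)


class TestRidRihaczek:
    def test_tone_peaks_at_its_frequency_bin(self):
        fs, t_len, f0 = 64.0, 64, 8.0
        tfd = rid_rihaczek(_tone(f0, fs, t_len), sigma=0.01, fs=fs)
        k0 = int(round(f0 * t_len / fs))
        assert np.all(np.abs(tfd.values).argmax(axis=1) == k0)

    def test_energy_preserved(self):
        x = np.random.default_rng(1).standard_normal(64)
        tfd = rid_rihaczek(x, sigma=0.01)
        energy = (np.abs(hilbert(x)) ** 2).sum()
        assert abs(np.real(tfd.values.sum()) / (64 * energy) - 1.0) < 0.02

    def test_zero_signal_gives_zero_tfd(self):
        tfd = rid_rihaczek(np.zeros(32), sigma=0.01)
        assert np.abs(tfd.values).max() < 1e-12

    def test_small_sigma_suppresses_cross_terms(self):
        # two well separated tones; cross-terms live midway between them
        fs, t_len = 128.0, 128
        x = _tone(10.0, fs, t_len) + _tone(50.0, fs, t_len)
        mid = int(round(30.0 * t_len / fs))
        band = slice(mid - 2, mid + 3)
        e_small = np.abs(rid_rihaczek(x, sigma=0.01, fs=fs).values[:, band]).sum()
        e_large = np.abs(rid_rihaczek(x, sigma=10.0, fs=fs).values[:, band]).sum()
        assert e_small < e_large

    def test_invalid_sigma_rejected(self):
        with pytest.raises(ValueError):
            rid_rihaczek(np.ones(16), sigma=0.0)


class TestPhaseDifference:
    def test_self_comparison_is_zero(self):
        tfd = rid_rihaczek(_tone(8.0, 64.0, 64), sigma=0.01, fs=64.0)
        assert np.abs(phase_difference(tfd, tfd)).max() < 1e-12

    def test_grid_mismatch_rejected(self):
        a = rid_rihaczek(np.ones(16) + np.arange(16.0), sigma=0.01)
        b = rid_rihaczek(np.ones(32) + np.arange(32.0), sigma=0.01)
        with pytest.raises(ValueError):
            phase_difference(a, b)

    def test_bilinear_invariance_to_constant_phase_offset(self):
        # a constant phase offset of a pure tone multiplies both x(t) and
        # X(f) and cancels in the bilinear form: the measured difference
        # at the tone bin is 0, not the offset
        fs, t_len, f0 = 64.0, 64, 8.0
        a = rid_rihaczek(_tone(f0, fs, t_len), sigma=0.01, fs=fs)
        b = rid_rihaczek(_tone(f0, fs, t_len, phase=np.pi / 3), sigma=0.01, fs=fs)
        k0 = int(round(f0 * t_len / fs))
        mid = slice(t_len // 4, 3 * t_len // 4)
        assert np.abs(phase_difference(a, b)[mid, k0]).max() < 1e-6


class TestPLV:
    def test_identical_trials_give_unit_plv(self):
        rng = np.random.default_rng(0)
        trials = rng.standard_normal((5, 64))
        p = plv(trials, trials.copy(), sigma=0.01)
        assert np.all(np.abs(p.values - 1.0) < 1e-9)

    def test_values_in_unit_interval(self):
        rng = np.random.default_rng(1)
        p = plv(rng.standard_normal((4, 64)), rng.standard_normal((4, 64)))
        assert np.all(p.values >= 0) and np.all(p.values <= 1)

    def test_independent_noise_matches_rayleigh_floor(self):
        rng = np.random.default_rng(2)
        k = 50
        p = plv(rng.standard_normal((k, 64)), rng.standard_normal((k, 64)))
        floor = np.sqrt(np.pi) / 2 / np.sqrt(k)
        assert abs(p.values.mean() - floor) / floor < 0.10

    def test_invariant_to_common_phase_shift(self):
        fs, t_len, k = 128.0, 128, 8
        rng = np.random.default_rng(3)
        base_i = np.empty((k, t_len))
        base_j = np.empty((k, t_len))
        shift_i = np.empty((k, t_len))
        shift_j = np.empty((k, t_len))
        for trial in range(k):
            f = rng.uniform(4, 8)
            ph = rng.uniform(-np.pi, np.pi)
            noise = 0.05 * rng.standard_normal((2, t_len))
            base_i[trial] = _tone(f, fs, t_len, ph) + noise[0]
            base_j[trial] = _tone(f, fs, t_len, ph + 0.4) + noise[1]
            common = rng.uniform(-np.pi, np.pi)
            shift_i[trial] = np.real(hilbert(base_i[trial]) * np.exp(1j * common))
            shift_j[trial] = np.real(hilbert(base_j[trial]) * np.exp(1j * common))
        a = plv(base_i, base_j, fs=fs)
        b = plv(shift_i, shift_j, fs=fs)
        sel = (a.freqs >= 4) & (a.freqs <= 8)
        assert abs(a.values[:, sel].mean() - b.values[:, sel].mean()) < 0.05

    def test_trial_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            plv(np.zeros((3, 16)), np.zeros((2, 16)))


class TestBuildFcn:
    def test_coupled_pair_fully_locked_without_noise(self):
        ts = synth_coupled_trials(
            6, 2, fs=128.0, duration=0.5, coupled_groups=((0, 1),),
            noise_sd=0.0, phase_jitter_sd=0.0, seed=0,
        )
        g = build_fcn(ts, t_window=(100.0, 400.0), f_band=(4.0, 8.0))
        assert g.weights[0, 1] > 1 - 1e-9

    def test_within_group_exceeds_between_group(self):
        ts = synth_coupled_trials(
            12, 5, fs=128.0, duration=0.5,
            coupled_groups=((0, 1), (2, 3)), noise_sd=0.1, seed=1,
        )
        g = build_fcn(ts, t_window=(100.0, 400.0), f_band=(4.0, 8.0))
        within = [g.weights[0, 1], g.weights[2, 3]]
        between = [g.weights[i, j] for i in (0, 1) for j in (2, 3, 4)]
        assert min(within) > max(between)

    def test_output_is_valid_weighted_graph(self):
        ts = synth_coupled_trials(4, 4, fs=128.0, duration=0.25,
                                  coupled_groups=((0, 1),), seed=2)
        g = build_fcn(ts, t_window=(50.0, 200.0), f_band=(4.0, 8.0))
        assert g.n_nodes == 4
        assert np.all(np.diag(g.weights) == 0)
        assert np.all((g.weights >= 0) & (g.weights <= 1))

    def test_58_channel_matrix_shape(self):
        ts = synth_coupled_trials(3, 58, fs=128.0, duration=0.5,
                                  coupled_groups=(tuple(range(10)),), seed=3)
        g = build_fcn(ts, t_window=(25.0, 75.0), f_band=(4.0, 8.0))
        assert g.weights.shape == (58, 58)

    def test_empty_selection_rejected(self):
        ts = synth_coupled_trials(2, 2, fs=128.0, duration=0.25, seed=4)
        with pytest.raises(ValueError):
            build_fcn(ts, t_window=(900.0, 950.0), f_band=(4.0, 8.0))


class TestSynthCoupledTrials:
    def test_seed_reproducibility(self):
        a = synth_coupled_trials(3, 4, seed=5, coupled_groups=((0, 1),))
        b = synth_coupled_trials(3, 4, seed=5, coupled_groups=((0, 1),))
        assert np.array_equal(a.data, b.data)

    def test_phase_jitter_decreases_within_group_plv(self):
        means = []
        for jitter in (0.0, 0.8, 2.0):
            vals = []
            for seed in range(5):
                ts = synth_coupled_trials(
                    10, 2, fs=128.0, duration=0.5, coupled_groups=((0, 1),),
                    noise_sd=0.05, phase_jitter_sd=jitter, seed=seed,
                )
                g = build_fcn(ts, t_window=(100.0, 400.0), f_band=(4.0, 8.0))
                vals.append(g.weights[0, 1])
            means.append(np.mean(vals))
        assert means[0] > means[1] > means[2]
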