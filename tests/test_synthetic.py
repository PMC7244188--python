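"""Generators: determinism, closed-form moments, conservation, trace contracts."""

import math

import numpy as np
import pytest

from calyx import synthetic as syn
from calyx.trains import TrainRecord, cumulative_curve


def _gen_all(seed):
    """Run every generator once under one root seed; return concatenated output."""
    out = []
    cfg = syn.SimConfig(seed=seed, n_sweeps=20)
    out.append(syn.gen_epsc_samples(syn.ReleaseModelParams(50, 0.3, 40.0, cv_q=0.3), cfg).amplitudes)
    dp = syn.DepletionParams(syn.ReleaseModelParams(100, 0.4, 40.0), tau_rec=2.0)
    out.append(syn.gen_std_train(dp, syn.SimConfig(seed=seed)).amplitudes)
    out.append(
        syn.gen_dose_response([0.1, 0.5, 1.0], 0.47, 76, 1.0, 2.0, syn.SimConfig(seed=seed))[
            "block_pct"
        ].to_numpy()
    )
    out.append(syn.gen_cm_trace(0.4, 9.0, syn.SimConfig(seed=seed), noise_sd=0.01).values[:500])
    pre, post = syn.gen_paired_spikes(50.0, 50, 0.3, syn.SimConfig(seed=seed))
    out.append(post.times)
    spk, _ = syn.gen_unit_raster(5.0, np.arange(20) * 0.5, 0.7, syn.SimConfig(seed=seed))
    out.append(spk.times)
    out.append(
        syn.gen_vm_trace(-70, -55, 0.3, 0.3, 1.0, 2.0, syn.SimConfig(seed=seed)).values[:500]
    )
    return np.concatenate(out)


def test_identical_seed_gives_identical_outputs():
    a = _gen_all(7)
    b = _gen_all(7)
    assert np.array_equal(a, b)
    assert not np.array_equal(a, _gen_all(8))


class TestEpscSamples:
    def test_no_release_gives_zero_amplitudes(self):
        s = syn.gen_epsc_samples(
            syn.ReleaseModelParams(300, 0.0, 40.0), syn.SimConfig(seed=1, n_sweeps=50)
        )
        assert np.all(s.amplitudes == 0.0)

    def test_deterministic_limit_all_sites_release(self):
        s = syn.gen_epsc_samples(
            syn.ReleaseModelParams(300, 1.0, 40.0, cv_q=0.0), syn.SimConfig(seed=1, n_sweeps=10)
        )
        assert np.all(s.amplitudes == 12_000.0)

    def test_moments_match_binomial_closed_forms(self):
        # N=300, p=0.1, q=40 pA: mean Npq = 1200 pA, var Nq^2 p(1-p) = 43200 pA^2
        n = 100_000
        s = syn.gen_epsc_samples(
            syn.ReleaseModelParams(300, 0.1, 40.0), syn.SimConfig(seed=2, n_sweeps=n)
        )
        se_mean = math.sqrt(43_200 / n)
        assert abs(s.amplitudes.mean() - 1200.0) < 3 * se_mean
        se_var = 43_200 * math.sqrt(2.0 / (n - 1))  # normal-approx SE of the variance
        assert abs(s.amplitudes.var(ddof=1) - 43_200.0) < 4 * se_var

    def test_quantal_variability_keeps_amplitudes_positive(self):
        s = syn.gen_epsc_samples(
            syn.ReleaseModelParams(20, 0.5, 10.0, cv_q=1.5), syn.SimConfig(seed=3, n_sweeps=200)
        )
        assert np.all(s.amplitudes >= 0.0)

    @pytest.mark.parametrize("bad", [dict(N=0, p_r=0.5, q=40.0), dict(N=10, p_r=1.5, q=40.0),
                                     dict(N=10, p_r=0.5, q=-1.0)])
    def test_invalid_parameters_rejected(self, bad):
        with pytest.raises(ValueError):
            syn.ReleaseModelParams(**bad)


class TestStdTrain:
    def test_expected_mode_first_amplitude_is_full_pool_release(self):
        dp = syn.DepletionParams(syn.ReleaseModelParams(300, 0.4, 40.0), tau_rec=2.0)
        s = syn.gen_std_train(dp, syn.SimConfig(seed=1), expected=True)
        assert s.amplitudes[0] == pytest.approx(300 * 0.4 * 40.0)

    def test_instant_refill_means_no_depression(self):
        dp = syn.DepletionParams(syn.ReleaseModelParams(300, 0.4, 40.0), tau_rec=1e-9)
        s = syn.gen_std_train(dp, syn.SimConfig(seed=1), expected=True)
        assert np.allclose(s.amplitudes, 300 * 0.4 * 40.0)

    def test_no_refill_cumulative_follows_geometric_series(self):
        # oracle: iterate the depletion recursion by hand
        N, p, q = 300, 0.4, 40.0
        dp = syn.DepletionParams(syn.ReleaseModelParams(N, p, q), tau_rec=math.inf, n_stim=30)
        s = syn.gen_std_train(dp, syn.SimConfig(seed=1), expected=True)
        cum = np.cumsum(s.amplitudes)
        k = np.arange(1, 31)
        assert np.allclose(cum, N * q * (1 - (1 - p) ** k), rtol=1e-12)
        assert cum[-1] < N * q  # approaches Nq from below

    def test_stochastic_train_never_releases_more_than_the_pool(self):
        N, q = 50, 40.0
        dp = syn.DepletionParams(syn.ReleaseModelParams(N, 0.9, q), tau_rec=math.inf, n_stim=40)
        for seed in range(20):
            s = syn.gen_std_train(dp, syn.SimConfig(seed=seed))
            assert s.amplitudes.sum() <= N * q + 1e-9
            assert np.all(s.amplitudes >= 0)


class TestRecoveryTests:
    def test_expected_fractions_follow_single_exponential(self):
        N, p, q, tau = 300, 0.4, 40.0, 2.0
        dp = syn.DepletionParams(syn.ReleaseModelParams(N, p, q), tau_rec=tau, n_stim=30)
        intervals = [0.1, 0.5, 1.0, 2.0, 4.0, 8.0]
        tests = syn.gen_recovery_tests(dp, intervals, syn.SimConfig(seed=1), expected=True)
        first = N * p * q
        fracs = np.array([a / first for _, a in tests])
        # oracle: f(t) = 1 - (1 - f0) exp(-t/tau) with f0 the depleted pool fraction
        pool = float(N)
        refill = 1 - math.exp(-dp.isi / tau)
        for _ in range(30):
            pool -= pool * p
            pool += (N - pool) * refill
        f0 = pool / N
        expect = 1 - (1 - f0) * np.exp(-np.asarray(intervals) / tau)
        assert np.allclose(fracs, expect, rtol=1e-12)


class TestDoseResponse:
    def test_noiseless_half_max_at_ec50(self):
        df = syn.gen_dose_response([0.47], 0.47, 76.0, 1.0, 0.0, syn.SimConfig(seed=1))
        assert np.allclose(df["block_pct"], 38.0)

    def test_block_vanishes_at_low_concentration(self):
        df = syn.gen_dose_response([1e-9], 0.47, 76.0, 1.0, 0.0, syn.SimConfig(seed=1))
        assert np.allclose(df["block_pct"], 0.0, atol=1e-6)

    def test_blocks_clipped_to_percent_range(self):
        df = syn.gen_dose_response([0.01, 10.0], 0.47, 99.0, 1.0, 50.0, syn.SimConfig(seed=1))
        assert df["block_pct"].between(0, 100).all()


class TestCmTrace:
    def test_zero_jump_gives_flat_trace(self):
        t = syn.gen_cm_trace(0.0, 9.86, syn.SimConfig(seed=1))
        assert np.allclose(t.values, t.values[0])

    def test_decay_value_at_measurement_window_matches_closed_form(self):
        t = syn.gen_cm_trace(0.41, 9.86, syn.SimConfig(seed=1), baseline=0.0, pulse_end=1.0)
        i = np.searchsorted(t.times, 1.45)
        assert t.values[i] == pytest.approx(0.41 * 2 ** (-0.45 / 9.86), rel=1e-3)

    def test_half_decay_is_by_construction(self):
        h = 5.0
        t = syn.gen_cm_trace(1.0, h, syn.SimConfig(seed=1), baseline=0.0, pulse_end=1.0, duration=20.0)
        i = np.searchsorted(t.times, 1.0 + h)
        assert t.values[i] == pytest.approx(0.5, rel=1e-3)

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError):
            syn.gen_cm_trace(0.4, 9.86, syn.SimConfig(seed=1), pulse_end=1.0, duration=1.2)

    def test_timestamps_strictly_increasing_and_units_declared(self):
        t = syn.gen_cm_trace(0.4, 9.86, syn.SimConfig(seed=1))
        assert np.all(np.diff(t.times) > 0)
        assert t.unit == "pF"


class TestCaCurrent:
    def test_rectangle_charge(self):
        t = syn.gen_ca_current(1.0, 20.0, syn.SimConfig(seed=1))
        q = -np.trapezoid(t.values, t.times) * 1e3  # nA*s -> pC
        assert q == pytest.approx(20.0, rel=1e-9)

    def test_zero_duration_gives_zero_trace(self):
        t = syn.gen_ca_current(1.0, 0.0, syn.SimConfig(seed=1))
        assert np.all(t.values == 0.0)

    def test_exponential_rise_integral_matches_symbolic_oracle(self):
        amp, dur, tau = 1.0, 20.0, 0.2
        t = syn.gen_ca_current(amp, dur, syn.SimConfig(seed=1), rise_tau_ms=tau)
        q = -np.trapezoid(t.values, t.times) * 1e3
        expect = amp * (dur - tau * (1 - math.exp(-dur / tau)))  # pC
        assert q == pytest.approx(expect, rel=1e-3)


class TestPairedSpikes:
    def test_no_failures_transmits_everything(self):
        pre, post = syn.gen_paired_spikes(100.0, 200, 0.0, syn.SimConfig(seed=1))
        assert len(post) == len(pre) == 200

    def test_total_failure_gives_empty_postsynaptic_train(self):
        _, post = syn.gen_paired_spikes(100.0, 200, 1.0, syn.SimConfig(seed=1))
        assert len(post) == 0

    def test_transmitted_fraction_matches_binomial_oracle(self):
        fracs = [
            len(syn.gen_paired_spikes(100.0, 200, 0.3, syn.SimConfig(seed=s))[1]) / 200
            for s in range(50)
        ]
        se = math.sqrt(0.3 * 0.7 / 200) / math.sqrt(50)
        assert abs(np.mean(fracs) - 0.7) < 3 * se


class TestUnitRaster:
    def test_reliable_transsynaptic_unit_spikes_once_per_stimulus(self):
        stim = np.arange(50) * 5.0
        spk, st = syn.gen_unit_raster(0.0, stim, 1.0, syn.SimConfig(seed=1))
        assert len(spk) == 50
        off = spk.times - st.times
        assert np.all((off >= 0.005) & (off <= 0.025))

    def test_total_collision_removes_every_antidromic_spike(self):
        stim = np.arange(50) * 5.0
        forced_bg = stim - 0.002  # a spike 2 ms before every stimulus
        spk, _ = syn.gen_unit_raster(
            0.0, stim, 1.0, syn.SimConfig(seed=1), mode="antidromic",
            background_times=forced_bg,
        )
        evoked = np.setdiff1d(np.round(spk.times, 6), np.round(forced_bg, 6))
        assert evoked.size == 0


class TestVmTrace:
    def test_no_up_dwell_gives_unimodal_down_state(self):
        t = syn.gen_vm_trace(-70, -55, 0.5, 0.0, 0.0, 5.0, syn.SimConfig(seed=1))
        assert np.all(t.values == -70.0)

    def test_noiseless_trace_is_two_valued(self):
        t = syn.gen_vm_trace(-70, -55, 0.2, 0.2, 0.0, 10.0, syn.SimConfig(seed=1))
        assert set(np.unique(t.values)) <= {-70.0, -55.0}

    def test_equal_dwells_give_half_occupancy(self):
        occ = [
            (syn.gen_vm_trace(-70, -55, 0.3, 0.3, 0.0, 60.0, syn.SimConfig(seed=s)).values > -62.5).mean()
            for s in range(10)
        ]
        # renewal process: long-run occupancy 1/2; dwell 0.3 s over 60 s -> ~100 cycles
        assert abs(np.mean(occ) - 0.5) < 3 * np.std(occ) / math.sqrt(10) + 0.01
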