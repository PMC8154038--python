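"""Unit and property tests for the spike-train statistics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mgcpn.spikes import (
    EXCITATORY,
    INHIBITORY,
    NONE,
    MzifrTrace,
    ResponseThresholds,
    SpikeTrainTrial,
    ZifrTrace,
    bin_rates,
    classify_response,
    compute_amplitudes,
    compute_mzifr,
    compute_onset_latency,
    compute_peak_latency,
    compute_thresholds,
    compute_zifr,
)
from mgcpn.stimuli import StimulusLabel


def trial(times, neuron="n1", stim=StimulusLabel.PP, idx=0):
    return SpikeTrainTrial(neuron, stim, idx, np.asarray(times, dtype=float))


def mz(values, neuron="n1", stim=StimulusLabel.PP, n=1):
    return MzifrTrace(np.asarray(values, dtype=float), neuron, stim, n)


class TestTrialInvariants:
    def test_rejects_out_of_window_spikes(self):
        with pytest.raises(ValueError):
            trial([0.5, 2.4])
        with pytest.raises(ValueError):
            trial([-0.1])

    def test_rejects_unsorted_times(self):
        with pytest.raises(ValueError):
            trial([1.2, 1.1])


class TestZifr:
    def test_hand_binning_oracle(self):
        # Spikes at 1.005 and 1.007 share the first stimulation bin (200 Hz);
        # 1.012 falls in the next (100 Hz); everything else is empty.
        t = trial([1.005, 1.007, 1.012])
        rates = bin_rates(t.spike_times)
        expected = np.zeros(240)
        expected[100] = 200.0
        expected[101] = 100.0
        np.testing.assert_allclose(rates, expected)

    def test_empty_trial_is_all_zero(self):
        z = compute_zifr(trial([]))
        np.testing.assert_array_equal(z.values, np.zeros(240))

    def test_perfectly_regular_train_is_all_zero(self):
        # One spike per 10 ms bin: constant 100 Hz, zero pre-stimulus SD.
        times = np.arange(240) * 0.01 + 0.005
        z = compute_zifr(trial(times))
        np.testing.assert_allclose(z.values, np.zeros(240))

    def test_zero_sd_fallback_uses_pooled_sd(self):
        times = np.arange(240) * 0.01 + 0.005  # constant 100 Hz
        extra = trial(np.sort(np.concatenate([times, [1.101]])))
        z = compute_zifr(extra, pooled_sd=50.0)
        # one doubled bin: (200 - 100) / 50
        assert z.values[110] == pytest.approx(2.0)

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(min_value=1, max_value=500), st.integers(0, 2**31 - 1))
    def test_pre_segment_standardized(self, n_spikes, seed):
        """Whenever the pre-stimulus SD is positive, the pre segment of the
        ZIFR has mean 0 and population SD 1."""
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 2.4, size=n_spikes))
        z = compute_zifr(trial(times))
        pre = z.values[:100]
        if bin_rates(times)[:100].std() > 0:
            assert pre.mean() == pytest.approx(0.0, abs=1e-12)
            assert pre.std() == pytest.approx(1.0, abs=1e-12)


class TestMzifr:
    def test_single_trial_identity(self):
        z = ZifrTrace(np.arange(240, dtype=float), "n1", StimulusLabel.PP, 0)
        m = compute_mzifr([z])
        np.testing.assert_array_equal(m.values, z.values)
        assert m.n_trials == 1

    def test_symmetric_traces_cancel(self):
        a = np.sin(np.arange(240))
        za = ZifrTrace(a, "n1", StimulusLabel.PP, 0)
        zb = ZifrTrace(-a, "n1", StimulusLabel.PP, 1)
        np.testing.assert_allclose(compute_mzifr([za, zb]).values, 0.0, atol=1e-15)

    def test_matches_brute_force_average(self, rng):
        traces = [
            ZifrTrace(rng.normal(size=240), "n1", StimulusLabel.PP, i)
            for i in range(3)
        ]
        expected = np.array(
            [np.mean([t.values[b] for t in traces]) for b in range(240)]
        )
        np.testing.assert_allclose(compute_mzifr(traces).values, expected)

    def test_mixed_stimuli_rejected(self):
        za = ZifrTrace(np.zeros(240), "n1", StimulusLabel.PP, 0)
        zb = ZifrTrace(np.zeros(240), "n1", StimulusLabel.BA, 0)
        with pytest.raises(ValueError):
            compute_mzifr([za, zb])


class TestThresholds:
    def test_standard_normal_pre(self, rng):
        values = np.zeros(240)
        pre = rng.normal(size=100)
        pre = (pre - pre.mean()) / pre.std()
        values[:100] = pre
        thr = compute_thresholds(mz(values))
        assert thr.t_upper == pytest.approx(1.96)
        assert thr.t_lower == pytest.approx(-1.96)

    def test_constant_pre_collapses(self):
        values = np.full(240, 0.7)
        thr = compute_thresholds(mz(values))
        assert thr.t_upper == pytest.approx(0.7)
        assert thr.t_lower == pytest.approx(0.7)

    def test_hand_computed_example(self):
        # 90 zeros and 10 ones: mean 0.1, population SD 0.3.
        values = np.zeros(240)
        values[:10] = 1.0
        thr = compute_thresholds(mz(values))
        assert thr.t_upper == pytest.approx(0.1 + 1.96 * 0.3)
        assert thr.t_lower == pytest.approx(0.1 - 1.96 * 0.3)


class TestClassification:
    thr = ResponseThresholds(1.96, -1.96)

    def test_quiescent_trace_is_none(self):
        cls = classify_response(mz(np.zeros(240)), self.thr)
        assert (cls.window_label, cls.sw1_label, cls.sw2_label) == (NONE, NONE, NONE)

    def test_single_suprathreshold_bin_is_excitatory(self):
        values = np.zeros(240)
        values[120] = 2.5
        cls = classify_response(mz(values), self.thr)
        assert cls.window_label == EXCITATORY

    def test_subwindow_rule_example(self):
        values = np.zeros(240)
        values[100:110] = 2.0  # SW(i) mean 2.0
        values[110:140] = -2.5  # SW(ii) mean -2.5
        cls = classify_response(mz(values), self.thr)
        assert cls.sw1_label == EXCITATORY
        assert cls.sw2_label == INHIBITORY

    def test_temporal_precedence_of_first_crossing(self):
        values = np.zeros(240)
        values[105] = -3.0
        values[120] = 3.0
        cls = classify_response(mz(values), self.thr)
        assert cls.window_label == INHIBITORY

    def test_per_bin_rule_matches_scan_oracle(self, rng):
        for _ in range(100):
            values = rng.normal(scale=1.5, size=240)
            trace = mz(values)
            thr = compute_thresholds(trace)
            cls = classify_response(trace, thr)
            # brute-force forward scan
            label = NONE
            for b in range(100, 140):
                if values[b] > thr.t_upper:
                    label = EXCITATORY
                    break
                if values[b] < thr.t_lower:
                    label = INHIBITORY
                    break
            assert cls.window_label == label


class TestAmplitudes:
    def test_constant_trace_zero(self):
        assert compute_amplitudes(mz(np.full(240, 3.3))) == (0.0, 0.0, 0.0)

    def test_boxcar_stimulation(self):
        values = np.zeros(240)
        values[100:140] = 3.0
        assert compute_amplitudes(mz(values)) == (3.0, 3.0, 0.0)

    def test_windowed_mean_oracle(self, rng):
        values = rng.normal(size=240)
        a1, a2, ap = compute_amplitudes(mz(values))
        base = values[:100].mean()
        assert a1 == pytest.approx(np.mean(values[100:110]) - base)
        assert a2 == pytest.approx(np.mean(values[110:140]) - base)
        assert ap == pytest.approx(np.mean(values[140:160]) - base)


class TestLatencies:
    def test_no_stimulation_spikes_undefined(self):
        assert compute_onset_latency(trial([0.1, 0.5])) is None

    def test_silent_baseline_first_spike(self):
        # Silent pre-stimulus: the zero-SD fallback makes any spike cross.
        assert compute_onset_latency(trial([1.0125])) == pytest.approx(12.0)

    def test_invariant_to_post_stimulus_spikes(self):
        base = trial([1.0125])
        with_post = trial([1.0125, 2.0, 2.1])
        assert compute_onset_latency(base) == compute_onset_latency(with_post)

    def test_peak_latency_first_bin_for_decaying_trace(self):
        values = np.zeros(240)
        values[100:140] = np.exp(-np.arange(40) / 8.0)
        assert compute_peak_latency(mz(values)) == 0.0

    def test_peak_latency_argmax_oracle(self):
        values = np.zeros(240)
        values[120] = 5.0  # 21st stimulation bin -> 200 ms
        assert compute_peak_latency(mz(values)) == pytest.approx(200.0)

    def test_flat_window_ties_to_zero(self):
        assert compute_peak_latency(mz(np.zeros(240))) == 0.0
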