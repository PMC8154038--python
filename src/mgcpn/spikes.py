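"""Spike-train response statistics for projection-neuron trials.

Every trial lives on a fixed 2.4 s clock: 1 s of pre-stimulus baseline,
a 0.4 s odor pulse starting at t = 1.0 s, and 1 s of post-stimulus time.
The core quantity is the Z-scored instantaneous firing rate (ZIFR): spike
counts in 10 ms bins converted to rates and standardized against the trial's
own 100 pre-stimulus bins.  Averaging ZIFR traces over repeated trials of the
same stimulus yields the MZIFR, on which all response detection operates:

* response thresholds  T_U / T_L = mean(MZIFR_PS) +/- 1.96 sigma(MZIFR_PS),
  where MZIFR_PS is the 100-bin pre-stimulus segment of the mean trace;
* a per-bin rule over the 40 stimulation bins (any bin above T_U -> excitatory,
  below T_L -> inhibitory), which is sensitive but carries a large familywise
  false-positive rate;
* a sub-window rule comparing the means of SW(i) (first 100 ms of stimulation)
  and SW(ii) (remaining 300 ms) against the same thresholds, which is the
  conservative response call;
* response amplitudes DeltaMZIFR: the trace re-zeroed to its pre-stimulus mean
  and averaged over SW(i), SW(ii) and a 200 ms post-stimulus window.

All standard deviations are population SDs (ddof = 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .stimuli import StimulusLabel, as_stimulus

# Trial clock (seconds) and 10 ms binning.
TRIAL_DURATION = 2.4
STIM_ONSET = 1.0
STIM_OFFSET = 1.4
BIN_WIDTH = 0.01

N_BINS = 240
PRE = slice(0, 100)
STIM = slice(100, 140)
SW1 = slice(100, 110)  # first 100 ms of stimulation
SW2 = slice(110, 140)  # remaining 300 ms
POST200 = slice(140, 160)  # 200 ms after stimulus offset

EXCITATORY = "excitatory"
INHIBITORY = "inhibitory"
NONE = "none"


@dataclass(frozen=True)
class SpikeTrainTrial:
    """One neuron's spike times for one stimulus presentation.

    Spike times are seconds on the half-open trial window [0, 2.4); a spike
    exactly at 2.4 s is invalid.  Times must be sorted ascending.
    """

    neuron_id: str
    stimulus: StimulusLabel
    trial_index: int
    spike_times: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise ValueError("spike_times must be one-dimensional")
        if times.size and (times.min() < 0.0 or times.max() >= TRIAL_DURATION):
            raise ValueError(
                f"spike times must lie in [0, {TRIAL_DURATION}) s; "
                f"got range [{times.min()}, {times.max()}]"
            )
        if np.any(np.diff(times) < 0):
            raise ValueError("spike times must be sorted ascending")
        object.__setattr__(self, "stimulus", as_stimulus(self.stimulus))


@dataclass(frozen=True)
class ZifrTrace:
    """Z-scored instantaneous firing rate of one trial, 240 x 10 ms bins."""

    values: np.ndarray
    neuron_id: str
    stimulus: StimulusLabel
    trial_index: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {values.shape}")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class MzifrTrace:
    """Mean ZIFR across repeated trials of one neuron x stimulus."""

    values: np.ndarray
    neuron_id: str
    stimulus: StimulusLabel
    n_trials: int

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {values.shape}")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ResponseThresholds:
    """Upper/lower response thresholds about the pre-stimulus MZIFR mean."""

    t_upper: float
    t_lower: float


@dataclass(frozen=True)
class ResponseClassification:
    """Response labels and amplitudes for one neuron x stimulus.

    ``window_label`` applies the per-bin rule; ``sw1_label``/``sw2_label``
    apply the sub-window-mean rule.  ``onset_latency_ms`` is defined only for
    excitatory responses (``None`` otherwise or when no crossing occurs).
    """

    window_label: str
    sw1_label: str
    sw2_label: str
    amp_sw1: float
    amp_sw2: float
    amp_post200: float
    onset_latency_ms: float | None = None
    peak_latency_ms: float = 0.0

    @property
    def subwindow_label(self) -> str:
        """Combined conservative call from the two sub-window labels."""
        labels = (self.sw1_label, self.sw2_label)
        if EXCITATORY in labels:
            return EXCITATORY
        if INHIBITORY in labels:
            return INHIBITORY
        return NONE


def bin_rates(spike_times: np.ndarray, bin_width: float = BIN_WIDTH) -> np.ndarray:
    """Raw instantaneous firing rate (Hz) per half-open bin [t, t + width)."""
    n = int(round(TRIAL_DURATION / bin_width))
    edges = np.arange(n + 1) * bin_width
    counts, _ = np.histogram(spike_times, bins=edges)
    return counts / bin_width


def _zscore_against_pre(rates: np.ndarray, n_pre: int, pooled_sd: float | None) -> np.ndarray:
    """Standardize a rate trace against its own pre-stimulus bins.

    If the pre-stimulus SD is zero (silent or perfectly regular baseline) the
    normalizer falls back to ``pooled_sd`` when given, else to 1.0, so that the
    trace becomes a mean-centered rate rather than dividing by zero.
    """
    pre = rates[:n_pre]
    mean = pre.mean()
    sd = pre.std()
    if sd == 0.0:
        sd = pooled_sd if pooled_sd is not None and pooled_sd > 0 else 1.0
    return (rates - mean) / sd


def compute_zifr(
    trial: SpikeTrainTrial,
    bin_width: float = BIN_WIDTH,
    pooled_sd: float | None = None,
) -> ZifrTrace:
    """Z-scored instantaneous firing rate of one trial in 10 ms bins.

    Parameters
    ----------
    trial
        The spike-time trial; its invariants guarantee in-window sorted times.
    bin_width
        Bin width in seconds; must tile the 2.4 s trial into 240 bins for the
        downstream window bookkeeping, so only the default is accepted here.
    pooled_sd
        Optional session-level pooled rate SD used as the normalizer when the
        trial's own pre-stimulus SD is zero.
    """
    if not np.isclose(bin_width, BIN_WIDTH):
        raise ValueError("ZIFR traces are defined on 10 ms bins")
    rates = bin_rates(trial.spike_times, bin_width)
    z = _zscore_against_pre(rates, n_pre=100, pooled_sd=pooled_sd)
    return ZifrTrace(z, trial.neuron_id, trial.stimulus, trial.trial_index)


def compute_mzifr(traces: Sequence[ZifrTrace]) -> MzifrTrace:
    """Element-wise mean of repeated-trial ZIFR traces (same neuron, stimulus)."""
    if not traces:
        raise ValueError("at least one ZIFR trace is required")
    first = traces[0]
    for t in traces[1:]:
        if t.stimulus != first.stimulus:
            raise ValueError(
                f"cannot average across stimuli: {first.stimulus} vs {t.stimulus}"
            )
        if t.neuron_id != first.neuron_id:
            raise ValueError(
                f"cannot average across neurons: {first.neuron_id} vs {t.neuron_id}"
            )
    values = np.mean([t.values for t in traces], axis=0)
    return MzifrTrace(values, first.neuron_id, first.stimulus, len(traces))


def compute_thresholds(mzifr: MzifrTrace | np.ndarray) -> ResponseThresholds:
    """Upper/lower thresholds mean(MZIFR_PS) +/- 1.96 sigma(MZIFR_PS).

    The SD is the population SD across the 100 pre-stimulus bins of the mean
    trace (ddof = 0).
    """
    values = mzifr.values if isinstance(mzifr, MzifrTrace) else np.asarray(mzifr)
    pre = values[PRE]
    mean = pre.mean()
    sd = pre.std()
    return ResponseThresholds(t_upper=mean + 1.96 * sd, t_lower=mean - 1.96 * sd)


def _label_bins(stim_bins: np.ndarray, thr: ResponseThresholds) -> str:
    """Per-bin rule with temporal precedence at the first crossing."""
    above = stim_bins > thr.t_upper
    below = stim_bins < thr.t_lower
    if not above.any() and not below.any():
        return NONE
    first_above = np.argmax(above) if above.any() else np.inf
    first_below = np.argmax(below) if below.any() else np.inf
    return EXCITATORY if first_above <= first_below else INHIBITORY


def _label_mean(mean_value: float, thr: ResponseThresholds) -> str:
    if mean_value > thr.t_upper:
        return EXCITATORY
    if mean_value < thr.t_lower:
        return INHIBITORY
    return NONE


def compute_amplitudes(mzifr: MzifrTrace | np.ndarray) -> tuple[float, float, float]:
    """Response amplitudes DeltaMZIFR over SW(i), SW(ii) and post-200 ms.

    The trace is first re-zeroed by subtracting its pre-stimulus mean, then
    averaged over each window.
    """
    values = mzifr.values if isinstance(mzifr, MzifrTrace) else np.asarray(mzifr)
    delta = values - values[PRE].mean()
    return float(delta[SW1].mean()), float(delta[SW2].mean()), float(delta[POST200].mean())


def stimulation_amplitude(mzifr: MzifrTrace | np.ndarray) -> float:
    """DeltaMZIFR averaged over the full 400 ms stimulation window."""
    values = mzifr.values if isinstance(mzifr, MzifrTrace) else np.asarray(mzifr)
    delta = values - values[PRE].mean()
    return float(delta[STIM].mean())


def compute_peak_latency(mzifr: MzifrTrace | np.ndarray) -> float:
    """Latency (ms after odor onset) of the maximal stimulation-window bin.

    Ties resolve to the earliest bin; the latency is the bin's start time.
    """
    values = mzifr.values if isinstance(mzifr, MzifrTrace) else np.asarray(mzifr)
    idx = int(np.argmax(values[STIM]))
    return idx * BIN_WIDTH * 1000.0


def compute_onset_latency(trial: SpikeTrainTrial) -> float | None:
    """Excitatory-response onset latency of a single trial, in ms.

    The trial is re-binned at 1 ms, Z-scored against its 1000 pre-stimulus
    1 ms bins, and an upper threshold is formed from that standardized
    pre-stimulus segment by the same mean + 1.96 SD formula.  The latency is
    the time from odor onset to the first suprathreshold bin at or after
    onset; ``None`` if the threshold is never exceeded.
    """
    rates = bin_rates(trial.spike_times, bin_width=0.001)
    z = _zscore_against_pre(rates, n_pre=1000, pooled_sd=None)
    pre = z[:1000]
    t_upper = pre.mean() + 1.96 * pre.std()
    stim_and_post = z[1000:]
    crossed = np.nonzero(stim_and_post > t_upper)[0]
    if crossed.size == 0:
        return None
    return float(crossed[0])  # 1 ms bins: index == ms after onset


def classify_response(
    mzifr: MzifrTrace,
    thresholds: ResponseThresholds | None = None,
    trials: Iterable[SpikeTrainTrial] | None = None,
) -> ResponseClassification:
    """Full response classification of one neuron x stimulus mean trace.

    Applies the per-bin rule and the sub-window rule against thresholds
    derived from the same trace (or thresholds passed explicitly), and
    attaches amplitudes and latencies.  Onset latency is reported only when
    the per-bin call is excitatory and single trials are supplied: it is then
    the mean over trials of each trial's own 1 ms-resolution onset latency.
    """
    if thresholds is None:
        thresholds = compute_thresholds(mzifr)
    stim_bins = mzifr.values[STIM]
    window_label = _label_bins(stim_bins, thresholds)
    sw1_label = _label_mean(float(mzifr.values[SW1].mean()), thresholds)
    sw2_label = _label_mean(float(mzifr.values[SW2].mean()), thresholds)
    amp_sw1, amp_sw2, amp_post = compute_amplitudes(mzifr)

    onset: float | None = None
    if window_label == EXCITATORY and trials is not None:
        latencies = [compute_onset_latency(t) for t in trials]
        defined = [v for v in latencies if v is not None]
        if defined:
            onset = float(np.mean(defined))

    return ResponseClassification(
        window_label=window_label,
        sw1_label=sw1_label,
        sw2_label=sw2_label,
        amp_sw1=amp_sw1,
        amp_sw2=amp_sw2,
        amp_post200=amp_post,
        onset_latency_ms=onset,
        peak_latency_ms=compute_peak_latency(mzifr),
    )
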