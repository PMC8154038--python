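"""Session-level spike analyses: MZIFR tables and classification reports.

Bridges raw recording sessions (lists of spike-train trials plus morphology
records) and the per-neuron statistics: trial Z-scoring with a session-level
pooled-SD fallback for silent baselines, trial averaging, response
classification, and tabular exports (per-neuron classification tables and
the neurons x 240-bin MZIFR matrix behind response heat maps).
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .spikes import (
    MzifrTrace,
    N_BINS,
    SpikeTrainTrial,
    bin_rates,
    classify_response,
    compute_mzifr,
    compute_thresholds,
    compute_zifr,
)
from .stimuli import StimulusLabel
from .synthetic import NeuronMorphology, RecordingSession


def pooled_rate_sd(trials: Sequence[SpikeTrainTrial]) -> float:
    """Session-level pooled SD of pre-stimulus bin rates.

    Used as the Z-scoring normalizer for trials whose own pre-stimulus SD is
    zero (silent baselines), so such traces stay on a comparable scale.
    """
    pre_rates = [bin_rates(t.spike_times)[:100] for t in trials]
    return float(np.std(np.concatenate(pre_rates)))


def session_mzifr(
    session: RecordingSession,
    use_pooled_fallback: bool = True,
) -> dict[tuple[str, StimulusLabel], MzifrTrace]:
    """Trial-averaged MZIFR trace per neuron x stimulus for a whole session."""
    pooled = pooled_rate_sd(session.trials) if use_pooled_fallback else None
    grouped: dict[tuple[str, StimulusLabel], list[SpikeTrainTrial]] = {}
    for t in session.trials:
        grouped.setdefault((t.neuron_id, t.stimulus), []).append(t)
    out: dict[tuple[str, StimulusLabel], MzifrTrace] = {}
    for key, trials in grouped.items():
        zifrs = [compute_zifr(t, pooled_sd=pooled) for t in trials]
        out[key] = compute_mzifr(zifrs)
    return out


def classification_table(
    session: RecordingSession,
    traces: Mapping[tuple[str, StimulusLabel], MzifrTrace] | None = None,
) -> pd.DataFrame:
    """Per neuron x stimulus response-classification table.

    Columns cover the per-bin and sub-window labels, the thresholds they used,
    the three DeltaMZIFR amplitudes, and onset/peak latencies.
    """
    if traces is None:
        traces = session_mzifr(session)
    rows = []
    for (neuron_id, stimulus), mz in sorted(
        traces.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        thr = compute_thresholds(mz)
        cls = classify_response(mz, thr, trials=session.trials_for(neuron_id, stimulus))
        rows.append(
            {
                "neuron_id": neuron_id,
                "stimulus": stimulus.value,
                "n_trials": mz.n_trials,
                "t_upper": thr.t_upper,
                "t_lower": thr.t_lower,
                "window_label": cls.window_label,
                "sw1_label": cls.sw1_label,
                "sw2_label": cls.sw2_label,
                "subwindow_label": cls.subwindow_label,
                "amp_sw1": cls.amp_sw1,
                "amp_sw2": cls.amp_sw2,
                "amp_post200": cls.amp_post200,
                "onset_latency_ms": cls.onset_latency_ms,
                "peak_latency_ms": cls.peak_latency_ms,
            }
        )
    return pd.DataFrame(rows)


def mzifr_matrix(
    traces: Mapping[tuple[str, StimulusLabel], MzifrTrace],
) -> pd.DataFrame:
    """Long heat-map matrix: one row per neuron x stimulus, 240 bin columns."""
    rows = {}
    for (neuron_id, stimulus), mz in sorted(
        traces.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
    ):
        rows[f"{neuron_id}|{stimulus.value}"] = mz.values
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=[f"bin_{i}" for i in range(N_BINS)])


def amplitude_lookup(
    traces: Mapping[tuple[str, StimulusLabel], MzifrTrace],
) -> dict[tuple[str, StimulusLabel], float]:
    """Full-stimulation-window DeltaMZIFR amplitude per neuron x stimulus."""
    from .spikes import stimulation_amplitude

    return {key: stimulation_amplitude(mz) for key, mz in traces.items()}
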