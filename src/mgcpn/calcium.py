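"""Calcium-imaging response statistics.

Fura-2 ratio traces (F340/F380, 100 frames at 10 Hz) are baseline-normalized
by subtracting the mean over frames 5-25 (0.5-2.5 s of the spontaneous
period), giving DeltaF340/F380 traces.  A study-wide response *Threshold* is
anchored on the vehicle-control traces: per frame, the across-individual
mean + 1.96 SD of the control DeltaF, maximized over frames.  A population
responds to a stimulus when the peak of its across-individual mean trace
within the 2 s stimulation window (frames 41-60) strictly exceeds that
threshold.  Response amplitude is the DeltaF averaged over the stimulation
window.

Frame indices below are 0-based slices of the 1-based frame conventions
(frames 5-25 -> indices 4..24; frames 41-60 -> indices 40..59).  SDs are
population SDs (ddof = 0), as in the spike statistics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .synthetic import CalciumRecording, N_FRAMES
from .stimuli import StimulusLabel

BASELINE_FRAMES = slice(4, 25)  # frames 5-25, 1-based inclusive
STIM_FRAMES = slice(40, 60)  # frames 41-60, the 2 s stimulation window
Z95 = 1.96


@dataclass(frozen=True)
class DeltaTrace:
    """Baseline-zeroed calcium trace (DeltaF340/F380)."""

    frames: np.ndarray
    individual_id: str = ""
    unit: str = ""
    stimulus: StimulusLabel | None = None

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.shape != (N_FRAMES,):
            raise ValueError(f"expected {N_FRAMES} frames, got {frames.shape}")
        object.__setattr__(self, "frames", frames)


def baseline_normalize(rec: CalciumRecording | np.ndarray) -> DeltaTrace:
    """Subtract the mean of the baseline frames from every frame."""
    if isinstance(rec, CalciumRecording):
        frames, meta = rec.frames, (rec.individual_id, rec.unit, rec.stimulus)
    else:
        frames = np.asarray(rec, dtype=float)
        if frames.shape != (N_FRAMES,):
            raise ValueError(f"expected {N_FRAMES} frames, got {frames.shape}")
        meta = ("", "", None)
    delta = frames - frames[BASELINE_FRAMES].mean()
    return DeltaTrace(delta, *meta)


def average_trials(deltas: Sequence[DeltaTrace]) -> DeltaTrace:
    """Element-wise mean of repeated-trial delta traces (same recording site)."""
    if not deltas:
        raise ValueError("at least one trace required")
    first = deltas[0]
    values = np.mean([d.frames for d in deltas], axis=0)
    return DeltaTrace(values, first.individual_id, first.unit, first.stimulus)


def compute_control_threshold(
    control_deltas: Sequence[DeltaTrace],
    axis: str = "individuals",
) -> float:
    """Response threshold anchored on per-individual control traces.

    With ``axis='individuals'`` (default): per frame, mean + 1.96 SD across
    individuals of the control DeltaF; the threshold is the maximum of that
    per-frame series.  With ``axis='frames'`` the mean/SD are instead taken
    across all frames of the pooled control traces (an alternative reading of
    the same formula, kept behind this switch).
    """
    if len(control_deltas) < 2:
        raise ValueError("threshold needs control traces from >= 2 individuals")
    stacked = np.stack([d.frames for d in control_deltas])  # individuals x frames
    if axis == "individuals":
        per_frame = stacked.mean(axis=0) + Z95 * stacked.std(axis=0)
        return float(per_frame.max())
    if axis == "frames":
        return float(stacked.mean() + Z95 * stacked.std())
    raise ValueError("axis must be 'individuals' or 'frames'")


def detect_population_response(
    stim_deltas: Sequence[DeltaTrace],
    threshold: float,
) -> bool:
    """True iff the across-individual mean trace peaks above the threshold.

    The peak is taken within the stimulation window and must be strictly
    greater than the threshold.
    """
    if not stim_deltas:
        raise ValueError("at least one trace required")
    mean_trace = np.mean([d.frames for d in stim_deltas], axis=0)
    return bool(mean_trace[STIM_FRAMES].max() > threshold)


def response_amplitude(delta: DeltaTrace | np.ndarray) -> float:
    """Mean DeltaF over the 2 s stimulation window."""
    frames = delta.frames if isinstance(delta, DeltaTrace) else np.asarray(delta)
    return float(frames[STIM_FRAMES].mean())


def population_response_table(
    recordings: Sequence[CalciumRecording],
    threshold_axis: str = "individuals",
) -> "pd.DataFrame":
    """Per-unit response table: does the population respond, and how strongly.

    Trials are averaged per individual x unit x stimulus before any statistic.
    For each unit, the control threshold is derived from that unit's own
    per-individual control traces; each stimulus row reports whether the
    across-individual mean trace exceeds it and the mean response amplitude.
    """
    import pandas as pd

    # individual x unit x stimulus -> trial-averaged delta trace
    grouped: dict[tuple[str, str, StimulusLabel], list[DeltaTrace]] = {}
    for rec in recordings:
        key = (rec.individual_id, rec.unit, rec.stimulus)
        grouped.setdefault(key, []).append(baseline_normalize(rec))
    averaged = {key: average_trials(traces) for key, traces in grouped.items()}

    units = sorted({u for _, u, _ in averaged})
    stimuli = sorted({s for _, _, s in averaged}, key=lambda s: s.value)
    rows = []
    for unit in units:
        controls = [
            d for (ind, u, s), d in averaged.items()
            if u == unit and s == StimulusLabel.CTRL
        ]
        thr = compute_control_threshold(controls, axis=threshold_axis)
        for stim in stimuli:
            traces = [
                d for (ind, u, s), d in averaged.items() if u == unit and s == stim
            ]
            rows.append(
                {
                    "unit": unit,
                    "stimulus": stim.value,
                    "n_individuals": len(traces),
                    "threshold": thr,
                    "responds": detect_population_response(traces, thr),
                    "amplitude": float(
                        np.mean([response_amplitude(d) for d in traces])
                    ),
                }
            )
    return pd.DataFrame(rows)
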