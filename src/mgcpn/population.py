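"""Cross-individual consistency of calcium population responses.

A response vector holds, for one individual and one MGC unit, the
trial-averaged response to every stimulus in a fixed order, where a response
is the mean ratio signal during the stimulation window minus that during the
pre-stimulation baseline.  Consistency between two individuals is the Pearson
correlation of their response vectors; a unit's consistency is summarized by
the mean over all unordered pairs, tested against a chance level of zero with
a one-sample t-test.

The pairwise correlations sharing an individual are not independent, so the
t-test is anticonservative; it is implemented as stated in the field's
convention and flagged in the package documentation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .calcium import BASELINE_FRAMES, STIM_FRAMES, DeltaTrace
from .stimuli import StimulusLabel
from .synthetic import CalciumRecording


@dataclass(frozen=True)
class ResponseVector:
    """Per-stimulus response amplitudes of one individual x unit."""

    individual_id: str
    unit: str
    values: np.ndarray
    stimulus_order: tuple[StimulusLabel, ...]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (len(self.stimulus_order),):
            raise ValueError("one value per stimulus is required")
        object.__setattr__(self, "values", values)


@dataclass(frozen=True)
class ConsistencyResult:
    """Pairwise-consistency summary for one MGC unit."""

    unit: str
    mean_r: float
    pairwise_r: np.ndarray  # individuals x individuals, NaN diagonal-excluded pairs
    individual_ids: tuple[str, ...]
    t_statistic: float
    p_value: float
    n_pairs: int


def build_response_vector(
    recordings: Sequence[CalciumRecording],
    stimulus_order: Sequence[StimulusLabel],
) -> ResponseVector:
    """Build one individual x unit response vector from raw ratio traces.

    For each stimulus the response is the trial average of (mean over the
    stimulation window - mean over the pre-stimulation baseline) of the raw
    F340/F380 trace.  All stimuli in ``stimulus_order`` must be present.
    """
    if not recordings:
        raise ValueError("no recordings given")
    individual = recordings[0].individual_id
    unit = recordings[0].unit
    by_stim: dict[StimulusLabel, list[float]] = {}
    for rec in recordings:
        if rec.individual_id != individual or rec.unit != unit:
            raise ValueError("recordings must come from one individual and one unit")
        resp = rec.frames[STIM_FRAMES].mean() - rec.frames[BASELINE_FRAMES].mean()
        by_stim.setdefault(rec.stimulus, []).append(float(resp))
    missing = [s.value for s in stimulus_order if s not in by_stim]
    if missing:
        raise ValueError(f"missing stimuli for {individual}/{unit}: {missing}")
    values = np.array([np.mean(by_stim[s]) for s in stimulus_order])
    return ResponseVector(individual, unit, values, tuple(stimulus_order))


def consistency_correlation(
    vectors: Sequence[ResponseVector],
    fisher_z: bool = False,
) -> ConsistencyResult:
    """Pairwise Pearson consistency of response vectors across individuals.

    Returns the full pairwise matrix, its mean over unordered pairs, and a
    one-sample t-test of the pairwise correlations against zero.  Pairs
    involving a zero-variance vector are excluded with a warning.  With
    ``fisher_z`` the t-test runs on arctanh-transformed correlations (the
    reported mean stays on the r scale).
    """
    if len(vectors) < 3:
        raise ValueError("need >= 3 individuals for a consistency t-test")
    unit = vectors[0].unit
    order = vectors[0].stimulus_order
    for v in vectors[1:]:
        if v.unit != unit:
            raise ValueError("vectors must come from a single MGC unit")
        if v.stimulus_order != order:
            raise ValueError("all vectors must share the same stimulus order")

    n = len(vectors)
    matrix = np.full((n, n), np.nan)
    np.fill_diagonal(matrix, 1.0)
    pair_values: list[float] = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = vectors[i].values, vectors[j].values
            if a.std() == 0 or b.std() == 0:
                warnings.warn(
                    f"zero-variance response vector in pair "
                    f"({vectors[i].individual_id}, {vectors[j].individual_id}); "
                    "pair excluded",
                    stacklevel=2,
                )
                continue
            r = float(stats.pearsonr(a, b).statistic)
            matrix[i, j] = matrix[j, i] = r
            pair_values.append(r)

    if len(pair_values) < 2:
        raise ValueError("fewer than two valid pairs; t-test undefined")
    sample = np.arctanh(np.clip(pair_values, -0.999999, 0.999999)) if fisher_z \
        else np.asarray(pair_values)
    t_stat, p_value = stats.ttest_1samp(sample, 0.0)
    return ConsistencyResult(
        unit=unit,
        mean_r=float(np.mean(pair_values)),
        pairwise_r=matrix,
        individual_ids=tuple(v.individual_id for v in vectors),
        t_statistic=float(t_stat),
        p_value=float(p_value),
        n_pairs=len(pair_values),
    )


def across_stimuli_correlation(
    mean_traces: Mapping[StimulusLabel, "np.ndarray | DeltaTrace"],
) -> "pd.DataFrame":
    """Stimulus x stimulus Pearson correlations of mean calcium traces.

    ``mean_traces`` maps each stimulus to its across-individual mean trace
    (full 100-frame DeltaF trace).  Entries involving a constant trace are
    undefined and reported as NaN.
    """
    import pandas as pd

    stimuli = list(mean_traces)
    arrays = []
    for s in stimuli:
        tr = mean_traces[s]
        arrays.append(tr.frames if isinstance(tr, DeltaTrace) else np.asarray(tr, float))
    n = len(stimuli)
    out = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(n):
            if i == j:
                out[i, j] = 1.0 if arrays[i].std() > 0 else np.nan
            elif arrays[i].std() > 0 and arrays[j].std() > 0:
                out[i, j] = stats.pearsonr(arrays[i], arrays[j]).statistic
    labels = [s.value for s in stimuli]
    return pd.DataFrame(out, index=labels, columns=labels)


def study_response_vectors(
    recordings: Sequence[CalciumRecording],
    stimulus_order: Sequence[StimulusLabel] | None = None,
) -> dict[str, list[ResponseVector]]:
    """Group a study's recordings into per-unit lists of response vectors."""
    if stimulus_order is None:
        seen: list[StimulusLabel] = []
        for rec in recordings:
            if rec.stimulus not in seen:
                seen.append(rec.stimulus)
        stimulus_order = seen
    grouped: dict[tuple[str, str], list[CalciumRecording]] = {}
    for rec in recordings:
        grouped.setdefault((rec.individual_id, rec.unit), []).append(rec)
    by_unit: dict[str, list[ResponseVector]] = {}
    for (ind, unit), recs in sorted(grouped.items()):
        by_unit.setdefault(unit, []).append(
            build_response_vector(recs, stimulus_order)
        )
    return by_unit
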