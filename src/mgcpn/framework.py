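"""Neuropil-level descriptive framework of projection-neuron output.

Each projection neuron innervates one or more output neuropils in the
lateral protocerebrum (VLP, SLP, SIP, LH, and the lALT-specific SIP column;
the mushroom-body calyces are excluded because the framework maps lateral
protocerebral outputs only).  For every neuropil x stimulus the framework
holds the element-wise mean of the member neurons' MZIFR traces and its
"described value": the baseline-zeroed amplitude of that mean trace over the
full 400 ms stimulation window.

A projection combination (e.g. VLP + SLP + SIP) is simulated by averaging
the combo's neuropil mean traces and taking the amplitude of the averaged
trace; simulation validity is quantified by the R^2 of a least-squares fit of
recorded member amplitudes on simulated amplitudes, pooled over combinations
and the four female-produced odorants.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .spikes import MzifrTrace, N_BINS, stimulation_amplitude
from .stimuli import FEMALE_PRODUCED, StimulusLabel
from .synthetic import NeuronMorphology

#: Neuropils the framework maps (lateral protocerebrum only).
FRAMEWORK_NEUROPILS = ("VLP", "SLP", "SIP", "LH", "column")

#: The four projection combinations of the validation experiment.
DEFAULT_COMBINATIONS: tuple[tuple[str, ...], ...] = (
    ("VLP", "SLP", "SIP"),
    ("SLP", "VLP"),
    ("VLP",),
    ("VLP", "LH"),
)


@dataclass(frozen=True)
class NeuropilCell:
    """One neuropil x stimulus entry of the framework."""

    mean_trace: np.ndarray  # 240-bin mean MZIFR
    described_value: float  # DeltaMZIFR amplitude of the mean trace
    n_members: int
    member_ids: tuple[str, ...]


class NeuropilActivityMap:
    """Mean firing trace and described value per output neuropil x stimulus."""

    def __init__(self, cells: Mapping[tuple[str, StimulusLabel], NeuropilCell]):
        self._cells = dict(cells)

    def __contains__(self, key: tuple[str, StimulusLabel]) -> bool:
        return key in self._cells

    def __getitem__(self, key: tuple[str, StimulusLabel]) -> NeuropilCell:
        return self._cells[key]

    def neuropils(self) -> list[str]:
        return sorted({n for n, _ in self._cells}, key=FRAMEWORK_NEUROPILS.index)

    def stimuli(self) -> list[StimulusLabel]:
        seen: list[StimulusLabel] = []
        for _, s in self._cells:
            if s not in seen:
                seen.append(s)
        return seen

    def items(self):
        return self._cells.items()


def framework_projection(morph: NeuronMorphology) -> tuple[str, ...]:
    """A neuron's output neuropils restricted to the framework set."""
    return tuple(n for n in morph.output_neuropils if n in FRAMEWORK_NEUROPILS)


def group_by_neuropil(
    morphologies: Sequence[NeuronMorphology],
    traces: Mapping[tuple[str, StimulusLabel], MzifrTrace],
    stimuli: Sequence[StimulusLabel] = FEMALE_PRODUCED,
) -> NeuropilActivityMap:
    """Average member MZIFR traces per output neuropil x stimulus.

    A neuron contributes to every framework neuropil it innervates.  Empty
    neuropil groups are omitted with a warning.
    """
    by_neuropil: dict[str, list[NeuronMorphology]] = {n: [] for n in FRAMEWORK_NEUROPILS}
    for morph in morphologies:
        proj = framework_projection(morph)
        if not proj:
            raise ValueError(
                f"neuron {morph.neuron_id} innervates no framework neuropil"
            )
        for n in proj:
            by_neuropil[n].append(morph)

    cells: dict[tuple[str, StimulusLabel], NeuropilCell] = {}
    for neuropil, members in by_neuropil.items():
        if not members:
            warnings.warn(f"neuropil {neuropil} has no member neurons; omitted",
                          stacklevel=2)
            continue
        for stim in stimuli:
            member_traces = []
            member_ids = []
            for morph in members:
                key = (morph.neuron_id, stim)
                if key not in traces:
                    raise KeyError(f"missing MZIFR trace for {key}")
                member_traces.append(traces[key].values)
                member_ids.append(morph.neuron_id)
            mean_trace = np.mean(member_traces, axis=0)
            cells[(neuropil, stim)] = NeuropilCell(
                mean_trace=mean_trace,
                described_value=stimulation_amplitude(mean_trace),
                n_members=len(member_ids),
                member_ids=tuple(member_ids),
            )
    return NeuropilActivityMap(cells)


def simulate_projection_response(
    combo: Sequence[str],
    activity_map: NeuropilActivityMap,
    stimulus: StimulusLabel,
) -> float:
    """Simulated amplitude of a projection combination for one stimulus.

    Averages the combo's neuropil mean traces element-wise, then takes the
    DeltaMZIFR amplitude of the averaged trace.  (For the windowed-mean
    amplitude the two orders commute; trace-first is used so nonlinear
    amplitude definitions would remain supported.)
    """
    traces = []
    for neuropil in combo:
        if (neuropil, stimulus) not in activity_map:
            raise KeyError(f"neuropil {neuropil} missing from the activity map")
        traces.append(activity_map[(neuropil, stimulus)].mean_trace)
    return stimulation_amplitude(np.mean(traces, axis=0))


@dataclass(frozen=True)
class ValidationResult:
    """Scatter of simulated vs recorded amplitudes and the pooled fit."""

    points: "pd.DataFrame"  # combo, stimulus, simulated, recorded, n_recorded
    r_squared: float
    slope: float
    intercept: float


def validate_simulation(
    activity_map: NeuropilActivityMap,
    morphologies: Sequence[NeuronMorphology],
    amplitudes: Mapping[tuple[str, StimulusLabel], float],
    combinations: Sequence[Sequence[str]] = DEFAULT_COMBINATIONS,
    stimuli: Sequence[StimulusLabel] = FEMALE_PRODUCED,
) -> ValidationResult:
    """Compare simulated combination responses with recorded neuron responses.

    For each combination x stimulus, the simulated value comes from
    :func:`simulate_projection_response` on the activity map, and the recorded
    value is the mean stimulation-window amplitude of the neurons (in
    ``morphologies``) whose framework projection set equals the combination.
    Combinations without any matching neuron contribute no points.  The pooled
    R^2 is from the least-squares linear fit of recorded on simulated values.
    """
    import pandas as pd

    rows = []
    for combo in combinations:
        members = [
            m for m in morphologies
            if set(framework_projection(m)) == set(combo)
        ]
        if not members:
            continue
        for stim in stimuli:
            recorded_vals = [amplitudes[(m.neuron_id, stim)] for m in members]
            rows.append(
                {
                    "combination": "+".join(combo),
                    "stimulus": stim.value,
                    "simulated": simulate_projection_response(combo, activity_map, stim),
                    "recorded": float(np.mean(recorded_vals)),
                    "n_recorded": len(recorded_vals),
                }
            )
    points = pd.DataFrame(rows)
    if len(points) < 3:
        raise ValueError("need >= 3 (combination, stimulus) points for a fit")
    sim = points["simulated"].to_numpy()
    rec = points["recorded"].to_numpy()
    if np.std(sim) == 0:
        warnings.warn("zero variance in simulated values; R^2 undefined", stacklevel=2)
        return ValidationResult(points, float("nan"), float("nan"), float("nan"))
    fit = stats.linregress(sim, rec)
    return ValidationResult(
        points=points,
        r_squared=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def dendritic_group(morph: NeuronMorphology) -> str:
    """Dendritic-arborization group: Cu, dma, dmp, or MGC (multiglomerular)."""
    if morph.uniglomerular:
        return morph.dendritic_units[0]
    return "MGC"


def group_mean_responses(
    morphologies: Sequence[NeuronMorphology],
    amplitudes: Mapping[tuple[str, StimulusLabel], float],
    stimuli: Sequence[StimulusLabel] = FEMALE_PRODUCED,
) -> "pd.DataFrame":
    """Mean +/- SEM response amplitude per dendritic group x stimulus.

    Groups follow the dendritic arborization (Cu, dma, dmp, multiglomerular
    -> MGC); empty groups are omitted.  SEM is NaN for singleton groups.
    """
    import pandas as pd

    groups: dict[str, list[NeuronMorphology]] = {}
    for morph in morphologies:
        groups.setdefault(dendritic_group(morph), []).append(morph)

    rows = []
    for group in ("Cu", "dma", "dmp", "MGC"):
        members = groups.get(group)
        if not members:
            continue
        for stim in stimuli:
            vals = np.array([amplitudes[(m.neuron_id, stim)] for m in members])
            sem = float(vals.std(ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan")
            rows.append(
                {
                    "group": group,
                    "stimulus": stim.value,
                    "n": len(vals),
                    "mean_amplitude": float(vals.mean()),
                    "sem": sem,
                }
            )
    return pd.DataFrame(rows)
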