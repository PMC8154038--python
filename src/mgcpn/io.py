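"""Tidy-CSV interchange formats and study configuration.

All on-disk formats are plain text.  Schemas:

* spike CSV: ``neuron_id, neuron_class, stimulus, trial, spike_time_s`` —
  long format, one row per spike; trials with zero spikes appear as a single
  row with an empty ``spike_time_s`` field.
* morphology TSV: ``neuron_id, neuron_class, tract, dendritic_units,
  output_neuropils, uniglomerular, protocol`` with ``;``-joined set fields.
* calcium CSV: ``individual, unit, stimulus, trial, frame, ratio`` — long
  format, one row per frame.
* ground-truth JSON: the tuning table's non-none kernels.

Study configuration is a YAML/JSON mapping validated against a fixed key set;
unknown keys are rejected.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .spikes import SpikeTrainTrial, TRIAL_DURATION
from .stimuli import StimulusLabel, as_stimulus
from .synthetic import (
    CalciumRecording,
    N_FRAMES,
    NeuronMorphology,
    RecordingSession,
    TuningTable,
)


class ValidationError(ValueError):
    """Raised for malformed input files or configurations."""


# --------------------------------------------------------------------------
# Spike data
# --------------------------------------------------------------------------

def write_spike_csv(session: RecordingSession, path: str | Path) -> None:
    rows = []
    for t in session.trials:
        if t.spike_times.size == 0:
            rows.append((t.neuron_id, t.stimulus.value, t.trial_index, ""))
        for s in t.spike_times:
            rows.append((t.neuron_id, t.stimulus.value, t.trial_index, repr(float(s))))
    frame = pd.DataFrame(rows, columns=["neuron_id", "stimulus", "trial", "spike_time_s"])
    frame.to_csv(path, index=False)


def read_spike_csv(path: str | Path) -> list[SpikeTrainTrial]:
    """Read a long-format spike CSV into validated trial records."""
    frame = pd.read_csv(path, dtype={"neuron_id": str, "stimulus": str},
                        float_precision="round_trip")
    required = {"neuron_id", "stimulus", "trial", "spike_time_s"}
    if not required <= set(frame.columns):
        raise ValidationError(f"spike CSV must have columns {sorted(required)}")
    trials: list[SpikeTrainTrial] = []
    for (neuron_id, stimulus, trial), group in frame.groupby(
        ["neuron_id", "stimulus", "trial"], sort=True
    ):
        times = group["spike_time_s"].dropna().to_numpy(dtype=float)
        times = np.sort(times)
        if times.size and (times.min() < 0 or times.max() >= TRIAL_DURATION):
            bad = times[(times < 0) | (times >= TRIAL_DURATION)][0]
            row = group.index[0] + 2  # header + 1-based
            raise ValidationError(
                f"spike time {bad} outside [0, {TRIAL_DURATION}) "
                f"for {neuron_id}/{stimulus}/trial {trial} (near line {row})"
            )
        trials.append(
            SpikeTrainTrial(
                neuron_id=str(neuron_id),
                stimulus=as_stimulus(str(stimulus)),
                trial_index=int(trial),
                spike_times=times,
            )
        )
    return trials


# --------------------------------------------------------------------------
# Morphology
# --------------------------------------------------------------------------

def write_morphology_tsv(
    morphologies: Sequence[NeuronMorphology], path: str | Path
) -> None:
    rows = [
        {
            "neuron_id": m.neuron_id,
            "neuron_class": m.neuron_class,
            "tract": m.tract,
            "dendritic_units": ";".join(m.dendritic_units),
            "output_neuropils": ";".join(m.output_neuropils),
            "uniglomerular": m.uniglomerular,
            "protocol": m.protocol,
        }
        for m in morphologies
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_morphology_tsv(path: str | Path) -> list[NeuronMorphology]:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {
        "neuron_id", "neuron_class", "tract", "dendritic_units",
        "output_neuropils", "uniglomerular", "protocol",
    }
    if not required <= set(frame.columns):
        raise ValidationError(f"morphology TSV must have columns {sorted(required)}")
    out = []
    for i, row in frame.iterrows():
        try:
            out.append(
                NeuronMorphology(
                    neuron_id=row["neuron_id"],
                    neuron_class=row["neuron_class"],
                    dendritic_units=tuple(row["dendritic_units"].split(";")),
                    tract=row["tract"],
                    uniglomerular=str(row["uniglomerular"]).lower() in ("true", "1"),
                    output_neuropils=tuple(row["output_neuropils"].split(";")),
                    protocol=row["protocol"],
                )
            )
        except ValueError as exc:
            raise ValidationError(f"morphology TSV line {i + 2}: {exc}") from exc
    return out


# --------------------------------------------------------------------------
# Calcium data
# --------------------------------------------------------------------------

def write_calcium_csv(
    recordings: Sequence[CalciumRecording], path: str | Path
) -> None:
    rows = []
    for rec in recordings:
        for frame_idx, ratio in enumerate(rec.frames):
            rows.append(
                (rec.individual_id, rec.unit, rec.stimulus.value, rec.trial,
                 frame_idx, repr(float(ratio)))
            )
    pd.DataFrame(
        rows, columns=["individual", "unit", "stimulus", "trial", "frame", "ratio"]
    ).to_csv(path, index=False)


def read_calcium_csv(path: str | Path) -> list[CalciumRecording]:
    frame = pd.read_csv(path, dtype={"individual": str, "unit": str, "stimulus": str},
                        float_precision="round_trip")
    required = {"individual", "unit", "stimulus", "trial", "frame", "ratio"}
    if not required <= set(frame.columns):
        raise ValidationError(f"calcium CSV must have columns {sorted(required)}")
    out = []
    for (ind, unit, stimulus, trial), group in frame.groupby(
        ["individual", "unit", "stimulus", "trial"], sort=True
    ):
        ordered = group.sort_values("frame")
        if not np.array_equal(ordered["frame"].to_numpy(), np.arange(N_FRAMES)):
            raise ValidationError(
                f"recording {ind}/{unit}/{stimulus}/trial {trial} must have "
                f"frames 0..{N_FRAMES - 1}"
            )
        out.append(
            CalciumRecording(
                individual_id=str(ind),
                unit=str(unit),
                stimulus=as_stimulus(str(stimulus)),
                trial=int(trial),
                frames=ordered["ratio"].to_numpy(dtype=float),
            )
        )
    return out


def write_ground_truth_json(tuning: TuningTable, path: str | Path) -> None:
    Path(path).write_text(json.dumps(tuning.ground_truth(), indent=2) + "\n")


# --------------------------------------------------------------------------
# Study configuration
# --------------------------------------------------------------------------

_CONFIG_KEYS = {
    "seed", "output_dir", "protocol", "trials_per_stimulus",
    "n_individuals", "noise_sd",
    "calcium_threshold_axis", "fisher_z",
    "stages", "population",
}
_STAGES = ("simulate", "spikes", "calcium", "population", "framework", "robustness")


@dataclass
class StudyConfig:
    """Validated pipeline configuration."""

    seed: int = 0
    output_dir: str = "results"
    protocol: str = "low"
    trials_per_stimulus: int = 5
    n_individuals: int = 8
    noise_sd: float = 0.01
    calcium_threshold_axis: str = "individuals"
    fisher_z: bool = False
    stages: tuple[str, ...] = _STAGES
    population: dict | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("low", "high"):
            raise ValidationError("protocol must be 'low' or 'high'")
        if self.protocol == "high" and self.trials_per_stimulus != 1:
            raise ValidationError("high protocol requires trials_per_stimulus = 1")
        if self.trials_per_stimulus < 1:
            raise ValidationError("trials_per_stimulus must be >= 1")
        if self.calcium_threshold_axis not in ("individuals", "frames"):
            raise ValidationError("calcium_threshold_axis must be 'individuals' or 'frames'")
        unknown = set(self.stages) - set(_STAGES)
        if unknown:
            raise ValidationError(f"unknown stage(s): {sorted(unknown)}")
        self.stages = tuple(self.stages)

    @classmethod
    def from_mapping(cls, mapping: dict) -> "StudyConfig":
        unknown = set(mapping) - _CONFIG_KEYS
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValidationError("config file must contain a mapping")
        return cls.from_mapping(data)

    def canonical_json(self) -> str:
        data = asdict(self)
        data["stages"] = list(self.stages)
        return json.dumps(data, sort_keys=True)

    def digest(self) -> str:
        """Stable hash of the configuration, stamped on every output."""
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:12]
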