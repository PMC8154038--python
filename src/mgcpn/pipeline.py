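"""End-to-end pipeline: simulate, analyze, and report.

``run_pipeline`` executes the enabled stages in order — synthetic data
generation, spike-train analysis, calcium analysis, population consistency,
the neuropil framework with simulation validation, and the assembly-shuffling
robustness check — writing tidy CSV/JSON outputs plus a run manifest (config
hash, seed, package version, completed stages) into the output directory.
Reruns with the same configuration and seed are numerically identical.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import amplitude_lookup, classification_table, mzifr_matrix, session_mzifr
from .calcium import baseline_normalize, average_trials, population_response_table
from .framework import group_by_neuropil, group_mean_responses, validate_simulation
from .io import (
    StudyConfig,
    write_calcium_csv,
    write_ground_truth_json,
    write_morphology_tsv,
    write_spike_csv,
)
from .population import across_stimuli_correlation, consistency_correlation, study_response_vectors
from .robustness import (
    cross_assembly_correlation,
    mean_offdiagonal,
    pairwise_neuron_correlations,
    shuffle_assemblies,
)
from .stimuli import StimulusLabel
from .synthetic import DEFAULT_TUNING, simulate_calcium_study, simulate_recording_session

log = logging.getLogger("mgcpn.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def _stamp(frame: pd.DataFrame, config: StudyConfig) -> pd.DataFrame:
    frame = frame.copy()
    frame["config_hash"] = config.digest()
    return frame


def run_pipeline(config: StudyConfig, output_dir: str | Path | None = None) -> Path:
    """Run all enabled stages; returns the results directory."""
    out = Path(output_dir if output_dir is not None else config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    completed: list[str] = []
    state: dict = {}

    stage_fns = {
        "simulate": _stage_simulate,
        "spikes": _stage_spikes,
        "calcium": _stage_calcium,
        "population": _stage_population,
        "framework": _stage_framework,
        "robustness": _stage_robustness,
    }
    for stage in config.stages:
        log.info("running stage %s", stage)
        try:
            stage_fns[stage](config, out, state)
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, exc) from exc
        completed.append(stage)

    manifest = {
        "config": json.loads(config.canonical_json()),
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "stages_completed": completed,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return out


def _stage_simulate(config: StudyConfig, out: Path, state: dict) -> None:
    session = simulate_recording_session(
        population=None,
        protocol=config.protocol,
        trials_per_stimulus=config.trials_per_stimulus,
        seed=config.seed,
    )
    recordings = simulate_calcium_study(
        n_individuals=config.n_individuals,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    state["session"] = session
    state["calcium"] = recordings
    write_spike_csv(session, out / "spikes.csv")
    write_morphology_tsv(session.morphologies, out / "morphologies.tsv")
    write_calcium_csv(recordings, out / "calcium.csv")
    write_ground_truth_json(DEFAULT_TUNING, out / "ground_truth.json")


def _require(state: dict, key: str, stage: str) -> object:
    if key not in state:
        raise RuntimeError(f"stage {stage!r} requires the 'simulate' stage")
    return state[key]


def _stage_spikes(config: StudyConfig, out: Path, state: dict) -> None:
    session = _require(state, "session", "spikes")
    traces = session_mzifr(session)
    state["traces"] = traces
    _stamp(classification_table(session, traces), config).to_csv(
        out / "spike_classification.csv", index=False
    )
    mzifr_matrix(traces).to_csv(out / "mzifr_matrix.csv")


def _stage_calcium(config: StudyConfig, out: Path, state: dict) -> None:
    recordings = _require(state, "calcium", "calcium")
    table = population_response_table(
        recordings, threshold_axis=config.calcium_threshold_axis
    )
    _stamp(table, config).to_csv(out / "calcium_responses.csv", index=False)


def _stage_population(config: StudyConfig, out: Path, state: dict) -> None:
    recordings = _require(state, "calcium", "population")
    by_unit = study_response_vectors(recordings)
    rows = []
    for unit, vectors in by_unit.items():
        res = consistency_correlation(vectors, fisher_z=config.fisher_z)
        rows.append(
            {
                "unit": unit,
                "mean_r": res.mean_r,
                "t_statistic": res.t_statistic,
                "p_value": res.p_value,
                "n_pairs": res.n_pairs,
            }
        )
    _stamp(pd.DataFrame(rows), config).to_csv(out / "consistency.csv", index=False)

    # Across-stimuli correlations of unit mean traces.
    for unit in sorted({r.unit for r in recordings}):
        per_stim: dict[StimulusLabel, np.ndarray] = {}
        for stim in sorted({r.stimulus for r in recordings}, key=lambda s: s.value):
            deltas = [
                baseline_normalize(r)
                for r in recordings
                if r.unit == unit and r.stimulus == stim
            ]
            per_stim[stim] = np.mean([d.frames for d in deltas], axis=0)
        across_stimuli_correlation(per_stim).to_csv(
            out / f"across_stimuli_{unit}.csv"
        )


def _stage_framework(config: StudyConfig, out: Path, state: dict) -> None:
    session = _require(state, "session", "framework")
    traces = state.get("traces") or session_mzifr(session)
    state["traces"] = traces
    activity_map = group_by_neuropil(session.morphologies, traces)
    rows = []
    trace_rows = {}
    for (neuropil, stim), cell in activity_map.items():
        rows.append(
            {
                "neuropil": neuropil,
                "stimulus": stim.value,
                "described_value": cell.described_value,
                "n_members": cell.n_members,
            }
        )
        trace_rows[f"{neuropil}|{stim.value}"] = cell.mean_trace
    _stamp(pd.DataFrame(rows), config).to_csv(out / "framework_values.csv", index=False)
    pd.DataFrame.from_dict(trace_rows, orient="index").to_csv(
        out / "framework_traces.csv"
    )

    amplitudes = amplitude_lookup(traces)
    validation = validate_simulation(activity_map, session.morphologies, amplitudes)
    _stamp(validation.points, config).to_csv(out / "simulation_scatter.csv", index=False)
    (out / "simulation_r2.json").write_text(
        json.dumps({"r_squared": validation.r_squared,
                    "slope": validation.slope,
                    "intercept": validation.intercept}) + "\n"
    )
    _stamp(
        group_mean_responses(session.morphologies, amplitudes), config
    ).to_csv(out / "group_mean_responses.csv", index=False)
    state["activity_map"] = activity_map


def _stage_robustness(config: StudyConfig, out: Path, state: dict) -> None:
    session = _require(state, "session", "robustness")
    traces = state.get("traces") or session_mzifr(session)
    result = shuffle_assemblies(session.morphologies, traces, seed=config.seed)
    pd.DataFrame(result.cross_assembly_r).to_csv(out / "cross_assembly_r.csv")
    pairwise = pairwise_neuron_correlations(session.morphologies, traces)
    pairwise.to_csv(out / "pairwise_neuron_r.csv")
    summary = {
        "mean_cross_assembly_r": cross_assembly_correlation(result),
        "mean_pairwise_neuron_r": mean_offdiagonal(pairwise),
    }
    summary["contrast"] = (
        summary["mean_cross_assembly_r"] - summary["mean_pairwise_neuron_r"]
    )
    (out / "robustness_summary.json").write_text(json.dumps(summary, indent=2) + "\n")
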