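"""Synthetic recording sessions with known ground truth.

This module generates spike-train sessions and calcium-imaging studies with
the statistical structure the downstream analyses assume, so that the whole
pipeline is testable without access to laboratory recordings.

Spike trains are inhomogeneous Poisson processes sampled by thinning.  Each
neuron class carries a baseline rate and, per stimulus, a response kernel
(phasic, tonic, phasic-tonic, delayed, inhibitory or none) whose amplitude is
expressed as a gain multiplier on the baseline.  The default population
mirrors a typical intracellular-recording sample of 42 macroglomerular-complex
projection neurons: 16 uniglomerular cumulus neurons, 4 dma and 4 dmp neurons
and 5 multiglomerular neurons in the medial tract, 3 mediolateral-tract
neurons, and 10 lateral-tract cumulus neurons.

Calcium traces emulate Fura-2 ratio recordings of medial-tract populations:
100 frames at 10 Hz (4 s spontaneous, 2 s stimulation, 4 s post), with a
shared unit x stimulus tuning profile scaled by per-individual gain and
corrupted by frame noise, across 8 individuals by default.

Randomness uses per-stream substreams keyed by (neuron index, stimulus,
trial), so enlarging a population never perturbs existing traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

from .stimuli import (
    CALCIUM_STIMULI,
    SPIKE_STIMULI,
    StimulusLabel,
    as_stimulus,
)
from .spikes import STIM_OFFSET, STIM_ONSET, TRIAL_DURATION, SpikeTrainTrial

MGC_UNITS = ("Cu", "dma", "dmp")
TRACTS = ("mALT", "mlALT", "lALT")
#: All output neuropils a projection neuron may innervate.
NEUROPILS = ("Ca", "VLP", "SLP", "SIP", "LH", "column")

KERNEL_SHAPES = ("none", "phasic", "tonic", "phasic_tonic", "delayed", "inhibitory")

#: Default kernel time constants (seconds).
PHASIC_TAU = 0.08
DELAYED_LATENCY = 0.15
INHIBITORY_DEPTH = 0.8  # fractional suppression of baseline


@dataclass(frozen=True)
class NeuronMorphology:
    """Morphological record of one projection neuron."""

    neuron_id: str
    neuron_class: str
    dendritic_units: tuple[str, ...]
    tract: str
    uniglomerular: bool
    output_neuropils: tuple[str, ...]
    protocol: str = "low"

    def __post_init__(self) -> None:
        if self.tract not in TRACTS:
            raise ValueError(f"unknown tract {self.tract!r}")
        if not set(self.dendritic_units) <= set(MGC_UNITS) | {"PCx"}:
            raise ValueError(f"unknown dendritic units {self.dendritic_units}")
        if self.uniglomerular and len(self.dendritic_units) != 1:
            raise ValueError("uniglomerular neurons have exactly one dendritic unit")
        if not self.output_neuropils:
            raise ValueError("output_neuropils must be non-empty")
        if not set(self.output_neuropils) <= set(NEUROPILS):
            raise ValueError(f"unknown neuropils {self.output_neuropils}")
        if "column" in self.output_neuropils and (
            self.tract != "lALT" or self.dendritic_units != ("Cu",)
        ):
            raise ValueError("the SIP column is innervated only by lateral-tract cumulus neurons")


@dataclass(frozen=True)
class NeuronClassSpec:
    """Template for a morphological class of projection neurons.

    ``optional_neuropils`` are innervated per-neuron with the given
    probability, reflecting within-class variability of terminal fields
    (e.g. cumulus medial-tract neurons always reach the VLP and SLP but only
    a subset extends into the SIP).
    """

    name: str
    dendritic_units: tuple[str, ...]
    tract: str
    uniglomerular: bool
    output_neuropils: tuple[str, ...]
    optional_neuropils: Mapping[str, float] = field(default_factory=dict)
    baseline_rate: float = 15.0  # Hz


#: Default class table.  Medial/mediolateral-tract neurons fire at 15 Hz at
#: rest, lateral-tract neurons at 30 Hz, preserving the quieter-medial /
#: louder-lateral contrast while keeping 10 ms bin counts dense enough for
#: Gaussian threshold statistics.
DEFAULT_CLASSES: dict[str, NeuronClassSpec] = {
    spec.name: spec
    for spec in (
        NeuronClassSpec(
            "Cu-mALT", ("Cu",), "mALT", True,
            ("Ca", "VLP", "SLP"), {"SIP": 0.5}, baseline_rate=15.0,
        ),
        NeuronClassSpec(
            "dma-mALT", ("dma",), "mALT", True,
            ("Ca", "VLP", "LH"), baseline_rate=15.0,
        ),
        NeuronClassSpec(
            "dmp-mALT", ("dmp",), "mALT", True,
            ("Ca", "VLP", "LH"), baseline_rate=15.0,
        ),
        NeuronClassSpec(
            "MGC-mALT", ("Cu", "dma", "dmp"), "mALT", False,
            ("Ca", "VLP", "LH"), baseline_rate=15.0,
        ),
        NeuronClassSpec(
            "MGC-mlALT", ("Cu", "dma", "dmp"), "mlALT", False,
            ("VLP",), baseline_rate=15.0,
        ),
        NeuronClassSpec(
            "Cu-lALT", ("Cu",), "lALT", True,
            ("column",), baseline_rate=30.0,
        ),
    )
}

#: Class counts of the default 42-neuron sample.
DEFAULT_POPULATION: dict[str, int] = {
    "Cu-mALT": 16,
    "dma-mALT": 4,
    "dmp-mALT": 4,
    "MGC-mALT": 5,
    "MGC-mlALT": 3,
    "Cu-lALT": 10,
}


@dataclass(frozen=True)
class Kernel:
    """Stimulus-response kernel of one neuron class x stimulus."""

    shape: str = "none"
    gain: float = 0.0
    latency: float = 0.0
    tau: float = PHASIC_TAU

    def __post_init__(self) -> None:
        if self.shape not in KERNEL_SHAPES:
            raise ValueError(f"unknown kernel shape {self.shape!r}")
        if self.gain < 0 or self.latency < 0 or self.tau < 0:
            raise ValueError("gain, latency and tau must be non-negative")


class TuningTable:
    """Mapping (neuron class, stimulus) -> response :class:`Kernel`.

    Missing entries default to a ``none`` kernel.  Control rows must stay
    ``none`` in any table used to anchor thresholds.
    """

    def __init__(self, entries: Mapping[tuple[str, StimulusLabel], Kernel] | None = None):
        self._entries: dict[tuple[str, StimulusLabel], Kernel] = {}
        if entries:
            for (cls, stim), kernel in entries.items():
                self._entries[(cls, as_stimulus(stim))] = kernel

    def get(self, neuron_class: str, stimulus: StimulusLabel | str) -> Kernel:
        return self._entries.get((neuron_class, as_stimulus(stimulus)), Kernel())

    def set(self, neuron_class: str, stimulus: StimulusLabel | str, kernel: Kernel) -> None:
        self._entries[(neuron_class, as_stimulus(stimulus))] = kernel

    def items(self):
        return self._entries.items()

    def responsive_pairs(self) -> set[tuple[str, StimulusLabel]]:
        """Ground-truth (class, stimulus) pairs carrying a non-none kernel."""
        return {key for key, k in self._entries.items() if k.shape != "none" and k.gain > 0}

    def ground_truth(self) -> list[dict]:
        """Exportable ground-truth labels for parameter-recovery tests."""
        return [
            {
                "neuron_class": cls,
                "stimulus": stim.value,
                "shape": k.shape,
                "gain": k.gain,
                "latency": k.latency,
                "tau": k.tau,
            }
            for (cls, stim), k in sorted(
                self._entries.items(), key=lambda kv: (kv[0][0], kv[0][1].value)
            )
            if k.shape != "none"
        ]


def _phasic(gain: float, latency: float, tau: float) -> Kernel:
    return Kernel("phasic", gain, latency, tau)


def _ptonic(gain: float, latency: float = 0.02) -> Kernel:
    return Kernel("phasic_tonic", gain, latency)


#: Default tuning.  Encodes the qualitative response map of the study system:
#: cumulus neurons (projecting to SLP/SIP) are driven by the primary pheromone
#: and the mixture; dma and dmp neurons (projecting to the LH) by the
#: behavioral antagonist and secondary pheromone, dma also weakly by the
#: pheromone mixture; multiglomerular and mediolateral-tract neurons respond
#: broadly; lateral-tract column neurons give fast phasic responses to the
#: primary pheromone and mixture only.
DEFAULT_TUNING = TuningTable({
    ("Cu-mALT", StimulusLabel.PM): _ptonic(6.0),
    ("Cu-mALT", StimulusLabel.PP): _ptonic(6.0),
    ("Cu-mALT", StimulusLabel.SP): Kernel("delayed", 1.5, DELAYED_LATENCY),
    ("dma-mALT", StimulusLabel.BA): _ptonic(5.0),
    ("dma-mALT", StimulusLabel.PM): _ptonic(3.0),
    ("dma-mALT", StimulusLabel.PP): _phasic(1.5, 0.02, PHASIC_TAU),
    ("dma-mALT", StimulusLabel.SP): _phasic(2.0, 0.02, PHASIC_TAU),
    ("dmp-mALT", StimulusLabel.SP): Kernel("delayed", 4.0, DELAYED_LATENCY),
    ("dmp-mALT", StimulusLabel.BA): _ptonic(4.0),
    ("dmp-mALT", StimulusLabel.PM): _phasic(2.0, 0.02, PHASIC_TAU),
    ("MGC-mALT", StimulusLabel.BA): _ptonic(3.0),
    ("MGC-mALT", StimulusLabel.SP): _phasic(2.0, 0.02, PHASIC_TAU),
    ("MGC-mALT", StimulusLabel.PM): _phasic(2.0, 0.02, PHASIC_TAU),
    ("MGC-mALT", StimulusLabel.PP): _phasic(1.5, 0.02, PHASIC_TAU),
    ("MGC-mlALT", StimulusLabel.PM): _ptonic(4.0),
    ("MGC-mlALT", StimulusLabel.PP): _ptonic(4.0),
    ("MGC-mlALT", StimulusLabel.SP): _phasic(3.0, 0.02, PHASIC_TAU),
    ("MGC-mlALT", StimulusLabel.BA): _phasic(3.0, 0.02, PHASIC_TAU),
    ("Cu-lALT", StimulusLabel.PM): _phasic(8.0, 0.005, PHASIC_TAU),
    ("Cu-lALT", StimulusLabel.PP): _phasic(8.0, 0.005, PHASIC_TAU),
})


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic RNG substream keyed by integers."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def generate_population(
    config: Mapping[str, int] | None = None,
    seed: int = 0,
    classes: Mapping[str, NeuronClassSpec] | None = None,
    protocol: str = "low",
) -> list[NeuronMorphology]:
    """Generate a population of morphology records from class counts.

    The default configuration reproduces the 42-neuron reference sample.
    Neuron IDs are ``<class><index>`` for the low-concentration protocol and
    ``<class><letter>`` for the high-concentration protocol.
    """
    config = dict(DEFAULT_POPULATION if config is None else config)
    classes = dict(DEFAULT_CLASSES if classes is None else classes)
    unknown = set(config) - set(classes)
    if unknown:
        raise ValueError(f"unknown neuron class(es): {sorted(unknown)}")
    if any(n < 0 for n in config.values()):
        raise ValueError("class counts must be >= 0")

    population: list[NeuronMorphology] = []
    idx = 0
    for name in config:  # caller-ordered; default dict order is stable
        spec = classes[name]
        for i in range(config[name]):
            rng = _substream(seed, 0, idx)
            neuropils = list(spec.output_neuropils)
            for npil, prob in spec.optional_neuropils.items():
                if rng.random() < prob:
                    neuropils.append(npil)
            suffix = str(i + 1) if protocol == "low" else _letters(i)
            population.append(
                NeuronMorphology(
                    neuron_id=f"{name}{suffix}",
                    neuron_class=name,
                    dendritic_units=spec.dendritic_units,
                    tract=spec.tract,
                    uniglomerular=spec.uniglomerular,
                    output_neuropils=tuple(neuropils),
                    protocol=protocol,
                )
            )
            idx += 1
    return population


def _letters(i: int) -> str:
    """0 -> 'a', 25 -> 'z', 26 -> 'aa', ..."""
    out = ""
    i += 1
    while i > 0:
        i, rem = divmod(i - 1, 26)
        out = chr(ord("a") + rem) + out
    return out


def _rate_function(
    baseline: float, kernel: Kernel, t: np.ndarray
) -> np.ndarray:
    """Firing rate (Hz) at times ``t`` for a baseline plus response kernel.

    Kernel shapes (t' = time since stimulus onset plus kernel latency):

    * phasic: gain * baseline * exp(-t'/tau)
    * tonic: gain * baseline over the remaining stimulus window
    * phasic_tonic: sum of the two
    * delayed: phasic with the delayed-response latency
    * inhibitory: -INHIBITORY_DEPTH * baseline over the stimulus window

    Negative rates are clamped at zero.
    """
    rate = np.full_like(t, baseline, dtype=float)
    if kernel.shape == "none" or (kernel.gain == 0 and kernel.shape != "inhibitory"):
        return rate
    start = STIM_ONSET + kernel.latency
    amp = kernel.gain * baseline
    since = t - start
    if kernel.shape in ("phasic", "delayed", "phasic_tonic"):
        mask = since >= 0
        rate[mask] += amp * np.exp(-since[mask] / kernel.tau)
    if kernel.shape in ("tonic", "phasic_tonic"):
        mask = (since >= 0) & (t < STIM_OFFSET)
        rate[mask] += amp
    if kernel.shape == "inhibitory":
        mask = (t >= start) & (t < STIM_OFFSET)
        rate[mask] -= INHIBITORY_DEPTH * baseline
    return np.clip(rate, 0.0, None)


def _max_rate(baseline: float, kernel: Kernel) -> float:
    if kernel.shape == "phasic_tonic":
        return baseline * (1.0 + 2.0 * kernel.gain)
    if kernel.shape in ("phasic", "delayed", "tonic"):
        return baseline * (1.0 + kernel.gain)
    return baseline


def simulate_spike_trial(
    neuron: NeuronMorphology,
    stimulus: StimulusLabel | str,
    tuning: TuningTable | None = None,
    baseline_rate: float | None = None,
    seed: int = 0,
    trial_index: int = 0,
    neuron_index: int = 0,
    gain_factor: float = 1.0,
    classes: Mapping[str, NeuronClassSpec] | None = None,
) -> SpikeTrainTrial:
    """Sample one spike-train trial by Poisson thinning.

    The rate function is the class baseline plus the tuned response kernel
    (scaled by ``gain_factor``, a per-neuron response-strength multiplier),
    clamped at zero.  The RNG substream is keyed by (neuron index, stimulus,
    trial), so trials are independent and reproducible.
    """
    stimulus = as_stimulus(stimulus)
    tuning = DEFAULT_TUNING if tuning is None else tuning
    classes = DEFAULT_CLASSES if classes is None else classes
    if baseline_rate is None:
        baseline_rate = classes[neuron.neuron_class].baseline_rate
    if baseline_rate <= 0:
        raise ValueError("baseline_rate must be positive")
    kernel = tuning.get(neuron.neuron_class, stimulus)
    if kernel.gain > 0:
        kernel = replace(kernel, gain=kernel.gain * gain_factor)

    stim_idx = list(StimulusLabel).index(stimulus)
    rng = _substream(seed, 1, neuron_index, stim_idx, trial_index)

    rate_max = _max_rate(baseline_rate, kernel)
    n_candidates = rng.poisson(rate_max * TRIAL_DURATION)
    candidates = np.sort(rng.uniform(0.0, TRIAL_DURATION, size=n_candidates))
    accept = rng.uniform(0.0, rate_max, size=n_candidates) < _rate_function(
        baseline_rate, kernel, candidates
    )
    return SpikeTrainTrial(
        neuron_id=neuron.neuron_id,
        stimulus=stimulus,
        trial_index=trial_index,
        spike_times=candidates[accept],
    )


@dataclass(frozen=True)
class RecordingSession:
    """A complete simulated intracellular-recording session."""

    morphologies: list[NeuronMorphology]
    trials: list[SpikeTrainTrial]
    protocol: str
    trials_per_stimulus: int
    stimuli: tuple[StimulusLabel, ...]
    gain_factors: dict[str, float] = field(default_factory=dict)

    def trials_for(
        self, neuron_id: str, stimulus: StimulusLabel | str
    ) -> list[SpikeTrainTrial]:
        stimulus = as_stimulus(stimulus)
        return [
            t for t in self.trials if t.neuron_id == neuron_id and t.stimulus == stimulus
        ]


def simulate_recording_session(
    population: Sequence[NeuronMorphology] | None = None,
    tuning: TuningTable | None = None,
    protocol: str = "low",
    trials_per_stimulus: int = 5,
    seed: int = 0,
    stimuli: Sequence[StimulusLabel] = SPIKE_STIMULI,
    gain_jitter_sd: float = 0.2,
    classes: Mapping[str, NeuronClassSpec] | None = None,
) -> RecordingSession:
    """Simulate a full session: every neuron x stimulus x trial.

    The high-concentration protocol never repeats a stimulus (adaptation at
    high doses), so ``trials_per_stimulus`` must be 1 there.  Each neuron
    carries a lognormal response-strength factor (sigma = ``gain_jitter_sd``)
    applied to all its kernels, modeling between-preparation variability.
    """
    if protocol not in ("low", "high"):
        raise ValueError("protocol must be 'low' or 'high'")
    if trials_per_stimulus < 1:
        raise ValueError("trials_per_stimulus must be >= 1")
    if protocol == "high" and trials_per_stimulus != 1:
        raise ValueError("the high-concentration protocol does not repeat trials")
    if population is None:
        population = generate_population(seed=seed, protocol=protocol, classes=classes)
    tuning = DEFAULT_TUNING if tuning is None else tuning

    gain_factors: dict[str, float] = {}
    trials: list[SpikeTrainTrial] = []
    for n_idx, neuron in enumerate(population):
        g = 1.0
        if gain_jitter_sd > 0:
            g = float(np.exp(_substream(seed, 2, n_idx).normal(0.0, gain_jitter_sd)))
        gain_factors[neuron.neuron_id] = g
        for stim in stimuli:
            for k in range(trials_per_stimulus):
                trials.append(
                    simulate_spike_trial(
                        neuron,
                        stim,
                        tuning=tuning,
                        seed=seed,
                        trial_index=k,
                        neuron_index=n_idx,
                        gain_factor=g,
                        classes=classes,
                    )
                )
    return RecordingSession(
        morphologies=list(population),
        trials=trials,
        protocol=protocol,
        trials_per_stimulus=trials_per_stimulus,
        stimuli=tuple(stimuli),
        gain_factors=gain_factors,
    )


# --------------------------------------------------------------------------
# Calcium imaging
# --------------------------------------------------------------------------

N_FRAMES = 100
FRAME_RATE = 10.0  # Hz
CA_STIM_START = 40  # 0-based frame index of stimulus onset (4 s)
CA_STIM_END = 60  # stimulus offset (6 s)
CA_TRIALS = 2


@dataclass(frozen=True)
class CalciumRecording:
    """One Fura-2 ratio trace: individual x MGC unit x stimulus x trial."""

    individual_id: str
    unit: str
    stimulus: StimulusLabel
    trial: int
    frames: np.ndarray

    def __post_init__(self) -> None:
        frames = np.asarray(self.frames, dtype=float)
        if frames.shape != (N_FRAMES,):
            raise ValueError(f"expected {N_FRAMES} frames, got {frames.shape}")
        if np.any(frames < 0):
            raise ValueError("ratio values must be non-negative")
        if self.unit not in MGC_UNITS:
            raise ValueError(f"unknown MGC unit {self.unit!r}")
        object.__setattr__(self, "frames", frames)
        object.__setattr__(self, "stimulus", as_stimulus(self.stimulus))


#: Default unit x stimulus calcium response amplitudes (peak DeltaF340/F380).
#: Cumulus responds to the pheromone mixture and primary component; dma is
#: broadly tuned including the behavioral antagonist; dmp to the secondary
#: component and the antagonist.
DEFAULT_UNIT_TUNING: dict[tuple[str, StimulusLabel], float] = {
    ("Cu", StimulusLabel.PM): 0.09,
    ("Cu", StimulusLabel.PP): 0.08,
    ("Cu", StimulusLabel.SP): 0.01,
    ("Cu", StimulusLabel.BA): 0.01,
    ("Cu", StimulusLabel.PLANT_PM): 0.06,
    ("dma", StimulusLabel.PM): 0.06,
    ("dma", StimulusLabel.PP): 0.05,
    ("dma", StimulusLabel.SP): 0.02,
    ("dma", StimulusLabel.BA): 0.07,
    ("dma", StimulusLabel.PLANT): 0.01,
    ("dma", StimulusLabel.PLANT_PM): 0.05,
    ("dmp", StimulusLabel.PM): 0.05,
    ("dmp", StimulusLabel.PP): 0.01,
    ("dmp", StimulusLabel.SP): 0.06,
    ("dmp", StimulusLabel.BA): 0.06,
    ("dmp", StimulusLabel.PLANT_PM): 0.04,
}


def calcium_response_shape() -> np.ndarray:
    """Unit-peak response shape over the 100-frame clock.

    Linear rise over 3 frames from stimulus onset, then exponential decay
    with a 1 s time constant — the phasic profile that decays over the course
    of the stimulation period.  Confined to frames at/after onset.
    """
    shape = np.zeros(N_FRAMES)
    rise = np.array([1 / 3, 2 / 3, 1.0])
    shape[CA_STIM_START : CA_STIM_START + 3] = rise
    decay_frames = np.arange(N_FRAMES - CA_STIM_START - 3)
    shape[CA_STIM_START + 3 :] = np.exp(-(decay_frames + 1) / FRAME_RATE)  # tau = 1 s
    return shape


def simulate_calcium_study(
    n_individuals: int = 8,
    unit_tuning: Mapping[tuple[str, StimulusLabel], float] | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    stimuli: Sequence[StimulusLabel] = CALCIUM_STIMULI,
    baseline_mean: float = 1.2,
    baseline_sd: float = 0.1,
    gain_sd: float = 0.3,
    amplitude_jitter_sd: float = 0.3,
    n_trials: int = CA_TRIALS,
) -> list[CalciumRecording]:
    """Simulate a calcium-imaging study across individuals.

    Each trace is an individual baseline constant plus the shared
    unit x stimulus response shape scaled by a per-individual lognormal gain
    and a per-(individual, unit, stimulus) lognormal amplitude jitter, plus
    Gaussian frame noise.  Two trials per stimulus by default.
    """
    if n_individuals < 2:
        raise ValueError("at least two individuals are required")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    tuning = DEFAULT_UNIT_TUNING if unit_tuning is None else dict(unit_tuning)
    shape = calcium_response_shape()

    recordings: list[CalciumRecording] = []
    for ind in range(n_individuals):
        ind_rng = _substream(seed, 3, ind)
        baseline = float(np.clip(ind_rng.normal(baseline_mean, baseline_sd), 0.1, None))
        gain = float(np.exp(ind_rng.normal(0.0, gain_sd))) if gain_sd > 0 else 1.0
        for u_idx, unit in enumerate(MGC_UNITS):
            for s_idx, stim in enumerate(stimuli):
                amp = tuning.get((unit, stim), 0.0)
                jitter = 1.0
                if amplitude_jitter_sd > 0 and amp > 0:
                    jitter = float(
                        np.exp(
                            _substream(seed, 4, ind, u_idx, s_idx).normal(
                                0.0, amplitude_jitter_sd
                            )
                        )
                    )
                for trial in range(n_trials):
                    rng = _substream(seed, 5, ind, u_idx, s_idx, trial)
                    trace = baseline + gain * jitter * amp * shape
                    if noise_sd > 0:
                        trace = trace + rng.normal(0.0, noise_sd, size=N_FRAMES)
                    recordings.append(
                        CalciumRecording(
                            individual_id=f"ind{ind + 1}",
                            unit=unit,
                            stimulus=stim,
                            trial=trial,
                            frames=np.clip(trace, 0.0, None),
                        )
                    )
    return recordings
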