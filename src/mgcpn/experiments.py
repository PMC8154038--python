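"""Self-contained simulation experiments on the synthetic study conditions.

These drivers reproduce, at desk scale, the calibration and validity checks
the analysis rests on: the false-positive level of the firing-rate response
thresholds under a homogeneous-Poisson null, split-sample validation of the
neuropil framework's projection-combination simulation, cross-individual
calcium consistency, and parameter recovery of the response classifier.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np

from .analysis import amplitude_lookup, session_mzifr
from .framework import framework_projection, group_by_neuropil, validate_simulation
from .population import ConsistencyResult, consistency_correlation, study_response_vectors
from .spikes import (
    EXCITATORY,
    NONE,
    STIM,
    classify_response,
    compute_mzifr,
    compute_thresholds,
    compute_zifr,
)
from .stimuli import StimulusLabel
from .synthetic import (
    TuningTable,
    generate_population,
    simulate_calcium_study,
    simulate_recording_session,
    simulate_spike_trial,
)


def null_threshold_exceedance(
    n_traces: int = 2000,
    trials_per_trace: int = 5,
    seed: int = 0,
) -> float:
    """Pooled fraction of stimulation-window MZIFR bins outside [T_L, T_U]
    under a homogeneous-Poisson null.

    Simulates ``n_traces`` neuron x stimulus traces with no response kernel,
    cycling through the default population (so the default mix of baseline
    firing rates is represented), and pools the per-bin exceedances.  A
    well-calibrated threshold yields ~5% (the nominal two-sided level).
    """
    population = generate_population(seed=seed)
    null_tuning = TuningTable()
    outside = 0
    total = 0
    for i in range(n_traces):
        neuron = population[i % len(population)]
        zifrs = [
            compute_zifr(
                simulate_spike_trial(
                    neuron, StimulusLabel.CTRL, tuning=null_tuning,
                    seed=seed + 1 + i, trial_index=k, neuron_index=i % len(population),
                )
            )
            for k in range(trials_per_trace)
        ]
        mzifr = compute_mzifr(zifrs)
        thr = compute_thresholds(mzifr)
        stim_bins = mzifr.values[STIM]
        outside += int(((stim_bins > thr.t_upper) | (stim_bins < thr.t_lower)).sum())
        total += stim_bins.size
    return outside / total


def split_framework_r2(seed: int, trials_per_stimulus: int = 5) -> float:
    """R^2 of recorded vs simulated amplitudes on a held-out neuron split.

    Simulates the default 42-neuron session, splits each projection-set
    stratum at random into two-thirds train / one-third test, builds the
    neuropil activity map on the training neurons only, and validates the
    projection-combination simulation against the held-out neurons' recorded
    amplitudes.
    """
    session = simulate_recording_session(
        trials_per_stimulus=trials_per_stimulus, seed=seed
    )
    traces = session_mzifr(session)
    amplitudes = amplitude_lookup(traces)

    groups = defaultdict(list)
    for m in session.morphologies:
        groups[frozenset(framework_projection(m))].append(m)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for key in sorted(groups, key=lambda k: sorted(k)):
        members = groups[key]
        order = rng.permutation(len(members))
        n_test = max(1, len(members) // 3)
        for rank, idx in enumerate(order):
            (test if rank < n_test else train).append(members[idx])

    activity_map = group_by_neuropil(train, traces)
    result = validate_simulation(activity_map, test, amplitudes)
    return result.r_squared


def calcium_consistency(seed: int = 1, **study_kwargs) -> dict[str, ConsistencyResult]:
    """Per-unit cross-individual consistency on a default calcium study."""
    recordings = simulate_calcium_study(seed=seed, **study_kwargs)
    return {
        unit: consistency_correlation(vectors)
        for unit, vectors in study_response_vectors(recordings).items()
    }


def classification_recovery(
    n_neurons: int = 500,
    trials_per_stimulus: int = 5,
    seed: int = 0,
) -> tuple[float, float]:
    """Parameter recovery of the sub-window response classifier.

    Simulates ``n_neurons`` default cumulus neurons.  For each, the tuned
    primary-pheromone stimulus (excitatory kernel, gain >= 3x baseline in the
    default table) should classify excitatory, and the control stimulus
    should classify none.  Returns (excitatory recovery rate, null
    specificity rate).
    """
    neuron = generate_population({"Cu-mALT": 1}, seed=0)[0]
    hits_exc = hits_none = 0
    for i in range(n_neurons):
        for stimulus, want in ((StimulusLabel.PP, EXCITATORY), (StimulusLabel.CTRL, NONE)):
            zifrs = [
                compute_zifr(
                    simulate_spike_trial(
                        neuron, stimulus, seed=seed + 1 + i, trial_index=k,
                        neuron_index=0,
                    )
                )
                for k in range(trials_per_stimulus)
            ]
            label = classify_response(compute_mzifr(zifrs)).subwindow_label
            if want == EXCITATORY and label == EXCITATORY:
                hits_exc += 1
            if want == NONE and label == NONE:
                hits_none += 1
    return hits_exc / n_neurons, hits_none / n_neurons
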