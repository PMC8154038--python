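"""Content validity of the neuropil framework via assembly shuffling.

Two complementary checks probe whether the framework's neuropil response
profiles are a property of the population rather than of particular neurons:

* *Assembly shuffling*: rebuild each neuropil's mean trace from a random
  two-thirds subset of its members, repeat five times, and correlate the
  repeats' concatenated neuropil x stimulus traces pairwise.  High
  cross-assembly correlations mean the profiles are stable under resampling.
* *Pairwise neuron correlations*: correlate the concatenated firing traces of
  every pair of neurons.  If these are clearly lower than the cross-assembly
  correlations, the stability is not an artifact of all neurons firing alike.

Both operate on the concatenated MZIFR traces over the four female-produced
odorants (controls and plant odors excluded).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .framework import FRAMEWORK_NEUROPILS, framework_projection
from .spikes import MzifrTrace
from .stimuli import FEMALE_PRODUCED, StimulusLabel
from .synthetic import NeuronMorphology, _substream


@dataclass(frozen=True)
class AssemblyShuffleResult:
    """Output of the two-thirds recruitment shuffling experiment."""

    n_repeats: int
    recruitment_fraction: float
    memberships: list[dict[str, tuple[str, ...]]]  # per repeat: neuropil -> ids
    assembly_vectors: np.ndarray  # repeats x (neuropil*stimulus*bins)
    cross_assembly_r: np.ndarray  # repeats x repeats
    neuropils: tuple[str, ...]
    stimuli: tuple[StimulusLabel, ...]


def shuffle_assemblies(
    morphologies: Sequence[NeuronMorphology],
    traces: Mapping[tuple[str, StimulusLabel], MzifrTrace],
    n_repeats: int = 5,
    fraction: float = 2 / 3,
    seed: int = 0,
    stimuli: Sequence[StimulusLabel] = FEMALE_PRODUCED,
) -> AssemblyShuffleResult:
    """Rebuild neuropil mean traces from random member subsets.

    Per repeat and neuropil, ``ceil(fraction * n)`` members are drawn
    uniformly without replacement; subsets are independent across repeats and
    neuropils (RNG substreams keyed by repeat x neuropil).  Neuropil groups of
    size one are used whole, with a warning.
    """
    if n_repeats < 2:
        raise ValueError("need >= 2 repeats")
    members_by_neuropil: dict[str, list[NeuronMorphology]] = {}
    for morph in morphologies:
        for n in framework_projection(morph):
            members_by_neuropil.setdefault(n, []).append(morph)
    neuropils = tuple(n for n in FRAMEWORK_NEUROPILS if n in members_by_neuropil)

    memberships: list[dict[str, tuple[str, ...]]] = []
    vectors: list[np.ndarray] = []
    for rep in range(n_repeats):
        chosen: dict[str, tuple[str, ...]] = {}
        segments: list[np.ndarray] = []
        for np_idx, neuropil in enumerate(neuropils):
            members = members_by_neuropil[neuropil]
            n = len(members)
            if n == 1:
                warnings.warn(
                    f"neuropil {neuropil} has a single member; whole group used",
                    stacklevel=2,
                )
                subset = members
            else:
                k = math.ceil(fraction * n)
                rng = _substream(seed, 6, rep, np_idx)
                idx = rng.choice(n, size=k, replace=False)
                subset = [members[i] for i in sorted(idx)]
            chosen[neuropil] = tuple(m.neuron_id for m in subset)
            for stim in stimuli:
                segments.append(
                    np.mean([traces[(m.neuron_id, stim)].values for m in subset], axis=0)
                )
        memberships.append(chosen)
        vectors.append(np.concatenate(segments))

    assembly = np.stack(vectors)
    cross = np.ones((n_repeats, n_repeats))
    for i in range(n_repeats):
        for j in range(i + 1, n_repeats):
            cross[i, j] = cross[j, i] = stats.pearsonr(assembly[i], assembly[j]).statistic
    return AssemblyShuffleResult(
        n_repeats=n_repeats,
        recruitment_fraction=fraction,
        memberships=memberships,
        assembly_vectors=assembly,
        cross_assembly_r=cross,
        neuropils=neuropils,
        stimuli=tuple(stimuli),
    )


def cross_assembly_correlation(result: AssemblyShuffleResult) -> float:
    """Mean off-diagonal Pearson correlation between shuffled assemblies.

    Pairs involving a constant assembly vector are excluded with a warning.
    """
    n = result.n_repeats
    if n < 2:
        raise ValueError("need >= 2 repeats")
    values = []
    for i in range(n):
        for j in range(i + 1, n):
            if result.assembly_vectors[i].std() == 0 or result.assembly_vectors[j].std() == 0:
                warnings.warn("constant assembly vector; pair excluded", stacklevel=2)
                continue
            values.append(result.cross_assembly_r[i, j])
    return float(np.mean(values))


def pairwise_neuron_correlations(
    morphologies: Sequence[NeuronMorphology],
    traces: Mapping[tuple[str, StimulusLabel], MzifrTrace],
    stimuli: Sequence[StimulusLabel] = FEMALE_PRODUCED,
) -> "pd.DataFrame":
    """Neuron x neuron Pearson correlations of concatenated firing traces.

    Each neuron's operand is its MZIFR traces over the female-produced
    stimuli, concatenated.  Neurons are ordered by class then ID (the block
    layout of class-sorted correlation matrices).  Rows/columns of constant
    traces are NaN.
    """
    import pandas as pd

    ordered = sorted(morphologies, key=lambda m: (m.neuron_class, m.neuron_id))
    ids = [m.neuron_id for m in ordered]
    concat = {
        m.neuron_id: np.concatenate(
            [traces[(m.neuron_id, s)].values for s in stimuli]
        )
        for m in ordered
    }
    n = len(ids)
    out = np.full((n, n), np.nan)
    for i in range(n):
        if concat[ids[i]].std() == 0:
            continue
        out[i, i] = 1.0
        for j in range(i + 1, n):
            if concat[ids[j]].std() == 0:
                continue
            r = stats.pearsonr(concat[ids[i]], concat[ids[j]]).statistic
            out[i, j] = out[j, i] = r
    return pd.DataFrame(out, index=ids, columns=ids)


def mean_offdiagonal(matrix: "pd.DataFrame") -> float:
    """Mean of the finite off-diagonal entries of a square correlation matrix."""
    values = matrix.to_numpy(dtype=float).copy()
    np.fill_diagonal(values, np.nan)
    return float(np.nanmean(values))
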