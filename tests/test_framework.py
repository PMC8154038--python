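"""Tests for the neuropil activity framework and simulation validation."""

import numpy as np
import pytest

from mgcpn.framework import (
    DEFAULT_COMBINATIONS,
    framework_projection,
    group_by_neuropil,
    group_mean_responses,
    simulate_projection_response,
    validate_simulation,
)
from mgcpn.spikes import MzifrTrace, stimulation_amplitude
from mgcpn.stimuli import FEMALE_PRODUCED, StimulusLabel
from mgcpn.synthetic import NeuronMorphology


def morph(nid, neuropils, cls="Cu-mALT", units=("Cu",), tract="mALT", uni=True):
    return NeuronMorphology(nid, cls, tuple(units), tract, uni, tuple(neuropils))


def traces_for(morphs, rng, stimuli=FEMALE_PRODUCED):
    return {
        (m.neuron_id, s): MzifrTrace(rng.normal(size=240), m.neuron_id, s, 5)
        for m in morphs
        for s in stimuli
    }


class TestGrouping:
    def test_single_member_trace_passthrough(self, rng):
        m = morph("n1", ("Ca", "VLP"))
        tr = traces_for([m], rng)
        amap = group_by_neuropil([m], tr)
        cell = amap[("VLP", StimulusLabel.PM)]
        np.testing.assert_array_equal(cell.mean_trace, tr[("n1", StimulusLabel.PM)].values)
        assert cell.n_members == 1
        assert ("Ca", StimulusLabel.PM) not in amap  # calyces excluded

    def test_two_member_average(self, rng):
        ms = [morph("n1", ("VLP",)), morph("n2", ("VLP",))]
        tr = traces_for(ms, rng)
        amap = group_by_neuropil(ms, tr)
        expected = (tr[("n1", StimulusLabel.PP)].values + tr[("n2", StimulusLabel.PP)].values) / 2
        np.testing.assert_allclose(amap[("VLP", StimulusLabel.PP)].mean_trace, expected)

    def test_brute_force_grouping_oracle(self, default_session, default_traces):
        amap = group_by_neuropil(default_session.morphologies, default_traces)
        for stim in FEMALE_PRODUCED:
            for neuropil in ("VLP", "SLP", "LH", "column"):
                member_traces = [
                    default_traces[(m.neuron_id, stim)].values
                    for m in default_session.morphologies
                    if neuropil in m.output_neuropils
                ]
                expected = np.mean(member_traces, axis=0)
                np.testing.assert_allclose(
                    amap[(neuropil, stim)].mean_trace, expected, atol=1e-10
                )

    def test_membership_conservation(self, default_session, default_traces):
        amap = group_by_neuropil(default_session.morphologies, default_traces)
        total = sum(
            amap[(n, FEMALE_PRODUCED[0])].n_members for n in amap.neuropils()
        )
        assert total >= len(default_session.morphologies)
        for m in default_session.morphologies:
            appearances = sum(
                1 for n in amap.neuropils()
                if m.neuron_id in amap[(n, FEMALE_PRODUCED[0])].member_ids
            )
            assert appearances == len(framework_projection(m))

    def test_empty_group_warns(self, rng):
        ms = [morph("n1", ("VLP",))]
        tr = traces_for(ms, rng)
        with pytest.warns(UserWarning, match="no member neurons"):
            amap = group_by_neuropil(ms, tr)
        assert ("SLP", StimulusLabel.PM) not in amap


class TestSimulation:
    def test_single_neuropil_combo_equals_described_value(self, rng):
        ms = [morph("n1", ("VLP",)), morph("n2", ("VLP",))]
        tr = traces_for(ms, rng)
        amap = group_by_neuropil(ms, tr)
        sim = simulate_projection_response(("VLP",), amap, StimulusLabel.PM)
        assert sim == pytest.approx(amap[("VLP", StimulusLabel.PM)].described_value)

    def test_identical_traces_identical_amplitude(self, rng):
        trace = rng.normal(size=240)
        ms = [morph("n1", ("VLP", "SLP"))]
        tr = {
            (("n1"), s): MzifrTrace(trace, "n1", s, 1) for s in FEMALE_PRODUCED
        }
        amap = group_by_neuropil(ms, tr)
        sim = simulate_projection_response(("VLP", "SLP"), amap, StimulusLabel.PP)
        assert sim == pytest.approx(stimulation_amplitude(trace))

    def test_average_then_amplitude_oracle(self, default_session, default_traces):
        amap = group_by_neuropil(default_session.morphologies, default_traces)
        combo = ("VLP", "SLP", "LH")
        for stim in FEMALE_PRODUCED:
            stacked = np.mean(
                [amap[(n, stim)].mean_trace for n in combo], axis=0
            )
            expected = stacked[100:140].mean() - stacked[:100].mean()
            assert simulate_projection_response(combo, amap, stim) == pytest.approx(expected)

    def test_missing_neuropil_rejected(self, rng):
        ms = [morph("n1", ("VLP",))]
        tr = traces_for(ms, rng)
        with pytest.warns(UserWarning):
            amap = group_by_neuropil(ms, tr)
        with pytest.raises(KeyError):
            simulate_projection_response(("VLP", "LH"), amap, StimulusLabel.PM)


class TestValidation:
    def _toy_population(self, rng):
        """Four neurons per combination, each innervating exactly that set."""
        combos = DEFAULT_COMBINATIONS
        morphs = []
        for c_idx, combo in enumerate(combos):
            for k in range(2):
                neuropils = combo if "LH" not in combo else combo
                cls = "MGC-mALT" if "LH" in combo else "Cu-mALT"
                units = ("Cu", "dma", "dmp") if cls == "MGC-mALT" else ("Cu",)
                morphs.append(
                    morph(f"c{c_idx}n{k}", neuropils, cls=cls, units=units,
                          uni=len(units) == 1)
                )
        return morphs

    def test_self_evaluation_single_neuropil_r2(self, rng):
        """Framework built and evaluated on the same VLP-only neurons is exact."""
        ms = [morph(f"n{i}", ("VLP",)) for i in range(4)]
        tr = traces_for(ms, rng)
        with pytest.warns(UserWarning):
            amap = group_by_neuropil(ms, tr)
        amps = {
            key: stimulation_amplitude(trace.values) for key, trace in tr.items()
        }
        res = validate_simulation(amap, ms, amps, combinations=[("VLP",)])
        np.testing.assert_allclose(
            res.points["simulated"], res.points["recorded"], atol=1e-12
        )
        assert res.r_squared == pytest.approx(1.0)

    def test_recorded_equal_simulated_r2_one(self, rng):
        ms = self._toy_population(rng)
        tr = traces_for(ms, rng)
        amap = group_by_neuropil(ms, tr)
        sim_amp = {
            (m.neuron_id, s): simulate_projection_response(
                framework_projection(m), amap, s
            )
            for m in ms
            for s in FEMALE_PRODUCED
        }
        res = validate_simulation(amap, ms, sim_amp)
        assert res.r_squared == pytest.approx(1.0)

    def test_affine_invariance_of_r2(self, rng):
        ms = self._toy_population(rng)
        tr = traces_for(ms, rng)
        amap = group_by_neuropil(ms, tr)
        affine = {
            (m.neuron_id, s): 2.0 * simulate_projection_response(
                framework_projection(m), amap, s
            ) + 1.0
            for m in ms
            for s in FEMALE_PRODUCED
        }
        res = validate_simulation(amap, ms, affine)
        assert res.r_squared == pytest.approx(1.0)
        assert res.slope == pytest.approx(2.0)

    def test_too_few_points_rejected(self, rng):
        ms = [morph("n1", ("VLP",))]
        tr = traces_for(ms, rng)
        amps = {key: 0.0 for key in tr}
        with pytest.warns(UserWarning):
            amap = group_by_neuropil(ms, tr)
        with pytest.raises(ValueError):
            validate_simulation(amap, ms, amps, combinations=[("VLP",)],
                                stimuli=FEMALE_PRODUCED[:2])


class TestGroupMeans:
    def test_hand_computed_sem(self):
        ms = [morph("n1", ("VLP",)), morph("n2", ("VLP",))]
        amps = {("n1", s): 1.0 for s in FEMALE_PRODUCED}
        amps.update({("n2", s): 3.0 for s in FEMALE_PRODUCED})
        table = group_mean_responses(ms, amps)
        row = table[(table.group == "Cu") & (table.stimulus == "PM")].iloc[0]
        assert row["mean_amplitude"] == pytest.approx(2.0)
        assert row["sem"] == pytest.approx(1.0)

    def test_singleton_group_sem_nan(self):
        ms = [morph("n1", ("VLP",))]
        amps = {("n1", s): 0.5 for s in FEMALE_PRODUCED}
        table = group_mean_responses(ms, amps)
        assert table["sem"].isna().all()
        assert (table.mean_amplitude == 0.5).all()

    def test_empty_groups_omitted_multiglomerular_mapped(self):
        ms = [
            morph("n1", ("VLP",)),
            morph("n2", ("VLP", "LH"), cls="MGC-mALT",
                  units=("Cu", "dma", "dmp"), uni=False),
        ]
        amps = {(m.neuron_id, s): 1.0 for m in ms for s in FEMALE_PRODUCED}
        table = group_mean_responses(ms, amps)
        assert set(table.group) == {"Cu", "MGC"}
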