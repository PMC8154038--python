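"""Classify odor responses of simulated neurons from their firing rates.

Computes per-trial Z-scored instantaneous firing rates (10 ms bins,
standardized against each trial's 1 s pre-stimulus baseline), averages them
into MZIFR traces, derives the response thresholds
T_U/T_L = mean(pre) +/- 1.96 SD(pre), and prints each stimulus's response
label and amplitude for one cumulus neuron.
"""

from mgcpn import simulate_recording_session
from mgcpn.analysis import classification_table

session = simulate_recording_session(trials_per_stimulus=5, seed=2)
table = classification_table(session)

neuron = session.morphologies[0].neuron_id
rows = table[table.neuron_id == neuron]
print(f"responses of {neuron}:")
print(rows[["stimulus", "window_label", "subwindow_label",
            "amp_sw1", "amp_sw2", "onset_latency_ms", "peak_latency_ms"]]
      .to_string(index=False))
# amp_sw1/amp_sw2 are DeltaMZIFR amplitudes (baseline-zeroed Z-scores) over
# the first 100 ms and remaining 300 ms of stimulation; the subwindow label
# is the conservative response call.  For a cumulus neuron, PM and PP should
# classify excitatory and the control should classify none.
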