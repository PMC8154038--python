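"""Simulate a default intracellular-recording session and inspect it.

Generates the 42-neuron reference population (16 cumulus, 4 dma, 4 dmp and
5 multiglomerular medial-tract neurons, 3 mediolateral-tract neurons, 10
lateral-tract neurons), simulates 5 trials of each of 6 odor stimuli per
neuron, and prints the session composition and one neuron's spike counts.
"""

import numpy as np

from mgcpn import generate_population, simulate_recording_session

population = generate_population(seed=1)
print(f"population: {len(population)} neurons")
by_class = {}
for m in population:
    by_class[m.neuron_class] = by_class.get(m.neuron_class, 0) + 1
for cls, n in sorted(by_class.items()):
    print(f"  {cls:10s} n={n}")

session = simulate_recording_session(trials_per_stimulus=5, seed=1)
print(f"\nsession: {len(session.trials)} trials "
      f"({len(population)} neurons x {len(session.stimuli)} stimuli x 5 trials)")

neuron = population[0]
print(f"\nspike counts for {neuron.neuron_id} "
      f"(outputs: {', '.join(neuron.output_neuropils)}):")
for stim in session.stimuli:
    counts = [t.spike_times.size for t in session.trials_for(neuron.neuron_id, stim)]
    print(f"  {stim.value:6s} mean {np.mean(counts):5.1f} spikes/trial {counts}")
# The tuned stimuli (PM, PP for a cumulus neuron) should show clearly more
# spikes than the hexane control, which reflects baseline firing only.
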