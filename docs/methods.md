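# Methods

This note documents the models, conventions, and design choices behind
`mgcpn`, in the spirit of a methods appendix: what each statistic assumes,
what the synthetic generator does and does not emulate, and where the design
was genuinely open.

## Trial clocks and windows

Spike trials are fixed at 2.4 s: bins 1–100 (10 ms each) are pre-stimulus,
bins 101–140 the 400 ms stimulation window, bins 141–240 post-stimulus.
Sub-window SW(i) is bins 101–110 (first 100 ms of stimulation), SW(ii) bins
111–140; the post-response window is the 20 bins after stimulus offset. Bins
are half-open `[t, t+Δ)`; a spike exactly at 2.4 s violates the trial
invariant and is rejected on input.

Calcium recordings are fixed at 100 frames at 10 Hz: baseline frames 5–25
(1-based, i.e. 0.5–2.5 s of the 4 s spontaneous period), stimulation frames
41–60 (4–6 s). The stimulus period is given in seconds upstream; the frame
indices are this package's fixed mapping.

## Z-scoring and thresholds (spikes)

ZIFR is computed per trial, standardized by that trial's own 100
pre-stimulus bins. This makes trials with different baseline rates
comparable before averaging. The SD convention is the population SD
(ddof = 0) everywhere; the multiplier 1.96 is used literally for all trial
counts (no small-sample t correction).

*Silent baselines.* If a trial's pre-stimulus SD is zero, the normalizer
falls back to a session-level pooled SD of pre-stimulus bin rates (and to
1.0 if that is also degenerate), so the trace becomes a mean-centered rate
rather than a division by zero. A fully constant trace therefore maps to all
zeros. The same fallback, with scale 1, applies in the 1 ms-binned onset
latency computation, where it has the intended effect that any stimulation
spike on a silent background is suprathreshold.

*Threshold axis.* The formula's σ is taken across the 100 bins of the mean
trace's pre-stimulus segment (not pooled across trials) — that is what the
notation states; the pooled alternative was considered and rejected as a
different statistic.

*Classification rules.* The per-bin rule (any stimulation bin outside
[T_L, T_U]) is sensitive but has a large familywise false-positive rate
(~40 bins at ~5% each), so on null data it flags most traces; this is
inherent in the rule, not a defect. The sub-window rule compares the *means*
of SW(i)/SW(ii) against the same per-bin thresholds and is strongly
conservative (the mean of 10–30 bins has a much smaller SD than a single
bin). The `subwindow_label` is therefore the response call used for
parameter-recovery statements. When both an upward and a downward crossing
occur in the per-bin scan, the temporally first crossing decides the label.

## Calcium threshold

The control threshold takes, per frame, the mean + 1.96 SD across
individuals of the trial-averaged control ΔF traces, then the maximum over
frames. Taking the maximum makes the nominal 5% level conservative for
response detection (detection compares a 20-frame stimulation peak against a
100-frame maximum). The alternative axis — mean/SD across all frames of the
pooled control traces — is available via `axis="frames"`. The "mean peak" in
detection is restricted to the stimulation window. Trial averaging (2 trials
per stimulus) precedes all statistics.

## Consistency statistics

Response vectors are built from raw ratio traces (stimulation-window mean
minus pre-stimulation mean, averaged over trials); building them from
baseline-zeroed traces gives identical values up to a shared constant.
Pairwise Pearson correlations within a unit are averaged and t-tested
against zero. Two caveats are deliberate: pairwise correlations sharing an
individual are not independent, so the t-test is anticonservative; and no
Fisher z-transform is applied by default (available as an option). Both
follow the field's reporting convention.

## Neuropil framework

The framework maps the lateral-protocerebral output neuropils {VLP, SLP,
SIP, LH, column}; the mushroom-body calyces are excluded because they are
not part of the lateral-protocerebral output map. A neuron contributes to
every framework neuropil it innervates. Described values use the full
400 ms stimulation window. Combination simulation averages traces first and
then takes the amplitude; for the windowed-mean amplitude this commutes with
averaging amplitudes, but trace-first keeps nonlinear amplitude definitions
possible. The recorded comparator in validation is the mean of member
amplitudes (equivalent under linearity). Low- and high-protocol neurons are
pooled.

In the held-out validation experiment (`experiments.split_framework_r2`),
the two-thirds/one-third split is stratified by projection set so every
combination retains at least one held-out neuron; the split is otherwise
uniform.

## Assembly shuffling

Two-thirds recruitment uses `ceil(2/3·n)` per neuropil, sampled without
replacement, independently across the 5 repeats and across neuropils (RNG
substreams keyed by repeat × neuropil). Correlation operands are the
concatenated neuropil × stimulus mean traces over the four female-produced
odorants (controls and plant odors excluded). Singleton neuropil groups are
used whole, with a warning.

## Synthetic generator

The generator exists so that every analysis stage can be exercised against
known ground truth; its defaults are the package's reference study
conditions.

*Spike trains* are inhomogeneous Poisson processes sampled by thinning
(exact for the piecewise kernels used). The rate is the class baseline plus
a stimulus kernel expressed as a gain multiplier on baseline: phasic
(`gain·exp(−t/τ)`, τ = 80 ms), tonic (boxcar over the stimulus window),
phasic-tonic (their sum), delayed (phasic with 150 ms latency), and
inhibitory (−0.8 × baseline boxcar, clamped at zero). The default tuning
table encodes the qualitative response map of the system: cumulus →
PM/PP (projecting SLP/SIP), dma/dmp → BA/SP (projecting LH), multiglomerular
and mediolateral classes broad, lateral-tract column neurons fast PM/PP
only. Hexane control and plant headspace carry no kernel. A per-neuron
lognormal response-strength factor (σ = 0.2) models between-preparation
variability.

*Baseline rates* are 15 Hz for medial/mediolateral-tract classes and 30 Hz
for lateral-tract classes. The literature for this system reports only that
medial-tract neurons are spontaneously much quieter than lateral-tract ones,
so the values are a design choice, fixed once by a null Monte-Carlo: below
roughly 15 Hz the 10 ms bin counts are so discrete that the Gaussian 1.96 σ
threshold no longer holds its nominal two-sided 5% level (the exceedance
fraction inflates to 6–9%), while at 15/30 Hz the pooled level is ~5.3%.
The 2× contrast preserves the quieter-medial observation. Baselines are
configurable per class.

*Calcium traces* are an individual baseline constant (ratio ≈ 1.2) plus a
shared unit × stimulus response shape — linear rise over 3 frames, then
exponential decay with τ = 1 s, the phasic profile that decays over the
stimulation period — scaled by a per-individual lognormal gain (σ = 0.3) and
a per-(individual, unit, stimulus) lognormal amplitude jitter (σ = 0.3),
plus Gaussian frame noise (SD 0.01). Default response amplitudes are
0.01–0.09 ΔF units with the same qualitative unit tuning as the spike table.
8 individuals, 2 trials per stimulus.

*Determinism.* All randomness flows through `numpy` `SeedSequence`
substreams keyed by (stream kind, neuron/individual index, stimulus, trial),
so identical configurations and seeds give byte-identical outputs and adding
neurons to a population never perturbs existing traces.

*What the generator does not emulate:* bursting and refractory structure,
adaptation across trials, correlated noise between simultaneously imaged
glomeruli, photobleaching and movement artifacts, and spike-sorting errors.
Passing tests therefore demonstrate the correctness and calibration of the
statistics under idealized Poisson/Gaussian conditions, not robustness to
every pathology of real recordings.

## Problem sizes in tests and experiments

The calibration experiment uses 2,000 simulated neuron × stimulus traces at
5 trials each; parameter recovery uses 500 neurons; framework validation
uses the default 42-neuron population with 5 trials per stimulus, 5 split
seeds; the calcium experiments use the default 8-individual study. These
sizes give stable Monte-Carlo estimates (binomial SE below half a percentage
point for the calibration fraction) at interactive runtimes.

## Known limitations

- The per-bin response rule is reported but deliberately not used for
  recovery claims (familywise error, above).
- The consistency t-test ignores pair dependence (above).
- The framework treats all neurons within an output neuropil as one
  homogeneous assembly; axonal conduction delays are not modeled, so the
  timing in neuropil mean traces reflects antennal-lobe spiking, not arrival
  at the neuropil.
- High-concentration protocol sessions have single trials by design, so
  their MZIFR equals the single-trial ZIFR and thresholds are accordingly
  noisier.
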