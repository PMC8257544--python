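# Methods

## The scientific question

Enzymatic depletion of the brain's extracellular matrix (ECM) in mature
neuronal cultures removes roughly 60% of inhibitory synapses, leaves
excitatory connectivity largely intact, and at the same time increases
the strength of the surviving inhibitory synapses. MEA recordings of
depleted cultures show elevated firing and bursting. The package
implements the in silico arm of that study: a spiking network in which
inhibitory *connectivity* (sparseness `C_inh`) and inhibitory *synaptic
weight* (`W_inh`) can be moved independently, to determine which change
drives the network outcome.

## Neuron and synapse model

Neurons follow the standard two-variable adaptive quadratic
integrate-and-fire formulation (`dv/dt = 0.04v² + 5v + 140 − u + I`,
`du/dt = a(bv − u)`, reset `v←c, u←u+d` at +30 mV), with the canonical
regular-spiking parameter set (a=0.02, b=0.2, c=−65 mV, d=8) for
excitatory cells and the fast-spiking set (a=0.1, b=0.2, c=−65 mV, d=2)
for interneurons. These two sets reproduce the experimental
classification rule: under a 500 ms step current the model interneuron
fires ≥5 Hz wherever it is suprathreshold and is always faster than the
excitatory cell at matched drive (e.g. 22 vs 8 Hz at amplitude 4). Note
that the *excitatory* cell has the slightly lower rheobase (3.6 vs 3.8
on a 0.2-step grid), so the classification is "interneurons are faster",
not "only interneurons spike".

Synapses are delta pulses: a presynaptic spike increments each target's
membrane potential by the weight (in mV) after a fixed 1 ms conduction
delay. This is the literal reading of weights defined as postsynaptic
membrane-potential changes; there are no conductances, reversal
potentials or short-term plasticity. Control weights are
`W_exc = +3.3 mV` and `W_inh = −6.6 mV`.

Integration uses a 1 ms event cycle with two 0.5 ms sub-steps for the
voltage equation and one recovery update per cycle (the standard stable
scheme for this model). Between sub-steps the voltage is clamped to
[−120, +30] mV. The upper clamp implements the spike cutoff; the lower
clamp is required because the quadratic nonlinearity is only meaningful
near the physiological range and a synchronous barrage of IPSPs would
otherwise produce nonphysical rebound spikes. −120 mV (a chloride
driving-force scale) was chosen because at −100 mV the clamp truncates
most of the control condition's per-cycle inhibition and thereby masks
the connectivity/weight structure under study, while results are
insensitive to any bound below −120.

## Network size and wiring

Sparseness is the fraction of a presynaptic population innervating an
average cell: each neuron receives exactly `round_half_up(C_exc·N_exc)`
excitatory and `round_half_up(C_inh·N_inh)` inhibitory afferents, drawn
uniformly without replacement, excluding self-connections. Wiring is
regenerated from a fresh random substream for every simulation
replicate, mimicking the variability of biological cultures.

The default network has 200 neurons (134 excitatory, 66 inhibitory,
preserving the cultures' ~67/33 mix). The size matters with delta-pulse
synapses at these weights: the total excitatory increment a fully
synchronized cycle delivers is `round(0.25·N_exc)·3.3 mV`, and once
that sum exceeds the ~95 mV reset-to-threshold gap the synchronized
state becomes absorbing — every neuron re-fires every cycle regardless
of adaptation, and the network locks at the refractory ceiling
(~1000 Hz/neuron; observed directly at N ≥ 600). N = 200 is a
deliberate desk-scale choice: the largest round size at which both the
control and the sparsified (`C_inh = 0.06`) networks stay below the
absorbing regime across the swept weight range while inhibition still
gates burst ignition and termination strongly enough to matter.

## Background drive and the near-critical operating point

Spontaneous activity is sustained by independent zero-mean Gaussian
current noise per neuron per millisecond, amplitude `drive_exc` for
excitatory and `drive_inh` for inhibitory cells (ratio 0.4). The
control operating point was calibrated with `calibrate_drive`, which
grid-searches the excitatory amplitude until the control network's
avalanche branching ratio falls in the declared near-critical band
0.7–1.3 and the median electrode bursting rate reaches ≥1 burst/min.
The calibrated defaults are `drive_exc = 4.0`, `drive_inh = 1.6`, which
put the control network at branching ratio ≈ 1.29 with coexisting
isolated spiking and recurrent population bursts. The branching ratio
is measured on 5 ms bins of the pooled spike train as the mean
next-bin/current-bin count ratio within avalanches (maximal runs of
non-empty bins); the band and bin width are declared conventions of
this package's diagnostic, not literature values. A 2 s burn-in is
simulated and discarded before any statistic.

## Virtual MEA and activity statistics

Electrodes observe disjoint random groups of 10–15 neurons (13
electrodes at the 200-neuron default, 59 on networks large enough to
fill a standard 8×8-minus-corners array); unassigned neurons are
unobserved, as on a physical array. Per electrode the package computes

- **MFR** — spikes per second of the pooled electrode train;
- **MBR** — bursts per minute, with bursts detected as maximal runs of
  ≥ `min_spikes` (default 5) spikes whose inter-spike intervals are all
  ≤ `max_isi` (default 100 ms), the standard ISI-threshold convention
  of MEA burst-analysis toolboxes.

Network averages are electrode means. Baseline-relative changes are
expressed per electrode as `100·(post − baseline)/baseline`, falling
back (flagged) to absolute differences when the baseline is zero.

## Experiment protocol

Conditions override `(C_inh, W_inh)` on a shared base configuration.
Every condition runs as 15 independent replicates; each replicate
derives its own seed (from the master seed, the condition parameters
and the replicate index) and regenerates wiring, initial state, noise
and electrode map. Control is `(0.15, −6.6 mV)`; "ECM depleted" is
`C_inh = 0.06` (40% of control, matching the measured ~60% loss of
inhibitory synapses). Replicate comparisons report mean ± s.e.m., the
percent difference of means, the two-tailed independent t-test (the
convention for the approximately normal simulation replicates) and the
Kruskal–Wallis test, with Bonferroni correction available across
condition pairs.

The sweep grid crosses `C_inh ∈ {0.20, 0.15, 0.125, 0.10, 0.06}` (the
named study levels plus one above control) with 9 inhibitory weight
levels spanning 0.75–2× the control magnitude (−4.95 to −13.2 mV).
Zero weight is excluded because the power form is singular there;
magnitudes below ~0.75× control are excluded because they push the
sparsified network into the absorbing saturated regime where rate
measures clip and the weight dependence is uninformative. The
correlation analysis evaluates Pearson r between the `C_inh` level and
the replicate-mean metric at the control weight.

**Model selection.** The dependence of a metric on `|W_inh|` is fitted
by least squares on the original scale as linear (`y = α + βx`) and
power (`y = a·x^b`, initialized from a log-log regression) and the
forms are compared by AICc computed from the residual sum of squares
(both forms have two parameters, so the comparison reduces to fit
quality); ties — including the degenerate both-fit-perfectly case —
go to the linear form. Non-positive metric values are excluded from
the power fit and flagged.

## Synthetic spike-train fixtures

`gen_poisson_train` produces homogeneous Poisson trains;
`gen_bursty_train` plants bursts of known spike count and intra-burst
ISI at chosen times and adds background spikes by rejection sampling so
that no background spike lies within the ISI threshold of a planted
burst or of another background spike. Ground truth is therefore exact:
under matching detector parameters the detected bursts are precisely
the planted intervals, which lets the metric tests act as oracles. The
fixtures emulate the statistics of bursting electrode signals, not
their biophysics: no waveforms, no noise superposition, no rate drift —
so fixture-based tests validate the analysis chain, not the realism of
the simulator.

## Problem sizes and runtime

All shipped analyses run at the 200-neuron default: the sparseness
sweep uses 60 s recordings (15 replicates × 4 levels), and the weight
grids use 30 s recordings (15 replicates × 9 levels × 2–4 sparseness
levels, repeated over 3 master seeds where seed stability is asserted).
These sizes keep the full test suite and the acceptance script in the
tens of minutes on a single CPU while leaving the replicate s.e.m.
small against the reported effects.

## What the model reproduces, and known limitations

Reproduced at the shipped scale, with 15-replicate protocols:

- strong negative, near-linear correlation of both MFR and MBR with
  `C_inh` (r ≈ −0.99 and −1.00 at the default seed);
- significant hyperactivity of the depleted condition at matched
  weights (≈ +31% MFR, +37% MBR, p < 10⁻⁴);
- weight compensation asymmetry: at `C_inh = 0.125` and `0.10` some
  swept weight restores mean MFR to within 10% of control (closest
  deviations < 1%), while at `C_inh = 0.06` no swept weight comes
  closer than ~13%;
- the power-law → linear switch of the *bursting-rate* dependence on
  `|W_inh|` between control and depleted sparseness, stable across
  master seeds.

The *firing-rate* dependence on `|W_inh|` is robustly power-law-like at
control sparseness, but at `C_inh = 0.06` the MFR profile retains a
slight convexity and model selection prefers the power form at this
network scale; the MBR dependence is where the regime switch is
seed-stable. This is the one qualitative aspect of the weight-sweep
analysis the desk-scale model does not reproduce for both metrics.

Other limitations: no conductance-based synapses, receptor kinetics,
short-term plasticity or distance-dependent wiring; single fixed
conduction delay; activity magnitudes (electrode MFR ~50 spikes/s, MBR
~150 bursts/min) are higher than typical biological cultures because
the small dense network bursts fast — directions and shapes of effects,
not absolute rates, are the quantities of interest; and the absorbing
synchronization analysis above means conclusions should not be
extrapolated to much larger networks without rescaling weights.
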