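"""Simulate the control network and read it out on the virtual MEA.

Builds the default control configuration (200 neurons, 67% excitatory,
C_inh = 0.15, W_inh = -6.6 mV, calibrated background drive), simulates
20 s of spontaneous activity, and prints the virtual-MEA statistics:
per-electrode mean firing rate (MFR) and mean bursting rate (MBR), plus
the avalanche branching ratio that diagnoses how close the network sits
to the spiking-bursting transition (~1 = near-critical).
"""

from ei_netsim import NetworkConfig, run_simulation, assign_electrodes
from ei_netsim.dynamics import substream
from ei_netsim.mea import avalanche_statistics, electrode_metrics

config = NetworkConfig(duration=20.0, seed=1)
spikes = run_simulation(config)
emap = assign_electrodes(spikes, n_electrodes=13, rng=substream(config.seed, 4))
table = electrode_metrics(spikes, emap)
av = avalanche_statistics(spikes)

print(f"{spikes.n_spikes} spikes from {spikes.n_neurons} neurons "
      f"over {config.duration:.0f} s")
print(table.to_string(index=False))
print(f"\nnetwork average MFR : {table['mfr_hz'].mean():6.2f} spikes/s")
print(f"network average MBR : {table['mbr_per_min'].mean():6.2f} bursts/min")
print(f"branching ratio     : {av.branching_ratio:6.3f}  (~1 => near-critical)")
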