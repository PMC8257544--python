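# YAML configuration schema

`ei-netsim simulate --config run.yaml` and `load_config()` accept a YAML
mapping with exactly the `NetworkConfig` field names. All fields are
optional; omitted fields take the control-condition defaults shown.

```yaml
n_exc: 134        # excitatory neurons
n_inh: 66         # inhibitory neurons (~33% of the network)
c_exc: 0.25       # excitatory sparseness, fraction in (0, 1)
c_inh: 0.15       # inhibitory sparseness ("ECM depleted": 0.06)
w_exc: 3.3        # excitatory synaptic weight, mV (>= 0)
w_inh: -6.6       # inhibitory synaptic weight, mV (<= 0)
drive_exc: 4.0    # background Gaussian current s.d., excitatory cells
drive_inh: 1.6    # background Gaussian current s.d., inhibitory cells
dt: 0.5           # voltage integration sub-step, ms
duration: 60.0    # recorded simulation time, s
burn_in: 2.0      # discarded initial transient, s
delay: 1.0        # synaptic conduction delay, ms
seed: 0           # master seed; all substreams derive from it
exc_params:       # optional neuron-model override
  label: excitatory
  a: 0.02
  b: 0.2
  c: -65.0
  d: 8.0
  spike_cutoff: 30.0
inh_params:
  label: inhibitory
  a: 0.1
  b: 0.2
  c: -65.0
  d: 2.0
  spike_cutoff: 30.0
```

Validation (`validate_config`) enforces sparseness in (0, 1), weight
signs, positive durations and the feasibility of the implied in-degrees
(`round(C·N)` must not exceed the presynaptic pool minus the cell
itself).
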