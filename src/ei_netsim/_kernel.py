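"""Numba time-stepping kernel for the pulse-coupled spiking network.

One millisecond is one event cycle: spikes registered at the top of the
cycle are reset and their postsynaptic voltage increments scheduled one
conduction delay ahead; pending increments due this cycle are applied;
then the membrane equation is advanced with ``n_sub`` sub-steps and the
recovery variable once.  Voltage is clamped to [V_FLOOR, spike_cutoff]
between sub-steps so that synchronous synaptic barrages cannot drive the
quadratic term to overflow or generate rebound artifacts.
"""

import numpy as np
from numba import njit

V_FLOOR = -120.0  # mV; hyperpolarization bound (chloride driving-force scale)

OVERFLOW = -1  # kernel return code: spike buffer capacity exceeded


@njit(cache=True)
def simulate_kernel(
    n_ms,
    delay_ms,
    n_sub,
    a,
    b,
    c,
    d,
    vpeak,
    sigma,
    i_const,
    indptr,
    targets,
    weights,
    v,
    u,
    noise_seed,
    spike_ids,
    spike_t_ms,
):
    """Advance the network ``n_ms`` milliseconds; record spikes in-place.

    Returns the number of spikes recorded, or OVERFLOW if the provided
    spike buffers were too small (the caller retries with larger ones).
    """
    np.random.seed(noise_seed)
    n = v.size
    nslots = delay_ms + 1
    buf = np.zeros((nslots, n))
    dtv = 1.0 / n_sub
    cap = spike_ids.size
    count = 0
    for t in range(n_ms):
        slot = t % nslots
        dslot = (t + delay_ms) % nslots
        # register threshold crossings from the previous cycle
        for i in range(n):
            if v[i] >= vpeak[i]:
                if count >= cap:
                    return OVERFLOW
                spike_ids[count] = i
                spike_t_ms[count] = t
                count += 1
                v[i] = c[i]
                u[i] += d[i]
                for e in range(indptr[i], indptr[i + 1]):
                    buf[dslot, targets[e]] += weights[e]
        # deliver voltage increments due this cycle, then integrate
        for i in range(n):
            vi = v[i] + buf[slot, i]
            buf[slot, i] = 0.0
            if vi < V_FLOOR:
                vi = V_FLOOR
            if vi >= vpeak[i]:
                vi = vpeak[i]
                v[i] = vi
                continue
            ui = u[i]
            curr = i_const[i]
            if sigma[i] > 0.0:
                curr += sigma[i] * np.random.standard_normal()
            for _ in range(n_sub):
                vi += dtv * (0.04 * vi * vi + 5.0 * vi + 140.0 - ui + curr)
                if vi >= vpeak[i]:
                    vi = vpeak[i]
                    break
                if vi < V_FLOOR:
                    vi = V_FLOOR
            u[i] = ui + a[i] * (b[i] * vi - ui)
            v[i] = vi
    return count
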