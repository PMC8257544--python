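"""Network model: neuron parameters, simulation configuration and random wiring.

The network consists of two populations, excitatory principal cells and
fast-spiking inhibitory interneurons, mixed roughly 2:1 as in mature
dissociated cortical cultures.  Connectivity is defined by *sparseness*:
the fraction of a presynaptic population that provides input to a single
cell.  Every postsynaptic neuron receives exactly ``round(C_exc * N_exc)``
excitatory and ``round(C_inh * N_inh)`` inhibitory afferents, drawn
uniformly at random without replacement (no self-connections, no duplicate
edges).  Each simulation instance regenerates the wiring from a fresh
random substream, mimicking the instance-to-instance variability of real
cultured networks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict

import numpy as np

__all__ = [
    "NeuronParams",
    "NetworkConfig",
    "Connectivity",
    "ConfigurationError",
    "EXCITATORY_PARAMS",
    "INHIBITORY_PARAMS",
    "round_half_up",
    "in_degrees",
    "build_connectivity",
    "validate_config",
]


class ConfigurationError(ValueError):
    """Raised for configurations whose invariants cannot be satisfied."""


@dataclass(frozen=True)
class NeuronParams:
    """Two-variable adaptive quadratic integrate-and-fire neuron parameters.

    The model follows the canonical ``dv/dt = 0.04 v^2 + 5 v + 140 - u + I``,
    ``du/dt = a (b v - u)`` formulation with an after-spike reset
    ``v <- c, u <- u + d`` once ``v`` reaches ``spike_cutoff``.

    Parameters
    ----------
    label:
        Population tag, ``"excitatory"`` or ``"inhibitory"``.
    a:
        Recovery timescale (1/ms); larger ``a`` gives faster recovery.
    b:
        Recovery sensitivity to subthreshold voltage (dimensionless).
    c:
        After-spike reset potential (mV).
    d:
        After-spike recovery increment (mV-equivalent).
    spike_cutoff:
        Voltage (mV) at which a spike is registered and the reset applied.
    """

    label: str
    a: float
    b: float
    c: float
    d: float
    spike_cutoff: float = 30.0

    def __post_init__(self) -> None:
        if self.label not in ("excitatory", "inhibitory"):
            raise ConfigurationError(f"unknown population label {self.label!r}")
        if self.a <= 0 or self.d <= 0:
            raise ConfigurationError("NeuronParams.a and .d must be > 0")
        if self.spike_cutoff <= self.c:
            raise ConfigurationError("spike_cutoff must exceed reset potential c")


#: Regular-spiking phenotype used for the excitatory population.
EXCITATORY_PARAMS = NeuronParams("excitatory", a=0.02, b=0.2, c=-65.0, d=8.0)
#: Fast-spiking phenotype used for the inhibitory population (>= 5 Hz under
#: a standard 500 ms suprathreshold current step; see ``dynamics``).
INHIBITORY_PARAMS = NeuronParams("inhibitory", a=0.1, b=0.2, c=-65.0, d=2.0)


@dataclass(frozen=True)
class NetworkConfig:
    """Complete parameterization of one simulated network experiment.

    Defaults encode the control condition: a 200-neuron desk-scale culture
    with ~33% inhibitory interneurons, excitatory sparseness
    ``C_exc = 0.25`` and inhibitory sparseness ``C_inh = 0.15``, synaptic
    weights +3.3 mV (excitatory) and -6.6 mV (inhibitory) expressed as the
    postsynaptic membrane-potential change caused by one presynaptic
    spike.  With delta-pulse synapses of this strength the network size
    bounds the recurrent barrage a population burst can deliver per
    cycle; 200 neurons keeps both the control and the sparsified
    (C_inh = 0.06) networks below the runaway-synchrony regime while
    preserving spiking-bursting transitions (see the drive calibration in
    ``experiments``).  The background drive defaults are the calibrated
    control values.
    """

    n_exc: int = 134
    n_inh: int = 66
    c_exc: float = 0.25
    c_inh: float = 0.15
    w_exc: float = 3.3
    w_inh: float = -6.6
    drive_exc: float = 4.0
    drive_inh: float = 1.6
    dt: float = 0.5
    duration: float = 60.0
    burn_in: float = 2.0
    delay: float = 1.0
    seed: int = 0
    exc_params: NeuronParams = field(default=EXCITATORY_PARAMS)
    inh_params: NeuronParams = field(default=INHIBITORY_PARAMS)

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    @property
    def k_exc(self) -> int:
        """Excitatory in-degree of every neuron."""
        return round_half_up(self.c_exc * self.n_exc)

    @property
    def k_inh(self) -> int:
        """Inhibitory in-degree of every neuron."""
        return round_half_up(self.c_inh * self.n_inh)

    def with_overrides(self, **kwargs) -> "NetworkConfig":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exc_params"] = asdict(self.exc_params)
        d["inh_params"] = asdict(self.inh_params)
        return d


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 rounded up (0.06*330=19.8 -> 20)."""
    return int(math.floor(x + 0.5))


def in_degrees(config: NetworkConfig) -> tuple[int, int]:
    """(excitatory, inhibitory) in-degree implied by the sparseness values."""
    return config.k_exc, config.k_inh


def validate_config(config: NetworkConfig) -> list[str]:
    """Check all NetworkConfig invariants; return human-readable violations.

    An empty list means the configuration is valid.  This never raises: it
    is a reporting operation used by the CLI and by ``build_connectivity``.
    """
    v: list[str] = []
    if config.n_exc < 1 or config.n_inh < 1:
        v.append("n_exc and n_inh must be >= 1")
    if not (0.0 < config.c_exc < 1.0):
        v.append(f"c_exc={config.c_exc}: sparseness must be in (0,1)")
    if not (0.0 < config.c_inh < 1.0):
        v.append(f"c_inh={config.c_inh}: sparseness must be in (0,1)")
    # zero is allowed on either side: it represents fully silenced synapses
    # (e.g. a complete GABA-receptor blockade sets the inhibitory weight to 0)
    if config.w_exc < 0:
        v.append(f"w_exc={config.w_exc}: W_exc must be > 0")
    if config.w_inh > 0:
        v.append(f"w_inh={config.w_inh}: W_inh must be < 0")
    if config.drive_exc < 0 or config.drive_inh < 0:
        v.append("drive amplitudes must be >= 0")
    if config.dt <= 0:
        v.append(f"dt={config.dt}: integration step must be > 0")
    if config.duration <= 0:
        v.append(f"duration={config.duration}: must be > 0")
    if config.burn_in < 0:
        v.append("burn_in must be >= 0")
    if config.delay < 0:
        v.append("delay must be >= 0")
    # in-degree feasibility: a neuron cannot receive more afferents than the
    # presynaptic pool holds after excluding itself
    if config.n_exc >= 1 and 0 < config.c_exc < 1:
        if config.k_exc > config.n_exc - 1:
            v.append(
                f"c_exc={config.c_exc} implies in-degree {config.k_exc} > "
                f"available excitatory pool {config.n_exc - 1}"
            )
    if config.n_inh >= 1 and 0 < config.c_inh < 1:
        if config.k_inh > config.n_inh - 1:
            v.append(
                f"c_inh={config.c_inh} implies in-degree {config.k_inh} > "
                f"available inhibitory pool {config.n_inh - 1}"
            )
    if config.exc_params.label != "excitatory":
        v.append("exc_params must be labelled 'excitatory'")
    if config.inh_params.label != "inhibitory":
        v.append("inh_params must be labelled 'inhibitory'")
    return v


@dataclass
class Connectivity:
    """Realized wiring of one network instance.

    Neurons are numbered 0..N-1 with excitatory ids first
    (``0..n_exc-1``), inhibitory ids after (``n_exc..n_exc+n_inh-1``).
    ``in_exc[j]`` / ``in_inh[j]`` hold the presynaptic ids of neuron j's
    excitatory / inhibitory afferents; every excitatory edge carries weight
    ``w_exc`` (mV), every inhibitory edge ``w_inh`` (mV), with a single
    fixed conduction delay.
    """

    n_exc: int
    n_inh: int
    in_exc: np.ndarray  # (N, k_exc) int32 presynaptic ids
    in_inh: np.ndarray  # (N, k_inh) int32 presynaptic ids
    w_exc: float
    w_inh: float
    delay_ms: float

    @property
    def n_total(self) -> int:
        return self.n_exc + self.n_inh

    def population(self, neuron_id: int) -> str:
        return "excitatory" if neuron_id < self.n_exc else "inhibitory"

    def afferents(self, post: int) -> list[tuple[int, float, float]]:
        """(pre, weight_mV, delay_ms) triples for one postsynaptic neuron."""
        out = [(int(p), self.w_exc, self.delay_ms) for p in self.in_exc[post]]
        out += [(int(p), self.w_inh, self.delay_ms) for p in self.in_inh[post]]
        return out

    @property
    def adjacency(self) -> dict[int, list[tuple[int, float, float]]]:
        return {j: self.afferents(j) for j in range(self.n_total)}

    def out_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Outgoing-edge CSR view (indptr, targets, weights) keyed by presynaptic id.

        This is the layout the simulation kernel consumes: when neuron i
        fires, ``targets[indptr[i]:indptr[i+1]]`` receive the corresponding
        weights after the conduction delay.
        """
        n = self.n_total
        pre = np.concatenate([self.in_exc.ravel(), self.in_inh.ravel()])
        post_exc = np.repeat(np.arange(n, dtype=np.int32), self.in_exc.shape[1])
        post_inh = np.repeat(np.arange(n, dtype=np.int32), self.in_inh.shape[1])
        post = np.concatenate([post_exc, post_inh])
        w = np.concatenate(
            [
                np.full(self.in_exc.size, self.w_exc),
                np.full(self.in_inh.size, self.w_inh),
            ]
        )
        order = np.argsort(pre, kind="stable")
        pre_s, post_s, w_s = pre[order], post[order], w[order]
        indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(indptr, pre_s + 1, 1)
        np.cumsum(indptr, out=indptr)
        return indptr, post_s.astype(np.int32), w_s.astype(np.float64)

    def to_edge_frame(self):
        """Edge list as a DataFrame with columns pre,post,weight_mV,delay_ms."""
        import pandas as pd

        indptr, targets, weights = self.out_csr()
        n_out = np.diff(indptr)
        return pd.DataFrame(
            {
                "pre": np.repeat(np.arange(self.n_total), n_out),
                "post": targets,
                "weight_mV": weights,
                "delay_ms": self.delay_ms,
            }
        )


def build_connectivity(config: NetworkConfig, rng: np.random.Generator) -> Connectivity:
    """Draw one random network instance satisfying the sparseness rules.

    Every postsynaptic neuron receives exactly ``k_exc`` excitatory and
    ``k_inh`` inhibitory afferents sampled uniformly without replacement
    from the respective population, excluding the neuron itself.  The same
    generator state reproduces the same wiring bit-for-bit.
    """
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))

    n_exc, n_inh = config.n_exc, config.n_inh
    n = n_exc + n_inh
    k_exc, k_inh = config.k_exc, config.k_inh

    in_exc = np.empty((n, k_exc), dtype=np.int32)
    in_inh = np.empty((n, k_inh), dtype=np.int32)
    exc_pool = np.arange(n_exc, dtype=np.int32)
    inh_pool = np.arange(n_exc, n, dtype=np.int32)
    for j in range(n):
        ep = exc_pool[exc_pool != j]
        ip = inh_pool[inh_pool != j]
        in_exc[j] = rng.choice(ep, size=k_exc, replace=False)
        in_inh[j] = rng.choice(ip, size=k_inh, replace=False)

    return Connectivity(
        n_exc=n_exc,
        n_inh=n_inh,
        in_exc=in_exc,
        in_inh=in_inh,
        w_exc=config.w_exc,
        w_inh=config.w_inh,
        delay_ms=config.delay,
    )
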