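"""File formats: spike-train CSV, YAML configs, run manifests.

Spike trains travel as plain CSV (``neuron_id,spike_time_s``, time-sorted
within neuron, 6 decimal places) with a JSON sidecar holding duration,
population ranges, seed and the full configuration, so externally
recorded trains can be analyzed with the same metrics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import yaml

from .dynamics import SpikeTrainSet
from .network import (
    EXCITATORY_PARAMS,
    INHIBITORY_PARAMS,
    NetworkConfig,
    NeuronParams,
)

__all__ = [
    "write_spike_csv",
    "read_spike_csv",
    "load_config",
    "save_config",
    "RunManifest",
]

_TIME_FMT = "%.6f"  # µs precision: lossless for 0.5 ms integration grid


def write_spike_csv(spike_set: SpikeTrainSet, path) -> None:
    """Write spikes as ``neuron_id,spike_time_s`` plus a JSON sidecar."""
    path = Path(path)
    with open(path, "w") as f:
        f.write("neuron_id,spike_time_s\n")
        for nid in sorted(spike_set.trains):
            for t in spike_set.trains[nid]:
                f.write(f"{nid},{_TIME_FMT % t}\n")
    sidecar = {
        "duration": spike_set.duration,
        "n_exc": spike_set.n_exc,
        "n_inh": spike_set.n_inh,
        "provenance": spike_set.provenance,
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as f:
        json.dump(sidecar, f, indent=1, default=str)


def read_spike_csv(path, duration: float | None = None) -> SpikeTrainSet:
    """Read a spike-train CSV (and its sidecar, if present).

    ``duration`` overrides the sidecar; one of the two must be available.
    Malformed rows raise with their line number; out-of-order times within
    a neuron are sorted with a warning-free pass (external recordings are
    not always time-sorted).
    """
    path = Path(path)
    ids: list[int] = []
    times: list[float] = []
    with open(path) as f:
        header = f.readline().strip()
        if header.replace(" ", "") != "neuron_id,spike_time_s":
            raise ValueError(f"{path}:1: expected header 'neuron_id,spike_time_s'")
        for lineno, line in enumerate(f, start=2):
            line = line.strip()
            if not line:
                continue
            parts = line.split(",")
            try:
                nid = int(parts[0])
                t = float(parts[1])
            except (IndexError, ValueError) as exc:
                raise ValueError(f"{path}:{lineno}: malformed row {line!r}") from exc
            if t < 0:
                raise ValueError(f"{path}:{lineno}: negative spike time {t}")
            ids.append(nid)
            times.append(t)

    sidecar_path = path.with_suffix(path.suffix + ".json")
    meta = {}
    if sidecar_path.exists():
        meta = json.loads(sidecar_path.read_text())
    if duration is None:
        duration = meta.get("duration")
    if duration is None:
        raise ValueError("duration not given and no sidecar found")

    ids_a = np.asarray(ids, dtype=np.int64)
    t_a = np.asarray(times, dtype=float)
    trains: dict[int, np.ndarray] = {}
    for nid in np.unique(ids_a):
        trains[int(nid)] = np.sort(t_a[ids_a == nid])
    n_total = (int(ids_a.max()) + 1) if len(ids_a) else 0
    n_exc = meta.get("n_exc", n_total)
    n_inh = meta.get("n_inh", 0)
    if n_exc + n_inh < n_total:
        n_exc, n_inh = n_total, 0
    return SpikeTrainSet(
        trains=trains,
        duration=float(duration),
        n_exc=int(n_exc),
        n_inh=int(n_inh),
        provenance=meta.get("provenance", {"source": str(path)}),
    )


def _params_from_dict(d: dict) -> NeuronParams:
    return NeuronParams(**d)


def load_config(path) -> NetworkConfig:
    """Load a NetworkConfig from YAML with exactly the field names."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key in ("exc_params", "inh_params"):
        if key in raw and isinstance(raw[key], dict):
            raw[key] = _params_from_dict(raw[key])
    raw.setdefault("exc_params", EXCITATORY_PARAMS)
    raw.setdefault("inh_params", INHIBITORY_PARAMS)
    known = {f.name for f in dataclasses.fields(NetworkConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config fields: {sorted(unknown)}")
    return NetworkConfig(**raw)


def save_config(config: NetworkConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def _file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Inventory of one run: config snapshot, seeds, output hashes.

    Sufficient to replay the run bit-identically: the config (incl. the
    master seed) determines every substream, and the hashes verify the
    replay.
    """

    def __init__(self, config: NetworkConfig, version: str):
        self.config = config
        self.version = version
        self.outputs: dict[str, str] = {}

    def add_output(self, path) -> None:
        self.outputs[str(Path(path).name)] = _file_sha256(path)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.config.seed,
            "config": self.config.to_dict(),
            "outputs": self.outputs,
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, default=str))

    @staticmethod
    def load(path) -> dict:
        return json.loads(Path(path).read_text())
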