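"""Synthetic spike-train fixtures with exact, known ground truth.

Generates homogeneous Poisson trains and trains with embedded bursts
whose boundaries are known by construction, emulating the signals a
bursting MEA electrode records.  Background spikes in bursty trains are
rejection-sampled so they can neither extend a planted burst nor form a
qualifying run of their own — the ground truth is therefore exact and
the burst detector can be tested as an oracle, not approximately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mea import DEFAULT_MAX_ISI_MS, DEFAULT_MIN_SPIKES

__all__ = ["BurstySpec", "SpecificationError", "gen_poisson_train", "gen_bursty_train"]


class SpecificationError(ValueError):
    """Raised when a BurstySpec cannot be realized."""


def gen_poisson_train(
    rate_hz: float, duration: float, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """Homogeneous Poisson spike train on [0, duration) seconds."""
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = rng.poisson(rate_hz * duration)
    return np.sort(rng.uniform(0.0, duration, size=n))


@dataclass(frozen=True)
class BurstySpec:
    """Plan for a spike train with embedded ground-truth bursts.

    Each burst is a run of ``spikes_per_burst`` spikes at a regular
    ``intra_isi_ms`` spacing, placed with its first spike at each entry of
    ``burst_times``.  ``max_isi_ms``/``min_spikes`` are the detection
    parameters the ground truth is exact for: the intra-burst ISI must lie
    strictly below the threshold and bursts must be separated (and clear
    of the recording edges) by more than the threshold.
    """

    burst_times: tuple[float, ...]
    spikes_per_burst: int = 10
    intra_isi_ms: float = 20.0
    background_rate_hz: float = 0.0
    duration: float = 60.0
    seed: int = 0
    max_isi_ms: float = DEFAULT_MAX_ISI_MS
    min_spikes: int = DEFAULT_MIN_SPIKES

    @property
    def burst_width_s(self) -> float:
        return (self.spikes_per_burst - 1) * self.intra_isi_ms / 1000.0

    def intervals(self) -> list[tuple[float, float]]:
        """Ground-truth (start, end) of each planted burst, in seconds."""
        return [(t, t + self.burst_width_s) for t in sorted(self.burst_times)]

    def validate(self) -> None:
        if self.spikes_per_burst < self.min_spikes:
            raise SpecificationError("spikes_per_burst must be >= min_spikes")
        if not (0 < self.intra_isi_ms < self.max_isi_ms):
            raise SpecificationError("intra_isi_ms must be in (0, max_isi_ms)")
        if self.background_rate_hz < 0:
            raise SpecificationError("background rate must be >= 0")
        gap = self.max_isi_ms / 1000.0
        iv = self.intervals()
        for s, e in iv:
            if s < 0 or e > self.duration:
                raise SpecificationError("burst outside recording window")
        for (_, e0), (s1, _) in zip(iv, iv[1:]):
            if s1 - e0 <= gap:
                raise SpecificationError(
                    "bursts must be separated by more than max_isi_ms"
                )


def gen_bursty_train(spec: BurstySpec) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Realize a BurstySpec; return (spike times, ground-truth intervals).

    Background spikes are drawn as a Poisson process thinned by rejection:
    a candidate is kept only if it lies more than ``max_isi_ms`` away from
    every planted burst and every other kept background spike.  Under
    matching detector parameters the detected bursts are then exactly the
    planted intervals.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    isi_s = spec.intra_isi_ms / 1000.0
    parts = [
        t0 + isi_s * np.arange(spec.spikes_per_burst)
        for t0 in sorted(spec.burst_times)
    ]
    intervals = spec.intervals()

    gap = spec.max_isi_ms / 1000.0
    n_bg = rng.poisson(spec.background_rate_hz * spec.duration)
    accepted: list[float] = []
    attempts = 0
    max_attempts = 1000 * max(1, n_bg)
    while len(accepted) < n_bg:
        if attempts > max_attempts:
            raise SpecificationError(
                "cannot place background spikes without violating burst "
                "separation; lower background_rate_hz or duration density"
            )
        attempts += 1
        t = rng.uniform(0.0, spec.duration)
        if any(s - gap <= t <= e + gap for s, e in intervals):
            continue
        if any(abs(t - b) <= gap for b in accepted):
            continue
        accepted.append(t)

    train = np.sort(np.concatenate(parts + [np.asarray(accepted)])) if parts or accepted else np.empty(0)
    return train, intervals
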