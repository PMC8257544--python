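"""Virtual multi-electrode array (MEA) and spike-train activity statistics.

A physical MEA electrode picks up the population spikes of a small group
of neurons (10-15 in mature dissociated cultures) near its site.  The
virtual array emulates this by assigning disjoint random groups of
neurons to electrodes; unassigned neurons are simply unobserved.  Per
electrode the module computes the two standard culture-activity
statistics: mean firing rate (MFR, spikes/s) and mean bursting rate
(MBR, bursts/min), with bursts detected as runs of >= ``min_spikes``
spikes whose inter-spike intervals all stay below an ISI threshold —
the convention of MEA burst-analysis toolboxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dynamics import SpikeTrainSet

__all__ = [
    "ElectrodeMap",
    "Burst",
    "BurstList",
    "assign_electrodes",
    "electrode_train",
    "mean_firing_rate",
    "detect_bursts",
    "mean_bursting_rate",
    "percent_change",
    "avalanche_statistics",
    "electrode_metrics",
    "DEFAULT_MAX_ISI_MS",
    "DEFAULT_MIN_SPIKES",
]

#: ISI-threshold burst detection defaults (standard MEA convention).
DEFAULT_MAX_ISI_MS = 100.0
DEFAULT_MIN_SPIKES = 5

#: 8x8 grid minus corners, one reference electrode: 59 active sites.
DEFAULT_N_ELECTRODES = 59
DEFAULT_GROUP_MIN = 10
DEFAULT_GROUP_MAX = 15


@dataclass
class ElectrodeMap:
    """Disjoint neuron groups observed by each electrode."""

    members: dict[int, np.ndarray]
    layout: str = "8x8 minus corners"

    @property
    def n_electrodes(self) -> int:
        return len(self.members)

    def validate(self, n_neurons: int | None = None) -> None:
        seen: set[int] = set()
        for eid, m in self.members.items():
            ms = set(int(x) for x in m)
            if seen & ms:
                raise ValueError(f"electrode {eid}: members overlap another electrode")
            seen |= ms
        if n_neurons is not None and seen and max(seen) >= n_neurons:
            raise ValueError("electrode member id outside network")


@dataclass(frozen=True)
class Burst:
    start: float  # s
    end: float  # s
    n_spikes: int


@dataclass
class BurstList:
    """Detected bursts for one electrode train, with the detector settings."""

    bursts: list[Burst]
    max_isi_ms: float
    min_spikes: int

    def __len__(self) -> int:
        return len(self.bursts)

    def intervals(self) -> list[tuple[float, float]]:
        return [(b.start, b.end) for b in self.bursts]


def assign_electrodes(
    spike_set: SpikeTrainSet | int,
    n_electrodes: int = DEFAULT_N_ELECTRODES,
    group_min: int = DEFAULT_GROUP_MIN,
    group_max: int = DEFAULT_GROUP_MAX,
    rng: np.random.Generator | None = None,
) -> ElectrodeMap:
    """Randomly group neurons into disjoint electrode populations.

    Group sizes are uniform on [group_min, group_max].  Neurons not drawn
    by any electrode are unobserved, as on a real array where most of the
    culture lies between electrode sites.

    ``spike_set`` may be a SpikeTrainSet or a plain neuron count.
    """
    n_neurons = spike_set if isinstance(spike_set, int) else spike_set.n_neurons
    if not (1 <= group_min <= group_max):
        raise ValueError("need 1 <= group_min <= group_max")
    if n_electrodes * group_max > n_neurons:
        raise ValueError(
            f"{n_electrodes} electrodes x up to {group_max} neurons exceeds "
            f"the {n_neurons}-neuron network"
        )
    rng = np.random.default_rng() if rng is None else rng
    sizes = rng.integers(group_min, group_max + 1, size=n_electrodes)
    pool = rng.permutation(n_neurons)
    members: dict[int, np.ndarray] = {}
    offset = 0
    for eid in range(n_electrodes):
        members[eid] = np.sort(pool[offset : offset + sizes[eid]]).astype(np.int64)
        offset += sizes[eid]
    return ElectrodeMap(members=members)


def electrode_train(spike_set: SpikeTrainSet, members) -> np.ndarray:
    """Pool member neurons' spikes into one sorted electrode signal.

    Multiset union: coincident spikes from different members are all kept,
    as they would superimpose in the electrode's population signal.
    """
    members = list(members)
    if not members:
        raise ValueError("electrode has no member neurons")
    for m in members:
        if int(m) not in spike_set.trains and not (0 <= int(m) < spike_set.n_neurons):
            raise KeyError(f"unknown neuron id {m}")
    parts = [spike_set.train(int(m)) for m in members]
    merged = np.concatenate(parts) if parts else np.empty(0)
    return np.sort(merged, kind="stable")


def mean_firing_rate(train: np.ndarray, duration: float) -> float:
    """Spikes per second over the recording."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    return len(train) / duration


def detect_bursts(
    train: np.ndarray,
    max_isi_ms: float = DEFAULT_MAX_ISI_MS,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> BurstList:
    """ISI-threshold burst detection (greedy maximal runs).

    A burst is a maximal run of consecutive spikes in which every
    inter-spike interval is <= ``max_isi_ms``, containing at least
    ``min_spikes`` spikes.  Input times are in seconds and must be sorted.
    """
    train = np.asarray(train, dtype=float)
    if np.any(np.diff(train) < 0):
        raise ValueError("spike train must be sorted")
    bursts: list[Burst] = []
    n = len(train)
    if n == 0:
        return BurstList(bursts, max_isi_ms, min_spikes)
    max_isi_s = max_isi_ms / 1000.0
    run_start = 0
    for i in range(1, n + 1):
        if i == n or train[i] - train[i - 1] > max_isi_s:
            run_len = i - run_start
            if run_len >= min_spikes:
                bursts.append(Burst(train[run_start], train[i - 1], run_len))
            run_start = i
    return BurstList(bursts, max_isi_ms, min_spikes)


def mean_bursting_rate(bursts: BurstList | int, duration: float) -> float:
    """Bursts per minute over the recording."""
    if duration <= 0:
        raise ValueError("duration must be > 0")
    n = len(bursts) if isinstance(bursts, BurstList) else int(bursts)
    return n / duration * 60.0


def percent_change(baseline: float, post: float) -> tuple[float, bool]:
    """Change relative to the same electrode's baseline, in percent.

    Returns ``(value, is_percent)``.  When the baseline is zero the
    percent form is undefined; the absolute difference is returned with
    ``is_percent=False`` instead of dividing by zero.
    """
    if baseline == 0:
        return post - baseline, False
    return 100.0 * (post - baseline) / baseline, True


@dataclass
class AvalancheStatistics:
    sizes: np.ndarray  # spike count per avalanche
    branching_ratio: float  # nan when undefined
    bin_ms: float
    n_bins: int

    @property
    def size_histogram(self) -> tuple[np.ndarray, np.ndarray]:
        if len(self.sizes) == 0:
            return np.empty(0, dtype=int), np.empty(0, dtype=int)
        return np.unique(self.sizes, return_counts=True)


def avalanche_statistics(
    spike_set: SpikeTrainSet, bin_ms: float = 5.0
) -> AvalancheStatistics:
    """Avalanche sizes and branching ratio of pooled network activity.

    Network spikes are binned at ``bin_ms``; an avalanche is a maximal run
    of consecutive non-empty bins, its size the total spike count.  The
    branching ratio is the mean, over consecutive bin pairs inside
    avalanches, of (next bin count) / (current bin count); it is ~1 when
    activity is marginally self-sustaining (near-critical), <1 subcritical
    and >1 supercritical.
    """
    n_bins = int(np.ceil(spike_set.duration * 1000.0 / bin_ms))
    if n_bins < 100:
        raise ValueError("recording must cover at least 100 bins")
    all_t = (
        np.concatenate([t for t in spike_set.trains.values()])
        if spike_set.trains
        else np.empty(0)
    )
    if len(all_t) == 0:
        return AvalancheStatistics(np.empty(0, dtype=int), float("nan"), bin_ms, n_bins)
    idx = np.minimum((all_t * 1000.0 / bin_ms).astype(np.int64), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sizes: list[int] = []
    ratios: list[float] = []
    cur = 0
    prev = 0
    for cnt in counts:
        if cnt > 0:
            if prev > 0:
                ratios.append(cnt / prev)
            cur += cnt
        else:
            if cur > 0:
                sizes.append(cur)
            cur = 0
        prev = cnt
    if cur > 0:
        sizes.append(cur)
    br = float(np.mean(ratios)) if ratios else float("nan")
    return AvalancheStatistics(np.asarray(sizes, dtype=int), br, bin_ms, n_bins)


def electrode_metrics(
    spike_set: SpikeTrainSet,
    electrode_map: ElectrodeMap,
    max_isi_ms: float = DEFAULT_MAX_ISI_MS,
    min_spikes: int = DEFAULT_MIN_SPIKES,
) -> pd.DataFrame:
    """Per-electrode MFR/MBR table.

    Columns: ``electrode_id, n_neurons, n_spikes, mfr_hz, n_bursts,
    mbr_per_min``.  Network averages are the column means (use
    ``df[["mfr_hz", "mbr_per_min"]].mean()``).
    """
    rows = []
    dur = spike_set.duration
    for eid in sorted(electrode_map.members):
        train = electrode_train(spike_set, electrode_map.members[eid])
        bursts = detect_bursts(train, max_isi_ms, min_spikes)
        rows.append(
            {
                "electrode_id": eid,
                "n_neurons": len(electrode_map.members[eid]),
                "n_spikes": len(train),
                "mfr_hz": mean_firing_rate(train, dur),
                "n_bursts": len(bursts),
                "mbr_per_min": mean_bursting_rate(bursts, dur),
            }
        )
    return pd.DataFrame(rows)
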