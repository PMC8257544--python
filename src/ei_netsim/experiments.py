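"""In silico experiments on inhibitory connectivity vs synaptic strength.

Reproduces the simulation protocol used to dissect how extracellular-
matrix depletion changes network activity: the control network
(C_inh = 0.15, W_inh = -6.6 mV) is compared against an "ECM depleted"
network whose inhibitory sparseness is reduced to 40% of control
(C_inh = 0.06), replicate conditions are swept over a (C_inh, W_inh)
grid with freshly generated wiring per replicate, and the dependence of
activity on inhibitory weight is classified as power-law-like or linear
by least-squares model selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .dynamics import run_simulation, substream
from .mea import (
    DEFAULT_GROUP_MAX,
    DEFAULT_GROUP_MIN,
    DEFAULT_MAX_ISI_MS,
    DEFAULT_MIN_SPIKES,
    DEFAULT_N_ELECTRODES,
    assign_electrodes,
    avalanche_statistics,
    electrode_metrics,
)
from .network import NetworkConfig

__all__ = [
    "Condition",
    "CONTROL",
    "ECM_DEPLETED",
    "SweepResult",
    "FitReport",
    "ModelFit",
    "CalibrationError",
    "DEFAULT_C_INH_LEVELS",
    "default_w_inh_levels",
    "replicate_seed",
    "run_replicate",
    "run_condition",
    "compare_conditions",
    "sweep_grid",
    "correlation_vs_cinh",
    "fit_power_vs_linear",
    "gaba_blockade_analog",
    "compensation_table",
    "calibrate_drive",
]


@dataclass(frozen=True)
class Condition:
    """A named (C_inh, W_inh) override of a base network configuration."""

    name: str
    c_inh: float
    w_inh: float

    def config(self, base: NetworkConfig, **extra) -> NetworkConfig:
        return replace(base, c_inh=self.c_inh, w_inh=self.w_inh, **extra)


#: Control inhibitory circuitry: 15% sparseness, -6.6 mV synapses.
CONTROL = Condition("control", c_inh=0.15, w_inh=-6.6)
#: ECM depleted: inhibitory sparseness at 40% of control, weight unchanged
#: (the weight dependence is explored separately by the W_inh sweep).
ECM_DEPLETED = Condition("ECM depleted", c_inh=0.06, w_inh=-6.6)

#: Sparseness levels examined: the named study levels plus one above control.
DEFAULT_C_INH_LEVELS = (0.20, 0.15, 0.125, 0.10, 0.06)


def default_w_inh_levels(n: int = 9) -> np.ndarray:
    """Inhibitory weight sweep: 0.75x to 2x the control magnitude.

    Zero weight is excluded because the power-law form a*|W|^b is singular
    there; magnitudes below ~0.75x control are excluded because with the
    sparsified (C_inh = 0.06) wiring they push the network into the
    saturated runaway-synchrony regime where rate measures clip at the
    refractory ceiling and the weight dependence is no longer informative.
    """
    return np.round(-6.6 * np.linspace(0.75, 2.0, n), 6)


def replicate_seed(master_seed: int, c_inh: float, w_inh: float, rep: int) -> int:
    """Deterministic 31-bit seed for one replicate of one condition."""
    key = (
        int(master_seed),
        int(round(c_inh * 1_000_000)),
        int(round(abs(w_inh) * 1_000_000)),
        int(rep),
    )
    return int(np.random.SeedSequence(key).generate_state(1)[0] % (2**31))


def _default_n_electrodes(n_neurons: int) -> int:
    """As many electrodes as the array has, fewer on small networks."""
    return min(DEFAULT_N_ELECTRODES, n_neurons // DEFAULT_GROUP_MAX)


def run_replicate(
    config: NetworkConfig,
    max_isi_ms: float = DEFAULT_MAX_ISI_MS,
    min_spikes: int = DEFAULT_MIN_SPIKES,
    n_electrodes: int | None = None,
) -> dict:
    """Simulate one network instance and measure it on the virtual MEA.

    Returns network-average MFR (spikes/s) and MBR (bursts/min) over the
    electrodes, plus the avalanche branching ratio of the pooled activity.
    """
    spikes = run_simulation(config)
    n_el = _default_n_electrodes(config.n_total) if n_electrodes is None else n_electrodes
    emap = assign_electrodes(
        spikes,
        n_electrodes=n_el,
        group_min=DEFAULT_GROUP_MIN,
        group_max=DEFAULT_GROUP_MAX,
        rng=substream(config.seed, 4),
    )
    table = electrode_metrics(spikes, emap, max_isi_ms, min_spikes)
    av = avalanche_statistics(spikes)
    return {
        "mfr_hz": float(table["mfr_hz"].mean()),
        "mbr_per_min": float(table["mbr_per_min"].mean()),
        "median_mbr_per_min": float(table["mbr_per_min"].median()),
        "frac_bursting_electrodes": float((table["n_bursts"] > 0).mean()),
        "branching_ratio": av.branching_ratio,
        "n_spikes": spikes.n_spikes,
    }


def run_condition(
    cond: Condition,
    base: NetworkConfig,
    n_replicates: int = 15,
    seed: int = 0,
    **metric_kwargs,
) -> pd.DataFrame:
    """Run ``n_replicates`` independent instances of one condition.

    Every replicate regenerates wiring, initial state, noise and the
    electrode map from its own derived seed, mirroring the protocol in
    which connectivity is newly generated per simulation instance.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rows = []
    for rep in range(n_replicates):
        rs = replicate_seed(seed, cond.c_inh, cond.w_inh, rep)
        config = cond.config(base, seed=rs)
        row = {"condition": cond.name, "c_inh": cond.c_inh, "w_inh": cond.w_inh,
               "rep": rep, "seed": rs}
        row.update(run_replicate(config, **metric_kwargs))
        rows.append(row)
    return pd.DataFrame(rows)


@dataclass
class Comparison:
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    percent_difference: float  # of means, b relative to a
    t_statistic: float
    t_pvalue: float
    kw_statistic: float
    kw_pvalue: float
    degenerate: bool = False  # zero variance on both sides, equal means


def compare_conditions(a: np.ndarray, b: np.ndarray) -> Comparison:
    """Two-sample comparison of replicate metrics.

    Reports the percent difference of means and both the two-tailed
    independent t-test (the convention for simulation replicates, which
    are approximately normal) and the Kruskal-Wallis test.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 replicates per side")
    ma, mb = a.mean(), b.mean()
    sa = a.std(ddof=1) / math.sqrt(len(a))
    sb = b.std(ddof=1) / math.sqrt(len(b))
    pct = 100.0 * (mb - ma) / ma if ma != 0 else float("nan")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0 and ma == mb:
        return Comparison(ma, sa, mb, sb, 0.0, 0.0, 1.0, 0.0, 1.0, degenerate=True)
    t_stat, t_p = stats.ttest_ind(a, b)
    try:
        kw_stat, kw_p = stats.kruskal(a, b)
    except ValueError:  # all values identical across both groups
        kw_stat, kw_p = 0.0, 1.0
    return Comparison(ma, sa, mb, sb, pct, float(t_stat), float(t_p),
                      float(kw_stat), float(kw_p))


@dataclass
class ModelFit:
    form: str  # "linear" or "power"
    params: tuple[float, ...]  # (intercept, slope) or (prefactor, exponent)
    rss: float
    r_squared: float
    aicc: float
    n_points: int
    flagged: str | None = None

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.form == "linear":
            return self.params[0] + self.params[1] * x
        return self.params[0] * np.power(x, self.params[1])


@dataclass
class FitReport:
    linear: ModelFit
    power: ModelFit
    selected: str  # "linear" or "power"


def _aicc(rss: float, n: int, k_params: int) -> float:
    """Small-sample-corrected information criterion from LS residuals."""
    k = k_params + 1  # +1 for the residual variance
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 <= 0:  # too few points for the correction term
        return aic
    return aic + 2 * k * (k + 1) / (n - k - 1)


def fit_power_vs_linear(w_levels: np.ndarray, metric_means: np.ndarray) -> FitReport:
    """Classify the dependence of a metric on |W_inh| as power-law or linear.

    Both forms, y = alpha + beta*x and y = a*x^b, are fitted by least
    squares on the original scale (the power fit is initialized from a
    log-log regression) and compared by a small-sample-corrected
    information criterion; ties go to the linear form.  ``w_levels`` may
    be given as signed weights; magnitudes are used.
    """
    x = np.abs(np.asarray(w_levels, dtype=float))
    y = np.asarray(metric_means, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 weight levels")
    if np.any(x <= 0):
        raise ValueError("power-law form requires nonzero weight levels")
    n = len(x)

    slope, intercept = np.polyfit(x, y, 1)
    rss_lin = float(np.sum((y - (intercept + slope * x)) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    r2_lin = 1.0 - rss_lin / tss if tss > 0 else 1.0
    linear = ModelFit("linear", (float(intercept), float(slope)), rss_lin,
                      r2_lin, _aicc(rss_lin, n, 2), n)

    flagged = None
    pos = y > 0
    if not np.all(pos):
        flagged = "non-positive metric values excluded from power fit"
    xp, yp = x[pos], y[pos]
    if len(xp) < 3:
        power = ModelFit("power", (float("nan"), float("nan")), float("inf"),
                         float("-inf"), float("inf"), int(pos.sum()),
                         flagged="too few positive points for power fit")
    else:
        b0, loga0 = np.polyfit(np.log(xp), np.log(yp), 1)
        try:
            popt, _ = optimize.curve_fit(
                lambda xx, a, b: a * np.power(xx, b),
                xp, yp, p0=(math.exp(loga0), b0), maxfev=20000,
            )
            a_hat, b_hat = float(popt[0]), float(popt[1])
        except RuntimeError:
            a_hat, b_hat = math.exp(loga0), float(b0)
        resid = yp - a_hat * np.power(xp, b_hat)
        rss_pow = float(np.sum(resid**2))
        tss_p = float(np.sum((yp - yp.mean()) ** 2))
        r2_pow = 1.0 - rss_pow / tss_p if tss_p > 0 else 1.0
        power = ModelFit("power", (a_hat, b_hat), rss_pow, r2_pow,
                         _aicc(rss_pow, len(xp), 2), len(xp), flagged)

    # lower criterion wins; ties (including both-fit-perfectly, where the
    # RSS difference is numerical noise) go to the linear form
    tie = abs(rss_lin - power.rss) <= 1e-9 * max(1.0, tss)
    selected = "power" if (power.aicc < linear.aicc and not tie) else "linear"
    return FitReport(linear=linear, power=power, selected=selected)


@dataclass
class SweepResult:
    """Replicate metrics over a (C_inh, W_inh) grid.

    ``data`` is long-form: one row per (c_inh, w_inh, rep) with columns
    ``mfr_hz`` and ``mbr_per_min``.  Failed cells, if any, are recorded
    in ``failures`` rather than aborting the sweep.
    """

    data: pd.DataFrame
    c_inh_levels: tuple[float, ...]
    w_inh_levels: tuple[float, ...]
    n_replicates: int
    base: NetworkConfig
    seed: int
    failures: list[dict] = field(default_factory=list)

    _METRICS = {"MFR": "mfr_hz", "MBR": "mbr_per_min"}

    def summary(self) -> pd.DataFrame:
        """Mean and s.e.m. of each metric per grid cell."""
        g = self.data.groupby(["c_inh", "w_inh"])
        out = g.agg(
            mfr_mean=("mfr_hz", "mean"),
            mfr_sem=("mfr_hz", "sem"),
            mbr_mean=("mbr_per_min", "mean"),
            mbr_sem=("mbr_per_min", "sem"),
            n=("rep", "size"),
        ).reset_index()
        return out

    def cell(self, c_inh: float, w_inh: float) -> pd.DataFrame:
        d = self.data
        return d[(np.isclose(d["c_inh"], c_inh)) & (np.isclose(d["w_inh"], w_inh))]

    def mean_metric(self, c_inh: float, w_inh: float, metric: str = "MFR") -> float:
        col = self._METRICS[metric]
        return float(self.cell(c_inh, w_inh)[col].mean())

    def weight_profile(self, c_inh: float, metric: str = "MFR") -> tuple[np.ndarray, np.ndarray]:
        """(w_inh levels, replicate-mean metric) at one sparseness level."""
        w = np.asarray(sorted(self.w_inh_levels))
        means = np.array([self.mean_metric(c_inh, wi, metric) for wi in w])
        return w, means

    def fit_reports(self, metric: str = "MFR") -> dict[float, FitReport]:
        """Power-vs-linear fit of metric vs |W_inh| per sparseness level."""
        return {
            c: fit_power_vs_linear(*self.weight_profile(c, metric))
            for c in self.c_inh_levels
        }


def sweep_grid(
    base: NetworkConfig,
    c_inh_levels=DEFAULT_C_INH_LEVELS,
    w_inh_levels=None,
    n_replicates: int = 15,
    seed: int = 0,
    **metric_kwargs,
) -> SweepResult:
    """Fill the full (C_inh, W_inh) grid with independent replicates."""
    if w_inh_levels is None:
        w_inh_levels = default_w_inh_levels()
    c_inh_levels = tuple(float(c) for c in c_inh_levels)
    w_inh_levels = tuple(float(w) for w in w_inh_levels)
    if not c_inh_levels or not w_inh_levels:
        raise ValueError("sweep levels must be nonempty")
    if any(w > 0 for w in w_inh_levels):
        raise ValueError("W_inh levels must be <= 0")
    rows = []
    failures = []
    for c in c_inh_levels:
        for w in w_inh_levels:
            cond = Condition(f"c={c},w={w}", c_inh=c, w_inh=w)
            try:
                df = run_condition(cond, base, n_replicates, seed, **metric_kwargs)
                rows.append(df)
            except Exception as exc:  # record, do not abort the grid
                failures.append({"c_inh": c, "w_inh": w, "error": repr(exc)})
    data = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    return SweepResult(data, c_inh_levels, w_inh_levels, n_replicates, base,
                       seed, failures)


def correlation_vs_cinh(
    sweep: SweepResult, metric: str = "MFR", w_inh: float = CONTROL.w_inh
) -> tuple[float, float]:
    """Pearson correlation of C_inh level vs replicate-mean metric.

    Evaluated at a fixed inhibitory weight (control, by default) across
    the swept sparseness levels.  Returns (r, p); r is NaN if the metric
    has no variance across levels.
    """
    c_levels = sorted(sweep.c_inh_levels)
    if len(c_levels) < 3:
        raise ValueError("need at least 3 C_inh levels")
    means = [sweep.mean_metric(c, w_inh, metric) for c in c_levels]
    if np.std(means) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(c_levels, means)
    return float(r), float(p)


def gaba_blockade_analog(
    cond: Condition,
    base: NetworkConfig,
    scale: float,
    n_replicates: int = 15,
    seed: int = 0,
    **metric_kwargs,
) -> pd.DataFrame:
    """Run a condition with inhibitory weights scaled toward zero.

    ``scale=1`` reproduces the condition unchanged; ``scale=0`` silences
    all inhibitory synapses — the in silico analog of a complete
    GABA_A-receptor blockade.
    """
    if not (0.0 <= scale <= 1.0):
        raise ValueError("scale must be in [0, 1]")
    scaled = Condition(f"{cond.name} (W_inh x{scale})", cond.c_inh, cond.w_inh * scale)
    return run_condition(scaled, base, n_replicates, seed, **metric_kwargs)


def compensation_table(
    sweep: SweepResult,
    control_mean: float,
    metric: str = "MFR",
    tolerance: float = 0.10,
) -> pd.DataFrame:
    """Which swept W_inh values restore the metric to near control?

    For every sparseness level, reports the closest approach of the
    replicate-mean metric to ``control_mean`` over the weight sweep and
    whether any weight brings it within ``tolerance`` (fractional).
    """
    rows = []
    for c in sweep.c_inh_levels:
        w, means = sweep.weight_profile(c, metric)
        rel = np.abs(means - control_mean) / control_mean
        i = int(np.argmin(rel))
        rows.append(
            {
                "c_inh": c,
                "best_w_inh": float(w[i]),
                "best_mean": float(means[i]),
                "closest_rel_deviation": float(rel[i]),
                "compensated": bool(rel[i] <= tolerance),
            }
        )
    return pd.DataFrame(rows)


class CalibrationError(RuntimeError):
    """No drive amplitude in the searched grid met the calibration goals."""


def calibrate_drive(
    base: NetworkConfig,
    target_band: tuple[float, float] = (0.7, 1.3),
    mbr_floor: float = 1.0,
    drive_grid: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[float, float, pd.DataFrame]:
    """Find background-drive amplitudes putting the control network in the
    near-critical spiking-bursting regime.

    The excitatory drive is searched over a grid (the inhibitory drive is
    scaled proportionally, preserving the base ratio); a candidate passes
    when the avalanche branching ratio lies in ``target_band`` and the
    median electrode MBR reaches ``mbr_floor`` bursts/min.  The base
    drive is tried first, so an already-calibrated configuration is
    returned unchanged.

    Returns (drive_exc, drive_inh, diagnostic trace).
    """
    lo, hi = target_band
    ratio = base.drive_inh / base.drive_exc if base.drive_exc > 0 else 0.4
    if drive_grid is None:
        drive_grid = np.arange(1.0, 10.5, 0.5)
    candidates = [base.drive_exc] + [float(g) for g in drive_grid
                                     if not np.isclose(g, base.drive_exc)]
    trace = []
    for dex in candidates:
        config = replace(base, drive_exc=dex, drive_inh=dex * ratio, seed=seed)
        m = run_replicate(config)
        ok = (lo <= m["branching_ratio"] <= hi) and (m["median_mbr_per_min"] >= mbr_floor)
        trace.append({"drive_exc": dex, "drive_inh": dex * ratio, **m, "pass": ok})
        if ok:
            return dex, dex * ratio, pd.DataFrame(trace)
    tdf = pd.DataFrame(trace)
    dist = (tdf["branching_ratio"] - (lo + hi) / 2).abs().fillna(np.inf)
    best = tdf.iloc[int(dist.argmin())]
    raise CalibrationError(
        f"no drive in grid met branching ratio in [{lo}, {hi}] with median "
        f"MBR >= {mbr_floor}; best candidate drive_exc={best['drive_exc']} "
        f"(branching ratio {best['branching_ratio']:.3f}, median MBR "
        f"{best['median_mbr_per_min']:.2f})"
    )
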