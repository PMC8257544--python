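import numpy as np
import pandas as pd
import pytest

from ei_netsim.experiments import (
    CONTROL,
    Condition,
    SweepResult,
    compare_conditions,
    compensation_table,
    correlation_vs_cinh,
    default_w_inh_levels,
    fit_power_vs_linear,
    gaba_blockade_analog,
    replicate_seed,
    run_condition,
    sweep_grid,
)
from ei_netsim.network import NetworkConfig

from _oracles import kruskal_wallis_h, t_statistic

# desk-scale base for the fast functional tests in this module
FAST_BASE = NetworkConfig(n_exc=67, n_inh=33, duration=5.0, burn_in=1.0)


def _fake_sweep(c_levels, w_levels, mfr_fn, n_rep=3):
    """SweepResult with fabricated metric values (no simulation)."""
    rows = []
    for c in c_levels:
        for w in w_levels:
            for rep in range(n_rep):
                rows.append(
                    {"c_inh": c, "w_inh": w, "rep": rep,
                     "mfr_hz": mfr_fn(c, w), "mbr_per_min": mfr_fn(c, w) * 2}
                )
    return SweepResult(pd.DataFrame(rows), tuple(c_levels), tuple(w_levels),
                       n_rep, NetworkConfig(), 0)


class TestStatisticalComparison:
    def test_toy_samples_match_hand_computation(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 3.0, 4.0]
        cmp = compare_conditions(a, b)
        assert cmp.percent_difference == pytest.approx(50.0)
        assert cmp.t_statistic == pytest.approx(-t_statistic(b, a))
        assert cmp.t_statistic == pytest.approx(t_statistic(a, b))
        assert cmp.kw_statistic == pytest.approx(kruskal_wallis_h(a, b))

    def test_identical_samples_degenerate(self):
        cmp = compare_conditions([2.0, 2.0, 2.0], [2.0, 2.0, 2.0])
        assert cmp.degenerate
        assert cmp.t_pvalue == 1.0 and cmp.kw_pvalue == 1.0
        assert cmp.percent_difference == 0.0

    def test_needs_two_per_side(self):
        with pytest.raises(ValueError):
            compare_conditions([1.0], [1.0, 2.0])


class TestModelSelection:
    def test_exact_line_selects_linear_by_tie_rule(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rep = fit_power_vs_linear(-x, 3.0 * x)
        assert rep.selected == "linear"
        assert rep.power.params[1] == pytest.approx(1.0, abs=1e-3)

    def test_noisy_power_law_selects_power(self, rng):
        x = np.linspace(1.0, 5.0, 9)
        y = 0.5 * x**2.5 * (1 + 0.01 * rng.standard_normal(9))
        rep = fit_power_vs_linear(-x, y)
        assert rep.selected == "power"
        assert rep.power.params[1] == pytest.approx(2.5, abs=0.1)

    def test_non_positive_metric_flagged(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        y = np.array([4.0, 2.0, 1.0, 0.0, -1.0])
        rep = fit_power_vs_linear(-x, y)
        assert rep.power.flagged is not None

    def test_too_few_levels(self):
        with pytest.raises(ValueError):
            fit_power_vs_linear([-1.0, -2.0, -3.0], [1.0, 2.0, 3.0])

    def test_default_levels_negative_nonzero(self):
        w = default_w_inh_levels()
        assert len(w) == 9 and np.all(w < 0)
        assert w.min() == pytest.approx(-13.2)


class TestCorrelation:
    def test_exact_linear_decrease(self):
        sweep = _fake_sweep([0.06, 0.10, 0.15], [-6.6], lambda c, w: 100 - 200 * c)
        r, p = correlation_vs_cinh(sweep, "MFR", w_inh=-6.6)
        assert r == pytest.approx(-1.0)

    def test_constant_metric_flagged(self):
        sweep = _fake_sweep([0.06, 0.10, 0.15], [-6.6], lambda c, w: 5.0)
        r, p = correlation_vs_cinh(sweep, "MFR", w_inh=-6.6)
        assert np.isnan(r)

    def test_needs_three_levels(self):
        sweep = _fake_sweep([0.06, 0.15], [-6.6], lambda c, w: c)
        with pytest.raises(ValueError):
            correlation_vs_cinh(sweep, "MFR", w_inh=-6.6)


class TestCompensation:
    def test_table_flags_restorable_levels(self):
        # metric rises as C_inh falls, but strong weights pull it back
        def mfr(c, w):
            return 50.0 + 400 * (0.15 - c) * (1.0 - abs(w) / 13.2)

        sweep = _fake_sweep([0.15, 0.10], np.linspace(-3.3, -13.2, 5), mfr)
        table = compensation_table(sweep, control_mean=50.0)
        row = table[table["c_inh"] == 0.10].iloc[0]
        assert row["compensated"]


class TestReplicateProtocol:
    def test_replicate_seed_deterministic_and_distinct(self):
        s1 = replicate_seed(7, 0.15, -6.6, 0)
        assert s1 == replicate_seed(7, 0.15, -6.6, 0)
        others = {
            replicate_seed(7, 0.15, -6.6, 1),
            replicate_seed(7, 0.06, -6.6, 0),
            replicate_seed(8, 0.15, -6.6, 0),
        }
        assert s1 not in others and len(others) == 3
        assert 0 <= s1 < 2**31

    def test_single_replicate_deterministic(self):
        df1 = run_condition(CONTROL, FAST_BASE, n_replicates=1, seed=3)
        df2 = run_condition(CONTROL, FAST_BASE, n_replicates=1, seed=3)
        assert df1["mfr_hz"].iloc[0] == df2["mfr_hz"].iloc[0]
        assert df1["mbr_per_min"].iloc[0] == df2["mbr_per_min"].iloc[0]

    def test_gaba_blockade_scale_one_is_identity(self):
        a = run_condition(CONTROL, FAST_BASE, n_replicates=2, seed=5)
        b = gaba_blockade_analog(CONTROL, FAST_BASE, scale=1.0, n_replicates=2,
                                 seed=5)
        assert np.allclose(a["mfr_hz"], b["mfr_hz"])

    def test_gaba_blockade_disinhibits(self):
        """Silencing inhibitory synapses raises activity above control."""
        base = FAST_BASE.with_overrides(n_exc=134, n_inh=66, duration=10.0)
        ctrl = run_condition(CONTROL, base, n_replicates=3, seed=6)
        blocked = gaba_blockade_analog(CONTROL, base, scale=0.0,
                                       n_replicates=3, seed=6)
        assert blocked["mfr_hz"].mean() > ctrl["mfr_hz"].mean()

    def test_single_cell_sweep_matches_run_condition(self):
        sweep = sweep_grid(FAST_BASE, c_inh_levels=[0.15], w_inh_levels=[-6.6],
                           n_replicates=2, seed=4)
        cond = Condition("c=0.15,w=-6.6", 0.15, -6.6)
        direct = run_condition(cond, FAST_BASE, n_replicates=2, seed=4)
        assert np.allclose(
            sweep.cell(0.15, -6.6)["mfr_hz"].to_numpy(), direct["mfr_hz"].to_numpy()
        )

    def test_calibrated_drive_is_fixed_point(self):
        """A base drive already in the near-critical band is kept unchanged."""
        from ei_netsim.experiments import calibrate_drive

        base = NetworkConfig(duration=20.0)
        dex, dinh, trace = calibrate_drive(base, drive_grid=np.array([]), seed=2)
        assert dex == base.drive_exc and dinh == base.drive_inh
        assert trace.iloc[-1]["pass"]

    def test_silent_network_calibrates_upward(self):
        from ei_netsim.experiments import calibrate_drive

        base = NetworkConfig(duration=20.0, drive_exc=0.0, drive_inh=0.0)
        dex, dinh, trace = calibrate_drive(base, drive_grid=np.array([4.0]),
                                           seed=2)
        assert dex > 0.0 and dinh > 0.0

    def test_calibration_failure_reports_best(self):
        from ei_netsim.experiments import CalibrationError, calibrate_drive

        base = NetworkConfig(duration=20.0, drive_exc=0.5, drive_inh=0.2)
        with pytest.raises(CalibrationError, match="best candidate"):
            calibrate_drive(base, drive_grid=np.array([1.0]), seed=2)

    def test_sweep_validates_levels(self):
        with pytest.raises(ValueError):
            sweep_grid(FAST_BASE, c_inh_levels=[0.15], w_inh_levels=[3.0])
        with pytest.raises(ValueError):
            sweep_grid(FAST_BASE, c_inh_levels=[], w_inh_levels=[-6.6])
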