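"""Tests of milk-loss and variability resilience indicators."""

import numpy as np
import pandas as pd
import pytest

from resilac.elc import N_DIM
from resilac.quantgen import Pedigree
from resilac.traits import (
    FluctuationEvent,
    compute_deviations,
    detect_fluctuations,
    finalize_cohort,
    lag1_autocorr,
    lnsd,
    lnsd_interval_halfwidth,
    milk_loss_traits,
    my305,
    select_window,
    skewness,
    summary_statistics,
    variability_traits,
)

from conftest import brute_force_fluctuations


class TestDeviations:
    def test_zero_when_equal(self):
        y = np.full(N_DIM, 30.0)
        np.testing.assert_array_equal(compute_deviations(y, y), np.zeros(N_DIM))

    def test_sign(self):
        fitted = np.full(N_DIM, 30.0)
        actual = fitted.copy()
        actual[100:110] -= 5
        dev = compute_deviations(actual, fitted)
        assert np.all(dev[100:110] == -5) and np.all(np.delete(dev, range(100, 110)) == 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compute_deviations(np.zeros(10), np.zeros(10))


class TestDetectFluctuations:
    def test_hand_example(self):
        fitted = np.full(N_DIM, 20.0)
        actual = fitted.copy()
        actual[50:62] = 17.0  # 12 days at dev -3; 17 < 18 = 0.9*20
        events = detect_fluctuations(actual, fitted)
        assert len(events) == 1
        ev = events[0]
        assert (ev.start_dim, ev.end_dim, ev.duration_days) == (51, 62, 12)
        assert ev.loss_kg == pytest.approx(36.0)

    def test_nine_day_run_is_not_an_event(self):
        fitted = np.full(N_DIM, 20.0)
        actual = fitted.copy()
        actual[50:59] = 10.0  # deep but only 9 days
        assert detect_fluctuations(actual, fitted) == []

    def test_exact_90_percent_boundary_is_not_deep_enough(self):
        fitted = np.full(N_DIM, 20.0)
        actual = fitted.copy()
        actual[50:65] = 18.0  # exactly 0.9*fitted: strict inequality fails
        assert detect_fluctuations(actual, fitted) == []
        actual[55] = 17.999
        assert len(detect_fluctuations(actual, fitted)) == 1

    def test_long_run_is_one_event(self):
        fitted = np.full(N_DIM, 20.0)
        actual = fitted.copy()
        actual[50:90] = 15.0  # 40 days: one event, never split
        events = detect_fluctuations(actual, fitted)
        assert len(events) == 1 and events[0].duration_days == 40

    def test_nadir_earliest_on_ties(self):
        fitted = np.full(N_DIM, 20.0)
        actual = fitted.copy()
        actual[50:62] = 17.0
        actual[[53, 57]] = 15.0  # two equal nadirs
        ev = detect_fluctuations(actual, fitted)[0]
        assert ev.nadir_dim == 54

    def test_matches_brute_force_scanner(self):
        """Equivalence with an exhaustive run enumerator on random
        autocorrelated deviation vectors."""
        rng = np.random.default_rng(20)
        for _ in range(200):
            fitted = np.full(N_DIM, 25.0)
            dev = np.empty(N_DIM)
            dev[0] = rng.normal()
            for t in range(1, N_DIM):
                dev[t] = 0.75 * dev[t - 1] + rng.normal(0, 1.5)
            actual = fitted + dev
            got = [
                (e.start_dim, e.end_dim, e.nadir_dim, e.duration_days, e.loss_kg)
                for e in detect_fluctuations(actual, fitted)
            ]
            expected = brute_force_fluctuations(actual, fitted)
            assert len(got) == len(expected)
            for g, e in zip(got, expected):
                assert g[:4] == e[:4]
                assert g[4] == pytest.approx(e[4])

    def test_dim_class_from_start(self):
        for start, lab in [(1, "1-44"), (44, "1-44"), (45, "45-99"), (100, "100-199"), (200, "200-305")]:
            ev = FluctuationEvent(start, start + 11, start + 2, 12, 30.0)
            assert ev.dim_class == lab


class TestMilkLossTraits:
    def test_my305(self):
        assert my305(np.full(N_DIM, 30.0)) == 9150.0

    def test_my305_linearity(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(30, 3, N_DIM), rng.normal(5, 1, N_DIM)
        assert my305(a + b) == pytest.approx(my305(a) + my305(b))
        assert my305(a) == pytest.approx(sum(float(v) for v in a))

    def test_aggregate_arithmetic(self):
        events = [
            FluctuationEvent(10, 21, 15, 12, 36.0),
            FluctuationEvent(100, 114, 105, 15, 50.0),
        ]
        ml, nml, tdml, mlp = milk_loss_traits(events, 8000.0)
        assert (ml, nml, tdml) == (86.0, 2, 27)
        assert mlp == pytest.approx(1.075)

    def test_no_events(self):
        assert milk_loss_traits([], 9000.0) == (0.0, 0, 0, 0.0)

    def test_nonpositive_my305_is_error(self):
        with pytest.raises(ValueError):
            milk_loss_traits([], 0.0)


class TestWindows:
    def test_window_lengths(self):
        dev = np.arange(N_DIM, dtype=float)
        assert select_window(dev, 1).size == 305
        assert select_window(dev, 2).size == 285  # 295 - 11 + 1
        assert select_window(dev, 3).size == 31  # DIM 60..90
        np.testing.assert_array_equal(select_window(dev, 2), dev[10:295])
        np.testing.assert_array_equal(select_window(dev, 3), dev[59:90])

    def test_window4_negative_days_only(self):
        dev = np.ones(N_DIM)
        dev[[5, 100, 200]] = -2.0
        np.testing.assert_array_equal(select_window(dev, 4), [-2.0] * 3)

    def test_all_positive_deviations_window4_traits_missing(self):
        dev = np.abs(np.random.default_rng(2).normal(1, 0.1, N_DIM))
        out = variability_traits(dev)
        assert np.isnan(out["Lnsd4"]) and np.isnan(out["Ra4"]) and np.isnan(out["Ske4"])


class TestVariabilityStatistics:
    def test_lnsd_closed_forms(self):
        base = np.array([0.0, 1.0, 2.0])  # SD exactly 1
        assert lnsd(base) == pytest.approx(0.0)
        assert lnsd(base * np.e) == pytest.approx(1.0)
        assert np.isnan(lnsd(np.full(5, 3.0)))

    def test_interval_halfwidth(self):
        assert lnsd_interval_halfwidth(1.11) == pytest.approx(5.94, abs=0.02)
        assert lnsd_interval_halfwidth(0.0) == pytest.approx(1.96)
        xs = np.linspace(-1, 2, 50)
        hw = [lnsd_interval_halfwidth(x) for x in xs]
        assert np.all(np.diff(hw) > 0)

    def test_lag1_ar_process(self):
        rng = np.random.default_rng(4)
        n = 10_000
        x = np.empty(n)
        x[0] = rng.normal()
        for t in range(1, n):
            x[t] = 0.8 * x[t - 1] + rng.normal()
        assert lag1_autocorr(x) == pytest.approx(0.8, abs=0.05)

    def test_lag1_alternating(self):
        x = np.tile([1.0, -1.0], 200)
        assert lag1_autocorr(x) == pytest.approx(-1.0, abs=0.01)

    def test_lag1_iid_near_zero(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=4000)
        assert abs(lag1_autocorr(x)) < 3 / np.sqrt(4000)

    def test_skewness_symmetric_zero(self):
        assert skewness(np.array([-2.0, -1.0, 0.0, 1.0, 2.0])) == pytest.approx(0.0)

    def test_skewness_right_tail_positive(self):
        rng = np.random.default_rng(6)
        assert skewness(rng.exponential(size=2000)) > 0.5

    def test_skewness_moment_formula_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.normal(size=rng.integers(10, 200))
            n = x.size
            m = x.mean()
            m2 = np.mean((x - m) ** 2)
            m3 = np.mean((x - m) ** 3)
            g1 = m3 / m2 ** 1.5
            expected = g1 * np.sqrt(n * (n - 1)) / (n - 2)
            assert skewness(x) == pytest.approx(expected, rel=1e-10)


class TestFinalizeCohort:
    def _pedigree(self):
        return Pedigree(
            ["s", "d", "ok", "nos"],
            ["0", "0", "s", "0"],
            ["0", "0", "d", "d"],
        )

    def _pheno(self, my305_values, cows):
        return pd.DataFrame({"cow_id": cows, "MY305": my305_values})

    def test_exactly_3sd_removed(self):
        vals = np.array([10.0] * 5 + [14.0] * 5 + [12.0])
        outlier = vals.mean() + 3 * vals.std(ddof=1)
        # the outlier shifts cohort mean/SD; solve by iteration on the full set
        df = self._pheno(np.append(vals, outlier) * 100, ["ok"] * 12)
        full = df["MY305"]
        flag = np.abs(full - full.mean()) >= 3 * full.std(ddof=1)
        out, report = finalize_cohort(df, self._pedigree())
        assert report["my305_3sd"] == int(flag.sum())
        assert len(out) == 12 - int(flag.sum())

    def test_unknown_parents_removed(self):
        df = self._pheno([9000.0, 9100.0], ["ok", "nos"])
        out, report = finalize_cohort(df, self._pedigree())
        assert report["unknown_parents"] == 1
        assert out["cow_id"].tolist() == ["ok"]

    def test_identical_my305_none_removed_by_sd_rule(self):
        df = self._pheno([9000.0] * 6, ["ok"] * 6)
        out, report = finalize_cohort(df, self._pedigree())
        assert report["my305_3sd"] == 0 and len(out) == 6


def test_event_recovery_on_injected_perturbations():
    """Deep injected events (depth >> noise) are recalled with duration
    error within two days."""
    from resilac.elc import evaluate_model, iterate_elc
    from resilac.synthetic import PerturbationEvent, simulate_daily_records

    from resilac.synthetic import apply_events

    rng = np.random.default_rng(9)
    truth = evaluate_model("wood", (30.0, 0.2, 0.005))
    recalled, total = 0, 0
    for rep in range(25):
        starts = [40 + 90 * k + int(rng.integers(0, 25)) for k in range(3)]
        events = [PerturbationEvent(s, int(rng.integers(14, 25)), 0.45) for s in starts]
        # alternating-sign noise: negative runs cannot extend more than one
        # day beyond an event, so the detector sees the injected geometry
        noise = rng.uniform(0.1, 0.4, truth.size) * np.where(np.arange(truth.size) % 2, 1, -1)
        y = apply_events(truth, events) + noise
        elc = iterate_elc(y, smooth=False)
        assert elc.qc_pass
        found = detect_fluctuations(y, elc.fitted)
        for ev in events:
            total += 1
            for f in found:
                if abs(f.start_dim - ev.start_dim) <= 2 and abs(
                    f.duration_days - ev.duration_days
                ) <= 2:
                    recalled += 1
                    break
    assert recalled / total >= 0.95


def test_summary_statistics_layout():
    df = pd.DataFrame({"MY305": [9000.0, 9500.0, 8500.0], "ML": [100.0, 200.0, 300.0]})
    out = summary_statistics(df, ["MY305", "ML"])
    assert list(out.columns) == ["trait", "N", "mean", "SD", "min", "max", "CV_pct"]
    row = out[out.trait == "ML"].iloc[0]
    assert row["mean"] == 200.0 and row["N"] == 3
    assert row["CV_pct"] == pytest.approx(50.0)
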