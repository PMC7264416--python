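"""Kaplan-Meier against the brute-force product-limit oracle, log-rank
against hand arithmetic and permutation, median-split screens, and Cox
covariate screening with planted hazards."""

import warnings

import numpy as np
import pandas as pd
import pytest

from coadmark.survival_analysis import (
    cox_screen,
    km_by_group,
    km_curve,
    logrank_test,
    median_split_screen,
    stratified_prb_screen,
)

from conftest import make_survival


def km_oracle(times, events):
    """Independent product-limit: loop over distinct event times, multiply
    (1 - d/n) over the explicit risk set."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out_t, out_s = [], []
    s = 1.0
    for t in sorted(set(times[events == 1])):
        n_risk = int((times >= t).sum())
        d = int(((times == t) & (events == 1)).sum())
        s *= 1.0 - d / n_risk
        out_t.append(t)
        out_s.append(s)
    return np.array(out_t), np.array(out_s)


class TestKM:
    def test_hand_product_limit(self):
        est = km_curve([1, 2, 3], [1, 1, 1])
        np.testing.assert_allclose(est.survival, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(est.at_risk, [3, 2, 1])

    def test_all_censored_flat(self):
        est = km_curve([5, 10, 15], [0, 0, 0])
        assert est.times.size == 0  # no steps: S stays at 1

    def test_censoring_shrinks_risk_set_without_step(self):
        est = km_curve([1, 2, 2, 3], [1, 0, 1, 1])
        t_or, s_or = km_oracle([1, 2, 2, 3], [1, 0, 1, 1])
        np.testing.assert_allclose(est.times, t_or)
        np.testing.assert_allclose(est.survival, s_or)

    def test_matches_oracle_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(25):
            n = int(rng.integers(1, 31))
            times = rng.integers(1, 15, n).astype(float)
            events = rng.integers(0, 2, n)
            est = km_curve(times, events)
            t_or, s_or = km_oracle(times, events)
            np.testing.assert_allclose(est.times, t_or)
            np.testing.assert_allclose(est.survival, s_or, atol=1e-12)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            km_curve([], [])

    def test_by_group(self):
        res = km_by_group([1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert set(res) == {"a", "b"}
        np.testing.assert_allclose(res["a"].survival, [0.5, 0.0])


def logrank_oracle(ta, ea, tb, eb):
    """Independent log-rank: explicit observed-vs-expected risk-table sums."""
    ta, tb = np.asarray(ta, float), np.asarray(tb, float)
    ea, eb = np.asarray(ea, int), np.asarray(eb, int)
    times = np.concatenate([ta, tb])
    events = np.concatenate([ea, eb])
    grp = np.concatenate([np.zeros(len(ta)), np.ones(len(tb))])
    O_E, V = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at = times >= t
        n = at.sum()
        n1 = (at & (grp == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (grp == 0)).sum()
        O_E += d1 - d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0
    return O_E**2 / V


class TestLogRank:
    def test_identical_groups_null(self):
        stat, p = logrank_test([1, 2, 3], [1, 1, 1], [1, 2, 3], [1, 1, 1])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_no_events_convention(self):
        stat, p = logrank_test([1, 2], [0, 0], [3, 4], [0, 0])
        assert (stat, p) == (0.0, 1.0)

    def test_hand_risk_table(self):
        """A={1,2} both events, B={3,4} both events: statistic matches the
        explicit risk-table arithmetic to 1e-9."""
        stat, _ = logrank_test([1, 2], [1, 1], [3, 4], [1, 1])
        assert stat == pytest.approx(logrank_oracle([1, 2], [1, 1], [3, 4], [1, 1]),
                                     abs=1e-9)

    def test_matches_oracle_random(self):
        rng = np.random.default_rng(1)
        for _ in range(15):
            na, nb = int(rng.integers(3, 15)), int(rng.integers(3, 15))
            ta = rng.integers(1, 20, na).astype(float)
            tb = rng.integers(1, 20, nb).astype(float)
            ea, eb = rng.integers(0, 2, na), rng.integers(0, 2, nb)
            if ea.sum() + eb.sum() == 0:
                continue
            stat, _ = logrank_test(ta, ea, tb, eb)
            assert stat == pytest.approx(logrank_oracle(ta, ea, tb, eb), abs=1e-9)

    def test_group_relabel_invariance(self):
        rng = np.random.default_rng(2)
        ta, tb = rng.integers(1, 30, 12).astype(float), rng.integers(1, 30, 9).astype(float)
        ea, eb = rng.integers(0, 2, 12), rng.integers(0, 2, 9)
        ea[0] = eb[0] = 1
        s1, p1 = logrank_test(ta, ea, tb, eb)
        s2, p2 = logrank_test(tb, eb, ta, ea)
        assert s1 == pytest.approx(s2, abs=1e-9)
        assert p1 == pytest.approx(p2, abs=1e-12)

    def test_p_value_agrees_with_permutation_null(self):
        """Chi-square p within Monte-Carlo error of a permutation null on a
        20-sample instance."""
        rng = np.random.default_rng(3)
        times = rng.exponential(10, 20)
        times[:10] *= 0.4
        events = np.ones(20, dtype=int)
        grp = np.array([0] * 10 + [1] * 10)
        stat, p = logrank_test(
            times[grp == 0], events[grp == 0], times[grp == 1], events[grp == 1]
        )
        n_perm, hits = 2000, 0
        for _ in range(n_perm):
            perm = rng.permutation(grp)
            s = logrank_oracle(
                times[perm == 0], events[perm == 0], times[perm == 1], events[perm == 1]
            )
            hits += s >= stat - 1e-12
        p_perm = hits / n_perm
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm) + 1e-3
        assert abs(p - p_perm) < 4 * se + 0.02


class TestMedianSplit:
    def test_even_split(self):
        surv = make_survival([10, 20, 30, 40], [1, 1, 1, 1])
        res = median_split_screen(
            pd.Series([1.0, 2.0, 3.0, 4.0], index=surv.data.index), surv
        )
        assert list(res.groups) == ["low", "low", "high", "high"]

    def test_ties_go_low(self):
        surv = make_survival([10, 20, 30, 40], [1, 1, 1, 1])
        res = median_split_screen(
            pd.Series([1.0, 2.0, 2.0, 3.0], index=surv.data.index), surv
        )
        assert list(res.groups) == ["low", "low", "low", "high"]

    def test_constant_feature_rejected(self):
        surv = make_survival([10, 20], [1, 1])
        with pytest.raises(ValueError, match="constant"):
            median_split_screen(pd.Series([1.0, 1.0], index=surv.data.index), surv)

    def test_power_against_planted_hazard(self):
        """High-group hazard ratio 3 at n = 200: log-rank p < 0.05 in >=90%
        of seeds."""
        hits, n_seeds = 0, 30
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=200)
            hazard = 0.01 * np.exp(np.log(3.0) * (x > np.median(x)))
            times = rng.exponential(1.0 / hazard)
            surv = make_survival(times, np.ones(200, dtype=int))
            res = median_split_screen(pd.Series(x, index=surv.data.index), surv)
            hits += res.p_value < 0.05
        assert hits >= 0.9 * n_seeds


class TestCoxScreen:
    def test_type_i_error_controlled(self):
        """A covariate independent of the hazard is flagged in <= ~5% of
        seeds (binomial slack applied)."""
        flags, n_seeds = 0, 60
        for seed in range(n_seeds):
            rng = np.random.default_rng(seed)
            times = rng.exponential(100, 300)
            surv = make_survival(
                times, np.ones(300, dtype=int), x=rng.normal(size=300)
            )
            row = cox_screen(surv, ["x"], mode="univariate")[0]
            flags += row.risk_factor
        assert flags <= 0.12 * n_seeds  # 5% nominal + binomial slack

    def test_all_constant_unestimable(self):
        surv = make_survival([10, 20, 30], [1, 1, 1], x=[1.0, 1.0, 1.0])
        rows = cox_screen(surv, ["x"])
        assert all(not r.estimable for r in rows)

    def test_multivariate_joint_fit(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=200)
        hz = 0.01 * np.exp(0.8 * x)
        times = rng.exponential(1.0 / hz)
        surv = make_survival(times, np.ones(200, dtype=int), x=x,
                             z=rng.normal(size=200))
        rows = cox_screen(surv, ["x", "z"], mode="multivariate")
        by = {r.covariate: r for r in rows}
        assert by["x"].risk_factor and by["x"].hazard_ratio > 1
        assert by["x"].ci_low <= by["x"].hazard_ratio <= by["x"].ci_high

    def test_univariate_binary_covariate_tracks_logrank(self):
        """Cox on one binary covariate and the log-rank test agree within a
        factor of 2 in p-value (asymptotically equivalent tests)."""
        rng = np.random.default_rng(5)
        g = np.array([0] * 60 + [1] * 60)
        hz = 0.01 * np.exp(0.9 * g)
        times = rng.exponential(1.0 / hz)
        surv = make_survival(times, np.ones(120, dtype=int), g=g.astype(float))
        row = cox_screen(surv, ["g"])[0]
        _, p_lr = logrank_test(times[g == 0], np.ones(60), times[g == 1], np.ones(60))
        assert 0.5 < (row.p_value + 1e-12) / (p_lr + 1e-12) < 2.0


class TestStratifiedScreen:
    def _fixture(self, seed=0, stratum_effect=True):
        rng = np.random.default_rng(seed)
        n = 300
        strat = pd.Series(["young"] * (n // 2) + ["old"] * (n // 2))
        x = rng.normal(size=n)
        loghr = np.where(
            (strat == "young") if stratum_effect else np.ones(n, bool),
            np.log(3.0) * (x > np.median(x)),
            0.0,
        )
        times = rng.exponential(1.0 / (0.01 * np.exp(loghr)))
        surv = make_survival(times, np.ones(n, dtype=int))
        strat.index = surv.data.index
        prof = pd.DataFrame({"prb": x}, index=surv.data.index)
        return prof, surv, strat

    def test_single_level_rejected(self):
        prof, surv, strat = self._fixture()
        with pytest.raises(ValueError, match="two"):
            stratified_prb_screen(prof, surv, strat * 0 + "all", ["prb"])

    def test_small_stratum_skipped_with_warning(self):
        prof, surv, strat = self._fixture()
        strat.iloc[:] = "big"
        strat.iloc[:2] = "tiny"
        with pytest.warns(UserWarning, match="tiny"):
            out = stratified_prb_screen(prof, surv, strat, ["prb"])
        assert set(out["stratum"]) == {"big"}

    def test_stratum_specific_effect_detected(self):
        """A hazard effect planted only in one stratum is significant there
        and not in the other, in most seeds."""
        hits, n_seeds = 0, 15
        for seed in range(n_seeds):
            prof, surv, strat = self._fixture(seed=seed)
            out = stratified_prb_screen(prof, surv, strat, ["prb"])
            sig = dict(zip(out["stratum"], out["significant"]))
            hits += sig["young"] and not sig["old"]
        assert hits >= 0.6 * n_seeds

    def test_identical_strata_identical_p(self):
        prof, surv, strat = self._fixture(seed=9, stratum_effect=False)
        half = len(strat) // 2
        prof2 = pd.concat([prof.iloc[:half], prof.iloc[:half].set_axis(
            prof.index[half:])])
        surv2 = make_survival(
            list(surv.os_days.iloc[:half]) * 2, list(surv.event.iloc[:half]) * 2
        )
        prof2.index = surv2.data.index
        strat2 = pd.Series(["a"] * half + ["b"] * half, index=surv2.data.index)
        out = stratified_prb_screen(prof2, surv2, strat2, ["prb"])
        ps = out["p_value"].to_numpy()
        assert ps[0] == pytest.approx(ps[1], abs=1e-12)
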