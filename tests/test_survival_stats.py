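"""Kaplan-Meier, log-rank, Cox and Fisher: worked examples, independent
oracles, and cross-checks against reference implementations."""

import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import stats

from rwevents import (
    DegenerateInformationError,
    cox_partial_loglik,
    cox_ph,
    fisher_exact,
    km_estimate,
    km_plot_data,
    logrank_test,
)

from conftest import surv


def simulate_cox_cohort(rng, n=500, log_hr=0.7, base_rate=1 / 100, censor_rate=1 / 300):
    x = (np.arange(n) % 2).astype(float)
    t_event = rng.exponential(1.0 / (base_rate * np.exp(log_hr * x)))
    t_cens = rng.exponential(1.0 / censor_rate, n)
    t = np.minimum(t_event, t_cens)
    e = (t_event <= t_cens).astype(int)
    return [surv(f"p{i}", t[i], e[i], group="B" if x[i] else "A",
                 cov={"x": x[i]}) for i in range(n)]


class TestKaplanMeier:
    def test_all_censored_survival_one(self):
        curve = km_estimate([surv(f"p{i}", t, 0) for i, t in enumerate([5, 9, 12])])
        assert len(curve.event_times) == 0 and curve.median is None

    def test_three_events_product_limit(self):
        curve = km_estimate([surv(f"p{i}", t, 1) for i, t in enumerate([1, 2, 3])])
        assert np.allclose(curve.survival, [2 / 3, 1 / 3, 0])
        assert curve.median == 2
        assert list(curve.n_at_risk) == [3, 2, 1]

    def test_censoring_between_events(self):
        recs = [surv("a", 1, 1), surv("b", 2, 0), surv("c", 3, 1)]
        curve = km_estimate(recs)
        assert list(curve.event_times) == [1, 3]
        assert np.allclose(curve.survival, [2 / 3, 0])
        assert list(curve.n_at_risk) == [3, 1]

    def test_censored_tied_with_event_counts_at_risk(self):
        recs = [surv("a", 5, 1), surv("b", 5, 0), surv("c", 9, 1)]
        curve = km_estimate(recs)
        # at t=5 three at risk, one event -> S=2/3; at t=9 one at risk -> 0
        assert np.allclose(curve.survival, [2 / 3, 0])

    def test_matches_empirical_survival_without_censoring(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 40))
            t = np.ceil(rng.exponential(50, n))
            curve = km_estimate([surv(f"p{i}", v, 1) for i, v in enumerate(t)])
            for tt, ss in zip(curve.event_times, curve.survival):
                assert ss == pytest.approx(np.mean(t > tt), abs=1e-12)

    def test_agrees_with_lifelines(self, rng):
        lifelines = pytest.importorskip("lifelines")
        for _ in range(100):
            n = int(rng.integers(5, 60))
            t = np.round(rng.exponential(100, n), 1) + 0.1
            e = rng.integers(0, 2, n)
            if e.sum() == 0:
                e[0] = 1
            curve = km_estimate([surv(f"p{i}", t[i], e[i]) for i in range(n)])
            kmf = lifelines.KaplanMeierFitter().fit(t, e)
            ref = kmf.survival_function_at_times(curve.event_times).to_numpy()
            assert np.max(np.abs(curve.survival - ref)) < 1e-12

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_plot_data_reconstructs_curve(self):
        recs = [surv("a", 1, 1), surv("b", 2, 0), surv("c", 3, 1)]
        curve = km_estimate(recs, label="g")
        steps = km_plot_data([curve])
        sub = steps[steps["kind"] == "step"]
        for tt, ss in zip(curve.event_times, curve.survival):
            at = sub[(sub["time"] == tt)]["survival"].min()
            assert at == pytest.approx(ss)
        assert (steps[steps["kind"] == "censor"]["time"] == [2.0]).all()


def logrank_oracle_2group(records):
    """Direct O/E/V computation from 2x2 hypergeometric moments per pooled
    event time (two groups)."""
    groups = sorted({r.group for r in records})
    o = e = v = 0.0
    for t in sorted({r.time for r in records if r.event}):
        n1 = sum(1 for r in records if r.time >= t and r.group == groups[0])
        n2 = sum(1 for r in records if r.time >= t and r.group == groups[1])
        d1 = sum(1 for r in records if r.time == t and r.event and r.group == groups[0])
        d = sum(1 for r in records if r.time == t and r.event)
        n = n1 + n2
        o += d1
        e += d * n1 / n
        if n > 1:
            v += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return (o - e) ** 2 / v


class TestLogRank:
    def test_identical_groups_statistic_zero(self):
        recs = []
        for g in ("A", "B"):
            recs += [surv(f"{g}{i}", t, e, group=g)
                     for i, (t, e) in enumerate([(5, 1), (9, 0), (12, 1)])]
        res = logrank_test(recs)
        assert res.statistic == pytest.approx(0, abs=1e-12)
        assert res.p_value == pytest.approx(1)

    def test_four_event_example_matches_hand_oracle(self):
        recs = [surv("a1", 1, 1, "A"), surv("a2", 2, 1, "A"),
                surv("b1", 10, 1, "B"), surv("b2", 11, 1, "B")]
        res = logrank_test(recs)
        assert res.statistic == pytest.approx(logrank_oracle_2group(recs), rel=1e-12)
        assert sum(res.observed.values()) == pytest.approx(sum(res.expected.values()))

    def test_single_group_errors(self):
        with pytest.raises(ValueError):
            logrank_test([surv("a", 1, 1, "A"), surv("b", 2, 1, "A")])

    def test_zero_events_errors(self):
        with pytest.raises(ValueError):
            logrank_test([surv("a", 1, 0, "A"), surv("b", 2, 0, "B")])

    def test_label_swap_invariance(self, rng):
        recs = simulate_cox_cohort(rng, n=60)
        res = logrank_test(recs)
        swapped = [surv(r.patient_id, r.time, r.event,
                        group=("A" if r.group == "B" else "B")) for r in recs]
        assert logrank_test(swapped).statistic == pytest.approx(res.statistic, rel=1e-9)

    def test_random_cohorts_match_oracle(self, rng):
        for _ in range(30):
            recs = simulate_cox_cohort(rng, n=int(rng.integers(10, 50)))
            if sum(r.event for r in recs) == 0 or len({r.group for r in recs}) < 2:
                continue
            res = logrank_test(recs)
            assert res.statistic == pytest.approx(logrank_oracle_2group(recs), rel=1e-9)

    def test_equals_cox_score_test_without_ties(self, rng):
        """In the 2-group no-ties limit the log-rank statistic equals the
        squared z of the Cox score test at beta = 0."""
        from rwevents.survival_stats import _cox_loglik_grad_hess

        t = rng.exponential(100, 40)  # continuous: no ties a.s.
        x = (np.arange(40) % 2).astype(float)
        recs = [surv(f"p{i}", t[i], 1, group="B" if x[i] else "A",
                     cov={"x": x[i]}) for i in range(40)]
        order = np.argsort(t)
        _, grad, info = _cox_loglik_grad_hess(
            np.zeros(1), t[order], np.ones(40, dtype=int),
            x[order].reshape(-1, 1), "breslow")
        score_chi2 = grad[0] ** 2 / info[0, 0]
        assert logrank_test(recs).statistic == pytest.approx(score_chi2, rel=1e-9)


def grid_search_beta(records, lo=-3.0, hi=3.0, step=1e-4):
    """Independent maximizer of the partial likelihood for one binary
    covariate: closed-form risk sums evaluated over a dense grid."""
    t = np.array([r.time for r in records])
    e = np.array([r.event for r in records], dtype=int)
    x = np.array([r.covariates["x"] for r in records])
    ev_t = np.sort(t[e == 1])
    n1 = np.array([np.sum((t >= tt) & (x == 1)) for tt in ev_t], dtype=float)
    n0 = np.array([np.sum((t >= tt) & (x == 0)) for tt in ev_t], dtype=float)
    x_ev = np.array([x[(t == tt) & (e == 1)][0] for tt in ev_t])
    grid = np.arange(lo, hi + step / 2, step)
    best_beta, best_ll = None, -np.inf
    for chunk in np.array_split(grid, 20):
        ll = (np.outer(x_ev, chunk).sum(axis=0)
              - np.log(n0[:, None] + n1[:, None] * np.exp(chunk[None, :])).sum(axis=0))
        j = int(np.argmax(ll))
        if ll[j] > best_ll:
            best_ll, best_beta = ll[j], chunk[j]
    return best_beta


class TestCox:
    def test_symmetric_groups_beta_zero(self):
        recs = []
        for xval in (0.0, 1.0):
            recs += [surv(f"g{xval}i{i}", t, e, cov={"x": xval})
                     for i, (t, e) in enumerate([(3, 1), (7, 0), (11, 1)])]
        fit = cox_ph(recs, ["x"])
        assert fit.coefficients["x"] == pytest.approx(0, abs=1e-10)
        assert fit.converged

    def test_recovery_and_grid_search_oracle(self, rng):
        recs = simulate_cox_cohort(rng, n=500, log_hr=0.7)
        fit = cox_ph(recs, ["x"])
        beta, se = fit.coefficients["x"], fit.standard_errors["x"]
        assert abs(beta - 0.7) < 3 * se
        assert abs(beta - grid_search_beta(recs)) <= 1e-4
        # the maximum dominates the null
        ll_hat = fit.log_partial_likelihood
        t = np.array([r.time for r in recs]); e = np.array([r.event for r in recs])
        x = np.array([[r.covariates["x"]] for r in recs])
        assert ll_hat >= cox_partial_loglik(np.zeros(1), t, e, x)

    def test_constant_covariate_errors(self):
        recs = [surv(f"p{i}", t, 1, cov={"x": 1.0}) for i, t in enumerate([1, 2, 3])]
        with pytest.raises(DegenerateInformationError):
            cox_ph(recs, ["x"])

    def test_complete_separation_flagged_not_raised(self):
        # all x=1 fail first: likelihood maximized at beta -> +inf
        recs = [surv(f"a{i}", t, 1, cov={"x": 1.0}) for i, t in enumerate([1, 2, 3, 4])]
        recs += [surv(f"b{i}", t, 1, cov={"x": 0.0}) for i, t in enumerate([10, 11, 12, 13])]
        fit = cox_ph(recs, ["x"])
        assert not fit.converged

    @pytest.mark.parametrize("ties", ["breslow", "efron"])
    def test_matches_lifelines(self, rng, ties):
        lifelines = pytest.importorskip("lifelines")
        import pandas as pd

        n = 150
        x = rng.integers(0, 2, n).astype(float)
        z = rng.normal(size=n)
        t = np.ceil(rng.exponential(80 * np.exp(-0.6 * x + 0.3 * z)))  # day ties
        e = (rng.uniform(size=n) < 0.8).astype(int)
        recs = [surv(f"p{i}", t[i], e[i], cov={"x": x[i], "z": z[i]})
                for i in range(n)]
        fit = cox_ph(recs, ["x", "z"], ties_method=ties)
        df = pd.DataFrame({"t": t, "e": e, "x": x, "z": z})
        # lifelines implements Efron tie handling
        if ties == "efron":
            cph = lifelines.CoxPHFitter().fit(df, "t", "e")
            for c in ("x", "z"):
                assert fit.coefficients[c] == pytest.approx(cph.params_[c], abs=1e-6)
                assert fit.standard_errors[c] == pytest.approx(
                    cph.standard_errors_[c], abs=1e-6)
        else:
            # Breslow and Efron agree in direction and roughly in size
            cph = lifelines.CoxPHFitter().fit(df, "t", "e")
            for c in ("x", "z"):
                assert np.sign(fit.coefficients[c]) == np.sign(cph.params_[c])
        assert fit.converged

    def test_hazard_ratio_and_ci_consistency(self, rng):
        recs = simulate_cox_cohort(rng, n=120)
        fit = cox_ph(recs, ["x"])
        b, se = fit.coefficients["x"], fit.standard_errors["x"]
        assert fit.hazard_ratios["x"] == pytest.approx(math.exp(b))
        assert fit.ci95["x"] == pytest.approx((b - 1.96 * se, b + 1.96 * se))


def fisher_enumeration_oracle(a, b, c, d):
    """Two-sided p by exact rational enumeration of all tables with the
    observed margins."""
    r1, r2, c1, n = a + b, c + d, a + c, a + b + c + d
    denom = math.comb(n, c1)
    p_obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    total = Fraction(0)
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        p_x = Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), denom)
        if p_x <= p_obs:
            total += p_x
    return total


class TestFisher:
    def test_uniform_table(self):
        res = fisher_exact([[1, 1], [1, 1]])
        assert res.odds_ratio == 1 and res.p_value == 1

    def test_three_one_example(self):
        res = fisher_exact([[3, 1], [1, 3]])
        assert res.p_value == pytest.approx(34 / 70)
        assert res.odds_ratio == 9

    def test_diagonal_table_infinite_or(self):
        res = fisher_exact([[2, 0], [0, 2]])
        assert math.isinf(res.odds_ratio)
        assert res.p_value == pytest.approx(float(fisher_enumeration_oracle(2, 0, 0, 2)))
        assert res.p_value == pytest.approx(1 / 3)

    def test_negative_cell_errors(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [1, 1]])

    def test_matches_scipy_on_random_tables(self, rng):
        for _ in range(200):
            a, b, c, d = rng.integers(0, 25, 4)
            if a + b + c + d == 0:
                continue
            ours = fisher_exact([[a, b], [c, d]]).p_value
            ref = stats.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)
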