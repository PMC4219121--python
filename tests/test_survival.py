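"""Survival engine: KM, log-rank, Efron Cox, pooled queries.

Each estimator is checked against an independent route: naive-loop
oracles written straight from the textbook definitions, and the
reference implementations in lifelines.
"""

import numpy as np
import pandas as pd
import pytest

from survpool.cohorts import ValidationError, assemble_compendium
from survpool.stratify import QuerySpec
from survpool.survival import (
    cox_binary,
    efron_partial_loglik,
    km_estimate,
    logrank_test,
    pooled_query,
)

from conftest import make_clinical, make_cohort, random_survival


# ---------------------------------------------------------------------------
# naive oracles
# ---------------------------------------------------------------------------

def km_oracle(times, events):
    """Product-limit estimate by explicit per-event-time loops."""
    out = []
    s = 1.0
    for u in sorted({t for t, e in zip(times, events) if e == 1}):
        n_at_risk = sum(1 for t in times if t >= u)
        d = sum(1 for t, e in zip(times, events) if t == u and e == 1)
        s *= 1.0 - d / n_at_risk
        out.append((u, s, n_at_risk))
    return out

def logrank_oracle(times, events, group):
    """O-E and variance sums by direct per-event-time tabulation."""
    o_minus_e = 0.0
    var = 0.0
    for u in sorted({t for t, e in zip(times, events) if e == 1}):
        at = [(t, e, g) for t, e, g in zip(times, events, group) if t >= u]
        n = len(at)
        n1 = sum(1 for t, e, g in at if g)
        d = sum(1 for t, e, g in at if t == u and e == 1)
        d1 = sum(1 for t, e, g in at if t == u and e == 1 and g)
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def efron_loglik_oracle(beta, times, events, group):
    """Efron partial log-likelihood written out with explicit loops."""
    ll = 0.0
    for u in sorted({t for t, e in zip(times, events) if e == 1}):
        risk = [g for t, e, g in zip(times, events, group) if t >= u]
        deaths = [g for t, e, g in zip(times, events, group) if t == u and e == 1]
        r_sum = sum(np.exp(beta * g) for g in risk)
        d_sum = sum(np.exp(beta * g) for g in deaths)
        ll += beta * sum(deaths)
        d = len(deaths)
        for l in range(d):
            ll -= np.log(r_sum - (l / d) * d_sum)
    return ll


def cox_beta_oracle(times, events, group):
    """Maximize the written-out Efron likelihood independently: coarse grid
    to bracket the stationary point, then root-finding on the numerical
    derivative."""
    from scipy.optimize import brentq

    h = 1e-6

    def deriv(b):
        return (efron_loglik_oracle(b + h, times, events, group)
                - efron_loglik_oracle(b - h, times, events, group)) / (2 * h)

    grid = np.linspace(-8, 8, 33)
    vals = [deriv(b) for b in grid]
    for lo, hi, flo, fhi in zip(grid, grid[1:], vals, vals[1:]):
        if flo > 0 >= fhi:
            return brentq(deriv, lo, hi, xtol=1e-13)
    raise ValueError("monotone likelihood")


def _instance(rng, n):
    t, e = random_survival(rng, n)
    g = rng.integers(0, 2, n).astype(bool)
    return t, e, g


def _valid(t, e, g):
    return e.sum() >= 2 and g.any() and not g.all() and e[g].sum() > 0 and e[~g].sum() > 0


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

class TestKM:
    def test_censored_only_survival_one(self):
        km = km_estimate([5.0, 10.0], [0, 0])
        assert km.event_times.size == 0
        assert km.evaluate(7.0) == 1.0

    def test_all_events_closed_form(self):
        km = km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
        np.testing.assert_allclose(km.survival_prob, [2 / 3, 1 / 3, 0.0])
        np.testing.assert_array_equal(km.at_risk, [3, 2, 1])

    def test_matches_oracle_and_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(10)
        for _ in range(25):
            t, e = random_survival(rng, int(rng.integers(5, 50)))
            if e.sum() == 0:
                continue
            km = km_estimate(t, e)
            oracle = km_oracle(t, e)
            np.testing.assert_allclose(km.event_times, [u for u, _, _ in oracle])
            np.testing.assert_allclose(km.survival_prob, [s for _, s, _ in oracle], atol=1e-12)
            np.testing.assert_array_equal(km.at_risk, [n for _, _, n in oracle])
            kmf = KaplanMeierFitter().fit(t, e)
            for u, s, _ in oracle:
                assert km.evaluate(u) == pytest.approx(kmf.predict(u), abs=1e-10)

    def test_time_scaling_invariance(self):
        rng = np.random.default_rng(11)
        t, e = random_survival(rng, 30)
        a, b = km_estimate(t, e), km_estimate(3.5 * t, e)
        np.testing.assert_allclose(b.event_times, 3.5 * a.event_times)
        np.testing.assert_allclose(b.survival_prob, a.survival_prob)

    def test_empty_input_error(self):
        with pytest.raises(ValidationError):
            km_estimate([], [])


# ---------------------------------------------------------------------------
# log-rank
# ---------------------------------------------------------------------------

class TestLogrank:
    def test_identical_groups_null(self):
        t = [1.0, 2.0, 3.0, 1.0, 2.0, 3.0]
        e = [1, 1, 0, 1, 1, 0]
        g = [True, True, True, False, False, False]
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_empty_group_identified(self):
        with pytest.raises(ValidationError, match="high group"):
            logrank_test([1.0, 2.0], [1, 1], [False, False])
        with pytest.raises(ValidationError, match="low group"):
            logrank_test([1.0, 2.0], [1, 1], [True, True])

    def test_matches_tabulation_oracle_and_lifelines(self):
        from lifelines.statistics import logrank_test as ll_logrank

        rng = np.random.default_rng(12)
        checked = 0
        while checked < 25:
            t, e, g = _instance(rng, int(rng.integers(8, 50)))
            if not _valid(t, e, g):
                continue
            chi2, p = logrank_test(t, e, g)
            assert chi2 == pytest.approx(logrank_oracle(t, e, g), abs=1e-10)
            r = ll_logrank(t[g], t[~g], e[g], e[~g])
            assert chi2 == pytest.approx(r.test_statistic, abs=1e-10)
            assert p == pytest.approx(r.p_value, abs=1e-12)
            checked += 1

    def test_label_exchange_invariance(self):
        rng = np.random.default_rng(13)
        t, e, g = _instance(rng, 40)
        chi2a, pa = logrank_test(t, e, g)
        chi2b, pb = logrank_test(t, e, ~g)
        assert chi2a == pytest.approx(chi2b, abs=1e-12)
        assert pa == pytest.approx(pb, abs=1e-12)


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

class TestCox:
    def test_matches_brute_force_likelihood_oracle(self):
        rng = np.random.default_rng(14)
        checked = 0
        while checked < 20:
            t, e, g = _instance(rng, int(rng.integers(10, 40)))
            if not _valid(t, e, g):
                continue
            fit = cox_binary(t, e, g)
            assert fit.converged
            assert fit.beta == pytest.approx(cox_beta_oracle(t, e, g), abs=1e-8)
            checked += 1

    def test_lifelines_agrees_to_its_own_tolerance(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(15)
        checked = 0
        while checked < 8:
            t, e, g = _instance(rng, 35)
            if not _valid(t, e, g):
                continue
            fit = cox_binary(t, e, g)
            cph = CoxPHFitter().fit(
                pd.DataFrame({"t": t, "e": e, "x": g.astype(int)}), "t", "e"
            )
            assert fit.beta == pytest.approx(cph.params_["x"], abs=1e-3)
            assert fit.se == pytest.approx(cph.standard_errors_["x"], abs=1e-3)
            checked += 1

    def test_vectorized_loglik_equals_naive(self):
        rng = np.random.default_rng(16)
        t, e, g = _instance(rng, 30)
        for beta in (-1.0, 0.0, 0.7):
            assert efron_partial_loglik(beta, t, e, g) == pytest.approx(
                efron_loglik_oracle(beta, t, e, g), abs=1e-10
            )

    def test_label_flip_symmetry(self):
        rng = np.random.default_rng(17)
        t, e, g = _instance(rng, 40)
        a, b = cox_binary(t, e, g), cox_binary(t, e, ~g)
        assert a.hr * b.hr == pytest.approx(1.0, abs=1e-9)
        assert a.ci_low == pytest.approx(1.0 / b.ci_high, rel=1e-9)
        assert a.ci_high == pytest.approx(1.0 / b.ci_low, rel=1e-9)

    def test_null_hr_near_one_large_sample(self):
        rng = np.random.default_rng(18)
        t, e = random_survival(rng, 3000, censoring=0.3)
        g = rng.integers(0, 2, 3000).astype(bool)
        fit = cox_binary(t, e, g)
        assert fit.hr == pytest.approx(1.0, abs=0.12)
        assert fit.ci_low < 1.0 < fit.ci_high

    def test_separation_flagged_not_crashed(self):
        # high group all fails before any low-group event: monotone likelihood
        t = np.array([1.0, 2.0, 3.0, 10.0, 11.0, 12.0])
        e = np.array([1, 1, 1, 1, 1, 1])
        g = np.array([True, True, True, False, False, False])
        fit = cox_binary(t, e, g)
        assert fit.flagged
        assert fit.ci_high == np.inf

    def test_preconditions(self):
        with pytest.raises(ValidationError, match="group is empty"):
            cox_binary([1.0, 2.0], [1, 1], [True, True])
        with pytest.raises(ValidationError, match="2 events"):
            cox_binary([1.0, 2.0], [1, 0], [True, False])


# ---------------------------------------------------------------------------
# pooled queries
# ---------------------------------------------------------------------------

class TestPooledQuery:
    def test_single_contributor_reduction(self, two_cohort_compendium):
        comp = two_cohort_compendium
        only_first = assemble_compendium([comp.cohorts[0]])
        # gene present only in cohort 1 of a two-cohort compendium
        import copy

        c2 = copy.deepcopy(comp.cohorts[1])
        c2.expression = c2.expression.drop(index="101")
        mixed = assemble_compendium([comp.cohorts[0], c2])
        spec = QuerySpec(genes=("101",))
        a = pooled_query(mixed, spec)
        b = pooled_query(only_first, spec)
        assert a.hr == b.hr and a.logrank_p == b.logrank_p and a.n == b.n

    def test_deterministic(self, two_cohort_compendium):
        spec = QuerySpec(genes=("102",))
        a = pooled_query(two_cohort_compendium, spec)
        b = pooled_query(two_cohort_compendium, spec)
        assert a.to_dict() == b.to_dict()
        np.testing.assert_array_equal(a.km_high.survival_prob, b.km_high.survival_prob)

    def test_pooling_copies_keeps_hr_shrinks_ci(self, two_cohort_compendium):
        import copy

        comp = two_cohort_compendium
        one = assemble_compendium([comp.cohorts[0]])
        copies = []
        for k in range(3):
            c = copy.deepcopy(comp.cohorts[0])
            c.dataset_id = f"copy{k}"
            c.expression.columns = [f"copy{k}_{s}" for s in c.expression.columns]
            c.clinical.index = pd.Index(c.expression.columns, name="sample_id")
            copies.append(c)
        tripled = assemble_compendium(copies)
        spec = QuerySpec(genes=("101",))
        a, b = pooled_query(one, spec), pooled_query(tripled, spec)
        # replicating samples manufactures tied event times, which Efron's
        # correction down-weights; the estimate is preserved only up to that
        # tie perturbation, while the CI must strictly shrink
        assert np.log(b.hr) == pytest.approx(np.log(a.hr), abs=0.05)
        assert (b.hr_ci_high - b.hr_ci_low) < (a.hr_ci_high - a.hr_ci_low)

    def test_multi_gene_all_high_vs_rest(self, two_cohort_compendium):
        res = pooled_query(two_cohort_compendium, QuerySpec(genes=("101", "102")))
        # all-high group must be smaller than either single-gene high group
        single = pooled_query(two_cohort_compendium, QuerySpec(genes=("101",)))
        assert res.n_high <= single.n_high
        assert res.n == res.n_high + res.n_low

    def test_missing_endpoint_samples_excluded(self):
        clin = make_clinical(
            [f"s{i}" for i in range(8)],
            os_time=[10, 20, 30, 40, 50, 60, np.nan, np.nan],
            os_event=[1, 1, 1, 1, 1.0, 1, np.nan, np.nan],
        )
        c = make_cohort("A", {"g": np.arange(8.0)}, clin)
        res = pooled_query(assemble_compendium([c]), QuerySpec(genes=("g",)))
        assert res.n == 6

    def test_unknown_gene_informative_error(self, two_cohort_compendium):
        with pytest.raises(ValidationError, match="no cohort contributes"):
            pooled_query(two_cohort_compendium, QuerySpec(genes=("zzz",)))

    def test_stratified_mode_close_to_unstratified_when_homogeneous(
        self, planted_compendium
    ):
        comp, _, _ = planted_compendium
        a = pooled_query(comp, QuerySpec(genes=("10004",)))
        b = pooled_query(comp, QuerySpec(genes=("10004",), stratified=True))
        assert np.log(b.hr) == pytest.approx(np.log(a.hr), abs=0.15)

    def test_planted_effect_recovered(self, planted_compendium):
        comp, truth, _ = planted_compendium
        res = pooled_query(comp, QuerySpec(genes=("10004",)))
        true_hr = float(np.exp(truth.set_index("entity").loc["10004", "log_hr"]))
        assert res.hr_ci_low <= true_hr <= res.hr_ci_high
        assert res.logrank_p < 1e-4

    def test_logrank_null_calibration(self):
        """With group labels independent of survival, log-rank rejects at
        ~5%: fraction over 400 simulated two-group queries within 5% +/- 3%."""
        rng = np.random.default_rng(19)
        hits = 0
        n_sim = 400
        for _ in range(n_sim):
            t, e = random_survival(rng, 60, censoring=0.3)
            g = rng.integers(0, 2, 60).astype(bool)
            if not _valid(t, e, g):
                n_sim -= 1
                continue
            _, p = logrank_test(t, e, g)
            hits += p < 0.05
        assert abs(hits / n_sim - 0.05) < 0.03
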