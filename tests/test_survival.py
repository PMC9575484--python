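"""Median-split log-rank and univariate Cox against independent oracles."""

import numpy as np
import pandas as pd
import pytest

from rbpnet.io import RunConfig
from rbpnet.survival import (_cox_loglik, cox_univariate, km_logrank,
                             km_table, survival_screen)

from conftest import make_annotation, make_matrix


def ann_from(times, events, sample_ids=None):
    n = len(times)
    return make_annotation(["high"] * n, os_time=times, os_event=events,
                           sample_ids=sample_ids)


class TestLogRank:
    def test_identical_groups_give_zero_statistic(self):
        # expression split puts (1,2,3)/(1,2,3) with equal event patterns in
        # both groups: observed == expected at every event time
        expr = pd.Series([1, 1, 1, 2, 2, 2.0],
                         index=[f"s{i}" for i in range(1, 7)])
        ann = ann_from([1, 2, 3, 1, 2, 3], [1, 1, 1, 1, 1, 1])
        res = km_logrank(expr, ann)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_six_subject_worked_example(self):
        # groups A (low expr) die at 1,2,3; B (high expr) at 4,5,6; hand
        # risk-table arithmetic: O_A=3, E_A=0.5+0.4+0.25=1.15,
        # V=0.25+0.24+0.1875=0.6775 -> chi2 = (3-1.15)^2/0.6775
        expr = pd.Series([1, 1, 1, 2, 2, 2.0],
                         index=[f"s{i}" for i in range(1, 7)])
        ann = ann_from([1, 2, 3, 4, 5, 6], [1] * 6)
        res = km_logrank(expr, ann)
        assert res.statistic == pytest.approx((3 - 1.15) ** 2 / 0.6775,
                                              rel=1e-9)
        assert (res.n_high, res.n_low) == (3, 3)

    def test_ties_at_median_go_to_low_group(self):
        expr = pd.Series([1, 1, 1, 1, 5, 5.0],
                         index=[f"s{i}" for i in range(1, 7)])
        ann = ann_from([1, 2, 3, 4, 5, 6], [1] * 6)
        res = km_logrank(expr, ann)
        assert (res.n_high, res.n_low) == (2, 4)

    def test_all_censored_rejected(self):
        expr = pd.Series([1, 2, 3, 4.0], index=[f"s{i}" for i in range(1, 5)])
        with pytest.raises(ValueError, match="events"):
            km_logrank(expr, ann_from([1, 2, 3, 4], [0, 0, 0, 0]))

    def test_km_table_is_nonincreasing_step_function(self, rng):
        n = 40
        expr = pd.Series(rng.normal(size=n),
                         index=[f"s{i}" for i in range(1, n + 1)])
        ann = ann_from(rng.exponential(10, size=n).round(1),
                       rng.integers(0, 2, size=n).tolist(),
                       sample_ids=list(expr.index))
        tbl = km_table(expr, ann)
        for _, grp in tbl.groupby("group"):
            surv = grp.sort_values("time")["survival"].to_numpy()
            assert (np.diff(surv) <= 1e-12).all()
            assert surv[0] <= 1.0 + 1e-12


def grid_search_beta(x, t, e, ties="efron"):
    """Independent maximizer: dense grid over the literal partial likelihood."""
    grid = np.linspace(-5, 5, 100_001)
    lls = np.array([_cox_loglik(b, x, t, e, ties)[0] for b in grid])
    return grid[np.argmax(lls)]


def naive_partial_loglik_no_ties(beta, x, t, e):
    """Literal textbook partial likelihood, valid when all times differ."""
    ll = 0.0
    for i in range(len(t)):
        if e[i]:
            risk = [j for j in range(len(t)) if t[j] >= t[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * np.array(x)[risk])))
    return ll


class TestCox:
    def test_five_subject_toy_matches_grid_search(self, cfg):
        x = np.array([0.5, -1.0, 0.0, 2.0, 1.0])
        t = [3.0, 5.0, 7.0, 2.0, 9.0]
        e = [1, 1, 0, 1, 1]
        expr = pd.Series(x, index=[f"s{i}" for i in range(1, 6)])
        res = cox_univariate(expr, ann_from(t, e), cfg)
        beta_grid = grid_search_beta(x, np.array(t), np.array(e))
        assert res.beta == pytest.approx(beta_grid, abs=1e-4)
        assert res.converged

    def test_loglik_matches_textbook_formula_without_ties(self, rng):
        x = rng.normal(size=8)
        t = rng.permutation(np.arange(1.0, 9.0))
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1])
        for beta in (-0.7, 0.0, 1.3):
            for ties in ("efron", "breslow"):
                ll, _, _ = _cox_loglik(beta, x, t, e, ties)
                assert ll == pytest.approx(
                    naive_partial_loglik_no_ties(beta, x, t, e), rel=1e-10)

    def test_matches_lifelines_with_ties(self, rng, cfg):
        from lifelines import CoxPHFitter
        n = 60
        x = rng.normal(size=n)
        t = rng.integers(1, 15, size=n).astype(float)  # heavy ties
        e = rng.integers(0, 2, size=n)
        if e.sum() < 2:
            e[:2] = 1
        expr = pd.Series(x, index=[f"s{i}" for i in range(n)])
        res = cox_univariate(expr, ann_from(t, e, sample_ids=list(expr.index)),
                             cfg)
        cph = CoxPHFitter()
        cph.fit(pd.DataFrame({"x": x, "t": t, "e": e}), "t", "e")
        assert res.beta == pytest.approx(cph.params_["x"], abs=1e-6)
        assert res.se == pytest.approx(cph.standard_errors_["x"], abs=1e-6)

    def test_efron_equals_breslow_without_ties(self, rng):
        n = 30
        x = rng.normal(size=n)
        t = rng.permutation(np.arange(1.0, n + 1.0))
        e = np.ones(n, dtype=int)
        expr = pd.Series(x, index=[f"s{i}" for i in range(n)])
        ann = ann_from(t, e, sample_ids=list(expr.index))
        b_e = cox_univariate(expr, ann, RunConfig(cox_tie_method="efron"))
        b_b = cox_univariate(expr, ann, RunConfig(cox_tie_method="breslow"))
        assert b_e.beta == pytest.approx(b_b.beta, abs=1e-9)

    def test_ci_brackets_hazard_ratio(self, rng, cfg):
        n = 50
        expr = pd.Series(rng.normal(size=n), index=[f"s{i}" for i in range(n)])
        ann = ann_from(rng.exponential(5, size=n), [1] * n,
                       sample_ids=list(expr.index))
        res = cox_univariate(expr, ann, cfg)
        assert res.ci_low <= res.hazard_ratio <= res.ci_high
        assert res.hazard_ratio > 0

    def test_perfect_separation_is_flagged_not_silent(self, cfg):
        # expression perfectly orders the death times: monotone likelihood
        x = np.arange(10.0)
        t = 10.0 - x
        expr = pd.Series(x, index=[f"s{i}" for i in range(10)])
        res = cox_univariate(expr, ann_from(t, [1] * 10,
                                            sample_ids=list(expr.index)), cfg)
        assert not res.converged
        assert res.diagnostic != ""

    def test_constant_expression_rejected(self, cfg):
        expr = pd.Series(np.ones(6), index=[f"s{i}" for i in range(6)])
        with pytest.raises(ValueError, match="constant"):
            cox_univariate(expr, ann_from([1, 2, 3, 4, 5, 6], [1] * 6,
                                          sample_ids=list(expr.index)), cfg)


def test_logrank_agrees_with_cox_on_binary_split(rng, cfg):
    """Score-test identity: log-rank p ~= Cox p for the dichotomized covariate."""
    n = 200
    x = rng.normal(size=n)
    t = rng.exponential(10 * np.exp(-0.1 * x))
    t = np.round(t, 6)  # effectively tie-free
    expr = pd.Series(x, index=[f"s{i}" for i in range(n)])
    ann = ann_from(t, [1] * n, sample_ids=list(expr.index))
    km = km_logrank(expr, ann)
    binary = pd.Series((x > np.median(x)).astype(float), index=expr.index)
    cox = cox_univariate(binary, ann, cfg)
    assert km.p_value == pytest.approx(cox.p_value, abs=1e-2)


def test_survival_screen_table(rng, cfg):
    n = 60
    m = make_matrix(rng.normal(size=(3, n)),
                    sample_ids=[f"s{i}" for i in range(n)])
    ann = ann_from(rng.exponential(10, size=n),
                   rng.integers(0, 2, size=n).tolist(),
                   sample_ids=[f"s{i}" for i in range(n)])
    tbl = survival_screen(m, ["g1", "g3"], ann, cfg)
    assert list(tbl.index) == ["g1", "g3"]
    assert {"logrank_p", "beta", "hazard_ratio", "cox_p"} <= set(tbl.columns)
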