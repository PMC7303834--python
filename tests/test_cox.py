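"""Distributed Cox regression: grids, risk-set sums, Efron/Breslow, survival."""

import math

import numpy as np
import pandas as pd
import pytest

from distreg import (
    Covariate,
    DDArray,
    DesignMatrix,
    ModelSpec,
    SiteDataset,
    aggregate_payloads,
    baseline_survival,
    collect_event_grid,
    compute_cox_intermediates,
    cox_fit_statistics,
    cox_score_information,
    newton_step,
    run_inprocess,
)
from distreg.cox import CoxEventGrid, CoxIterationPayload, grid_payload
from distreg.oracle import pooled_fit
from distreg.protocol import ConvergenceWarning, NoEventsError
from distreg.synthetic import default_spec, partition_fixed_dataset


def _design(values):
    values = np.asarray(values, dtype=float).reshape(len(values), -1)
    return DesignMatrix(
        columns=[f"x{i}" for i in range(values.shape[1])],
        values=values, intercept=False,
    )


def _grid(times, events):
    agg = aggregate_payloads(
        [grid_payload(np.asarray(t, float), np.asarray(e, float), f"s{i}", "d")
         for i, (t, e) in enumerate(zip(times, events))]
    )
    return collect_event_grid(agg)


# ---------------------------------------------------------------------------
# Event grid


def test_grid_union_merges_cross_site_ties():
    grid = _grid([[3, 5], [5, 9]], [[1, 1], [1, 1]])
    assert grid.times.tolist() == [3.0, 5.0, 9.0]
    assert grid.d.tolist() == [1.0, 2.0, 1.0]


def test_single_site_grid_is_its_event_times():
    grid = _grid([[4, 4, 7, 2]], [[1, 1, 1, 0]])
    assert grid.times.tolist() == [4.0, 7.0]
    assert grid.d.tolist() == [2.0, 1.0]


def test_two_site_grid_matches_pooled_enumeration():
    rng = np.random.default_rng(0)
    t1, t2 = rng.integers(1, 20, 15), rng.integers(1, 20, 12)
    e1, e2 = rng.binomial(1, 0.7, 15), rng.binomial(1, 0.7, 12)
    grid = _grid([t1, t2], [e1, e2])
    pooled_t = np.concatenate([t1, t2]).astype(float)
    pooled_e = np.concatenate([e1, e2])
    expected, counts = np.unique(pooled_t[pooled_e == 1], return_counts=True)
    assert np.array_equal(grid.times, expected)
    assert np.array_equal(grid.d, counts.astype(float))


def test_no_events_raises():
    with pytest.raises(NoEventsError):
        _grid([[5, 6]], [[0, 0]])


# ---------------------------------------------------------------------------
# Risk-set sums


def test_zero_beta_risk_sums_count_at_risk():
    X = np.array([[1.0], [2.0], [3.0], [4.0]])
    times = np.array([2.0, 3.0, 3.0, 5.0])
    events = np.array([1.0, 1.0, 1.0, 0.0])
    grid = _grid([times], [events])
    payload = compute_cox_intermediates(_design(X), times, events,
                                        np.zeros(1), grid)
    # at t=2 all 4 at risk; at t=3 three remain (censor at 5 still at risk)
    assert payload.s0.value.tolist() == [4.0, 3.0]
    assert payload.s1.value[:, 0].tolist() == [10.0, 9.0]
    assert payload.d.value.tolist() == [1.0, 2.0]
    assert payload.s.value[:, 0].tolist() == [1.0, 5.0]


def test_site_with_nobody_at_risk_contributes_zero():
    X = np.array([[1.0], [1.5]])
    times = np.array([2.0, 3.0])
    events = np.array([1.0, 1.0])
    grid = CoxEventGrid(times=np.array([2.0, 3.0, 50.0]),
                        d=np.array([1.0, 1.0, 1.0]))
    payload = compute_cox_intermediates(_design(X), times, events,
                                        np.zeros(1), grid)
    assert payload.s0.value[2] == 0.0


def test_risk_sums_match_per_subject_loop():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(10, 2))
    times = rng.integers(1, 8, 10).astype(float)
    events = rng.binomial(1, 0.8, 10).astype(float)
    beta = rng.normal(scale=0.4, size=2)
    grid = _grid([times], [events])
    payload = compute_cox_intermediates(_design(X), times, events, beta, grid)
    w = np.exp(X @ beta)
    for j, t in enumerate(grid.times):
        at_risk = times >= t
        assert payload.s0.value[j] == pytest.approx(w[at_risk].sum(), abs=1e-12)
        assert np.allclose(payload.s1.value[j],
                           (w[at_risk, None] * X[at_risk]).sum(axis=0),
                           rtol=0, atol=1e-12)
        dead = (times == t) & (events == 1)
        assert np.allclose(
            payload.s2d.value[j],
            sum(w[i] * np.outer(X[i], X[i]) for i in np.flatnonzero(dead))
            if dead.any() else np.zeros((2, 2)),
            rtol=0, atol=1e-12,
        )


# ---------------------------------------------------------------------------
# Score / information


def _agg_payload(Xs, ts, es, beta, grid):
    return CoxIterationPayload.from_payload(
        aggregate_payloads(
            [
                compute_cox_intermediates(
                    _design(X), np.asarray(t, float), np.asarray(e, float),
                    beta, grid,
                ).as_payload(f"s{i}", "d")
                for i, (X, t, e) in enumerate(zip(Xs, ts, es))
            ]
        )
    )


def test_efron_equals_breslow_without_ties():
    rng = np.random.default_rng(2)
    X = rng.normal(size=(9, 2))
    times = np.arange(1.0, 10.0)  # unique event times
    events = np.ones(9)
    beta = rng.normal(scale=0.3, size=2)
    grid = _grid([times], [events])
    agg = _agg_payload([X], [times], [events], beta, grid)
    for a, b in zip(
        cox_score_information(agg, grid, beta, "efron"),
        cox_score_information(agg, grid, beta, "breslow"),
    ):
        assert np.allclose(np.asarray(a), np.asarray(b), rtol=0, atol=0)


def test_single_event_loglik_is_log_risk_count():
    X = np.zeros((5, 1))
    times = np.array([3.0, 4.0, 5.0, 6.0, 7.0])
    events = np.array([1.0, 0.0, 0.0, 0.0, 0.0])
    grid = _grid([times], [events])
    agg = _agg_payload([X], [times], [events], np.zeros(1), grid)
    ll, _, _ = cox_score_information(agg, grid, np.zeros(1), "efron")
    assert ll == pytest.approx(-math.log(5.0), abs=1e-14)


def _brute_efron_ll(X, times, events, beta):
    eta = X @ beta
    w = np.exp(eta)
    ll = 0.0
    for t in np.unique(times[events == 1]):
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        risk = times >= t
        ll += eta[dead].sum()
        s0 = w[risk].sum()
        s0d = w[dead].sum()
        for k in range(d):
            ll -= math.log(s0 - k / d * s0d)
    return ll


def test_two_site_tie_matches_brute_force_and_numeric_gradient():
    X1 = np.array([[0.0, 1.0], [1.0, 0.0], [0.5, 0.5]])
    X2 = np.array([[1.0, 1.0], [0.0, 0.0], [2.0, -1.0]])
    t1 = np.array([2.0, 4.0, 4.0])  # tie at 4 within site 1
    t2 = np.array([4.0, 5.0, 7.0])  # and across sites
    e1 = np.array([1.0, 1.0, 1.0])
    e2 = np.array([1.0, 0.0, 1.0])
    beta = np.array([0.3, -0.2])
    grid = _grid([t1, t2], [e1, e2])
    agg = _agg_payload([X1, X2], [t1, t2], [e1, e2], beta, grid)
    ll, grad, _ = cox_score_information(agg, grid, beta, "efron")
    X = np.vstack([X1, X2])
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    assert ll == pytest.approx(_brute_efron_ll(X, times, events, beta),
                               abs=1e-12)
    h = 1e-6
    for j in range(2):
        step = np.zeros(2)
        step[j] = h
        numeric = (
            _brute_efron_ll(X, times, events, beta + step)
            - _brute_efron_ll(X, times, events, beta - step)
        ) / (2 * h)
        assert grad[j] == pytest.approx(numeric, abs=1e-8)


def test_zero_gradient_is_stationary():
    beta = np.array([0.1, 0.2])
    out = newton_step(np.zeros(2), -np.eye(2), beta, ["a", "b"])
    assert np.array_equal(out, beta)


def test_converged_estimates_match_lifelines_and_sksurv(small_pool):
    from lifelines import CoxPHFitter
    from sksurv.linear_model import CoxPHSurvivalAnalysis

    from distreg.protocol import expand_design

    spec = default_spec("cox", convergence_epsilon=1e-12, max_iterations=60)
    model = pooled_fit(spec, small_pool)
    design = expand_design(SiteDataset("pool", small_pool), spec)

    df = pd.DataFrame(design.values,
                      columns=[f"c{i}" for i in range(design.p)])
    df["T"] = small_pool["days_to_wl20"].to_numpy()
    df["E"] = small_pool["wl20_event"].to_numpy()
    cph = CoxPHFitter(penalizer=0.0)
    cph.fit(df, duration_col="T", event_col="E",
            fit_options={"precision": 1e-12, "max_steps": 500})
    assert np.allclose(model.beta, cph.params_.to_numpy(), rtol=0, atol=1e-8)
    assert np.allclose(model.se, cph.standard_errors_.to_numpy(),
                       rtol=0, atol=1e-8)
    assert -0.5 * model.fit_statistics["neg2_loglik"] == pytest.approx(
        cph.log_likelihood_, abs=1e-8
    )

    spec_b = default_spec("cox", tie_method="breslow",
                          convergence_epsilon=1e-12, max_iterations=60)
    model_b = pooled_fit(spec_b, small_pool)
    y = np.array(
        list(zip(small_pool["wl20_event"].astype(bool),
                 small_pool["days_to_wl20"])),
        dtype=[("e", bool), ("t", float)],
    )
    sk = CoxPHSurvivalAnalysis(ties="breslow", tol=1e-12, n_iter=200)
    sk.fit(design.values, y)
    assert np.allclose(model_b.beta, sk.coef_, rtol=0, atol=1e-8)


def test_monotone_likelihood_hits_iteration_cap():
    # covariate perfectly orders the event times: the MLE diverges
    df = pd.DataFrame(
        {
            "x": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            "t": [6.0, 5.0, 4.0, 3.0, 2.0, 1.0],
            "e": [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        }
    )
    spec = ModelSpec(family="cox", outcome="t", event="e",
                     covariates=[Covariate("x")], max_iterations=25)
    with pytest.warns(ConvergenceWarning):
        model = run_inprocess([SiteDataset("s1", df)], spec)
    assert not model.converged
    assert model.iterations == 25


def test_fit_statistic_identities():
    stats = cox_fit_statistics(loglik=-33108.8635, p=23, total_events=4199)
    assert stats["aic"] - stats["neg2_loglik"] == pytest.approx(46.0, abs=1e-9)
    assert stats["sbc"] - stats["neg2_loglik"] == pytest.approx(
        23 * math.log(4199), abs=1e-9
    )
    trivial = cox_fit_statistics(loglik=-5.0, p=0, total_events=3)
    assert trivial["aic"] == trivial["sbc"] == trivial["neg2_loglik"]


# ---------------------------------------------------------------------------
# Baseline survival


def test_zero_beta_baseline_steps():
    X = np.zeros((4, 1))
    times = np.array([1.0, 2.0, 3.0, 4.0])
    events = np.ones(4)
    grid = _grid([times], [events])
    agg = _agg_payload([X], [times], [events], np.zeros(1), grid)
    curve = baseline_survival(agg, grid, np.zeros(1), np.zeros(1))
    h0 = np.cumsum([1 / 4, 1 / 3, 1 / 2, 1 / 1])
    assert np.allclose(curve.survival, np.exp(-h0), rtol=0, atol=1e-14)
    assert curve.survival[0] < 1.0
    assert np.all(np.diff(curve.survival) < 0)


def test_median_is_first_time_survival_drops_to_half():
    # craft risk sums so S = (0.9, 0.6, 0.4) at times (10, 20, 30)
    target = np.array([0.9, 0.6, 0.4])
    h0 = -np.log(target)
    inc = np.diff(np.concatenate([[0.0], h0]))
    grid = CoxEventGrid(times=np.array([10.0, 20.0, 30.0]), d=np.ones(3))
    agg = CoxIterationPayload(
        n=3, s0=DDArray(1.0 / inc), s1=DDArray(np.zeros((3, 1))),
        s2=DDArray(np.zeros((3, 1, 1))), d=DDArray(np.ones(3)),
        s=DDArray(np.zeros((3, 1))), s0d=DDArray(np.zeros(3)),
        s1d=DDArray(np.zeros((3, 1))), s2d=DDArray(np.zeros((3, 1, 1))),
        iteration=0,
    )
    curve = baseline_survival(agg, grid, np.zeros(1), np.zeros(1))
    assert np.allclose(curve.survival, target, rtol=0, atol=1e-12)
    assert curve.median_time == 30.0


def test_median_undefined_when_survival_stays_high(small_pool):
    target = np.array([0.95, 0.9])
    h0 = -np.log(target)
    inc = np.diff(np.concatenate([[0.0], h0]))
    grid = CoxEventGrid(times=np.array([5.0, 6.0]), d=np.ones(2))
    agg = CoxIterationPayload(
        n=2, s0=DDArray(1.0 / inc), s1=DDArray(np.zeros((2, 1))),
        s2=DDArray(np.zeros((2, 1, 1))), d=DDArray(np.ones(2)),
        s=DDArray(np.zeros((2, 1))), s0d=DDArray(np.zeros(2)),
        s1d=DDArray(np.zeros((2, 1))), s2d=DDArray(np.zeros((2, 1, 1))),
        iteration=0,
    )
    curve = baseline_survival(agg, grid, np.zeros(1), np.zeros(1))
    assert curve.median_time is None


# ---------------------------------------------------------------------------
# End-to-end properties


def test_partition_invariance_both_tie_methods(small_pool):
    for tie in ("efron", "breslow"):
        spec = default_spec("cox", tie_method=tie)
        pooled = pooled_fit(spec, small_pool)
        for k, scheme in [(2, "contiguous"), (3, "round_robin"), (5, "random")]:
            parts = partition_fixed_dataset(small_pool, k, scheme, seed=3)
            model = run_inprocess(parts, spec)
            assert np.allclose(model.beta, pooled.beta, rtol=0, atol=1e-10)
            assert np.allclose(model.se, pooled.se, rtol=0, atol=1e-10)
            surv_d = model.diagnostics["survival"]["survival"]
            surv_p = pooled.diagnostics["survival"]["survival"]
            assert np.allclose(surv_d, surv_p, rtol=0, atol=1e-10)


def test_log_partial_likelihood_nondecreasing(small_sites, specs):
    model = run_inprocess(small_sites, specs["cox"])
    path = model.history["loglik"]
    assert all(b >= a - 1e-10 for a, b in zip(path, path[1:]))
    assert model.converged and model.iterations <= 25
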