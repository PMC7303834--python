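"""Distributed Cox proportional hazards regression.

Sites evaluate risk-set sums S0(t) = sum_{T_i >= t} w_i, S1(t) = sum x_i w_i,
S2(t) = sum x_i x_i' w_i (w_i = exp(x_i beta)) at every *global* event time,
plus per-time tie counts and tied-event sums, and ship only those.  The
analysis center assembles the Efron- or Breslow-corrected partial-likelihood
score and observed information and takes plain Newton-Raphson steps.  Because
risk-set sums are evaluated on the shared global grid, events tied across
sites form one tie group, and the distributed Efron result equals the pooled
Efron result.

Sharing the global grid discloses the set of event times (with multiplicities)
to every site — a far weaker disclosure than any individual row, but worth
noting when events are rare.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._accum import DDArray, dd_sum
from .protocol import (
    DesignMatrix,
    NoEventsError,
    NonIdentifiableError,
    Payload,
    RiskSetUnderflowError,
    solve_spd,
)

KIND_GRID = "cox.grid"
KIND_RISK = "cox.risk"


@dataclass
class CoxEventGrid:
    """Sorted distinct global event times with total tie counts."""

    times: np.ndarray  # strictly increasing
    d: np.ndarray  # ties per time, >= 1

    @property
    def n_times(self) -> int:
        return len(self.times)

    @property
    def total_events(self) -> int:
        return int(round(float(self.d.sum())))


def grid_payload(times, events, site_id: str, digest: str) -> Payload:
    """Site's distinct event times and tie counts (protocol round 0)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    ev_times = times[events == 1]
    uniq, counts = np.unique(ev_times, return_counts=True)
    return Payload(
        kind=KIND_GRID,
        site_id=site_id,
        iteration=0,
        digest=digest,
        n=len(times),
        keyed={"events": {float(t): float(c) for t, c in zip(uniq, counts)}},
    )


def collect_event_grid(agg: Payload) -> CoxEventGrid:
    """Union-merged global event grid from the aggregated round-0 payload."""
    merged = agg.keyed.get("events", {})
    if not merged:
        raise NoEventsError("no events at any site")
    times = np.array(sorted(merged), dtype=float)
    d = np.array([merged[t] for t in times], dtype=float)
    return CoxEventGrid(times=times, d=d)


@dataclass
class CoxIterationPayload:
    """Risk-set and tied-event sums on the global grid at one beta."""

    n: int
    s0: DDArray  # (T,)
    s1: DDArray  # (T, p)
    s2: DDArray  # (T, p, p)
    d: DDArray  # (T,) site-local tie counts
    s: DDArray  # (T, p) site-local event covariate sums
    s0d: DDArray  # (T,)
    s1d: DDArray  # (T, p)
    s2d: DDArray  # (T, p, p)
    iteration: int

    def as_payload(self, site_id: str, digest: str,
                   kind: str = KIND_RISK) -> Payload:
        return Payload(
            kind=kind,
            site_id=site_id,
            iteration=self.iteration,
            digest=digest,
            n=self.n,
            components={
                "s0": self.s0, "s1": self.s1, "s2": self.s2,
                "d": self.d, "s": self.s,
                "s0d": self.s0d, "s1d": self.s1d, "s2d": self.s2d,
            },
        )

    @classmethod
    def from_payload(cls, payload: Payload) -> "CoxIterationPayload":
        c = payload.components
        return cls(
            n=payload.n, s0=c["s0"], s1=c["s1"], s2=c["s2"],
            d=c["d"], s=c["s"], s0d=c["s0d"], s1d=c["s1d"], s2d=c["s2d"],
            iteration=payload.iteration,
        )


def compute_cox_intermediates(design: DesignMatrix, times, events, beta,
                              grid: CoxEventGrid,
                              iteration: int = 0) -> CoxIterationPayload:
    """Site risk-set sums at every global grid time.

    The risk set at t is {i : T_i >= t} — subjects censored exactly at t are
    still at risk at t.  Suffix sums are built from per-interval increments
    in compensated arithmetic, so aggregation over sites reproduces the
    pooled sums at full double precision.
    """
    X = design.values
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=float)
    n, p = X.shape
    T = grid.n_times
    beta = np.asarray(beta, dtype=np.float64)
    w = np.exp(X @ beta)
    wx = X * w[:, None]

    # bucket b = number of grid times <= T_i; row i is at risk at grid[j]
    # (0-based) iff b >= j + 1
    bucket = np.searchsorted(grid.times, times, side="right")

    s0 = [None] * T
    s1 = [None] * T
    s2 = [None] * T
    acc0 = DDArray.zeros(())
    acc1 = DDArray.zeros((p,))
    acc2 = DDArray.zeros((p, p))
    for j in range(T, 0, -1):
        rows = np.flatnonzero(bucket == j)
        if rows.size:
            Xr = X[rows]
            wr = w[rows]
            wxr = wx[rows]
            acc0 = acc0 + dd_sum(wr)
            acc1 = acc1 + dd_sum(wxr)
            acc2 = acc2 + dd_sum(wxr[:, :, None] * Xr[:, None, :])
        s0[j - 1] = acc0
        s1[j - 1] = acc1
        s2[j - 1] = acc2

    def stack(parts, shape):
        return DDArray(
            np.stack([q.hi for q in parts]) if parts else np.zeros((0,) + shape),
            np.stack([q.lo for q in parts]) if parts else np.zeros((0,) + shape),
        )

    d = np.zeros(T)
    s_ev = [DDArray.zeros((p,)) for _ in range(T)]
    s0d = [DDArray.zeros(()) for _ in range(T)]
    s1d = [DDArray.zeros((p,)) for _ in range(T)]
    s2d = [DDArray.zeros((p, p)) for _ in range(T)]
    ev_rows = np.flatnonzero(events == 1)
    if ev_rows.size:
        pos = np.searchsorted(grid.times, times[ev_rows])
        for j in np.unique(pos):
            rows = ev_rows[pos == j]
            if j >= T or grid.times[j] != times[rows[0]]:
                # event time absent from the global grid: protocol breach
                raise RiskSetUnderflowError(
                    f"site event time {times[rows[0]]} missing from global grid"
                )
            Xr = X[rows]
            wr = w[rows]
            wxr = wx[rows]
            d[j] = rows.size
            s_ev[j] = dd_sum(Xr)
            s0d[j] = dd_sum(wr)
            s1d[j] = dd_sum(wxr)
            s2d[j] = dd_sum(wxr[:, :, None] * Xr[:, None, :])

    return CoxIterationPayload(
        n=n,
        s0=stack(s0, ()),
        s1=stack(s1, (p,)),
        s2=stack(s2, (p, p)),
        d=DDArray(d),
        s=stack(s_ev, (p,)),
        s0d=stack(s0d, ()),
        s1d=stack(s1d, (p,)),
        s2d=stack(s2d, (p, p)),
        iteration=iteration,
    )


def cox_score_information(agg: CoxIterationPayload, grid: CoxEventGrid, beta,
                          tie_method: str = "efron"):
    """Log partial likelihood, score and Hessian from aggregated sums.

    Breslow: per event time, ll_t = s_t' beta - d_t ln S0; Efron replaces the
    risk-set sums by S_k - (k/d_t) S_k^D for k = 0..d_t-1, averaging the tied
    events out of the risk set.  With d_t = 1 the two coincide.
    """
    beta = np.asarray(beta, dtype=np.float64)
    p = len(beta)
    S0 = agg.s0.value
    S1 = agg.s1.value
    S2 = agg.s2.value
    D = agg.d.value
    S = agg.s.value
    S0D = agg.s0d.value
    S1D = agg.s1d.value
    S2D = agg.s2d.value

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))
    for j in range(grid.n_times):
        d_j = int(round(float(D[j])))
        if d_j < 1:
            raise NoEventsError(f"grid time {grid.times[j]} has no events")
        if S0[j] <= 0:
            raise RiskSetUnderflowError(
                f"non-positive risk-set sum at time {grid.times[j]}"
            )
        s_j = S[j]
        ll += float(s_j @ beta)
        if tie_method == "breslow" or d_j == 1:
            ll -= d_j * math.log(S0[j])
            m1 = S1[j] / S0[j]
            grad += s_j - d_j * m1
            hess -= d_j * (S2[j] / S0[j] - np.outer(m1, m1))
        else:
            frac = np.arange(d_j) / d_j  # k/d for k = 0..d-1
            r = S0[j] - frac * S0D[j]
            if np.any(r <= 0):
                raise RiskSetUnderflowError(
                    f"non-positive Efron denominator at time {grid.times[j]}"
                )
            ll -= float(np.log(r).sum())
            Z = S1[j][None, :] - frac[:, None] * S1D[j][None, :]
            Zr = Z / r[:, None]
            grad += s_j - Zr.sum(axis=0)
            inv_r = 1.0 / r
            hess -= (
                float(inv_r.sum()) * S2[j]
                - float((frac * inv_r).sum()) * S2D[j]
                - Zr.T @ Zr
            )
    return ll, grad, hess


def newton_step(gradient, hessian, beta, columns) -> np.ndarray:
    """beta + (-H)^{-1} g — plain Newton-Raphson on the partial likelihood."""
    step = solve_spd(-np.asarray(hessian), gradient, columns,
                     NonIdentifiableError)
    return np.asarray(beta, dtype=np.float64) + step


def cox_fit_statistics(loglik: float, p: int, total_events: int) -> dict:
    """-2 log L, AIC = -2logL + 2p, SBC = -2logL + p ln(events)."""
    neg2 = -2.0 * loglik
    return {
        "neg2_loglik": neg2,
        "aic": neg2 + 2 * p,
        "sbc": neg2 + p * math.log(total_events),
    }


@dataclass
class SurvivalCurve:
    """Breslow-estimator survival function at a reference covariate vector."""

    times: np.ndarray
    survival: np.ndarray
    reference: np.ndarray
    median_time: float | None

    def to_dict(self) -> dict:
        return {
            "times": self.times.tolist(),
            "survival": self.survival.tolist(),
            "reference": self.reference.tolist(),
            "median_time": self.median_time,
        }


def baseline_survival(agg: CoxIterationPayload, grid: CoxEventGrid, beta,
                      reference) -> SurvivalCurve:
    """Survival curve S(t | x_ref) from the final-beta aggregated payload.

    Breslow cumulative baseline hazard H0(t) = sum_{t_j <= t} d_j / S0(t_j);
    S(t | x) = exp(-H0(t) exp(x' beta)).  The median is the smallest grid
    time with S <= 0.5 (no interpolation), or None if never reached.
    """
    S0 = agg.s0.value
    D = agg.d.value
    if np.any(S0 <= 0):
        raise RiskSetUnderflowError("non-positive risk-set sum in baseline hazard")
    h0 = np.cumsum(D / S0)
    reference = np.asarray(reference, dtype=float)
    surv = np.exp(-h0 * math.exp(float(reference @ np.asarray(beta, dtype=float))))
    below = np.flatnonzero(surv <= 0.5)
    median = float(grid.times[below[0]]) if below.size else None
    return SurvivalCurve(
        times=grid.times.copy(), survival=surv, reference=reference,
        median_time=median,
    )
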