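"""Distributed linear regression from aggregated SSCP moments.

One round of sums-of-squares-and-cross-products aggregation gives the exact
least-squares solution in closed form; a second round returns residual sums
of squares for the model-fit statistics, so the whole protocol completes in
exactly two iterations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._accum import DDArray, dd_sum
from .protocol import (
    CollinearityError,
    DesignMatrix,
    EmptySiteError,
    Payload,
    solve_spd,
    spd_inverse,
)

_CHUNK = 8192

KIND_MOMENTS = "linear.moments"
KIND_RESIDUALS = "linear.residuals"


@dataclass
class LinearIntermediate:
    """Site- or network-level moment sums sufficient for least squares."""

    n: int
    xtx: DDArray  # p x p
    xty: DDArray  # p
    yty: DDArray  # scalar
    sum_y: DDArray  # scalar

    def as_payload(self, site_id: str, iteration: int, digest: str) -> Payload:
        return Payload(
            kind=KIND_MOMENTS,
            site_id=site_id,
            iteration=iteration,
            digest=digest,
            n=self.n,
            components={
                "xtx": self.xtx,
                "xty": self.xty,
                "yty": self.yty,
                "sum_y": self.sum_y,
            },
        )

    @classmethod
    def from_payload(cls, payload: Payload) -> "LinearIntermediate":
        return cls(
            n=payload.n,
            xtx=payload.components["xtx"],
            xty=payload.components["xty"],
            yty=payload.components["yty"],
            sum_y=payload.components["sum_y"],
        )


def compute_linear_intermediates(design: DesignMatrix, y) -> LinearIntermediate:
    """Accumulate a site's SSCP moments (compensated, partition-invariant)."""
    y = np.asarray(y, dtype=np.float64)
    X = design.values
    n = X.shape[0]
    if n != y.shape[0]:
        raise ValueError("design/outcome length mismatch")
    if n < 1:
        raise EmptySiteError("site contributed no rows")
    p = X.shape[1]
    xtx = DDArray.zeros((p, p))
    xty = DDArray.zeros((p,))
    yty = DDArray.zeros(())
    sum_y = DDArray.zeros(())
    for start in range(0, n, _CHUNK):
        Xc = X[start : start + _CHUNK]
        yc = y[start : start + _CHUNK]
        xtx = xtx + dd_sum(Xc[:, :, None] * Xc[:, None, :])
        xty = xty + dd_sum(Xc * yc[:, None])
        yty = yty + dd_sum(yc * yc)
        sum_y = sum_y + dd_sum(yc)
    return LinearIntermediate(n=n, xtx=xtx, xty=xty, yty=yty, sum_y=sum_y)


def compute_residual_ss(design: DesignMatrix, y, beta) -> DDArray:
    """Site contribution to the residual sum of squares at the final estimates."""
    y = np.asarray(y, dtype=np.float64)
    r = y - design.values @ np.asarray(beta, dtype=np.float64)
    acc = DDArray.zeros(())
    for start in range(0, len(r), _CHUNK):
        rc = r[start : start + _CHUNK]
        acc = acc + dd_sum(rc * rc)
    return acc


def solve_linear(agg: LinearIntermediate, columns):
    """Closed-form least squares from aggregated moments.

    Returns ``(beta, covariance, sigma2, sse, sst)`` with
    SSE = y'y - beta'X'y, SST = y'y - (sum y)^2 / n and
    covariance = sigma2 * (X'X)^{-1}, sigma2 = SSE / (n - p).
    """
    xtx = agg.xtx.value
    xty = agg.xty.value
    n = agg.n
    p = xtx.shape[0]
    if n <= p:
        raise EmptySiteError(f"need n > p ({n} rows, {p} columns)")
    beta = solve_spd(xtx, xty, columns, CollinearityError)
    yty = agg.yty.item()
    sum_y = agg.sum_y.item()
    sse = yty - float(beta @ xty)
    sst = yty - sum_y * sum_y / n
    sigma2 = sse / (n - p)
    covariance = sigma2 * spd_inverse(xtx, columns, CollinearityError)
    return beta, covariance, sigma2, sse, sst


def linear_fit_statistics(n: int, p: int, sse: float, sst: float,
                          sawa_variance: str = "mle") -> dict:
    """R^2, AIC and the two Bayesian information criteria (SAS conventions).

    AIC = n ln(SSE/n) + 2p;  Schwarz BIC = n ln(SSE/n) + p ln n;
    Sawa BIC = n ln(SSE/n) + 2(p+2)q - 2q^2 with q = n sigma2 / SSE and
    sigma2 the full-model error-variance estimate (SSE/n or SSE/(n-p)).
    """
    if not (sst > 0):
        raise ValueError("SST must be positive")
    stats: dict = {"r2": 1.0 - sse / sst}
    if sse <= 1e-14 * sst:  # exact fit up to rounding of the residuals
        stats["r2"] = 1.0
        stats.update(aic=None, bic_sawa=None, bic_schwarz=None,
                     information_criteria_defined=False)
        return stats
    base = n * math.log(sse / n)
    sigma2 = sse / n if sawa_variance == "mle" else sse / (n - p)
    q = n * sigma2 / sse
    stats["aic"] = base + 2 * p
    stats["bic_sawa"] = base + 2 * (p + 2) * q - 2 * q * q
    stats["bic_schwarz"] = base + p * math.log(n)
    stats["information_criteria_defined"] = True
    return stats


def residual_payload(design: DesignMatrix, y, beta, site_id: str,
                     iteration: int, digest: str) -> Payload:
    return Payload(
        kind=KIND_RESIDUALS,
        site_id=site_id,
        iteration=iteration,
        digest=digest,
        n=design.n,
        components={"sse": compute_residual_ss(design, y, beta)},
    )
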