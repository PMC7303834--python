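"""Distributed logistic regression via distributed IRLS, with privacy-binned
calibration and discrimination diagnostics.

Each site returns the score vector X'(y - mu), the Fisher information X'WX
(W = diag(mu(1-mu))) and its log-likelihood contribution at the current
parameter vector; the analysis center aggregates and takes the Newton/IRLS
step.  After convergence, predicted values leave the sites only as bins of
``roc_bin_size`` records (mean prediction plus outcome counts), from which
the center reconstructs the ROC curve, AUC and the Hosmer-Lemeshow test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as _chi2

from ._accum import DDArray, dd_sum
from .protocol import (
    DegenerateGroupError,
    DesignMatrix,
    DraError,
    NonIdentifiableError,
    Payload,
    check_convergence,  # noqa: F401  (re-exported convergence check)
    solve_spd,
)

_CHUNK = 8192

KIND_IRLS = "logistic.irls"
KIND_DIAGNOSTICS = "logistic.diagnostics"


@dataclass
class GlmIterationPayload:
    """One IRLS round of summary statistics from a site (or the network)."""

    n: int
    gradient: DDArray  # p
    information: DDArray  # p x p
    loglik: DDArray  # scalar
    iteration: int

    def as_payload(self, site_id: str, digest: str, kind: str = KIND_IRLS,
                   bins: np.ndarray | None = None) -> Payload:
        payload = Payload(
            kind=kind,
            site_id=site_id,
            iteration=self.iteration,
            digest=digest,
            n=self.n,
            components={
                "gradient": self.gradient,
                "information": self.information,
                "loglik": self.loglik,
            },
        )
        if bins is not None:
            payload.stacked["bins"] = bins
        return payload

    @classmethod
    def from_payload(cls, payload: Payload) -> "GlmIterationPayload":
        return cls(
            n=payload.n,
            gradient=payload.components["gradient"],
            information=payload.components["information"],
            loglik=payload.components["loglik"],
            iteration=payload.iteration,
        )


def predicted_probabilities(design: DesignMatrix, beta) -> np.ndarray:
    eta = design.values @ np.asarray(beta, dtype=np.float64)
    return 1.0 / (1.0 + np.exp(-eta))


def compute_glm_intermediates(design: DesignMatrix, y, beta,
                              iteration: int = 0) -> GlmIterationPayload:
    """Score, information and log-likelihood sums at ``beta`` for one site."""
    y = np.asarray(y, dtype=np.float64)
    X = design.values
    p = X.shape[1]
    mu = predicted_probabilities(design, beta)
    w = mu * (1.0 - mu)
    # log-likelihood terms written to stay finite for mu -> 0/1 at y opposite
    eta = X @ np.asarray(beta, dtype=np.float64)
    ll_terms = y * eta - np.logaddexp(0.0, eta)
    gradient = DDArray.zeros((p,))
    information = DDArray.zeros((p, p))
    loglik = DDArray.zeros(())
    for start in range(0, X.shape[0], _CHUNK):
        Xc = X[start : start + _CHUNK]
        rc = (y - mu)[start : start + _CHUNK]
        wc = w[start : start + _CHUNK]
        gradient = gradient + dd_sum(Xc * rc[:, None])
        information = information + dd_sum(
            (wc[:, None, None] * Xc[:, :, None]) * Xc[:, None, :]
        )
        loglik = loglik + dd_sum(ll_terms[start : start + _CHUNK])
    return GlmIterationPayload(
        n=X.shape[0], gradient=gradient, information=information,
        loglik=loglik, iteration=iteration,
    )


def irls_step(agg: GlmIterationPayload, beta, columns) -> np.ndarray:
    """One Fisher-scoring update: beta + (X'WX)^{-1} X'(y - mu)."""
    info = agg.information.value
    step = solve_spd(info, agg.gradient.value, columns, NonIdentifiableError)
    return np.asarray(beta, dtype=np.float64) + step


def logistic_fit_statistics(total_loglik: float, n: int, p: int) -> dict:
    """-2 log L, AIC = -2logL + 2p, SC = -2logL + p ln n."""
    neg2 = -2.0 * total_loglik
    return {
        "neg2_loglik": neg2,
        "aic": neg2 + 2 * p,
        "sc": neg2 + p * math.log(n),
    }


# ---------------------------------------------------------------------------
# Privacy-binned diagnostics


@dataclass
class RocBin:
    """Aggregated run of ``size`` site-local predictions."""

    mean_predicted: float
    events: int
    nonevents: int
    size: int

    def __post_init__(self):
        if self.events + self.nonevents != self.size:
            raise DraError("bin counts do not sum to bin size")
        if min(self.events, self.nonevents, self.size) < 0:
            raise DraError("negative bin count")


def bin_predictions(predicted, outcomes, bin_size: int) -> np.ndarray:
    """Summarize site-local predictions in runs of ``bin_size`` records.

    Records are sorted ascending by predicted value (stable; ties keep
    site-local row order); the final partial bin keeps its true size.
    Returns an array with columns (mean predicted, events, nonevents, size).
    """
    if bin_size < 1:
        raise ValueError("bin_size must be >= 1")
    predicted = np.asarray(predicted, dtype=float)
    outcomes = np.asarray(outcomes, dtype=float)
    order = np.argsort(predicted, kind="stable")
    pred = predicted[order]
    y = outcomes[order]
    rows = []
    for start in range(0, len(pred), bin_size):
        chunk_p = pred[start : start + bin_size]
        chunk_y = y[start : start + bin_size]
        size = len(chunk_p)
        events = int(round(float(chunk_y.sum())))
        rows.append([float(chunk_p.mean()), events, size - events, size])
    return np.asarray(rows, dtype=float).reshape(-1, 4)


def _merge_bins(bins: np.ndarray) -> np.ndarray:
    """Merge all sites' bins; equal mean-predictions collapse to one row."""
    bins = np.asarray(bins, dtype=float).reshape(-1, 4)
    order = np.argsort(bins[:, 0], kind="stable")
    bins = bins[order]
    merged = []
    for row in bins:
        if merged and merged[-1][0] == row[0]:
            merged[-1][1] += row[1]
            merged[-1][2] += row[2]
            merged[-1][3] += row[3]
        else:
            merged.append(list(row))
    return np.asarray(merged, dtype=float)


def roc_from_bins(bins: np.ndarray):
    """ROC curve and trapezoidal AUC from all sites' aggregated bins.

    Bins are sorted descending by mean predicted value and traced as one
    operating-point step each; ties in the mean prediction merge into a
    single (diagonal) step, which counts tied pairs as half-concordant.
    Returns ``(points, auc)`` with points as (1 - specificity, sensitivity)
    starting at (0, 0).
    """
    merged = _merge_bins(bins)[::-1]  # descending by mean prediction
    events = merged[:, 1]
    nonevents = merged[:, 2]
    total_events = float(events.sum())
    total_nonevents = float(nonevents.sum())
    if total_events == 0 or total_nonevents == 0:
        raise DraError("AUC undefined: need at least one event and one nonevent")
    sens = np.concatenate([[0.0], np.cumsum(events) / total_events])
    fpr = np.concatenate([[0.0], np.cumsum(nonevents) / total_nonevents])
    points = np.column_stack([fpr, sens])
    auc = float(np.trapezoid(sens, fpr))
    return points, auc


def hosmer_lemeshow_from_bins(bins: np.ndarray, hl_groups: int = 10):
    """Hosmer-Lemeshow calibration test from aggregated prediction bins.

    Bins (ascending by mean prediction) are partitioned into ``hl_groups``
    groups at cumulative-count boundaries nearest n*k/groups.  Expected
    events per group come from the bin mean predictions; the statistic is
    sum (O-E)^2 / (E (1 - E/n_g)) on groups - 2 degrees of freedom.
    """
    if hl_groups < 3:
        raise ValueError("hl_groups must be >= 3")
    merged = _merge_bins(bins)
    sizes = merged[:, 3]
    n = float(sizes.sum())
    if n < hl_groups:
        raise DraError(f"need at least {hl_groups} records for {hl_groups} groups")
    cum = np.cumsum(sizes)
    cuts = []
    for k in range(1, hl_groups):
        target = n * k / hl_groups
        idx = int(np.argmin(np.abs(cum - target)))
        cuts.append(idx)
    # group g covers bins (cuts[g-1], cuts[g]]
    bounds = [-1] + sorted(set(cuts)) + [len(merged) - 1]
    chi2 = 0.0
    groups = 0
    for lo, hi in zip(bounds[:-1], bounds[1:]):
        if hi <= lo:
            continue
        seg = merged[lo + 1 : hi + 1]
        n_g = float(seg[:, 3].sum())
        if n_g == 0:
            continue
        observed = float(seg[:, 1].sum())
        expected = float((seg[:, 3] * seg[:, 0]).sum())
        if expected <= 0 or expected >= n_g:
            raise DegenerateGroupError(
                f"group with expected count {expected:.3g} of {n_g:.3g} records"
            )
        chi2 += (observed - expected) ** 2 / (expected * (1.0 - expected / n_g))
        groups += 1
    df = groups - 2
    pvalue = float(_chi2.sf(chi2, df)) if df > 0 else float("nan")
    return chi2, df, pvalue


def diagnostics_payload(design: DesignMatrix, y, beta, iteration: int,
                        site_id: str, digest: str, bin_size: int) -> Payload:
    """Final-round payload: score/information/loglik at the final estimates
    plus the site's privacy bins."""
    glm = compute_glm_intermediates(design, y, beta, iteration=iteration)
    bins = bin_predictions(predicted_probabilities(design, beta), y, bin_size)
    return glm.as_payload(site_id, digest, kind=KIND_DIAGNOSTICS, bins=bins)
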