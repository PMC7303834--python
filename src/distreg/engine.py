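"""Center-side session state machines and the partner-side compute dispatch.

The same :class:`CenterSession` subclasses and :func:`partner_compute` power
both the in-process driver (:func:`run_inprocess`) and the file-based
orchestrator, so the two execution modes produce bit-identical models.
"""

from __future__ import annotations

import warnings

import numpy as np

from . import cox as _cox
from . import linear as _linear
from . import logistic as _logistic
from .protocol import (
    INSTRUCTION_COMPUTE,
    INSTRUCTION_DIAGNOSTICS,
    INSTRUCTION_STOP,
    ComputationDirective,
    ConvergenceWarning,
    DraError,
    FittedModel,
    ModelSpec,
    NonIdentifiableError,
    Payload,
    ProtocolError,
    SiteDataset,
    aggregate_payloads,
    check_convergence,
    design_columns,
    expand_design,
    spd_inverse,
)

__all__ = ["CenterSession", "make_session", "partner_compute", "run_inprocess"]


class CenterSession:
    """Drives one model fit; transport-agnostic.

    Call :meth:`next_directive` / :meth:`receive` alternately until a ``stop``
    directive is produced, then read :meth:`result`.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.columns = design_columns(spec)
        self.p = len(self.columns)
        self.digest = spec.digest
        self.model: FittedModel | None = None
        self._round = 0
        self._done = False

    def next_directive(self) -> ComputationDirective | None:
        if self._done:
            return None
        if self.model is not None:
            self._done = True
            return ComputationDirective(
                instruction=INSTRUCTION_STOP,
                iteration=self._round,
                digest=self.digest,
            )
        return self._next()

    def receive(self, agg: Payload) -> None:
        if agg.digest != self.digest:
            raise ProtocolError("aggregated payload carries a foreign model digest")
        self._absorb(agg)
        self._round += 1

    def result(self) -> FittedModel:
        if self.model is None:
            raise ProtocolError("session has not finished")
        return self.model

    # subclass hooks
    def _next(self) -> ComputationDirective:  # pragma: no cover - abstract
        raise NotImplementedError

    def _absorb(self, agg: Payload) -> None:  # pragma: no cover - abstract
        raise NotImplementedError


class LinearSession(CenterSession):
    """Two-round closed-form protocol: moments, then residual fit statistics."""

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        self._solution = None

    def _next(self) -> ComputationDirective:
        if self._round == 0:
            return ComputationDirective(
                instruction=INSTRUCTION_COMPUTE, iteration=0, digest=self.digest
            )
        return ComputationDirective(
            instruction=INSTRUCTION_DIAGNOSTICS,
            iteration=self._round,
            digest=self.digest,
            beta=self._solution["beta"],
        )

    def _absorb(self, agg: Payload) -> None:
        if self._round == 0:
            moments = _linear.LinearIntermediate.from_payload(agg)
            beta, cov, sigma2, sse, sst = _linear.solve_linear(
                moments, self.columns
            )
            self._solution = {
                "beta": beta, "cov": cov, "sigma2": sigma2,
                "sse_closed": sse, "sst": sst, "n": agg.n,
            }
        else:
            sol = self._solution
            sse = agg.scalar("sse")  # residual-round SSE at the final beta
            stats = _linear.linear_fit_statistics(
                sol["n"], self.p, sse, sol["sst"],
                sawa_variance=self.spec.sawa_variance,
            )
            stats.update(sse=sse, sst=sol["sst"], sigma2=sol["sigma2"])
            self.model = FittedModel(
                family="linear",
                columns=self.columns,
                beta=sol["beta"],
                se=np.sqrt(np.diag(sol["cov"])),
                covariance=sol["cov"],
                iterations=2,
                converged=True,
                fit_statistics=stats,
                n=sol["n"],
                digest=self.digest,
            )


class LogisticSession(CenterSession):
    """Distributed IRLS with a post-convergence diagnostics round."""

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        self.beta = np.zeros(self.p)
        self.updates = 0
        self.converged = False
        self._phase = "irls"
        self._loglik_path: list = []

    def _next(self) -> ComputationDirective:
        instruction = (
            INSTRUCTION_COMPUTE if self._phase == "irls"
            else INSTRUCTION_DIAGNOSTICS
        )
        return ComputationDirective(
            instruction=instruction,
            iteration=self._round,
            digest=self.digest,
            beta=self.beta,
        )

    def _absorb(self, agg: Payload) -> None:
        glm = _logistic.GlmIterationPayload.from_payload(agg)
        if self._phase == "irls":
            self._loglik_path.append(glm.loglik.item())
            beta_new = _logistic.irls_step(glm, self.beta, self.columns)
            self.updates += 1
            self.converged = check_convergence(
                self.beta, beta_new, self.spec.convergence_epsilon
            )
            self.beta = beta_new
            if self.converged or self.updates >= self.spec.max_iterations:
                if not self.converged:
                    warnings.warn(
                        f"logistic model did not converge in "
                        f"{self.spec.max_iterations} iterations",
                        ConvergenceWarning,
                        stacklevel=4,
                    )
                self._phase = "diagnostics"
        else:
            self._loglik_path.append(glm.loglik.item())
            cov = spd_inverse(
                glm.information.value, self.columns, NonIdentifiableError
            )
            stats = _logistic.logistic_fit_statistics(
                glm.loglik.item(), agg.n, self.p
            )
            diagnostics = {}
            bins = agg.stacked.get("bins")
            if bins is not None and len(bins):
                try:
                    points, auc = _logistic.roc_from_bins(bins)
                    diagnostics["roc_points"] = points
                    diagnostics["auc"] = auc
                except DraError as exc:
                    diagnostics["auc_error"] = str(exc)
                if agg.n >= self.spec.hl_groups:
                    try:
                        chi2, df, pval = _logistic.hosmer_lemeshow_from_bins(
                            bins, self.spec.hl_groups
                        )
                        diagnostics.update(
                            hl_chi2=chi2, hl_df=df, hl_pvalue=pval
                        )
                    except DraError as exc:
                        diagnostics["hl_error"] = str(exc)
                diagnostics["bins"] = bins
            self.model = FittedModel(
                family="logistic",
                columns=self.columns,
                beta=self.beta,
                se=np.sqrt(np.diag(cov)),
                covariance=cov,
                iterations=self.updates,
                converged=self.converged,
                fit_statistics=stats,
                n=agg.n,
                digest=self.digest,
                diagnostics=diagnostics,
                history={"loglik": self._loglik_path},
            )


class CoxSession(CenterSession):
    """Grid collection, distributed Newton-Raphson, then diagnostics."""

    def __init__(self, spec: ModelSpec):
        super().__init__(spec)
        self.beta = np.zeros(self.p)
        self.grid: _cox.CoxEventGrid | None = None
        self.updates = 0
        self.converged = False
        self._phase = "grid"
        self._loglik_path: list = []

    def _grid_params(self) -> dict:
        return {
            "grid_times": self.grid.times.tolist(),
            "stage": "risk",
        }

    def _next(self) -> ComputationDirective:
        if self._phase == "grid":
            return ComputationDirective(
                instruction=INSTRUCTION_COMPUTE,
                iteration=0,
                digest=self.digest,
                params={"stage": "grid"},
            )
        if self._phase == "newton":
            return ComputationDirective(
                instruction=INSTRUCTION_COMPUTE,
                iteration=self._round,
                digest=self.digest,
                beta=self.beta,
                params=self._grid_params(),
            )
        return ComputationDirective(
            instruction=INSTRUCTION_DIAGNOSTICS,
            iteration=self._round,
            digest=self.digest,
            beta=self.beta,
            params=self._grid_params(),
        )

    def _absorb(self, agg: Payload) -> None:
        if self._phase == "grid":
            self.grid = _cox.collect_event_grid(agg)
            self._phase = "newton"
            return
        payload = _cox.CoxIterationPayload.from_payload(agg)
        ll, grad, hess = _cox.cox_score_information(
            payload, self.grid, self.beta, self.spec.tie_method
        )
        if self._phase == "newton":
            self._loglik_path.append(ll)
            beta_new = _cox.newton_step(grad, hess, self.beta, self.columns)
            self.updates += 1
            self.converged = check_convergence(
                self.beta, beta_new, self.spec.convergence_epsilon
            )
            self.beta = beta_new
            if self.converged or self.updates >= self.spec.max_iterations:
                if not self.converged:
                    warnings.warn(
                        f"cox model did not converge in "
                        f"{self.spec.max_iterations} iterations "
                        f"(possible monotone likelihood)",
                        ConvergenceWarning,
                        stacklevel=4,
                    )
                self._phase = "diagnostics"
        else:
            self._loglik_path.append(ll)
            cov = spd_inverse(-hess, self.columns, NonIdentifiableError)
            total_events = self.grid.total_events
            stats = _cox.cox_fit_statistics(ll, self.p, total_events)
            # mean covariates of patients with events, assembled distributively
            reference = payload.s.value.sum(axis=0) / total_events
            curve = _cox.baseline_survival(
                payload, self.grid, self.beta, reference
            )
            self.model = FittedModel(
                family="cox",
                columns=self.columns,
                beta=self.beta,
                se=np.sqrt(np.diag(cov)),
                covariance=cov,
                iterations=self.updates,
                converged=self.converged,
                fit_statistics=stats,
                n=agg.n,
                digest=self.digest,
                diagnostics={
                    "survival": curve.to_dict(),
                    "median_time": curve.median_time,
                    "total_events": total_events,
                },
                history={"loglik": self._loglik_path},
            )


_SESSIONS = {
    "linear": LinearSession,
    "logistic": LogisticSession,
    "cox": CoxSession,
}


def make_session(spec: ModelSpec) -> CenterSession:
    return _SESSIONS[spec.family](spec)


# ---------------------------------------------------------------------------
# Partner side


def partner_compute(site: SiteDataset, spec: ModelSpec,
                    directive: ComputationDirective) -> Payload:
    """Execute one directive against a site's individual-level data.

    Only aggregate statistics are returned; this is the single function
    allowed to touch row-level data during the protocol.
    """
    if directive.digest != spec.digest:
        raise ProtocolError(
            f"site {site.site_id!r}: directive digest {directive.digest} does "
            f"not match the configured model ({spec.digest})"
        )
    design = expand_design(site, spec)
    digest = spec.digest
    if spec.family == "linear":
        y = site.data[spec.outcome].to_numpy(dtype=float)
        if directive.instruction == INSTRUCTION_COMPUTE:
            moments = _linear.compute_linear_intermediates(design, y)
            return moments.as_payload(site.site_id, directive.iteration, digest)
        return _linear.residual_payload(
            design, y, directive.beta, site.site_id, directive.iteration, digest
        )
    if spec.family == "logistic":
        y = site.data[spec.outcome].to_numpy(dtype=float)
        if directive.instruction == INSTRUCTION_COMPUTE:
            glm = _logistic.compute_glm_intermediates(
                design, y, directive.beta, iteration=directive.iteration
            )
            return glm.as_payload(site.site_id, digest)
        return _logistic.diagnostics_payload(
            design, y, directive.beta, directive.iteration,
            site.site_id, digest, spec.roc_bin_size,
        )
    # cox
    times = site.data[spec.outcome].to_numpy(dtype=float)
    events = site.data[spec.event].to_numpy(dtype=float)
    if directive.params.get("stage") == "grid":
        return _cox.grid_payload(times, events, site.site_id, digest)
    grid = _cox.CoxEventGrid(
        times=np.asarray(directive.params["grid_times"], dtype=float),
        d=np.zeros(len(directive.params["grid_times"])),
    )
    payload = _cox.compute_cox_intermediates(
        design, times, events, directive.beta, grid,
        iteration=directive.iteration,
    )
    return payload.as_payload(site.site_id, digest)


def run_inprocess(sites, spec: ModelSpec) -> FittedModel:
    """Run the full distributed protocol in one process (no files).

    Semantically identical to the file-based orchestrator: same sessions,
    same partner computations, same aggregation.
    """
    sites = list(sites)
    if not sites:
        raise ProtocolError("need at least one site")
    session = make_session(spec)
    while True:
        directive = session.next_directive()
        if directive is None or directive.instruction == INSTRUCTION_STOP:
            break
        payloads = [partner_compute(s, spec, directive) for s in sites]
        session.receive(aggregate_payloads(payloads))
    return session.result()
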