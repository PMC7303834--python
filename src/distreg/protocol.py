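"""Shared domain types, design-matrix construction and payload plumbing.

The privacy boundary of the whole package lives here: a :class:`SiteDataset`
never leaves its node; the only objects written to a transfer directory are
:class:`ComputationDirective` (center -> partners) and :class:`Payload`
(partners -> center), both of which carry exclusively aggregate statistics.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from ._accum import DDArray

# ---------------------------------------------------------------------------
# Errors


class DraError(Exception):
    """Base class for all distributed-regression errors."""


class SpecError(DraError):
    """Invalid model specification."""


class SchemaError(DraError):
    """Site data does not match the declared covariate schema."""


class ProtocolError(DraError):
    """Payload/directive bookkeeping violation (iteration, digest, shape)."""


class PayloadError(DraError):
    """Malformed payload or directive file."""


class EmptySiteError(DraError):
    """A site contributed no rows."""


class CollinearityError(DraError):
    """Aggregated cross-product matrix is numerically singular."""


class NonIdentifiableError(DraError):
    """Aggregated information matrix is not positive definite."""


class NoEventsError(DraError):
    """No events anywhere in the network."""


class RiskSetUnderflowError(DraError):
    """Risk-set sum S0 is non-positive at an event time."""


class DegenerateGroupError(DraError):
    """A calibration group has expected count 0 or n_g."""


class ConvergenceWarning(UserWarning):
    """Model hit the iteration cap without meeting the convergence criterion."""


# ---------------------------------------------------------------------------
# Model specification

VALID_FAMILIES = ("linear", "logistic", "cox")


@dataclass(frozen=True)
class Covariate:
    """One declared model covariate.

    Continuous/count covariates enter as-is; categorical covariates are
    expanded to reference-coded indicators using the declared level order.
    """

    name: str
    kind: str = "continuous"  # "continuous" | "categorical"
    levels: tuple = ()
    reference: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("continuous", "categorical"):
            raise SpecError(f"covariate {self.name!r}: unknown kind {self.kind!r}")
        if self.kind == "categorical":
            levels = tuple(str(v) for v in self.levels)
            object.__setattr__(self, "levels", levels)
            if len(levels) < 2:
                raise SpecError(f"covariate {self.name!r}: needs >=2 levels")
            ref = str(self.reference) if self.reference is not None else levels[0]
            object.__setattr__(self, "reference", ref)
            if ref not in levels:
                raise SpecError(
                    f"covariate {self.name!r}: reference {ref!r} not among levels {levels}"
                )

    def to_dict(self) -> dict:
        d = {"name": self.name, "kind": self.kind}
        if self.kind == "categorical":
            d["levels"] = list(self.levels)
            d["reference"] = self.reference
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "Covariate":
        return cls(
            name=d["name"],
            kind=d.get("kind", "continuous"),
            levels=tuple(d.get("levels", ())),
            reference=d.get("reference"),
        )


@dataclass
class ModelSpec:
    """Family, outcome, covariates and protocol settings for one analysis.

    Parameters
    ----------
    family : {"linear", "logistic", "cox"}
    outcome : str
        Outcome column (linear: continuous; logistic: 0/1 indicator;
        cox: event time in days, strictly positive).
    covariates : list of Covariate
    event : str, optional
        Event-indicator column (cox only).
    tie_method : {"efron", "breslow"}
        Partial-likelihood treatment of tied event times (cox only).
    convergence_epsilon : float
        Iterations stop when the maximum absolute change in any parameter
        estimate falls below this value.  Default 0.01.
    max_iterations : int
        Hard cap on update iterations.  Default 25.
    roc_bin_size : int
        Privacy bin size for transferred predicted values.  Default 6.
    hl_groups : int
        Number of Hosmer-Lemeshow risk groups.  Default 10.
    sawa_variance : {"mle", "unbiased"}
        Error-variance estimator used inside Sawa's BIC (linear only):
        SSE/n ("mle", default) or SSE/(n-p) ("unbiased").
    """

    family: str
    outcome: str
    covariates: list = field(default_factory=list)
    event: Optional[str] = None
    tie_method: str = "efron"
    convergence_epsilon: float = 0.01
    max_iterations: int = 25
    roc_bin_size: int = 6
    hl_groups: int = 10
    sawa_variance: str = "mle"

    def __post_init__(self):
        if self.family not in VALID_FAMILIES:
            raise SpecError(f"unknown family {self.family!r}")
        self.covariates = [
            c if isinstance(c, Covariate) else Covariate.from_dict(c)
            for c in self.covariates
        ]
        if not self.covariates:
            raise SpecError("at least one covariate is required")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise SpecError("duplicate covariate names")
        if self.family == "cox" and not self.event:
            raise SpecError("cox family requires an event-indicator column")
        if self.tie_method not in ("efron", "breslow"):
            raise SpecError(f"unknown tie method {self.tie_method!r}")
        if not (self.convergence_epsilon > 0):
            raise SpecError("convergence_epsilon must be positive")
        if self.max_iterations < 1:
            raise SpecError("max_iterations must be >= 1")
        if self.roc_bin_size < 1:
            raise SpecError("roc_bin_size must be >= 1")
        if self.hl_groups < 3:
            raise SpecError("hl_groups must be >= 3")
        if self.sawa_variance not in ("mle", "unbiased"):
            raise SpecError(f"unknown sawa_variance {self.sawa_variance!r}")

    @property
    def has_intercept(self) -> bool:
        # The Cox partial likelihood has no intercept.
        return self.family in ("linear", "logistic")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["covariates"] = [c.to_dict() for c in self.covariates]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(**d)

    @classmethod
    def from_json(cls, path) -> "ModelSpec":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @property
    def digest(self) -> str:
        """Short stable digest binding payloads and directives to one spec."""
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Site data


@dataclass
class SiteDataset:
    """One data partner's individual-level analytical table.  Never transmitted."""

    site_id: str
    data: pd.DataFrame

    @property
    def n(self) -> int:
        return len(self.data)

    def validate(self, spec: ModelSpec) -> None:
        """Check the harmonized schema this site promised to share."""
        cols = [c.name for c in spec.covariates] + [spec.outcome]
        if spec.event:
            cols.append(spec.event)
        missing = [c for c in cols if c not in self.data.columns]
        if missing:
            raise SchemaError(f"site {self.site_id!r}: missing columns {missing}")
        sub = self.data[cols]
        if sub.isna().any().any():
            bad = sub.columns[sub.isna().any()].tolist()
            raise SchemaError(f"site {self.site_id!r}: missing values in {bad}")
        if spec.family == "logistic":
            y = self.data[spec.outcome].to_numpy()
            if not np.isin(y, (0, 1)).all():
                raise SchemaError(
                    f"site {self.site_id!r}: outcome {spec.outcome!r} not in {{0,1}}"
                )
        if spec.family == "cox":
            t = self.data[spec.outcome].to_numpy(dtype=float)
            if not (t > 0).all():
                raise SchemaError(
                    f"site {self.site_id!r}: event times must be strictly positive"
                )
            e = self.data[spec.event].to_numpy()
            if not np.isin(e, (0, 1)).all():
                raise SchemaError(
                    f"site {self.site_id!r}: event indicator not in {{0,1}}"
                )

    @classmethod
    def from_csv(cls, site_id: str, path) -> "SiteDataset":
        return cls(site_id=site_id, data=pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Design matrix


@dataclass
class DesignMatrix:
    columns: list
    values: np.ndarray  # n x p, float64
    intercept: bool

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def p(self) -> int:
        return self.values.shape[1]


def design_columns(spec: ModelSpec) -> list:
    """Deterministic design column order, derivable from the spec alone.

    Declared covariate order; categorical levels in declared order with the
    reference level dropped.  Every site therefore produces bit-identical
    column layouts without seeing each other's data.
    """
    cols = ["(intercept)"] if spec.has_intercept else []
    for cov in spec.covariates:
        if cov.kind == "continuous":
            cols.append(cov.name)
        else:
            cols.extend(
                f"{cov.name}[{lev}]" for lev in cov.levels if lev != cov.reference
            )
    return cols


def expand_design(site: SiteDataset, spec: ModelSpec) -> DesignMatrix:
    """Expand a site's table into the model design matrix."""
    site.validate(spec)
    n = site.n
    blocks = []
    if spec.has_intercept:
        blocks.append(np.ones((n, 1)))
    for cov in spec.covariates:
        col = site.data[cov.name]
        if cov.kind == "continuous":
            blocks.append(col.to_numpy(dtype=np.float64).reshape(n, 1))
        else:
            vals = col.astype(str).to_numpy()
            unseen = sorted(set(vals) - set(cov.levels))
            if unseen:
                raise SchemaError(
                    f"site {site.site_id!r}: column {cov.name!r} has value(s) "
                    f"{unseen} outside declared levels {list(cov.levels)}"
                )
            for lev in cov.levels:
                if lev == cov.reference:
                    continue
                blocks.append((vals == lev).astype(np.float64).reshape(n, 1))
    values = np.hstack(blocks) if blocks else np.empty((n, 0))
    return DesignMatrix(columns=design_columns(spec), values=values,
                        intercept=spec.has_intercept)


# ---------------------------------------------------------------------------
# Directives and payloads

INSTRUCTION_COMPUTE = "compute_intermediates"
INSTRUCTION_DIAGNOSTICS = "compute_diagnostics"
INSTRUCTION_STOP = "stop"
INSTRUCTIONS = (INSTRUCTION_COMPUTE, INSTRUCTION_DIAGNOSTICS, INSTRUCTION_STOP)


@dataclass
class ComputationDirective:
    """Analysis-center instruction driving one protocol round."""

    instruction: str
    iteration: int
    digest: str
    beta: Optional[np.ndarray] = None
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.instruction not in INSTRUCTIONS:
            raise ProtocolError(f"unknown instruction {self.instruction!r}")
        if self.iteration < 0:
            raise ProtocolError("iteration must be >= 0")
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=np.float64)

    def to_dict(self) -> dict:
        return {
            "schema": "dra-directive/1",
            "instruction": self.instruction,
            "iteration": self.iteration,
            "digest": self.digest,
            "beta": None if self.beta is None else self.beta.tolist(),
            "params": self.params,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ComputationDirective":
        try:
            return cls(
                instruction=d["instruction"],
                iteration=d["iteration"],
                digest=d["digest"],
                beta=d.get("beta"),
                params=d.get("params", {}),
            )
        except KeyError as exc:
            raise PayloadError(f"directive missing field {exc}") from exc


@dataclass
class Payload:
    """Summary-level intermediate statistics — the only data crossing sites.

    ``components`` are elementwise-additive double-double blocks;
    ``keyed`` blocks union-merge on key and sum values (event-time grids);
    ``stacked`` blocks concatenate row-wise (privacy bins).
    """

    kind: str
    site_id: str
    iteration: int
    digest: str
    n: int
    components: dict = field(default_factory=dict)  # name -> DDArray
    keyed: dict = field(default_factory=dict)  # name -> {float key: float}
    stacked: dict = field(default_factory=dict)  # name -> 2-D float array

    def component(self, name: str) -> np.ndarray:
        """Collapsed float64 view of an additive block."""
        return self.components[name].value

    def scalar(self, name: str) -> float:
        return float(self.components[name].hi)


def aggregate_payloads(payloads) -> Payload:
    """Elementwise-sum partner payloads at the analysis center.

    Additive blocks are combined in double-double arithmetic so the result
    matches a pooled one-pass computation at full double precision; keyed
    blocks union-merge; stacked blocks concatenate in payload order.
    """
    payloads = list(payloads)
    if not payloads:
        raise ProtocolError("no payloads to aggregate")
    first = payloads[0]
    for p in payloads[1:]:
        if p.kind != first.kind:
            raise ProtocolError(f"payload kind mismatch: {p.kind} vs {first.kind}")
        if p.iteration != first.iteration:
            raise ProtocolError(
                f"iteration mismatch: site {p.site_id!r} sent {p.iteration}, "
                f"expected {first.iteration}"
            )
        if p.digest != first.digest:
            raise ProtocolError(f"model digest mismatch at site {p.site_id!r}")
        if set(p.components) != set(first.components) or set(p.keyed) != set(
            first.keyed
        ) or set(p.stacked) != set(first.stacked):
            raise ProtocolError(f"component name mismatch at site {p.site_id!r}")
    components = {}
    for name, block in first.components.items():
        acc = block.copy()
        for p in payloads[1:]:
            other = p.components[name]
            if other.shape != block.shape:
                raise ProtocolError(
                    f"shape mismatch for block {name!r} at site {p.site_id!r}: "
                    f"{other.shape} vs {block.shape}"
                )
            acc = acc + other
        components[name] = acc
    keyed = {}
    for name in first.keyed:
        merged: dict = {}
        for p in payloads:
            for k, v in p.keyed[name].items():
                merged[k] = merged.get(k, 0.0) + v
        keyed[name] = dict(sorted(merged.items()))
    stacked = {}
    for name in first.stacked:
        blocks = [np.asarray(p.stacked[name], dtype=float) for p in payloads]
        widths = {b.shape[1] for b in blocks if b.size}
        if len(widths) > 1:
            raise ProtocolError(f"stacked block {name!r}: column-count mismatch")
        stacked[name] = np.vstack([b for b in blocks]) if blocks else np.empty((0, 0))
    return Payload(
        kind=first.kind,
        site_id="<aggregate>",
        iteration=first.iteration,
        digest=first.digest,
        n=sum(p.n for p in payloads),
        components=components,
        keyed=keyed,
        stacked=stacked,
    )


# ---------------------------------------------------------------------------
# Payload serialization (JSON; doubles round-trip exactly via shortest repr)


def _encode_dd(arr: DDArray) -> dict:
    return {
        "shape": list(arr.shape),
        "hi": arr.hi.ravel().tolist(),
        "lo": arr.lo.ravel().tolist(),
    }


def _decode_dd(d: dict, name: str) -> DDArray:
    try:
        shape = tuple(d["shape"])
        hi = np.array(d["hi"], dtype=np.float64).reshape(shape)
        lo = np.array(d["lo"], dtype=np.float64).reshape(shape)
    except (KeyError, TypeError, ValueError) as exc:
        raise PayloadError(f"malformed component block {name!r}: {exc}") from exc
    return DDArray(hi, lo)


def write_payload(payload: Payload, path) -> None:
    doc = {
        "schema": "dra-payload/1",
        "kind": payload.kind,
        "site_id": payload.site_id,
        "iteration": payload.iteration,
        "digest": payload.digest,
        "n": payload.n,
        "components": {k: _encode_dd(v) for k, v in payload.components.items()},
        "keyed": {
            k: {"keys": [float(t) for t in v], "values": [float(x) for x in v.values()]}
            for k, v in payload.keyed.items()
        },
        "stacked": {
            k: {
                "shape": list(np.asarray(v).shape),
                "data": np.asarray(v, dtype=float).ravel().tolist(),
            }
            for k, v in payload.stacked.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_payload(path) -> Payload:
    try:
        with open(path) as fh:
            doc = json.load(fh)
    except json.JSONDecodeError as exc:
        raise PayloadError(f"cannot parse payload file {path}: {exc}") from exc
    if not isinstance(doc, dict) or doc.get("schema") != "dra-payload/1":
        raise PayloadError(f"file {path} is not a payload document")
    try:
        components = {
            k: _decode_dd(v, k) for k, v in doc.get("components", {}).items()
        }
        keyed = {}
        for k, v in doc.get("keyed", {}).items():
            keys, values = v["keys"], v["values"]
            if len(keys) != len(values):
                raise PayloadError(f"keyed block {k!r}: keys/values length mismatch")
            keyed[k] = dict(zip(map(float, keys), map(float, values)))
        stacked = {}
        for k, v in doc.get("stacked", {}).items():
            shape = tuple(v["shape"])
            stacked[k] = np.array(v["data"], dtype=float).reshape(shape)
        return Payload(
            kind=doc["kind"],
            site_id=doc["site_id"],
            iteration=doc["iteration"],
            digest=doc["digest"],
            n=doc["n"],
            components=components,
            keyed=keyed,
            stacked=stacked,
        )
    except PayloadError:
        raise
    except (KeyError, TypeError, ValueError) as exc:
        raise PayloadError(f"malformed payload file {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Convergence and fitted models


def check_convergence(beta, beta_new, epsilon: float) -> bool:
    """True iff the maximum absolute parameter change is below ``epsilon``."""
    beta = np.asarray(beta, dtype=float)
    beta_new = np.asarray(beta_new, dtype=float)
    if beta.shape != beta_new.shape:
        raise ProtocolError(
            f"parameter-vector length mismatch: {beta.shape} vs {beta_new.shape}"
        )
    if not (epsilon > 0):
        raise SpecError("epsilon must be positive")
    return bool(np.max(np.abs(beta_new - beta), initial=0.0) < epsilon)


@dataclass
class FittedModel:
    """Estimates, uncertainties and fit statistics from one analysis run."""

    family: str
    columns: list
    beta: np.ndarray
    se: np.ndarray
    covariance: np.ndarray
    iterations: int
    converged: bool
    fit_statistics: dict
    n: int
    digest: str
    diagnostics: dict = field(default_factory=dict)
    history: dict = field(default_factory=dict)

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.beta, "se": self.se}, index=self.columns
        )

    def to_dict(self) -> dict:
        def clean(x):
            if isinstance(x, np.ndarray):
                return x.tolist()
            if isinstance(x, (np.floating, np.integer)):
                return x.item()
            if isinstance(x, float) and math.isnan(x):
                return None
            if isinstance(x, dict):
                return {k: clean(v) for k, v in x.items()}
            if isinstance(x, (list, tuple)):
                return [clean(v) for v in x]
            return x

        return {
            "schema": "dra-report/1",
            "family": self.family,
            "columns": list(self.columns),
            "beta": self.beta.tolist(),
            "se": self.se.tolist(),
            "covariance": self.covariance.tolist(),
            "iterations": self.iterations,
            "converged": self.converged,
            "fit_statistics": clean(self.fit_statistics),
            "n": self.n,
            "digest": self.digest,
            "diagnostics": clean(self.diagnostics),
            "history": clean(self.history),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def from_json(cls, path) -> "FittedModel":
        with open(path) as fh:
            d = json.load(fh)
        if d.get("schema") != "dra-report/1":
            raise PayloadError(f"file {path} is not a model report")
        return cls(
            family=d["family"],
            columns=d["columns"],
            beta=np.array(d["beta"], dtype=float),
            se=np.array(d["se"], dtype=float),
            covariance=np.array(d["covariance"], dtype=float),
            iterations=d["iterations"],
            converged=d["converged"],
            fit_statistics=d["fit_statistics"],
            n=d["n"],
            digest=d["digest"],
            diagnostics=d.get("diagnostics", {}),
            history=d.get("history", {}),
        )


# ---------------------------------------------------------------------------
# Shared linear algebra helpers


def solve_spd(matrix: np.ndarray, rhs: np.ndarray, columns, error_cls):
    """Solve a symmetric positive-definite system via Cholesky.

    Near-singularity is judged on the diagonally normalized (correlation
    form) matrix, so the check is invariant to covariate units: a reciprocal
    condition estimate below 1e-10 there raises ``error_cls`` naming the
    (near-)dependent columns.
    """
    from scipy.linalg import cho_factor, cho_solve, eigh

    matrix = np.asarray(matrix, dtype=float)
    diag = np.diag(matrix)
    if np.any(diag <= 0):
        bad = [columns[i] for i in np.flatnonzero(diag <= 0)]
        raise error_cls(f"zero or negative diagonal for columns {bad}")
    scale = 1.0 / np.sqrt(diag)
    scaled = matrix * np.outer(scale, scale)
    w = np.linalg.eigvalsh(scaled)
    wmax = float(w[-1])
    if wmax <= 0 or float(w[0]) / wmax < 1e-10:
        _, vecs = eigh(scaled)
        v = np.abs(vecs[:, 0])
        bad = [columns[i] for i in np.flatnonzero(v > 0.3 * v.max())]
        raise error_cls(
            f"matrix is singular or near-singular (scaled rcond "
            f"{float(w[0]) / wmax if wmax > 0 else 0:.2e}); "
            f"dependent columns likely among {bad}"
        )
    c = cho_factor(matrix, lower=True)
    return cho_solve(c, np.asarray(rhs, dtype=float))


def spd_inverse(matrix: np.ndarray, columns, error_cls) -> np.ndarray:
    inv = solve_spd(matrix, np.eye(matrix.shape[0]), columns, error_cls)
    return (inv + inv.T) / 2.0
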