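"""Pooled reference fits and distributed-vs-pooled difference reports.

The pooled fit runs the very same protocol engine on the concatenated rows
as a single site, so every convention (dummy coding, tie handling, stopping
rule, fit-statistic formulas) matches by construction; the difference report
is the verification surface for the equivalence claim.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import run_inprocess
from .protocol import FittedModel, ModelSpec, SchemaError, SiteDataset


def pooled_fit(spec: ModelSpec, rows: pd.DataFrame,
               site_id: str = "<pooled>") -> FittedModel:
    """Fit the model on the pooled individual-level table."""
    pooled = SiteDataset(site_id=site_id, data=rows.reset_index(drop=True))
    return run_inprocess([pooled], spec)


_NUMERIC = (int, float, np.floating, np.integer)


@dataclass
class DifferenceReport:
    """Signed distributed-minus-pooled differences, coefficient by coefficient."""

    table: pd.DataFrame  # estimate/SE rows per coefficient
    statistics: pd.DataFrame  # shared fit statistics
    max_abs_difference: float
    tolerance: float

    @property
    def passed(self) -> bool:
        return self.max_abs_difference < self.tolerance

    def __str__(self) -> str:
        lines = [
            self.table.to_string(float_format=lambda v: f"{v: .6e}"),
            "",
            self.statistics.to_string(float_format=lambda v: f"{v: .6e}"),
            "",
            f"max |difference| = {self.max_abs_difference:.3e} "
            f"({'PASS' if self.passed else 'FAIL'} at {self.tolerance:.0e})",
        ]
        return "\n".join(lines)


def compare_models(distributed: FittedModel, pooled: FittedModel,
                   tolerance: float = 1e-6) -> DifferenceReport:
    """Tabulate distributed-vs-pooled differences in estimates, SEs and
    shared fit statistics."""
    if distributed.digest != pooled.digest:
        raise SchemaError("models were fitted under different specifications")
    if list(distributed.columns) != list(pooled.columns):
        raise SchemaError("coefficient name mismatch between models")
    est_diff = distributed.beta - pooled.beta
    se_diff = distributed.se - pooled.se
    table = pd.DataFrame(
        {
            "estimate_dra": distributed.beta,
            "estimate_pooled": pooled.beta,
            "diff_estimate": est_diff,
            "se_dra": distributed.se,
            "se_pooled": pooled.se,
            "diff_se": se_diff,
        },
        index=list(distributed.columns),
    )
    shared = [
        k
        for k, v in distributed.fit_statistics.items()
        if k in pooled.fit_statistics
        and isinstance(v, _NUMERIC) and not isinstance(v, bool)
        and isinstance(pooled.fit_statistics[k], _NUMERIC)
    ]
    stats = pd.DataFrame(
        {
            "dra": [float(distributed.fit_statistics[k]) for k in shared],
            "pooled": [float(pooled.fit_statistics[k]) for k in shared],
        },
        index=shared,
    )
    stats["diff"] = stats["dra"] - stats["pooled"]
    diffs = np.concatenate(
        [np.abs(est_diff), np.abs(se_diff), np.abs(stats["diff"].to_numpy())]
    )
    return DifferenceReport(
        table=table,
        statistics=stats,
        max_abs_difference=float(diffs.max(initial=0.0)),
        tolerance=tolerance,
    )
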