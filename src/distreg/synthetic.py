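"""Synthetic horizontally partitioned cohorts with known truth.

Emulates a three-site bariatric-surgery follow-up study: one shared covariate
draw per subject (exposure, demographics, utilization counts, categorical
race/year/site) feeds three coexisting outcomes — a continuous change in BMI,
a binary >=20%-weight-loss indicator, and a time to >=20% weight loss with
administrative censoring at day 365.  Event times are drawn from a
proportional-hazards Weibull model and rounded *up* to whole days, which
deliberately produces heavy within- and cross-site ties so the Efron
correction is genuinely exercised.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .protocol import Covariate, ModelSpec, SiteDataset

__all__ = [
    "CohortConfig",
    "generate_cohort",
    "partition_fixed_dataset",
    "default_spec",
    "TRUE_BETA",
]

RACE_LEVELS = ("white", "unknown", "aian", "asian", "black", "nhpi")
RACE_PROBS = (0.62, 0.12, 0.03, 0.05, 0.14, 0.04)
YEAR_LEVELS = ("2010", "2011", "2012", "2013", "2014", "2015")

# True generating coefficients keyed by design column, magnitudes chosen to
# resemble a bariatric change-in-BMI test case (exposure = sleeve gastrectomy
# vs bypass; linear outcome includes a ~-1 coefficient on baseline BMI, so the
# model explains most of the outcome variance).
TRUE_BETA = {
    "linear": {
        "(intercept)": 34.0, "exposure": 2.05, "age": -0.033,
        "bmi_baseline": -1.0, "comorbidity": 0.044, "n_ambulatory": -0.031,
        "n_ed": 0.103, "n_inpatient": 0.887, "n_nonacute": 1.323,
        "n_other_ambulatory": 0.022, "days_bmi_measure": 0.012,
        "race[unknown]": 0.942, "race[aian]": -0.309, "race[asian]": -0.169,
        "race[black]": 1.520, "race[nhpi]": -1.223, "female": -1.224,
        "year[2011]": 0.152, "year[2012]": -0.249, "year[2013]": -0.023,
        "year[2014]": 0.328, "year[2015]": -0.258,
        "site[2]": -1.106, "site[3]": -0.110,
    },
    "logistic": {
        "(intercept)": 2.116, "exposure": -1.067, "age": -0.016,
        "bmi_baseline": 0.0003, "comorbidity": -0.026, "n_ambulatory": 0.012,
        "n_ed": -0.062, "n_inpatient": -0.121, "n_nonacute": 0.425,
        "n_other_ambulatory": 0.004, "days_bmi_measure": -0.003,
        "race[unknown]": -0.397, "race[aian]": -0.139, "race[asian]": -0.373,
        "race[black]": -0.296, "race[nhpi]": -0.029, "female": 0.200,
        "year[2011]": -0.103, "year[2012]": 0.055, "year[2013]": -0.120,
        "year[2014]": -0.110, "year[2015]": 0.037,
        "site[2]": -0.104, "site[3]": 0.755,
    },
    "cox": {
        "exposure": -0.582, "age": -0.011, "bmi_baseline": -0.0001,
        "comorbidity": -0.008, "n_ambulatory": 0.006, "n_ed": -0.019,
        "n_inpatient": -0.086, "n_nonacute": 0.066,
        "n_other_ambulatory": 0.003, "days_bmi_measure": -0.002,
        "race[unknown]": -0.189, "race[aian]": -0.075, "race[asian]": -0.223,
        "race[black]": -0.185, "race[nhpi]": -0.197, "female": -0.009,
        "year[2011]": -0.080, "year[2012]": -0.025, "year[2013]": -0.095,
        "year[2014]": -0.169, "year[2015]": 0.248,
        "site[2]": -0.153, "site[3]": 0.334,
    },
}


@dataclass
class CohortConfig:
    """Study conditions for the generator.

    Defaults mirror the three-partner test case: site sizes (1706, 2728,
    1018), ~18% exposure prevalence, administrative censoring at day 365 and
    an event fraction around 75% by end of follow-up.
    """

    seed: int
    site_sizes: tuple = (1706, 2728, 1018)
    beta_linear: dict = field(default_factory=lambda: dict(TRUE_BETA["linear"]))
    beta_logistic: dict = field(
        default_factory=lambda: dict(TRUE_BETA["logistic"])
    )
    beta_cox: dict = field(default_factory=lambda: dict(TRUE_BETA["cox"]))
    linear_noise_sd: float = 2.0
    exposure_prob: float = 0.18
    female_prob: float = 0.77
    weibull_shape: float = 1.2
    weibull_scale: float = 146.0  # days; ~75% events by day 365 at the mean
    censor_day: int = 365
    poisson_means: dict = field(
        default_factory=lambda: {
            "comorbidity": 1.2, "n_ambulatory": 10.0, "n_ed": 0.8,
            "n_inpatient": 0.3, "n_nonacute": 0.05,
            "n_other_ambulatory": 5.0, "days_bmi_measure": 30.0,
        }
    )

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if any(n < 1 for n in self.site_sizes):
            raise ValueError("every site needs n >= 1")
        for prob in (self.exposure_prob, self.female_prob):
            if not (0 < prob < 1):
                raise ValueError("probabilities must lie in (0, 1)")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def default_spec(family: str, **overrides) -> ModelSpec:
    """The 23-covariate model specification matching the generator's schema."""
    site_levels = tuple(
        str(i + 1) for i in range(len(overrides.pop("site_sizes", (0, 0, 0))))
    )
    covariates = [
        Covariate("exposure"),
        Covariate("age"),
        Covariate("bmi_baseline"),
        Covariate("comorbidity"),
        Covariate("n_ambulatory"),
        Covariate("n_ed"),
        Covariate("n_inpatient"),
        Covariate("n_nonacute"),
        Covariate("n_other_ambulatory"),
        Covariate("days_bmi_measure"),
        Covariate("race", kind="categorical", levels=RACE_LEVELS,
                  reference="white"),
        Covariate("female"),
        Covariate("year", kind="categorical", levels=YEAR_LEVELS,
                  reference="2010"),
        Covariate("site", kind="categorical", levels=site_levels,
                  reference="1"),
    ]
    outcome = {"linear": "bmi_change", "logistic": "wl20", "cox": "days_to_wl20"}
    kwargs = dict(
        family=family,
        outcome=outcome[family],
        covariates=covariates,
        event="wl20_event" if family == "cox" else None,
    )
    kwargs.update(overrides)
    return ModelSpec(**kwargs)


def _beta_vector(beta_map: dict, columns) -> np.ndarray:
    return np.array([beta_map.get(c, 0.0) for c in columns], dtype=float)


def _linear_predictor(df: pd.DataFrame, beta_map: dict,
                      intercept: bool) -> np.ndarray:
    lp = np.full(len(df), beta_map.get("(intercept)", 0.0) if intercept else 0.0)
    for key, coef in beta_map.items():
        if key == "(intercept)" or coef == 0.0:
            continue
        if "[" in key:
            name, lev = key[:-1].split("[")
            lp += coef * (df[name].astype(str).to_numpy() == lev)
        else:
            lp += coef * df[key].to_numpy(dtype=float)
    return lp


def generate_cohort(config: CohortConfig):
    """Draw the partitioned cohort.

    Returns ``(sites, truth)`` — a list of :class:`SiteDataset` (one per
    partner, deterministic per-site substreams of the master seed) and a
    truth record echoing the generating coefficients and configuration.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(len(config.site_sizes))
    sites = []
    total_events = 0
    for idx, (n, stream) in enumerate(zip(config.site_sizes, streams)):
        rng = np.random.default_rng(stream)
        df = pd.DataFrame(
            {
                "site": np.repeat(str(idx + 1), n),
                "exposure": rng.binomial(1, config.exposure_prob, n).astype(float),
                "age": rng.uniform(18.0, 79.0, n),
                "bmi_baseline": _truncated_normal(rng, 45.0, 7.0, 35.0, n),
                "female": rng.binomial(1, config.female_prob, n).astype(float),
                "race": rng.choice(RACE_LEVELS, size=n, p=RACE_PROBS),
                "year": rng.choice(YEAR_LEVELS, size=n),
            }
        )
        for name, mean in config.poisson_means.items():
            df[name] = rng.poisson(mean, n).astype(float)

        lp_lin = _linear_predictor(df, config.beta_linear, intercept=True)
        df["bmi_change"] = lp_lin + rng.normal(0.0, config.linear_noise_sd, n)

        lp_log = _linear_predictor(df, config.beta_logistic, intercept=True)
        df["wl20"] = rng.binomial(1, 1.0 / (1.0 + np.exp(-lp_log))).astype(float)

        lp_cox = _linear_predictor(df, config.beta_cox, intercept=False)
        u = rng.uniform(size=n)
        raw = config.weibull_scale * (
            -np.log(u) / np.exp(lp_cox)
        ) ** (1.0 / config.weibull_shape)
        days = np.maximum(np.ceil(raw), 1.0)
        event = (days <= config.censor_day).astype(float)
        days = np.minimum(days, float(config.censor_day))
        df["days_to_wl20"] = days
        df["wl20_event"] = event
        total_events += int(event.sum())
        sites.append(SiteDataset(site_id=f"site{idx + 1}", data=df))

    if total_events == 0:
        import warnings

        warnings.warn(
            "degenerate survival configuration: 0 events generated",
            UserWarning,
            stacklevel=2,
        )
    truth = {
        "config": config.to_dict(),
        "beta": {
            "linear": dict(config.beta_linear),
            "logistic": dict(config.beta_logistic),
            "cox": dict(config.beta_cox),
        },
        "total_events": total_events,
        "n_total": int(sum(config.site_sizes)),
    }
    return sites, truth


def _truncated_normal(rng, mean, sd, lower, n):
    out = rng.normal(mean, sd, n)
    bad = out < lower
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = out < lower
    return out


def pooled_frame(sites) -> pd.DataFrame:
    """Concatenate site tables (the pooled individual-level view)."""
    return pd.concat([s.data for s in sites], ignore_index=True)


def partition_fixed_dataset(rows: pd.DataFrame, k: int, scheme: str = "contiguous",
                            seed: int | None = None):
    """Split a fixed table into k sites: a disjoint cover preserving all rows.

    The data's own ``site`` column (a covariate) is untouched; only the
    custody of rows changes, which is exactly what partition-invariance
    tests need to vary.
    """
    n = len(rows)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"cannot split {n} rows across {k} sites")
    if scheme == "contiguous":
        parts = np.array_split(np.arange(n), k)
    elif scheme == "round_robin":
        parts = [np.arange(i, n, k) for i in range(k)]
    elif scheme == "random":
        rng = np.random.default_rng(seed)
        perm = rng.permutation(n)
        parts = np.array_split(perm, k)
    else:
        raise ValueError(f"unknown partition scheme {scheme!r}")
    return [
        SiteDataset(site_id=f"part{i + 1}",
                    data=rows.iloc[idx].reset_index(drop=True))
        for i, idx in enumerate(parts)
    ]


def write_cohort(sites, truth, directory) -> None:
    """Emit per-site CSVs plus the truth record as JSON."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for site in sites:
        site.to_csv(directory / f"{site.site_id}.csv")
    with open(directory / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
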