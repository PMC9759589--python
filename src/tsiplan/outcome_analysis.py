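"""Two-year treatment-outcome analysis on cohort tables.

Endpoints are binary status at a fixed horizon (default 24 months): tumor
growth control (no persistent volumetric growth) and serviceable hearing
preservation (maintained Gardner-Robertson class I/II).  The binary outcomes
are modelled as time-to-event with administrative censoring at the end of
follow-up, so fixed-horizon rates and Cox proportional-hazards fits stay
mutually consistent.  Cox models use the partial likelihood with the Efron
tie approximation (via lifelines) and Wald confidence intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError
from scipy import stats

GROWTH_COVARIATES = ["age", "sex", "tv_cm3", "koos", "margin_dose_gy",
                     "ci", "si", "gi", "ei", "vios"]
HEARING_COVARIATES = GROWTH_COVARIATES + ["cochlear_dose_gy", "cochlea_distance_mm"]


def event_rate(events, times=None, horizon: float = 24.0) -> float:
    """Fraction event-free at the horizon.

    ``events`` are binary event flags; with ``times`` given, only events at or
    before the horizon count.  All records must be observed to the horizon or
    to their event, so the rate is the exact count ratio.
    """
    events = np.asarray(events, dtype=float)
    if len(events) == 0:
        raise ValueError("no records")
    if times is not None:
        times = np.asarray(times, dtype=float)
        events = events * (times <= horizon)
    return 1.0 - float(events.sum()) / len(events)


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    model: str  # "univariable" | "multivariable"
    converged: bool = True


def _prepare(records: pd.DataFrame, covariates, duration_col, event_col) -> pd.DataFrame:
    df = records[list(covariates) + [duration_col, event_col]].copy()
    if "sex" in df.columns and df["sex"].dtype == object:
        df["sex"] = (df["sex"] == "F").astype(float)
    df = df.dropna()
    if int(df[event_col].sum()) < 10:
        raise ValueError("need at least 10 events for a Cox fit")
    return df


def _fit_one(df, covariates, duration_col, event_col, model_label) -> list[CoxResult]:
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[list(covariates) + [duration_col, event_col]],
                duration_col=duration_col,
                event_col=event_col,
            )
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return [
            CoxResult(c, float("nan"), float("nan"), float("nan"), float("nan"),
                      model_label, converged=False)
            for c in covariates
        ]
    summary = cph.summary
    out = []
    for c in covariates:
        row = summary.loc[c]
        out.append(
            CoxResult(
                covariate=c,
                hazard_ratio=float(np.exp(row["coef"])),
                ci_low=float(np.exp(row["coef lower 95%"])),
                ci_high=float(np.exp(row["coef upper 95%"])),
                p=float(row["p"]),
                model=model_label,
            )
        )
    return out


def cox_fit(
    records: pd.DataFrame,
    covariates,
    duration_col: str = "growth_time_months",
    event_col: str = "growth_event",
    mode: str = "multivariable",
) -> list[CoxResult]:
    """Cox proportional-hazards results (Efron ties, Wald CIs).

    ``mode="univariable"`` fits each covariate alone; ``"multivariable"``
    fits all covariates jointly.  Constant covariates are rejected.
    """
    if mode not in ("univariable", "multivariable"):
        raise ValueError("mode must be 'univariable' or 'multivariable'")
    df = _prepare(records, covariates, duration_col, event_col)
    for c in covariates:
        if df[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant")
    if mode == "multivariable":
        return _fit_one(df, list(covariates), duration_col, event_col, mode)
    results = []
    for c in covariates:
        results.extend(_fit_one(df, [c], duration_col, event_col, mode))
    return results


def cox_table(results: list[CoxResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results])


def mann_whitney(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U (exact for small tie-free samples)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two observations")
    small = len(a) <= 8 and len(b) <= 8
    no_ties = len(np.unique(np.concatenate([a, b]))) == len(a) + len(b)
    method = "exact" if (small and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
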