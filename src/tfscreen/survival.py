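"""Survival analysis: marker dichotomization, Kaplan–Meier, log-rank, Cox.

The marker (gene expression) is split into high/low groups at the median by
default (mean available), curves are estimated with the product-limit
estimator, groups compared with the log-rank (Mantel–Cox) test, and
adjusted hazard ratios obtained from a Cox proportional-hazards model with
Efron handling of tied event times.  Categorical covariates are dummy-coded
against an explicit reference level; subjects with a missing category can be
retained through an explicit "missing" level.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


def dichotomize(values, method: str = "median") -> tuple[pd.Series, float]:
    """Split marker values into high/low at the median or mean.

    Returns a boolean Series (True = high, strictly above the cutpoint) and
    the cutpoint itself.  A constant marker cannot be split and raises.
    """
    values = pd.Series(values)
    if values.nunique() < 2:
        raise ValueError("marker is constant; cannot dichotomize")
    if method == "median":
        cut = float(values.median())
    elif method == "mean":
        cut = float(values.mean())
    else:
        raise ValueError(f"unknown method {method!r}; use 'median' or 'mean'")
    return values > cut, cut


def km_fit(times, events, groups) -> pd.DataFrame:
    """Product-limit survival curves per group.

    Returns a long DataFrame with columns group, time, survival, at_risk,
    events; survival starts at 1 and is non-increasing within each group.
    """
    times = np.asarray(times, dtype=float)
    if (times < 0).any():
        raise ValueError("negative survival time")
    events = np.asarray(events, dtype=int)
    groups = pd.Series(list(groups))
    frames = []
    for g in groups.unique():
        mask = (groups == g).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        tab = kmf.event_table
        surv = kmf.survival_function_["KM_estimate"]
        frames.append(
            pd.DataFrame(
                {
                    "group": g,
                    "time": tab.index.to_numpy(),
                    "survival": surv.reindex(tab.index).to_numpy(),
                    "at_risk": tab["at_risk"].to_numpy(),
                    "events": tab["observed"].to_numpy(),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Log-rank (Mantel–Cox) chi-square statistic and p-value, 1 df for 2 groups."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() == 0:
        warnings.warn("no events observed; log-rank p = 1", stacklevel=2)
        return 0.0, 1.0
    res = multivariate_logrank_test(times, list(groups), events)
    return float(res.test_statistic), float(res.p_value)


def prepare_design(
    cohort: pd.DataFrame,
    categorical: dict[str, str] | None = None,
    missing_level: str = "missing",
) -> pd.DataFrame:
    """Dummy-code categorical covariates against declared reference levels.

    ``categorical`` maps column name -> reference level.  NaNs in a
    categorical column become an explicit ``missing`` level so those
    subjects stay in the fit.
    """
    out = cohort.copy()
    for col, ref in (categorical or {}).items():
        filled = out[col].astype(object).where(out[col].notna(), missing_level)
        levels = [l for l in pd.unique(filled) if l != ref]
        if ref not in set(filled):
            raise ValueError(f"reference level {ref!r} absent from column {col!r}")
        for level in levels:
            out[f"{col}[{level}]"] = (filled == level).astype(float)
        out = out.drop(columns=col)
    return out


def cox_fit(
    cohort: pd.DataFrame,
    duration_col: str = "time",
    event_col: str = "event",
    terms: list[str] | None = None,
    categorical: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties) with Wald intervals.

    Returns a Table-2-style summary DataFrame indexed by term with columns
    coef, hr, ci_low, ci_high, se and p.
    """
    data = prepare_design(cohort, categorical)
    if terms is not None:
        expanded = [
            c for c in data.columns
            if c in terms or any(c.startswith(f"{t}[") for t in terms)
        ]
        data = data[[duration_col, event_col, *expanded]]
    if data[event_col].sum() == 0:
        raise ValueError("no events; Cox model cannot be fit")
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    s = cph.summary
    return pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": np.exp(s["coef"]),
            "ci_low": np.exp(s["coef"] - 1.96 * s["se(coef)"]),
            "ci_high": np.exp(s["coef"] + 1.96 * s["se(coef)"]),
            "se": s["se(coef)"],
            "p": s["p"],
        }
    )
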