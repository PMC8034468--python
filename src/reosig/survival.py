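"""Survival evaluation of predicted risk groups.

Thin, validated wrappers over lifelines: Kaplan-Meier product-limit curves,
the two-group log-rank test, Cox proportional-hazards fits (Efron handling of
tied event times) and the Schoenfeld-residual test of the proportionality
assumption. Records are rows of a DataFrame with ``time`` (months, > 0),
``event`` (1 = relapse/event, 0 = censored), a ``risk_group`` label and
optional covariate columns.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import proportional_hazard_test

__all__ = [
    "km_curve",
    "logrank_test",
    "CoxResult",
    "cox_fit",
    "schoenfeld_test",
    "truncate_followup",
]


def _check_records(records: pd.DataFrame) -> pd.DataFrame:
    if len(records) == 0:
        raise ValueError("no survival records")
    if (records["time"] <= 0).any():
        raise ValueError("follow-up times must be positive")
    if not records["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 or 1")
    return records


def km_curve(records: pd.DataFrame) -> pd.DataFrame:
    """Product-limit survival estimate; returns (time, survival) step points.

    Survival starts at 1.0 (time 0) and is nonincreasing; right-censoring is
    honoured.
    """
    _check_records(records)
    fitter = KaplanMeierFitter()
    fitter.fit(records["time"], records["event"])
    curve = fitter.survival_function_
    return pd.DataFrame(
        {"time": curve.index.to_numpy(dtype=float),
         "survival": curve.iloc[:, 0].to_numpy(dtype=float)}
    )


def logrank_test(records_a: pd.DataFrame, records_b: pd.DataFrame) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value).

    With no events in either group the test is undefined and (0, 1) is
    returned.
    """
    _check_records(records_a)
    _check_records(records_b)
    if records_a["event"].sum() + records_b["event"].sum() == 0:
        return 0.0, 1.0
    result = _ll_logrank(
        records_a["time"], records_b["time"],
        event_observed_A=records_a["event"], event_observed_B=records_b["event"],
    )
    return float(result.test_statistic), float(result.p_value)


@dataclasses.dataclass
class CoxResult:
    """Cox fit summary: per-term HR, 95% CI and Wald p, plus diagnostics."""

    summary: pd.DataFrame  # index: term; columns hr, ci_lower, ci_upper, coef, se, p
    converged: bool
    n_used: int
    n_dropped: int
    model: CoxPHFitter | None = None
    data: pd.DataFrame | None = None

    def hazard_ratio(self, term: str) -> float:
        return float(self.summary.loc[term, "hr"])


def cox_fit(
    records: pd.DataFrame,
    covariates: list[str] | None = None,
    risk_col: str = "risk_group",
    high_label: str = "high_risk",
) -> CoxResult:
    """Cox proportional-hazards fit of event times on the predicted risk group.

    The risk group enters as an indicator (1 = ``high_label``); extra
    covariate columns may be added to the formula. Records with a missing
    covariate are dropped and counted in ``n_dropped``. Ties use the Efron
    approximation (lifelines default). Non-convergence (e.g. complete
    separation) is flagged rather than raised.
    """
    _check_records(records)
    covariates = covariates or []
    if records[risk_col].nunique() < 2:
        raise ValueError("need at least two distinct risk groups")
    if records["event"].sum() == 0:
        raise ValueError("no events observed")
    cols = ["time", "event", risk_col] + covariates
    data = records[cols].copy()
    n_before = len(data)
    data = data.dropna()
    data[risk_col] = (data[risk_col] == high_label).astype(float)
    data = pd.get_dummies(data, drop_first=True, dtype=float)
    fitter = CoxPHFitter()
    try:
        with np.errstate(all="ignore"):
            fitter.fit(data, duration_col="time", event_col="event")
        converged = True
    except ConvergenceError:
        return CoxResult(
            summary=pd.DataFrame(), converged=False,
            n_used=len(data), n_dropped=n_before - len(data),
        )
    raw = fitter.summary
    summary = pd.DataFrame(
        {
            "hr": np.exp(raw["coef"]),
            "ci_lower": np.exp(raw["coef lower 95%"]),
            "ci_upper": np.exp(raw["coef upper 95%"]),
            "coef": raw["coef"],
            "se": raw["se(coef)"],
            "p": raw["p"],
        }
    )
    return CoxResult(
        summary=summary, converged=True,
        n_used=len(data), n_dropped=n_before - len(data),
        model=fitter, data=data,
    )


def schoenfeld_test(result: CoxResult, term: str | None = None) -> float:
    """Schoenfeld-residual test of the proportional-hazards assumption.

    Correlates scaled Schoenfeld residuals with event-time rank; returns the
    p-value for ``term`` (default: the risk-group indicator, i.e. the first
    fitted term). Requires a converged fit with at least three events.
    """
    if not result.converged or result.model is None or result.data is None:
        raise ValueError("Schoenfeld test requires a converged Cox fit")
    if int(result.data["event"].sum()) < 3:
        raise ValueError("Schoenfeld test needs at least three events")
    test = proportional_hazard_test(result.model, result.data, time_transform="rank")
    table = test.summary
    if term is None:
        term = result.summary.index[0]
    return float(table.loc[term, "p"].iloc[0] if hasattr(table.loc[term, "p"], "iloc")
                 else table.loc[term, "p"])


def truncate_followup(records: pd.DataFrame, horizon: float) -> pd.DataFrame:
    """Administrative censoring at a horizon (e.g. 36 or 60 months).

    Events after the horizon become censored observations at the horizon;
    follow-up times are capped there.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    out = records.copy()
    late = out["time"] > horizon
    out.loc[late, "event"] = 0
    out.loc[late, "time"] = horizon
    return out
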