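"""Kaplan–Meier estimation, log-rank tests and Cox proportional hazards.

Thin, typed wrappers around lifelines with the conventions used across the
pipeline: times in days, event = 1 for death/progression, Efron handling of
tied event times, and Wald 95% confidence intervals on hazard ratios.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


class SurvivalError(ValueError):
    pass


@dataclasses.dataclass
class SurvivalData:
    """Right-censored survival outcomes for a cohort.

    time : positive event/censoring times (days).
    event : 1 = event observed, 0 = censored.
    endpoint : label, e.g. 'OS' or 'DFS'.
    """

    time: np.ndarray
    event: np.ndarray
    endpoint: str = "OS"
    patient_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise SurvivalError("time and event must be aligned")
        if self.time.size == 0:
            raise SurvivalError("no subjects")
        if not np.all(np.isfinite(self.time)) or np.any(self.time <= 0):
            raise SurvivalError("times must be positive and finite")
        if not np.all(np.isin(self.event, (0, 1))):
            raise SurvivalError("event must be 0 or 1")
        if self.patient_ids is None:
            self.patient_ids = np.arange(self.time.size)
        else:
            self.patient_ids = np.asarray(self.patient_ids)

    @property
    def n(self) -> int:
        return self.time.size

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(
            self.time[idx], self.event[idx], self.endpoint, self.patient_ids[idx]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_ids,
                "time_days": self.time,
                "event": self.event,
                "endpoint": self.endpoint,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, endpoint: str = "OS") -> "SurvivalData":
        sub = df[df["endpoint"] == endpoint] if "endpoint" in df else df
        return cls(
            sub["time_days"].to_numpy(),
            sub["event"].to_numpy(),
            endpoint,
            sub["patient_id"].to_numpy() if "patient_id" in sub else None,
        )


@dataclasses.dataclass
class CoxFit:
    """Result of a Cox proportional-hazards fit (one row per covariate)."""

    covariates: list[str]
    coef: np.ndarray
    se: np.ndarray
    hr: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    p: np.ndarray
    converged: bool
    ties: str = "efron"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "covariate": self.covariates,
                "coef": self.coef,
                "se": self.se,
                "HR": self.hr,
                "CI95_lower": self.ci_lower,
                "CI95_upper": self.ci_upper,
                "p": self.p,
            }
        )


def km_estimate(data: SurvivalData) -> pd.DataFrame:
    """Product-limit survival curve: time, S(t) and at-risk counts."""
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, data.event)
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    return pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(),
            "at_risk": table["at_risk"].to_numpy(),
        }
    )


def logrank_test(data: SurvivalData, groups: Sequence) -> tuple[float, int, float]:
    """Log-rank chi-square test across >=2 groups.

    Returns (statistic, degrees of freedom, two-sided p).
    """
    groups = np.asarray(groups)
    if groups.shape[0] != data.n:
        raise SurvivalError("groups must align with subjects")
    labels, counts = np.unique(groups, return_counts=True)
    if labels.size < 2:
        raise SurvivalError("need at least two non-empty groups")
    res = multivariate_logrank_test(data.time, groups, data.event)
    return float(res.test_statistic), int(labels.size - 1), float(res.p_value)


def cox_fit(
    data: SurvivalData,
    covariates: np.ndarray | pd.DataFrame,
    ties: str = "efron",
    names: Sequence[str] | None = None,
) -> CoxFit:
    """Cox proportional-hazards regression via partial likelihood.

    Ties are handled by the Efron correction by default ('breslow' is
    accepted); confidence intervals are Wald, exp(coef +/- 1.96 * SE).
    Constant covariates and non-convergent fits raise rather than return
    silent output.
    """
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        X = covariates.to_numpy(dtype=float)
    else:
        X = np.asarray(covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        names = list(names) if names is not None else [f"x{i}" for i in range(X.shape[1])]
    if X.shape[0] != data.n:
        raise SurvivalError("covariates must align with subjects")
    if data.n <= X.shape[1]:
        raise SurvivalError("need more subjects than covariates")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [names[i] for i in np.where(sds == 0)[0]]
        raise SurvivalError(f"constant covariate(s): {bad}")
    if ties != "efron":
        raise NotImplementedError(
            "only Efron tie handling is available in this build"
        )

    df = pd.DataFrame(X, columns=names)
    df["time"] = data.time
    df["event"] = data.event
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except Exception as exc:  # monotone likelihood, separation, ...
        raise SurvivalError(f"Cox fit failed: {exc}") from exc

    coef = cph.params_.to_numpy()
    se = cph.standard_errors_.to_numpy()
    return CoxFit(
        covariates=names,
        coef=coef,
        se=se,
        hr=np.exp(coef),
        ci_lower=np.exp(coef - 1.959963984540054 * se),
        ci_upper=np.exp(coef + 1.959963984540054 * se),
        p=cph.summary["p"].to_numpy(),
        converged=True,
        ties=ties,
    )
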