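"""Classification metric suite and survival statistics.

Confusion-matrix metrics (accuracy, sensitivity, specificity, precision,
NPV, balanced accuracy, MCC, F1) with explicit zero-denominator
conventions; Kaplan-Meier curves with the log-rank test; Cox proportional
hazards with Efron tie handling and Wald chi-square p-values, via
lifelines.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test

__all__ = [
    "ConfusionCounts",
    "MetricSet",
    "confusion_metrics",
    "km_logrank",
    "cox_ph",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    npv: float
    balanced_accuracy: float
    mcc: float
    f1: float
    undefined: tuple[str, ...] = ()

    def as_dict(self) -> dict[str, float]:
        d = asdict(self)
        d.pop("undefined")
        return d


def confusion_metrics(c: ConfusionCounts) -> MetricSet:
    """Standard closed-form metrics from one confusion matrix.

    Conventions for empty denominators: sensitivity/specificity/precision/
    NPV are 0 (flagged in ``undefined``); MCC is 0 whenever any marginal
    is zero.
    """
    if c.total == 0:
        raise ValueError("confusion matrix is empty")
    undefined: list[str] = []

    def _ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (c.tp + c.tn) / c.total
    sensitivity = _ratio(c.tp, c.tp + c.fn, "sensitivity")
    specificity = _ratio(c.tn, c.tn + c.fp, "specificity")
    precision = _ratio(c.tp, c.tp + c.fp, "precision")
    npv = _ratio(c.tn, c.tn + c.fn, "npv")
    balanced = (sensitivity + specificity) / 2.0
    marg = [c.tp + c.fp, c.tp + c.fn, c.tn + c.fp, c.tn + c.fn]
    if any(m == 0 for m in marg):
        mcc = 0.0
        undefined.append("mcc")
    else:
        mcc = (c.tp * c.tn - c.fp * c.fn) / math.sqrt(
            float(marg[0]) * marg[1] * marg[2] * marg[3]
        )
    if precision + sensitivity == 0:
        f1 = 0.0
        undefined.append("f1")
    else:
        f1 = 2 * precision * sensitivity / (precision + sensitivity)
    return MetricSet(
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        npv=npv,
        balanced_accuracy=balanced,
        mcc=mcc,
        f1=f1,
        undefined=tuple(undefined),
    )


def km_logrank(
    times: np.ndarray, events: np.ndarray, groups: np.ndarray
) -> tuple[dict[object, pd.DataFrame], float, float]:
    """Kaplan-Meier curves per group plus the two-group log-rank test.

    Returns ``(curves, chi_square, p_value)`` where ``curves`` maps each
    group label to its survival table (time, at-risk, events, estimate).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError("log-rank comparison requires exactly two groups")
    if events.sum() == 0:
        raise ValueError("need at least one observed event")
    curves: dict[object, pd.DataFrame] = {}
    for lbl in labels:
        sel = groups == lbl
        if sel.sum() == 0:
            raise ValueError(f"group {lbl!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[sel], events[sel], label=str(lbl))
        tbl = kmf.event_table.copy()
        tbl["estimate"] = kmf.survival_function_.iloc[:, 0].values
        curves[lbl] = tbl
    sel = groups == labels[0]
    res = logrank_test(times[sel], times[~sel], events[sel], events[~sel])
    return curves, float(res.test_statistic), float(res.p_value)


def cox_ph(
    df: pd.DataFrame,
    duration_col: str = "time_months",
    event_col: str = "event",
    covariate_cols: tuple[str, ...] = ("risk_group", "age", "sex", "size_cm"),
) -> pd.DataFrame:
    """Cox proportional-hazards fit (Efron ties, Wald chi-square p-values).

    Binary string covariates (e.g. sex M/F) are dummy-coded.  Returns the
    per-covariate summary with coefficients, hazard ratios, 95% CIs and
    two-sided Wald p-values.
    """
    data = df[[duration_col, event_col, *covariate_cols]].copy()
    for col in covariate_cols:
        if data[col].dtype == object:
            codes, _ = pd.factorize(data[col])
            data[col] = codes
    n_events = int(np.asarray(data[event_col], dtype=bool).sum())
    if n_events < len(covariate_cols) + 1:
        raise ValueError("too few events for the number of covariates")
    cph = CoxPHFitter()
    cph.fit(data, duration_col=duration_col, event_col=event_col)
    summary = cph.summary
    return pd.DataFrame(
        {
            "coef": summary["coef"],
            "hazard_ratio": summary["exp(coef)"],
            "hr_ci_lower": summary["exp(coef) lower 95%"],
            "hr_ci_upper": summary["exp(coef) upper 95%"],
            "wald_p": summary["p"],
        }
    )
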