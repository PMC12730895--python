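"""Outcome evaluation: ROC/AUC, Youden cutoff, Kaplan–Meier curves,
univariate Cox hazard ratio and the TCR x TMB stratified response table.

ROC points use the strict ``score > threshold`` convention so that the
Youden-maximizing threshold composes exactly with the classifier's
"high iff score strictly above cutoff" rule. The trapezoidal AUC under this
convention equals the tie-corrected concordance probability
U / (n1 n2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import stats

from .errors import DegenerateDataError, EvaluationError
from .types import CohortTable


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending; trailing -inf
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float


def roc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC over all distinct score thresholds; tied scores contribute 1/2
    to the AUC through the trapezoid over the tie block."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or (~labels).all():
        raise EvaluationError("ROC undefined with a single outcome class")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    thresholds = np.append(np.unique(scores)[::-1], -np.inf)
    sens = np.empty(len(thresholds))
    spec = np.empty(len(thresholds))
    for i, t in enumerate(thresholds):
        flagged = scores > t
        sens[i] = (flagged & labels).sum() / n_pos
        spec[i] = (~flagged & ~labels).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    return RocCurve(thresholds=thresholds, sensitivity=sens, specificity=spec, auc=auc)


def youden_cutoff(curve: RocCurve) -> float:
    """Threshold maximizing J = sensitivity + specificity - 1; ties break
    toward the smallest threshold (the more sensitive classifier)."""
    j = curve.sensitivity + curve.specificity - 1.0
    best = np.flatnonzero(j >= j.max() - 1e-12)
    return float(curve.thresholds[best[-1]])  # thresholds descend


def kaplan_meier(
    times: Sequence[float],
    events: Sequence[bool],
    groups: Sequence[str],
) -> dict[str, pd.DataFrame]:
    """Product-limit survival estimate per group.

    Returns per group a frame with columns ``time``, ``survival`` and
    ``at_risk``; censored subjects leave the risk set after their time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise EvaluationError("survival times must be >= 0")
    out: dict[str, pd.DataFrame] = {}
    for g in pd.unique(groups):
        mask = groups == g
        kmf = KaplanMeierFitter()
        kmf.fit(times[mask], events[mask])
        table = kmf.event_table
        frame = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
                "at_risk": table["at_risk"].reindex(
                    kmf.survival_function_.index
                ).to_numpy(),
            }
        )
        out[str(g)] = frame
    return out


@dataclass
class CoxResult:
    beta: float
    se: float
    hr: float
    hr_ci: tuple[float, float]
    p_value: float  # Wald
    n_events: int


def _breslow_neg_loglik_terms(
    times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per distinct event time: (#events, #group-1 events, risk-set sizes)."""
    event_times = np.unique(times[events])
    d = np.empty(len(event_times))
    d1 = np.empty(len(event_times))
    n0 = np.empty(len(event_times))
    n1 = np.empty(len(event_times))
    for i, t in enumerate(event_times):
        at_event = events & (times == t)
        risk = times >= t
        d[i] = at_event.sum()
        d1[i] = (at_event & (x == 1)).sum()
        n0[i] = (risk & (x == 0)).sum()
        n1[i] = (risk & (x == 1)).sum()
    return d, d1, np.stack([n0, n1])


def breslow_partial_loglik(
    beta: float, times: np.ndarray, events: np.ndarray, x: np.ndarray
) -> float:
    """Breslow-tied Cox partial log-likelihood for a binary covariate."""
    d, d1, (n0, n1) = _breslow_neg_loglik_terms(times, events, x)
    return float(np.sum(beta * d1 - d * np.log(n0 + n1 * np.exp(beta))))


def cox_univariate(
    times: Sequence[float],
    events: Sequence[bool],
    group: Sequence[int],
    max_iter: int = 100,
    tol: float = 1e-10,
) -> CoxResult:
    """Univariate Cox proportional hazards for a binary group indicator,
    Breslow tie handling, Newton–Raphson, Wald CI and p-value.

    Raises :class:`DegenerateDataError` when a group has no events or the
    partial likelihood is monotone (complete separation of event
    experience) — no silent estimate.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    x = np.asarray(group, dtype=int)
    if set(np.unique(x)) - {0, 1}:
        raise EvaluationError("group indicator must be binary 0/1")
    if not events.any():
        raise DegenerateDataError("no events observed; hazard ratio undefined")
    for g in (0, 1):
        if not events[x == g].any():
            raise DegenerateDataError(
                f"group {g} has no events; Cox estimate would not converge"
            )
    d, d1, (n0, n1) = _breslow_neg_loglik_terms(times, events, x)
    beta = 0.0
    for _ in range(max_iter):
        e = np.exp(beta)
        denom = n0 + n1 * e
        mu = n1 * e / denom  # expected group-1 share of the risk set
        grad = float(np.sum(d1 - d * mu))
        info = float(np.sum(d * mu * (1.0 - mu)))
        if info <= 0:
            raise DegenerateDataError("singular information; degenerate risk sets")
        step = grad / info
        beta += step
        if abs(beta) > 35:
            raise DegenerateDataError(
                "monotone partial likelihood (complete separation); "
                "hazard ratio diverges"
            )
        if abs(step) < tol:
            break
    se = 1.0 / math.sqrt(float(np.sum(d * (n1 * math.exp(beta) /
                                           (n0 + n1 * math.exp(beta))) *
                                      (1 - n1 * math.exp(beta) /
                                       (n0 + n1 * math.exp(beta))))))
    z = beta / se
    p = 2.0 * stats.norm.sf(abs(z))
    ci = (math.exp(beta - 1.959963984540054 * se), math.exp(beta + 1.959963984540054 * se))
    return CoxResult(
        beta=float(beta),
        se=float(se),
        hr=float(math.exp(beta)),
        hr_ci=ci,
        p_value=float(p),
        n_events=int(events.sum()),
    )


@dataclass
class SurvivalFit:
    """Kaplan–Meier curves per group plus the univariate hazard ratio."""

    curves: dict[str, pd.DataFrame]
    cox: CoxResult


def survival_analysis(
    times: Sequence[float], events: Sequence[bool], group: Sequence[int]
) -> SurvivalFit:
    group = np.asarray(group, dtype=int)
    labels = np.where(group == 1, "high", "low")
    return SurvivalFit(
        curves=kaplan_meier(times, events, labels),
        cox=cox_univariate(times, events, group),
    )


def stratified_response_table(
    cohort: CohortTable,
    tmb_cutoff: float = 10.0,
    tcr_cutoff: float | None = None,
) -> pd.DataFrame:
    """Response counts and rates in the four (TCR level x TMB level) strata.

    Defaults: TMB high above 10 mutations/Mb (the regulatory cutoff); TCR
    high above the cohort median entropy. Empty strata report an undefined
    (NaN) rate, never 0.
    """
    labeled = cohort.labeled()
    tmb = pd.to_numeric(labeled["tmb"], errors="coerce")
    tcr = pd.to_numeric(labeled["tcr_entropy"], errors="coerce")
    if tcr_cutoff is None:
        tcr_cutoff = float(tcr.median())
    responder = labeled["outcome"] == "responder"
    rows = []
    for tcr_level, tmb_level in (
        ("low", "low"), ("high", "low"), ("low", "high"), ("high", "high"),
    ):
        mask = (
            ((tcr > tcr_cutoff) == (tcr_level == "high"))
            & ((tmb > tmb_cutoff) == (tmb_level == "high"))
            & tcr.notna()
            & tmb.notna()
        )
        n_resp = int((responder & mask).sum())
        n_non = int((~responder & mask).sum())
        total = n_resp + n_non
        rows.append(
            {
                "tcr_repertoire": tcr_level,
                "tmb": tmb_level,
                "non_responders": n_non,
                "responders": n_resp,
                "response_rate": (n_resp / total) if total else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def auc_compare_report(
    models: Mapping[str, Sequence[float]], labels: Sequence[bool]
) -> tuple[pd.DataFrame, dict[str, RocCurve]]:
    """Per-model AUC table plus the underlying ROC curves (overlay data)."""
    labels = np.asarray(labels, dtype=bool)
    curves = {name: roc(scores, labels) for name, scores in models.items()}
    table = pd.DataFrame(
        [{"model": name, "auc": curve.auc} for name, curve in curves.items()]
    )
    return table, curves
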