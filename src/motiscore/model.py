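"""Score fitting and scoring.

The score is a weighted sum of z-scored biomarkers. Candidates are screened
by two-sided Fisher's exact test (categorical flags) or Mann–Whitney U
(continuous values) at alpha = 0.05, mutually correlated survivors
(Spearman |rho| > 0.5) are pruned keeping the larger effect, and each
retained biomarker's weight is its -log10 p-value normalized so the weights
sum to one. Standardization constants come from the discovery cohort; the
decision cutoff maximizes Youden's J on the discovery ROC.
"""

from __future__ import annotations

import datetime as _dt
import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .errors import FittingError, ScoringError
from .types import (
    BiomarkerPanel,
    CANDIDATE_BIOMARKERS,
    CATEGORICAL_BIOMARKERS,
    CohortTable,
    ScoreModel,
)

#: floor applied to p-values before taking logs (numerical safety)
P_FLOOR = 1e-300


@dataclass
class SelectionEntry:
    name: str
    test_used: str | None  # "fisher" | "mann_whitney" | None (undefined)
    p_value: float | None
    effect_size: float | None
    selected: bool
    rejection_reason: str  # "nonsignificant" | "correlated" | "none"
    retained_partner: str | None = None


SelectionResult = dict[str, SelectionEntry]


def _rank_biserial(x: np.ndarray, y: np.ndarray, u_statistic: float) -> float:
    """|r| = |2 U / (n1 n2) - 1| — common-language effect size on [0, 1]."""
    return abs(2.0 * u_statistic / (len(x) * len(y)) - 1.0)


def _log_odds_effect(table: np.ndarray) -> float:
    """Haldane-corrected |log OR| mapped to [0, 1] via tanh(|logOR|/2)
    (Yule's Q in magnitude), comparable to rank-biserial."""
    a, b = table[0]
    c, d = table[1]
    log_or = math.log(((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5)))
    return abs(math.tanh(log_or / 2.0))


def _test_one(
    values: np.ndarray, responder: np.ndarray, categorical: bool
) -> tuple[str, float, float] | None:
    """Return (test_used, p, effect) or None when the test is undefined."""
    x = values[responder]
    y = values[~responder]
    if len(x) < 2 or len(y) < 2 or len(np.unique(values)) < 2:
        return None
    if categorical:
        present = values != 0
        table = np.array(
            [
                [int(present[responder].sum()), int((~present[responder]).sum())],
                [int(present[~responder].sum()), int((~present[~responder]).sum())],
            ]
        )
        _, p = stats.fisher_exact(table, alternative="two-sided")
        return "fisher", float(p), _log_odds_effect(table)
    # Exact Mann-Whitney for small tie-free samples, otherwise the normal
    # approximation with tie and continuity correction.
    if len(x) <= 8 and len(y) <= 8 and len(np.unique(values)) == len(values):
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return "mann_whitney", float(res.pvalue), _rank_biserial(x, y, float(res.statistic))


def select_biomarkers(
    cohort: CohortTable,
    alpha: float = 0.05,
    candidates: tuple[str, ...] = CANDIDATE_BIOMARKERS,
) -> SelectionResult:
    """Screen each candidate against the binary outcome.

    Missing values are dropped pairwise per biomarker. A biomarker constant
    across all samples is auto-rejected (the test is undefined).
    """
    labeled = cohort.labeled()
    responder = (labeled["outcome"] == "responder").to_numpy()
    if responder.sum() < 2 or (~responder).sum() < 2:
        raise FittingError("need >= 2 samples per outcome group to fit")
    result: SelectionResult = {}
    for name in candidates:
        if name not in labeled.columns:
            continue
        col = pd.to_numeric(labeled[name], errors="coerce").to_numpy(dtype=float)
        keep = ~np.isnan(col)
        outcome = _test_one(
            col[keep], responder[keep], categorical=name in CATEGORICAL_BIOMARKERS
        )
        if outcome is None:
            result[name] = SelectionEntry(
                name, None, None, None, False, "nonsignificant"
            )
            continue
        test_used, p, effect = outcome
        selected = p < alpha
        result[name] = SelectionEntry(
            name,
            test_used,
            p,
            effect,
            selected,
            "none" if selected else "nonsignificant",
        )
    return result


def prune_correlated(
    selection: SelectionResult,
    cohort: CohortTable,
    rho_max: float = 0.5,
) -> SelectionResult:
    """Among selected pairs with Spearman |rho| > rho_max, reject the member
    with the smaller effect size, iterating in descending-|rho| order."""
    labeled = cohort.labeled()
    selected = [n for n, e in selection.items() if e.selected]
    correlations = []
    for a, b in itertools.combinations(selected, 2):
        xa = pd.to_numeric(labeled[a], errors="coerce")
        xb = pd.to_numeric(labeled[b], errors="coerce")
        keep = xa.notna() & xb.notna()
        if keep.sum() < 3:
            continue
        rho = stats.spearmanr(xa[keep], xb[keep]).statistic
        if np.isnan(rho):
            continue
        correlations.append((abs(float(rho)), a, b))
    for rho_abs, a, b in sorted(correlations, reverse=True):
        if rho_abs <= rho_max:
            break
        ea, eb = selection[a], selection[b]
        if not (ea.selected and eb.selected):
            continue
        # smaller effect loses; stable tie-break on candidate order
        loser, keeper = (ea, eb) if ea.effect_size < eb.effect_size else (eb, ea)
        loser.selected = False
        loser.rejection_reason = "correlated"
        loser.retained_partner = keeper.name
    return selection


def fit_weights(selection: SelectionResult) -> dict[str, float]:
    """Normalized -log10 p-value weights over the selected biomarkers."""
    selected = [e for e in selection.values() if e.selected]
    if not selected:
        raise FittingError("no biomarker passed selection; cannot fit weights")
    raw = {e.name: -math.log10(max(e.p_value, P_FLOOR)) for e in selected}
    total = math.fsum(raw.values())
    return {name: value / total for name, value in raw.items()}


def fit_standardization(
    cohort: CohortTable, selected: list[str]
) -> tuple[dict[str, float], dict[str, float]]:
    """Discovery-cohort mean and sample SD (n-1 denominator) per biomarker."""
    labeled = cohort.labeled()
    means, sds = {}, {}
    for name in selected:
        col = pd.to_numeric(labeled[name], errors="coerce").dropna()
        mu = float(col.mean())
        sd = float(col.std(ddof=1))
        if not sd > 0:
            raise FittingError(f"biomarker {name!r} is constant; SD = 0")
        means[name], sds[name] = mu, sd
    return means, sds


def score_sample(
    panel: BiomarkerPanel | dict[str, float], model: ScoreModel
) -> float:
    """Weighted sum of z-scores of the selected biomarkers.

    Missing selected biomarkers raise; nothing is imputed by default.
    """
    values = panel.as_dict() if isinstance(panel, BiomarkerPanel) else dict(panel)
    total = 0.0
    for name in model.selected:
        x = values.get(name)
        if x is None or (isinstance(x, float) and math.isnan(x)):
            raise ScoringError(f"selected biomarker {name!r} missing from panel")
        total += model.weights[name] * (x - model.means[name]) / model.sds[name]
    return total


def score_cohort(cohort: CohortTable, model: ScoreModel) -> pd.Series:
    scores = {}
    for _, row in cohort.frame.iterrows():
        values = {name: row.get(name) for name in model.selected}
        values = {
            k: (None if pd.isna(v) else float(v)) for k, v in values.items()
        }
        scores[row["sample_id"]] = score_sample(values, model)
    return pd.Series(scores, name="motiscore")


def classify(score: float, model: ScoreModel) -> str:
    """"high" iff score strictly exceeds the cutoff; ties classify low
    (conservative toward not recommending therapy)."""
    if model.cutoff is None:
        raise ScoringError("model cutoff is unset; fit or set it first")
    return "high" if score > model.cutoff else "low"


def fit_score_model(
    cohort: CohortTable,
    alpha: float = 0.05,
    rho_max: float = 0.5,
    seed: int | None = None,
    set_cutoff: bool = True,
    candidates: tuple[str, ...] = CANDIDATE_BIOMARKERS,
) -> tuple[ScoreModel, SelectionResult]:
    """Full fit: selection -> correlation pruning -> weights ->
    standardization -> Youden cutoff on the discovery scores."""
    selection = select_biomarkers(cohort, alpha=alpha, candidates=candidates)
    selection = prune_correlated(selection, cohort, rho_max=rho_max)
    weights = fit_weights(selection)
    selected = [n for n in candidates if n in weights]
    means, sds = fit_standardization(cohort, selected)
    model = ScoreModel(
        selected=selected,
        p_values={n: selection[n].p_value for n in selected},
        weights={n: weights[n] for n in selected},
        means=means,
        sds=sds,
        cutoff=None,
        provenance={
            "n": int(len(cohort.labeled())),
            "n_responders": int(cohort.responder_mask().sum()),
            "seed": seed,
            "date": _dt.date.today().isoformat(),
        },
    )
    if set_cutoff:
        from .evaluation import roc, youden_cutoff

        labeled_ids = cohort.labeled()["sample_id"]
        scores = score_cohort(cohort, model).loc[labeled_ids]
        labels = (cohort.labeled()["outcome"] == "responder").to_numpy()
        model.cutoff = float(youden_cutoff(roc(scores.to_numpy(), labels)))
    model.validate()
    return model, selection


def selection_report(selection: SelectionResult) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "biomarker": e.name,
                "test": e.test_used,
                "p_value": e.p_value,
                "effect_size": e.effect_size,
                "selected": e.selected,
                "rejection_reason": e.rejection_reason,
                "retained_partner": e.retained_partner,
            }
            for e in selection.values()
        ]
    )
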