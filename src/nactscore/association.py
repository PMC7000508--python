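"""Cohort-adjusted logistic association of signature z-scores with pCR.

Models are of the form

    logit P(pCR) = intercept + β·z_score [+ β2·z_other] + cohort dummies

with cohort entered as reference-coded categorical dummies (alphabetically
first cohort as reference — the score odds ratios are invariant to that
choice).  Odds ratios are per 1 SD of the score (the predictors are
per-cohort z-scores); confidence intervals are Wald, exp(β ± z·SE), and
p-values are two-sided Wald.  No clinical covariates, interactions, or
multiplicity adjustment enter the models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .expression_io import ClinicalTable, GeneExpression, select_er_pos_her2_neg
from .logistic import LogisticFit, fit_logistic
from .scoring import build_score_table
from .signatures import SignatureDefinition

_PREDICTOR_COLUMNS = {"ms12": "z_ms12", "rs21": "z_rs21"}
_COLLINEARITY_LIMIT = 0.999


@dataclass
class AssociationResult:
    """Fitted model summary for one (single or combined) association model.

    ``table`` has one row per score predictor with columns coef, se, or,
    ci_low, ci_high, p.  ``params`` keeps the full coefficient vector
    (intercept, scores, cohort dummies) and ``sample_cohorts`` the cohort
    label of each analysis sample, which together suffice to reconstruct
    predicted probabilities.
    """

    model: str
    table: pd.DataFrame
    n: int
    events: int
    cohorts: list[str]
    reference_cohort: str
    converged: bool
    loglik: float
    threshold_percentile: float | None = None
    params: pd.Series = field(default_factory=pd.Series)
    sample_cohorts: pd.Series = field(default_factory=pd.Series)


def _analysis_frame(
    scores: pd.DataFrame, clin: ClinicalTable
) -> tuple[pd.DataFrame, pd.Series]:
    """Scores restricted to the ER+/HER2− known-response subset, plus outcome."""
    ids = [s for s in select_er_pos_her2_neg(clin, require_response=True)
           if s in scores.index]
    if not ids:
        raise ValidationError("analysis subset is empty (no scored ER+/HER2− "
                              "samples with known response)")
    sub = scores.loc[ids]
    pcr = clin.data.set_index("sample_id")["pcr"]
    y = pcr.loc[ids].astype(int)
    return sub, y


def _design(sub: pd.DataFrame, predictors: list[str]) -> tuple[np.ndarray, list[str], str]:
    cohorts = sorted(sub["cohort"].unique())
    reference = cohorts[0]
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for pred in predictors:
        cols.append(sub[pred].to_numpy(dtype=float))
        names.append(pred)
    for cohort in cohorts[1:]:
        cols.append((sub["cohort"] == cohort).to_numpy(dtype=float))
        names.append(f"cohort[{cohort}]")
    return np.column_stack(cols), names, reference


def _fit(sub: pd.DataFrame, y: pd.Series, predictors: list[str]) -> tuple[LogisticFit, list[str], str]:
    X, names, reference = _design(sub, predictors)
    fit = fit_logistic(y.to_numpy(), X, names=names)
    return fit, names, reference


def _result(
    model: str,
    fit: LogisticFit,
    names: list[str],
    predictors: list[str],
    sub: pd.DataFrame,
    y: pd.Series,
    reference: str,
    threshold_percentile: float | None,
) -> AssociationResult:
    summ = fit.wald_summary()
    rows = []
    for pred in predictors:
        i = names.index(pred)
        rows.append(
            {
                "predictor": pred,
                "coef": summ["coef"][i],
                "se": summ["se"][i],
                "or": summ["or"][i],
                "ci_low": summ["ci_low"][i],
                "ci_high": summ["ci_high"][i],
                "p": summ["p"][i],
            }
        )
    return AssociationResult(
        model=model,
        table=pd.DataFrame(rows).set_index("predictor"),
        n=len(sub),
        events=int(y.sum()),
        cohorts=sorted(sub["cohort"].unique()),
        reference_cohort=reference,
        converged=fit.converged,
        loglik=fit.loglik,
        threshold_percentile=threshold_percentile,
        params=pd.Series(fit.params, index=names),
        sample_cohorts=sub["cohort"].copy(),
    )


def single_score_association(
    scores: pd.DataFrame,
    clin: ClinicalTable,
    which: str,
    threshold_percentile: float | None = None,
) -> AssociationResult:
    """Cohort-adjusted logistic model of pCR on one signature z-score."""
    if which not in _PREDICTOR_COLUMNS:
        raise ValidationError(f"unknown score '{which}' (expected ms12 or rs21)")
    pred = _PREDICTOR_COLUMNS[which]
    sub, y = _analysis_frame(scores, clin)
    fit, names, reference = _fit(sub, y, [pred])
    return _result(f"single:{which}", fit, names, [pred], sub, y, reference,
                   threshold_percentile)


def combined_association(
    scores: pd.DataFrame,
    clin: ClinicalTable,
    threshold_percentile: float | None = None,
) -> AssociationResult:
    """Cohort-adjusted logistic model including both signature z-scores."""
    sub, y = _analysis_frame(scores, clin)
    r = np.corrcoef(sub["z_ms12"], sub["z_rs21"])[0, 1]
    if abs(r) > _COLLINEARITY_LIMIT:
        raise ValidationError(
            f"scores are near-collinear (|r| = {abs(r):.4f} > {_COLLINEARITY_LIMIT}); "
            "fit single-score models instead"
        )
    preds = ["z_ms12", "z_rs21"]
    fit, names, reference = _fit(sub, y, preds)
    return _result("combined", fit, names, preds, sub, y, reference,
                   threshold_percentile)


def response_probability_curve(
    result: AssociationResult, grid: np.ndarray | None = None
) -> pd.DataFrame:
    """Marginally standardized probability-of-response curve.

    For each grid value z of the (single) score, the predicted probability is
    the average over the analysis samples' cohort memberships of
    inverse-logit(intercept + β·z + cohort effect).  Grid values outside
    [−5, 5] trigger a warning but are still computed.
    """
    preds = [n for n in result.params.index if n.startswith("z_")]
    if len(preds) != 1:
        raise ValidationError("response curve requires a single-score model")
    if grid is None:
        grid = np.linspace(-3.0, 3.0, 61)
    grid = np.asarray(grid, dtype=float)
    if grid.size and (grid.min() < -5 or grid.max() > 5):
        warnings.warn("response-curve grid extends outside [-5, 5]", stacklevel=2)
    beta = result.params[preds[0]]
    offsets = np.full(len(result.sample_cohorts), result.params["intercept"])
    for i, cohort in enumerate(result.sample_cohorts):
        key = f"cohort[{cohort}]"
        if key in result.params.index:
            offsets[i] += result.params[key]
    probs = [float(np.mean(expit(offsets + beta * z))) for z in grid]
    return pd.DataFrame({"z": grid, "probability": probs})


def score_correlation(scores: pd.DataFrame, subset=None) -> tuple[float, pd.Series]:
    """Pearson correlation of the two z-scores, pooled and per cohort.

    Pooling the per-cohort z-scores removes cohort location/scale, so the
    pooled r is not confounded by platform shifts.
    """
    sub = scores if subset is None else scores.loc[[s for s in subset if s in scores.index]]
    if len(sub) < 3:
        raise ValidationError("score correlation needs at least 3 samples")
    for col in ("z_ms12", "z_rs21"):
        if sub[col].std(ddof=1) == 0:
            raise ValidationError(f"zero variance in {col}")
    pooled = float(np.corrcoef(sub["z_ms12"], sub["z_rs21"])[0, 1])
    per_cohort = (
        sub.groupby("cohort")
        .apply(lambda d: float(np.corrcoef(d["z_ms12"], d["z_rs21"])[0, 1]),
               include_groups=False)
        .rename("r")
    )
    return pooled, per_cohort


def sensitivity_sweep(
    gene_expression: dict[str, GeneExpression],
    clin: ClinicalTable,
    ms12: SignatureDefinition,
    rs21: SignatureDefinition,
    grid: tuple[float, ...] = (75.0, 80.0, 85.0, 90.0),
) -> pd.DataFrame:
    """Proliferation-floor sensitivity analysis.

    For each percentile in ``grid`` the RS is recomputed (re-floor →
    re-combine → re-z-score) and both the single-score RS model and the
    combined model are refitted; the MS columns come from the combined model
    (the MS itself has no threshold and is recomputed identically each time).
    Returns one row per percentile.
    """
    rows = []
    for p in grid:
        if not 0.0 <= p <= 100.0:
            raise ValidationError(f"sweep percentile {p} not in [0, 100]")
        table = build_score_table(gene_expression, clin, ms12, rs21, percentile=p)
        rs_single = single_score_association(table, clin, "rs21", threshold_percentile=p)
        comb = combined_association(table, clin, threshold_percentile=p)
        row = {"percentile": p}
        for prefix, res, pred in (
            ("rs_single", rs_single, "z_rs21"),
            ("comb_ms", comb, "z_ms12"),
            ("comb_rs", comb, "z_rs21"),
        ):
            t = res.table.loc[pred]
            row.update(
                {
                    f"{prefix}_coef": t["coef"],
                    f"{prefix}_or": t["or"],
                    f"{prefix}_ci_low": t["ci_low"],
                    f"{prefix}_ci_high": t["ci_high"],
                    f"{prefix}_p": t["p"],
                }
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("percentile")
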