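"""Signature score computation: group averaging, percentile floor, linear
combination, and per-cohort z-standardization.

The central object is the score table: one row per sample with the raw and
per-cohort z-scored values of both signatures.  z-scores use the sample
standard deviation (denominator n−1) computed over the analysis subset
(ER-positive/HER2-negative samples with known response), so the logistic
odds ratios downstream are "per 1 SD" in the analysis population.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError
from .expression_io import ClinicalTable, GeneExpression, select_er_pos_her2_neg
from .signatures import SignatureDefinition

SCORE_COLUMNS = ("sample_id", "cohort", "raw_ms12", "raw_rs21", "z_ms12", "z_rs21")


def compute_group_scores(
    g: GeneExpression, sig: SignatureDefinition, missing_policy: str = "renormalize"
) -> pd.DataFrame:
    """Per-sample group scores and singleton gene values.

    Returns a DataFrame (samples x [group labels + singleton genes]).  Each
    group score is the weighted mean of its member genes.  Under the
    ``renormalize`` policy a group member absent from ``g`` is dropped and
    the remaining weights renormalized (the weighted mean of the genes that
    are present); under ``strict`` any absent gene is an error.  A group with
    *all* members missing, or a missing singleton gene, is always an error.
    """
    if missing_policy not in {"renormalize", "strict"}:
        raise ValidationError(f"unknown missing_policy '{missing_policy}'")
    present = set(g.genes)
    out: dict[str, pd.Series] = {}
    for gname, members in sig.groups.items():
        have = {gene: w for gene, w in members.items() if gene in present}
        absent = sorted(set(members) - set(have))
        if not have:
            raise ValidationError(
                f"signature '{sig.name}': all genes of group '{gname}' missing "
                f"from cohort '{g.cohort_id}': {absent}"
            )
        if absent and missing_policy == "strict":
            raise ValidationError(
                f"signature '{sig.name}': group '{gname}' gene(s) {absent} "
                f"missing from cohort '{g.cohort_id}'"
            )
        weights = np.array(list(have.values()), dtype=float)
        block = g.values.loc[list(have)]
        out[gname] = block.mul(weights, axis=0).sum(axis=0) / weights.sum()
    for gene in sig.singleton_weights:
        if gene not in present:
            raise ValidationError(
                f"signature '{sig.name}': singleton gene '{gene}' missing from "
                f"cohort '{g.cohort_id}'"
            )
        out[gene] = g.values.loc[gene]
    return pd.DataFrame(out, index=g.sample_ids)


def apply_percentile_floor(
    values: pd.Series, reference: Iterable[str], p: float
) -> pd.Series:
    """Floor ``values`` at the p-th percentile of the reference subset.

    The percentile uses linear interpolation between order statistics
    (position h = (n−1)·p/100 + 1).  The floor is applied to *all* samples;
    ``p = 0`` returns the input unchanged.
    """
    if not 0.0 <= p <= 100.0:
        raise ValidationError(f"percentile {p} not in [0, 100]")
    if p == 0:
        return values.copy()
    ref_ids = [s for s in reference if s in values.index]
    if not ref_ids:
        raise ValidationError("percentile floor: empty reference subset")
    t = float(np.percentile(values.loc[ref_ids].to_numpy(), p))
    return values.clip(lower=t)


def combine_score(group_scores: pd.DataFrame, sig: SignatureDefinition) -> pd.Series:
    """Linear combination: Σ group_weight·group score + Σ singleton weight·gene."""
    score = pd.Series(0.0, index=group_scores.index)
    for gname, w in sig.group_weights.items():
        if gname not in group_scores.columns:
            raise ValidationError(f"group '{gname}' missing from group scores")
        score += w * group_scores[gname]
    for gene, w in sig.singleton_weights.items():
        if gene not in group_scores.columns:
            raise ValidationError(f"singleton '{gene}' missing from group scores")
        score += w * group_scores[gene]
    score.name = f"raw_{sig.name}"
    return score


def compute_ms12(g: GeneExpression, sig: SignatureDefinition) -> pd.Series:
    """Raw 12-gene MS: weighted sum over the eight target genes.

    All eight genes must be present (no drop policy — at least one probe per
    gene is available on all supported platforms)."""
    gs = compute_group_scores(g, sig, missing_policy="strict")
    return combine_score(gs, sig)


def compute_rs21(
    g: GeneExpression,
    sig: SignatureDefinition,
    er_positive_ids: Iterable[str],
    percentile: float | None = None,
    missing_policy: str = "renormalize",
) -> pd.Series:
    """Raw 21-gene RS with the proliferation floor applied.

    The floor percentile defaults to the signature's threshold policy; the
    reference population is the ER-positive samples of this cohort.
    """
    gs = compute_group_scores(g, sig, missing_policy=missing_policy)
    if sig.threshold is not None:
        p = sig.threshold.percentile if percentile is None else percentile
        gs = gs.copy()
        gs[sig.threshold.group] = apply_percentile_floor(
            gs[sig.threshold.group], er_positive_ids, p
        )
    return combine_score(gs, sig)


def zscore_by_cohort(
    raw: pd.Series, cohorts: pd.Series, subset: Iterable[str] | None = None
) -> pd.Series:
    """Within-cohort z-standardization.

    Mean and sample SD (ddof = 1) are computed over ``subset`` (default: all
    samples) separately per cohort, then applied to every sample of that
    cohort.  A cohort whose subset has fewer than 2 samples or zero variance
    is an error naming the cohort.
    """
    sub = set(subset) if subset is not None else set(raw.index)
    z = pd.Series(np.nan, index=raw.index, dtype=float)
    for cohort in sorted(cohorts.unique()):
        ids = cohorts.index[cohorts == cohort]
        ref = [s for s in ids if s in sub]
        if len(ref) < 2:
            raise ValidationError(
                f"cohort '{cohort}': fewer than 2 analysis samples for z-scoring"
            )
        mu = raw.loc[ref].mean()
        sd = raw.loc[ref].std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValidationError(f"cohort '{cohort}': zero variance in raw score")
        z.loc[ids] = (raw.loc[ids] - mu) / sd
    return z


def build_score_table(
    gene_expression: Mapping[str, GeneExpression],
    clinical: ClinicalTable,
    ms12: SignatureDefinition,
    rs21: SignatureDefinition,
    percentile: float | None = None,
) -> pd.DataFrame:
    """Score every cohort and assemble the per-sample score table.

    Per cohort: compute group scores, floor the RS proliferation group at the
    configured (or overridden) percentile of its ER-positive samples, combine
    into raw scores, then z-standardize within cohort over the analysis
    subset (ER+/HER2− with known response).

    Returns a DataFrame indexed by sample_id with columns cohort, raw_ms12,
    raw_rs21, z_ms12, z_rs21.
    """
    analysis_ids = set(select_er_pos_her2_neg(clinical, require_response=True))
    clin = clinical.data
    frames = []
    for cohort in sorted(gene_expression):
        g = gene_expression[cohort]
        cohort_clin = clin[clin["cohort"] == cohort]
        er_pos = cohort_clin.loc[cohort_clin["er_status"] == "positive", "sample_id"]
        ms = compute_ms12(g, ms12)
        rs = compute_rs21(g, rs21, er_positive_ids=er_pos, percentile=percentile)
        frames.append(
            pd.DataFrame({"cohort": cohort, "raw_ms12": ms, "raw_rs21": rs})
        )
    table = pd.concat(frames)
    table.index.name = "sample_id"
    cohorts = table["cohort"]
    table["z_ms12"] = zscore_by_cohort(table["raw_ms12"], cohorts, analysis_ids)
    table["z_rs21"] = zscore_by_cohort(table["raw_rs21"], cohorts, analysis_ids)
    return table


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index_label="sample_id")


def read_score_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    missing = {"cohort", "raw_ms12", "raw_rs21", "z_ms12", "z_rs21"} - set(df.columns)
    if missing:
        raise ValidationError(f"score table missing columns: {sorted(missing)}")
    return df
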