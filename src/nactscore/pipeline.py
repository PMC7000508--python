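"""End-to-end orchestration: read → normalize → collapse → score → models →
report, over multiple cohorts, with deterministic, self-describing outputs.

Numeric report formatting is fixed: odds ratios and confidence limits to two
decimals, p-values to two significant figures.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .association import (
    AssociationResult,
    combined_association,
    response_probability_curve,
    score_correlation,
    sensitivity_sweep,
    single_score_association,
)
from .errors import NactScoreError, PipelineError
from .expression_io import (
    ClinicalTable,
    GeneExpression,
    collapse_probes,
    read_annotation,
    read_clinical,
    read_expression,
    scale_normalize,
    select_er_pos_her2_neg,
)
from .scoring import build_score_table, write_score_table
from .signatures import SignatureDefinition, default_ms12, default_rs21, load_signature

logger = logging.getLogger("nactscore")

DEFAULT_SWEEP_GRID = (75.0, 80.0, 85.0, 90.0)


@dataclass(frozen=True)
class CohortInput:
    """File locations and dialect for one cohort."""

    cohort_id: str
    expression_path: str
    annotation_path: str
    clinical_path: str
    dialect: str = "plain_tsv"
    normalize: bool = False


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    cohorts: list[CohortInput]
    ms12_path: str | None = None
    rs21_path: str | None = None
    threshold_percentile: float = 80.0
    sweep_grid: tuple[float, ...] = DEFAULT_SWEEP_GRID
    output_dir: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cohorts:
            raise NactScoreError("run config needs at least one cohort")
        if not 0.0 <= self.threshold_percentile <= 100.0:
            raise NactScoreError("threshold percentile must be in [0, 100]")

    def signatures(self) -> tuple[SignatureDefinition, SignatureDefinition]:
        ms12 = load_signature(self.ms12_path) if self.ms12_path else default_ms12()
        rs21 = load_signature(self.rs21_path) if self.rs21_path else default_rs21()
        return ms12, rs21


@dataclass
class AnalysisReport:
    """All quantities of a full run, ready for serialization."""

    cohort_summary: pd.DataFrame
    association: pd.DataFrame
    score_table: pd.DataFrame
    pooled_correlation: float
    per_cohort_correlation: pd.Series
    sensitivity: pd.DataFrame | None
    curves: dict[str, pd.DataFrame]
    provenance: dict = field(default_factory=dict)

    @property
    def pooled_pcr_count(self) -> int:
        return int(self.cohort_summary["n_pcr"].sum())


def format_or(x: float) -> str:
    return f"{x:.2f}"


def format_p(p: float) -> str:
    return f"{p:.2g}"


def _cohort_summary(clin: ClinicalTable) -> pd.DataFrame:
    rows = []
    for cohort in clin.cohorts:
        d = clin.data[clin.data["cohort"] == cohort]
        sub = ClinicalTable(d.copy())
        analysis = d["sample_id"].isin(select_er_pos_her2_neg(sub, require_response=False))
        evaluable = d["sample_id"].isin(select_er_pos_her2_neg(sub, require_response=True))
        rows.append(
            {
                "cohort": cohort,
                "n_total": len(d),
                "n_er_pos_her2_neg": int(analysis.sum()),
                "n_with_response": int(evaluable.sum()),
                "n_pcr": int(d.loc[evaluable, "pcr"].sum()),
            }
        )
    return pd.DataFrame(rows).set_index("cohort")


def _association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for pred, t in res.table.iterrows():
            rows.append(
                {
                    "model": res.model,
                    "signature": pred.replace("z_", ""),
                    "or": t["or"],
                    "ci_low": t["ci_low"],
                    "ci_high": t["ci_high"],
                    "p": t["p"],
                    "coef": t["coef"],
                    "se": t["se"],
                    "n": res.n,
                    "events": res.events,
                }
            )
    return pd.DataFrame(rows)


def load_cohort_data(
    cfg: RunConfig,
    genes: list[str],
) -> tuple[dict[str, GeneExpression], ClinicalTable]:
    """Read, optionally normalize, and gene-collapse every configured cohort."""
    gene_expression: dict[str, GeneExpression] = {}
    clin_frames = []
    for ci in cfg.cohorts:
        try:
            m = read_expression(ci.expression_path, dialect=ci.dialect, cohort_id=ci.cohort_id)
            if ci.normalize:
                m = scale_normalize(m)
            ann = read_annotation(ci.annotation_path)
            g = collapse_probes(m, ann, genes)
            if g.missing_genes:
                logger.info(
                    "cohort %s: gene(s) without probes: %s",
                    ci.cohort_id, ", ".join(g.missing_genes),
                )
            clin = read_clinical(ci.clinical_path)
            cdata = clin.data[clin.data["cohort"] == ci.cohort_id]
            if cdata.empty:
                raise NactScoreError(
                    f"clinical file {ci.clinical_path} has no rows for cohort "
                    f"'{ci.cohort_id}'"
                )
        except NactScoreError as exc:
            raise PipelineError("load", ci.cohort_id, exc) from exc
        gene_expression[ci.cohort_id] = g
        clin_frames.append(cdata)
    # canonical row order: results are then invariant (to the byte) under
    # permutation of the configured cohort list
    merged = (
        pd.concat(clin_frames, ignore_index=True)
        .sort_values(["cohort", "sample_id"], kind="mergesort")
        .reset_index(drop=True)
    )
    return gene_expression, ClinicalTable(merged)


def analyze_study(
    gene_expression: dict[str, GeneExpression],
    clinical: ClinicalTable,
    ms12: SignatureDefinition,
    rs21: SignatureDefinition,
    threshold_percentile: float = 80.0,
    sweep_grid: tuple[float, ...] | None = DEFAULT_SWEEP_GRID,
    provenance: dict | None = None,
) -> AnalysisReport:
    """Run scoring + all association analyses on gene-level data in memory."""
    def _stage(stage):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except NactScoreError as exc:
                raise PipelineError(stage, None, exc) from exc
        return wrap

    scores = _stage("score")(
        build_score_table, gene_expression, clinical, ms12, rs21,
        percentile=threshold_percentile,
    )
    ms_single = _stage("associate")(
        single_score_association, scores, clinical, "ms12",
        threshold_percentile=threshold_percentile,
    )
    rs_single = _stage("associate")(
        single_score_association, scores, clinical, "rs21",
        threshold_percentile=threshold_percentile,
    )
    combined = _stage("associate")(
        combined_association, scores, clinical,
        threshold_percentile=threshold_percentile,
    )
    analysis_ids = select_er_pos_her2_neg(clinical, require_response=True)
    pooled_r, per_cohort_r = _stage("correlate")(score_correlation, scores, analysis_ids)
    curves = {
        "ms12": response_probability_curve(ms_single),
        "rs21": response_probability_curve(rs_single),
    }
    sensitivity = None
    if sweep_grid:
        sensitivity = _stage("sweep")(
            sensitivity_sweep, gene_expression, clinical, ms12, rs21, tuple(sweep_grid)
        )
    prov = {
        "package_version": __version__,
        "threshold_percentile": threshold_percentile,
        "sweep_grid": list(sweep_grid) if sweep_grid else [],
        "reference_cohort": ms_single.reference_cohort,
        "n_analysis": ms_single.n,
        "events": ms_single.events,
    }
    if provenance:
        prov.update(provenance)
    logger.info(
        "analysis: n=%d, events=%d, reference cohort=%s, floor percentile=%s",
        ms_single.n, ms_single.events, ms_single.reference_cohort, threshold_percentile,
    )
    return AnalysisReport(
        cohort_summary=_cohort_summary(clinical),
        association=_association_frame([ms_single, rs_single, combined]),
        score_table=scores,
        pooled_correlation=pooled_r,
        per_cohort_correlation=per_cohort_r,
        sensitivity=sensitivity,
        curves=curves,
        provenance=prov,
    )


def write_study_files(study, out_dir: str | Path, dialect: str = "plain_tsv") -> list[CohortInput]:
    """Serialize a synthetic study to the TSV formats the pipeline reads.

    Writes one expression file per cohort (plain TSV or a minimal GEO
    series-matrix text dialect), a shared probe-annotation file, the pooled
    clinical table, and the ground-truth table; returns ready-to-use cohort
    inputs (round-trip guarantee with ``run_full_analysis``).
    """
    from .expression_io import write_annotation, write_clinical, write_expression

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann_path = out / "annotation.tsv"
    clin_path = out / "clinical.tsv"
    write_annotation(study.annotation, ann_path)
    write_clinical(study.clinical, clin_path)
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    inputs = []
    for name, m in study.expression.items():
        path = out / f"{name}_expression.tsv"
        if dialect == "series_matrix":
            body = m.values.to_csv(sep="\t", float_format="%.6g", index_label="ID_REF")
            path.write_text(
                '!Series_title\t"synthetic study"\n'
                "!series_matrix_table_begin\n" + body + "!series_matrix_table_end\n"
            )
        else:
            write_expression(m, path)
        inputs.append(
            CohortInput(name, str(path), str(ann_path), str(clin_path), dialect=dialect)
        )
    return inputs


def run_full_analysis(cfg: RunConfig) -> AnalysisReport:
    """Execute the full pipeline from files, per the run configuration."""
    ms12, rs21 = cfg.signatures()
    genes = sorted(set(ms12.genes) | set(rs21.genes))
    gene_expression, clinical = load_cohort_data(cfg, genes)
    analysis_spec = repr(
        (
            sorted((c.cohort_id, c.dialect, c.normalize) for c in cfg.cohorts),
            cfg.ms12_path,
            cfg.rs21_path,
            cfg.threshold_percentile,
            tuple(cfg.sweep_grid),
        )
    )
    prov = {
        "config_hash": hashlib.sha256(analysis_spec.encode()).hexdigest()[:16],
        "dialects": {c.cohort_id: c.dialect for c in cfg.cohorts},
        "seed": cfg.seed,
    }
    report = analyze_study(
        gene_expression, clinical, ms12, rs21,
        threshold_percentile=cfg.threshold_percentile,
        sweep_grid=cfg.sweep_grid,
        provenance=prov,
    )
    if cfg.output_dir:
        write_report(report, cfg.output_dir)
    return report


def render_association_text(report: AnalysisReport) -> str:
    """Human-readable association block (single-score and combined models)."""
    lines = ["Association of expression scores with pCR (OR per 1 SD)", ""]
    assoc = report.association
    for block, title in (("single", "Single score analysis"), ("combined", "Combined analysis")):
        lines.append(title)
        sel = assoc[assoc["model"].str.startswith(block)]
        for _, row in sel.iterrows():
            name = {"ms12": "12-gene MS", "rs21": "21-gene RS"}[row["signature"]]
            lines.append(
                f"  {name:<12} OR {format_or(row['or'])} "
                f"(95% CI {format_or(row['ci_low'])}, {format_or(row['ci_high'])}) "
                f"p = {format_p(row['p'])}"
            )
        lines.append("")
    lines.append(
        f"n = {int(assoc['n'].iloc[0])}, events = {int(assoc['events'].iloc[0])}, "
        f"pooled score correlation r = {report.pooled_correlation:.2f}"
    )
    return "\n".join(lines) + "\n"


def write_report(report: AnalysisReport, out_dir: str | Path) -> list[Path]:
    """Serialize a report: TSV tables, curve data, and a text summary.

    On failure, files already written for this report are removed so no
    partial output survives.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        def _w(name: str, writer) -> None:
            path = out / name
            writer(path)
            written.append(path)

        _w("cohort_summary.tsv", lambda p: report.cohort_summary.to_csv(p, sep="\t"))
        _w("association.tsv", lambda p: report.association.assign(
            **{
                "or": report.association["or"].map(format_or),
                "ci_low": report.association["ci_low"].map(format_or),
                "ci_high": report.association["ci_high"].map(format_or),
                "p": report.association["p"].map(format_p),
            }
        ).to_csv(p, sep="\t", index=False))
        _w("scores.tsv", lambda p: write_score_table(report.score_table, p))
        _w("correlation.tsv", lambda p: report.per_cohort_correlation.to_frame().assign(
            pooled=report.pooled_correlation).to_csv(p, sep="\t"))
        for name, curve in report.curves.items():
            _w(f"curve_{name}.tsv", lambda p, c=curve: c.to_csv(p, sep="\t", index=False))
        if report.sensitivity is not None and len(report.sensitivity):
            _w("sensitivity.tsv", lambda p: report.sensitivity.to_csv(p, sep="\t"))
        else:
            logger.info("sensitivity grid empty; sweep file omitted")
        _w("report.txt", lambda p: p.write_text(render_association_text(report)))
        _w("provenance.json", lambda p: p.write_text(
            json.dumps(report.provenance, indent=2, sort_keys=True, default=str) + "\n"))
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    return written
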