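"""Reading, validation, normalization and probe collapsing of expression data.

The pipeline consumes probe-level log2 expression matrices that have already
been between-array normalized upstream (RMA for Affymetrix, or similar); the
only normalization offered here is simple-scaling (``scale_normalize``), the
between-array shift used for Illumina bead-chip data.  Two text dialects are
supported: a plain TSV (header row = sample ids, first column = probe ids)
and a minimal GEO series-matrix dialect where the data block sits between
``!series_matrix_table_begin`` / ``!series_matrix_table_end`` markers.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ValidationError

_ER_HER2_POSITIVE = {"p", "pos", "positive", "1"}
_ER_HER2_NEGATIVE = {"n", "neg", "negative", "0"}
_PCR_TRUE = {"1", "true", "yes", "pcr"}
_PCR_FALSE = {"0", "false", "no", "rd"}


@dataclass
class ExpressionMatrix:
    """Probe-level log2 intensities for one cohort (probes x samples)."""

    cohort_id: str
    values: pd.DataFrame  # index = probe ids, columns = sample ids

    def __post_init__(self) -> None:
        idx, cols = self.values.index, self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique())
            raise ValidationError(f"duplicate probe ids: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique())
            raise ValidationError(f"duplicate sample ids: {dups}")
        if self.values.shape[1] < 2:
            raise ValidationError(
                f"cohort '{self.cohort_id}' has {self.values.shape[1]} sample(s); "
                "need at least 2"
            )
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.floating):
            self.values = self.values.astype(float)
            arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)):
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise ValidationError(
                f"non-finite value for probe '{idx[i]}', sample '{cols[j]}'"
            )

    @property
    def probe_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ProbeAnnotation:
    """Mapping from probe id to gene symbol (many probes may share a gene)."""

    mapping: Mapping[str, str]

    def __post_init__(self) -> None:
        for probe, gene in self.mapping.items():
            if not isinstance(gene, str) or not gene.strip():
                raise ValidationError(f"probe '{probe}' maps to an empty gene symbol")

    def probes_for(self, gene: str) -> list[str]:
        return [p for p, g in self.mapping.items() if g == gene]


@dataclass
class GeneExpression:
    """Gene-level matrix after probe collapsing (genes x samples).

    ``probe_counts`` records, per gene, how many probes were averaged;
    ``missing_genes`` lists requested genes with no mapped probe.
    """

    cohort_id: str
    values: pd.DataFrame
    probe_counts: dict[str, int]
    missing_genes: list[str] = field(default_factory=list)

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class ClinicalTable:
    """Per-sample clinical metadata.

    Columns: sample_id, cohort, er_status and her2_status in
    {"positive", "negative", "unknown"}, pcr as nullable integer (1 = complete
    pathologic response, 0 = residual disease, <NA> = missing).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "cohort", "er_status", "her2_status", "pcr"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns: {sorted(missing)}")
        dup = self.data.duplicated(subset=["cohort", "sample_id"])
        if dup.any():
            bad = self.data.loc[dup, "sample_id"].tolist()
            raise ValidationError(f"duplicate sample ids within cohort: {bad}")
        pcr = self.data["pcr"]
        ok = pcr.isna() | pcr.isin([0, 1])
        if not ok.all():
            raise ValidationError("pcr column must contain only 1, 0 or missing")
        self.data = self.data.reset_index(drop=True)
        self.data["pcr"] = self.data["pcr"].astype("Int64")

    @property
    def cohorts(self) -> list[str]:
        return sorted(self.data["cohort"].unique())

    def subset(self, sample_ids: Iterable[str]) -> "ClinicalTable":
        ids = set(sample_ids)
        return ClinicalTable(self.data[self.data["sample_id"].isin(ids)].copy())


def _parse_numeric_block(text: str, origin: str) -> pd.DataFrame:
    """Parse a TSV block into a float DataFrame, naming any offending cell."""
    df = pd.read_csv(_io.StringIO(text), sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str).str.strip('"')
    df.columns = df.columns.astype(str).str.strip('"')
    if df.index.has_duplicates:
        dups = sorted(df.index[df.index.duplicated()].unique())
        raise ValidationError(f"{origin}: duplicate probe ids: {dups}")
    try:
        return df.astype(float)
    except (TypeError, ValueError):
        for probe, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValidationError(
                        f"{origin}: non-numeric value '{cell}' for probe "
                        f"'{probe}', sample '{sample}'"
                    ) from None
        raise  # pragma: no cover - unreachable


def read_expression(
    path: str | Path, dialect: str = "plain_tsv", cohort_id: str | None = None
) -> ExpressionMatrix:
    """Read a probe-level expression matrix.

    Parameters
    ----------
    path:
        TSV file; header row of sample ids, first column of probe ids.
    dialect:
        ``"plain_tsv"`` or ``"series_matrix"`` (rows outside the
        table-begin/table-end block are skipped).
    cohort_id:
        Cohort label; defaults to the file stem.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"expression file not found: {path}")
    cohort = cohort_id if cohort_id is not None else path.stem
    text = path.read_text()
    if dialect == "plain_tsv":
        block = text
    elif dialect == "series_matrix":
        lines, keep, inside = text.splitlines(), [], False
        for line in lines:
            marker = line.strip().lower()
            if marker.startswith("!series_matrix_table_begin"):
                inside = True
                continue
            if marker.startswith("!series_matrix_table_end"):
                inside = False
                continue
            if inside:
                keep.append(line)
        if not keep:
            raise ValidationError(f"{path}: no series-matrix table block found")
        block = "\n".join(keep)
    else:
        raise ValidationError(
            f"unknown dialect '{dialect}' (expected plain_tsv or series_matrix)"
        )
    values = _parse_numeric_block(block, str(path))
    return ExpressionMatrix(cohort_id=cohort, values=values)


def write_expression(m: ExpressionMatrix, path: str | Path, precision: int = 6) -> None:
    """Write an ExpressionMatrix as plain TSV (round-trips with read_expression)."""
    m.values.to_csv(path, sep="\t", float_format=f"%.{precision}g", index_label="probe_id")


def scale_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Between-array simple-scaling normalization on the log2 scale.

    Each sample column is shifted so that its mean equals the grand mean of
    all column means; within-column variances are untouched.  Idempotent.
    """
    if m.values.shape[1] < 2:
        raise ValidationError("scale_normalize needs at least 2 samples")
    col_means = m.values.mean(axis=0)
    shifted = m.values - (col_means - col_means.mean())
    return ExpressionMatrix(cohort_id=m.cohort_id, values=shifted)


def collapse_probes(
    m: ExpressionMatrix, ann: ProbeAnnotation, genes: Iterable[str]
) -> GeneExpression:
    """Collapse probe rows to gene rows by unweighted averaging.

    All probes annotated to a requested gene are averaged, with no filtering.
    Genes without any mapped probe are reported in ``missing_genes`` rather
    than silently dropped; the caller's signature-level policy decides what
    to do about them.
    """
    genes = list(genes)
    if not genes:
        raise ValidationError("collapse_probes: empty gene list")
    probe_index = pd.Index(m.probe_ids)
    rows, counts, missing = {}, {}, []
    for gene in genes:
        probes = [p for p in ann.probes_for(gene) if p in probe_index]
        if not probes:
            missing.append(gene)
            continue
        rows[gene] = m.values.loc[probes].mean(axis=0)
        counts[gene] = len(probes)
    values = pd.DataFrame(rows).T
    if values.empty:
        values = pd.DataFrame(columns=m.sample_ids, dtype=float)
    values = values[m.sample_ids]
    return GeneExpression(
        cohort_id=m.cohort_id, values=values, probe_counts=counts, missing_genes=missing
    )


def _parse_status(raw: object) -> str:
    s = str(raw).strip().lower()
    if s in _ER_HER2_POSITIVE:
        return "positive"
    if s in _ER_HER2_NEGATIVE:
        return "negative"
    return "unknown"


def _parse_pcr(raw: object):
    s = str(raw).strip().lower()
    if s in _PCR_TRUE:
        return 1
    if s in _PCR_FALSE:
        return 0
    return pd.NA


def read_clinical(path: str | Path) -> ClinicalTable:
    """Read a clinical TSV with columns sample_id, cohort, er_status,
    her2_status, pcr.

    ER/HER2 status accepts {P, pos, positive, 1} / {N, neg, negative, 0}
    case-insensitively; anything else becomes "unknown" (and therefore never
    passes the ER+/HER2− filter).  pcr accepts 1/0 (also yes/no, pCR/RD);
    anything else is missing.
    """
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"clinical file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "cohort", "er_status", "her2_status", "pcr"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: clinical table missing columns {sorted(missing)}")
    out = pd.DataFrame(
        {
            "sample_id": df["sample_id"].astype(str),
            "cohort": df["cohort"].astype(str),
            "er_status": df["er_status"].map(_parse_status),
            "her2_status": df["her2_status"].map(_parse_status),
            "pcr": df["pcr"].map(_parse_pcr),
        }
    )
    return ClinicalTable(out)


def write_clinical(clin: ClinicalTable, path: str | Path) -> None:
    clin.data.to_csv(path, sep="\t", index=False)


def read_annotation(path: str | Path) -> ProbeAnnotation:
    """Read a probe->gene annotation TSV with columns probe_id, gene."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"annotation file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "gene"} <= set(df.columns):
        raise ValidationError(f"{path}: annotation needs columns probe_id, gene")
    df = df.dropna(subset=["gene"])
    if df["probe_id"].duplicated().any():
        dups = sorted(df.loc[df["probe_id"].duplicated(), "probe_id"].unique())
        raise ValidationError(f"{path}: probe(s) mapped more than once: {dups}")
    return ProbeAnnotation(dict(zip(df["probe_id"], df["gene"])))


def write_annotation(ann: ProbeAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        {"probe_id": list(ann.mapping), "gene": list(ann.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def select_er_pos_her2_neg(clin: ClinicalTable, require_response: bool = True) -> list[str]:
    """Sample ids with ER-positive, HER2-negative status (the analysis
    population); with ``require_response``, additionally non-missing pCR.

    Unknown receptor status never passes the filter.  An empty result is
    legal (the caller decides whether that is fatal).
    """
    d = clin.data
    mask = (d["er_status"] == "positive") & (d["her2_status"] == "negative")
    if require_response:
        mask &= d["pcr"].notna()
    return d.loc[mask, "sample_id"].tolist()
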