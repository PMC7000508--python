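"""Published per-cohort summary counts of the six public neo-adjuvant series.

The package ships the cohort-level summary of the six GEO microarray series
(GSE20194, GSE20271, GSE25066, GSE32646, GSE34138, GSE41998): total patients,
total pathologic complete responses, and the same two counts restricted to
the ER-positive/HER2-negative subpopulation.  These counts parameterize the
paper-like simulation defaults and the pooled-count checks; they are summary
statistics, not expression data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd


def published_cohort_table() -> pd.DataFrame:
    """Cohort summary counts, one row per GEO series, indexed by accession."""
    with resources.files("nactscore.data").joinpath("cohorts.tsv").open() as fh:
        df = pd.read_csv(fh, sep="\t")
    return df.set_index("accession")


def pooled_counts() -> dict[str, int]:
    """Pooled evaluable ER+/HER2− sample count and pCR count across cohorts."""
    t = published_cohort_table()
    return {
        "n_er_pos_her2_neg": int(t["n_er_pos_her2_neg"].sum()),
        "n_pcr": int(t["n_pcr_er_pos_her2_neg"].sum()),
    }
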