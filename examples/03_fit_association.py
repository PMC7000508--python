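"""Fit the cohort-adjusted logistic models of pCR on the signature z-scores.

Three models are fitted on the ER+/HER2− analysis subset: each score alone,
and both together, always with the cohort as a categorical adjustment.
Odds ratios are per 1 SD of the score with 95% Wald intervals.
"""

import nactscore as ns

study = ns.generate_study(ns.default_paperlike_config(seed=1))
ms12, rs21 = ns.default_ms12(), ns.default_rs21()
genes = sorted(set(ms12.genes) | set(rs21.genes))
gene_expression = {
    name: ns.collapse_probes(m, study.annotation, genes)
    for name, m in study.expression.items()
}
scores = ns.build_score_table(gene_expression, study.clinical, ms12, rs21)

results = [
    ns.single_score_association(scores, study.clinical, "ms12"),
    ns.single_score_association(scores, study.clinical, "rs21"),
    ns.combined_association(scores, study.clinical),
]
print("model         predictor   OR    95% CI        p")
for res in results:
    for pred, row in res.table.iterrows():
        print(f"{res.model:<13} {pred:<10}  {row['or']:.2f}  "
              f"({row['ci_low']:.2f}, {row['ci_high']:.2f})  {row['p']:.2g}")

curve = ns.response_probability_curve(results[0])
print("\npredicted pCR probability along the 12-gene score (marginal over cohorts):")
for z in (-2, 0, 2):
    p = float(curve.loc[curve["z"].round(1) == z, "probability"].iloc[0])
    print(f"  z = {z:+d}: {100 * p:.1f}%")
print("Single-score odds ratios above 1 mean higher score -> higher response "
      "probability; in the combined model only the better-measured score "
      "retains a significant coefficient.")
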