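"""Sensitivity of the 21-gene score to the proliferation floor percentile.

The Recurrence Score floors its proliferation group average at a percentile
of the ER-positive distribution; everything below the floor becomes the
same value, removing discrimination there.  Sweeping the floor from the
75th to the 90th percentile shows the single-score RS coefficient shrinking
while the combined-model comparison is essentially unchanged.
"""

import nactscore as ns

study = ns.generate_study(ns.default_paperlike_config(seed=1))
ms12, rs21 = ns.default_ms12(), ns.default_rs21()
genes = sorted(set(ms12.genes) | set(rs21.genes))
gene_expression = {
    name: ns.collapse_probes(m, study.annotation, genes)
    for name, m in study.expression.items()
}

table = ns.sensitivity_sweep(
    gene_expression, study.clinical, ms12, rs21, grid=(75.0, 80.0, 85.0, 90.0)
)
view = table[["rs_single_coef", "rs_single_p", "comb_ms_p", "comb_rs_p"]].copy()
view["rs_single_coef"] = view["rs_single_coef"].round(4)
for col in ("rs_single_p", "comb_ms_p", "comb_rs_p"):
    view[col] = view[col].map("{:.2g}".format)
print(view.to_string())
print("\nrs_single_coef falls as the floor rises (less of the proliferation "
      "signal survives); comb_ms_p stays small while comb_rs_p stays large, "
      "so the head-to-head conclusion does not depend on the floor choice.")
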