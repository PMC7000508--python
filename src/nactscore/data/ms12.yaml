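# 12-gene Molecular Score (microarray approximation).
#
# Eight target genes entering the score directly as a weighted sum; the
# assay's four normalization/control genes are not used here because the
# expression matrices arrive already between-array normalized.  Proliferation
# axis genes carry positive weights, ER-signaling axis genes negative weights.
# Downstream analysis z-scores the raw score per cohort, so results are
# invariant to any positive affine rescaling of these weights; only the sign
# pattern and relative magnitudes matter.
name: ms12
groups: {}
group_weights: {}
singleton_weights:
  BIRC5: 0.22
  UBE2C: 0.32
  DHCR7: 0.33
  AZGP1: -0.21
  IL6ST: -0.39
  MGP: -0.10
  RBBP8: -0.07
  STC2: -0.11
threshold: null
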