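# 21-gene Recurrence Score (microarray approximation, unscaled).
#
# Sixteen target genes: four gene groups (proliferation, ER, HER2, invasion)
# plus three singleton genes; the five housekeeper/reference genes are not
# used because matrices arrive already between-array normalized.  Group score
# = weighted mean of member genes (weights below); raw score = sum of
# group_weights x group score + singleton contributions.  The proliferation
# group is floored at a percentile of its distribution in ER-positive
# patients before combination (threshold block below); no clipping to the
# commercial 0-100 report scale is applied.
name: rs21
groups:
  proliferation:
    BIRC5: 1.0
    MKI67: 1.0
    MYBL2: 1.0
    CCNB1: 1.0
    AURKA: 1.0
  er:
    ESR1: 0.8
    PGR: 1.2
    BCL2: 1.0
    SCUBE2: 1.0
  her2:
    GRB7: 0.9
    ERBB2: 0.1
  invasion:
    CTSL2: 1.0
    MMP11: 1.0
group_weights:
  proliferation: 1.04
  er: -0.34
  her2: 0.47
  invasion: 0.10
singleton_weights:
  CD68: 0.05
  GSTM1: -0.08
  BAG1: -0.07
threshold:
  group: proliferation
  percentile: 80.0
  reference: er_positive
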