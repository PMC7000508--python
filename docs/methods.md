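# Methods

## Scope and data model

The package analyzes multi-cohort probe-level log2 expression matrices that
have already been between-array normalized upstream (RMA for Affymetrix
data; for Illumina bead-chip data a simple-scaling step is provided:
each sample column is shifted so its mean equals the grand mean of column
means, which preserves within-sample variances and is idempotent). Raw
CEL/bead-level processing is out of scope by design: the pipeline's own
content begins at the normalized matrix.

Two input text dialects are read: plain TSV (header = sample ids, first
column = probe ids) and a minimal GEO series-matrix dialect (rows between
`!series_matrix_table_begin` / `!series_matrix_table_end`). Anything else is
rejected loudly, as are duplicate probe/sample ids and non-numeric cells
(the error names the probe and sample). Clinical tables carry sample id,
cohort, ER status, HER2 status and pCR; receptor encodings
{P, pos, positive, 1} / {N, neg, negative, 0} are accepted
case-insensitively and anything else becomes *unknown*, which never passes
the ER+/HER2− filter — inconsistent public annotations must fail closed,
not leak into the analysis population.

## Score approximation

Probes are collapsed to genes by the unweighted arithmetic mean of all
probes annotated to the symbol, with no variance or cross-hybridization
filtering; per-gene probe counts are recorded as provenance, and genes with
no probe are reported as missing rather than dropped silently.

Signatures are declarative YAML configs (gene groups with within-group
weights, group weights, singleton weights, optional threshold policy). The
shipped defaults transcribe the two published algorithms' structure:

* `rs21.yaml`: proliferation, ER, HER2, invasion groups plus CD68, GSTM1,
  BAG1 singletons; group weights +1.04 / −0.34 / +0.47 / +0.10; an
  80th-percentile floor on the proliferation group referenced to
  ER-positive patients.
* `ms12.yaml`: eight singleton genes, positive on the proliferation axis
  (BIRC5, UBE2C, DHCR7), negative on the ER axis (AZGP1, IL6ST, MGP, RBBP8,
  STC2).

Config validation checks the *structure and sign pattern* only, not exact
magnitudes: per-cohort z-standardization makes every downstream result
invariant to positive affine rescaling of the weights (verified by test),
so the analysis does not depend on the coefficients' absolute scale. Each
assay's housekeeper/reference genes are unused because the matrices arrive
already normalized. The commercial clip-and-rescale to report ranges is
deliberately not applied: it is not needed for z-scored analysis and would
interact badly with it.

Percentile convention: linear interpolation between order statistics,
position h = (n−1)·p/100 + 1 (numpy's default). The floor threshold is
computed per cohort on the ER-positive samples (consistent with per-cohort
z-scoring; whether the original analysis pooled cohorts here is not
documented, so the per-cohort choice is pinned and logged) and applied to
all samples; p = 0 is the identity. Only the proliferation group is
thresholded — the RT-PCR assay also floors the HER2 group on its own scale,
but on the microarray scale no such floor is described, so none is applied.

Missing-gene policy: for RS groups, a missing member is dropped and the
weighted mean taken over the remaining members (the only policy consistent
with "group = average of available gene averages"; exercised by the
bead-chip cohort lacking MYBL2). A group with all members missing, or any
missing MS target gene or RS singleton, is an error.

z-scores use mean and sample SD (ddof = 1) computed per cohort over the
analysis subset (ER+/HER2− with known response) and are applied to all
samples of the cohort; a zero-variance cohort is an error naming the
cohort.

## Association models

All models are maximum-likelihood logistic regressions with intercept,
score z-score(s), and reference-coded cohort dummies (alphabetically first
cohort as reference — score odds ratios are invariant to this choice, which
is pinned for byte-stable output). No clinical covariates, interactions or
multiplicity adjustment. Inference is Wald: OR = exp(β), 95% CI =
exp(β ± 1.96·SE), two-sided p from the normal tail; Wald and
likelihood-ratio significance calls agree in ≥98% of non-borderline
synthetic replicates (tested).

The fitter is a small IRLS implementation: convergence when the maximum
absolute score gradient < 1e-8 or the relative log-likelihood change
< 1e-10, at most 100 iterations, with step-halving whenever a Newton step
would decrease the log-likelihood, one final Newton polish step (quadratic
convergence to near machine precision), and Wald covariance = inverse
observed information. Degenerate outcomes, numerically rank-deficient
designs (condition number > 1e12) and diverging linear predictors
(|η| > 30, perfect separation) raise typed errors. A quasi-separated
*nuisance* dummy — e.g. a small cohort with zero events in a Monte-Carlo
replicate — converges to a large finite coefficient under the
log-likelihood criterion and leaves score inference intact; its infinite
CI is reported as such. Frequency weights allow aggregated (contingency
table) data to be fitted exactly; on any single-binary-covariate problem
the fitted OR equals the closed-form sample odds ratio (tested exhaustively
over all 2×2 tables with cells in [1, 30]).

Entering two predictors with |r| > 0.999 raises a collinearity error.
Response-probability curves use marginal standardization: for each grid
value z, the mean over the analysis samples' cohort memberships of
inverse-logit(intercept + β·z + cohort effect). The score correlation is
the Pearson r of the pooled per-cohort z-scores (pooling raw scores would
be confounded by platform shifts), with per-cohort values alongside.

The sensitivity sweep recomputes the RS from gene level (re-floor,
re-combine, re-z-score) at each percentile of the grid (default 75, 80, 85,
90) and refits the single-score RS and combined models.

## Synthetic-study generator

Each sample carries four standard-normal latent factors: proliferation P
and ER-signaling E with correlation ρ (default −0.3: within ER-positive
disease, more proliferative tumors tend to have lower ER-signaling
output), plus two outcome-irrelevant assay axes — H for the HER2/GRB7
amplicon (residual co-variation of ERBB2 and GRB7 within HER2-negative
tumors) and S for stromal/invasion expression (MMP11, CTSL2, CD68). Gene
value = baseline + cohort platform shift + loadings·(P, E, H, S) +
N(0, residual SD); probe value = gene value + fixed per-probe offset
(drawn once, SD 1.2 — probe affinities differ a lot) + N(0, 0.25). Probe
counts per gene vary from 1 to 3, so probe collapsing is a real denoising
step. Default residual SD is 0.45 for signature genes and 0.3 for the five
housekeepers (which load on nothing).

The outcome is logit P(pCR) = α_cohort + β_P·P + β_E·E. ER and HER2 labels
are independent of expression by default (an optional mode ties ER-positive
status to high E for realism); missing response is injected at a configured
fraction. Randomness is keyed per cohort name and a shared gene-constant
stream, so adding or reordering cohorts never perturbs the others.

The default ("paper-like") configuration emulates the six-series study
shape: per-cohort total patient counts (178, 278, 115, 279, 486, 178),
ER+/HER2− fraction 0.65 × 0.795 ≈ 0.52 (≈782 of 1514), missing-response
fraction 0.023 (≈764 evaluable pooled), and per-cohort baselines α_c
calibrated by Gauss–Hermite quadrature + root finding so each cohort's
marginal pCR rate equals its published ER+/HER2− rate (pooled ≈8%). The
bead-chip-like cohort has a distinct platform shift and lacks MYBL2.

Outcome direction and magnitude are a *simulation design* choice: the
direction is exactly the latent combination the MS measures (higher
proliferation, lower ER signaling → response), and the magnitude
(β_P = 0.49, β_E = −0.46) is set so the combined-model comparison of the
two scores has ~90% designed power at the pooled study scale. This yields
single-score odds ratios around 2.0 per SD — deliberately somewhat stronger
than typically observed for these scores (~1.7) — because the generator's
purpose is validating the machinery at adequate power, not imitating one
dataset's point estimates. With these defaults the two approximated scores
correlate at r ≈ 0.66.

What the generator does **not** emulate: microarray spatial artifacts,
saturation and background at the low end of the dynamic range, copy-number
or discrete subtype structure, correlated residuals beyond the four
factors, and any dependence of chemotherapy regimen on cohort. Passing
tests therefore demonstrate correctness of the pipeline's computations and
calibration of its inference under the assumed generative structure — not
that the scores behave identically on real tumors.

## Validation studies

* **Oracle equivalence.** Group/score computations match independently
  coded weighted-mean and dot-product oracles to 1e-12 on random fixtures;
  the logistic fitter matches the closed-form 2×2 odds ratio to better than
  1e-8 over the exhaustive grid and an independent GLM implementation to
  1e-8 on random designs.
* **Parameter recovery.** Over 200 paper-scale replicates, the mean fitted
  MS log-OR is compared to a brute-force oracle that rebuilds the measured
  score directly from the generative model (latents + gene noise +
  probe-averaging noise, no pipeline code) and fits the same model. The
  oracle is evaluated both at the study's own scale (1500 replicates of
  n = 764 — the like-for-like reference, since the logistic MLE carries a
  small upward finite-sample bias at ~60 events) and at n = 10^6 (the
  large-sample limit); agreement is required within 3 Monte-Carlo SEs of
  the matched-scale truth.
* **Coverage.** 95% Wald CIs cover a true per-SD log-OR of log(1.6) in
  0.95 ± 0.02 of 1000 replicates at n = 2000 and an 8% base rate.
* **Qualitative comparison.** With the default generator, the combined
  model shows MS p < 0.05 and RS p > 0.05 in ≥80% of 100 paper-scale
  replicates, and the expected single-score RS coefficient is
  non-increasing as the proliferation floor rises 75 → 90 (paired
  Monte-Carlo comparison).

Problem sizes above (200/1000/100 replicates; oracle at 10^6) are the
package's chosen simulation sizes; `scripts/acceptance.py` recomputes all
of them from a single seed.

## Known limitations

* Signature weight magnitudes are shipped defaults editable in YAML; only
  their sign structure is enforced, and conclusions are scale-invariant but
  not weight-ratio-invariant — users approximating a specific published
  assay must supply its exact coefficients.
* The reproduction of the original six-series analysis requires external
  normalization (RMA/bead processing) that this package intentionally does
  not perform.
* Logistic estimates at few events are slightly biased away from zero (no
  Firth correction is applied, matching the original analysis convention);
  the validation compares against a matched-scale oracle for this reason.
* The percentile-floor reference population ("ER-positive patients") is
  implemented per cohort; a pooled-reference variant would differ slightly
  when cohort proliferation distributions differ.
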