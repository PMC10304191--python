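# Methods

This note documents the models, parameter choices and numerical
conventions behind `ocprisk`, and what the synthetic-data experiments
do and do not demonstrate.

## Exposure model

The chronic dietary intake of a contaminant group g for an individual i
is additive over the seven surveyed foods:

    EDI_ig = Σ_f C[f,g] · Cons_if / Bw_i        (mg/kg-bw/day)

with C the mean concentration (mg/kg), Cons the daily consumption
(kg/day; milk volumes are treated as mass at density 1.0, which the
source questionnaires never convert) and Bw the individual body weight.
The lifetime-averaged form multiplies by the exposure-frequency
fraction EF/365 and the duration/averaging ratio ED/AT (default AT =
70 years = 25,550 days, the carcinogenic-risk convention). EF is used
as a *dimensionless fraction* of the year, not a day count: the naive
product of EF in days with ED in days would change the units of EDI
and make the comparison with an ADI meaningless.

Acute risk uses the single-sitting intake ESTI = Σ_f F_f · HR:P_f / Bw̄
(full portion × highest residue level over mean body weight).

Hazard characterization: HQ = HI_ratio = EDI/ADI, with the hazard flag
raised strictly above 1.0 (a food at exactly its ADI is borderline
non-hazardous); the percentage forms cHQ = HI_pct = 100·EDI/ADI and
aHQ = 100·ESTI/ARfD. The ratio and percentage forms are exposed as
separate named fields because both conventions circulate; they are
consistent by construction (HI_pct = 100·HI_ratio always). Groups
without a published reference dose — HCB and HCH have no ADI — return
explicitly not-computable (None) indices, never silent zeros. MPC
fold-excess is C/MPC per (food, group) cell, flagged above 1. Heavy
metals get EDI and MPC excess; HQ/HI only if the user supplies an
ADI-equivalent (none by default).

## Genotype statistics and susceptibility scores

Allele frequencies for codominant SNVs are obtained by allele counting;
for the GSTT1/GSTM1 whole-gene deletions only the homozygous-null
phenotype is assay-observable, so the null-allele frequency is the
square root of the null fraction under Hardy–Weinberg proportions.
(For GSTM1, 110 positive / 110 null, this estimator gives 0.707; the
raw phenotype fraction 0.500 is reported separately — both are
exposed, and neither is forced to match the other.)

The HWE test is the Pearson χ² of observed vs expected (np², 2npq,
nq²) counts without continuity correction. The default tail is taken
at **df = 2** because the bundled reference summaries' p-values are
consistent only with that convention (e.g. χ² = 15.445 → p = 0.0004;
χ² = 3.878 → p = 0.144); the textbook df = 1 (three cells, one
estimated allele frequency) is available by argument. Note df = 2 is
conservative for HWE-true data, so rejection rates run below nominal.
Samples with a genotyping call rate strictly below 98% are dropped.

Susceptibility scores: each marker scores 1 when a non-functional
(risk) allele is present — dominant coding, since the scoring rule is
about presence, not dosage; an additive 0/0.5/1 coding is available
behind a flag for sensitivity analysis. Deletion markers score 1 only
for null/null ("+/−" is indistinguishable from "+/+"). The cluster
score is the mean over the cluster's non-missing markers, giving the
three regression predictors X5 (repair, 4 markers), X6 (detoxification,
9) and X7 (antioxidant, 8) in [0, 1]. A fully missing cluster is an
error rather than an imputed value.

## Risk regression

Both outcomes are fitted by OLS with intercept — the health outcome is
an ordinal disease count, but the published model and its printed
statistics are linear-model quantities, so no ordinal link is used.
Standard errors are classical homoskedastic ones (a robust option
exists but defaults off, matching the source analysis which used none);
t_i = b_i/S_bi is compared with fixed critical values 2.263 (health)
and 2.693 (genetic). These are treated as user-supplied constants
rather than recomputed Student quantiles: their provenance in the
source analysis is unclear (they do not equal t-quantiles at the
stated n and m), so reproducing them is the faithful choice. Adjusted
R² uses the (n−1)/(n−m−1) correction.

The X2/X3/X4 fold-excess predictors are operationalizations of
"exceedance of permissible levels" that the source analysis leaves
unspecified:

* X2 — consumption-weighted mean over foods of C/MPC, averaged over
  pesticide groups with complete MPC columns (short-term,
  concentration-based);
* X3 — mean over pesticide groups with an ADI of EDI/ADI (chronic,
  intake-based; depends on body weight where X2 does not);
* X4 — as X2 over the heavy metals.

`mean` can be swapped for `max` or `count`-of-exceedances via the
`summary` option, since the original choice is unrecoverable.

Influence decomposition: factor j's raw weight is its squared
semipartial correlation R²_full − R²_−j, clipped at 0 and rescaled so
the shares sum to the explained variability 100·R². For orthogonal
predictors this reduces to the marginal 100·r² of each factor. The
decomposition method is a genuinely open choice (commonality analysis,
LMG, standardized-β products would all be defensible); semipartials
were chosen as the simplest method with the orthogonal-case identity,
and the rescaling makes the "shares sum to explained variability"
reading exact.

Predictive ability binarizes both the model scores and the observed
outcomes at their own arithmetic means and reports the concordant
fraction. It is invariant under positive affine transforms of the
scores and undefined (an error) for zero-variance inputs.

## Synthetic cohort

The generator's defaults are the study conditions: seven villages with
the surveyed n (32+26+31+25+27+25+25 = 191), sex ratios, ages
(truncated normal on [18, 85], mean ± sd per village ≈ 41–53 ± 3–14 y),
body weights by sex (truncated normal, ≥ 40 kg), and per-village food
consumption. Consumption is lognormal, moment-matched to the surveyed
mean and sd, because the survey sds are of the order of the means
(strong right skew) and intakes cannot be negative. Genotypes are
drawn per variant under HWE at the observed risk-allele frequencies
(GSTM1 uses the sqrt estimate 0.707 so the simulated null-phenotype
fraction reproduces the observed 0.50). Smoking and alcohol
prevalences are not reported in the source tables; 0.20 and 0.25 were
fixed once as plausible for a mixed-sex rural cohort. The 151-person
analysis subset is drawn uniformly from the 191 simulated people,
treating the blood-donor/questionnaire gap as missingness completely
at random.

Contamination is a base (food × group) table scaled per village. The
published per-village group exposures are *not* reproducible — they
derive from unavailable individual chemistry data — and are mutually
inconsistent with the published regression equations: intakes of the
published magnitude against the published ADIs give fold-excesses of
order 10–10³, while the equations' predictions (and the published
individual risk indices ≈ 0.66–0.73) are of order 1. The defaults
therefore put each pesticide group near half its ADI at the reference
diet, so X2/X3/X4 are O(1); per-food patterns concentrate residues in
cucumbers, pears and peppers (pesticides) and use a distinct pattern
for metals so the two MPC predictors are not collinear; per-village
scale factors (3.0 down to 0.002) emulate the published ordering, with
the two control-region villages essentially uncontaminated. ARfD
(10× ADI), MPC, highest-residue (3× mean) and portion tables are
synthetic stand-ins, as the originals sit in an unavailable appendix.

Outcomes: latent Y = β·X + ε with the published coefficient vectors
and ε ~ N(0, σ). The observables are the latent rounded and clipped at
0 (health rank) and clipped to [0, 100] (aberration %); the continuous
latents are retained so that σ = 0 recovery of the generating
coefficients is exact to machine precision, and the refitting
experiments run on the latents to keep the estimator unbiased (the
rounded/clipped observables add a discretization distortion that is a
property of the outcome coding, not of the model).

σ is calibrated by bisection so the mean refitted R² on 151-person
analysis sets matches the published determination coefficients —
24.74% (health) and 14.24% (genetic). The calibrated defaults, frozen
in `cohort.py`, are σ_health = 1.625 and σ_genetic = 2.5 (40
replicates per bisection step; the mean R² is monotone in σ between 1
at σ=0 and the m/(n−1) overfitting floor). On held-out seeds these
give mean R² ≈ 0.241–0.247 and 0.143–0.153.

What passing these experiments shows: the fitting machinery is
correct (oracle agreement to 1e-8), unbiased at the study's n under
the generating model (≈95% ±2 SE coverage), and the simulator's noise
level is consistent with the published explained-variability anchors.
What it does not show: anything about the real cohort's coefficient
values, predictive-ability counts or per-factor shares — those depend
on the unavailable individual-level data, and the published numbers
are used only as calibration anchors, never as assertions.

## Numerical conventions and sizes

* Report rounding mirrors the source tables (frequencies and χ² to
  3 d.p.); all internal computation is double precision.
* Truncated normals are drawn by rejection; lognormal parameters are
  σ² = ln(1+(sd/m)²), μ = ln m − σ²/2.
* One global seed; demographics, genotypes, outcomes and subsampling
  use independent child streams spawned from it, so the pipeline is
  byte-identical under a fixed seed.
* Simulation experiments use 200 replicates of n = 151 with 9
  predictors; the OLS oracle check uses 100 random 151×9 designs.
* Rank-deficient designs are rejected with the collinear columns
  named (QR with pivoting); hazard indices with absent reference
  doses are None; zero-variance predictive-ability inputs raise.

## Known limitations

* The simulator emulates marginal distributions per village but not
  within-household correlation, diet seasonality, measurement error in
  the questionnaires, or linkage between markers (variants are drawn
  independently, including the three GSTP1 SNVs).
* The contamination and reference-dose defaults are synthetic; real
  analyses should supply measured tables via the CSV interfaces.
* OLS on an ordinal disease count is a faithful reproduction choice,
  not a statistical recommendation.
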