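# Methods

## Probe-level encoding and filtering

CNV calls arrive as (sample, chromosome, start, end, type, copy number, QS)
with QS ∈ [−1, 1]; the sign encodes the call type (negative = deletion) and
the magnitude the caller's confidence. Only high-confidence calls,
|QS| > 0.5 strictly, are encoded; the cut is the `qs_cut` parameter.
Coordinates are 1-based inclusive everywhere (PennCNV-style), and a probe
at position p is covered by a call iff start ≤ p ≤ end — a call ending
exactly at a probe's position includes it. When nested calls leave one
sample with both a retained duplication and deletion over the same probe,
the entry is set to 0 (the "no confident CNV" state) and the conflict is
counted and logged; this situation has no principled resolution at the
genotype level and 0 is the conservative choice. The matrix is stored
sparsely (CSR, int8); the DUP and DEL views are materialized per probe on
demand, with the disregarded CNV type mapped to missing.

Probes with CNV carrier frequency strictly below `freq_cut`
(default 10⁻⁴, i.e. 0.01%) are excluded; a frequency exactly at the cut is
retained. Remaining probes are pruned with a greedy windowed procedure on
the signed genotypes (window 500 probes, step 250, r² > 0.9999): within a
window, the later-positioned member of any super-correlated pair is
removed, keeping the proxy earliest in the region; zero-variance probes
correlate with nothing and are never removed. The procedure is
deterministic and idempotent.

## The four dosage models

Each probe × disease regression uses one of four encodings of
g ∈ {−1, 0, +1}: mirror (g; one effect per additional copy), U-shape
(|g|; any deviation from copy-neutral acts in one direction),
duplication-only (carriers of the disregarded type are dropped from that
regression, not zero-imputed — zero-imputation would contaminate the
copy-neutral reference class), and deletion-only (deletion carriers coded
1, so the coefficient is the effect of carrying the deletion). With this
harmonization every reported beta is the effect of the CNV, or of one
additional copy under the mirror model. On a probe without deletion
carriers the mirror and U-shape dosages coincide exactly, and so do the
fits.

## Pre-filtering

Before regression, each (probe, disease) pair is screened with an exact
2×3 genotypic test (rows control/case, columns deletion/neutral/
duplication). The two-sided p sums, under the multivariate hypergeometric
null with fixed margins, the probabilities of all tables no more probable
than the observed one (probability-mass ordering, the convention of
standard exact-test implementations); a zero-margin genotype column
collapses the test to the 2×2 exact test. The enumeration runs over the
two free cells of the control row, which is fast because carrier margins
are small for rare CNVs. A probe enters the mirror/U-shape scans if
Fisher p ≤ 10⁻³ and at least 2 cases are found among CNV carriers; the
type-specific scans additionally require ≥ 2 cases among carriers of that
type. Genomic inflation of the screen is monitored with the median-based
lambda (median 1-df chi-square quantile over its null median).

## Firth-fallback logistic regression

The per-probe fit is Newton–Raphson maximum likelihood with step halving
(tolerance 10⁻⁸ on the step, 100 iterations). The fit falls back to
Firth's Jeffreys-prior penalized likelihood — modified score
U*(β) = Xᵀ(y − p + h(½ − p)) with h the weighted-design leverages,
penalized log-likelihood ℓ(β) + ½ log|XᵀWX| — when ML fails to converge,
any |β| exceeds 10, or the genotype × outcome table has an empty cell.
The empty-cell trigger makes the behavior deterministic where separation
is certain rather than relying on iteration diagnostics alone. Inference
is Wald in both branches (p = 2Φ(−|β/se|), 95% CI exp(β ± 1.96 se)),
matching the usual GWAS reporting convention; the SE comes from the
inverse observed information at the optimum. Collinear design columns are
dropped by QR with column pivoting and reported with β = 0, se = ∞, p = 1.
On well-conditioned data with every carrier-class cell ≥ 10 the fallback
never triggers (regression-tested).

The disease-burden outcome (count of diagnoses across the panel) is
quantitative and scanned with per-probe OLS under the same encodings,
masking, and covariates, with classical homoskedastic t inference.

## Covariate selection

Per disease, one joint logistic regression of status on age, sex,
genotyping array, and the principal components; covariates with
coefficient p ≤ 0.05 are retained (a single multivariable model, not
univariable screens). Constant columns are dropped first, missing values
are handled complete-case per disease, and non-convergence retains all
covariates with a warning. For the quantitative disease burden the
analogous joint OLS is used. Covariates are variance-standardized inside
every downstream regression.

## Multiplicity

N_eff is the sum over chromosomes of the smallest k such that the top-k
eigenvalues of the per-chromosome probe correlation matrix (signed CNV
genotypes, zero-variance probes excluded) reach 99.5% of the trace. The
variance fraction is the `neff_variance_fraction` parameter; 99.5% is the
standard choice of the effective-test estimator lineage this follows.
Thresholds are genome-wide 0.05/N_eff and experiment-wide
0.05/(N_eff × n_traits), kept at full precision internally and rounded to
two significant figures for display. At the reference study scale
(N_eff = 6,633, 61 traits) these evaluate to 7.5 × 10⁻⁶ and 1.2 × 10⁻⁷.

## Conditional analysis and CNV regions

Stepwise conditional analysis iterates: take the most significant probe
with p ≤ threshold as a lead, add its encoded genotype to the covariates
(samples with a masked conditioning value are dropped), rescan, stop when
nothing passes; a guard aborts after 20 rounds with diagnostics. After
conditioning, the lead itself is perfectly collinear with the conditioning
column and is reported with p = 1 by construction, which also retires all
its r² = 1 proxies.

A lead's CNVR spans the most distant probes within ±3 Mb whose r² with the
lead is ≥ 0.5; for U-shape signals the correlation is computed on |g|, and
for the type-specific models on the type-masked dosage over
pairwise-complete samples. An isolated lead yields a single-probe
interval. Signals of one disease whose regions overlap by ≥ 1 bp merge
into one association (several significant models); regions then merge
across diseases by transitive ≥ 1 bp overlap into unique, non-overlapping
CNVRs with union-extent boundaries. Merging is idempotent and
order-invariant. The best model is the lowest-p significant model; the
main model is the duplication- or deletion-only model when one is
significant (it names the driving CNV type), otherwise the best model;
both type-specific models significant at once is flagged for manual
review. Gene counts are ≥ 1 bp interval overlaps against a supplied gene
table — deliberately not transcript-aware annotation, since the count
feeds only descriptive output.

## Validation tiers

Three statistics gauge each disease signal at the validation threshold
p ≤ 10⁻⁴: (i) the probe's genotypic exact Fisher p from the screen;
(ii) OLS of the logistic *response* residuals y − p̂ (covariate-only
model) on each significantly-associated encoding, lowest p reported —
response residuals are used because that is the quantity the procedure
defines, and the OLS inference is homoskedastic Wald, flagged as a
sensitivity point; (iii) a Cox proportional-hazards model (Efron ties,
via lifelines) of age at last healthy measurement — onset age for cases,
age at the administrative cutoff (default 2021-09-30) for controls — on
covariates plus each encoding, lowest genotype p reported. Tier 1/2/3 =
confirmed by 3/2/1 statistics; burden signals are tier 1 unconditionally
(quantitative outcomes lack the binary-trait caveats); a signal confirmed
by none is demoted to an explicit tier 4 with a warning rather than
dropped. Kaplan–Meier curves (Greenwood-variance-based bands) accompany
the survival comparisons.

## Replication

Each lead is matched to the closest successfully-regressed replication
probe inside its CNVR (equidistant ties to the smaller position), tested
under the discovery best model, and its two-sided p is converted to a
directional p: p/2 when the effect sign matches discovery, 1 − p/2
otherwise — exactly the stated adjustment, with no separate one-sided fit.
Strict replication uses 0.05/(number of evaluable signals). Enrichment of
significant replications is a one-sided binomial tail P(X ≥ k),
X ~ Bin(n, α), with fold k/(nα), evaluated over α = 0.1 down to 0.005 in
steps of 0.005. At the reference counts (7 of 49 at α = 0.05) this gives
fold 2.9 and p 0.011.

## BMI confounding

A signal is screened when (i) BMI associates with the disease at
0.05/n_traits in the covariate-adjusted model and (ii) the lead genotype
associates with BMI at 0.05/n_signals, BMI having been rank-based
inverse-normal transformed (Φ⁻¹((rank − ½)/n), average ranks for ties) and
residualized on age, age², sex, array, and PCs. Eligible signals are refit
with BMI as an extra covariate; the coefficient change is tested with
z = (β₁ − β₂)/√(se₁² + se₂²) against a normal reference at
0.05/n_eligible — the standard coefficient-comparison form; the
independence assumption between the two fits is conservative and logged.
A signal whose BMI-adjusted p rises above the genome-wide threshold is
flagged as likely BMI-driven. Signals with BMI missing for more than half
their carriers are non-evaluable.

## Burden analyses

Per sample, six metrics: Mb and distinct-gene counts of high-confidence
autosomal CNVs, duplications, and deletions, with cnv = dup + del enforced
in both units on every emitted table (the gene metric counts distinct
genes per sample and type; the cnv metric is the sum of the two types, so
a gene hit by both a duplication and a deletion contributes to each).
Associations are logistic (diseases) or OLS (disease burden) with
disease-relevant covariates; variance explained is the McFadden pseudo-R²
or adjusted R² of the covariate-free model, and significance is
0.05/n_traits.

Partitioned burdens split each metric into subset (calls overlapping a
partition under any-1-bp or reciprocal-50% overlap, respecting each
interval's type-applicability) and corrected = total − subset, an exact
identity per sample, type, and unit. A consequence in gene units: a gene
entering the subset is subtracted from the corrected burden even when a
non-subset call also touches it. The partition family CNVR / GD / R1 =
CNVR ∩ GD / R2 = GD \ R1 / R3 = CNVR \ R1 is built by ≥ 1 bp intersection.
A call straddling two partitions can contribute to both subset burdens;
exclusivity is not imposed and the situation is logged. For GWAS-signal
correction, a call of type T is omitted from a disease's burdens when it
overlaps (≥ 1 bp) a CNVR associated with that disease through mirror or
U-shape (either type) or through its own type-specific model; the cnv
metric remains dup + del after omission, so a duplication overlapping a
deletion-only-associated region is retained.

## The synthetic cohort generator

The generator defines the study conditions for every test. It emulates:
CNV loci with carrier frequencies in [0, 0.05] (defaults 0.004 per type in
the demo genome; the rare-recurrent regime), recurrent breakpoint
categories with sampling weights plus a 5% atypical-breakpoint minority
with random breakpoints inside the locus; QS magnitudes uniform on
(0.5, 1] for high-confidence calls with a `qs_noise` fraction (default
20%) drawn with |QS| ≤ 0.5 — this fraction is a free parameter of the
generator, not an empirical estimate; at most one CNV per sample per
locus, and overlapping locus definitions are rejected. Covariates: age
uniform on ~[40, 70] years derived from birth dates against a 2008
baseline, 54% female, 10% secondary array, standard-normal PCs (4 by
default, configurable). Disease status is Bernoulli from a logistic
liability whose intercept is root-solved so the realized population
prevalence matches the target; CNV effects act per encoded dosage unit
under one of the four mechanisms, optionally routed through BMI
(standard-normal, shifted by `bmi_shift` per encoded unit, entering the
liability with its own coefficient). Onset ages for cases are Weibull
proportional hazards (shape 4; scale 65/ln2^{1/4} ≈ 71.2 years so the
baseline median onset is 65 — a right-skewed, late-onset profile);
controls are censored at the cutoff date; a configurable fraction of
controls (default 2%) is relabeled excluded to emulate exclusion lists.
Randomness flows from one master seed through per-stage child streams
keyed on the stage name, so adding a stage never perturbs another.

What it does not emulate: raw microarray intensities or the calling step,
relatedness or ancestry structure beyond PC covariates, realistic
linkage-disequilibrium outside the CNV loci, diagnosis-code noise, or any
dependence between the status-generating logistic model and the
onset-generating hazards model beyond shared dosage effects. Passing
tests therefore demonstrate correctness of the statistical machinery
under the stated generative assumptions, not robustness to the artifacts
of real array data.

## Numerical choices and problem sizes

Fisher enumeration uses log-gamma binomials with a 10⁻⁹ log-tolerance on
the probability-mass ordering (ties count as "no more probable"). The
intercept calibration brackets [−30, 30] on the logit scale. Collinearity
detection uses a 10⁻¹⁰ relative residual cut. The test suite runs its
simulation-based checks at cohort sizes of 2,000–30,000 samples with one
biobank-scale recovery run at n = 100,000, 20 null cohorts for type-I
calibration, and 100 replicates for the Cox recovery property; the demo
pipeline uses 20,000 discovery and 10,000 replication samples — sizes
chosen so the whole suite completes in a few minutes on one CPU while
keeping every property's expected margin wide.

## Known limitations

The exact 2×3 test enumerates the control row's free cells and is
intended for rare-carrier margins; dense tables with large margins would
enumerate millions of cells. Wald inference understates evidence in deep
separation compared to penalized-likelihood-ratio tests. The response-
residual regression inherits binary-outcome heteroskedasticity; its null
calibration is verified by simulation at moderate carrier counts but
degrades below ~50 carriers. The CoxPH validation estimates a hazard
ratio that mixes risk and onset-timing effects when, as in the generator,
carrier status raises both — it is a validation statistic, not an
estimator of the generative hazard ratio. Replication matching assumes
the two cohorts share a coordinate system; no liftover is performed.
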