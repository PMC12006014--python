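# Methods

`cihmet` re-implements, as a tested library, a multi-tissue metabolomics
workflow for finding endogenous susceptibility markers of
chemotherapy-induced hepatotoxicity (CIH) in colorectal-cancer patients:
three metabolomic views — colorectal tissue (CRT), plasma and urine — are
preprocessed, tested for differential metabolites, integrated with a
latent-factor model tolerant of missing views, filtered through pathway
enrichment and a correlation network, condensed into a biomarker panel by
random-forest stability selection, and complemented by a two-sample
Mendelian-randomization (MR) estimator suite. Because no patient-level data
are public, every stage is exercised against a synthetic-cohort generator
with planted ground truth.

## The synthetic cohort

The generator emulates the study layout: 63 patients (19 CIH cases, 44
normal), with per-view coverage 54 (CRT), 49 (plasma) and 44 (urine);
missing views are missing completely at random. Covariates: age ~
N(57, 10²) years, BMI ~ N(23.5, 3²) kg/m², two-thirds male — matched to the
cohort's published marginals.

Intensities are log2-normal. On the log2 scale, entry (i, j) of view v is

    baseline_j + (Z W_v')_ij + group_i · log2FC_j + eps_ij,  eps ~ N(0, noise_sd²)

and the stored intensity is 2^x. This makes planted log2 fold-changes exact
in expectation after the log2 transform downstream. Choices that matter:

* **Group labels first.** Labels are drawn, then effects conditioned on the
  label — a case-control design matching the retrospective grouping. No
  liability model and no clinical ALT/AST thresholds are simulated.
* **Planted effect sizes.** Ordinary differential metabolites get
  |log2FC| ~ U(0.16, 0.95) with random sign — the span of the effect sizes
  reported for the study's candidate biomarkers. Panel biomarkers get
  |log2FC| = 2.5 by default: near-separating markers, consistent with the
  published panel's odds ratios in the hundreds-to-thousands and its
  quasi-separation-wide confidence intervals.
* **Latent structure.** K_true = 3 shared factors with per-view loadings
  N(0, 0.5²), each view emphasizing the factors through a geometric
  activity profile (1, 0.6, 0.36) rotated across views. The rotation gives
  each factor a dominant tissue — the pattern the factor stage is expected
  to report — and is also what makes factors rotationally identifiable.
  Biomarkers additionally load ±1.5 on factor 1 (sign-aligned with their
  effect), forming the correlated hub module that candidate selection
  exploits.
* **Baselines.** Per-feature baselines ~ U(8, 12) on the log2 scale, and
  300 features per view by default. Both are chosen so that no feature
  commands more than a few percent of a sample's total intensity: sum
  normalization is compositional, and planted effects survive it only when
  closure is a second-order effect. (Real untargeted runs have thousands of
  features, so this mirrors reality; small synthetic views with strong
  planted effects would otherwise leak group signal into every feature.)
* **MR sets.** Exposure betas ~ U(0.05, 0.15) (effect alleles
  pre-harmonized), outcome betas = slope × exposure + noise; exactly
  round(k × fraction) instruments receive a directional outcome offset —
  the invalid-instrument regime the robust estimators are built for.

What the generator does **not** emulate: raw spectra, retention times,
ion-mode artifacts beyond the duplicate-compound mechanism, batch effects,
non-Gaussian heavy tails, and missingness mechanisms other than MCAR.
Passing tests therefore demonstrate correctness of the estimators and the
recovery behavior under the stated model — not robustness to every failure
mode of real instrument data.

All randomness flows from a master seed through named sub-streams (CRC32 of
the stream name mixed into a `SeedSequence`), so any single stage re-run in
isolation reproduces its draws and full runs are byte-identical.

## Preprocessing

Per view: the 80% rule (keep features observed in ≥ 80% of samples; zeros
count as missing, i.e. "not detected"), sum normalization to relative
abundances, half-minimum imputation of remaining gaps, log2 transform.
Order is fixed as listed. The 80% rule is applied over all samples by
default with a per-group variant available. Duplicate compounds measured in
both ionization modes collapse to the mode with the larger median peak
area. Printed percentages in cohort tables round half-away-from-zero to one
decimal — note that a cohort table's printed 15.8% for a 10/63 cell is not
reproducible under any standard rounding (10/63 = 15.87%); that cell is
treated as a typo and excluded from checks. The coefficient of variation
uses the sample (n−1) standard deviation.

## Differential expression

Per-feature OLS of log2 abundance on (intercept, group, age, male
indicator, BMI ≥ 24 indicator), vectorized across features. Variances are
moderated empirically: (d0, s0²) estimated by matching the mean and
variance of log s_g² through digamma/trigamma inversion (Newton iterations
on the trigamma inverse), posterior variance
s²_post = (d0 s0² + d_g s_g²)/(d0 + d_g), moderated t referred to
t(d0 + d_g). When the spread of log-variances is fully explained by
chi-square sampling noise, d0 = ∞ and the prior variance is the geometric
mean of the observed variances (so exactly-equal variances pass through
unchanged). Tests are two-sided; BH adjustment is applied within tissue;
the selection gate is raw p < 0.05 with the adjusted p reported alongside.

## Factor integration

A Gaussian group factor analysis with per-factor-per-view ARD — a
simplified member of the multi-omics factor analysis family, not a port of
the published variational implementation. The MAP objective is minimized
by exact block coordinate descent over factor scores Z (per observation
pattern), per-view loadings W_v, noise precisions tau_v and ARD precisions
alpha_vk. Tiny Gamma hyperpriors (rate 1e-6 on alpha, 1e-9 on tau) keep
the precision updates bounded while preserving exact block minimization,
so the objective is provably monotone; an increase > 1e-6 aborts the run.
Patients missing a view contribute nothing to that view's terms, and their
scores solve the normal equations of their observed views only.

Initialization is an SVD warm start on the zero-filled concatenation plus
seeded jitter; convergence is relative objective change < 1e-8 (default)
with max_iter 5000 (the pipeline uses smaller budgets, below). After
fitting, factors are re-ordered by total variance explained — "LF1" is
always the most explanatory — and factors whose variance share falls below
the Marchenko–Pastur noise floor ((√(n−1) + √p)² / ((n−1)p)) in every view
are pruned, with a `min_factors` floor for callers that need at least one.
Variance explained is R²(k, v) = 1 − SS(X_v − z_k w_vk') / SS(X_v) on the
per-feature centered, unit-scaled data. The most group-discriminative
factor maximizes the absolute two-sample t of its scores; metabolite
ranking is by absolute weight with lexicographic tie-breaks. No
significance test on weights is implemented (none is defined for this
model); ranking is by |weight| only.

## Pathway enrichment

Local GMT-style pathway sets replace any web service. The test is the
hypergeometric upper tail P(X ≥ hits) with the background equal to all
metabolites surviving preprocessing in that tissue; disease-category
pathways are excluded before testing. A pathway passes at p < 0.05 with
≥ 3 hits. Pathway weight = mean |LF weight| of the hit metabolites and
direction = sign of their mean log2FC ("up" on an exact zero, with a
warning); both aggregations are pluggable (mean/median/sum). Ranking is by
weight, ties by smaller p then pathway ID.

## Correlation network

Pearson correlations over pairwise-complete samples among eligible
differential metabolites (those with |factor weight| above the median that
also sit in a top-3 enriched pathway). "r² ≥ 0.4" is read literally as
squared correlation (|r| ≥ 0.632); an `absolute` mode thresholds |r| ≥ 0.4
instead, since the published notation is ambiguous. Candidates are the
best-connected nodes: degree descending, ties by mean |r| of incident
edges, then feature ID; the default cut is the 75th degree percentile.

## Panel construction

Stability selection: each of n_runs (default 1000) runs fits a random
forest (default 500 trees, √p features per split) on a bootstrap resample;
a feature "appears" when its impurity importance ranks in the run's top_k
(default 10). The panel is every feature appearing in ≥ freq_threshold
runs (default 500). Candidate columns are canonicalized (sorted) before
fitting so frequencies are exactly column-order invariant. A caveat worth
stating: because runs resample the *same* dataset, a noise feature with a
lucky sample correlation persists across runs — null panels are rare but
not impossible, contrary to a naive binomial argument that assumes
independent runs.

The panel feeds a multivariate logistic regression (maximum likelihood;
Wald 95% CIs exponentiated to odds-ratio scale). Separation — likely with
small cohorts and near-separating markers — is detected and answered with
an L2-penalized refit, flagged on the model (its CIs are then not
reported). The 7:3 train/test split is stratified by class through
largest-remainder apportionment, protecting the 19-case minority. AUC is
trapezoidal integration of the empirical ROC, which equals the normalized
Mann–Whitney U exactly; it is reported for train, test, whole and external
sets, the external set being scored by the frozen model with features
aligned by ID.

## Mendelian randomization

Closed forms throughout: Wald ratio with first-order delta SE; IVW
beta = Σ(bx·by/sey²)/Σ(bx²/sey²) with fixed SE = 1/√Σ(bx²/sey²) and a
multiplicative random-effects inflation max(1, √(Q/(k−1))); MR-Egger as
weighted least squares with a free intercept after orienting exposure
betas non-negative (t reference with k−2 df); weighted median as the
interpolated 50th weighted percentile of the ratios (weights = inverse
delta-method variances) with a seeded parametric-bootstrap SE (default
1000 draws); Cochran's Q against the fixed-effects estimate with a
χ²(k−1) reference; leave-one-out re-estimation flagging any drop that
moves the estimate outside the full-set 95% CI. CIs are normal-theory
beta ± 1.96·SE everywhere. Instrument selection and LD clumping are out of
scope; inputs are pre-harmonized summary tables.

## Pipeline, problem sizes, and known limitations

`run_pipeline` chains the stages from a single config; a master seed fans
out per stage, each stage's tables are written as TSV, and the report is
emitted as JSON and text. Defaults follow the full-scale analysis (1000
runs, 500 trees, K = 10, max_iter 5000).

The test and acceptance suites run the same machinery at reduced problem
sizes so the whole suite completes on one CPU: stability-selection
simulations use 5-tree forests per run (the ranking statistic, not the
forest size, is what is under test), and end-to-end replicates use 200
runs with a proportional threshold of 100, K = 6 and max_iter = 200. At
these sizes the plasma model — the one carried to external validation —
reaches whole-set AUC ≥ 0.9 in over 90% of simulated cohorts, while
requiring all three tissue models to clear 0.9 simultaneously succeeds in
only about two-thirds of cohorts; the acceptance property is therefore
stated on the plasma model. Panel recovery of the five planted biomarkers
averages about 70% at this scale: module-correlated candidates split
random-forest importance, so frequencies hover near the 50% threshold.
Larger cohorts or stronger markers push both numbers up; the behavior is a
property of stability selection with correlated features, not a defect of
the implementation.

Other limitations: the factor model is rotationally identified only
through per-view activity differences (equal dense loadings in every view
cannot be disambiguated, by symmetry); sum normalization is compositional
and distorts planted effects when single features dominate a sample's
total; and the MR weighted-median robustness guarantee presumes instrument
precision high enough that per-ratio noise is small against the
contamination being rejected.
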