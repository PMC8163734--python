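# Methods

## The causal model

Per subject i the generator (and the analysis it validates) assumes

* instrument: G_i ~ Binomial(2, MAF), minor-allele dosage of each of
  `n_instruments` independent SNPs;
* exposure (serum albumin, g/dL):
  `alb_i = μ + a_G·(ΣG_i − E) + covariate effects + c·U_i + ε_i`,
  with U_i ~ N(0,1) an unobserved confounder and ε_i ~ N(0, σ_alb);
* hypertension onset: proportional hazards with Weibull baseline
  (shape 1 = exponential, the default),
  `h_i(t) = h₀·exp(b_alb·(alb_i − μ) + d·U_i + γ'x_i)`;
* blood-pressure drift: per-subject linear slopes,
  `slope_i = s₀ + b_BP·(alb_i − μ) + d_BP·U_i + η_i`, observed only
  through exam values carrying N(0, 4 mmHg) measurement error (the
  protocol averages three readings per arm);
* observation: exams every 24 months up to 144 months. Hypertension is
  *detected* at the first exam with SBP ≥ 140 or DBP ≥ 90 mmHg or an
  antihypertensive-medication flag; after latent onset the emitted BP is
  forced across the threshold so detection fires at the first post-onset
  exam, and pre-onset BP is clamped just below it so measurement noise
  cannot trigger detection before onset. Censoring is administrative.

U is the only source of exposure–outcome confounding; genotype is
independent of U by construction, which is exactly the instrumental-
variable assumption the estimators rely on.

### Default parameters (the study conditions)

| parameter | default | rationale |
|---|---|---|
| n_subjects | 4,325 | analysis-cohort size |
| MAF | 0.30 | common-variant instrument |
| a_G | −0.030 g/dL per allele | gives first-stage F ≈ 16–18 at n = 4,325 under dominant coding, the regime of the published F statistics |
| μ, σ_alb, c | 4.185, 0.25, 0.15 g/dL | total albumin SD ≈ 0.30 with ~27% of subjects at or below the 4.0 g/dL hypoalbuminemia cutoff |
| b_alb | log 0.75 per g/dL | causal hazard ratio on the scale of the control-function estimates |
| b_BP / b_BP(DBP) | −0.05 / 0 mmHg/month per g/dL | SBP causal, DBP association purely confounded — mirrors the qualitative 2SLS contrast between the two outcomes |
| d, d_BP | 0.10 per unit U, 0.02 mmHg/month | moderate confounding on both pathways |
| h₀ | 0.002 /month | ~25–30% cumulative incidence over 144 months (the source does not state its event count; flagged as an assumption) |
| visit interval / follow-up | 24 / 144 months | biennial exams over ~12 years |
| age, sex, smoking | N(49.5, 8.2), 45.3% male, 25.8% smokers | cohort margins; conveniences, not calibration claims |

Baseline SBP/DBP are truncated below the diagnostic thresholds because
prevalent hypertension is an exclusion criterion; exam noise can still
push a baseline reading over 140/90, and such subjects are excluded by
the eligibility filter as prevalent cases — as they would be in the real
study. Emitted BPs are clamped to a physiologic range (SBP 60–299,
DBP 50.5–299) to satisfy the reader's plausibility contract.

## Estimators

**OLS / 2SLS.** Classical homoskedastic standard errors; the 2SLS
variance uses stage-2 residuals evaluated at the observed exposure.
First-stage F is the Wald F of the instrument block. Instruments enter
IV analyses in dominant coding by default (configurable); F < 10 raises
a weak-instrument warning.

**Durbin–Wu–Hausman.** Control-function (augmented-regression) form: the
stage-1 residual joins the outcome OLS and its coefficient is t-tested.
The classical contrast form is kept as a cross-check and, evaluated at a
common error variance, is algebraically the squared augmented t
statistic. A design note that shaped the calibration studies: because
exposure and stage-1 residual are nearly collinear, the residual
coefficient is estimated with 2SLS precision, so the test's noncentrality
is bounded by `sqrt(F−1)·c/σ_alb` no matter how strong the confounder's
outcome-side effect is. The "strong confounding" power configuration
therefore puts half of the non-genetic albumin variance on U
(c = σ_alb = 0.2) and uses d_BP = 0.15, giving noncentrality ≈ 3.4 and
power ≈ 0.9 at F ≈ 16–19.

**2SRI Cox.** Stage 1: OLS of albumin on instrument + covariates; stage
2: Cox model on albumin + stage-1 residual + covariates. The albumin
coefficient is the causal log-HR; the residual coefficient's p-value is
an endogeneity diagnostic. The default CI is the naive stage-2 Wald
interval, which ignores first-stage uncertainty (most plausibly what the
published tables report); a subject-level bootstrap rerunning both stages
is provided and labelled as the recommended alternative.

**Cox partial likelihood.** Own Newton–Raphson implementation with
step-halving; Breslow ties by default (visit-grid event times make ties
pervasive and the original analysis was most plausibly SAS PHREG, whose
default is Breslow), Efron optional and cross-checked against lifelines.
Monotone likelihoods raise a convergence error; constant or collinear
covariates raise a rank error. Adjusted survival curves use the Breslow
baseline cumulative hazard at covariate means.

**Proportional-hazards supremum test.** Kolmogorov-type supremum of the
standardized cumulative score process, with p-values from Gaussian-
multiplier resampling including the correction for estimating β. Seeded
and deterministic.

**Restricted cubic splines.** Harrell's restricted truncated-power basis
(k−1 columns, scaled by (t_k−t_1)²), default 4 knots at the
5/35/65/95th exposure percentiles (the source states neither count nor
placement; recorded in output metadata). Curves are reported relative to
albumin 4.0 g/dL — exactly 0 (difference scale) or 1 (HR scale) with
zero-width CI at the reference — with pointwise delta-method intervals.
Nonlinearity is a Wald test on the k−2 nonlinear coefficients.

**Association scan.** One maximum-likelihood logistic fit per SNP and
genetic model, Wald p-values, complete-case per SNP, no imputation and no
multiple-testing correction (min-P is a screening statistic and is
anticonservative by construction — the null-panel fraction with
min-P < α exceeds α; this is documented, not "corrected"). The solver is
a batched Newton–Raphson sharing the covariate block across SNPs,
validated against statsmodels to 1e−6 and needed to make the 150,000
fits of the null-panel calibration affordable.

## What the calibration studies do and do not show

The cohort behind the published analysis is access-restricted, so the
suite validates the machinery by parameter recovery, not by reproducing
printed estimates. Study conditions:

* **IV recovery** (n = 5,000, 200 replicates): runs the full file-free
  pipeline per replicate. The configuration switches the hazard pathway
  off (b_alb = d = 0) so that event-driven truncation of the ΔBP window
  cannot select on U, and keeps drift small enough that the pre-onset BP
  clamp essentially never binds — both needed for the omitted-variable-
  bias closed form `b_BP + d_BP·c/Var(alb|covariates)` to be the exact
  OLS limit. The instrument is strong (a_G = −0.10 per allele) so the
  5% recovery band measures estimator bias, not instrument noise.
* **2SRI recovery** (n = 4,325, 200 replicates, true HR 0.75): uses the
  latent continuous event times (grid-coarsened times attenuate any Cox
  coefficient through heavy ties; that is a property of interval
  detection, not of the estimator under test) and a strong instrument
  (a_G = −0.30), again so the 10% band measures bias. The ~−3% residual
  bias observed is the expected mix of control-function non-collapsibility
  (the part of U orthogonal to the residual acts as a small frailty) and
  Monte-Carlo noise. The naive Cox bias direction equals sign(c·d).
* **GWAS null** (50,000 SNPs × 3 models, 2,000 subjects): λ within
  [0.97, 1.03] and KS distance from uniform < 0.02 per model.
* **Exact oracles**: the Hardy–Weinberg test matches an independent
  exact-rational enumeration for all 23,425 tables with total ≤ 50; Cox
  coefficients match brute-force 1-D partial-likelihood maximization to
  1e−4; Kaplan–Meier and log-rank match longhand risk-set arithmetic.

Passing these shows the estimators do what their theory claims under the
generator's assumptions (linear first stage, proportional hazards,
exclusion restriction, no LD, no population structure). It does not show
robustness to pleiotropy, stratification, LD between markers, or
misspecified hazards — none of which the generator emulates, and all of
which are out of scope.

## Numerical choices and degenerate inputs

Newton tolerances: 1e−8 (batched logistic), 1e−10 coefficient change
(Cox) with step-halving and divergence detection at |β| > 50. HWE ties
between equally probable heterozygote configurations are resolved with a
1+1e−12 relative tolerance. Minor-allele orientation is computed per
dataset from observed frequencies; ties at 0.5 keep the ALT (VCF) or
column (TSV) orientation. Missing dosages propagate through model codings
and are dropped per SNP. The visit-grid ΔBP excludes the diagnosis visit
itself ("last measurement just before the diagnosis"); a config flag
includes it. eGFR uses CKD-EPI 2009 without the race coefficient
(single-ethnicity cohort). All tabular output is TSV with headers;
seeds fan out to stages by hashing the stage name, so any stage can be
rerun in isolation byte-identically.
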