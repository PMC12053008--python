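# Methods

`metabridge` implements a multi-modal discovery chain for *bridge
metabolites* — circulating metabolites whose conditional-dependence
structure ties depression-symptom items to cardiovascular risk factors —
and validates every stage on synthetic data with known ground truth.
This note documents the models, the defaults and why they were chosen,
the numerical details, and what the synthetic benchmarks do and do not
demonstrate.

## The discovery chain

1. **Imputation.** Missing phenotype entries are filled by
   chained-equations multiple imputation (scikit-learn's iterative
   imputer), with a random-forest regressor per column by default
   (`estimator="bayesian_ridge"` gives a much faster linear variant).
   The chain runs `n_rounds` refinement rounds (default 10) and is
   collapsed to a single completed table, because the network stage
   consumes one dataset; Rubin's-rules pooling across completed sets is
   deliberately out of scope. Observed cells are never altered; ordinal
   items are rounded and clipped into their level range. A diagnostics
   table (mean, SD, quartiles per column, complete-case vs imputed)
   accompanies every run.

2. **Covariate screen and adjustment.** Each network variable is F-tested
   against each covariate — one-way ANOVA across groups for categorical
   covariates (sex), the equivalent single-regressor F-test for
   continuous ones (age) — and flagged at `alpha = 0.05` (the screening
   level is configurable). Flagged variables are replaced by their OLS
   residuals on the flagged covariates (dummy-coded where categorical).
   Ordinal items are residualized on their integer coding, accepting
   non-integer adjusted values downstream; variables typed categorical
   are skipped and logged, since a residual of a nominal variable is
   undefined.

3. **Mixed graphical model.** The pairwise MGM is estimated by nodewise
   L1-penalized regression: a linear lasso for Gaussian nodes, an L1
   multinomial logistic regression for categorical ones, with all
   predictors standardized (categorical predictors one-hot coded over
   all levels). An edge requires nonzero cross-parameters in **both**
   nodewise fits (AND rule; OR available); its weight is the mean
   absolute cross-parameter across the two fits, and a sign is attached
   only when both endpoints are continuous and the coefficient signs
   agree. Edge presence is exact zero after penalization — there is no
   post-hoc thresholding.

   *Penalty selection.* Each node's λ is picked on a 50-point log-spaced
   path (λ_max down to λ_max·10⁻³) by the extended BIC. The EBIC is
   scored on an **OLS refit of each candidate support** rather than on
   the penalized fit itself: with penalized likelihoods, decreasing λ is
   rewarded merely for undoing shrinkage on strong edges, which drags
   neighbouring noise edges into the selected model; refitting each
   support removes that artefact. The chosen support's coefficients are
   likewise the OLS refit (relaxed-lasso style) — at the support's entry
   λ the penalized values are nearly zero and would understate edge
   strength — so EBIC-selected edge weights sit on the partial-
   correlation scale, while fixed-λ fits return the raw penalized
   coefficients. With refit scoring, γ = 0.25 proved
   anti-conservative on independence benchmarks, so the default is
   γ = 0.5 — the value recommended in the EBIC literature for graph
   selection — which in our calibration runs recovers a planted
   3-node chain in 20/20 seeds while returning an empty graph on
   independent data in ≥19/20 seeds. Ties are broken toward the sparser
   support, then toward the larger λ. γ remains configurable.

   *Ordinal items.* Symptom items (scores 0–3, strongly right-skewed)
   are modeled as Gaussian nodes by default: integer-coded and
   standardized. This keeps signs and partial correlations defined for
   symptom edges at the cost of treating a 4-level item as continuous;
   `ordinal_as="categorical"` switches to multinomial treatment (signs
   then undefined). Thresholding a latent Gaussian at these margins
   attenuates latent-scale correlations by roughly a quarter to a third,
   which the planted-bridge benchmarks absorb.

4. **Bridge enumeration and scoring.** A bridge pathway is a (risk
   factor, metabolite, symptom) triple with both metabolite edges
   nonzero. Metabolites are scored by degree centrality within the
   metabolite–metabolite sub-network (full-network degree is reported
   alongside, since either may be meant by "central") and by
   *jointness*: the number of distinct (risk factor, symptom) pairs the
   metabolite bridges. The count definition is the default because it
   reproduces the worked example's arithmetic — six pathways across
   five metabolites sum to jointness 6 — and matches the intent of
   "specifically relevant to both groups"; a weighted variant
   (Σ min(|w_rf|, |w_sym|) over bridged pairs) is provided for
   continuous ranking. Low degree with high jointness is the preferred
   profile (low degree limits pleiotropic involvement in other
   pathways); this preference orders the candidate list but never
   filters it.

5. **Stability and significance.** Edge stability: B nonparametric
   bootstrap resamples of subjects (default B = 100), network refit with
   identical settings per resample; each edge gets its mean weight, a
   2.5/97.5-percentile interval, a min–max interval (both are reported
   since either convention is in circulation), and a presence fraction.
   Degenerate resamples with a constant column are redrawn up to a retry
   cap. Significance: the permutation null (default N = 1000) for a
   pair's partial correlation is built Freedman–Lane style — both
   members are residualized on the conditioning covariates and the
   *metabolite's* residuals are permuted — so the covariate structure is
   preserved under the null; permuting raw values would also destroy the
   covariate association and inflate the null. The two-sided p-value
   uses the add-one correction, p = (1 + #{|r⋆| ≥ |r|})/(N+1), so the
   smallest attainable p is 1/(N+1).

6. **Verdicts and selection.** Each bridge metabolite receives three
   verdicts in {pass, semi, fail}: stability (minimum bootstrap presence
   fraction over its bridge edges: ≥0.9 pass, ≥0.5 semi), permutation
   (both edge sides significant at 0.05: pass; one side: semi), and
   robustness (minimum number of ladder covariate sets with p < 0.05
   over its pairs: ≥4 of 6 pass, ≥2 semi). A metabolite is selected when
   at least two verdicts are semi-or-better **and** at least one is a
   full pass. The cutoffs are explicit configuration; they encode a
   "semi-high on two of three assessments" rule whose exact numeric
   boundaries are otherwise a free choice, and every run logs them.

7. **Covariate-ladder replication.** Each metabolite–phenotype pair is
   re-estimated by OLS (metabolite as dependent variable, phenotype as
   independent) under six covariate sets: ∅, {age}, {sex}, {age, sex},
   {age, sex, smoking}, {age, sex, smoking, physical activity}, with
   classical standard errors. Binary phenotypes use the same linear
   contract (linear probability model) to keep one uniform estimand
   across mixed dependent types. Ladder covariates absent from the
   replication table are dropped from their rungs with the rung count
   preserved, so robustness counts stay comparable; the drop is logged.

8. **Two-sample Mendelian randomization.** Instruments are exposure SNPs
   with p < 5×10⁻⁸ (LD clumping needs a reference panel and is replaced
   by optional positional thinning). Harmonization aligns outcome
   records to the exposure effect allele, handling order swaps (sign and
   frequency flip) and strand flips (complements); palindromic A/T–C/G
   SNPs are resolved by allele frequency and excluded when either
   frequency is within 0.08 of 0.5. Estimators: IVW over per-SNP Wald
   ratios with first-order weights w = β_X²/se_Y² (the dominant
   convention; se_X enters only via diagnostics), with multiplicative
   random-effects SE inflation √(Q/df) applied when Q/df > 1; the
   weighted median (interpolated weighted 50th percentile of ratios,
   parametric-bootstrap SE, 1000 draws); and MR-Egger (WLS with free
   intercept after orienting β_X > 0, SEs inflated by max(1, √(Q/df))).
   Cochran's Q uses df = k−1 (IVW) or k−2 (Egger). Instrument strength
   is the squared z-score; min F ≤ 10 raises a weak-instrument flag.
   Effects are reported with OR = exp(β) and 95% CI = exp(β ± 1.96·se).
   Bidirectional runs re-select instruments per direction and refuse
   identical exposure/outcome files.

## The synthetic-data generator

The cohort generator emulates the structure of a population cohort with
NMR metabolomics and a symptom questionnaire: 1,599 subjects by default;
21 ordinal symptom items (0–3) with right-skewed margins (default
0.60/0.25/0.10/0.05 — the item distributions of such questionnaires put
most mass at zero, and the exact skew is a free parameter); 52 Gaussian
metabolites; 3 continuous risk factors; sex (54% female) and age
(37.8 ± 5 y) covariates, plus inert smoking (19%) and physical-activity
columns so the full replication ladder can run; 21% MCAR missingness on
symptoms versus 0.5% on risk factors.

The conditional-dependence graph is specified as target partial
correlations assembled into a unit-diagonal precision matrix (off-diagonal
−ρ), so each edge's partial correlation equals its target exactly and is
invariant to the rescaling of the covariance to unit variances; a
non-positive-definite assembly raises an error naming the likely
offending edges. Ordinal items are produced by Gaussian-copula
thresholding — the latent column is cut at its empirical quantiles so
realized category frequencies match the requested skew exactly — after
covariate effects are added on the latent scale. All randomness flows
from one integer seed through a splittable generator; identical seeds
give byte-identical tables.

The GWAS generator draws per-SNP true exposure effects uniform on
[0.05, 0.15] with the effect allele defined as trait-increasing (so
directional pleiotropy survives MR-Egger's β_X > 0 orientation), standard
errors 1/√(2·maf·(1−maf)·n) for unit-variance traits, outcome effects
β_Y = β_causal·β_true + α + noise with α ~ N(pleiotropy mean, sd) on the
invalid fraction, and deliberate allele mischief (order swaps, strand
flips, palindromic SNPs) in the outcome file to exercise harmonization.

**What the benchmarks do not show.** The generator's data are MCAR,
linear, and homoskedastic on the latent scale; real cohort data have
informative missingness, non-linear metabolite–symptom relations, and
measurement heteroskedasticity. The GWAS simulator draws independent
SNPs (no LD) with balanced pleiotropy structure under the InSIDE
assumption. Passing these suites therefore certifies the statistical
machinery — selection consistency, calibration, estimator recovery —
under the stated generating model, not the substantive findings one
would obtain on restricted-access cohort data.

## Problem sizes and numerical choices

The validation battery (`metabridge.validation`, driven by
`scripts/acceptance.py` and `tests/test_acceptance.py`) uses: chain and
null-graph calibration over 20 seeds at n = 2000/1000; permutation
type-I over 200 null replicates of N = 1000 permutations at n = 300;
bootstrap presence at n = 1500, B = 100; end-to-end recovery over 20
seeds of the 27-node fixture (n = 1500) with B = 25 bootstraps, N = 300
permutations and the linear imputer — reduced resampling sizes chosen so
repeated whole-pipeline runs stay cheap, with verdict thresholds
unchanged; MR batteries over 100 replicates (500 for Q calibration).

Numerical details: lasso solved by coordinate descent on the whole λ
path with warm starts; logistic fits by SAGA at tol 10⁻⁶ (subject-order
invariance to optimizer tolerance); OLS residualization via
`numpy.linalg.lstsq` with explicit rank checks (rank-deficient designs
raise rather than silently pseudo-invert); permutation correlations
computed as one matrix product over standardized residuals; RSS floored
at 10⁻¹² inside EBIC to keep logs finite on noiseless toys; EBIC ties
resolved sparser-first. Bootstrap intervals use linear-interpolation
percentiles, so at B = 2 the 2.5/97.5 interval coincides with min–max.

## Known limitations

- Categorical-node penalty selection scores the penalized multinomial
  likelihood (no support refit); with few categorical nodes in the
  intended rosters this asymmetry is unmeasurable in the benchmarks.
- The weighted-median bootstrap SE is parametric (normal perturbations
  of the summary effects), matching common practice but not a
  nonparametric resample of instruments.
- Positional thinning is a stand-in for LD clumping and does not model
  linkage structure.
- The jointness count is a graph-combinatorial score; it does not weigh
  edge signs, so a metabolite bridging with opposing-sign edges counts
  the same as one with concordant signs (the weighted variant partially
  addresses this).
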