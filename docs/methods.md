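# Methods

## Model

Every test in the pipeline is a single-feature random-intercept model

    g(E[y_ij]) = x_ij' beta + b_i,     b_i ~ N(0, sigma_b^2)

where *i* indexes individuals (sample donors), *j* their repeated samples,
and the fixed effects contain the tested variable (time, or any metadata
column passed as `test_var`) plus, in the covariate loop, exactly one
covariate. The family and link follow the declared data type:

| data type  | family                | link     | dispersion            |
|------------|-----------------------|----------|-----------------------|
| count      | negative binomial NB2 | log      | size k (Var = mu + mu^2/k) |
| proportion | beta                  | logit    | precision phi         |
| binary     | Bernoulli             | logit    | —                     |
| ordinal    | proportional odds     | logit    | L−1 cutpoints         |
| continuous | gaussian              | identity | residual sigma^2      |

Continuous features are first mapped through a rank-based inverse-normal
transform (Blom offsets, mean ranks for ties), so the linear model sees an
approximately standard-normal response regardless of the raw scale.
Proportions of exactly 0 or 1 are squeezed to the open interval by
`(y(n−1)+0.5)/n` before beta fitting. Ordinal responses with only two
observed levels degrade to logistic regression.

### Estimation

The scalar random intercept is integrated out by adaptive Gauss–Hermite
quadrature (default 10 nodes). For each individual the integrand is
re-centered at its posterior mode (found by a vectorized Newton iteration
across all individuals at once) and re-scaled by the curvature there, which
keeps a few nodes accurate even when the conditional posterior is much
narrower than the random-effect prior — the relevant regime for
high-information count data. The optimizer is L-BFGS-B over
(beta, log sigma_b, dispersion) with an analytic gradient; because the
gradient is exact only for *fixed* node positions, optimization runs an
outer loop that freezes the nodes, solves the frozen problem, re-freezes,
and repeats to self-consistency (typically 2–4 outer iterations). One node
is handled as an exact Laplace approximation (numeric gradients; it is only
a fallback rung). The gaussian family has a closed-form marginal likelihood
and is delegated to statsmodels' linear mixed model (ML).

Standard errors come from a finite-difference Hessian of the marginal
deviance at the optimum; per-term tests are Wald z (chi-square for
multi-column factor terms). The NB fit was validated coefficient-by-
coefficient against glmmTMB on identical data (agreement to ~1e-3) and by a
Monte-Carlo check that the 95% Wald interval covers the simulating
coefficient in ≥ 90/100 replicates; both run in the test suite.

Non-convergence walks a retry ladder — perturbed restart, Laplace, then a
fixed-effects-only GLM flagged as downgraded — so a feature degrades
gracefully rather than returning NA. A constant response or a rank-deficient
design (e.g. a covariate duplicating the tested variable) is flagged as
non-converged with a named reason, never silently repaired.

## Significance and classification

Per run, a feature is significant iff its null-model BH *q* < `q_null`
(default 0.1) **and** its post-hoc BH *q* < `q_posthoc` (default 0.05). The
post-hoc family is, in disc mode, all pairwise time-level contrasts of all
features pooled into one BH family; in cont mode, the Spearman rank test of
the tested variable against each feature. Requiring both filters is what
drives the false-discovery behavior of the pipeline: the parametric and
rank-based routes rarely agree on a null feature by chance.

Significant features enter the covariate loop. Candidate covariates are
screened per feature at raw p < `alpha_screen` (0.05) — Wilcoxon for binary
categorical, Kruskal–Wallis for multi-level categorical, Spearman for
continuous — then each selected covariate joins the tested variable in one
joint GLMM. Classification uses raw within-model p-values at `alpha_model`
(0.05): time significant in every converged model → `OK_nrc`; otherwise any
model with time non-significant and the covariate significant → `RC`; else
`EC`. An empty candidate set gives `OK_nc`. Non-converged covariate models
are excluded from the universal quantifier (and logged) rather than counted
as failures. In disc mode "time significant" inside a joint model means any
pairwise contrast significant, keeping step 2 consistent with the
feature-level criterion. Rows missing the covariate under test are dropped
from that covariate's model only.

## Simulator

The generator emulates a two-time-point intervention cohort. Per individual
and feature, latent trajectories are multivariate normal with AR(1)
within-individual correlation `Corr(y_s, y_t) = rho_AR^|s−t|` (default
rho_AR = 0.7, a typical within-subject stability for gut microbiome
abundances); each feature gets a baseline drawn once per dataset from
N(0, 1), giving the log-normal spread of relative abundances real profiles
show. Spiked features (20 of 200 by default) receive a linear mean shift
`beta * t`. Counts are per-feature Poisson draws around the exponentiated
latent value, scaled so the expected per-sample total matches `depth`
(default 50 000); marginally this is a log-normal mixture, i.e.
overdispersed counts. Features are deliberately *not* allocated
compositionally from a fixed read total: multinomial allocation would push
every non-spiked feature down as spiked features grow, planting a spurious
time signal in features the design promises are identically distributed
across time points. Consequently row sums vary around `depth` rather than
equalling it; `apply_depth_bias` (rarefaction to per-time-point depths) is
the tool for studying depth artifacts explicitly.

The effect-size knob is calibrated, not assumed: `calibrate_effect` bisects
on beta until the median Spearman rho of spiked-feature counts against time
hits the target (±0.02), using 5 pilot replicates of 50 features with common
random numbers (fixed internal seeds) so the bisection is monotone and
deterministic. Calibration is a property of the study design, so its seeds
are independent of the per-dataset seed.

Dummy covariates are copies of the time column with a calibrated number of
entries flipped to another time level (realized Spearman rho within ±0.03 of
target, never an exact copy). A tie-preserving discrete dummy is the only
way to reach rho ≈ 0.99 against a two-level time variable: any continuous
dummy breaks the ties and caps Spearman's rho at ≈ 0.87 for balanced groups.
The same cap is enforced for spiked-feature effect targets
(`SimConfig.validate` rejects infeasible targets by name).

`shuffle_time_within_individual` permutes time labels independently per
individual, leaving features and covariates untouched — the negative control
in which no real association with (new) time survives and the ground truth
is reset to all-null.

### What the simulator does not emulate

Zero inflation beyond what the log-normal-Poisson tail produces, taxon-taxon
correlations, compositional coupling, uneven sampling schedules, and
missingness. Passing tests on these data therefore demonstrate correct
behavior of the statistical machinery under the stated generative
assumptions, not robustness to every pathology of real sequencing data.

## Benchmark conventions

Feature calls are scored against truth as accuracy, TPR, FDR and MCC. A
replicate with zero positive calls has FDR 0 (this makes "median FDR = 0"
well defined on null data); TPR is missing when the truth has no positives;
MCC is 0 when a confusion-matrix marginal is 0.

For covariate detection, the dummy is run as the tested variable with true
time among the candidate covariates; a spiked feature is correctly handled
when its dummy verdict is `NS`, `RC` or `EC`. `covariate_success` reports
both the per-replicate *rate* of correctly handled spiked features and the
stricter all-features indicator. The rate is the headline quantity: the
classification tests the dummy at alpha = 0.05 conditional on time, so with
one dummy its per-feature failure share sits near 0.05 by construction and
the expected rate near 0.95, while the probability that all 20 spiked
features succeed at once is only ~0.36 — the all-or-nothing indicator is
reported but is not a meaningful 0.95-scale summary.

### Problem sizes

The shipped experiments use 20 replicates for the spiked-design metrics
(n = 38 individuals), 20 replicates per correlation level for covariate
detection (n = 75), and 10 shuffled negative controls — the package's
desk-scale defaults, chosen so a full verification pass completes in
minutes; `replicate_runner` accepts any grid and replicate count for larger
studies.

## Numerical choices and edge cases

* Quadrature: 10 nodes default; 5 and 25 agree to < 1e-3 on well-behaved
  fits (tested). Mode-finding Newton tolerance 1e-9, with step clipping.
* Bounds: log sigma_b ∈ [−5, 3] (sigma_b^2 from ~4e-5, effectively zero, to
  e^6); NB log-size ∈ [−8, 13].
* BH adjustment passes missing p-values through and excludes them from the
  family size; Holm and Bonferroni are available alternatives.
* Wilcoxon screen: exhaustive enumeration below a combined n of 10, else the
  tie-corrected normal approximation without continuity correction (which
  makes the two-group Kruskal–Wallis chi-square exactly its square).
* Cliff's delta is computed by sorted-array rank counting (O((m+n) log n)),
  ties contributing zero; it equals the brute-force pair count (tested).
* TMM follows edgeR's double-trimmed weighted M-value mean (validated
  against `calcNormFactors` in the suite); GMPR includes the self-ratio in
  its geometric mean like the reference implementation; CSS uses a fixed
  0.5 quantile and a fixed count-like rescale (1000) so output is invariant
  to global depth rescaling; CLR's default pseudocount is half the smallest
  nonzero value; rarefaction is multivariate-hypergeometric (without
  replacement), seeded.
* The cuneiform plot writes deterministic SVG (fixed hash salt, no
  timestamp): re-rendering identical results is byte-identical.

## Known limitations

No random slopes, crossed random effects, or zero-inflated families; no
joint multi-covariate adjustment (that contrast with all-at-once modeling is
the point of the design); effect sizes are marginal, not partial — when a
covariate truly drives a feature, the reported Spearman/Cliff value still
reflects the unadjusted association. Post-hoc BH pooling across features is
the stricter reading of a global post-hoc family; a per-feature family would
be slightly more permissive.
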