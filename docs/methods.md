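# Methods

`mrpipe` implements a two-sample Mendelian randomization (MR) workflow for
summary-level GWAS data: a standardized quantitative exposure (the motivating
application is a circulating metabolite measured by NMR in ~121,600 biobank
participants) instrumented by a handful of genome-wide-significant SNPs, and
binary or quantitative outcomes drawn from large GWAS consortia. This note
records the models, the defaults and why they were chosen, what the synthetic
generator does and does not emulate, and the numerical choices a maintainer
would want to know.

## Instrument selection and QC

Candidate instruments are SNPs with exposure p strictly below `p_threshold`
(default 5e-8). Greedy clumping takes the smallest-p remaining candidate as an
index SNP and discards candidates with r² above `r2_threshold` (default 1e-3)
to any retained index. LD is an explicit input (a square r² matrix); SNPs
missing from the matrix are treated as unlinked and logged loudly, so a run
without LD data degrades visibly rather than silently. Ties in p are broken by
(chrom, pos, rsid) so clumping is invariant to input row order.

Per-SNP strength is F = (beta/se)²; F < 10 flags a conventionally weak
instrument. Variance explained assumes a standardized exposure:
r² = 2·eaf·(1−eaf)·beta². Confounder screening is table-driven: a long-format
(rsid, trait, p) annotation table replaces live phenotype-catalogue queries;
hits below the screening threshold flag the instrument but never remove it —
removal is a sensitivity-analysis decision made by the pipeline (below).

## Harmonization

Exposure and outcome records are matched by rsid. Outcome records whose
alleles are swapped relative to the exposure have beta negated and eaf
reflected; strand-complemented records are complemented first. Palindromic
pairs (A/T, C/G) are always dropped — frequency-based inference is
deliberately not attempted, because the exposure GWAS's allele frequencies are
not guaranteed to transfer across outcome cohorts. Duplicate rsids keep the
smallest-p record and are logged as `duplicate`.

## Estimators

All estimators operate on the per-SNP Wald ratios beta_out/beta_exp with
first-order standard errors se_out/|beta_exp| (exposure noise ignored; the
tests bound the approximation error by Monte Carlo). Two-sided p-values use
the normal distribution throughout, matching summary-data MR convention.
Binary-outcome estimates are additionally reported as odds ratios per SD of
exposure; all computation stays on the log-odds scale.

- **IVW (multiplicative random effects).** Weighted mean of the ratios with
  weights 1/ratio_se². The standard error is inflated by
  sqrt(max(1, Q/(k−1))), where Q is Cochran's Q — over-dispersion widens the
  interval, under-dispersion never narrows it. This floor is conservative: at
  small k it costs a few percent of power relative to the nominal curve
  (visible in the power-validation test).
- **MR-Egger.** SNPs oriented so beta_exp > 0, then a weighted regression of
  beta_out on beta_exp *with* intercept, weights 1/se_out². The intercept and
  its (residual-scale-inflated, floored at 1) standard error form the
  directional-pleiotropy test; the slope is the causal estimate under InSIDE.
  Known limitation inherited from the standard formulation: when the
  pleiotropy variance greatly exceeds the outcome sampling variance, the
  1/se_out² weights are mis-specified and the intercept test's size creeps
  above nominal; the size simulation below therefore uses pleiotropy on the
  scale of se_out. Weak instruments (F ≲ 30) likewise inflate the test
  (regression dilution); no SIMEX-style correction is applied.
- **Weighted median.** Ratios sorted, weights normalized, cumulative
  percentile p_j = Σ_{i≤j} w_i − w_j/2, linear interpolation at 0.5.
  Consistent while valid instruments carry >50% of weight. Standard error by
  parametric bootstrap (default 1000 draws, mandatory seed).
- **Weighted mode.** Argmax over a 512-point grid of a weighted normal-kernel
  density with bandwidth h = factor · 0.9 · min(sd, 1.4826·MAD) · k^(−1/5);
  a zero bandwidth (point mass) returns the heaviest ratio. Bootstrap SE as
  above.
- **Penalized debiased IVW (pIVW).** The IVW denominator Σ beta_exp²/se_out²
  overstates instrument strength by the exposure sampling variance; the
  debiased denominator subtracts it and is then penalized away from zero via
  the positive root of μ̃² − μ̂·μ̃ − λ·V̂ = 0 (λ default 1; λ→0 or
  se_exp→0 recovers the unpenalized form). The variance estimator is the
  estimating-equation sandwich with a method-of-moments balanced-pleiotropy
  component τ² (floored at 0). The extras report the instrument-strength
  statistic μ̂/√V̂.
- **MR-PRESSO.** Observed statistic: weighted residual sum of squares where
  each SNP's residual uses the leave-one-out IVW fit. Null distribution from
  parametric simulations under the fitted model (vectorized; default 1000).
  Per-SNP outlier p-values from the same simulations, Bonferroni-adjusted;
  outliers below 0.05 are removed and the corrected estimate is exactly
  `ivw()` on the remainder. A distortion test (random same-size removals) is
  reported but never auto-applied.

## Colocalization

Single-causal-variant Bayesian colocalization over a region: per-SNP
Wakefield log approximate Bayes factors, log ABF = ½(log(1−r) + r·z²) with
shrinkage r = w²/(w² + se²), prior effect SD w = 0.2 (quantitative) or 0.15
(log-odds, binary). Hypothesis likelihoods sum single-causal configurations
with priors p1 = p2 = 1e-4, p12 = 1e-5; H3's Σ_{i≠j} term factorizes as
(Σ₁)(Σ₂) − Σ₁₂ and everything is computed in log space (log-sum-exp and a
guarded log-diff-exp), so |z| beyond 30 cannot overflow. A region reduced to
one shared SNP is valid but flagged: H3 is identically zero there.

The pipeline uses PP_H4 ≥ 0.8 (configurable) to call a shared causal variant.

## Sensitivity sets, meta-analysis, sex differences, power

For each outcome the pipeline builds a sensitivity instrument set: every
confounder-flagged instrument is excluded unless its colocalization with that
outcome supports a shared variant (PP_H4 at or above the threshold — read as
vertical pleiotropy, the variant acting through the exposure). A flagged SNP
that is also outcome-associated but has no colocalization result is a hard
error, because the retain/drop decision would otherwise be silent. All
estimators run on both the main and the sensitivity set.

Estimates from two outcome GWAS of the same disease are pooled by
fixed-effect inverse variance on the beta scale; Cochran's Q, its p, and
I² = max(0, (Q−df)/Q)·100 report between-dataset heterogeneity. Fixed effect
was chosen because k = 2 makes random-effects variance estimation degenerate.
The sex-difference test is z = (b_m − b_w)/√(se_m² + se_w²), algebraically the
two-group Cochran Q test (the equality is asserted to 1e-12 in tests).

Multiple testing uses a Bonferroni threshold alpha/n_tests (n_tests is
configuration, default 15, i.e. 0.05/15 ≈ 0.003); p-values between the
corrected threshold and alpha are classed "suggestive".

Power uses the normal approximation for summary-data MR: the causal-estimate
SE is 1/√(n·r²·cf·(1−cf)) for a binary outcome with case fraction cf (cf term
dropped for quantitative outcomes), and the minimum detectable effect at
power 1−β is (z_{1−α/2} + z_{1−β})·SE. This is asymptotic in both instrument
strength and instrument count; the validation simulation uses 60 instruments
with mean F ≈ 100 because at k = 9 the over-dispersion floor alone costs
~5-7% power relative to the nominal 80%.

## Bidirectional MR

The reverse direction selects instruments from the outcome GWAS under the
same thresholds and swaps the roles. When the outcome's only heritable signal
is downstream of the exposure (as in the forward-only synthetic scenario),
reverse selection usually finds nothing — the section then reads "not
estimable" rather than failing — and when it finds a single hit, that hit is
the forward signal leaking through and no reverse IVW exists. This mirrors
how a real bi-directional analysis degrades.

## The synthetic generator

`generate_mr_dataset` draws maf ~ U(0.05, 0.5), true exposure effects γ_j
normal and rescaled so Σ 2·maf(1−maf)·γ² equals `r2_total`, and observed
effects with the exact asymptotic standard errors 1/√(2·maf(1−maf)·n)
(binary outcomes inflated by the case-fraction variance). Pleiotropy modes:
`balanced` (zero-mean), `directional` (nonzero mean, oriented by sign(γ) —
i.e. relative to the exposure-increasing allele, since an orientation-blind
shift averages out of every estimator), and `inside_violating` (α correlated
with γ). `pleiotropy_fraction` restricts pleiotropy to a random subset;
`n_outliers`/`outlier_shift_sds` spike individual outcome effects;
`weak_fraction` down-scales a subset of γ to expected F ≈ 3–8;
`inject_palindromic`/`inject_allele_swaps` create harmonization hazards. The
generating truth (γ, α, maf, affected rsids, seed) is returned and
JSON-serializable.

Defaults emulate the motivating study's scale: k = 9 instruments, exposure
n = 121,577, outcome n = 500,000 binary with case fraction 0.25. The default
`r2_total` is 0.001: the smallest round value at which all nine instruments
are strong in expectation (mean expected F ≈ 14.5 > 10). (At the frequently
quoted 0.05% variance explained, expected F would be ~7.8, which contradicts
an all-instruments-strong design.)

What the generator does **not** emulate: sample overlap between exposure and
outcome cohorts (noise is independent by construction), LD between
instruments (instrument SNPs are exchangeable and unlinked; LD appears only
in the colocalization regions via an AR(1) correlation), allele-frequency
drift between cohorts, and individual-level binary-trait likelihoods (ses use
the case-fraction variance approximation). Passing tests therefore certify
the estimators' statistical contracts under clean two-sample assumptions, not
robustness to overlap or LD mis-specification.

`generate_coloc_region` draws regional z-scores from MVN(Rλ, R) with
R_ij = rho^|i−j| and a causal configuration per scenario (`shared`,
`distinct` with index r² < 0.01, `trait1_only`, `null`).

## Simulation sizes used in validation

The acceptance script and acceptance-style tests run, per check: 500
replicates (IVW coverage/unbiasedness at true OR 0.62, nine strong
instruments with r² = 2% so that the first-order-Wald attenuation ~β/F is
negligible against the Monte-Carlo SE), 1000 replicates (robust-estimator
contract at k = 150 with 40% directional pleiotropy — at small k the χ²(1)
distribution of per-SNP weights lets the invalid minority carry >50% of
weight too often for any median-based estimator; pIVW strong/weak regimes at
mean F ≈ 101 and ≈ 5), 2000 replicates (Egger intercept size, k = 40,
F ≈ 91), 200 replicates (MR-PRESSO detection/false-removal at 1000 internal
simulations; colocalization scenario recovery at m = 100, rho = 0.9,
z = 10). Everything runs in well under a minute per check on one CPU.

## Degenerate inputs and tie-breaks

- `harmonize` with an empty instrument list, estimators below their minimum
  SNP counts, and selection with zero significant candidates raise typed
  errors naming the offending quantity.
- A bootstrap SE of exactly zero (degenerate resamples) is replaced by the
  smallest positive double so downstream z-statistics stay finite.
- p-values are floored at the smallest positive double rather than printed
  as 0.
- The weighted-mode bandwidth falls back to the heaviest ratio when the
  robust spread is zero.
- `ColocResult` enforces ΣPP = 1 to 1e-9 at construction.
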