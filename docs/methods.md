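# Methods

## Statistical model

Two-sample MR treats per-SNP association estimates from two
non-overlapping GWAS as data. For instrument j, let β̂_exp,j (se_exp,j) be
its exposure association and β̂_out,j (se_out,j) its outcome association
after harmonization. Under the instrumental-variable assumptions
(relevance, no confounding, exclusion restriction) each Wald ratio
rⱼ = β̂_out,j/β̂_exp,j estimates the same causal effect β, and the IVW
estimator is the inverse-variance-weighted mean of the ratios with
first-order weights wⱼ = β̂²_exp,j/se²_out,j — equivalently, weighted least
squares of β̂_out on β̂_exp through the origin with weights 1/se²_out.
Fixed-effect inference uses se = (Σwⱼ)^(-1/2); the default
multiplicative-random-effects (MRE) mode inflates this by
max(1, √(Q/(n−1))), with Q the weighted residual sum of squares. The MRE
floor matters in practice: when the outcome GWAS is much larger than the
exposure GWAS (here ~456k vs ~18k), the exposure-side estimation noise
violates the no-measurement-error assumption behind the first-order
weights, Q/(n−1) sits well above 1 even without pleiotropy, and the
fixed-effect SE would be anti-conservative.

MR-Egger re-orients instruments so β̂_exp ≥ 0 and adds an unconstrained
intercept to the weighted regression; under the InSIDE assumption the
intercept estimates the mean directional pleiotropic effect and the slope
a pleiotropy-adjusted causal effect. Both SEs carry the analogous
max(1, √(Q/(n−2))) dispersion floor. All p-values and CIs use the normal
approximation (1.96 for 95%), matching how odds ratios and CIs are
conventionally computed from summary-data MR; t-quantiles are not used.

Cochran's Q over the Wald ratios (χ², n−1 df) flags heterogeneity. The
MR-PRESSO-style test computes the observed weighted RSS around
leave-one-out IVW fits, then simulates the instrument set parametrically
(β̂*_exp,j ~ N(β̂_exp,j, se²_exp,j), β̂*_out,j ~ N(β(−j)·β̂_exp,j, se²_out,j))
and compares: the global p is the add-one tail fraction of simulated RSS
at or above the observed one, and each SNP's residual term is compared to
its own simulated distribution with Bonferroni correction across SNPs.
Monte-Carlo p-values use (r+1)/(n+1) and so are never exactly zero. The
original procedure's distortion step (re-estimation after outlier
removal) is intentionally absent: these diagnostics gate claims rather
than correct estimates.

## Mediation

The two-step decomposition estimates β_A (exposure→mediator MR), β_B
(mediator→outcome MR using the mediator's own instruments, univariable)
and β_total (exposure→outcome MR), and defines

  indirect = β_A·β_B, direct = β_total − β_A·β_B,
  proportion mediated = indirect / β_total (signed ratio).

The indirect effect's SE is the first-order delta (Sobel) formula
√(β_A²se_B² + β_B²se_A²); its CI is the empirical quantile interval of
a*·b* over independent normal draws (the distribution-of-product
approach, default 100,000 draws), which remains valid in the skewed
small-z regime where the Sobel interval is poor. The proportion's CI
divides each product draw by an independent draw of the total effect.
The draws treat the three leg estimates as independent, which ignores
the covariance induced by sharing the outcome GWAS; with distinct
instrument sets per leg this covariance is small. A pathway is
*significant* when the indirect p < 0.05 and the proportion lies strictly
in (0, 1); inconsistent mediation (indirect opposing the total) is
thereby excluded by design.

β_B is deliberately univariable rather than multivariable-MR-adjusted:
the two-step screening design estimates each leg with the trait's own
genome-wide instruments, and the direct effect is obtained by
subtraction, not joint modelling.

## Screening pipeline

Instrument funnel per exposure: p < 1×10⁻⁵ (strict), optional exclusion
list, greedy LD clumping (r² < 0.001, 10 Mb window, lowest p kept, ties
broken by smaller SE then lexicographic SNP id), per-SNP F = (β/SE)² ≥ 10
(inclusive). Exposures whose funnel empties are recorded as excluded, not
errors. Claims require IVW p < 0.05 with no multiple-testing correction —
the screening convention for hypothesis generation across hundreds of
taxa/metabolites, accepting the implied false-discovery load. Gating is
asymmetric by default: exposures flagged pleiotropic (Egger intercept or
PRESSO global p < 0.05) are dropped from claims, mediators are retained
(discovery-maximising), and targets with a significant, sensitivity-clean
reverse-direction estimate are flagged bidirectional and excluded from
mediation. Both switches are config options.

Harmonization conventions: SNPs are matched by id only; non-palindromic
alleles are resolved by letters (including strand complements);
palindromic SNPs (A/T, C/G) are oriented by requiring both allele
frequencies on the same side of 0.5 and dropped when either frequency is
missing or inside the (0.42, 0.58) ambiguity window; anything else is
unmatchable and dropped with an audit count. A missing frequency on a
non-palindromic SNP is harmless.

## Synthetic data generator

`simulate_triangle` emulates the summary statistics of three GWAS from
one population. Each trait has its own instrument block: exposure-block
effects γⱼ ~ N(0, sd²_exp) propagate a·γⱼ to the mediator and
(direct + a·b)·γⱼ to the outcome; mediator-block effects δⱼ reach the
outcome only through the mediator (b·δⱼ); outcome-block effects εⱼ feed
back on the exposure with the reverse-causation coefficient (0 by
default). Horizontal pleiotropy αⱼ ~ N(mean, sd²) is added to the
exposure block's outcome effects *relative to the exposure-increasing
allele* — the orientation in which the Egger intercept measures
directional pleiotropy; defining it unconditionally would cancel the mean
under re-orientation and make "directional" pleiotropy undetectable by
construction. Reported effects add N(0, se²) noise with the
standardized-trait approximation se = 1/√(2·n·EAF·(1−EAF)),
EAF ~ U(0.05, 0.95); p-values are two-sided normal. Everything is
deterministic given the seed.

Default study conditions (chosen once, as a realistic regime): sample
sizes 18,340 (exposure), 8,299 (mediator), 456,348 (outcome) — typical of
consortium microbiome, plasma-metabolome and biobank disease GWAS;
instrument strengths sd 0.10 (microbial abundances: weak, many
sub-threshold), 0.30 (metabolites: strong cis loci), 0.05 (disease
log-odds); 30 SNPs per block; mediation split a=0.3, b=0.4, direct=0.2
(total 0.32, proportion mediated 37.5%). The strong-mediator/weak-exposure
asymmetry is also what keeps step-2 instruments genuinely the mediator's
own: with comparable strengths, exposure instruments would pass the
mediator's selection threshold and bias β_B toward total/a.

What the generator does *not* model — and what passing tests therefore do
not establish about real data: linkage disequilibrium (SNPs are
independent; clumping is exercised on synthetic r² fixtures), sample
overlap, population stratification, winner's-curse correction (selection
acts on the noisy betas, as in practice, so mild attenuation of strong
effects is present and visible in the recovery tests), case-control
ascertainment (binary-trait betas use the same Gaussian summary
approximation on the log-odds scale), and multi-mediator correlation.

## Numerical conventions and problem sizes

- p-values are clipped to [5e-324, 1] so they remain in (0, 1].
- Clumping and all screens are deterministic: ties broken by (p, SE, id).
- Explained variance R² = 2·EAF·(1−EAF)·β² (standardized trait), capped
  below 1, reported missing when EAF is absent; the affected SNP is not
  excluded on that account.
- MR-PRESSO defaults: 5,000 simulations, outlier significance 0.05
  Bonferroni-corrected across instruments; tests use 1,000 simulations.
- Product/ratio Monte-Carlo intervals: 100,000 draws by default, 10,000
  minimum.
- Degenerate inputs raise typed errors: zero exposure effect (Wald),
  collinear exposure effects (Egger), zero total effect (proportion),
  empty instrument sets (no-instruments signal consumed by the screens).
- Validation is total at the I/O boundary: rows violating any record
  invariant are dropped with a logged count; datasets are otherwise
  immutable downstream.

Simulation sizes in the test-suite and acceptance script were chosen to
give stable statistics at interactive runtimes: 2,000 replicates for
type-I-error calibration (IVW band (0.04, 0.06) at nominal 5%, Monte-Carlo
sd ≈ 0.005), 100 seeds for PRESSO power/null rates, 400 replicates for
product-interval coverage, 20–25 replicates for recovery means. The
calibration fixture uses 50 candidate SNPs at instrument sd 0.2 (~40
surviving selection) because the max(1,·) dispersion floor makes the
Egger intercept test conservative at small df; at ~38 df the expected
rejection is ≈0.04–0.05, comfortably inside the stated band.

## Known limitations

- No proxy-SNP lookup when an instrument is missing from the outcome file.
- No Steiger directionality filtering; reverse causation is handled by the
  explicit reverse screen only.
- No weighted-median/mode estimators and no multivariable MR.
- The confounder scan is represented by a user-supplied SNP exclusion
  list, not a live annotation query.
- LD information enters only through the pairwise-r² panel interface; no
  genotype-level computation.
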