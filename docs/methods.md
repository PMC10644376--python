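# Methods

## Model and assumptions

`mrkit` implements two-sample Mendelian randomization with summary
statistics: SNPs serve as instrumental variables for an exposure, and the
causal effect of the exposure on an outcome is estimated from the per-SNP
association statistics of two independent, non-overlapping GWAS.  Validity
rests on the three instrumental-variable assumptions:

1. **Relevance** — each instrument is robustly associated with the exposure
   (enforced by the p < 5×10⁻⁸ selection filter and the F > 10 gate);
2. **Independence** — instruments are independent of confounders of the
   exposure–outcome relation (unverifiable from summary data; the
   randomness of allele assignment at conception is the design argument);
3. **Exclusion restriction** — instruments affect the outcome only through
   the exposure.  Violations (horizontal pleiotropy) are what the
   sensitivity battery probes.

Effects are on the log-odds scale for binary traits; results are reported
as odds ratios per unit increase in the exposure's liability.  Reporting
"per 1 SD" for a binary exposure is a common but loosely defined
convention; `mrkit` reports per-unit log-odds effects and leaves any
rescaling to the user.

## Harmonization

Outcome effects are aligned onto the exposure's effect allele.  Orientation
is resolved by identity, allele swap, strand complement, or
complement-swap, in that order; anything else is dropped as incompatible.
Palindromic SNPs (A/T, C/G) carry no strand information in their allele
labels, so they are aligned by effect-allele frequency when both
frequencies are available and outside 0.5 ± `palindrome_eaf_window`
(default 0.08, a closed interval with a 1e-12 epsilon so printed boundary
frequencies like 0.42 behave as written), and dropped otherwise.  Duplicate
SNP IDs within a table are a hard error rather than silently deduplicated,
because instrument counts feed directly into inference.

## Instrument selection

Greedy LD clumping visits SNPs in ascending p-value order (ties broken by
genomic coordinate, then ID, for determinism) and keeps a SNP iff its r²
with every kept SNP on the same chromosome within the window (default
10,000 kb, |Δpos| ≤ window) is below the threshold (default 0.001).  The LD
panel is a user-supplied precomputed matrix; the package never derives LD
from genotypes, and reproducing a published reference-panel clumping
requires that panel as input.  Instruments genome-wide significant for the
*outcome* are excluded as likely pleiotropic or reverse-direction signals.

Instrument strength uses F = (β̂/se)², the squared Wald z — for a
single-SNP instrument this equals the regression F, and its minimum among
genome-wide-significant SNPs is z²(p=5×10⁻⁸) ≈ 29.7.  Variance explained
follows r² = F/(F + n − 2) per SNP, summed over (independent) instruments.

## Estimators

Numerical conventions, chosen to match standard summary-data MR practice:

* IVW weights are first-order (β̂ₓ²/σᵧ²), ignoring exposure-side
  uncertainty; the random-effects flavour is multiplicative with the SE
  inflation floored at 1, and p-values come from the normal distribution.
* MR-Egger orients instruments to β̂ₓ ≥ 0 before fitting, applies the same
  multiplicative overdispersion floor, and uses t-distribution p-values on
  J − 2 degrees of freedom.  The regression itself is a statsmodels WLS
  fit; the floor is applied on top of it.
* The weighted median sorts Wald ratios, builds the cumulative-weight grid
  sⱼ = Σₖ≤ⱼ wₖ − wⱼ/2 with normalized weights, and linearly interpolates at
  s = 0.5 (endpoints are returned when 0.5 falls outside the grid).  Its SE
  is a parametric bootstrap (default 1000 replicates) that redraws both βₓ
  and βᵧ from their reported SEs; the seed is mandatory, making the point
  estimate deterministic and the SE reproducible.
* Confidence intervals use the fixed 1.96 multiplier throughout.

## Sensitivity analyses

Cochran's Q uses the fixed-effects IVW estimate and IVW weights; I² =
max(0, (Q − df)/Q)·100, with the 25/75 cut-points labelling low, moderate
(closed interval) and high heterogeneity.

The outlier test follows the MR-PRESSO recipe: each SNP's weighted squared
residual is measured against the IVW slope fitted *without* that SNP; the
global statistic is the residual sum, compared against `n_sim` (default
1000) parametric redraws of βᵧ around the leave-one-out predictions.
Empirical p-values are floored at 1/(n_sim+1), and per-SNP calls are
Bonferroni-corrected at α = 0.05.  A consequence of the empirical floor is
granularity: with 1000 simulations and more than ~50 instruments the
Bonferroni threshold 0.05/J is below the smallest attainable p-value, so
per-SNP outlier calls require raising `n_sim` — the same behaviour as the
original method at its default settings.  When outliers are flagged, the
distortion test compares the shift in the IVW estimate after their removal
with the shifts produced by removing equally many randomly chosen inliers.

Leave-one-out refits the random-effects IVW J times and flags any exclusion
that changes the sign of the estimate or moves its p-value across 0.05.
Funnel data pairs each Wald ratio with its precision 1/se; plotting is a
thin layer the user can apply with any tool.

## Power

Binary-outcome power uses the non-centrality approximation
z = ln(OR)·√(n·r²·K(1−K)) with two-sided power
1 − Φ(z₁₋α/₂ − z) + Φ(−z₁₋α/₂ − z).  It is exact at the null (power = α at
OR = 1), symmetric in OR ↔ 1/OR, and monotone in n, r² and |ln OR|.  Note
that published power figures for comparable designs are sometimes higher
than this approximation yields — e.g. a reported 57 % for a rare-outcome
design (682 cases of 361,822, r² = 0.152, OR = 1.21) where direct
evaluation gives ≈ 49 % — because the exact inputs entered into web
calculators (which n, which r², one- vs two-sided α) are often
under-specified.  `mrkit` exposes every input so alternative conventions
can be probed, and does not force agreement.

## The synthetic generator

`simulate_two_sample` works at the summary level: it never simulates
genotypes.  Per SNP it draws an effect-allele frequency (uniform on
[0.05, 0.95]), attaches the case-control log-odds SE
1/√(2p(1−p)·n·K(1−K)), draws the true strength F from a truncated Pareto on
[29.7, 1487.9] with shape 1.0183 (solved so the mean strength is ≈116 —
a realistic spectrum for a genome-wide-significant instrument panel of a
well-powered autoimmune-disease GWAS; for 77 instruments at n ≈ 58,000 the
implied total variance explained is ≈15 %), and samples observed effects
normally around the truth.  Outcome means are `true_beta·b + α` with the
pleiotropic effect α defined on the exposure-increasing allele (so
"directional" pleiotropy stays directional after Egger's orientation step);
`inside_violation` correlates α with instrument strength to break InSIDE.
Defaults mirror a 77-instrument study with exposure n = 58,284
(K = 0.246) and outcome n = 361,822 (K = 0.00188), true causal log-OR 0.19.

The generator emulates: sampling noise of two independent case-control
GWAS, allele-orientation and strand scrambling between the two tables, a
configurable palindromic fraction (default 5 %), and the three pleiotropy
regimes.  It does **not** emulate: LD between instruments (they are
post-clumping by construction), sample overlap between the two studies,
winner's-curse selection of instruments discovered in the same data,
allele-frequency differences between cohorts, or non-normal effect-size
errors.  Passing calibration tests therefore demonstrates correctness of
the estimators under the stated generative model, not robustness to those
real-data complications.

## Problem sizes and degenerate inputs

The test-suite replicate studies use 1000 replicates for IVW calibration
(mean recovery, 95 % CI coverage, type-I error) and the Egger-bias
comparison, 200 replicate datasets for the outlier test's null behaviour
and per-regime Egger rejection rates, and 100 random block-diagonal
fixtures for the clumping oracle — sizes at which Monte-Carlo error is well
inside the asserted tolerances while the whole suite runs in seconds.
Degenerate inputs are errors, not silent results: zero exposure effect
(undefined Wald ratio), fewer instruments than an estimator's minimum
(1 for IVW with a warning, 3 for Egger/median, 4 for the outlier test),
missing seeds for any stochastic step, and empty post-selection instrument
sets (the failing stage is named in the exception).

## Known limitations

* First-order IVW weights understate uncertainty when exposure effects are
  weak; the F > 10 gate keeps this second-order term small but nonzero.
* The weighted-median bootstrap SE, while seeded, is itself an estimate;
  its Monte-Carlo error scales as 1/√n_boot.
* The outlier test's empirical p-value granularity (above).
* No proxy-SNP lookup, no Steiger directionality filtering, no multivariable
  or mode-based estimators; instruments absent from the outcome GWAS are
  simply dropped at the intersection step and reported in the selection log.
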