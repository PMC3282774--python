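# Methods

## Data model

A study is one case-control comparison of a biallelic SNP with genotype
counts (GG, GC, CC) per arm plus metadata (author, year, country, ethnicity,
genotyping method). Counts are the sufficient statistic: any percentage
columns in an input file are ignored. The packaged rs2910164 fixture carries
the published per-study counts verbatim; their case total (4225) differs by
13 from the figure quoted in the source abstract (4238), a discrepancy the
source does not reconcile — we keep the counts, since every downstream number
is a function of them. G is the reference/major allele and C the variant
throughout.

## Hardy-Weinberg testing

Controls are tested with the plain Pearson chi-square on the three genotype
classes against expected counts Np², 2Npq, Nq² (q the control C-allele
frequency), 1 df, no Yates correction — the continuity-corrected variant
would not reproduce the published p = 0.019 for the one flagged study.
Monomorphic arms give chi2 = 0, p = 1 by construction. Studies violating HWE
at α = 0.05 are flagged but retained by default (matching how the motivating
analysis handled its one violating study); `exclude_hwe_violations` is a
sensitivity switch.

## Genetic models and per-study effects

The four contrasts partition or collapse the genotype classes: HET (GC vs
GG) and HOM (CC vs GG) drop the excluded class entirely; DOM (GC+CC vs GG)
and REC (CC vs GC+GG) preserve both arms. Per-study effects are odds ratios
with Woolf standard errors on the log scale. When a cell is zero, 0.5 is
added to all four cells (Haldane-Anscombe) and the estimate is flagged; the
fixture never needs this, but synthetic small studies do. A table with an
empty exposure column carries no information and raises instead of
estimating. CIs are 95% throughout, z = 1.959964.

## Pooling and heterogeneity

The default fixed-effects estimator is Mantel-Haenszel on the 2×2 tables
with the Robins-Breslow-Greenland variance — the estimator named by the
motivating analysis and the binary-data default of the major meta-analysis
packages. Inverse-variance fixed pooling is kept as a cross-check (the two
agree within 2% on every fixture stratum, a property the tests assert).
Cochran's Q and DerSimonian-Laird τ² are always computed from
inverse-variance weights regardless of which pooled estimator is reported;
I² = max(0, (Q − df)/Q)·100. Model selection follows the two-step
convention: random effects when the Q-test p ≤ 0.10, fixed otherwise;
single-study strata report the study's own OR/CI with heterogeneity marked
not applicable. The pooled effect is tested with a two-sided Z test.

## Multiplicity

The family is the four genetic-model association tests within one stratum
(m = 4). Both Holm step-down and plain Bonferroni are reported: the two
agree on the smallest p (where the published adjusted value 0.076 =
0.019 × 4 sits) but diverge on the second-smallest, and the source's
narrative — only the recessive model surviving the 0.1 threshold — matches
plain Bonferroni while citing the step-down method, so we surface both.
The published adjustment was evidently applied to p-values at 3-decimal
reporting precision (0.019 × 4 = 0.076 exactly, versus 0.0776 from full
precision); the acceptance script mirrors that convention when reproducing
the published value, while `holm_adjust` itself is precision-agnostic.

## Publication bias

Begg's test rank-correlates variance-standardised deviates
tᵢ = (yᵢ − ŷ)/√(vᵢ − v̂) with the variances vᵢ; Var(S) uses the
tie-adjusted Kendall formula and the p-value the continuity-corrected normal
approximation (z = (|S|−1)/√Var S), which is what reproduces the published
0.707 at k = 6, |S| = 3. Egger's test is OLS of the standard normal deviate
on precision with the intercept referred to t(k−2), the convention of the
standard meta-analysis software. Both report a non-computable result (p =
NaN) rather than an error below k = 3. Degenerate Egger fits with zero
residual variance treat the intercept as known exactly.

## Synthetic data generator

Controls are multinomial draws from HWE probabilities ((1−q)², 2q(1−q), q²)
at a configurable C-allele frequency, optionally distorted by an
inbreeding-style coefficient f (p² + fpq, 2pq(1−f), q² + fpq). Cases use the
standard retrospective-sampling construction: the control genotype
distribution tilted by per-genotype odds ratios (1, OR_het·e^ε, OR_hom·e^ε′)
and renormalised, with ε, ε′ ~ N(0, τ²) per study injecting between-study
heterogeneity on the log-OR scale. Default scenario: four studies sized like
the European subgroup of the fixture (88/155, 754/1243, 805/904, 1130/596
cases/controls), q = 0.27 (the European control allele frequency), a purely
recessive OR_hom = 1.3 (the effect size the motivating analysis detected),
τ = 0. Random streams derive from (seed, replicate, study_index) via
`SeedSequence` spawn keys, so adding studies or replicates never perturbs
earlier draws.

What the generator does *not* emulate: linkage disequilibrium, covariates,
population stratification, genotyping error, or selective publication.
Passing calibration tests therefore shows the estimators are correct under
clean multinomial sampling, not that real literatures are free of those
complications.

## Numerical and design choices

- The simulation harness runs the full pipeline per replicate and reports
  rejection rate, mean pooled log-OR bias and 95% CI coverage with
  Monte-Carlo standard errors. Calibration checks use 2000 replicates for
  the null type-I error and 1000 for effect recovery; the examples use 400
  as a quick illustration.
- τ² truncates at zero, so DL pooling coincides with IV fixed pooling
  whenever Q ≤ df (asserted as a property test).
- Reports round for display only (2 decimals for ORs, 3 for p-values);
  the JSON export carries full precision and is byte-deterministic for a
  given input and configuration.
- Out of scope by design: Peto pooling, Hartung-Knapp, meta-regression,
  leave-one-out/cumulative analysis, trim-and-fill, exact HWE tests, and the
  per-allele contrast — none appear in the motivating analysis.

## Known limitations

- The Begg and Z-test p-values rely on normal approximations; at very small
  k or sparse tables an exact or permutation approach would be preferable.
- The MH estimator's small-sample downward bias is visible (though well
  within Monte-Carlo error) in the recovery simulations.
- One published subgroup heterogeneity value (European heterozygote
  p_Q 0.263) reproduces at 0.268 — at the edge of display rounding; every
  other published cell agrees to the stated tolerances.
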