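# Methods

## The problem

Nuclear pleomorphism is the least reproducible of the three components of
the Nottingham (Modified Bloom–Richardson) grade for invasive breast
cancer: the conventional criteria ask the pathologist to judge nuclear size
and shape variability relative to normal epithelium, without a measurement.
`pleograde` implements a quantitative alternative built on two per-case
variables measured from calibrated images of the most pleomorphic tumor
areas:

* **LNS** (largest nuclear size) — the longest-axis diameter of the largest
  tumor nuclei, averaged over a few selected cells, in µm;
* **SNS** (smallest nuclear size) — the same for the smallest nuclei;
* **NSD** = LNS − SNS — intratumoral nuclear-size heterogeneity.

Cases are re-scored 1 (mild) / 2 (moderate) / 3 (marked) from LNS and NSD
using cut-offs anchored to the moderate-pleomorphism reference group, and
the modified scores are compared with the pathologists' original scores.

## Measurement model

A nucleus is its boundary polygon in pixel coordinates (origin top-left,
x rightward, y downward, pixel-center convention). Its diameter is the
*geometric diameter* of the polygon — the maximum pairwise distance between
boundary points — which matches the manual pole-to-pole ruler gesture and,
unlike a fitted-ellipse major axis, has an exact brute-force oracle: the
implementation prunes candidates with a convex hull but is tested to equal
the O(n²) all-pairs maximum bit for bit.

Label masks are converted to outlines by Moore-neighbor boundary tracing on
pixel centers. This is written in-house deliberately: contour extraction by
interpolated level sets places vertices half a pixel outside the pixel
centers and cuts corners, which breaks the pixel-center diameter
convention; ordered pixel-center traces keep a filled w×h rectangle's
diameter at exactly √((w−1)² + (h−1)²).

Per case, nuclei flagged `incomplete_membrane`, `multinucleated` or
`crushed_or_obscured` are excluded; the remaining diameters are calibrated
(µm = px × µm/px) and reduced to LNS/SNS as the means of the `k_extreme`
largest/smallest diameters. Defaults:

* `k_extreme = 3` (range 1–10): a handful of extreme pleomorphic cells per
  case is what a reader measures in practice; averaging several stabilizes
  the extremes against a single outlier.
* calibration `6.5 µm/px`: the constant the grading thresholds were
  developed with. It is physically surprising for a 400× field — it may
  encode a scale-bar convention of the original software rather than a true
  pixel pitch — so it is a free parameter everywhere; all downstream
  statistics scale linearly with it, and the agreement statistics are
  invariant to it once cut-offs are derived on the same scale.
* diameters from all of a case's images are pooled before top-k selection,
  since the extreme nuclei of a tumor need not sit in one field.

With a single admissible nucleus LNS = SNS and NSD = 0; a case with no
admissible nuclei is an error, not a silent omission.

## Cut-offs and the modified score

For each variable v ∈ {LNS, NSD}, the training cohort's grade-2 cases give
a reference mean m and sample SD s (n−1 denominator), and the cut-offs are

    lower = m − c·s,   upper = m + c·s,   c = sd_multiplier (default 1).

Scores: 1 if v < lower, 2 if lower ≤ v ≤ upper, 3 if v > upper. The middle
interval is closed on both ends so boundary values deterministically score
2. The ±1 SD default is the minimal reading of "cut-offs based on the
standard deviation of the grade-2 group"; the multiplier is a config knob
because the exact constant used originally is not recoverable.

The LNS and NSD scores are combined into the modified nuclear grade by one
of three rules (the original combination rule is likewise not
recoverable, so all three are implemented and selectable):

* `rounded_mean_up` (default): arithmetic mean, .5 ties toward the higher
  grade — clinically conservative;
* `max`: worst of the two;
* `lns_priority`: the LNS-based score decides (NSD ignored on conflict).

Cut-offs are derived once in phase 1, serialized with their provenance
(reference mean/SD, multiplier, n, cohort hash), and applied frozen in
phase 2; the validation code path contains no statistic of the validation
set's reference group.

## Agreement statistics

For a 3×3 cross-tabulation of modified (rows) vs original (columns) scores
with cell proportions p_ij, row margins p_i·, column margins p·j:

    po = Σ p_ii,   pe = Σ p_i· p·i,   κ = (po − pe) / (1 − pe).

The significance test uses the large-sample variance of κ under H₀: κ = 0,

    se₀² = [pe + pe² − Σ_i p_i· p·i (p_i· + p·i)] / [n (1 − pe)²],

with z = κ/se₀ and a two-sided normal p. Linear and quadratic weighted κ
are available (Fleiss–Cohen–Everitt H₀ variance, which reduces to the
formula above for identity weights) but unweighted κ is the default and the
reported statistic. Interpretation uses the Landis–Koch bands, with
κ ≥ 0.6 additionally labelled good reliability; the band name is always
printed next to the numeric value.

Pair analysis partitions the n cases into concordant (|Δgrade| = 0),
adjacent discordant (|Δ| = 1) and critical discordant (|Δ| = 2); critical
discordances (a mild case re-scored marked, or vice versa) are the
clinically alarming kind and are counted separately.

Fisher's exact test is generalized to r×c tables: p is the total
multivariate-hypergeometric probability, over all tables with the observed
margins, of tables no more probable than the observed one (ties accepted
within relative 1e-12). Enumeration is exact with a 10⁷-table budget —
every in-scope table is tiny — with a seeded permutation Monte-Carlo
fallback that reports its binomial standard error. Empty rows/columns are
dropped first; they carry probability 1.

## ANOVA and normality

One-way fixed-effects ANOVA is implemented in two algebraically identical
forms: from raw groups, and from (n, mean, SD) summaries via
SSB = Σ nᵢ(meanᵢ − grand mean)², SSW = Σ (nᵢ−1)sdᵢ². The summary form lets
published group tables be re-analysed without raw data; the two routes are
tested to agree to 1e-9 relative. Post hoc comparisons are two-sided
t-tests on the pooled within-group mean square with Bonferroni
multiplication by k(k−1)/2, clipped to 1.

Shapiro–Wilk is delegated to scipy (3 ≤ n ≤ 5000). The Lilliefors-corrected
KS test computes D against the normal with sample-estimated mean and SD and
obtains p by seeded Monte-Carlo under the composite null
(default 10⁴ replicates) rather than lookup tables, so it is reproducible
and well-defined at any n ≥ 4.

One published inconsistency is handled explicitly: a 120-case, 3-group
one-way ANOVA has within-group df 117, while the source tables print
"(2,119)"; the reconstructed F (≈11.10) matches the printed 11.101 only
under df 117, so the printed df is treated as a typo and 117 is reported.

## Synthetic data

`generate_cohort` draws per-case (SNS, LNS) from a grade-conditional
bivariate normal, rejection-resampled until 0 < SNS < LNS (bounded by
`max_resamples`); NSD is the identity LNS − SNS, never sampled
independently, so the NSD group structure emerges rather than being
imposed. The phase-1 defaults are the development cohort's printed
summaries with the 13/80/27 (≈1:6:2) grade mix, with three reconstruction
choices:

* **Correlation.** The published marginal SD triples (SNS, LNS, NSD)
  determine the within-grade SNS–LNS correlation through
  Var(NSD) = Var(LNS) + Var(SNS) − 2ρσσ: ρ ≈ 0.612 (grade 1) and 0.598
  (grade 2). The defaults use these implied values so all three marginal
  SDs are matched simultaneously; grade 3 assumes ρ = 0.605, the midpoint.
  `GradeDistribution` exposes ρ as a free parameter (generic default 0.4).
* **Grade-3 LNS SD** is not published; it is solved from the grade-3 NSD SD
  at the assumed correlation (≈101.7 µm).
* **Grade-1 LNS mean.** The published grade-wise LNS means are internally
  inconsistent: their size-weighted mean misses the published overall LNS
  mean (337.56 vs 340.49 µm) and the grade-1 value contradicts the NSD
  identity (247.37 − 180.21 = 67.16, not the published grade-1 NSD mean
  94.16). Substituting 274.37 µm — a plausible digit transposition —
  reconciles both anchors exactly, so the generator uses it; with the
  printed value the generator could not reproduce the published grade-1 NSD
  mean at all.

`generate_field` renders non-overlapping elliptical nuclei into a 16-bit
label mask, with outlines sampled at ≥64 boundary vertices (enough that the
polygon diameter is within 0.5 px of the analytic 2a) and ground-truth
diameters 2·a·calibration. Overlap is rejected at paint time (any collision
raises), and random placement uses a conservative bounding-circle test with
a 2 px guard band. The fields emulate geometry only — no H&E color,
texture, chromatin, staining variation, or segmentation error — so passing
end-to-end tests demonstrates the correctness of the measurement and
statistics machinery on known geometry, not robustness to real
histology-image artifacts.

## Numerical and design choices

* Determinism: every stochastic component (cohorts, fields, Monte-Carlo
  p-values) takes an explicit integer seed; fixed seed ⇒ bit-identical
  output, and reports are byte-identical apart from their timestamp.
* Diameter exactness: the hull-pruned diameter uses the same floating-point
  expression as the all-pairs reference, so equality is exact, not
  approximate.
* Degenerate inputs fail loudly: zero reference variance, sd_multiplier 0
  (lower = upper), constant samples to normality tests, pe = 1 in kappa,
  and exhausted rejection-sampling budgets all raise typed errors that the
  CLI maps to exit codes (2 input, 3 degenerate statistics).
* Problem sizes: simulated studies run at the study's own cohort sizes
  (120 training / 53 validation); property tests that need tighter sampling
  error use 10× cohorts (1200 cases), where grade-wise means are required
  to land within 3 standard errors of their generating values.

## Limitations

* The synthetic generator reproduces first and second moments per grade,
  not the shape of real nuclear-size distributions (truncation, skew,
  measurement error of a human reader).
* The cut-off multiplier and score-combination rule are declared
  assumptions; regraded distribution counts therefore need not match any
  particular published split, and agreement statistics on synthetic
  validation cohorts fluctuate substantially at n = 53.
* Segmentation of real H&E images is out of scope: the package consumes
  outlines or label masks produced elsewhere.
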