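# Methods

## Data model

A study table holds one row per published study: arm sizes, risk-allele
relative frequencies per arm, optional genotype count triples (EE, EK,
KK), optional trio counts with transmitted/untransmitted risk alleles,
and optional covariates (mean BMI, age, % male per arm). Designs are
`population` (case-control), `family` (trios only) or `both`. Validation
enforces non-negative counts, frequencies in [0, 1], genotype triples
that sum to the arm size and imply the reported frequency to within
0.005, and trio counts for family designs. The packaged fixture
transcribes the 48-study KCNJ11 E23K / T2D table verbatim, including two
control frequencies (0.61) that are suspected transcription errors in
the source and one nominal "minor" allele frequency above 0.5; they are
retained deliberately so the fixture is the printed record, not a
cleaned version of it.

## Effect sizes

The allele-contrast 2×2 table is reconstructed from reported
frequencies: the risk-allele count per arm is the nearest integer
(half-away-from-zero) of `2·N·f`, with the complementary cell absorbing
the remainder so each arm contributes exactly `2N` alleles. Alleles are
treated as independent observations (the standard allele-contrast
convention; no within-individual correlation adjustment). Genotype
models take their cells directly from the genotype triples. The log odds
ratio uses the Woolf variance `Σ 1/cell`. A Haldane–Anscombe 0.5 is
added to all four cells only when at least one cell is zero — never
otherwise; no fixture study triggers it after reconstruction, so
results there are insensitive to the choice. The Hardy–Weinberg test is
the 1-df chi-square against expected counts at the sample allele
frequency (not the exact test: reproducible, and adequate at the sample
sizes involved); a monomorphic arm is defined to fit trivially
(chi2 = 0, p = 1).

## Pooling and heterogeneity

Fixed-effect and DerSimonian–Laird estimators are closed-form as given
in the README. τ² is truncated at zero; no iterative (REML /
Paule–Mandel) refinement is offered — the package is deliberately
deterministic and closed-form throughout. Confidence intervals use the
normal 0.975 quantile 1.959964 (not 2). With a single study the DL path
degrades to fixed with a warning. Subgroup analysis pools each level by
DL and tests between-stratum heterogeneity with
`Q_b = Σ_g W_g (θ̂_g − θ̄)²`, `W_g = se_g⁻²` (the mixed-effects
convention: random effects within strata, fixed between). Leave-one-out
re-pools the k possible (k−1)-subsets in input order.

Stratum membership is an explicit user mapping, not an automatic
grouping: the fixture's "Chinese"-labeled row is excluded from the
ethnic strata by default — reproducing the published stratum of 14 East
Asian studies — and restored by `map_ethnicity={"Chinese": "East Asian"}`.
The published sample-size strata (22 large / 26 small over 48 rows)
cannot be reconstructed from the printed per-study case counts: applying
the stated rule (≥ 1000 cases) to the fixture yields 19 large
case-control studies, and the package reports what the arithmetic gives.

## Family-based studies and cross-design combination

TDT effects are `ln(T/U)` with variance `1/T + 1/U`; a zero count adds
0.5 to both. The two published family studies print trio totals but not
T/U counts, so the fixture carries `n_trios` only and TDT operations are
exercised on synthetic trios; the published pooled TDT OR (0.87) is a
non-reproducible reference, not a test target. The combined analysis is
two-stage: DL within each design, inverse-variance across the two
design-level estimates, with a 1-df Q testing cross-design consistency.
(Entering TDT estimates as ordinary rows of one DL pool is a defensible
alternative; the two-stage form was chosen because it separates the
stratification-robust family evidence and makes the consistency test
explicit.)

## Meta-regression and small-study bias

Meta-regression is weighted least squares of `y` on an intercept plus
moderators, with residual τ² from the method of moments on fixed-effect
weighted residuals — `τ² = max(0, (Q_E − (k−p)) / tr(P))` with
`P = W − WX(X'WX)⁻¹X'W` — applied once, after which coefficients, normal
z-tests and the final fit use weights `1/(v_i + τ²)`. With an
intercept-only design this reproduces the DL pool exactly (tested to
1e-10). Categorical moderators are dummy-coded against the first level
in input order; rows with missing moderators are dropped and counted.
The proportion of heterogeneity explained is
`max(0, 1 − τ²_resid/τ²_null)`, clipped to [0, 1].

Egger's test is the classical unweighted OLS of the standardized effect
on precision with a t-test on the intercept (k−2 df). When all
precisions are equal the intercept and slope are not separable; the test
warns and returns the mean standardized effect as the intercept with
zero slope. Funnel output is coordinates only (points plus the pseudo-95%
boundary around the fixed-effect pool); plotting is left to the caller.

## Translation

PAR is `(OR−1)/OR × f` — the published PAR percentages are not
recoverable from any printed (OR, frequency) pair via that formula, so
the report computes PAR from the package's own pooled ORs and weighted
control frequencies rather than asserting the printed values. The power
calculation is the two-sided two-proportion normal approximation on
allele counts: `p1 = p0·OR/(1−p0+p0·OR)`,
`m = (z_{1−α/2}+z_{1−β})²(p1q1 + p0q0/r)/(p1−p0)²` alleles per case
group, `⌈m/2⌉` individuals, with a nearest-hundred presentation value
(α = 0.05, power 0.80, allocation r = 1 by default). Frequency summaries
weight by control arm size; their CI is descriptive (weighted
between-study SD / √k with a normal quantile), since the original CI
construction is unstated.

## Synthetic data

The generator states one world and keeps it: per study a true effect
`θ_i ~ Normal(μ, τ²)` with defaults μ = log 1.12 and τ² = 0.02, a
control risk-allele frequency `p0 ~ Beta(15, 25)` (mean 0.375, matching
the observed spread of control frequencies), per-arm sizes log-uniform
on [100, 5000] (the fixture's central range, trimmed of its two extreme
arms), and k = 48 studies. Observed frequencies come from binomial
allele sampling, or — in genotype mode — from multinomial genotype
sampling: controls at Hardy–Weinberg proportions, cases with genotype
risks 1 : OR : OR² renormalized against the control proportions
(computed exactly, no rejection sampling). Family studies draw
heterozygous-parent transmissions `H ~ Binomial(2·n_trios, 2p(1−p))`
and `T ~ Binomial(H, OR/(1+OR))` — a simplification that ignores
parental genotype correlation within trios. Optional publication
selection suppresses, with a configurable probability, studies that are
both small (total below twice the geometric mid-size) and
non-significant, redrawing until a study survives. One seed drives
everything through counter-indexed substreams, so tables are
byte-reproducible and study *i* keeps its draws when k changes.

What the generator does **not** emulate: linkage disequilibrium,
covariate-dependent allele frequencies, genotyping error, HWE violations
in controls, or shared controls between studies. A green simulation test
therefore establishes correctness of the estimators under the stated
sampling model, not robustness to those real-data features.

Calibration checks run at parameters fixed in advance: Egger's type-I
error is checked on homogeneous (τ² = 0) unbiased collections, because
the classical Egger test is only calibrated under the homogeneous null
and is known to be anticonservative under heterogeneity — a limitation,
not a defect of the implementation.

## Numerical and reporting choices

Presentation rounding (2 dp for ORs and frequencies, nearest hundred for
sample sizes) lives only in the report writers; computation paths carry
full precision. No multiple-testing adjustment is applied across
subgroups (none was applied in the source analysis). JSON reports are
schema-versioned and byte-deterministic for identical inputs; NaN (e.g.
an undefined cross-design Q) serializes as null.

## Known limitations

Reconstructing allele counts from two-decimal frequencies loses up to
half a count per arm, so fixture results track but do not exactly equal
an analysis of the original genotype counts (overall allele OR 1.10 here
vs 1.12 published, inside the bracket [1.06, 1.16] the reconstruction
supports). Genotype-model and BMI-stratified analyses of the real 48
studies are impossible from the printed record and are demonstrated on
synthetic data only. No Mantel–Haenszel pooling, Hartung–Knapp
adjustment, Begg rank test, or trim-and-fill.
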