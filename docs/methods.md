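# Methods

## The phasetype coding

For two biallelic loci with alleles {A, a} and {B, b} (capital =
alternative allele), each individual carries an unordered pair of
two-locus haplotypes — a diplotype, with ten distinct states. Phase
relations are coded additively: for each allele pair (i, j),

* `Cis_ij`  = number of the individual's haplotypes carrying i and j
  together (0, 1 or 2);
* `Trans_ij` = number of cross-homologue pairings with i on one
  chromosome and j on the other.

Together with the additive genotypes `G_A`, `G_B` and the dominance
(heterozygosity) indicators `D_A`, `D_B`, the coding satisfies exact
integer identities:

    Cis_AB + Cis_Ab = Trans_AB + Trans_Ab = G_A
    Cis_AB + Cis_aB = Trans_AB + Trans_aB = G_B
    Σ cis = Σ trans = 2
    Cis_ab = 2 − G_A − G_B + Cis_AB

`verify_identities` checks all of these on any coding, and the test
suite reproduces the complete 10 × 12 table cell-for-cell.

## The RoP model and tests

The model is a GLM (identity/Gaussian or logit/binomial link)

    g(E(Y)) = β₀ + β_GA G_A + β_DA D_A + β_GB G_B + β_DB D_B
                 + β_Pcis P_cis + β_Ptrans P_trans + covariates,

with `P_cis = Cis_AB` and `P_trans = Trans_AB` by default. Cis and trans
effects are tested separately, 1 df each. Because every alternative
phasetype coding is an invertible linear function of `(1, G_A, G_B,
P_cis, P_trans)`, the score, Wald and likelihood-ratio statistics are
identical under any reference-allele choice; the fitted values are also
invariant. Only the *sign* of the phase coefficient depends on the
coding: a true `Cis_AB` effect reappears with the same sign under
`Cis_ab` and with opposite sign under `Cis_aB`/`Cis_Ab`. The tests are
therefore tests of the *presence* of a phase effect, not of its
direction.

Choices made where the design was open:

* **Default test: LRT.** The three tests are equivalent under the null
  by the invariance theorem, and the LRT behaves best near boundary
  aliasing; Wald and score are exposed (`test_type=`). Which of the
  three generated the published comparisons is not stated; finite-sample
  power differences are negligible at the simulated sizes.
* **Gaussian inference uses the χ² reference** to match the GLM framing;
  an exact F option (`inference="f"`) is provided for small samples.
* **Fitting** is iteratively reweighted least squares with a 1e-8
  relative deviance tolerance, 100-iteration cap and step-halving.
  Rank deficiency is detected with a pivoted QR; aliased columns are
  excluded and *reported by name*. An aliased phase term makes the
  corresponding test `inestimable` rather than silently dropping it,
  because a dropped phase column changes the hypothesis (this situation
  arises in practice, e.g. when one haplotype class is absent, and
  under strong LD between a rare and a common variant, where the cis
  term collapses onto the rare variant's genotype — `estimability_report`
  diagnoses both).
* **Perfect separation** (binomial) is flagged when fitted logits reach
  the clip boundary while the deviance vanishes.
* **Covariates** enter additively; stratified analyses (e.g. by sex, as
  appropriate on the X chromosome) are performed by subsetting.
* **Degenerate cohorts** with fewer than three distinct diplotypes are
  rejected: the phase columns cannot be separated from genotypes.

### Recessive phase effects

Additive phasetypes are weak against recessive cis mechanisms, mirroring
the single-locus situation. Two joint 2-df strategies test
H₀: β_Pcis = β_Dcis = 0 with `Dcis = 1[P_cis = 1]`: variant 1 keeps the
trans phase terms, variant 2 omits them (more power, but type-I-error
risk if the truth is in trans). The four phase terms obey the exact
identity `P_cis − Dcis = P_trans − Dtrans` (both equal twice the AB/AB
indicator), so variant 1's written design is never full rank; the model
is identified by excluding the redundant `Dtrans` column — precisely
what a sequential fitter (e.g. R's `glm`) does by aliasing the last
collinear column — leaving the same column space and a well-defined 2-df
test. A strict full-vs-reduced comparison of the unidentified design
would instead collapse to 1 df, with the recessive-cis direction inside
the null span. The 4-df genotype interaction test remains the most
powerful option for recessive cis effects: the recessive cis mean vector
lies exactly in the span of the additive×dominance interaction design
(an exact linear-algebra fact on the ten diplotypes, checked in the
tests).

### Multi-allelic markers and LD blocks

With m and n alleles per marker, non-reference additive/dominance
genotype terms and cis/trans phasetypes enter per allele (pair), and the
joint cis and trans tests take (m−1)(n−1) df each, minus any aliased
terms (counted and reported). `block_to_marker` converts a phased
variant window into one multi-allelic marker by treating each distinct
haplotype string as an allele; the most frequent haplotype is the
reference (ties broken lexicographically, so labelling is
deterministic). Samples with any unphased heterozygote in the window are
excluded with a logged count. Merging similar haplotypes within a block
to reduce df is out of scope.

## Benchmarks

* **1-df genotype interaction**: H₀: β_GAGB = 0 over additive main
  effects. Inflates under LD with dominant/recessive marginal effects.
* **4-df interaction**: joint null on GA·GB, GA·DB, DA·GB, DA·DB over
  the full main-effects model; calibrated in all marginal-effect
  scenarios.
* **Saturated 5-df test**: the four interactions plus V, where V = 1 iff
  both loci are heterozygous with the alternative alleles in cis. On the
  ten diplotypes this design spans any phase-effect mean structure
  (verified exactly), but the extra df cost power, and the sign of β_V
  confounds reference choice with mechanism, so cis and trans cannot be
  distinguished.
* **Haplotype odds-ratio test**: χ² = log(ÔR)² / (v̂₁ + v̂₀), 1 df, with
  log(ÔR) the difference of case and control log cross-ratios of the
  four haplotype frequencies and v̂ᵢ = (1/2nᵢ) Σ 1/f̂ per group. The
  variance sums the reciprocals of *all four* haplotype frequencies (the
  standard log-OR variance); frequencies come from observed phased
  counts, not EM reconstruction. Zero frequencies are a hard error by
  default — silent corrections change the statistic — with an optional
  0.5 pseudo-count continuity correction. Under a rare outcome the
  log-OR approximates the additive cis effect (hence OR-test power
  matches the RoP cis test there) and vanishes under pure trans effects.
* **3-df haplotype regression**: joint test of Cis_AB, Cis_Ab, Cis_aB
  with Cis_ab as reference and no marginal-effect adjustment; sensitive
  to main effects, so a significant result does not demonstrate phase.

## Simulation framework

Haplotypes are drawn under Hardy–Weinberg equilibrium from the four
frequencies implied by (p_A, p_B, D′): f_AB = p_A p_B + D′·D_max, with
D_max = min(p_A(1−p_B), (1−p_A)p_B) for D′ ≥ 0 and
min(p_A p_B, (1−p_A)(1−p_B)) for D′ < 0.

Phenotype generators (the study conditions; intercept −2 throughout,
which for logistic models is a baseline prevalence of 0.12):

| group | models | defaults |
|---|---|---|
| continuous | allelic heterogeneity; additive cis; additive trans | β = 0.5 per-locus / 1.5 phase; σ = 1 |
| logistic, type-I error | additive / dominant / recessive marginal effects at one or both loci | β = 1 |
| logistic, power | additive / dominant cis and trans; recessive cis | β = 0.5 (additive/dominant), 1.5 (recessive) |

Binary outcomes are produced by rejection sampling of fresh individuals
until exactly n_cases and n_controls (1000 each by default) are
collected, with a 10⁷-draw cap guarding impossible configurations.
Rates are computed over n_iter iterations (1000 by default) at α = 0.05,
with Monte-Carlo SE √(r(1−r)/n_iter); tests returning a non-ok status
are excluded from the denominator and counted. Per-iteration generators
derive from the master seed and the iteration index through
`SeedSequence` spawn keys, so runs are reproducible and parallelisable.

**Switch errors** model phasing mistakes: with probability equal to the
error rate, a double heterozygote's haplotype assignment is swapped at
one locus (AB/ab ↔ Ab/aB) — the only diplotypes in which a switch is
observable. Corruption happens after phenotype generation, emulating
mis-phased observed data, and never alters genotypes. The switch-error
experiment calibrates the cis effect to a target heritability
h² = β²·Var(P_cis)/(β²·Var(P_cis) + σ²) with Var(P_cis) computed exactly
from the population diplotype distribution and σ fixed at 1 (only the
ratio matters for power), then estimates cis power and trans type-I
error at each error rate. All rates share each iteration's cohort and
phenotype (a paired, common-random-numbers design chosen to stabilise
the retention ratios at no extra cost).

An exact asymptotic companion to the simulations: for Gaussian outcomes
the 1-df noncentrality is n β² s²/σ², with s² the population residual
variance of the tested phase term after projection on the adjustment
columns (computed from exact diplotype moments). This analytic route
(`analytic_power`, and `power_ratio_surface(method="analytic")`) is the
default for mapping LD power ratios over allele-frequency grids, with
simulation available for finite-sample checks. It reproduces the
characteristic geometry: LD helps cis detection when both variants are
rare, erases it when a rare variant pairs with a common one in complete
LD (the cis term degenerates into the rare genotype), and hurts trans
detection most when allele frequencies are similar.

### What the generator does and does not emulate

The synthetic cohorts are unrelated individuals at exactly two loci in
HWE with perfectly observed (or deliberately corrupted) phase. Real data
add relatedness and population structure, genotyping/calling error,
missingness, multi-locus LD beyond the pair, and phase sets of finite
length; none of these are modelled. Passing the suite therefore
demonstrates the statistical properties of the tests under the stated
sampling models, not robustness to cohort artefacts — covariate
adjustment and the complete-case phase-set handling in the VCF reader
are the only concessions to real-data structure.

### Observed behaviour worth recording

Two quantitative facts established with exact population computations
(and visible in the simulation suite):

* Under the both-loci *additive* logistic marginal-effect model at
  realistic frequencies, the population haplotype log cross-ratio is
  numerically negligible (|log OR| ≤ 0.025 over p_A, p_B ∈ [0.05, 0.95]
  at β = 1), so the haplotype OR test barely inflates at n = 1000+1000.
  Its characteristic inflation under dual marginal effects appears
  clearly under *dominant* effects at both loci (asymptotic rejection up
  to ~0.08 at these sizes), which is the configuration the suite uses to
  demonstrate it.
* The trans LRT is mildly anti-conservative in finite samples under
  strong LD with equal allele frequencies: at 2000 subjects, D′ = 0.8
  and p_A = p_B = 0.2 its true level is ≈ 0.06, returning to 0.05 by
  ~8000 subjects (the Wald test is conservative, ≈ 0.034, in the same
  cells). The cause is the rarity of the three trans-informative
  diplotypes there, which leaves little effective information in the
  trans direction; the same geometry that reduces trans *power* under
  LD also degrades the χ² approximation slightly.
* At a 10% switch-error rate the 1-df cis noncentrality is attenuated by
  ≈ (1−r)² regardless of allele frequencies; how much *power* survives
  depends on where the zero-error power sits on the curve. With
  h² = 0.003 and n = 5000, retention is ≈ 95% when both variants are
  rare and ≈ 92% when both are common, and the trans test's level drifts
  to ≈ 0.06 (with clear inflation, ≈ 0.10, at a 20% rate). Moderate
  phasing error therefore costs little power but is not entirely free.

## Interfaces

`RoPModel(...).fit()` returns a results object with coefficient
estimates, the two 1-df phase tests, `summary()` and a tidy
`to_frame()`. The `rop` command line exposes `encode` (VCF pair →
phasetype TSV, columns in the canonical table order), `test` (adds a
phenotype table; RoP by default, benchmarks by name; `--stratify-by`
equals independent subset runs) and `simulate` (YAML/JSON scenario file
→ tidy rates TSV). VCF input is 1-based, as read; multi-allelic records
are rejected on the biallelic path with a pointer to the multi-allelic
coding; haploid genotypes (e.g. male X) are outside the diploid VCF path
— a minimal haploid cis coding (`haploid_cis_code`, single haplotype,
trans undefined) is provided as a documented extension.

## Known limitations

* Phasing itself, imputation, mixed models/relatedness, X-inactivation
  modelling and genome-wide scanning strategies (windowing, multiple
  testing) are out of scope.
* The recessive-cis strategies inherit the identifiability ceiling
  described above; genuinely recessive cis mechanisms are best screened
  with the 4-df interaction test.
* The haploid coding is an extension, not an established convention;
  trans effects are undefined with a single homologue.
* Score and Wald tests can disagree with the LRT in tiny samples; the
  F option is preferable for Gaussian n below a few dozen.
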