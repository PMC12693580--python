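# Methods

## Model

We consider an admixed cohort of *n* diploid individuals genotyped at *p*
biallelic variants, each haplotype carrying a binary local-ancestry call
(1 = African, 0 = European). Global ancestry ā<sub>i</sub> is the
genome-wide mean of an individual's 2*p* calls.

Ancestry-specific causal effects per variant are drawn i.i.d. from a
mean-zero bivariate normal,

    (β'_Eur,j, β'_Afr,j) ~ N(0, [[σ'²_Eur, τ'], [τ', σ'²_Afr]]),

with σ'²_Eur = r² / (2 Σ_j f'_Eur,j(1−f'_Eur,j)), the African variance
analogous, and τ' = r²ρ / (2 √(S_Eur S_Afr)) where S is the per-ancestry
heterozygosity sum. This normalisation makes the genetic variance of a
homogeneous cohort approximately r²; ρ is the cross-ancestry effect
correlation. At |ρ| = 1 draws are exactly proportional (the sampler uses
the direct construction β_Afr = σ_Afr(ρz₁ + √(1−ρ²)z₂), which remains
valid where the covariance matrix is singular).

Individual-level effects expand the ancestral pair under the **local**
model (haplotype effect = ancestral effect of the haplotype's call) or the
**global** model (convex combination weighted by ā<sub>i</sub>, identical
on both haplotypes). Phenotypes are y = Σ_j Σ_h β·x̂ + ε with demeaned
dosages x̂ = x − f(local ancestry) and ε normal with variance
max(0, 1 − Var̂(genetic value)), calibrated per draw so the sample
phenotypic variance is ≈ 1. Per-draw calibration (rather than a
per-parameter-set constant) keeps every simulated trait on the same scale;
the difference is O(1/√n) and immaterial for all reported quantities.

Tagging effects are the deterministic rescaling β = β'·θ with
θ = λ √(f'(1−f') / f(1−f)) per ancestry, where λ is the haplotypic
correlation between the causal and tagging alleles within an ancestry
background, estimated as λ̂ = [P̂(1,1) − f̂f̂′]/√(f̂(1−f̂)f̂′(1−f̂′)) on
haplotypes sharing the requested ancestry at both loci. No GWAS estimation
noise is added (an unbiased-estimation idealisation); a noise hook can be
layered on top by perturbing the tagging effect vectors before scoring.

## Conditional average effects and LAACor

The average effect conditioned on a local ancestry at variant *j* is the
carrier-haplotype mean of the individual effect (a diploid double-carrier
contributes twice). Under the local model these averages are exactly
(β'_Afr, β'_Eur), so their across-variant correlation equals ρ. Under the
global model the averages obey the carrier-weight identity
avg_Afr = ω₁β'_Eur + ω₂β'_Afr and avg_Eur = ω₃β'_Eur + ω₄β'_Afr, where
(ω₁, ω₂) are the carrier means of (1−ā, ā) over African-call haplotypes
and (ω₃, ω₄) the European-call analogues (ω₁+ω₂ = ω₃+ω₄ = 1). The implied
covariance terms are

    u = σ'²_Eur ω₁² + 2τ'ω₁ω₂ + σ'²_Afr ω₂²
    v = σ'²_Eur ω₃² + 2τ'ω₃ω₄ + σ'²_Afr ω₄²
    w = σ'²_Eur ω₁ω₃ + τ'(ω₂ω₃ + ω₁ω₄) + σ'²_Afr ω₂ω₄

and the per-variant LAACor is w/√(uv). The genome-wide parameter is pooled
as Σ_j w_j / √(Σ_j u_j · Σ_j v_j): this is the natural population value of
the across-variant sample correlation for mean-zero effects, and the test
suite verifies it against the empirical correlation over effect redraws
(variants lacking carriers of an ancestry are excluded, not imputed).
Because a single locus's local ancestry is a weak predictor of global
ancestry, ω₂ ≈ ω₄ on realistic cohorts and the global-model LAACor sits
near 1 even when ρ is small — the package's central quantitative point.
Tagging-scope LAACor reuses the same machinery on the θ-scaled effects;
ancestry-discordant LD (λ_Afr ≠ λ_Eur) depresses the local-model value
below ρ while the global-model value stays high.

## Synthetic cohorts

The generator emulates a two-way African/European admixed biobank cohort:

- **Global ancestry**: Beta(7.4812, 1.9424), calibrated (least squares on
  the analytic quartile means) so that quartile-subgroup means approximate
  (0.61, 0.79, 0.85, 0.92); mean ≈ 0.79, sd ≈ 0.125. Only the four
  subgroup means of the emulated cohort are published, so the full shape
  is a package choice; LAACor magnitudes depend mildly on the resulting
  ancestry spread.
- **Local ancestry**: `independent` mode draws each call i.i.d.
  Bernoulli(ā_i) — the clean analogue of a panel of approximately
  independent markers; `tract` mode runs a two-state Markov chain along a
  uniform genetic map with breakpoint rate = generations/Morgan (default
  15, the usual single-pulse approximation for African-American
  admixture) and stationary probability ā_i.
- **Allele frequencies**: Balding–Nichols around an ancestral frequency
  q ~ U(0.05, 0.95) with default F_ST = 0.15 (typical African–European
  differentiation), clipped to [0.01, 0.99] to protect the 1/√(f(1−f))
  effect scalings.
- **Haplotypes**: alleles Bernoulli(f of the call's ancestry),
  independent across haplotypes — the two haplotypes of an individual are
  simulated independently.
- **Causal–tagging pairs**: per haplotype the pair of alleles is drawn
  from the bivariate Bernoulli implied by the ancestry's (f', f, λ);
  targets violating the Fréchet bounds are rejected (or, in the study-2
  generator, clipped to the feasible range). Default study-2 profile:
  λ_Eur ~ U(0.9, 0.995) (λ² ≥ 0.8), λ_Afr = λ_Eur scaled down by a
  U(0, 0.5) discordance factor, and tagging frequencies jittered around
  causal frequencies (sd 0.02).

What the generator does **not** emulate: realistic LD beyond the single
causal–tagging pair, linked ancestry tracts in `independent` mode,
assortative mating or ancestry-correlated environment, genotyping or
phasing error, and local-ancestry inference error (calls are generated,
never inferred). Passing tests therefore validate the statistical
machinery and the models' internal predictions, not robustness of the
conclusions to real-data artifacts.

## Simulation studies

Study 1 (causal variants known) scores the cohort with the European causal
effects; study 2 (tagging) scores tagging variants with plug-in European
tagging effects derived from allele frequencies and LD estimated on a
separate simulated homogeneous European panel (default n = 5000),
mirroring the practice of taking weights from an external European
reference. Demeaning uses sample ancestry-conditioned frequencies by
default (generating-truth mode exists for oracle tests). Default
scaled-down sizes are n = 2000, p = 1000, 5 cohort replicates, 100
effect/phenotype redraws per configuration; all sizes are configurable.
Mean squared score–phenotype correlations are reported with Monte-Carlo
standard errors and normal 95% CIs, overall and per global-ancestry
quartile.

The distinguishability grid applies a two-sided Wilcoxon rank-sum test
(normal approximation) to the per-draw squared correlations of the two
models within each (ρ, r²) bin at α = 0.01, one test per score type and
cohort replicate, reporting the proportion significant. No
multiple-testing correction is applied (raw proportions are the quantity
of interest). All-tied comparisons are skipped and counted. A null
calibration routine draws both arms under the identical model and checks
the empirical rejection rate against the nominal level.

## Closed forms and their scope

The expected squared correlations (README) assume idealised conditions:
identical allele frequencies across markers, a shared ancestry
distribution across individuals, concordant ancestry between an
individual's haplotypes, small between-ancestry frequency gaps, and
approximately independent haplotypes. These are deliberately **not**
enforced; `theory.conditions_diagnostic` reports how far a cohort sits
from each. On the default calibrated cohort the approximations hold to
within ~1% absolute in r² terms; the residual model gap in E[Cor²(TotPGS,
y)] is of order 10⁻³ and is covered by the Monte-Carlo error of the
prescribed draw counts. The advantage threshold is returned as the exact
boundary solution ρ* = √(1−ā)/(1+√(1−ā)) (≈ 0.31 at ā = 0.8, → 0.5 as
ā → 0). Tagging-variant score behaviour has no closed form here and is
assessed purely by simulation.

## Numerical choices and edge cases

- All randomness flows from one master seed through `numpy`
  `SeedSequence` spawning; identical seeds give bit-identical outputs.
- Zero-variance score or phenotype vectors raise rather than returning a
  silent 0 correlation; monomorphic strata make LD estimation raise;
  variants with single-ancestry carriers propagate NaN and are excluded
  from pooled quantities.
- Genetic variance exceeding 1 floors the noise variance at 0 with a
  warning.
- Effects batches use a Cholesky-free bivariate construction so ρ = ±1 is
  exact; ρ within 10⁻⁹ of ±1 is snapped to keep proportionality exact.
- Subgroup splitting ranks by global ancestry with a stable sort and cuts
  into equal sizes (±1); ties keep input order.
- Real local-ancestry input is binarised by argmax upstream of this
  package; msp windows are closed intervals and variants outside all
  windows are an error, not silently dropped.

## Known limitations

- The pooled genome-wide LAACor definition Σw/√(ΣuΣv) is one natural
  aggregate; alternatives (mean of per-variant correlations) differ
  slightly when ω varies strongly across variants.
- Independent-marker mode understates LAACor sampling covariance relative
  to linked markers.
- Tagging-effect draws are not re-standardised to force the
  tagging-variant genetic variance to r²; the θ-scaled distribution is
  taken as-is, so tagging-scenario r² values are interpretable only
  relative to each other.
- Continuous traits only; no covariates, no binary/liability traits.
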