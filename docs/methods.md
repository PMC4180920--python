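# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the design decisions behind `multiline_gp`.

## The problem setting

Three closed layer-type lines are bred separately: two "sibling" brown
lines (B1, B2) that separated recently, and one white line (W1) that
diverged long ago. Each line has genotyped and phenotyped training animals
from older generations and a youngest validation generation whose
phenotypes are withheld. The question is whether pooling training data
across lines helps predict the validation animals of a target line, and
whether models that shrink SNP effects equally (GBLUP/RRBLUP), reduce
dimension (RRPCA), or select variables (BayesC/BSSVS) answer it
differently.

## Synthetic-data generator

The generator produces the *statistical structure* such a dataset exhibits,
not any real dataset.

**Base population and drift.** Founder allele frequencies are drawn from
Uniform(0.05, 0.5) — mimicking a post-QC SNP panel in which rare variants
have already been removed while leaving room for line-specific fixation to
arise by drift. Founder genotypes are Hardy–Weinberg draws. Each line then
descends from the common base by gene dropping through
`generations_since_split` unrecorded generations of `effective_size`
random-mating parents. SNPs segregate independently (no linkage map, no
recombination model): the analyses under study need realistic
allele-frequency divergence and relationship structure, not within-
chromosome LD decay. This is the generator's main fidelity limit — SNPs
tag QTL through co-inheritance in pedigrees and through being causal
themselves (QTL are a subset of the panel), not through population LD, so
passing tests say nothing about marker density or LD-phase questions.

**Divergence calibration.** Defaults are effective size 50 with 20
generations of drift for each sibling line and 200 for the distant line.
With the folded (minor-allele) frequency correlated between lines, this
lands the sibling pair near 0.35 and sibling-vs-distant near 0.05–0.1,
matching the relatedness contrast the experiments require. The calibration
is an exposed config (`LineSpec`), not hard-coded.

**Recorded cohorts.** After drift, each line expands into a recorded
pedigree: generation 0 (the final drift generation) as pedigree founders,
two training generations (~half the training set each), a pool of
genotyped but non-phenotyped females in the second training generation, and
a validation generation. A validation animal's sire is a training male; its
dam is a training female with probability `dam_overlap` (default 2/3,
matching the partial dam overlap such validation designs show) and a pool
female otherwise. The mechanism behind the overlap is not observable in
real data summaries, so it is a knob rather than an assertion.

**Genetic architecture and phenotypes.** `n_qtl` positions are sampled
without replacement from the panel; per-line allele-substitution effects
are multivariate normal across lines with a configurable correlation
matrix. Defaults: 0.7 between the sibling lines (recent separation, largely
shared architecture) and 0.1 with the distant line — chosen so that
cross-line prediction between distant lines carries essentially no signal,
which is what distinguishes the distant-line experiments from the sibling
ones. True breeding value is the QTL dot product; the residual variance is
set from the *realized* genetic variance so the achieved heritability hits
the target (0.41 sibling lines, 0.51 distant line) even in small
simulations; hatch-week effects (default 6 classes, SD 0.25 trait units)
are added as per-class normal shifts. One RNG stream per stage, all derived
deterministically from the run seed; the same config reproduces every
output bit for bit.

**Default sizes.** The full-scale configuration uses ~1000 training and 240
validation animals per line and a 4000-SNP panel. Tests and the acceptance
script run a scaled replicate (300 training, 100 validation, 1200 SNPs,
10 replicates) — the package's choice of desk-scale problem sizes; the
qualitative pattern is size-stable, absolute accuracies are not.

## Quality control

The four SNP edits are applied to all lines simultaneously: call rate
< 0.95, MAF < 0.02 (strict, a SNP at exactly 0.02 is kept), no observed
homozygote, and Hardy–Weinberg chi-square > 600 (strict). The HWE statistic
is the 3-class goodness-of-fit chi-square against expectations from the
observed allele frequency, without continuity correction — consistent with
the very permissive 600 threshold, which only removes gross genotyping
artefacts. All rules are evaluated for every SNP and all violated rules
tagged, so per-rule removal counts are unambiguous. Missing genotypes
surviving QC are mean-imputed per SNP before matrix algebra. Phenotypes are
pre-corrected for hatch week by a one-way least-squares fit estimated on
training animals only and applied to all animals, so validation phenotypes
never influence the correction.

## Relationship matrices

* **A** by the recursive tabular method; founders unrelated and non-inbred.
* **G (VanRaden method 1)** with column centring 2pᵢ and denominator
  2Σpᵢ(1−pᵢ), frequencies from the combined multi-line data; built once on
  all lines and reused for every training scenario.
* **G (% identity)**: mean per-SNP score with identical homozygotes 1,
  opposite homozygotes 0, anything involving a heterozygote 0.5.
* **G (excess homozygosity)**: ([O(H_id) − O(H_op)] − E(H)) / (p − E(H)).
  The expectation E(H) is not fully determined by the published formula;
  two variants are implemented and recorded in the matrix metadata:
  `pairwise` (default) Σ(pᵢ⁴ + qᵢ⁴ − 2pᵢ²qᵢ²), the expected
  identical-minus-opposite homozygote count for two independent HWE
  individuals, and `individual` Σ(1 − 2pᵢqᵢ), the per-individual expected
  homozygosity that PLINK-style heterozygosity utilities use. Neither is
  asserted to be "the" published variant. Note the matrix's diagonal sits
  on an inbreeding-like scale (≈0.5 at intermediate frequencies), so its
  effective shrinkage differs from VanRaden G; EBV correlations between the
  two are high (0.95–0.99 at desk scale) and grow with panel density.

G matrices are not blended with the identity. Where a solve needs
conditioning, a 1e−6 diagonal ridge is added (recorded in metadata); if a
matrix is indefinite — possible for the excess-homozygosity G — the
phenotype covariance is bent by shifting its diagonal just past the most
negative eigenvalue, again recorded.

## Predictors

**Centring/scaling.** Marker models operate on genotypes centred and scaled
to unit variance per SNP, with moments estimated on the scenario's training
animals and re-applied (stored constants) to validation animals. VanRaden G
instead uses all-line frequencies — the deliberate asymmetry between the
marker-design convention and the G-matrix convention; it is why RRBLUP and
GBLUP_VR correlate slightly below 1 in practice (RRBLUP's per-SNP scaling
up-weights low-MAF SNPs, GBLUP_VR scales all SNPs jointly).

**Ridge / mixed model.** Direct dense solves throughout (Cholesky):
iterative solvers are an implementation detail at production scale and a
liability at desk scale. Ridge uses whichever of the primal (p × p) and
dual (n × n) systems is smaller; both are exact. The animal model has the
overall mean as the only fixed effect (phenotypes are pre-corrected);
validation phenotypes are treated as missing and their EBV obtained jointly
from u = σ²ₐ K(·,t) V⁻¹(y − μ̂) with V = σ²ₐK_tt + σ²ₑI and μ̂ the GLS
mean. EBV are reported without the intercept (genetic merit on the trait
scale), which makes them directly comparable across models; correlations
and accuracies are unaffected.

**RRPCA.** The projection is the leading right-singular-vector rows of the
centred training design, with orthonormal rows (TTᵗ = I_d). A trace-1
normalization of the projector would only recover a single direction;
orthonormal rows are the standard PCA constraint consistent with retaining
hundreds of components. The default dimension is the smallest d whose
cumulative eigenvalue fraction reaches 0.97. PCA reference set defaults to
the training animals of *all* lines (the widest reference), regardless of
the lines in the regression training set; the ridge coefficient α is reused
from RRBLUP — the PC basis is orthonormal so the penalty is comparable — with
an override available. `pc_sweep` traces accuracy over any d grid and any
choice of reference set; d never exceeds the design rank (< n_train).

**Variance components.** Taken from the simulation's realized values (the
stand-in for components from routine genetic evaluation); REML/Gibbs
estimation is out of scope. For multi-line training sets, σ²ₐ and σ²ₑ are
arithmetically averaged over member lines and h², α re-derived from the
averages (so h² of the average ≠ average of h²). The per-SNP prior variance
is σ²_w = σ²ₐ/p with p the scenario's segregating-SNP count. Accuracy is
always computed with the *target line's* h².

## Gibbs samplers

Single-site samplers with residual updating; standard full conditionals
(the published description delegates them to external references, so they
are written out here):

* SNP j: with r_j = z_jᵗe (residual with j's contribution removed) and
  c_j = z_jᵗz_j, the marginal likelihood of a state with effect variance v
  is proportional to (σ²ₑ/(c_j v + σ²ₑ))^½ exp(r_j²v / 2σ²ₑ(c_j v + σ²ₑ)).
  The indicator is Bernoulli over {large, small/null} with prior (1−π, π);
  the effect is then drawn from N(r_j/(c_j + σ²ₑ/v), σ²ₑ/(c_j + σ²ₑ/v)),
  or set to 0 in BayesC's null state.
* σ²_w: scaled-inverse-chi-square, df ν + m (BayesC, m = number included,
  sum over included w²) or ν + p (BSSVS, small-state effects entering as
  c·w²); σ²ₑ: scaled-inverse-chi-square with df ν + n on the residual sum
  of squares. Priors are weakly informative (ν = 4.2) with scales matched
  to the initial values. The overall mean is an unpenalized location.

**Initial values.** BayesC starts σ²_w at σ²ₐ/p (genotypes are unit
variance, so total genetic variance divided by SNP count). For BSSVS the
same raw value would imply a modeled genetic variance of
p·((1−π) + π/c)·σ²_w ≈ 0.011·σ²ₐ at π = 0.999, c = 100; the chain must then
inflate σ²_w by two orders of magnitude and mixes pathologically (the
package observed seed-to-seed EBV correlations of 0.4). The BSSVS
large-effect variance is therefore calibrated as σ²ₐ/(p·((1−π) + π/c)) so
the mixture-implied genetic variance matches σ²ₐ — the standard BSSVS
calibration. π is fixed (0.9 BayesC, 0.999 BSSVS), not estimated.

**Defaults.** Chain 10 000, burn-in 2 000, thinning 10, c = 100 — field
convention, all configurable. Chains are deterministic given the config
seed (the numba kernel seeds its own RNG). Posterior summaries are means
over kept draws; the inclusion probability is the fraction of kept draws in
the large-effect state; an autocorrelation-based effective-sample-size
diagnostic is reported for σ²ₑ (NaN flags a degenerate constant chain). A
non-finite residual variance aborts the chain with diagnostics. In the
n ≪ p many-small-effects regime both samplers act as near-equal shrinkage
predictors; at desk scale their posterior-mean EBVs agree to r > 0.95 only
once Monte Carlo noise is beaten down (long chains), which is how the
cross-model agreement test is run.

## Scenario design and evaluation

For L lines every non-empty subset of lines is a training set (7 for three
lines), evaluated per target line on that line's validation animals.
Pedigree BLUP is attached only to the own-line scenario; a multi-line A
matrix is refused rather than silently built (there are no pedigree ties
between lines). Scenario SNP subsets are the SNPs segregating among the
actual training individuals, so every design can be centred and scaled. One
model's numerical failure is recorded and never aborts the batch; reruns
from one config are byte-identical.

Accuracy = corr(EBV, pre-corrected validation phenotype)/√h², sign
preserved (negative accuracies are reported as such). Approximate SE =
√((1 − ρ̂²)/(N − 2))/√h² with ρ̂ the raw correlation — the literal reading
of the formula; the alternative reading (plugging in the accuracy itself)
is available behind a flag because published SE footnotes are not exactly
reproducible under either reading at h² ≈ 0.5. Bias b₁ regresses phenotype
on EBV; its SE is the SD of b₁ over bootstrap resamples of animals
(pairs, not residuals; resamples with zero EBV variance are redrawn), and
|b₁ − 1| ≥ 2·SE flags significant dispersion bias (an exact slope of 1 is
never flagged). The pedigree-link diagnostic is the mean squared A-matrix
entry over validation × training pairs.

## Known limitations

* No linkage map: questions about SNP density, LD persistence across
  lines, or LD-phase reversal cannot be studied with this generator.
* No selection during line divergence (pure drift), no genotyping-error
  model, no individual-level QC.
* Variance components are inputs, not estimated.
* The excess-homozygosity E(H) is implemented in two defensible variants;
  results with that matrix should state which was used (metadata records
  it).
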