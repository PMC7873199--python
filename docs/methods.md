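# Methods

This note documents the statistical models, parameter defaults, simulator
design, and numerical choices behind `amylocnv`. It states no empirical
result beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Coverage genotyping

**Model.** For a locus with diploid copy number C, reads over the
paralogous target units accumulate in proportion to C while reads over a
nearby copy-invariant reference region accumulate in proportion to 2.
With densities d = reads/bp, the continuous estimate is
CN_raw = 2·d_target/d_reference.

**Unit normalization.** The target density divides the *summed* read
count over all paralogous units by the length of *one* repeat unit
(20,000 bp for *AMY1*, whose three near-identical units each span ~20 kb).
This is the only normalization under which a true-CN-C sample has
expectation C: dividing by the full ~60-kb span would compress the
estimate three-fold and could not produce the observed 2–22 copy range
from a density ratio. The scaling constant (default 2) and unit length
are configuration fields, so sensitivity to this choice can be checked
directly.

**Coordinates.** Internally all intervals are 0-based half-open.
Samtools-style region strings (as printed in locus configs) are 1-based
inclusive and converted on parse; BED files are read natively. One
internal convention eliminates off-by-one drift between the two input
styles.

**Counting semantics.** A record counts for an interval if its aligned
span overlaps by ≥ 1 bp, matching `samtools view -c` region semantics.
The default flag policy excludes unmapped, secondary and supplementary
records and *keeps* duplicates (plain `samtools view -c` filters
nothing); a stricter preset excluding duplicates is provided. Strand is
ignored throughout. *AMY1* is counted with no MAPQ floor — the repeats
depress local mapping quality and a floor would bias the count — while
*AMY2A*/*AMY2B* use MAPQ ≥ 20. These policies ship as data in the
default region config, not as code.

**Alignability QC.** Over the target intervals, the fraction of properly
paired reads lacking `XA:Z`/`SA:Z` tags (unique alignments) and the
fraction with MAPQ above a threshold are reported; the Phred conversion
10^(−q/10) of the threshold (0.01 at MAPQ 20) bounds the residual
mis-mapping probability. A sample with zero properly paired reads gets
NaN fractions and an explicit flag, never a silent zero.

## Parity-conditional rounding

Diploid *AMY1* and *AMY2A* copy numbers share even/odd parity because
the cluster's structural haplotypes carry them together. *AMY2A* (and
*AMY2B*) are rounded half-up to the nearest integer; *AMY1* is rounded
to the nearest integer whose parity matches the *AMY2A* call. When the
raw *AMY1* value is exactly midway between the two admissible integers,
the larger is taken — a deterministic, documented tie rule. By
construction |AMY1_int − AMY1_raw| ≤ 1 and parity consistency holds for
every output.

*AMY2B* is genotyped but excluded from association by default: its calls
almost always equal *AMY2A* and, when they differ, *AMY2B* is the
invariant one, so it adds no signal. Zero-copy *AMY2A* is retained (the
biological range includes 0); only *AMY1* = 0 triggers removal. No cap
is applied to *AMY2A* by default; the *AMY1* cap (14) is a parameter.

## ddPCR estimation and reconciliation

With N ≈ 20,000 droplets, a droplet is positive once it contains ≥ 1
target molecule, so the positive count k estimates the per-droplet
concentration λ = −ln(1 − k/N). The plain estimator
CN = 2·FAM/HEX uses the positive-count ratio directly (the published
formula); `poisson_correct=True` uses the λ ratio and is recommended —
the plain ratio is biased low by saturation once occupancies grow, and
the two agree within 1% only when both occupancies are small *and* the
two channel concentrations are within ~0.015 of each other (the
first-order relative difference is (λ_FAM − λ_HEX)/2).

The control probe marks a two-copy gene, so the ratio is scaled by 2.
Two independent *AMY1* probes are reconciled against the *AMY2A* call:
each probe estimate is rounded half-up and called concordant if its
parity matches *AMY2A* (the interpretation used throughout; strict
integer-equality concordance is available behind a flag). Both
concordant → average; exactly one → keep it; none → average. Averaged
values re-apply parity rounding, so the reconciled call always shares
*AMY2A* parity. Concordance between WGS and ddPCR is evaluated on final
integers, two calls (both loci) per sample.

## Association model

**Preprocessing.** Outliers beyond 3 SD of the full-sample mean are
removed in a single pass (mean/SD not re-estimated), then the trait is
rank inverse-normal transformed, y = Φ⁻¹((r − 0.5)/n) with average ranks
for ties (the Blom offset (r − 3/8)/(n + 1/4) is available; the choice
is conventional and switchable).

**Kinship.** Pairwise kinship below 0.05 is set to zero (pairs treated
as unrelated); exactly 0.05 is retained (strict "lower than" rule). The
GRM is A = 2Φ — the factor is a configurable constant because mixed-model
software conventions differ — giving A_ii = 1 for outbred individuals
and h² = σ²g/(σ²g + σ²e) = 1/(1 + δ).

**REML.** The model y = Xb + xβ + g + e with Var(g) = σ²g·A,
Var(e) = σ²e·I is fit by restricted maximum likelihood profiled over
δ = σ²e/σ²g. A is eigendecomposed once; because thresholded kinship from
family cohorts is block-diagonal, the decomposition is done per connected
component (families of four cost 4³ each instead of n³), and can be
reused across phenotype replicates — this is what makes the
1,000-replicate calibration experiments cheap. The profile likelihood is
evaluated on a 49-point log-δ grid spanning e^±12 and refined by bounded
scalar minimization (tolerance 1e−8, ≤ 200 iterations); the fit is
deterministic given inputs. β/SE come from GLS at the optimum; P is the
two-sided normal approximation of the Wald statistic. With identity
kinship the fit collapses exactly to OLS (verified to 1e−6). Non-PSD
kinship raises an error suggesting a diagonal jitter.

**Other statistics.** Bonferroni thresholds use rational arithmetic
(0.05/(3 outcomes × 2 predictors) = 1/120, displayed as 8.33 × 10⁻³ at 3
significant digits). Logistic models are ML fits with Wald CIs; obesity
is BMI ≥ 30 vs < 25 with the middle band excluded; separation raises an
explicit error advising penalization. Polychoric correlation uses the
two-step estimator — marginal thresholds from cumulative proportions,
then ρ maximizing the bivariate-normal cell likelihood over (−1, 1)
(bounded Brent, thresholds clipped at ±8 where the normal mass is
negligible) — with a likelihood-ratio P against ρ = 0; empty margin
categories are collapsed with a warning.

## Ancestry workflow

The exact Hardy-Weinberg test conditions on allele counts and sums
probabilities of heterozygote counts no more likely than observed,
computed by the standard recurrence in log space (monomorphic sites give
P = 1). Variant QC keeps MAF > 0.01, call rate > 0.9, HWE P > 10⁻⁶.
LD pruning is greedy within windows spanning 50 kb from the window's
first variant: while any retained pair exceeds r² = 0.05 the lower-MAF
member is dropped (ties → later position), then the window start advances
by 5 variants; an exhaustive pairwise scan over the retained set is
provided as an independent post-condition check. PCA standardizes
dosage columns (missing values mean-imputed per variant, PLINK-like),
drops zero-variance columns with a warning, and fixes signs so each
component's largest-magnitude loading is positive. Ancestry is assigned
to the nearest reference centroid in PC space; samples whose
nearest/second-nearest distance ratio exceeds 0.5 have no clear majority
ancestry and are labelled admixed (the margin is a parameter; 0.5 means
"the best centroid must be at least twice as close as the runner-up").

Sliding windows rank individuals by PC1 and take complete windows of 750
with starts every 85 ranks — a *step* of 85, which yields exactly 10
windows over 1,518 individuals and 3 over 948; an overlap of 85 would
not reproduce those counts, so step is the interpretation implemented
(both parameters configurable). Within each window the trait is
re-filtered and re-transformed by default (switchable to a global
transform), then regressed on CN with covariates by OLS, or by logistic
regression for binary outcomes; constant-CN windows are flagged and
skipped.

## Simulator design

The generators emulate the study's statistical structure, not its raw
data:

* **Cohort**: families of two parents and two children; pedigree-expected
  kinship (parent-offspring and full sibs 0.25, spouses 0); sex
  Bernoulli(0.5); age Normal(39.11, 12.03) truncated to [18, 80].
  Ancestry proportions default to 1518:948 Arab:Persian.
* **Copy numbers**: two haplotypes per founder drawn from
  ancestry-specific tables; children inherit one haplotype per parent.
  The packaged tables are constructed (no public haplotype table exists)
  to reproduce the reported diploid means — *AMY1* 6.92/7.60 and *AMY2A*
  2.06/2.27 for Arab/Persian — and every haplotype carries *AMY1* and
  *AMY2A* counts of equal parity, making diploid parity exact by
  construction. They live in a versioned YAML data file, not code.
* **Read counts**: target ~ Poisson(CN·depth·unit_length), reference ~
  Poisson(2·depth·reference_length), with depth = 0.1 reads/bp per
  haploid copy (~30× diploid coverage at 150-bp reads). A shared
  per-sample gamma factor (CV 0.1) mimics library-size variation and
  cancels in the density ratio; optional independent per-region gamma
  noise (CV 0 by default) does not cancel and stresses calling accuracy.
  At these depths the Poisson relative SD makes integer miscalls
  vanishingly rare, which is why near-perfect call accuracy on clean
  simulations is expected rather than remarkable.
* **Phenotypes**: y = β_cn·CN + β_sex·sex + β_age·age_std + g + e with
  g drawn per family block from N(0, σ²g·2Φ); defaults β_cn = −0.02
  SD/copy, h² = 0.3, residual variance 1. Binary outcomes are logistic
  in group-centred CN: obesity (baseline prevalence 0.39, OR 0.93/copy)
  and dietary restraint (baselines 0.54 Arab / 0.60 Persian, OR
  0.94/copy), so group prevalences match their baselines in expectation.
* **ddPCR**: positives ~ Binomial(20,000, 1 − e^(−λ)) per channel with
  λ_target = λ_control·CN/2; panel of two *AMY1* probes and one *AMY2A*
  probe, three replicates.
* **Genotype matrices**: Balding-Nichols drift — ancestral frequency
  U(0.05, 0.95), population frequencies Beta(p(1−Fst)/Fst,
  (1−p)(1−Fst)/Fst) — with alleles thresholded from latent normals that
  follow an AR(1) within blocks, giving decaying local LD. Admixed
  individuals draw from a per-individual mixture (weight U(0.35, 0.65))
  of two population frequencies.
* **BAM fixtures**: miniature sorted/indexed BAMs on a 100-kb toy contig
  with controlled positions, MAPQ, flags and XA/SA tags; bases are
  placeholders (sequence content is irrelevant to coverage genotyping).

All generators are pure functions of their parameters and RNG; seed
replay is bit-identical (tested).

**What passing tests do and do not show.** The simulators omit GC bias,
mapping artifacts, batch effects, genotyping error in the kinship, and
assortative/inbred mating beyond nuclear families. Recovery of β, h²,
OR and ρ on simulated data demonstrates that the estimators are correct
and calibrated under the generating model — it does not certify the
cohort-level estimates of any real population, which require the gated
raw data.

## Experiment sizes

The replicate experiments fix one cohort (and its kinship
eigendecomposition) and resimulate phenotypes: type-I calibration uses
n = 800 with 1,000 null replicates; effect-size recovery n = 3,000 with
200 replicates at β = −0.02; heritability recovery n = 2,000 with 10
replicates at h² ∈ {0.2, 0.45}; odds-ratio recovery n = 950; call
accuracy 1,000 samples; polychoric recovery n = 5,000. These sizes give
Monte-Carlo error comfortably inside each check's tolerance on a single
CPU.

## Known limitations

* The Wald normal approximation is mildly anticonservative at small n;
  the type-I calibration experiment quantifies this at n = 800.
* The REML profile assumes a single genetic variance component; shared
  household/environment effects would inflate ĥ².
* LD pruning is greedy and order-dependent within windows, as in
  standard practice; it guarantees the post-condition, not a unique or
  maximal retained set.
* The ddPCR simulator treats droplet volumes as exactly equal and
  channels as independent; real assays add pipetting and threshold
  noise, so real-data concordance will be somewhat lower than simulated.
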