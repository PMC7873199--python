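# amylocnv

Coverage-based discrete copy-number genotyping of the human amylase genes
(*AMY1*, *AMY2A*, *AMY2B*) from whole-genome sequencing, with droplet
digital PCR (ddPCR) validation and kinship-aware association analysis of
copy number against adiposity traits.

The salivary (*AMY1*) and pancreatic (*AMY2A*) amylase genes sit in a
tandem paralogous cluster on chromosome 1 and are among the most
copy-number-variable genes in the human genome; their diploid copy number
(CN) tracks ancestral dietary starch exposure and has been repeatedly —
and inconsistently — linked to adiposity. This package implements the full
analysis stack needed to study that question in a family-structured
cohort, and ships seeded simulators of every input (read counts, droplet
counts, pedigrees, traits, genotype matrices) so the whole pipeline can be
exercised and calibrated end-to-end without access to controlled biobank
data.

## What it computes

**Copy-number genotyping** (`amylocnv.regions`, `amylocnv.cn_calling`).
Reads overlapping the locus's paralogous target units and a nearby
copy-invariant (two-copy) reference region are counted from an indexed
BAM with samtools-compatible semantics. With read densities
d = reads/bp, the continuous diploid copy number is

    CN_raw = 2 · d_target / d_reference,

where the target density is normalized by the length of one ~20-kb repeat
unit so that a sample truly carrying C copies has expectation C. Integer
calls exploit the structural haplotypes of the cluster: diploid *AMY1*
and *AMY2A* copy numbers share even/odd parity, so *AMY2A* is rounded
half-up first and *AMY1* is then rounded to the nearest integer of
matching parity (parity-conditional rounding). Samples with *AMY1* = 0
are dropped and rare calls above 14 copies winsorized before association.

**ddPCR validation** (`amylocnv.ddpcr`). CN = 2 · FAM/HEX
positive-droplet ratio (optionally Poisson-corrected via
λ = −ln(1 − k/N)); two independent *AMY1* probes are reconciled against
the *AMY2A* call through shared parity, and WGS/ddPCR concordance is
summarized over both loci.

**Association and heritability** (`amylocnv.assoc`). Traits are
outlier-filtered (±3 SD) and rank inverse-normal transformed, pairwise
kinship below 0.05 is zeroed, and the variance-component model

    y = Xb + x·β + g + e,   g ~ N(0, σ²g·2Φ),   e ~ N(0, σ²e·I)

is fit by REML (profiled over δ = σ²e/σ²g after a per-family-block
eigendecomposition of the GRM), giving the Wald β/SE/P per CN copy and
h² = σ²g/(σ²g+σ²e). Logistic case/control models (obesity: BMI ≥ 30 vs
< 25), polychoric correlation between ordinal CN pairs, exact Bonferroni
accounting, and Wilcoxon/χ² descriptive tests are included.

**Ancestry stratification** (`amylocnv.ancestry`). Exact Hardy-Weinberg
test, MAF/call-rate/HWE variant QC, greedy windowed LD pruning
(50 kb, r² ≤ 0.05), PCA of standardized dosages, nearest-centroid
ancestry assignment with an admixture margin, and PC1-ranked sliding
windows (750 individuals, step 85) for testing whether the CN-adiposity
effect varies along an ancestry gradient.

**Simulation** (`amylocnv.simulate`). Seeded generators for all of the
above, plus recovery experiments (type-I calibration, effect-size and
heritability recovery, ddPCR bias) used by the test suite and the
acceptance script.

## Worked example

```python
import numpy as np
from amylocnv import simulate as sim
from amylocnv.assoc import inverse_normal, lmm_fit, remove_outliers, threshold_kinship
from amylocnv.cn_calling import call_genotypes
from amylocnv.regions import default_regions

rng = np.random.default_rng(7)
cohort = sim.simulate_cohort(2000, rng=rng)              # 500 families of 4
cn_truth = sim.simulate_cn(cohort, rng=rng)              # haplotype-based CNs
counts = sim.simulate_counts_cohort(cn_truth, default_regions(), rng=rng)
calls = call_genotypes(counts)                           # parity-conditional calls

pheno = sim.simulate_phenotypes(cohort, cn_truth, beta_cn=-0.02, h2=0.3, rng=rng)
mask = (np.abs(pheno["trait"] - pheno["trait"].mean())
        <= 3 * pheno["trait"].std()).to_numpy()
sub = pheno[mask]
y = inverse_normal(remove_outliers(pheno["trait"].to_numpy())).values
K = threshold_kinship(cohort.kinship, 0.05)[np.ix_(mask.nonzero()[0], mask.nonzero()[0])]
age_std = (sub["age"] - sub["age"].mean()) / sub["age"].std()
X = np.column_stack([sub["sex"], age_std])
fit = lmm_fit(y, X, K, predictor=sub["amy1"].to_numpy(float))
a = fit.assoc
print(f"AMY1 ~ trait: n={a.n}, beta={a.beta:.4f}, SE={a.se:.4f}, "
      f"P={a.p:.3g}, h2={fit.h2:.3f}")
```

This prints (integer-call accuracy against truth is 1.0000 on this run):

```
AMY1 ~ trait: n=1996, beta=-0.0352, SE=0.0119, P=0.00305, h2=0.269
```

i.e. the pipeline recovers a negative per-copy effect on the simulated
adiposity trait (truth −0.02 SD/copy, estimate within sampling error) and
a heritability near the simulated 0.30, while accounting for the family
structure through the thresholded kinship matrix.

The same flow is available from the shell:

```
amylocnv simulate --out sim/ --n 400 --seed 7
amylocnv call --counts sim/counts.tsv --out cn.tsv
amylocnv associate --cn cn.tsv --pheno sim/pheno.tsv --kinship sim/kinship.tsv \
    --trait trait --out assoc.tsv
amylocnv validate --ddpcr sim/droplets.tsv --cn cn.tsv --out validation.tsv
```

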