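"""Seeded synthetic-data generators emulating the study's statistical
structure, plus the parameter-recovery experiments built on them.

No raw cohort data is publicly available, so every pipeline input is
simulated:

* family cohorts (two parents, two children by default) with
  pedigree-expected kinship (parent-offspring and full sibs 0.25),
  sex ~ Bernoulli(0.5), age ~ Normal(39, 12) truncated to [18, 80];
* diploid amylase copy numbers drawn as sums of two ancestry-specific
  haplotypes (children inherit one haplotype per parent); the default
  haplotype tables are constructed so diploid means match the reported
  Arab/Persian means (AMY1 6.92/7.60, AMY2A 2.06/2.27) and so AMY1/AMY2A
  parity is exact;
* Poisson read counts over the paralogous units at ~30x depth
  (target ~ Poisson(CN * depth * unit_length), reference ~
  Poisson(2 * depth * reference_length), with an optional shared
  per-sample gamma library factor that cancels in the density ratio);
* miniature indexed BAM fixtures on a toy contig with controlled MAPQ,
  flags and XA/SA tags;
* quantitative traits y = beta_cn*CN + covariate effects + g + e with a
  kinship-structured polygenic component (target heritability h2) and
  logistic binary outcomes (obesity, dietary restraint) with configurable
  per-copy odds ratios;
* ddPCR droplet counts (positives ~ Binomial(N, 1 - exp(-lambda)));
* two/three-population genotype matrices under a Balding-Nichols
  fixation-index model with optional AR-style local LD and admixed
  individuals.

All generators are pure functions of (parameters, rng/seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .ancestry import GenotypeMatrix
from .assoc import KinshipEigen, lmm_fit, logistic_fit, polychoric, threshold_kinship
from .cn_calling import conditional_round
from .ddpcr import DdPCRMeasurement, ddpcr_cn
from .regions import CountRecord, GenomicInterval, LocusRegionDef

__all__ = [
    "HaplotypeTable",
    "default_haplotype_tables",
    "Cohort",
    "simulate_cohort",
    "simulate_cn",
    "simulate_counts",
    "simulate_counts_cohort",
    "simulate_bam_fixture",
    "ReadSpec",
    "write_bam",
    "toy_locus",
    "simulate_phenotypes",
    "simulate_ddpcr",
    "simulate_genotype_matrix",
    "simulate_ordinal_pair",
    "cn_call_accuracy_experiment",
    "beta_recovery_experiment",
    "type1_error_experiment",
    "h2_recovery_experiment",
    "or_recovery_experiment",
    "ddpcr_bias_experiment",
]

# Defaults chosen to mirror the study conditions: ~30x diploid coverage of
# 150-bp paired reads corresponds to 0.2 reads/bp diploid, i.e. 0.1 reads/bp
# per haploid copy.
DEFAULT_DEPTH = 0.1
DEFAULT_SHARED_CV = 0.1


# ---------------------------------------------------------------------------
# haplotype tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeTable:
    """Joint haploid (AMY1, AMY2A, AMY2B) copy distribution for one ancestry."""

    amy1: np.ndarray
    amy2a: np.ndarray
    amy2b: np.ndarray
    freq: np.ndarray

    def __post_init__(self) -> None:
        for name in ("amy1", "amy2a", "amy2b"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if (arr < 0).any():
                raise ValueError(f"{name} copies must be >= 0")
            object.__setattr__(self, name, arr)
        f = np.asarray(self.freq, dtype=float)
        if not math.isclose(f.sum(), 1.0, abs_tol=1e-9):
            raise ValueError(f"haplotype frequencies must sum to 1, got {f.sum()}")
        object.__setattr__(self, "freq", f)

    @property
    def mean_diploid_amy1(self) -> float:
        return 2.0 * float(self.amy1 @ self.freq)

    @property
    def mean_diploid_amy2a(self) -> float:
        return 2.0 * float(self.amy2a @ self.freq)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        """Indices of ``size`` haplotypes sampled by frequency."""
        return rng.choice(len(self.freq), size=size, p=self.freq)


def default_haplotype_tables() -> dict[str, HaplotypeTable]:
    """The packaged synthetic Arab/Persian haplotype tables."""
    ref = resources.files("amylocnv.data").joinpath("haplotype_tables.yaml")
    with resources.as_file(ref) as path:
        with open(path) as fh:
            doc = yaml.safe_load(fh)
    out = {}
    for group, rows in doc.items():
        out[group] = HaplotypeTable(
            amy1=np.array([r["amy1"] for r in rows]),
            amy2a=np.array([r["amy2a"] for r in rows]),
            amy2b=np.array([r["amy2b"] for r in rows]),
            freq=np.array([r["freq"] for r in rows]),
        )
    return out


# ---------------------------------------------------------------------------
# cohort and pedigree
# ---------------------------------------------------------------------------

@dataclass
class Cohort:
    samples: pd.DataFrame  # sample_id, family_id, role, ancestry, sex, age
    kinship: np.ndarray    # pedigree-expected pairwise kinship (diag 0.5)

    @property
    def n(self) -> int:
        return len(self.samples)


def simulate_cohort(
    n_samples: int,
    ancestry_props: Mapping[str, float] | None = None,
    family_size: tuple[int, int] = (2, 2),
    rng: np.random.Generator | int | None = None,
) -> Cohort:
    """Family-structured cohort with pedigree-expected kinship.

    Families hold ``family_size = (n_parents, n_children)`` members with
    n_parents in {1, 2}; ``n_samples`` is rounded down to whole families.
    Parent-offspring and full-sib kinship is 0.25, spouses and
    between-family pairs 0.  Ancestry is assigned per family.
    """
    rng = np.random.default_rng(rng)
    if ancestry_props is None:
        ancestry_props = {"arab": 1518 / 2466, "persian": 948 / 2466}
    n_parents, n_children = family_size
    if n_parents not in (1, 2) or n_children < 0:
        raise ValueError(f"inconsistent family spec {family_size}")
    fam_n = n_parents + n_children
    n_families = n_samples // fam_n
    if n_families == 0:
        raise ValueError(f"n_samples={n_samples} below one family of {fam_n}")
    groups = list(ancestry_props)
    probs = np.array([ancestry_props[g] for g in groups], dtype=float)
    probs = probs / probs.sum()
    fam_anc = rng.choice(groups, size=n_families, p=probs)

    rows = []
    n_total = n_families * fam_n
    K = np.zeros((n_total, n_total))
    i = 0
    for f in range(n_families):
        members = []
        for p in range(n_parents):
            rows.append(
                dict(sample_id=f"F{f:04d}_P{p}", family_id=f, role="parent",
                     ancestry=fam_anc[f])
            )
            members.append((i, "parent"))
            i += 1
        for c in range(n_children):
            rows.append(
                dict(sample_id=f"F{f:04d}_C{c}", family_id=f, role="child",
                     ancestry=fam_anc[f])
            )
            members.append((i, "child"))
            i += 1
        for a, ra in members:
            K[a, a] = 0.5
            for b, rb in members:
                if a >= b:
                    continue
                if ra == "parent" and rb == "parent":
                    phi = 0.0  # spouses unrelated
                else:
                    phi = 0.25  # parent-offspring or full sibs
                K[a, b] = K[b, a] = phi
    df = pd.DataFrame(rows)
    df["sex"] = rng.integers(0, 2, size=n_total)  # 0 male, 1 female
    age = rng.normal(39.11, 12.03, size=n_total)
    while True:  # truncate to [18, 80]
        bad = (age < 18) | (age > 80)
        if not bad.any():
            break
        age[bad] = rng.normal(39.11, 12.03, size=int(bad.sum()))
    df["age"] = age
    return Cohort(samples=df, kinship=K)


def simulate_cn(
    cohort: Cohort,
    tables: Mapping[str, HaplotypeTable] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """True diploid copy numbers; children inherit one haplotype per parent.

    Founders draw two haplotypes from their ancestry's table.  Because the
    default tables give every haplotype equal AMY1/AMY2A parity, diploid
    parity consistency holds for every sample by construction.
    """
    rng = np.random.default_rng(rng)
    if tables is None:
        tables = default_haplotype_tables()
    df = cohort.samples
    hap_idx = np.zeros((len(df), 2), dtype=int)
    out_rows = []
    for fam, idx in df.groupby("family_id", sort=False).groups.items():
        idx = np.asarray(idx)
        anc = df.loc[idx[0], "ancestry"]
        table = tables[anc]
        parents = [i for i in idx if df.loc[i, "role"] == "parent"]
        children = [i for i in idx if df.loc[i, "role"] == "child"]
        for p in parents:
            hap_idx[p] = table.draw(rng, 2)
        for c in children:
            if len(parents) == 2:
                h1 = hap_idx[parents[0], rng.integers(0, 2)]
                h2 = hap_idx[parents[1], rng.integers(0, 2)]
            elif len(parents) == 1:
                h1 = hap_idx[parents[0], rng.integers(0, 2)]
                h2 = table.draw(rng, 1)[0]
            else:
                h1, h2 = table.draw(rng, 2)
            hap_idx[c] = (h1, h2)
    for i, sid in enumerate(df["sample_id"]):
        anc = df["ancestry"].iloc[i]
        t = tables[anc]
        h1, h2 = hap_idx[i]
        out_rows.append(
            dict(
                sample_id=sid,
                amy1=int(t.amy1[h1] + t.amy1[h2]),
                amy2a=int(t.amy2a[h1] + t.amy2a[h2]),
                amy2b=int(t.amy2b[h1] + t.amy2b[h2]),
            )
        )
    return pd.DataFrame(out_rows)


# ---------------------------------------------------------------------------
# coverage counts
# ---------------------------------------------------------------------------

def simulate_counts(
    true_cn: float,
    locus: LocusRegionDef,
    depth: float = DEFAULT_DEPTH,
    shared_factor: float = 1.0,
    region_cv: float = 0.0,
    sample_id: str = "",
    rng: np.random.Generator | int | None = None,
) -> CountRecord:
    """Poisson read counts for one sample x locus.

    target ~ Poisson(f * CN * depth * unit_length),
    reference ~ Poisson(f * 2 * depth * reference_length),
    where ``f`` is the shared library-size factor (cancels in the density
    ratio) optionally multiplied by independent per-region gamma noise with
    CV ``region_cv`` (does not cancel; stresses calling accuracy).
    """
    rng = np.random.default_rng(rng)
    if depth < 0:
        raise ValueError("depth must be >= 0")

    def _gamma(cv: float) -> float:
        if cv <= 0:
            return 1.0
        shape = 1.0 / cv**2
        return float(rng.gamma(shape, 1.0 / shape))

    lam_t = shared_factor * _gamma(region_cv) * true_cn * depth * locus.unit_length
    lam_r = shared_factor * _gamma(region_cv) * 2.0 * depth * locus.reference_length
    target = int(rng.poisson(lam_t)) if lam_t > 0 else 0
    reference = int(rng.poisson(lam_r)) if lam_r > 0 else 0
    return CountRecord(
        sample_id=sample_id,
        locus_name=locus.locus_name,
        target_count=target,
        reference_count=reference,
        target_density=target / locus.unit_length,
        reference_density=reference / locus.reference_length,
    )


def simulate_counts_cohort(
    cn: pd.DataFrame,
    regions: Mapping[str, LocusRegionDef],
    depth: float = DEFAULT_DEPTH,
    shared_cv: float = DEFAULT_SHARED_CV,
    region_cv: float = 0.0,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Long counts table for a cohort's true CN table (columns amy1/amy2a/amy2b)."""
    rng = np.random.default_rng(rng)
    rows = []
    for _, r in cn.iterrows():
        if shared_cv > 0:
            shape = 1.0 / shared_cv**2
            f = float(rng.gamma(shape, 1.0 / shape))
        else:
            f = 1.0
        for locus_name, locus in regions.items():
            col = locus_name.lower()
            if col not in cn.columns:
                continue
            rec = simulate_counts(
                float(r[col]), locus, depth, f, region_cv, str(r["sample_id"]), rng
            )
            rows.append(rec.__dict__)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# miniature BAM fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSpec:
    """One synthetic alignment record for a BAM fixture."""

    pos: int
    mapq: int = 60
    properly_paired: bool = True
    xa: bool = False
    sa: bool = False
    duplicate: bool = False
    secondary: bool = False
    unmapped: bool = False
    length: int = 100


def write_bam(
    reads: Sequence[ReadSpec],
    path,
    contig: str = "chrT",
    contig_length: int = 100_000,
) -> str:
    """Write, sort and index a BAM of synthetic records; returns the path."""
    import pysam

    path = str(path)
    tmp = path + ".unsorted.bam"
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": contig, "LN": contig_length}],
    }
    with pysam.AlignmentFile(tmp, "wb", header=header) as out:
        for i, spec in enumerate(reads):
            a = pysam.AlignedSegment(out.header)
            a.query_name = f"read{i:07d}"
            a.query_sequence = "A" * spec.length
            a.query_qualities = pysam.qualitystring_to_array("I" * spec.length)
            flag = 0
            if spec.unmapped:
                flag |= 0x4
            else:
                a.reference_id = 0
                a.reference_start = spec.pos
                a.mapping_quality = spec.mapq
                a.cigarstring = f"{spec.length}M"
            if spec.properly_paired and not spec.unmapped:
                flag |= 0x1 | 0x2 | 0x40
                a.next_reference_id = 0
                a.next_reference_start = spec.pos
            if spec.duplicate:
                flag |= 0x400
            if spec.secondary:
                flag |= 0x100
            a.flag = flag
            if spec.xa:
                a.set_tag("XA", f"{contig},+{spec.pos + 1},{spec.length}M,1;")
            if spec.sa:
                a.set_tag("SA", f"{contig},{spec.pos + 1},+,{spec.length}M,60,0;")
            out.write(a)
    pysam.sort("-o", path, tmp)
    Path(tmp).unlink()
    pysam.index(path)
    return path


def toy_locus(
    locus_name: str = "TOY",
    contig: str = "chrT",
    mapq_min: int = 0,
) -> LocusRegionDef:
    """A small three-unit locus on the 100-kb toy contig used by fixtures."""
    return LocusRegionDef(
        locus_name=locus_name,
        target_intervals=(
            GenomicInterval(contig, 10_000, 12_000),
            GenomicInterval(contig, 20_000, 22_000),
            GenomicInterval(contig, 30_000, 32_000),
        ),
        unit_length=2_000,
        reference_intervals=(
            GenomicInterval(contig, 50_000, 54_000),
            GenomicInterval(contig, 60_000, 64_000),
        ),
        mapq_min=mapq_min,
    )


def simulate_bam_fixture(
    true_cn: float,
    out_path,
    locus: LocusRegionDef | None = None,
    depth: float = DEFAULT_DEPTH,
    contig: str = "chrT",
    contig_length: int = 100_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, LocusRegionDef]:
    """Sorted indexed BAM whose per-interval counts realize simulate_counts.

    Reads are placed uniformly with their full span inside each interval so
    interval counts are exact.  Target intervals share the locus's Poisson
    expectation proportionally to length.
    """
    rng = np.random.default_rng(rng)
    locus = locus or toy_locus(contig=contig)
    read_len = 100
    reads: list[ReadSpec] = []
    total_t = sum(iv.length for iv in locus.target_intervals)
    for iv in locus.target_intervals:
        lam = true_cn * depth * locus.unit_length * iv.length / total_t
        n = int(rng.poisson(lam))
        for pos in rng.integers(iv.start, iv.end - read_len, size=n):
            reads.append(ReadSpec(pos=int(pos)))
    for iv in locus.reference_intervals:
        lam = 2.0 * depth * iv.length
        n = int(rng.poisson(lam))
        for pos in rng.integers(iv.start, iv.end - read_len, size=n):
            reads.append(ReadSpec(pos=int(pos)))
    path = write_bam(reads, out_path, contig, contig_length)
    return path, locus


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def _polygenic(
    kinship: np.ndarray, sigma2_g: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw g ~ N(0, sigma2_g * 2K) per kinship block (families)."""
    import scipy.sparse
    import scipy.sparse.csgraph

    n = kinship.shape[0]
    A = 2.0 * kinship
    pattern = scipy.sparse.csr_matrix((np.abs(A) > 0).astype(np.int8))
    _, labels = scipy.sparse.csgraph.connected_components(pattern, directed=False)
    g = np.zeros(n)
    for c in np.unique(labels):
        idx = np.where(labels == c)[0]
        block = A[np.ix_(idx, idx)] * sigma2_g
        L = np.linalg.cholesky(block + 1e-12 * np.eye(len(idx)))
        g[idx] = L @ rng.standard_normal(len(idx))
    return g


def simulate_phenotypes(
    cohort: Cohort,
    cn: pd.DataFrame,
    beta_cn: float = -0.02,
    h2: float = 0.3,
    beta_sex: float = 0.2,
    beta_age: float = 0.1,
    resid_var: float = 1.0,
    or_obesity: float = 0.93,
    obesity_base: float = 0.39,
    or_restraint: float = 0.94,
    restraint_base: Mapping[str, float] | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Adiposity-like trait plus binary obesity / dietary-restraint outcomes.

    trait = beta_cn*AMY1 + beta_sex*sex + beta_age*age_std + g + e with
    Var(g) = h2*resid_var structured by 2K and Var(e) = (1-h2)*resid_var,
    so the trait is in residual-SD units and beta_cn is SD per copy.
    Binary outcomes follow logistic models with per-copy odds ratios on
    group-centred copy number, so the group prevalences stay at their
    configured baselines in expectation.
    """
    rng = np.random.default_rng(rng)
    if restraint_base is None:
        restraint_base = {"arab": 0.54, "persian": 0.60}
    df = cohort.samples.merge(cn, on="sample_id", validate="1:1")
    n = len(df)
    sigma2_g = h2 * resid_var
    sigma2_e = (1.0 - h2) * resid_var
    g = _polygenic(cohort.kinship, sigma2_g, rng) if sigma2_g > 0 else np.zeros(n)
    e = rng.normal(0.0, math.sqrt(sigma2_e), size=n)
    age_std = (df["age"].to_numpy() - df["age"].mean()) / df["age"].std()
    amy1 = df["amy1"].to_numpy(dtype=float)
    trait = beta_cn * amy1 + beta_sex * df["sex"].to_numpy() + beta_age * age_std + g + e

    anc = df["ancestry"].to_numpy()
    cn_centered = amy1 - pd.Series(amy1).groupby(anc).transform("mean").to_numpy()
    logit_ob = math.log(obesity_base / (1 - obesity_base)) + math.log(or_obesity) * cn_centered
    obese = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_ob))
    base = np.array([restraint_base.get(a, 0.5) for a in anc])
    logit_rs = np.log(base / (1 - base)) + math.log(or_restraint) * cn_centered
    restraint = rng.random(n) < 1.0 / (1.0 + np.exp(-logit_rs))

    out = df[["sample_id", "family_id", "ancestry", "sex", "age"]].copy()
    out["amy1"] = df["amy1"]
    out["amy2a"] = df["amy2a"]
    out["trait"] = trait
    out["obese"] = obese.astype(int)
    out["restraint"] = restraint.astype(int)
    return out


# ---------------------------------------------------------------------------
# ddPCR droplets
# ---------------------------------------------------------------------------

def simulate_ddpcr(
    true_cn: Mapping[str, float],
    droplets: int = 20_000,
    lambda_control: float = 0.5,
    replicates: int = 3,
    sample_id: str = "",
    rng: np.random.Generator | int | None = None,
) -> list[DdPCRMeasurement]:
    """Droplet counts for the three-probe panel (2x AMY1, 1x AMY2A).

    Target molecules per droplet are Poisson with rate
    lambda_control * CN / 2; a droplet is positive once it holds >= 1
    molecule, so positive counts are Binomial(droplets, 1 - exp(-lambda)).
    """
    rng = np.random.default_rng(rng)
    if droplets <= 0:
        raise ValueError("droplet count must be positive")
    if lambda_control <= 0:
        raise ValueError("lambda_control must be positive")
    probes = {"AMY1_p1": "amy1", "AMY1_p2": "amy1", "AMY2A_p1": "amy2a"}
    out = []
    p_hex = 1.0 - math.exp(-lambda_control)
    for probe_id, key in probes.items():
        lam_fam = lambda_control * true_cn[key] / 2.0
        p_fam = 1.0 - math.exp(-lam_fam)
        for rep in range(replicates):
            out.append(
                DdPCRMeasurement(
                    sample_id=sample_id,
                    probe_id=probe_id,
                    replicate=rep,
                    fam_positive=int(rng.binomial(droplets, p_fam)),
                    hex_positive=int(rng.binomial(droplets, p_hex)),
                    total_droplets=droplets,
                )
            )
    return out


# ---------------------------------------------------------------------------
# structured genotype matrices
# ---------------------------------------------------------------------------

def simulate_genotype_matrix(
    n_per_pop: Mapping[str, int],
    m_variants: int = 500,
    fst: float = 0.05,
    ld_rho: float = 0.0,
    ld_block: int = 20,
    admixed_frac: float = 0.0,
    spacing_bp: int = 1_000,
    chrom: str = "1",
    rng: np.random.Generator | int | None = None,
) -> tuple[GenotypeMatrix, np.ndarray]:
    """Balding-Nichols two/three-population dosages with optional local LD.

    Per variant, an ancestral frequency p ~ U(0.05, 0.95) drifts to
    population frequencies Beta(p(1-Fst)/Fst, (1-p)(1-Fst)/Fst).  Each
    haplotype allele is the threshold of a latent standard normal; within
    blocks of ``ld_block`` consecutive variants the latents follow an
    AR(1) with coefficient ``ld_rho``, giving decaying local LD.  A
    fraction ``admixed_frac`` of individuals draw each variant from a
    per-individual mixture of two population frequencies (mixing weight
    ~ U(0.35, 0.65)); their labels are "Admixed".

    Returns the matrix and the true population labels.
    """
    rng = np.random.default_rng(rng)
    if m_variants < 2:
        raise ValueError("need >= 2 variants")
    pops = list(n_per_pop)
    p_anc = rng.uniform(0.05, 0.95, size=m_variants)
    freqs = {}
    for pop in pops:
        if fst <= 0:
            freqs[pop] = p_anc.copy()
        else:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            freqs[pop] = np.clip(rng.beta(a, b), 1e-4, 1 - 1e-4)

    def _latent(n_hap: int) -> np.ndarray:
        z = rng.standard_normal((n_hap, m_variants))
        if ld_rho > 0:
            for j in range(1, m_variants):
                if j % ld_block != 0:
                    z[:, j] = ld_rho * z[:, j - 1] + math.sqrt(1 - ld_rho**2) * z[:, j]
        return z

    from scipy.stats import norm

    blocks = []
    labels = []
    for pop in pops:
        n = n_per_pop[pop]
        n_adm = int(round(admixed_frac * n)) if pop == pops[0] else 0
        n_pure = n - n_adm
        if n_pure > 0:
            z = _latent(2 * n_pure)
            thresh = norm.ppf(freqs[pop])[None, :]
            hap = (z < thresh).astype(float)
            blocks.append(hap[0::2] + hap[1::2])
            labels.extend([pop] * n_pure)
        if n_adm > 0 and len(pops) >= 2:
            other = pops[1]
            alpha = rng.uniform(0.35, 0.65, size=n_adm)
            fmix = alpha[:, None] * freqs[pop][None, :] + (1 - alpha)[:, None] * freqs[other][None, :]
            z = _latent(2 * n_adm)
            th = norm.ppf(fmix)
            hap0 = (z[0::2] < th).astype(float)
            hap1 = (z[1::2] < th).astype(float)
            blocks.append(hap0 + hap1)
            labels.extend(["Admixed"] * n_adm)
    dosages = np.vstack(blocks)
    n_total = dosages.shape[0]
    G = GenotypeMatrix(
        dosages=dosages,
        sample_ids=np.array([f"S{i:05d}" for i in range(n_total)]),
        variant_ids=np.array([f"var{j:06d}" for j in range(m_variants)]),
        chrom=np.array([chrom] * m_variants),
        pos=np.arange(m_variants) * spacing_bp,
    )
    return G, np.array(labels)


def simulate_ordinal_pair(
    rho: float,
    n: int,
    row_cuts: Sequence[float] = (-1.0, 0.0, 1.0),
    col_cuts: Sequence[float] = (-0.5, 0.5),
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Ordinal contingency table from thresholding a latent bivariate normal
    with correlation ``rho`` (generator truth for polychoric recovery)."""
    rng = np.random.default_rng(rng)
    z1 = rng.standard_normal(n)
    z2 = rho * z1 + math.sqrt(1 - rho**2) * rng.standard_normal(n)
    x = np.digitize(z1, row_cuts)
    y = np.digitize(z2, col_cuts)
    table = np.zeros((len(row_cuts) + 1, len(col_cuts) + 1))
    np.add.at(table, (x, y), 1)
    return table


# ---------------------------------------------------------------------------
# recovery experiments (simulation truths -> pipeline estimates)
# ---------------------------------------------------------------------------

def cn_call_accuracy_experiment(
    n_samples: int = 1000,
    depth: float = DEFAULT_DEPTH,
    seed: int | None = 0,
) -> dict[str, float]:
    """Fraction of integer AMY1/AMY2A calls equal to simulated truth at ~30x."""
    from .regions import default_regions

    rng = np.random.default_rng(seed)
    regions = default_regions()
    cohort = simulate_cohort(n_samples, rng=rng)
    cn = simulate_cn(cohort, rng=rng)
    counts = simulate_counts_cohort(cn, regions, depth=depth, rng=rng)
    from .cn_calling import call_genotypes

    calls = call_genotypes(counts).merge(cn, on="sample_id", suffixes=("_call", "_true"))
    return {
        "amy1_accuracy": float((calls["amy1_call"] == calls["amy1_true"]).mean()),
        "amy2a_accuracy": float((calls["amy2a_call"] == calls["amy2a_true"]).mean()),
        "n": len(calls),
    }


def _assoc_setup(n: int, seed, h2: float):
    """Shared cohort + eigendecomposition for replicate experiments."""
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(n, rng=rng)
    cn = simulate_cn(cohort, rng=rng)
    K = threshold_kinship(cohort.kinship, 0.05)
    eigen = KinshipEigen(2.0 * K)
    df = cohort.samples
    age_std = (df["age"].to_numpy() - df["age"].mean()) / df["age"].std()
    X = np.column_stack([df["sex"].to_numpy(dtype=float), age_std])
    return rng, cohort, cn, eigen, X


def beta_recovery_experiment(
    n: int = 3000,
    n_reps: int = 200,
    beta: float = -0.02,
    h2: float = 0.3,
    seed: int | None = 0,
) -> dict[str, float]:
    """Mean LMM effect-size estimate over phenotype replicates on one cohort."""
    rng, cohort, cn, eigen, X = _assoc_setup(n, seed, h2)
    betas = []
    for _ in range(n_reps):
        pheno = simulate_phenotypes(cohort, cn, beta_cn=beta, h2=h2, rng=rng)
        fit = lmm_fit(
            pheno["trait"].to_numpy(), X, predictor=pheno["amy1"].to_numpy(),
            eigen=eigen,
        )
        betas.append(fit.assoc.beta)
    betas = np.asarray(betas)
    return {
        "mean_beta": float(betas.mean()),
        "sd_beta": float(betas.std(ddof=1)),
        "sign_rate": float(np.mean(np.sign(betas) == np.sign(beta))),
        "n": cohort.n,
        "n_reps": n_reps,
    }


def type1_error_experiment(
    n: int = 800,
    n_reps: int = 1000,
    h2: float = 0.3,
    alpha: float = 0.05,
    seed: int | None = 0,
) -> dict[str, float]:
    """Rejection rate under the null (beta_cn = 0) at level ``alpha``."""
    rng, cohort, cn, eigen, X = _assoc_setup(n, seed, h2)
    rejections = 0
    for _ in range(n_reps):
        pheno = simulate_phenotypes(cohort, cn, beta_cn=0.0, h2=h2, rng=rng)
        fit = lmm_fit(
            pheno["trait"].to_numpy(), X, predictor=pheno["amy1"].to_numpy(),
            eigen=eigen,
        )
        if fit.assoc.p < alpha:
            rejections += 1
    return {
        "rejection_rate": rejections / n_reps,
        "n": cohort.n,
        "n_reps": n_reps,
        "alpha": alpha,
    }


def h2_recovery_experiment(
    n: int = 2000,
    n_reps: int = 10,
    h2_true: float = 0.3,
    seed: int | None = 0,
) -> dict[str, float]:
    """Mean REML heritability estimate over phenotype replicates."""
    rng, cohort, cn, eigen, X = _assoc_setup(n, seed, h2_true)
    h2s = []
    for _ in range(n_reps):
        pheno = simulate_phenotypes(cohort, cn, beta_cn=0.0, h2=h2_true, rng=rng)
        fit = lmm_fit(pheno["trait"].to_numpy(), X, eigen=eigen)
        h2s.append(fit.h2)
    return {
        "mean_h2": float(np.mean(h2s)),
        "sd_h2": float(np.std(h2s, ddof=1)),
        "n": cohort.n,
        "n_reps": n_reps,
    }


def or_recovery_experiment(
    n: int = 950,
    n_reps: int = 500,
    odds_ratio: float = 0.93,
    seed: int | None = 0,
) -> dict[str, float]:
    """Mean logistic odds-ratio estimate for a binary outcome per CN copy."""
    rng = np.random.default_rng(seed)
    cohort = simulate_cohort(n, rng=rng)
    cn = simulate_cn(cohort, rng=rng)
    ors = []
    for _ in range(n_reps):
        pheno = simulate_phenotypes(cohort, cn, or_obesity=odds_ratio, rng=rng)
        res = logistic_fit(
            pheno["obese"].to_numpy(),
            pheno["amy1"].to_numpy(),
            pheno["sex"].to_numpy(dtype=float),
        )
        ors.append(res.odds_ratio)
    return {"mean_or": float(np.mean(ors)), "n": n, "n_reps": n_reps}


def ddpcr_bias_experiment(
    true_cn: float = 6.0,
    lambda_control: float = 0.5,
    droplets: int = 20_000,
    n_reps: int = 1000,
    seed: int | None = 0,
) -> dict[str, float]:
    """Mean Poisson-corrected ddPCR estimate over independent measurements."""
    rng = np.random.default_rng(seed)
    vals = []
    for rep in range(n_reps):
        m = simulate_ddpcr(
            {"amy1": true_cn, "amy2a": 2.0},
            droplets=droplets,
            lambda_control=lambda_control,
            replicates=1,
            rng=rng,
        )[0]  # first AMY1 probe
        vals.append(ddpcr_cn(m, poisson_correct=True))
    return {
        "mean_cn": float(np.mean(vals)),
        "sd_cn": float(np.std(vals, ddof=1)),
        "n_reps": n_reps,
    }
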