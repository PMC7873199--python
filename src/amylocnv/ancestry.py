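"""Population-structure tools: variant QC, LD pruning, PCA, ancestry
assignment, and PC1 sliding-window stratified association.

The ancestry workflow mirrors standard genotype-array practice: variants
are filtered on minor-allele frequency, call rate and an exact
Hardy-Weinberg test; remaining variants are greedily LD-pruned within
50-kb windows; principal components of the standardized dosage matrix
separate subpopulations; individuals are assigned to the nearest
reference centroid in PC space, with near-equidistant samples labelled
admixed.  To probe whether an association varies along an ancestry
gradient, individuals are ranked by PC1 and the model is refit inside
overlapping fixed-size windows of that ranking.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .assoc import inverse_normal, logistic_fit, remove_outliers

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "PCAResult",
    "AncestryAssignment",
    "WindowSpec",
    "hwe_exact_test",
    "variant_qc",
    "ld_prune",
    "ld_violations",
    "pca",
    "group_centroids",
    "assign_ancestry",
    "sliding_windows",
    "windowed_association",
]


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Biallelic dosage matrix (samples x variants), NaN = missing."""

    dosages: np.ndarray
    sample_ids: np.ndarray
    variant_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.sample_ids = np.asarray(self.sample_ids)
        self.variant_ids = np.asarray(self.variant_ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=int)
        n, m = self.dosages.shape
        if len(self.sample_ids) != n:
            raise ValueError("sample_ids length mismatch")
        if not (len(self.variant_ids) == len(self.chrom) == len(self.pos) == m):
            raise ValueError("variant metadata length mismatch")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0/1/2 or missing (NaN)")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def subset_variants(self, idx) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.dosages[:, idx],
            self.sample_ids,
            self.variant_ids[idx],
            self.chrom[idx],
            self.pos[idx],
        )

    @classmethod
    def from_vcf(cls, path) -> "GenotypeMatrix":
        """Load biallelic sites from a VCF; genotypes become 0/1/2 dosages."""
        import pysam

        vf = pysam.VariantFile(str(path))
        samples = list(vf.header.samples)
        dos, vids, chroms, poss = [], [], [], []
        for rec in vf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            row = []
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt is None or any(a is None for a in gt):
                    row.append(np.nan)
                else:
                    row.append(float(sum(gt)))
            dos.append(row)
            vids.append(rec.id or f"{rec.chrom}:{rec.pos}")
            chroms.append(rec.chrom)
            poss.append(rec.pos - 1)
        vf.close()
        return cls(
            np.array(dos, dtype=float).T if dos else np.empty((len(samples), 0)),
            np.array(samples),
            np.array(vids),
            np.array(chroms),
            np.array(poss, dtype=int),
        )

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        """Load a dosage TSV: columns variant_id, chrom, pos, then samples."""
        df = pd.read_csv(path, sep="\t")
        meta = df[["variant_id", "chrom", "pos"]]
        dos = df.drop(columns=["variant_id", "chrom", "pos"]).to_numpy(dtype=float).T
        return cls(
            dos,
            np.array(df.columns[3:]),
            meta["variant_id"].to_numpy(),
            meta["chrom"].to_numpy(),
            meta["pos"].to_numpy(),
        )


@dataclass(frozen=True)
class QCReport:
    n_input: int
    n_kept: int
    n_fail_maf: int
    n_fail_call_rate: int
    n_fail_hwe: int


@dataclass(frozen=True)
class AncestryAssignment:
    sample_id: str
    group: str
    coords: np.ndarray


@dataclass(frozen=True)
class WindowSpec:
    """Sliding windows over a PC1 ranking of individuals."""

    window_size: int = 750
    step: int = 85

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.window_size:
            raise ValueError("require 0 < step <= window_size")


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test.

    Conditions on the observed allele counts and sums the probabilities of
    every heterozygote count at most as likely as the observed one.
    Probabilities follow the standard recurrence over heterozygote counts
    (which share the rare-allele-count parity).  Monomorphic sites return
    P = 1 by convention.
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise ValueError("empty genotype table")
    n_rare = 2 * min(n_AA, n_aa) + n_Aa  # rare-allele count
    n_rare = min(n_rare, 2 * n - n_rare)
    if n_rare == 0:
        return 1.0
    # heterozygote counts share parity with the rare-allele count
    het_min = n_rare % 2
    hets = list(range(het_min, n_rare + 1, 2))
    # recurrence: p(h+2)/p(h) = [ (nr-h)(2n-nr-h) ] / [ (h+2)(h+1)/4 ] ... use
    # upward/downward recurrence from the mode for stability
    probs = np.zeros(len(hets))
    # start from the largest het count and recur downward:
    # p(h-2)/p(h) = h (h-1) / [ (nr - h + 2)(2n - nr - h + 2) ]
    logp = np.zeros(len(hets))
    for i in range(len(hets) - 2, -1, -1):
        h = hets[i + 1]
        ratio = (h * (h - 1)) / ((n_rare - h + 2) * (2 * n - n_rare - h + 2))
        logp[i] = logp[i + 1] + math.log(ratio)
    logp -= logp.max()
    probs = np.exp(logp)
    probs /= probs.sum()
    obs = probs[hets.index(n_Aa)] if n_Aa in hets else None
    if obs is None:
        raise ValueError(
            f"heterozygote count {n_Aa} inconsistent with allele counts"
        )
    return float(min(1.0, probs[probs <= obs * (1.0 + 1e-12)].sum()))


# ---------------------------------------------------------------------------
# variant QC and LD pruning
# ---------------------------------------------------------------------------

def _variant_stats(dos: np.ndarray):
    present = ~np.isnan(dos)
    call_rate = present.mean(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        p_alt = np.nanmean(dos, axis=0) / 2.0
    maf = np.minimum(p_alt, 1.0 - p_alt)
    return call_rate, maf


def variant_qc(
    G: GenotypeMatrix,
    maf_min: float = 0.01,
    call_rate_min: float = 0.9,
    hwe_p_min: float = 1e-6,
) -> tuple[GenotypeMatrix, QCReport]:
    """Keep variants with MAF > maf_min, call rate > call_rate_min and
    HWE exact P > hwe_p_min; per-criterion failure counts are reported."""
    dos = G.dosages
    call_rate, maf = _variant_stats(dos)
    hwe_p = np.ones(G.n_variants)
    for j in range(G.n_variants):
        col = dos[:, j]
        col = col[~np.isnan(col)]
        if len(col) == 0:
            hwe_p[j] = 1.0
            continue
        n_aa = int(np.sum(col == 2))
        n_het = int(np.sum(col == 1))
        n_AA = int(np.sum(col == 0))
        hwe_p[j] = hwe_exact_test(n_AA, n_het, n_aa)
    ok_maf = maf > maf_min
    ok_cr = call_rate > call_rate_min
    ok_hwe = hwe_p > hwe_p_min
    keep = ok_maf & ok_cr & ok_hwe
    if not keep.any():
        raise ValueError("all variants removed by QC")
    report = QCReport(
        n_input=G.n_variants,
        n_kept=int(keep.sum()),
        n_fail_maf=int((~ok_maf).sum()),
        n_fail_call_rate=int((~ok_cr).sum()),
        n_fail_hwe=int((~ok_hwe).sum()),
    )
    return G.subset_variants(keep), report


def _impute_mean(dos: np.ndarray) -> np.ndarray:
    out = dos.copy()
    col_mean = np.nanmean(out, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_r, nan_c = np.where(np.isnan(out))
    out[nan_r, nan_c] = col_mean[nan_c]
    return out


def ld_prune(
    G: GenotypeMatrix,
    window_bp: int = 50_000,
    step_variants: int = 5,
    r2_max: float = 0.05,
) -> np.ndarray:
    """Greedy windowed LD pruning; returns indices of retained variants.

    Within each window (variants spanning <= ``window_bp`` from the window's
    first variant), while any retained pair has squared dosage correlation
    above ``r2_max``, the member with the lower MAF is removed (ties: the
    later position).  The window start then advances by ``step_variants``.
    The retained set has no violating pair within any window.
    """
    _, maf = _variant_stats(G.dosages)
    dos = _impute_mean(G.dosages)
    alive = np.ones(G.n_variants, dtype=bool)
    for chrom in pd.unique(G.chrom):
        cidx = np.where(G.chrom == chrom)[0]
        pos = G.pos[cidx]
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"variant positions unsorted on {chrom}")
        start = 0
        while start < len(cidx):
            lo = pos[start]
            in_win = cidx[(pos >= lo) & (pos <= lo + window_bp)]
            live = in_win[alive[in_win]]
            while len(live) > 1:
                Z = dos[:, live]
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r = np.corrcoef(Z, rowvar=False)
                r2 = np.nan_to_num(r, nan=0.0) ** 2
                np.fill_diagonal(r2, 0.0)
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] <= r2_max:
                    break
                vi, vj = live[i], live[j]
                if maf[vi] < maf[vj]:
                    drop = vi
                elif maf[vj] < maf[vi]:
                    drop = vj
                else:
                    drop = max(vi, vj)  # tie -> later position
                alive[drop] = False
                live = live[live != drop]
            start += step_variants
        # cleanup sweep: the stepped scan can miss a pair that never shares
        # a scanned window; enforce the post-condition over every retained
        # pair within the window span
        changed = True
        while changed:
            changed = False
            live = cidx[alive[cidx]]
            lp = G.pos[live]
            for a in range(len(live)):
                for b in range(a + 1, len(live)):
                    if lp[b] - lp[a] > window_bp:
                        break
                    x, y = dos[:, live[a]], dos[:, live[b]]
                    if np.std(x) == 0 or np.std(y) == 0:
                        continue
                    r = np.corrcoef(x, y)[0, 1]
                    if r * r > r2_max:
                        va, vb = live[a], live[b]
                        if maf[va] < maf[vb]:
                            drop = va
                        elif maf[vb] < maf[va]:
                            drop = vb
                        else:
                            drop = max(va, vb)
                        alive[drop] = False
                        changed = True
                if changed:
                    break
    return np.where(alive)[0]


def ld_violations(
    G: GenotypeMatrix,
    kept: np.ndarray,
    window_bp: int = 50_000,
    r2_max: float = 0.05,
) -> int:
    """Exhaustive post-condition check: number of retained pairs within a
    window whose r^2 exceeds the threshold (0 after a correct prune)."""
    dos = _impute_mean(G.dosages)
    kept = np.asarray(kept)
    n_bad = 0
    for a in range(len(kept)):
        for b in range(a + 1, len(kept)):
            va, vb = kept[a], kept[b]
            if G.chrom[va] != G.chrom[vb]:
                continue
            if abs(int(G.pos[va]) - int(G.pos[vb])) > window_bp:
                continue
            x, y = dos[:, va], dos[:, vb]
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r = np.corrcoef(x, y)[0, 1]
            if r * r > r2_max:
                n_bad += 1
    return n_bad


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

@dataclass
class PCAResult:
    coords: np.ndarray            # samples x n_components
    explained_variance: np.ndarray  # full spectrum
    loadings: np.ndarray          # kept variants x n_components
    kept_variants: np.ndarray     # indices into the input matrix


def pca(G: GenotypeMatrix, n_components: int = 10) -> PCAResult:
    """PCA of the column-standardized dosage matrix.

    Missing dosages are mean-imputed per variant; zero-variance columns are
    dropped with a warning.  Sign convention: the largest-|loading| entry
    of each component is positive.
    """
    if G.n_samples < 2 or G.n_variants < 2:
        raise ValueError("need >= 2 samples and >= 2 variants for PCA")
    Z = _impute_mean(G.dosages)
    sd = Z.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance variants")
    if not keep.any():
        raise ValueError("no variable variants; PCA undefined")
    kept = np.where(keep)[0]
    Z = (Z[:, keep] - Z[:, keep].mean(axis=0)) / sd[keep]
    U, S, Vt = np.linalg.svd(Z, full_matrices=False)
    n_components = min(n_components, len(S))
    # fix signs on the variant-loading vectors
    for k in range(len(S)):
        jmax = np.argmax(np.abs(Vt[k]))
        if Vt[k, jmax] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    coords = U[:, :n_components] * S[:n_components]
    explained = S**2 / (G.n_samples - 1)
    return PCAResult(coords, explained, Vt[:n_components].T, kept)


def group_centroids(coords: np.ndarray, labels) -> dict[str, np.ndarray]:
    """Mean PC coordinates per labelled group."""
    labels = np.asarray(labels)
    return {g: coords[labels == g].mean(axis=0) for g in pd.unique(labels)}


def assign_ancestry(
    coords: np.ndarray,
    reference_centroids: Mapping[str, np.ndarray],
    admixed_margin: float = 0.5,
    sample_ids=None,
) -> list[AncestryAssignment]:
    """Nearest-centroid assignment in PC space.

    A sample whose nearest/second-nearest centroid distance ratio exceeds
    ``admixed_margin`` has no clear majority ancestry and is labelled
    ``Admixed`` (an exactly equidistant sample always is).
    """
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if np.isnan(coords).any():
        raise ValueError("missing PC coordinates")
    groups = list(reference_centroids)
    if len(groups) < 2:
        raise ValueError("need centroids for >= 2 groups")
    cents = np.stack([np.asarray(reference_centroids[g], dtype=float) for g in groups])
    if sample_ids is None:
        sample_ids = [str(i) for i in range(len(coords))]
    out = []
    for sid, c in zip(sample_ids, coords):
        d = np.linalg.norm(cents - c[None, : cents.shape[1]], axis=1)
        order = np.argsort(d)
        d1, d2 = d[order[0]], d[order[1]]
        ratio = d1 / d2 if d2 > 0 else 1.0
        group = "Admixed" if ratio > admixed_margin else groups[order[0]]
        out.append(AncestryAssignment(str(sid), group, c))
    return out


# ---------------------------------------------------------------------------
# PC1 sliding windows
# ---------------------------------------------------------------------------

def sliding_windows(n_individuals: int, spec: WindowSpec = WindowSpec()) -> list[np.ndarray]:
    """Complete fixed-size windows over ranks 0..n-1 with starts 0, step, 2*step...

    Only full windows are returned: count = floor((n - size)/step) + 1.
    """
    size, step = spec.window_size, spec.step
    if n_individuals < size:
        raise ValueError(f"n={n_individuals} smaller than window size {size}")
    n_windows = (n_individuals - size) // step + 1
    return [np.arange(s * step, s * step + size) for s in range(n_windows)]


def windowed_association(
    pc1,
    trait,
    cn,
    covariates=None,
    spec: WindowSpec = WindowSpec(),
    binary: bool = False,
    within_window_transform: bool = True,
) -> pd.DataFrame:
    """Re-fit the CN-trait model inside PC1-ranked sliding windows.

    Individuals are ranked by PC1; within each window the trait is
    outlier-filtered (3 SD) and inverse-normal transformed (unless
    ``within_window_transform`` is off or the outcome is binary), then
    regressed on CN plus covariates — ordinary least squares for
    quantitative traits, logistic for binary outcomes.  Windows where CN
    is constant are flagged and skipped.
    """
    import statsmodels.api as sm

    pc1 = np.asarray(pc1, dtype=float)
    trait = np.asarray(trait, dtype=float)
    cn = np.asarray(cn, dtype=float)
    C = None
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
    order = np.argsort(pc1, kind="mergesort")
    rows = []
    for w_idx, window in enumerate(sliding_windows(len(pc1), spec)):
        sel = order[window]
        t, x = trait[sel], cn[sel]
        Cw = C[sel] if C is not None else None
        if np.all(x == x[0]):
            rows.append(
                dict(window=w_idx, n=len(sel), beta=np.nan, se=np.nan, p=np.nan,
                     mean_pc1=float(pc1[sel].mean()), flag="constant_cn")
            )
            continue
        if binary:
            res = logistic_fit(t, x, Cw)
            rows.append(
                dict(window=w_idx, n=res.n, beta=res.beta, se=res.se, p=res.p,
                     odds_ratio=res.odds_ratio, mean_pc1=float(pc1[sel].mean()),
                     flag="")
            )
            continue
        if within_window_transform:
            tv = remove_outliers(t)
            keep_mask = np.abs(t - np.nanmean(t)) <= 3 * np.nanstd(t, ddof=1)
            x_w = x[keep_mask]
            Cw_w = Cw[keep_mask] if Cw is not None else None
            t_w = inverse_normal(tv).values
        else:
            t_w, x_w, Cw_w = t, x, Cw
        design = [np.ones(len(t_w)), x_w]
        if Cw_w is not None:
            design.append(Cw_w)
        X = np.column_stack(design)
        fit = sm.OLS(t_w, X).fit()
        rows.append(
            dict(window=w_idx, n=len(t_w), beta=float(fit.params[1]),
                 se=float(fit.bse[1]), p=float(fit.pvalues[1]),
                 mean_pc1=float(pc1[sel].mean()), flag="")
        )
    return pd.DataFrame(rows)
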