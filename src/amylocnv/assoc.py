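"""Kinship-aware association testing, heritability, and related statistics.

The core model is a variance-component (animal-model) regression

    y = X b + x beta + g + e,     g ~ N(0, sigma2_g * A),   e ~ N(0, sigma2_e * I)

where ``A = grm_factor * Phi`` is the genetic relationship matrix built from
the pairwise kinship matrix ``Phi`` (``grm_factor`` defaults to 2, so an
outbred individual has A_ii = 1 and narrow-sense heritability is
``h2 = sigma2_g / (sigma2_g + sigma2_e)``).  Variance components are
estimated by restricted maximum likelihood, profiled over the variance
ratio ``delta = sigma2_e / sigma2_g`` after an eigendecomposition of A
(EMMA-style).  Because kinship matrices thresholded at phi < 0.05 are
block-diagonal over family clusters, the decomposition is performed per
connected component, which makes replicate-heavy simulation studies cheap.

Also provided: the trait-preprocessing conventions (single-pass 3-SD
outlier removal, then rank-based inverse-normal transformation), kinship
thresholding, Bonferroni accounting, logistic case/control models,
polychoric correlation for ordinal copy-number tables, and the Wilcoxon /
chi-square descriptive tests.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.sparse
import scipy.sparse.csgraph
import scipy.stats
import statsmodels.api as sm

__all__ = [
    "TraitVector",
    "KinshipMatrix",
    "AssocResult",
    "HeritabilityEstimate",
    "LMMFit",
    "KinshipEigen",
    "remove_outliers",
    "inverse_normal",
    "threshold_kinship",
    "lmm_fit",
    "heritability",
    "bonferroni_threshold",
    "round_sig",
    "LogisticResult",
    "logistic_fit",
    "dichotomize_bmi",
    "PolychoricResult",
    "polychoric",
    "ordinal_table",
    "wilcoxon_rank_sum",
    "chi_square_test",
]


# ---------------------------------------------------------------------------
# trait preprocessing
# ---------------------------------------------------------------------------

@dataclass
class TraitVector:
    """A named trait with its sample keys and transformation state."""

    values: np.ndarray
    sample_ids: np.ndarray | None = None
    transform_state: str = "raw"
    n_removed: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.sample_ids is not None:
            self.sample_ids = np.asarray(self.sample_ids)
            if len(self.sample_ids) != len(self.values):
                raise ValueError("sample_ids and values length mismatch")


def _as_trait(trait) -> TraitVector:
    if isinstance(trait, TraitVector):
        return trait
    return TraitVector(np.asarray(trait, dtype=float))


def remove_outliers(trait, k: float = 3.0) -> TraitVector:
    """Single-pass removal of values more than ``k`` SD from the full-input mean.

    Mean and SD come from the complete input (not re-estimated after each
    removal).  A zero-variance input is returned unchanged with a warning.
    """
    tv = _as_trait(trait)
    x = tv.values
    if np.sum(np.isfinite(x)) < 3:
        raise ValueError("need >= 3 non-missing values for outlier removal")
    mu = np.nanmean(x)
    sd = np.nanstd(x, ddof=1)
    if sd == 0:
        warnings.warn("zero-variance trait; outlier removal skipped")
        return TraitVector(x.copy(), tv.sample_ids, "outlier-filtered", 0)
    keep = np.abs(x - mu) <= k * sd
    keep &= np.isfinite(x)
    ids = tv.sample_ids[keep] if tv.sample_ids is not None else None
    return TraitVector(x[keep], ids, "outlier-filtered", int(np.sum(~keep)))


def inverse_normal(trait, offset: str = "half") -> TraitVector:
    """Rank-based inverse-normal transformation.

    ``offset='half'`` maps rank r (average ranks for ties) to
    Phi^-1((r - 0.5)/n); ``offset='blom'`` uses (r - 3/8)/(n + 1/4).
    The output is monotone in the input and approximately standard normal.
    """
    tv = _as_trait(trait)
    x = tv.values
    if np.unique(x).size < 2:
        raise ValueError("inverse-normal transform undefined for all-tied input")
    r = scipy.stats.rankdata(x, method="average")
    n = len(x)
    if offset == "half":
        q = (r - 0.5) / n
    elif offset == "blom":
        q = (r - 3.0 / 8.0) / (n + 0.25)
    else:
        raise ValueError(f"unknown offset {offset!r}")
    y = scipy.stats.norm.ppf(q)
    return TraitVector(y, tv.sample_ids, "inverse-normal", tv.n_removed)


# ---------------------------------------------------------------------------
# kinship
# ---------------------------------------------------------------------------

@dataclass
class KinshipMatrix:
    """Symmetric pairwise kinship coefficients (diagonal 0.5 for outbred)."""

    values: np.ndarray
    sample_ids: np.ndarray | None = None
    threshold: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("kinship matrix must be square")


def threshold_kinship(kinship, threshold: float = 0.05):
    """Zero out off-diagonal kinship below ``threshold`` (pairs treated as
    unrelated).  Exactly-threshold values are retained (strict < rule)."""
    if isinstance(kinship, KinshipMatrix):
        out = threshold_kinship(kinship.values, threshold)
        return KinshipMatrix(out, kinship.sample_ids, threshold)
    K = np.asarray(kinship, dtype=float)
    if K.ndim != 2 or K.shape[0] != K.shape[1]:
        raise ValueError("kinship matrix must be square")
    if not np.allclose(K, K.T, atol=1e-10):
        raise ValueError("kinship matrix must be symmetric")
    out = K.copy()
    off = ~np.eye(K.shape[0], dtype=bool)
    out[off & (out < threshold)] = 0.0
    return out


# ---------------------------------------------------------------------------
# REML linear mixed model
# ---------------------------------------------------------------------------

class KinshipEigen:
    """Eigendecomposition of a GRM, computed per connected (family) block.

    Thresholded kinship matrices from family cohorts decompose into small
    diagonal blocks; eigendecomposing each block separately turns an
    O(n^3) factorization into O(sum of block sizes cubed) and lets one
    decomposition be reused across many phenotype replicates.
    """

    def __init__(self, grm: np.ndarray):
        A = np.asarray(grm, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(A, A.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")
        n = A.shape[0]
        pattern = scipy.sparse.csr_matrix((np.abs(A) > 0).astype(np.int8))
        n_comp, labels = scipy.sparse.csgraph.connected_components(
            pattern, directed=False
        )
        self.n = n
        self.blocks: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        eigs = []
        order = []
        for c in range(n_comp):
            idx = np.where(labels == c)[0]
            sub = A[np.ix_(idx, idx)]
            s, U = np.linalg.eigh(sub)
            if s.min() < -1e-6 * max(1.0, s.max()):
                raise ValueError(
                    "GRM is not positive semidefinite "
                    f"(min eigenvalue {s.min():.3g}); consider adding a small "
                    "diagonal jitter"
                )
            s = np.clip(s, 0.0, None)
            self.blocks.append((idx, U, s))
            eigs.append(s)
            order.append(idx)
        self.eigenvalues = np.concatenate(eigs)
        self.order = np.concatenate(order)

    def rotate(self, v: np.ndarray) -> np.ndarray:
        """Apply U^T to a vector or (n, p) matrix, rows in block order."""
        v = np.asarray(v, dtype=float)
        out = np.empty_like(v)
        pos = 0
        for idx, U, _ in self.blocks:
            out[pos : pos + len(idx)] = U.T @ v[idx]
            pos += len(idx)
        return out


@dataclass(frozen=True)
class AssocResult:
    predictor: str
    trait: str
    n: int
    beta: float
    se: float
    p: float
    method: str = "lmm-reml"


@dataclass(frozen=True)
class HeritabilityEstimate:
    trait: str
    sigma2_g: float
    sigma2_e: float

    @property
    def h2(self) -> float:
        total = self.sigma2_g + self.sigma2_e
        return self.sigma2_g / total if total > 0 else 0.0


@dataclass(frozen=True)
class LMMFit:
    """Full result of one REML fit (association + variance components)."""

    n: int
    beta: np.ndarray
    se: np.ndarray
    sigma2_g: float
    sigma2_e: float
    h2: float
    loglik: float
    assoc: AssocResult | None = None


def _reml_profile(delta: float, s: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profile REML log-likelihood (up to a constant) at variance ratio delta."""
    w = 1.0 / (s + delta)
    XtW = Xt * w[:, None]
    XtWX = Xt.T @ XtW
    XtWy = XtW.T @ yt
    L = scipy.linalg.cho_factor(XtWX)
    beta = scipy.linalg.cho_solve(L, XtWy)
    r = yt - Xt @ beta
    R = float(np.sum(w * r * r))
    n, p = Xt.shape
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(L[0]))))
    ll = -0.5 * ((n - p) * math.log(R) + float(np.sum(np.log(s + delta))) + logdet_XtWX)
    return ll, beta, R, XtWX


def lmm_fit(
    y,
    X=None,
    kinship=None,
    predictor=None,
    *,
    grm_factor: float = 2.0,
    eigen: KinshipEigen | None = None,
    trait_name: str = "trait",
    predictor_name: str = "cn",
    max_iter: int = 200,
    tol: float = 1e-8,
) -> LMMFit:
    """REML fit of the kinship variance-component model.

    Parameters
    ----------
    y : array
        Trait values (typically inverse-normal transformed).
    X : array or None
        Covariate matrix WITHOUT an intercept column (one is added).
    kinship : array or KinshipMatrix
        Thresholded pairwise kinship; the GRM used is ``grm_factor * Phi``.
        Ignored when ``eigen`` is supplied.
    predictor : array or None
        Focal predictor (e.g. AMY1 copy number).  When given, the returned
        ``assoc`` carries its Wald beta/SE and two-sided normal P.
    eigen : KinshipEigen, optional
        Precomputed decomposition, for replicate reuse.

    The variance ratio ``delta = sigma2_e/sigma2_g`` is profiled on a log
    grid and refined by bounded scalar minimization (relative tolerance
    ``tol``, at most ``max_iter`` iterations); the fit is deterministic.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    cols = [np.ones(n)]
    if X is not None:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        cols.append(X)
    if predictor is not None:
        cols.append(np.asarray(predictor, dtype=float).reshape(n, 1))
    Xfull = np.column_stack(cols)
    p = Xfull.shape[1]
    if n < p + 2:
        raise ValueError(f"n={n} too small for {p} fixed effects")

    if eigen is None:
        if kinship is None:
            raise ValueError("either kinship or eigen must be supplied")
        K = kinship.values if isinstance(kinship, KinshipMatrix) else np.asarray(kinship)
        eigen = KinshipEigen(grm_factor * K)
    if eigen.n != n:
        raise ValueError("kinship dimension does not match trait length")

    s = eigen.eigenvalues
    yt = eigen.rotate(y)
    Xt = eigen.rotate(Xfull)

    def neg_ll(log_delta: float) -> float:
        return -_reml_profile(math.exp(log_delta), s, yt, Xt)[0]

    grid = np.linspace(-12.0, 12.0, 49)
    vals = np.array([neg_ll(g) for g in grid])
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, len(grid) - 1)]
    res = scipy.optimize.minimize_scalar(
        neg_ll,
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": tol, "maxiter": max_iter},
    )
    if not res.success and not np.isfinite(res.fun):
        raise RuntimeError(f"REML optimization failed to converge: {res}")
    delta = math.exp(res.x)
    ll, beta, R, XtWX = _reml_profile(delta, s, yt, Xt)
    sigma2_g = R / (n - p)
    sigma2_e = delta * sigma2_g
    h2 = 1.0 / (1.0 + delta)
    cov_beta = sigma2_g * np.linalg.inv(XtWX)
    se = np.sqrt(np.diag(cov_beta))

    assoc = None
    if predictor is not None:
        b1, se1 = float(beta[-1]), float(se[-1])
        z = b1 / se1
        assoc = AssocResult(
            predictor=predictor_name,
            trait=trait_name,
            n=n,
            beta=b1,
            se=se1,
            p=float(2.0 * scipy.stats.norm.sf(abs(z))),
        )
    return LMMFit(
        n=n,
        beta=beta,
        se=se,
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        h2=h2,
        loglik=ll,
        assoc=assoc,
    )


def heritability(
    y, X=None, kinship=None, *, grm_factor: float = 2.0,
    eigen: KinshipEigen | None = None, trait_name: str = "trait",
) -> HeritabilityEstimate:
    """Variance components from the null (no focal predictor) REML fit."""
    fit = lmm_fit(
        y, X, kinship, None, grm_factor=grm_factor, eigen=eigen, trait_name=trait_name
    )
    return HeritabilityEstimate(trait_name, fit.sigma2_g, fit.sigma2_e)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bonferroni_threshold(
    alpha: float = 0.05, n_outcomes: int = 1, n_predictors_or_groups: int = 1
) -> float:
    """alpha / (n_outcomes * n_predictors_or_groups), exact via rationals."""
    if n_outcomes <= 0 or n_predictors_or_groups <= 0:
        raise ValueError("test counts must be positive integers")
    frac = Fraction(alpha).limit_denominator(10**9) / (
        n_outcomes * n_predictors_or_groups
    )
    return float(frac)


def round_sig(x: float, digits: int = 3) -> float:
    """Round to ``digits`` significant digits (display convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + digits - 1)


# ---------------------------------------------------------------------------
# logistic case/control model
# ---------------------------------------------------------------------------

class SeparationError(RuntimeError):
    pass


@dataclass(frozen=True)
class LogisticResult:
    n: int
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    p: float


def logistic_fit(outcome, predictor, covariates=None) -> LogisticResult:
    """Maximum-likelihood logistic regression of a binary outcome on a
    copy-number predictor (plus covariates); Wald 95% CI on the OR scale."""
    y = np.asarray(outcome, dtype=float).ravel()
    classes = np.unique(y)
    if not np.array_equal(np.sort(classes), [0.0, 1.0]):
        raise ValueError("outcome must contain both classes coded 0/1")
    x = np.asarray(predictor, dtype=float).reshape(-1, 1)
    design = [np.ones((len(y), 1)), x]
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        design.append(C)
    X = np.column_stack(design)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
        except Exception as exc:  # statsmodels raises on perfect separation
            raise SeparationError(
                "logistic fit failed (possible complete separation); "
                "consider a penalized model"
            ) from exc
    beta = float(fit.params[1])
    se = float(fit.bse[1])
    if not np.isfinite(se) or abs(beta) > 20:
        raise SeparationError(
            "degenerate logistic estimates suggest separation; "
            "consider a penalized model"
        )
    z = scipy.stats.norm.ppf(0.975)
    return LogisticResult(
        n=len(y),
        beta=beta,
        se=se,
        odds_ratio=math.exp(beta),
        ci_low=math.exp(beta - z * se),
        ci_high=math.exp(beta + z * se),
        p=float(fit.pvalues[1]),
    )


def dichotomize_bmi(
    bmi, case_min: float = 30.0, control_max: float = 25.0
) -> tuple[np.ndarray, np.ndarray]:
    """Obesity case/control coding: BMI >= 30 cases, BMI < 25 controls,
    intermediate band excluded.  Returns (labels, included_mask)."""
    b = np.asarray(bmi, dtype=float)
    cases = b >= case_min
    controls = b < control_max
    mask = cases | controls
    return cases[mask].astype(int), mask


# ---------------------------------------------------------------------------
# polychoric correlation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PolychoricResult:
    rho: float
    p: float
    loglik: float
    row_thresholds: np.ndarray
    col_thresholds: np.ndarray


def ordinal_table(x, y) -> np.ndarray:
    """Contingency table of two ordinal variables (categories sorted)."""
    return pd.crosstab(pd.Series(x), pd.Series(y)).to_numpy()


def _bvn_rect_probs(rho: float, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Cell probabilities of a standard bivariate normal over the grid with
    row cut-points ``a`` and column cut-points ``b`` (inner thresholds)."""
    CLIP = 8.0
    aa = np.concatenate(([-CLIP], np.clip(a, -CLIP, CLIP), [CLIP]))
    bb = np.concatenate(([-CLIP], np.clip(b, -CLIP, CLIP), [CLIP]))
    mvn = scipy.stats.multivariate_normal(
        mean=[0.0, 0.0], cov=[[1.0, rho], [rho, 1.0]]
    )
    G = np.array([[mvn.cdf([u, v]) for v in bb] for u in aa])
    probs = G[1:, 1:] - G[:-1, 1:] - G[1:, :-1] + G[:-1, :-1]
    return np.clip(probs, 1e-300, None)


def polychoric(table) -> PolychoricResult:
    """Two-step polychoric correlation of an ordinal contingency table.

    Marginal thresholds come from cumulative proportions via the normal
    quantile; the latent correlation maximizes the bivariate-normal cell
    likelihood.  The P-value is a likelihood-ratio test against rho = 0.
    Empty margin categories are collapsed away with a warning.
    """
    T = np.asarray(table, dtype=float)
    if T.ndim != 2:
        raise ValueError("table must be 2-dimensional")
    keep_r = T.sum(axis=1) > 0
    keep_c = T.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn("collapsing empty margin categories")
        T = T[keep_r][:, keep_c]
    if T.shape[0] < 2 or T.shape[1] < 2:
        raise ValueError("need >= 2 non-empty categories on each margin")
    n = T.sum()
    a = scipy.stats.norm.ppf(np.cumsum(T.sum(axis=1))[:-1] / n)
    b = scipy.stats.norm.ppf(np.cumsum(T.sum(axis=0))[:-1] / n)

    def neg_ll(rho: float) -> float:
        return -float(np.sum(T * np.log(_bvn_rect_probs(rho, a, b))))

    res = scipy.optimize.minimize_scalar(
        neg_ll, bounds=(-0.999, 0.999), method="bounded", options={"xatol": 1e-6}
    )
    rho_hat = float(res.x)
    ll1 = -float(res.fun)
    ll0 = -neg_ll(0.0)
    lrt = max(0.0, 2.0 * (ll1 - ll0))
    p = float(scipy.stats.chi2.sf(lrt, df=1))
    return PolychoricResult(rho_hat, p, ll1, a, b)


# ---------------------------------------------------------------------------
# descriptive group tests
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(x, y, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) P-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    return float(
        scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue
    )


def chi_square_test(table) -> float:
    """Chi-square P-value for a categorical contingency table (no Yates)."""
    T = np.asarray(table, dtype=float)
    return float(scipy.stats.chi2_contingency(T, correction=False).pvalue)
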