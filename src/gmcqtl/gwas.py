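"""Mixed-linear-model association scan for the GMC traits.

The model for a trait vector ``y`` over ``n`` accessions is

    y = X b + Z g + e,   g ~ N(0, sigma2_g K),   e ~ N(0, sigma2_e I)

with ``K`` the VanRaden genomic relationship matrix and ``X`` an intercept
plus optional principal-component covariates.  Variance components are
estimated once by REML through a single eigendecomposition of ``K`` and a
1-D Brent search over ``delta = sigma2_e / sigma2_g`` (the EMMA device); the
per-SNP test is a generalized-least-squares F test of the dosage effect,
reusing the null variance components for every SNP ("P3D").

Effects are reported under the major-allele-zero convention: the estimate
attached to each SNP (the favorable allele effect, FAE) is the effect of one
copy of the minor allele, with the major allele as zero reference, so its
sign says whether the germplasm minor allele raises or lowers the trait.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .core_io import MISSING, DegenerateInputError, GenotypeMatrix

logger = logging.getLogger("gmcqtl")

_LOG10_DELTA_BOUNDS = (-5.0, 5.0)
_BRENT_XATOL = 1e-8


# ---------------------------------------------------------------------------
# Kinship and PCA
# ---------------------------------------------------------------------------

def _imputed_dosage(G: GenotypeMatrix) -> np.ndarray:
    """Dosage as float with missing calls mean-imputed per SNP."""
    d = G.dosage.astype(float)
    miss = G.dosage == MISSING
    if miss.any():
        d[miss] = np.nan
        col_mean = np.nanmean(d, axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        d = np.where(np.isnan(d), col_mean[None, :], d)
    return d


def vanraden_kinship(G: GenotypeMatrix) -> np.ndarray:
    """VanRaden genomic relationship matrix K = Z Z' / (2 sum p(1-p)).

    Z is the allele-frequency-centered dosage matrix; monomorphic SNPs are
    excluded (they contribute nothing to Z and would zero the denominator).
    Missing dosages are mean-imputed per SNP before centering.
    """
    if G.n_accessions < 2:
        raise DegenerateInputError("kinship needs at least 2 accessions")
    d = _imputed_dosage(G)
    p = d.mean(axis=0) / 2.0
    poly = (p > 0.0) & (p < 1.0)
    if not poly.any():
        raise DegenerateInputError("all SNPs monomorphic; kinship undefined")
    d = d[:, poly]
    p = p[poly]
    Z = d - 2.0 * p[None, :]
    denom = 2.0 * np.sum(p * (1.0 - p))
    K = (Z @ Z.T) / denom
    return (K + K.T) / 2.0


@dataclass
class CovariateSet:
    """Fixed-effect design: intercept plus optional PC score columns."""

    matrix: np.ndarray  # n x (1 + k)
    names: list[str]

    @property
    def n_pcs(self) -> int:
        return self.matrix.shape[1] - 1


def genotype_pca(G: GenotypeMatrix, k: int, scale: bool = False) -> CovariateSet:
    """Top-k principal-component scores of the centered dosage matrix.

    Sign convention: each PC is flipped so that its largest-magnitude SNP
    loading is positive, making scores deterministic.  ``k <= 0`` yields an
    intercept-only covariate set.
    """
    n = G.n_accessions
    if k >= n:
        raise ValueError(f"k={k} must be < number of accessions ({n})")
    ones = np.ones((n, 1))
    if k <= 0:
        return CovariateSet(ones, ["intercept"])
    d = _imputed_dosage(G)
    Z = d - d.mean(axis=0, keepdims=True)
    if scale:
        sd = Z.std(axis=0)
        Z = Z[:, sd > 0] / sd[sd > 0]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    k = min(k, len(s))
    scores = U[:, :k] * s[:k]
    for j in range(k):
        load = Vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return CovariateSet(np.hstack([ones, scores]),
                        ["intercept"] + [f"PC{j + 1}" for j in range(k)])


# ---------------------------------------------------------------------------
# REML via eigendecomposition (EMMA)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    delta: float          # sigma2_e / sigma2_g
    loglik: float         # REML log-likelihood at the optimum
    delta_identifiable: bool = True

    @property
    def h2(self) -> float:
        return self.sigma2_g / (self.sigma2_g + self.sigma2_e)


def _eigendecompose(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() < -1e-8 * max(1.0, s.max()):
        raise ValueError(f"kinship not PSD (min eigenvalue {s.min():.3g})")
    return np.clip(s, 0.0, None), U


def _reml_profile(delta: float, s: np.ndarray, ys: np.ndarray, Xs: np.ndarray,
                  logdet_xtx: float, ml: bool = False) -> tuple[float, float]:
    """Profiled (RE)ML log-likelihood and sigma2_g at a given delta.

    Works in the eigenbasis of K: V = sigma2_g * diag(s + delta).
    """
    n, p = Xs.shape
    w = 1.0 / (s + delta)
    XtWX = Xs.T @ (w[:, None] * Xs)
    XtWy = Xs.T @ (w * ys)
    beta = np.linalg.solve(XtWX, XtWy)
    r = ys - Xs @ beta
    rss = float(np.sum(w * r * r))
    logdet_v = float(np.sum(np.log(s + delta)))
    if ml:
        sigma2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + n + logdet_v)
    else:
        sigma2 = rss / (n - p)
        sign, logdet_xwx = np.linalg.slogdet(XtWX)
        ll = -0.5 * ((n - p) * np.log(2 * np.pi * sigma2) + (n - p)
                     + logdet_v + logdet_xwx - logdet_xtx)
    return ll, sigma2


def fit_null_reml(y: np.ndarray, X: CovariateSet | np.ndarray, K: np.ndarray,
                  eig: tuple[np.ndarray, np.ndarray] | None = None,
                  ml: bool = False) -> VarianceComponents:
    """REML (or ML) variance components of the null model y = Xb + g + e.

    One eigendecomposition of K, then Brent minimization of the negative
    profiled likelihood over log10(delta) in [-5, 5].
    """
    Xm = X.matrix if isinstance(X, CovariateSet) else np.asarray(X, float)
    y = np.asarray(y, float)
    s, U = eig if eig is not None else _eigendecompose(K)
    ys = U.T @ y
    Xs = U.T @ Xm
    _, logdet_xtx = np.linalg.slogdet(Xm.T @ Xm)

    def neg_ll(log10_delta: float) -> float:
        return -_reml_profile(10.0 ** log10_delta, s, ys, Xs, logdet_xtx, ml)[0]

    res = optimize.minimize_scalar(neg_ll, bounds=_LOG10_DELTA_BOUNDS,
                                   method="bounded",
                                   options={"xatol": _BRENT_XATOL})
    cands = [res.x, *_LOG10_DELTA_BOUNDS]
    vals = [neg_ll(c) for c in cands]
    best = cands[int(np.argmin(vals))]
    delta = 10.0 ** best
    ll, sigma2_g = _reml_profile(delta, s, ys, Xs, logdet_xtx, ml)

    # flat profile (e.g. K = I): only sigma2_g * (1 + delta) is identified
    lo = -neg_ll(_LOG10_DELTA_BOUNDS[0])
    hi = -neg_ll(_LOG10_DELTA_BOUNDS[1])
    identifiable = (max(abs(ll - lo), abs(ll - hi)) > 1e-6)
    if not identifiable:
        logger.info("delta unidentifiable (flat REML profile); any split of "
                    "total variance along the ridge is equivalent")
    return VarianceComponents(sigma2_g, delta * sigma2_g, delta, ll,
                              identifiable)


def select_pcs_bic(y: np.ndarray, G: GenotypeMatrix, K: np.ndarray,
                   k_max: int,
                   eig: tuple[np.ndarray, np.ndarray] | None = None) -> int:
    """Number of PC covariates (0..k_max) minimizing BIC of the null model.

    BIC = -2 * ML log-likelihood + n_par * log(n); ties go to the smaller k.
    """
    if k_max <= 0:
        return 0
    y = np.asarray(y, float)
    keep = ~np.isnan(y)
    Gk = G.take_accessions(np.nonzero(keep)[0]) if not keep.all() else G
    Kk = K[np.ix_(keep, keep)] if not keep.all() else K
    yk = y[keep]
    eig = _eigendecompose(Kk) if (eig is None or not keep.all()) else eig
    pcs = genotype_pca(Gk, k_max)
    n = len(yk)
    best_k, best_bic = 0, np.inf
    for k in range(k_max + 1):
        Xk = pcs.matrix[:, :k + 1]
        vc = fit_null_reml(yk, Xk, Kk, eig=eig, ml=True)
        n_par = (k + 1) + 2
        bic = -2.0 * vc.loglik + n_par * np.log(n)
        if bic < best_bic - 1e-12:
            best_bic, best_k = bic, k
    return best_k


# ---------------------------------------------------------------------------
# Association scan
# ---------------------------------------------------------------------------

ASSOC_COLUMNS = ["snp", "chrom", "pos", "maf", "n_used", "beta", "fae", "se",
                 "minus_log10_p", "flag"]


def estimate_fae(beta_alt: float, alt_freq: float) -> tuple[float, str]:
    """Favorable allele effect from the ALT-dosage effect estimate.

    The reference allele is frequency-defined (the major allele is zero);
    the reported effect is per copy of the minor allele.  At an exact 0.5
    tie the REF allele is kept as reference (effect allele = ALT), logged.
    """
    if alt_freq == 0.5:
        logger.info("allele frequencies tied at 0.5; REF kept as reference")
        return beta_alt, "freq_tie"
    if alt_freq < 0.5:
        return beta_alt, ""
    return -beta_alt, ""


def scan_mlm(y: np.ndarray, X: CovariateSet | np.ndarray, K: np.ndarray,
             G: GenotypeMatrix, p3d: bool = True,
             maf_threshold: float = 0.01) -> pd.DataFrame:
    """GLS association scan of every SNP against trait vector ``y``.

    Accessions with missing phenotype are dropped globally; accessions with
    a missing dosage are dropped per SNP (case-wise deletion).  SNPs below
    the MAF threshold are emitted untested with flag ``low_maf``.  With
    ``p3d=True`` (default) the null variance components are reused for all
    SNPs; ``p3d=False`` re-estimates delta per SNP.
    """
    Xm = X.matrix if isinstance(X, CovariateSet) else np.asarray(X, float)
    y = np.asarray(y, float)
    keep = ~np.isnan(y)
    if not keep.all():
        G = G.take_accessions(np.nonzero(keep)[0])
        Xm = Xm[keep]
        K = K[np.ix_(keep, keep)]
        y = y[keep]
    n, p = Xm.shape

    s, U = _eigendecompose(K)
    vc = fit_null_reml(y, Xm, K, eig=(s, U))
    delta = vc.delta

    ys = U.T @ y
    Xs = U.T @ Xm
    w = 1.0 / (s + delta)

    dosage = G.dosage
    miss = dosage == MISSING
    n_used = n - miss.sum(axis=0)
    d = dosage.astype(float)
    d[miss] = np.nan
    with np.errstate(invalid="ignore"):
        alt_freq = np.nanmean(d, axis=0) / 2.0
    maf = np.minimum(alt_freq, 1.0 - alt_freq)

    beta = np.full(G.n_snps, np.nan)
    se = np.full(G.n_snps, np.nan)
    mlp = np.full(G.n_snps, np.nan)
    flags = np.array([""] * G.n_snps, dtype=object)

    testable = maf >= maf_threshold
    flags[~testable] = "low_maf"

    complete = ~miss.any(axis=0)
    fast = testable & complete & (True if p3d else False)

    if p3d and fast.any():
        Gs = U.T @ dosage[:, fast].astype(float)
        wX = w[:, None] * Xs
        A = Xs.T @ wX                           # p x p
        Ainv = np.linalg.inv(A)
        Xwy = Xs.T @ (w * ys)
        yWy = float(np.sum(w * ys * ys))
        yMy = yWy - Xwy @ Ainv @ Xwy
        GwX = Gs.T @ wX                          # m x p
        gWg = np.einsum("ij,i,ij->j", Gs, w, Gs)
        gWy = Gs.T @ (w * ys)
        GA = GwX @ Ainv
        gMg = gWg - np.einsum("ij,ij->i", GA, GwX)
        gMy = gWy - GA @ Xwy
        dfree = n - p - 1
        with np.errstate(divide="ignore", invalid="ignore"):
            b = gMy / gMg
            rss = yMy - b * gMy
            sigma2 = rss / dfree
            fstat = b * b * gMg / sigma2
            serr = np.sqrt(sigma2 / gMg)
        pval = stats.f.sf(fstat, 1, dfree)
        idx = np.nonzero(fast)[0]
        beta[idx] = b
        se[idx] = serr
        mlp[idx] = -np.log10(np.clip(pval, 1e-320, None))
        degen = ~np.isfinite(fstat)
        flags[idx[degen]] = "degenerate"
        mlp[idx[degen]] = np.nan

    slow = testable & ~fast
    for j in np.nonzero(slow)[0]:
        ok = ~miss[:, j]
        b, serr, pv = _gls_single(y[ok], Xm[ok], K[np.ix_(ok, ok)],
                                  d[ok, j], None if not p3d else delta)
        beta[j], se[j] = b, serr
        if np.isfinite(pv):
            mlp[j] = -np.log10(max(pv, 1e-320))
        else:
            flags[j] = "degenerate"

    fae = np.full(G.n_snps, np.nan)
    for j in range(G.n_snps):
        if np.isfinite(beta[j]):
            fae[j], tie = estimate_fae(float(beta[j]), float(alt_freq[j]))
            if tie and not flags[j]:
                flags[j] = tie

    return pd.DataFrame({
        "snp": [sn.id for sn in G.snps],
        "chrom": [sn.chrom for sn in G.snps],
        "pos": [sn.pos for sn in G.snps],
        "maf": maf,
        "n_used": n_used,
        "beta": beta,
        "fae": fae,
        "se": se,
        "minus_log10_p": mlp,
        "flag": flags,
    }, columns=ASSOC_COLUMNS)


def _gls_single(y: np.ndarray, Xm: np.ndarray, K: np.ndarray, g: np.ndarray,
                delta: float | None) -> tuple[float, float, float]:
    """Dense GLS F-test of one SNP (used for missing-dosage subsets and the
    per-SNP re-estimation path)."""
    if delta is None:
        vc = fit_null_reml(y, Xm, K)
        delta = vc.delta
    n = len(y)
    Xfull = np.column_stack([Xm, g])
    p_full = Xfull.shape[1]
    V = K + delta * np.eye(n)
    c, low = cho_factor(V)
    Vinv_X = cho_solve((c, low), Xfull)
    Vinv_y = cho_solve((c, low), y)
    A = Xfull.T @ Vinv_X
    try:
        coef = np.linalg.solve(A, Xfull.T @ Vinv_y)
        Ainv = np.linalg.inv(A)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan
    r = y - Xfull @ coef
    rss = float(r @ cho_solve((c, low), r))
    dfree = n - p_full
    if dfree <= 0 or Ainv[-1, -1] <= 0 or rss <= 0:
        return float(coef[-1]), np.nan, np.nan
    sigma2 = rss / dfree
    serr = np.sqrt(sigma2 * Ainv[-1, -1])
    fstat = (coef[-1] / serr) ** 2
    return float(coef[-1]), float(serr), float(stats.f.sf(fstat, 1, dfree))


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def genomic_control_lambda(assoc: pd.DataFrame) -> float:
    """Genomic-inflation factor: median association chi2 over its null median."""
    mlp = assoc["minus_log10_p"].to_numpy(float)
    mlp = mlp[np.isfinite(mlp)]
    if mlp.size == 0:
        return np.nan
    pvals = np.power(10.0, -mlp)
    chi2 = stats.chi2.isf(np.clip(pvals, 1e-320, 1.0), df=1)
    return float(np.median(chi2) / stats.chi2.isf(0.5, df=1))


def write_association(assoc: pd.DataFrame, path) -> None:
    out = assoc.copy()
    for c in ("maf", "beta", "fae", "se", "minus_log10_p"):
        out[c] = out[c].map(lambda v: "." if not np.isfinite(v) else format(v, ".6g"))
    out.to_csv(path, sep="\t", index=False)


def read_association(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["."],
                     dtype={"chrom": str, "flag": str})
    df["flag"] = df["flag"].fillna("")
    return df
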