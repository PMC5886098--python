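"""LD score regression: SNP heritability, cross-trait genetic
correlation and the sample-overlap intercept, plus the direct
null-SNP Z-score correlation estimate of overlap.

The univariate regression fits E[chi2_j] = 1 + n_j h2 l_j / m with
heteroskedasticity weights 1/(2 (1 + n h2 l/m)^2), iterated twice from
an OLS start.  The bivariate regression fits
E[z1 z2] = c + sqrt(n1 n2) gcov l / m, whose intercept c estimates the
shared-sample correlation of the null statistics.  Standard errors
come from a delete-one block jackknife over contiguous SNP blocks
(200 by default, standard practice for this estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .overlap import position_ordered_prune, pvalue_informed_prune
from .sumstats import SumStats


@dataclass
class UnivariateLdscFit:
    h2: float
    h2_se: float
    intercept: float
    intercept_se: float
    n_snps: int
    m: int
    n_blocks: int


@dataclass
class GeneticCorrelationResult:
    """Bivariate LDSC estimates for one trait pair."""

    h2_1: float
    h2_1_se: float
    h2_2: float
    h2_2_se: float
    gcov: float
    gcov_se: float
    rg: float
    rg_se: float
    intercept_1: float
    intercept_2: float
    intercept_cross: float
    intercept_cross_se: float
    p_rg: float
    n_snps_used: int
    n_jackknife_blocks: int

    def to_dict(self) -> dict:
        return {k: (None if isinstance(v, float) and np.isnan(v) else v)
                for k, v in self.__dict__.items()}


def _wls(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Weighted least squares of y on [x, 1]; returns (slope, intercept)."""
    sw = np.sqrt(w)
    X = np.column_stack([x * sw, sw])
    coef, *_ = np.linalg.lstsq(X, y * sw, rcond=None)
    return coef


def _wls_jackknife(x: np.ndarray, y: np.ndarray, w: np.ndarray,
                   n_blocks: int) -> tuple[np.ndarray, np.ndarray]:
    """Full WLS fit plus delete-one-block coefficient estimates.

    Blocks are contiguous runs of SNPs in the given (genomic) order.
    Uses per-block normal-equation sums so each deletion is O(1).
    """
    m = len(x)
    if n_blocks < 2 or n_blocks > m:
        raise ValueError("need 2 <= n_blocks <= number of SNPs")
    X = np.column_stack([x, np.ones(m)])
    bounds = np.linspace(0, m, n_blocks + 1).astype(int)
    A_blocks = np.empty((n_blocks, 2, 2))
    c_blocks = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        sl = slice(bounds[b], bounds[b + 1])
        Xw = X[sl] * w[sl, None]
        A_blocks[b] = Xw.T @ X[sl]
        c_blocks[b] = Xw.T @ y[sl]
    A = A_blocks.sum(axis=0)
    c = c_blocks.sum(axis=0)
    full = np.linalg.solve(A, c)
    deleted = np.empty((n_blocks, 2))
    for b in range(n_blocks):
        deleted[b] = np.linalg.solve(A - A_blocks[b], c - c_blocks[b])
    return full, deleted


def _jackknife_se(deleted: np.ndarray) -> float:
    nb = len(deleted)
    return float(np.sqrt((nb - 1) / nb * ((deleted - deleted.mean()) ** 2).sum()))


def _regression_inputs(s: SumStats, l: pd.Series):
    li = l.reindex(s.df.index)
    mask = li.notna().to_numpy()
    z = s.df["z"].to_numpy()[mask]
    n = s.df["n"].to_numpy()[mask]
    return z, n, li.to_numpy()[mask], mask


def _snp_filter(s: SumStats) -> SumStats:
    """Standard pre-regression hygiene where the fields exist:
    info > 0.9 and eaf in (0.01, 0.99); no-op otherwise."""
    keep = np.ones(len(s), dtype=bool)
    info = s.df["info"]
    eaf = s.df["eaf"]
    if info.notna().any():
        keep &= (info > 0.9).fillna(False).to_numpy()
    if eaf.notna().any():
        keep &= eaf.between(0.01, 0.99, inclusive="neither").fillna(False).to_numpy()
    return s.subset(s.df.index[keep]) if not keep.all() else s


def univariate_ldsc(s: SumStats, l: pd.Series, m: int | None = None,
                    n_blocks: int = 200) -> UnivariateLdscFit:
    """Estimate SNP heritability and the LDSC intercept for one trait."""
    s = _snp_filter(s)
    z, n, li, _ = _regression_inputs(s, l)
    if len(z) < 200:
        raise ValueError("need at least 200 SNPs with LD scores")
    if (n <= 0).any():
        raise ValueError("sample sizes must be positive")
    m = int(m if m is not None else len(z))

    chi2 = z ** 2
    x = n * li / m                       # slope of chi2 on x is h2 itself
    coef = _wls(x, chi2, np.ones_like(x))
    for _ in range(2):
        h2_cur = float(np.clip(coef[0], 0.0, 1.0))
        w = 1.0 / (2.0 * (1.0 + h2_cur * x) ** 2)
        coef = _wls(x, chi2, w)
    full, deleted = _wls_jackknife(x, chi2, w, n_blocks)
    return UnivariateLdscFit(
        h2=float(full[0]), h2_se=_jackknife_se(deleted[:, 0]),
        intercept=float(full[1]), intercept_se=_jackknife_se(deleted[:, 1]),
        n_snps=len(z), m=m, n_blocks=n_blocks)


def bivariate_ldsc(a: SumStats, b: SumStats, l: pd.Series, m: int | None = None,
                   n_blocks: int = 200) -> GeneticCorrelationResult:
    """Cross-trait LDSC on a harmonised pair: genetic covariance,
    genetic correlation rg, and the sample-overlap cross intercept.

    The jackknife deletes the same contiguous SNP blocks from all
    three regressions, so the rg standard error reflects the joint
    sampling variability of gcov, h2_1 and h2_2.  If either h2
    estimate is non-positive, rg is reported as missing (NaN).
    """
    a, b = _snp_filter(a), _snp_filter(b)
    if not a.df.index.equals(b.df.index):
        shared = a.df.index[a.df.index.isin(b.df.index)]
        a, b = a.subset(shared), b.subset(shared)
    z1, n1, li, _ = _regression_inputs(a, l)
    z2, n2, _, _ = _regression_inputs(b, l)
    if len(z1) < 200:
        raise ValueError("need at least 200 shared SNPs with LD scores")
    m = int(m if m is not None else len(z1))

    x1 = n1 * li / m
    x2 = n2 * li / m
    xc = np.sqrt(n1 * n2) * li / m       # slope of z1 z2 on xc is gcov

    # univariate weights/fits (shared SNP set, shared block partition)
    def _uni(x, chi2):
        coef = _wls(x, chi2, np.ones_like(x))
        for _ in range(2):
            h2c = float(np.clip(coef[0], 0.0, 1.0))
            w = 1.0 / (2.0 * (1.0 + h2c * x) ** 2)
            coef = _wls(x, chi2, w)
        return _wls_jackknife(x, chi2, w, n_blocks)

    full1, del1 = _uni(x1, z1 ** 2)
    full2, del2 = _uni(x2, z2 ** 2)

    y = z1 * z2
    coef = _wls(xc, y, np.ones_like(xc))
    h1c = float(np.clip(full1[0], 0.0, 1.0))
    h2c = float(np.clip(full2[0], 0.0, 1.0))
    for _ in range(2):
        gcov_cur = float(np.clip(coef[0], -1.0, 1.0))
        rho_cur = float(coef[1])
        w = 1.0 / ((1.0 + h1c * x1) * (1.0 + h2c * x2)
                   + (gcov_cur * xc + rho_cur) ** 2)
        coef = _wls(xc, y, w)
    fullc, delc = _wls_jackknife(xc, y, w, n_blocks)

    h2_1, h2_2 = float(full1[0]), float(full2[0])
    gcov = float(fullc[0])
    if h2_1 > 0 and h2_2 > 0:
        rg = gcov / np.sqrt(h2_1 * h2_2)
        with np.errstate(invalid="ignore"):
            denom = np.sqrt(np.clip(del1[:, 0], 1e-12, None)
                            * np.clip(del2[:, 0], 1e-12, None))
            rg_del = delc[:, 0] / denom
        rg_se = _jackknife_se(rg_del)
        p_rg = float(2.0 * stats.norm.sf(abs(rg) / rg_se)) if rg_se > 0 else np.nan
    else:
        rg, rg_se, p_rg = np.nan, np.nan, np.nan

    return GeneticCorrelationResult(
        h2_1=h2_1, h2_1_se=_jackknife_se(del1[:, 0]),
        h2_2=h2_2, h2_2_se=_jackknife_se(del2[:, 0]),
        gcov=gcov, gcov_se=_jackknife_se(delc[:, 0]),
        rg=float(rg), rg_se=float(rg_se),
        intercept_1=float(full1[1]), intercept_2=float(full2[1]),
        intercept_cross=float(fullc[1]), intercept_cross_se=_jackknife_se(delc[:, 1]),
        p_rg=p_rg, n_snps_used=len(z1), n_jackknife_blocks=n_blocks)


def truncated_null_corr(c: float, z_cut: float, n_nodes: int = 64) -> float:
    """Pearson correlation of a standard bivariate normal with
    correlation ``c`` after rectangular truncation to |z| < z_cut in
    both coordinates (Gauss-Legendre quadrature)."""
    if not -1 < c < 1:
        raise ValueError("|c| must be < 1")
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    x = x * z_cut
    w = w * z_cut
    s = np.sqrt(1.0 - c * c)
    px = stats.norm.pdf(x)
    pdf = px[:, None] * stats.norm.pdf((x[None, :] - c * x[:, None]) / s) / s
    wij = w[:, None] * w[None, :] * pdf
    mass = wij.sum()
    sxy = (wij * np.outer(x, x)).sum() / mass
    sxx = (wij * (x ** 2)[:, None]).sum() / mass
    syy = (wij * (x ** 2)[None, :]).sum() / mass
    return float(sxy / np.sqrt(sxx * syy))


def invert_truncated_corr(r_obs: float, z_cut: float) -> float:
    """Recover the untruncated null correlation c from the observed
    Pearson correlation of doubly |z|-truncated Z-scores.

    Selecting SNPs with |z| < z_cut in both traits attenuates the
    correlation (for z_cut = 1.96 a true c = 0.3 shows up as ~0.24);
    this inverts the monotone truncated-correlation map.  Observations
    beyond the attainable range clip to +-1.
    """
    from scipy.optimize import brentq

    hi = 0.999999
    bound = truncated_null_corr(hi, z_cut)   # odd in c, so symmetric
    if r_obs >= bound:
        return 1.0
    if r_obs <= -bound:
        return -1.0
    return float(brentq(lambda c: truncated_null_corr(c, z_cut) - r_obs,
                        -hi, hi, xtol=1e-10))


def z_correlation_overlap(a: SumStats, b: SumStats, blocks, ld: dict,
                          z_cut: float = 1.96, r2_cut: float = 0.2) -> float:
    """Scalar sample-overlap estimate from null-SNP Z correlation.

    Pearson correlation of the two traits' Z-scores over independent
    (r2-pruned) SNPs that are null in both traits (|z| < z_cut),
    de-attenuated for the double truncation so the returned value
    estimates the correlation of the untruncated null statistics.
    """
    kept = position_ordered_prune(a, blocks, ld, prune_r2=r2_cut)
    za = a.df.loc[kept, "z"].to_numpy()
    zb = b.df.loc[kept, "z"].to_numpy()
    null = (np.abs(za) < z_cut) & (np.abs(zb) < z_cut)
    if null.sum() < 30:
        raise ValueError(f"only {int(null.sum())} qualifying null SNPs (< 30)")
    r_obs = float(np.corrcoef(za[null], zb[null])[0, 1])
    return invert_truncated_corr(r_obs, z_cut)
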