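"""Cross-phenotype association statistics and replication meta-analysis.

``S_hom`` combines the studies' Z-scores under a homogeneous-effect
assumption through a study correlation matrix R (estimated from
independent null SNPs); with R = I and inverse-variance weights it is
exactly the squared Z of a fixed-effects inverse-variance-weighted
meta-analysis.  ``S_het`` maximises the same statistic over a grid of
|Z| truncation levels tau, gaining power when effects are
heterogeneous; its null distribution is obtained by Monte Carlo from
N(0, R).  The module also provides the IVW meta-analysis itself and
the exact binomial direction-of-effect sign test used for
replication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ldsc import invert_truncated_corr
from .overlap import position_ordered_prune
from .sumstats import SumStats, harmonize_pair

logger = logging.getLogger(__name__)

DEFAULT_TAU_GRID = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)

_EIG_FLOOR = 1e-6


@dataclass
class StudyCorrMatrix:
    """Correlation of the studies' null test statistics."""

    labels: list
    R: np.ndarray
    repaired: bool = False

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        k = len(self.labels)
        if R.shape != (k, k):
            raise ValueError("R shape does not match labels")
        if not np.allclose(R, R.T, atol=1e-8):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-8):
            raise ValueError("R must have unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ValueError("R must be positive definite (within 1e-8)")
        self.R = R


def nearest_pd_repair(R: np.ndarray, floor: float = _EIG_FLOOR) -> tuple[np.ndarray, bool]:
    """Floor the eigenvalues at ``floor`` and restore the unit diagonal."""
    w, v = np.linalg.eigh(R)
    if w.min() >= floor:
        return R, False
    w = np.clip(w, floor, None)
    R2 = (v * w) @ v.T
    d = np.sqrt(np.diag(R2))
    R2 = R2 / np.outer(d, d)
    np.fill_diagonal(R2, 1.0)
    return (R2 + R2.T) / 2.0, True


@dataclass
class CpassocResult:
    variant_id: str
    s_hom: float
    p_hom: float
    s_het: float
    p_het: float
    tau_argmax: float


@dataclass
class MetaResult:
    """Fixed-effects IVW meta-analysis of one variant."""

    variant_id: str
    pooled_beta: float
    pooled_se: float
    or_: float
    ci95: tuple
    p_meta: float
    direction_string: str
    n_studies: int


def estimate_corr_matrix(studies, blocks, ld: dict, z_cut: float = 1.96,
                         r2_cut: float = 0.2) -> StudyCorrMatrix:
    """Pairwise Pearson correlation of Z over independent null SNPs.

    For every study pair, the shared variants are harmonised, pruned
    at ``r2_cut`` in genomic order (a data-independent selection) and
    restricted to SNPs with |z| < ``z_cut`` in both members; the raw
    Pearson correlation is de-attenuated for the double truncation
    (see :func:`crosstrait.ldsc.invert_truncated_corr`).  A
    nearest-positive-definite repair (eigenvalue floor 1e-6) is
    applied and logged if the raw matrix is not PD.
    """
    studies = list(studies)
    if len(studies) < 2:
        raise ValueError("need at least two studies")
    k = len(studies)
    R = np.eye(k)
    for i in range(k):
        for j in range(i + 1, k):
            si, sj = harmonize_pair(studies[i], studies[j])
            kept = position_ordered_prune(si, blocks, ld, prune_r2=r2_cut)
            zi = si.df.loc[kept, "z"].to_numpy()
            zj = sj.df.loc[kept, "z"].to_numpy()
            null = (np.abs(zi) < z_cut) & (np.abs(zj) < z_cut)
            if null.sum() < 30:
                raise ValueError(
                    f"only {int(null.sum())} qualifying null SNPs for pair "
                    f"({studies[i].trait_name}, {studies[j].trait_name})")
            r_obs = float(np.corrcoef(zi[null], zj[null])[0, 1])
            R[i, j] = R[j, i] = invert_truncated_corr(r_obs, z_cut)
    R2, repaired = nearest_pd_repair(R)
    if repaired:
        logger.warning("study correlation matrix was not positive definite; "
                       "applied eigenvalue-floor repair")
    return StudyCorrMatrix([s.trait_name for s in studies], R2, repaired)


def _shom_stat(z: np.ndarray, w: np.ndarray, R: np.ndarray) -> float:
    Rinv_w = np.linalg.solve(R, w)
    return float((Rinv_w @ z) ** 2 / (w @ Rinv_w))


def s_hom(z, n, R: StudyCorrMatrix) -> tuple[float, float]:
    """Homogeneous-effect cross-phenotype statistic and its 1-df
    chi-square p-value.  Weights are sqrt(n)."""
    z = np.asarray(z, dtype=float)
    n = np.asarray(n, dtype=float)
    if z.shape != n.shape or z.ndim != 1 or len(z) != len(R.labels):
        raise ValueError("z, n and R dimensions must agree")
    stat = _shom_stat(z, np.sqrt(n), R.R)
    return stat, float(stats.chi2.sf(stat, df=1))


def _shet_stats_batch(Z: np.ndarray, w: np.ndarray, R: np.ndarray,
                      tau_grid) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised S_het over variants (rows of Z).

    For each tau, the S_hom-type statistic is computed over the subset
    of studies with |z| > tau (0 when the subset is empty); S_het is
    the maximum over the grid.  Returns (stats, tau_argmax).
    """
    V, k = Z.shape
    tau_grid = np.asarray(tau_grid, dtype=float)
    # precompute R^{-1}-projected weights for every study subset
    cache: dict = {}

    def subset_terms(mask_bits: int):
        if mask_bits not in cache:
            idx = [i for i in range(k) if mask_bits >> i & 1]
            Rs = R[np.ix_(idx, idx)]
            ws = w[idx]
            v = np.linalg.solve(Rs, ws)
            cache[mask_bits] = (idx, v, float(ws @ v))
        return cache[mask_bits]

    stats_grid = np.zeros((len(tau_grid), V))
    absZ = np.abs(Z)
    for ti, tau in enumerate(tau_grid):
        mask = absZ > tau
        bits = mask @ (1 << np.arange(k))
        for mb in np.unique(bits):
            if mb == 0:
                continue
            rows = bits == mb
            idx, v, denom = subset_terms(int(mb))
            num = (Z[np.ix_(rows, idx)] @ v) ** 2
            stats_grid[ti, rows] = num / denom
    best = stats_grid.max(axis=0)
    tau_argmax = tau_grid[stats_grid.argmax(axis=0)]
    return best, tau_argmax


def s_het_batch(Z, n, R: StudyCorrMatrix, tau_grid=DEFAULT_TAU_GRID,
                n_mc: int = 5000, seed: int = 0):
    """S_het for many variants sharing one correlation matrix.

    The Monte-Carlo null (draws from N(0, R), same statistic) is
    computed once and shared; p = (r + 1)/(n_mc + 1) with r the count
    of null draws at or above the observed statistic.
    Returns (stat, p, tau_argmax) arrays.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    n = np.asarray(n, dtype=float)
    tau_grid = np.asarray(tau_grid, dtype=float)
    if len(tau_grid) == 0 or tau_grid[0] != 0 or (np.diff(tau_grid) <= 0).any():
        raise ValueError("tau_grid must be ascending and start at 0")
    if n_mc < 100:
        raise ValueError("n_mc must be >= 100")
    w = np.sqrt(n)
    stat, tau_argmax = _shet_stats_batch(Z, w, R.R, tau_grid)

    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(R.R)
    Z0 = rng.standard_normal((n_mc, len(R.labels))) @ L.T
    null_stat, _ = _shet_stats_batch(Z0, w, R.R, tau_grid)
    null_sorted = np.sort(null_stat)
    r = n_mc - np.searchsorted(null_sorted, stat, side="left")
    p = (r + 1.0) / (n_mc + 1.0)
    return stat, p, tau_argmax


def s_het(z, n, R: StudyCorrMatrix, tau_grid=DEFAULT_TAU_GRID,
          n_mc: int = 5000, seed: int = 0) -> tuple[float, float, float]:
    """Heterogeneity-robust statistic for one variant (see
    :func:`s_het_batch`)."""
    stat, p, tau = s_het_batch(np.atleast_2d(z), n, R, tau_grid, n_mc, seed)
    return float(stat[0]), float(p[0]), float(tau[0])


def ivw_meta(betas, ses, variant_id: str = "") -> MetaResult:
    """Fixed-effects inverse-variance-weighted meta-analysis.

    Studies with missing (NaN) effect or SE are skipped and marked
    '?' in the direction string.
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    ok = np.isfinite(betas) & np.isfinite(ses)
    if (ses[ok] <= 0).any():
        raise ValueError("standard errors must be positive")
    if not ok.any():
        raise ValueError("all studies missing")
    w = 1.0 / ses[ok] ** 2
    pooled = float((w * betas[ok]).sum() / w.sum())
    pooled_se = float(1.0 / np.sqrt(w.sum()))
    zstat = pooled / pooled_se
    direction = "".join(
        "?" if not o else ("+" if b >= 0 else "-")
        for o, b in zip(ok, betas))
    return MetaResult(
        variant_id=variant_id, pooled_beta=pooled, pooled_se=pooled_se,
        or_=float(np.exp(pooled)),
        ci95=(float(np.exp(pooled - 1.96 * pooled_se)),
              float(np.exp(pooled + 1.96 * pooled_se))),
        p_meta=float(2.0 * stats.norm.sf(abs(zstat))),
        direction_string=direction, n_studies=int(ok.sum()))


def sign_test(direction_strings, studies: int) -> float:
    """Exact two-sided binomial test for direction-of-effect
    concordance across studies.

    A variant is concordant when all its non-missing directions agree
    and none is missing; the null concordance probability is
    (1/2)^(studies-1).  Two-sided p doubles the smaller tail (capped
    at 1).
    """
    eligible = 0
    concordant = 0
    for s in direction_strings:
        if len(s) != studies:
            raise ValueError(f"direction string {s!r} does not have {studies} entries")
        if "?" in s:
            continue
        eligible += 1
        if len(set(s)) == 1:
            concordant += 1
    if eligible == 0:
        raise ValueError("no eligible variants for the sign test")
    p0 = 0.5 ** (studies - 1)
    lo = stats.binom.cdf(concordant, eligible, p0)
    hi = stats.binom.sf(concordant - 1, eligible, p0)
    return float(min(1.0, 2.0 * min(lo, hi)))


def cpassoc_scan(a: SumStats, b: SumStats, R: StudyCorrMatrix,
                 tau_grid=DEFAULT_TAU_GRID, n_mc: int = 5000,
                 seed: int = 0) -> pd.DataFrame:
    """S_hom / S_het over every shared variant of a harmonised pair."""
    if not a.df.index.equals(b.df.index):
        raise ValueError("pair must be harmonised first")
    Z = np.column_stack([a.df["z"].to_numpy(), b.df["z"].to_numpy()])
    n = np.array([float(a.df["n"].median()), float(b.df["n"].median())])
    w = np.sqrt(n)
    Rinv_w = np.linalg.solve(R.R, w)
    shom = (Z @ Rinv_w) ** 2 / (w @ Rinv_w)
    p_hom = stats.chi2.sf(shom, df=1)
    shet, p_het, tau = s_het_batch(Z, n, R, tau_grid, n_mc, seed)
    return pd.DataFrame({
        "variant_id": a.df.index, "z1": Z[:, 0], "z2": Z[:, 1],
        "s_hom": shom, "p_hom": p_hom,
        "s_het": shet, "p_het": p_het, "tau_argmax": tau,
    }).set_index("variant_id")
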