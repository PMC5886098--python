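"""SNP-based overlap analysis between two traits.

Implements p-value-informed LD pruning, per-threshold 2x2 overlap
tests, an empirical permutation null, and the selection of overlap
candidates for replication.

The pruning rule is the classical greedy clump: sort variants by the
first trait's p-value (ascending; ties by chromosome, position,
variant id) and walk the list, keeping a variant only if its r^2 with
every previously kept variant of the same LD block is at most
``prune_r2``.  Cross-block r^2 is zero by construction, so the greedy
pass decomposes exactly into independent per-block passes.

The permutation null shuffles the second trait's p-values (the
BMD-role dataset), recomputing the chi-square at every threshold from
the same shuffle.  Because a permutation leaves both margins of the
2x2 table fixed, the chi-square of a permuted table is the
fixed-margin closed form in the both-below count n11, which is what
the engine evaluates.  The empirical p-value uses the add-one
estimator and counts only exceedances whose enrichment direction
matches the observed table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import SumStats

#: the ten analysis thresholds
DEFAULT_THRESHOLDS = (0.5, 0.1, 0.05, 0.04, 0.03, 0.02, 0.01, 0.005, 0.001, 5e-4)


@dataclass
class OverlapConfig:
    thresholds: tuple = DEFAULT_THRESHOLDS
    prune_r2: float = 0.05
    n_perm: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) == 0 or (t <= 0).any() or (t >= 1).any():
            raise ValueError("thresholds must lie strictly in (0, 1)")
        if (np.diff(t) >= 0).any():
            raise ValueError("thresholds must be strictly descending")
        if not 0 < self.prune_r2 < 1:
            raise ValueError("prune_r2 must lie in (0, 1)")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class OverlapResult:
    """Overlap evidence at one p-value threshold."""

    threshold: float
    n_total: int
    n_overlap: int                  # below threshold in both traits
    n_below_1: int                  # below threshold in trait 1
    n_below_2: int
    table2x2: tuple                 # (n11, n10, n01, n00)
    chi2: float
    p_chi2: float
    enriched: bool = True           # observed overlap at/above expectation
    p_perm: float = np.nan


@dataclass
class OverlapAnalysis:
    """Pruned panel plus per-threshold overlap results for one pair."""

    variant_ids: list
    a_p: np.ndarray
    b_p: np.ndarray
    results: list = field(default_factory=list)
    config: OverlapConfig | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.results])


def _greedy_prune(s: SumStats, blocks, ld: dict, prune_r2: float,
                  order_all: np.ndarray) -> list:
    df = s.df
    assign = blocks.assignment
    missing = [v for v in df.index if v not in assign]
    if missing:
        raise ValueError(f"variants without LD-block assignment: {missing[:5]}")

    keep_ids = set()
    by_block: dict = {}
    idx_arr = df.index.to_numpy()
    for i in order_all:
        by_block.setdefault(assign[idx_arr[i]], []).append(idx_arr[i])

    r2_max = float(prune_r2)
    for bid, vids in by_block.items():
        mat = ld[bid]
        rows = [mat.index_of(v) for v in vids]
        r = mat.r
        kept_rows: list[int] = []
        for v, ri in zip(vids, rows):
            if not kept_rows or (r[ri, kept_rows] ** 2 <= r2_max).all():
                kept_rows.append(ri)
                keep_ids.add(v)
    return [v for v in df.index if v in keep_ids]


def pvalue_informed_prune(s: SumStats, blocks, ld: dict,
                          prune_r2: float = 0.05) -> list:
    """Greedy p-value-ordered pruning at ``prune_r2``.

    Variants are visited in ascending p (ties by chromosome, position,
    variant id); a variant is retained iff its r2 with every already
    retained variant of its block is <= ``prune_r2``.  Returns the
    retained ids in the input's row order.
    """
    df = s.df
    order_all = np.lexsort((df.index.to_numpy(dtype="U"), df["pos"].to_numpy(),
                            df["chrom"].to_numpy(dtype="U"),
                            df["pvalue"].to_numpy()))
    return _greedy_prune(s, blocks, ld, prune_r2, order_all)


def position_ordered_prune(s: SumStats, blocks, ld: dict,
                           prune_r2: float = 0.2) -> list:
    """Greedy pruning in genomic order — a data-independent selection.

    Used where an independent SNP panel is needed without conditioning
    on the association statistics (e.g. estimating the null Z-score
    correlation between studies): p-value-informed pruning would
    preferentially retain large-|z| SNPs within LD clumps and bias
    such estimates upward.
    """
    df = s.df
    order_all = np.lexsort((df.index.to_numpy(dtype="U"), df["pos"].to_numpy(),
                            df["chrom"].to_numpy(dtype="U")))
    return _greedy_prune(s, blocks, ld, prune_r2, order_all)


def _chi2_2x2(n11: float, ka: float, kb: float, n: float):
    """Pearson chi-square of the fixed-margin 2x2 table (no continuity
    correction); NaN when any margin is zero."""
    if min(ka, kb, n - ka, n - kb) == 0:
        return np.nan
    num = n * (n11 * n - ka * kb) ** 2
    den = ka * (n - ka) * kb * (n - kb)
    return num / den


def threshold_overlap(a_p: np.ndarray, b_p: np.ndarray, t: float) -> OverlapResult:
    """2x2 overlap table at threshold ``t`` (strict 'p < t') plus the
    1-df Pearson chi-square without continuity correction."""
    a_p = np.asarray(a_p, dtype=float)
    b_p = np.asarray(b_p, dtype=float)
    if a_p.shape != b_p.shape:
        raise ValueError("p-value vectors must be aligned and equal length")
    if not 0 < t < 1:
        raise ValueError("threshold must lie in (0, 1)")
    below_a = a_p < t
    below_b = b_p < t
    n = len(a_p)
    n11 = int((below_a & below_b).sum())
    ka, kb = int(below_a.sum()), int(below_b.sum())
    table = (n11, ka - n11, kb - n11, n - ka - kb + n11)
    chi2 = _chi2_2x2(n11, ka, kb, n)
    p = float(stats.chi2.sf(chi2, df=1)) if np.isfinite(chi2) else np.nan
    return OverlapResult(threshold=float(t), n_total=n, n_overlap=n11,
                         n_below_1=ka, n_below_2=kb, table2x2=table,
                         chi2=float(chi2) if np.isfinite(chi2) else np.nan,
                         p_chi2=p, enriched=bool(n11 * n >= ka * kb))


def permutation_overlap(a_p, b_p, cfg: OverlapConfig,
                        variant_ids=None) -> OverlapAnalysis:
    """Empirical overlap p-values from a shared permutation stream.

    One shuffle of ``b_p`` per replicate is reused across all
    thresholds.  ``p_perm = (1 + r) / (n_perm + 1)`` where ``r`` counts
    replicates whose chi-square is at least as large as observed —
    the observed test p-value compared against the permutation null
    distribution.  The ``enriched`` flag of each result records
    whether the observed overlap exceeds its expectation, so an excess
    and a deficit of overlap are never conflated in reports.
    """
    a_p = np.asarray(a_p, dtype=float)
    b_p = np.asarray(b_p, dtype=float)
    thresholds = np.asarray(cfg.thresholds, dtype=float)
    results = [threshold_overlap(a_p, b_p, t) for t in thresholds]

    m = len(a_p)
    A = np.stack([a_p < t for t in thresholds])          # (T, m) bool
    B = np.stack([b_p < t for t in thresholds])
    ka = A.sum(axis=1).astype(float)
    kb = B.sum(axis=1).astype(float)
    chi2_obs = np.array([r.chi2 for r in results])
    defined = np.isfinite(chi2_obs)
    exceed = np.zeros(len(thresholds), dtype=np.int64)
    rng = np.random.default_rng(cfg.seed)
    A_i8 = A.astype(np.int8)
    B_i8 = B.astype(np.int8)
    for _ in range(cfg.n_perm):
        perm = rng.permutation(m)
        n11 = (A_i8 & B_i8[:, perm]).sum(axis=1).astype(float)
        num = m * (n11 * m - ka * kb) ** 2
        den = ka * (m - ka) * kb * (m - kb)
        with np.errstate(invalid="ignore", divide="ignore"):
            chi2_perm = num / den
        exceed += (defined & (chi2_perm >= chi2_obs)).astype(np.int64)

    p_perm = (1.0 + exceed) / (cfg.n_perm + 1.0)
    for r, pp, ok in zip(results, p_perm, defined):
        r.p_perm = float(pp) if ok else 1.0
    ids = list(variant_ids) if variant_ids is not None else list(range(m))
    return OverlapAnalysis(ids, a_p, b_p, results, cfg)


def select_candidates(analyses, colocs, p_t: float = 0.005) -> list:
    """Replication candidate set: the union of (i) variants below
    ``p_t`` in both traits in any pruned comparison and (ii) each
    colocalisation-flagged region's top SNP per trait; deduplicated,
    sorted by variant id.
    """
    chosen: set = set()
    for an in analyses:
        mask = (an.a_p < p_t) & (an.b_p < p_t)
        chosen.update(np.asarray(an.variant_ids, dtype=object)[mask].tolist())
    for cr in colocs:
        if getattr(cr, "flagged_h3", False) or getattr(cr, "flagged_h4", False):
            if cr.top_snp_trait1 is not None:
                chosen.add(cr.top_snp_trait1)
            if cr.top_snp_trait2 is not None:
                chosen.add(cr.top_snp_trait2)
    return sorted(chosen)
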