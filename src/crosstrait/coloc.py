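"""Regional Bayesian colocalisation of two traits' association signals.

Per approximately independent LD block, posterior probabilities are
computed for five hypotheses under the standard single-causal-variant-
per-trait-per-region frame:

* H0 — no variant in the region is associated with either trait;
* H1 / H2 — one variant associated with trait 1 only / trait 2 only;
* H3 — one variant associated with both traits (colocalisation);
* H4 — two distinct variants, one per trait.

Per-SNP evidence is the Wakefield approximate Bayes factor computed
from the Z-score and SE under a normal effect prior of variance W.
Sample overlap between the two studies enters the shared-causal (H3)
evidence through an exact bivariate-normal Bayes factor whose null
correlates the two Z-scores by the overlap coefficient c; at c = 0 it
factorises into the two univariate ABFs.  All hypothesis sums are
accumulated in log space.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import SumStats

PP_FLAG_THRESHOLD = 0.9  # reporting flag: PP(H3) or PP(H4) at/above this

HYPOTHESES = ("H0", "H1", "H2", "H3", "H4")


@dataclass
class ColocPriors:
    """Per-SNP prior probabilities and effect-variance hyperpriors.

    ``p1``/``p2`` — prior that a given SNP is causal for one trait
    only; ``p12`` — causal for both; ``W1``/``W2`` — prior variance of
    the (additive-scale) effect at a causal SNP.
    """

    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    W1: float = 0.04
    W2: float = 0.04

    def __post_init__(self) -> None:
        if not (0 < self.p12 <= min(self.p1, self.p2)):
            raise ValueError("need 0 < p12 <= min(p1, p2)")
        if self.p1 + self.p2 + self.p12 >= 1:
            raise ValueError("p1 + p2 + p12 must be < 1")
        if self.W1 <= 0 or self.W2 <= 0:
            raise ValueError("prior effect variances must be positive")


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one region."""

    block_id: str
    n_snps: int
    pp: np.ndarray                       # H0..H4, sums to 1
    top_snp_trait1: str | None
    top_snp_trait2: str | None
    flagged_h3: bool
    flagged_h4: bool
    chrom: str | None = None
    start: int | None = None
    stop: int | None = None

    @property
    def modal_hypothesis(self) -> str:
        return HYPOTHESES[int(np.argmax(self.pp))]


def wakefield_abf(z, se, W: float):
    """Log approximate Bayes factor for association at one variant.

    With V = se^2:  log ABF = 0.5 log(V/(V+W)) + z^2 W / (2 (V+W)).
    Accepts scalars or arrays.
    """
    z = np.asarray(z, dtype=float)
    V = np.asarray(se, dtype=float) ** 2
    if np.any(np.asarray(se) <= 0) or W <= 0:
        raise ValueError("se and W must be positive")
    out = 0.5 * np.log(V / (V + W)) + z ** 2 * W / (2.0 * (V + W))
    return out if out.ndim else float(out)


def joint_shared_abf(z1, z2, se1, se2, priors: ColocPriors, c: float = 0.0):
    """Log Bayes factor for a shared causal variant at one SNP.

    Ratio of bivariate-normal densities of (z1, z2) under
    cov [[1 + W1/V1, c], [c, 1 + W2/V2]] (shared causal, independent
    effect sizes) versus [[1, c], [c, 1]] (null with sample overlap).
    Reduces exactly to the sum of the two univariate Wakefield log
    ABFs when c = 0.
    """
    if not -1 < c < 1:
        raise ValueError("|c| must be < 1")
    z1 = np.asarray(z1, dtype=float)
    z2 = np.asarray(z2, dtype=float)
    V1 = np.asarray(se1, dtype=float) ** 2
    V2 = np.asarray(se2, dtype=float) ** 2
    if np.any(np.asarray(se1) <= 0) or np.any(np.asarray(se2) <= 0):
        raise ValueError("standard errors must be positive")
    a1 = 1.0 + priors.W1 / V1
    a2 = 1.0 + priors.W2 / V2
    det1 = a1 * a2 - c * c
    det0 = 1.0 - c * c
    # quadratic forms z' Sigma^{-1} z for 2x2 covariances
    q1 = (a2 * z1 ** 2 - 2.0 * c * z1 * z2 + a1 * z2 ** 2) / det1
    q0 = (z1 ** 2 - 2.0 * c * z1 * z2 + z2 ** 2) / det0
    out = 0.5 * (np.log(det0) - np.log(det1)) + 0.5 * (q0 - q1)
    return out if out.ndim else float(out)


def region_posteriors(variant_ids, z1, se1, z2, se2,
                      priors: ColocPriors | None = None, c: float = 0.0,
                      block_id: str = "") -> ColocResult:
    """Five-hypothesis posterior for one region.

    Evidence relative to H0 (baseline 1):
    H1 = p1 sum_j ABF1_j;  H2 = p2 sum_j ABF2_j;
    H3 = p12 sum_j jointABF_j;
    H4 = p1 p2 sum_{j != k} ABF1_j ABF2_k
    — all in log-sum-exp arithmetic.  A single-SNP region has
    PP(H4) = 0 structurally.
    """
    priors = priors or ColocPriors()
    z1 = np.atleast_1d(np.asarray(z1, dtype=float))
    z2 = np.atleast_1d(np.asarray(z2, dtype=float))
    se1 = np.atleast_1d(np.asarray(se1, dtype=float))
    se2 = np.atleast_1d(np.asarray(se2, dtype=float))
    ids = [str(v) for v in variant_ids]
    k = len(ids)
    if not (len(z1) == len(z2) == len(se1) == len(se2) == k) or k == 0:
        raise ValueError("aligned non-empty per-SNP vectors required")

    la1 = np.atleast_1d(wakefield_abf(z1, se1, priors.W1))
    la2 = np.atleast_1d(wakefield_abf(z2, se2, priors.W2))
    la12 = np.atleast_1d(joint_shared_abf(z1, z2, se1, se2, priors, c))

    lh0 = 0.0
    lh1 = np.log(priors.p1) + logsumexp(la1)
    lh2 = np.log(priors.p2) + logsumexp(la2)
    lh3 = np.log(priors.p12) + logsumexp(la12)
    if k == 1:
        lh4 = -np.inf
    else:
        pairs = la1[:, None] + la2[None, :]
        np.fill_diagonal(pairs, -np.inf)
        lh4 = np.log(priors.p1) + np.log(priors.p2) + logsumexp(pairs)

    lh = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lh - logsumexp(lh))
    pp /= pp.sum()

    top1 = ids[int(np.argmax(np.abs(z1)))]
    top2 = ids[int(np.argmax(np.abs(z2)))]
    return ColocResult(block_id=block_id, n_snps=k, pp=pp,
                       top_snp_trait1=top1, top_snp_trait2=top2,
                       flagged_h3=bool(pp[3] >= PP_FLAG_THRESHOLD),
                       flagged_h4=bool(pp[4] >= PP_FLAG_THRESHOLD))


def genome_coloc_scan(a: SumStats, b: SumStats, blocks,
                      priors: ColocPriors | None = None,
                      c: float = 0.0) -> list:
    """Run :func:`region_posteriors` over every LD block with data.

    Requires a harmonised pair with complete block assignment; returns
    results sorted by max(PP(H3), PP(H4)) descending.
    """
    if len(blocks) == 0:
        raise ValueError("no LD blocks supplied")
    assign = blocks.assignment
    missing = [v for v in a.df.index if v not in assign]
    if missing:
        raise ValueError(f"variants without block assignment: {missing[:5]}")

    binfo = blocks.blocks.set_index("block_id")
    groups: dict = {}
    for v in a.df.index:
        groups.setdefault(assign[v], []).append(v)

    out = []
    for bid in blocks.block_ids:
        vids = groups.get(bid)
        if not vids:
            continue
        da = a.df.loc[vids]
        db = b.df.loc[vids]
        res = region_posteriors(vids, da["z"].to_numpy(), da["se"].to_numpy(),
                                db["z"].to_numpy(), db["se"].to_numpy(),
                                priors, c, block_id=bid)
        res.chrom = str(binfo.loc[bid, "chrom"])
        res.start = int(binfo.loc[bid, "start"])
        res.stop = int(binfo.loc[bid, "stop"])
        out.append(res)
    out.sort(key=lambda r: -max(r.pp[3], r.pp[4]))
    return out
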