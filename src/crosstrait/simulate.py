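"""Synthetic paired GWAS summary statistics with known truth.

Emulates the study design this package targets: a case-control
osteoarthritis-like trait paired with a quantitative bone-mineral-
density-like trait, sharing a panel of common variants laid out in
approximately independent LD blocks.  Two generators are provided:

* :func:`simulate_polygenic_pair` — genome-wide polygenic effects from
  a bivariate normal with tunable SNP heritabilities and genetic
  correlation, plus sample-overlap-correlated null noise; this is the
  regime LD score regression estimates from.
* :func:`simulate_coloc_regions` — sparse per-region causal
  configurations matching the five colocalisation hypotheses H0-H4.

Within a block with signed LD matrix R, observed Z-vectors follow

    Z_t = R @ lam_t + eps_t,   lam_t = sqrt(n_t) * beta_t,

with (eps_1, eps_2) jointly normal, per-trait covariance R and
cross-trait covariance overlap_c * R.  Effects are on the
standardised-genotype scale (log-odds with effective n for the binary
trait), which makes beta = z / sqrt(n) and se = 1 / sqrt(n) exact.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .ld import LDBlocks, LDMatrix, ar1_matrix, write_blocks, write_ld_matrix
from .sumstats import SumStats, effective_sample_size, write_sumstats

#: non-ambiguous allele pairs cycled across simulated variants
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]

_BP_SPACING = 5000  # synthetic inter-SNP spacing in base pairs


@dataclass
class SimConfig:
    """Study conditions for the polygenic generator.

    Defaults mirror the target design: an OA-like case-control study
    (7,410 cases / 11,009 controls -> effective n 17,716) against an
    LSBMD-like quantitative study (n = 31,800), genome-wide genetic
    correlation 0.18, SNP heritabilities 0.2 / 0.25, and a small
    residual sample-overlap correlation of the null Z-scores (0.05).
    """

    m_snps: int = 20_000
    block_size: int = 50
    #: scalar AR(1) rho for homogeneous LD, or a (low, high) range cycled
    #: across blocks. Heterogeneous block LD mirrors the genome's mix of
    #: high- and low-LD regions and gives the LD-score regressor the
    #: between-SNP variation the estimator relies on.
    ld_rho: float | tuple = (0.0, 0.9)
    n1: float | None = None      # derived from cases/controls when None
    n2: float = 31_800.0
    trait_types: tuple = ("binary", "quantitative")
    trait_names: tuple = ("OA", "BMD")
    n_cases: int = 7_410
    n_controls: int = 11_009
    h2_1: float = 0.20
    h2_2: float = 0.25
    rg: float = 0.18
    overlap_c: float = 0.05
    n_chrom: int = 22
    seed: int = 0

    def __post_init__(self) -> None:
        if self.m_snps < 1:
            raise ValueError("m_snps must be >= 1")
        if not (0 <= self.h2_1 <= 1 and 0 <= self.h2_2 <= 1):
            raise ValueError("heritabilities must lie in [0, 1]")
        if not -1 <= self.rg <= 1:
            raise ValueError("|rg| must be <= 1")
        if not -1 < self.overlap_c < 1:
            raise ValueError("overlap_c must lie in (-1, 1)")
        if self.block_size < 1:
            raise ValueError("block_size must be >= 1")
        if self.n1 is None:
            self.n1 = effective_sample_size(self.n_cases, self.n_controls)


@dataclass
class RegionScenario:
    """One region's causal configuration under hypotheses H0-H4."""

    block_id: str
    hypothesis: str               # "H0" .. "H4"
    causal_ids: list = field(default_factory=list)
    effect_z: float = 8.0

    _EXPECTED = {"H0": 0, "H1": 1, "H2": 1, "H3": 1, "H4": 2}

    def __post_init__(self) -> None:
        if self.hypothesis not in self._EXPECTED:
            raise ValueError(f"unknown hypothesis {self.hypothesis!r}")
        if len(self.causal_ids) != self._EXPECTED[self.hypothesis]:
            raise ValueError(f"{self.hypothesis} requires "
                             f"{self._EXPECTED[self.hypothesis]} causal ids")
        if self.hypothesis == "H4" and len(set(self.causal_ids)) != 2:
            raise ValueError("H4 requires two distinct causal ids")


@dataclass
class SimTruth:
    """Ground truth of a simulation: per-variant effects and labels."""

    table: pd.DataFrame           # variant_id, block_id, beta1, beta2
    params: dict
    scenarios: pd.DataFrame | None = None


def build_panel(cfg: SimConfig) -> tuple[LDBlocks, dict]:
    """Synthesise the variant panel: blocks plus per-block LD matrices."""
    m, bs = cfg.m_snps, cfg.block_size
    n_blocks = (m + bs - 1) // bs
    per_chrom = max(1, (n_blocks + cfg.n_chrom - 1) // cfg.n_chrom)
    if isinstance(cfg.ld_rho, (tuple, list)):
        low, high = cfg.ld_rho
        cycle = 8  # decouple LD strength from genomic position
        rhos = [low + (high - low) * (b % cycle) / (cycle - 1)
                for b in range(n_blocks)]
    else:
        rhos = [float(cfg.ld_rho)] * n_blocks
    rows, mats = [], {}
    vid = 0
    for b in range(n_blocks):
        size = min(bs, m - b * bs)
        chrom = str(b // per_chrom + 1)
        at = b % per_chrom
        start = at * bs * _BP_SPACING
        stop = start + size * _BP_SPACING
        block_id = f"b{b:05d}"
        ids = [f"rs{vid + j + 1:07d}" for j in range(size)]
        vid += size
        rows.append((chrom, start, stop, block_id, ids))
        mats[block_id] = LDMatrix(block_id, ids, ar1_matrix(size, rhos[b]))
    blocks = LDBlocks(pd.DataFrame(
        [(c, s, e, bid) for c, s, e, bid, _ in rows],
        columns=["chrom", "start", "stop", "block_id"]))
    for (chrom, start, stop, bid, ids) in rows:
        for j, v in enumerate(ids):
            blocks.assignment[v] = bid
    return blocks, mats


def _block_sqrt(mat: LDMatrix) -> np.ndarray:
    """Symmetric PSD square root of the block LD matrix, memoised."""
    got = getattr(mat, "_sqrt_cache", None)
    if got is not None:
        return got
    w, v = np.linalg.eigh(mat.r)
    s = (v * np.sqrt(np.clip(w, 0.0, None))) @ v.T
    mat._sqrt_cache = s
    return s


def _panel_frame(blocks: LDBlocks, mats: dict) -> pd.DataFrame:
    """Per-variant chrom/pos/allele/block scaffold in block order."""
    recs = []
    binfo = blocks.blocks.set_index("block_id")
    for bid in blocks.block_ids:
        mat = mats[bid]
        chrom = binfo.loc[bid, "chrom"]
        start = int(binfo.loc[bid, "start"])
        step = max(1, (int(binfo.loc[bid, "stop"]) - start) // max(1, len(mat)))
        for j, v in enumerate(mat.variant_ids):
            ea, oa = _ALLELE_PAIRS[(zlib.crc32(bid.encode()) + j) % len(_ALLELE_PAIRS)]
            recs.append((v, str(chrom), start + j * step, ea, oa, bid))
    return pd.DataFrame(recs, columns=["variant_id", "chrom", "pos",
                                       "effect_allele", "other_allele", "block_id"])


def _assemble_sumstats(panel: pd.DataFrame, z: np.ndarray, n: float, eaf: np.ndarray,
                       name: str, ttype: str, n_cases=None, n_controls=None) -> SumStats:
    rt_n = np.sqrt(n)
    df = panel[["variant_id", "chrom", "pos", "effect_allele", "other_allele"]].copy()
    df["beta"] = z / rt_n
    df["se"] = 1.0 / rt_n
    df["pvalue"] = 2.0 * stats.norm.sf(np.abs(z))
    df["z"] = z
    df["n"] = float(n)
    df["eaf"] = eaf
    df["info"] = np.nan
    df = df.set_index("variant_id")
    return SumStats(name, ttype, df, n_cases, n_controls)


def _correlated_noise(rng: np.random.Generator, sqrt_r: np.ndarray,
                      c: float) -> tuple[np.ndarray, np.ndarray]:
    k = sqrt_r.shape[0]
    u = rng.standard_normal((2, k))
    e1 = sqrt_r @ u[0]
    e2 = sqrt_r @ (c * u[0] + np.sqrt(1.0 - c * c) * u[1])
    return e1, e2


def simulate_polygenic_pair(cfg: SimConfig,
                            panel: tuple[LDBlocks, dict] | None = None
                            ) -> tuple[SumStats, SumStats, SimTruth]:
    """Draw a paired set of genome-wide summary statistics.

    Per-SNP true effects come from a bivariate normal with variances
    h2_i/m and covariance rg*sqrt(h2_1*h2_2)/m; observed Z-scores add
    LD propagation and overlap-correlated noise block by block.
    Bit-identical for a fixed seed and panel.
    """
    blocks, mats = build_panel(cfg) if panel is None else panel
    pf = _panel_frame(blocks, mats)
    m = len(pf)

    ss = np.random.SeedSequence(cfg.seed)
    child = ss.spawn(2 + len(blocks))
    rng0 = np.random.default_rng(child[0])

    s1, s2 = np.sqrt(cfg.h2_1 / m), np.sqrt(cfg.h2_2 / m)
    g = rng0.standard_normal((2, m))
    beta1 = s1 * g[0]
    beta2 = s2 * (cfg.rg * g[0] + np.sqrt(1.0 - cfg.rg ** 2) * g[1])
    eaf = np.random.default_rng(child[1]).uniform(0.05, 0.95, size=m)

    z1 = np.empty(m)
    z2 = np.empty(m)
    offset = 0
    for i, bid in enumerate(blocks.block_ids):
        mat = mats[bid]
        k = len(mat)
        sl = slice(offset, offset + k)
        offset += k
        rng = np.random.default_rng(child[2 + i])
        e1, e2 = _correlated_noise(rng, _block_sqrt(mat), cfg.overlap_c)
        z1[sl] = mat.r @ (np.sqrt(cfg.n1) * beta1[sl]) + e1
        z2[sl] = mat.r @ (np.sqrt(cfg.n2) * beta2[sl]) + e2

    a = _assemble_sumstats(pf, z1, cfg.n1, eaf, cfg.trait_names[0],
                           cfg.trait_types[0], cfg.n_cases, cfg.n_controls)
    b = _assemble_sumstats(pf, z2, cfg.n2, eaf, cfg.trait_names[1], cfg.trait_types[1])
    truth = SimTruth(
        pd.DataFrame({"variant_id": pf["variant_id"], "block_id": pf["block_id"],
                      "beta1": beta1, "beta2": beta2}),
        params={**asdict(cfg)})
    return a, b, truth


def simulate_coloc_regions(scenarios, blocks: LDBlocks, ld: dict,
                           overlap_c: float = 0.0, seed: int = 0,
                           n1: float = 10_000.0, n2: float = 10_000.0
                           ) -> tuple[SumStats, SumStats, SimTruth]:
    """Simulate regions with fixed causal configurations (H0-H4).

    Each scenario places non-centrality ``effect_z`` at its causal
    SNP(s) — one trait only for H1/H2, the same SNP in both traits for
    H3, two distinct SNPs for H4 — and propagates it through the block
    LD as R @ lam before adding overlap-correlated noise.
    """
    wanted = [sc.block_id for sc in scenarios]
    sub = LDBlocks(blocks.blocks[blocks.blocks["block_id"].isin(wanted)]
                   .set_index("block_id").loc[wanted].reset_index()
                   [["chrom", "start", "stop", "block_id"]].copy())
    mats = {bid: ld[bid] for bid in wanted}
    for v, bid in blocks.assignment.items():
        if bid in mats:
            sub.assignment[v] = bid
    pf = _panel_frame(sub, mats)

    child = np.random.SeedSequence(seed).spawn(len(scenarios) + 1)
    eaf = np.random.default_rng(child[0]).uniform(0.05, 0.95, size=len(pf))

    z1 = np.empty(len(pf))
    z2 = np.empty(len(pf))
    b1_true = np.zeros(len(pf))
    b2_true = np.zeros(len(pf))
    labels = []
    offset = 0
    for i, sc in enumerate(scenarios):
        mat = mats[sc.block_id]
        k = len(mat)
        lam1 = np.zeros(k)
        lam2 = np.zeros(k)
        idx = [mat.index_of(v) for v in sc.causal_ids]
        if sc.hypothesis == "H1":
            lam1[idx[0]] = sc.effect_z
        elif sc.hypothesis == "H2":
            lam2[idx[0]] = sc.effect_z
        elif sc.hypothesis == "H3":
            lam1[idx[0]] = sc.effect_z
            lam2[idx[0]] = sc.effect_z
        elif sc.hypothesis == "H4":
            lam1[idx[0]] = sc.effect_z
            lam2[idx[1]] = sc.effect_z
        rng = np.random.default_rng(child[1 + i])
        e1, e2 = _correlated_noise(rng, _block_sqrt(mat), overlap_c)
        sl = slice(offset, offset + k)
        offset += k
        z1[sl] = mat.r @ lam1 + e1
        z2[sl] = mat.r @ lam2 + e2
        b1_true[sl] = lam1 / np.sqrt(n1)
        b2_true[sl] = lam2 / np.sqrt(n2)
        labels.append((sc.block_id, sc.hypothesis, ",".join(sc.causal_ids),
                       sc.effect_z))

    a = _assemble_sumstats(pf, z1, n1, eaf, "trait1", "quantitative")
    b = _assemble_sumstats(pf, z2, n2, eaf, "trait2", "quantitative")
    truth = SimTruth(
        pd.DataFrame({"variant_id": pf["variant_id"], "block_id": pf["block_id"],
                      "beta1": b1_true, "beta2": b2_true}),
        params={"overlap_c": overlap_c, "seed": seed, "n1": n1, "n2": n2},
        scenarios=pd.DataFrame(labels, columns=["block_id", "hypothesis",
                                                "causal_ids", "effect_z"]))
    return a, b, truth


def make_fixture(cfg: SimConfig, out_dir, n_replication: float | None = None) -> list:
    """Write a complete, self-sufficient pipeline input set.

    Produces the two trait tables, the block BED file, one LD matrix
    per block, the truth table, and an independent replication cohort
    for the first (OA-like) trait drawn with the same true effects and
    fresh noise.  Returns the list of paths written.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    blocks, mats = build_panel(cfg)
    a, b, truth = simulate_polygenic_pair(cfg, (blocks, mats))

    paths = []
    p = out / "trait1.sumstats.tsv"
    write_sumstats(a, p)
    paths.append(p)
    p = out / "trait2.sumstats.tsv"
    write_sumstats(b, p)
    paths.append(p)
    p = out / "blocks.bed"
    write_blocks(blocks, p)
    paths.append(p)
    ld_dir = out / "ld"
    ld_dir.mkdir(exist_ok=True)
    for bid, mat in mats.items():
        mp = ld_dir / f"{bid}.ld.txt"
        write_ld_matrix(mat, mp)
        paths.append(mp)
    p = out / "truth.tsv"
    truth.table.to_csv(p, sep="\t", index=False, float_format="%.10g")
    paths.append(p)

    # replication cohort: same beta1, fresh noise, no cross-trait coupling
    n_rep = cfg.n1 if n_replication is None else n_replication
    rep_child = np.random.SeedSequence(cfg.seed).spawn(2 + len(blocks) + 1)[-1]
    rng = np.random.default_rng(rep_child)
    pf = _panel_frame(blocks, mats)
    beta1 = truth.table["beta1"].to_numpy()
    z = np.empty(len(pf))
    offset = 0
    for bid in blocks.block_ids:
        mat = mats[bid]
        k = len(mat)
        sl = slice(offset, offset + k)
        offset += k
        z[sl] = mat.r @ (np.sqrt(n_rep) * beta1[sl]) + _block_sqrt(mat) @ rng.standard_normal(k)
    rep = _assemble_sumstats(pf, z, n_rep, a.df["eaf"].to_numpy(),
                             cfg.trait_names[0] + "_replication", cfg.trait_types[0])
    p = out / "trait1_replication.sumstats.tsv"
    write_sumstats(rep, p)
    paths.append(p)
    return paths
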