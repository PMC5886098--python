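"""End-to-end orchestration: harmonise -> genetic correlation ->
overlap/permutation -> colocalisation -> CPASSOC -> candidate
selection -> replication meta-analysis, with seeded reproducibility.

Reports are plain TSV/JSON and are the data of record; a run manifest
captures inputs, parameters and the seed so a run can be re-executed
identically.  All randomness derives from a single top-level seed via
fixed per-stage substreams, so disabling one stage never changes
another stage's output.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as _st

from . import __version__
from .coloc import ColocPriors, genome_coloc_scan
from .cpassoc import cpassoc_scan, estimate_corr_matrix, ivw_meta, sign_test
from .ld import ld_scores, load_blocks, load_ld_dir
from .ldsc import bivariate_ldsc, z_correlation_overlap
from .overlap import (OverlapConfig, permutation_overlap,
                      pvalue_informed_prune, select_candidates)
from .sumstats import SumStats, harmonize_pair, read_sumstats, write_sumstats

logger = logging.getLogger(__name__)

STAGES = ("harmonize", "rg", "overlap", "coloc", "cpassoc", "candidates", "meta")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Validated description of one pipeline run."""

    trait1_path: str
    trait2_path: str
    blocks_path: str
    ld_dir: str
    out_dir: str
    replication_paths: list = field(default_factory=list)
    trait1_meta: dict = field(default_factory=lambda: {
        "trait_name": "trait1", "trait_type": "binary"})
    trait2_meta: dict = field(default_factory=lambda: {
        "trait_name": "trait2", "trait_type": "quantitative"})
    seed: int = 0
    thresholds: tuple = None
    prune_r2: float = 0.05
    n_perm: int = 10_000
    priors: dict = field(default_factory=dict)
    tau_grid: tuple = (0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
    n_mc: int = 5000
    candidate_p_t: float = 0.005
    n_jackknife_blocks: int = 200
    stages: dict = field(default_factory=dict)   # stage name -> bool

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def enabled(self, stage: str) -> bool:
        return bool(self.stages.get(stage, True))

    def validate(self) -> None:
        for p in [self.trait1_path, self.trait2_path, self.blocks_path,
                  self.ld_dir, *self.replication_paths]:
            if not Path(p).exists():
                raise FileNotFoundError(f"configured path does not exist: {p}")


def _stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage substream seed, independent of toggles."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(stage_index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path, index=False) -> None:
    df.to_csv(path, sep="\t", index=index, na_rep="NA", float_format=_FLOAT_FMT)


def qq_export(s: SumStats) -> tuple[pd.DataFrame, float]:
    """Observed vs expected -log10 p pairs plus the genomic inflation
    factor lambda (median chi-square over its null median)."""
    p = np.sort(s.df["pvalue"].to_numpy())
    m = len(p)
    expected = (np.arange(1, m + 1) - 0.5) / m
    chi2 = _st.chi2.isf(np.clip(p, 1e-300, 1.0), df=1)
    lam = float(np.median(chi2) / _st.chi2.ppf(0.5, df=1))
    table = pd.DataFrame({
        "expected_neglog10_p": -np.log10(expected),
        "observed_neglog10_p": -np.log10(np.clip(p, 1e-300, None)),
    })
    return table, lam


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order.

    Returns the manifest dictionary (also written to
    ``out_dir/manifest.json``).  A stage failure writes a FAILED
    marker naming the stage and re-raises.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_fh = logging.FileHandler(out / "run.log", mode="w")
    log_fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("crosstrait")
    root.addHandler(log_fh)
    root.setLevel(logging.INFO)

    manifest: dict = {
        "version": __version__, "seed": cfg.seed,
        "inputs": {p: _sha256(p) for p in
                   [cfg.trait1_path, cfg.trait2_path, cfg.blocks_path,
                    *cfg.replication_paths]},
        "parameters": {k: v for k, v in asdict(cfg).items()
                       if k not in ("stages",)},
        "stages": [], "reports": [],
    }
    current = None
    try:
        blocks = load_blocks(cfg.blocks_path)
        ld = load_ld_dir(cfg.ld_dir, blocks)
        a = read_sumstats(cfg.trait1_path, trait_meta=cfg.trait1_meta)
        b = read_sumstats(cfg.trait2_path, trait_meta=cfg.trait2_meta)

        def stage(name):
            nonlocal current
            current = name
            t0 = time.perf_counter()
            logger.info("stage %s: start", name)
            return t0

        def done(name, t0, *reports):
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)})
            manifest["reports"].extend(str(r) for r in reports)
            logger.info("stage %s: done", name)

        # -- harmonize ------------------------------------------------
        t0 = stage("harmonize")
        a, b = harmonize_pair(a, b)
        blocks.assign(a.df.index, a.df["chrom"], a.df["pos"])
        r1 = out / "trait1.harmonized.tsv"
        r2 = out / "trait2.harmonized.tsv"
        if cfg.enabled("harmonize"):
            write_sumstats(a, r1)
            write_sumstats(b, r2)
            done("harmonize", t0, r1, r2)

        overlap_cfg = OverlapConfig(
            thresholds=tuple(cfg.thresholds) if cfg.thresholds else
            OverlapConfig.__dataclass_fields__["thresholds"].default,
            prune_r2=cfg.prune_r2, n_perm=cfg.n_perm,
            seed=_stage_seed(cfg.seed, 0))

        # -- genetic correlation --------------------------------------
        if cfg.enabled("rg"):
            t0 = stage("rg")
            scores = ld_scores(ld.values())
            res = bivariate_ldsc(a, b, scores, n_blocks=cfg.n_jackknife_blocks)
            r = out / "rg.json"
            r.write_text(json.dumps(res.to_dict(), indent=2) + "\n")
            qq1, lam1 = qq_export(a)
            qq2, lam2 = qq_export(b)
            _write_tsv(qq1, out / "trait1.qq.tsv")
            _write_tsv(qq2, out / "trait2.qq.tsv")
            (out / "lambda.json").write_text(json.dumps(
                {"trait1": lam1, "trait2": lam2}, indent=2) + "\n")
            done("rg", t0, r, out / "trait1.qq.tsv", out / "trait2.qq.tsv",
                 out / "lambda.json")

        # -- overlap / permutation ------------------------------------
        analysis = None
        if cfg.enabled("overlap"):
            t0 = stage("overlap")
            kept = pvalue_informed_prune(a, blocks, ld, cfg.prune_r2)
            analysis = permutation_overlap(
                a.df.loc[kept, "pvalue"].to_numpy(),
                b.df.loc[kept, "pvalue"].to_numpy(),
                overlap_cfg, variant_ids=kept)
            r = out / "overlap.tsv"
            _write_tsv(analysis.to_frame().drop(columns=["table2x2"])
                       .assign(n_pruned=len(kept)), r)
            done("overlap", t0, r)

        # -- colocalisation -------------------------------------------
        colocs = []
        if cfg.enabled("coloc"):
            t0 = stage("coloc")
            try:
                c = z_correlation_overlap(a, b, blocks, ld)
            except ValueError:
                logger.warning("overlap correlation unavailable; using c=0")
                c = 0.0
            colocs = genome_coloc_scan(a, b, blocks, ColocPriors(**cfg.priors), c)
            rows = [{
                "block_id": cr.block_id, "n_snps": cr.n_snps,
                "chrom": cr.chrom, "start_1based": (cr.start or 0) + 1,
                "stop_1based": cr.stop,
                "top_snp_trait1": cr.top_snp_trait1,
                "top_snp_trait2": cr.top_snp_trait2,
                "pp_h0": cr.pp[0], "pp_h1": cr.pp[1], "pp_h2": cr.pp[2],
                "pp_h3": cr.pp[3], "pp_h4": cr.pp[4],
                "modal_hypothesis": cr.modal_hypothesis,
                "flagged_h3": cr.flagged_h3, "flagged_h4": cr.flagged_h4,
                "overlap_c": c,
            } for cr in colocs]
            r = out / "coloc.tsv"
            _write_tsv(pd.DataFrame(rows), r)
            done("coloc", t0, r)

        # -- CPASSOC --------------------------------------------------
        if cfg.enabled("cpassoc"):
            t0 = stage("cpassoc")
            R = estimate_corr_matrix([a, b], blocks, ld)
            tab = cpassoc_scan(a, b, R, cfg.tau_grid, cfg.n_mc,
                               seed=_stage_seed(cfg.seed, 1))
            r = out / "cpassoc.tsv"
            _write_tsv(tab.reset_index(), r)
            (out / "study_corr.json").write_text(json.dumps(
                {"labels": R.labels, "R": R.R.tolist(),
                 "repaired": R.repaired}, indent=2) + "\n")
            done("cpassoc", t0, r, out / "study_corr.json")

        # -- candidate selection --------------------------------------
        candidates = []
        if cfg.enabled("candidates"):
            t0 = stage("candidates")
            analyses = [analysis] if analysis is not None else []
            candidates = select_candidates(analyses, colocs, cfg.candidate_p_t)
            prov = {}
            for an in analyses:
                mask = (an.a_p < cfg.candidate_p_t) & (an.b_p < cfg.candidate_p_t)
                for v in np.asarray(an.variant_ids, dtype=object)[mask]:
                    prov.setdefault(v, set()).add("overlap")
            for cr in colocs:
                if cr.flagged_h3 or cr.flagged_h4:
                    for v in (cr.top_snp_trait1, cr.top_snp_trait2):
                        prov.setdefault(v, set()).add("coloc-top")
            r = out / "candidates.tsv"
            _write_tsv(pd.DataFrame(
                {"variant_id": candidates,
                 "provenance": [",".join(sorted(prov.get(v, set())))
                                for v in candidates]}), r)
            done("candidates", t0, r)

        # -- replication meta-analysis --------------------------------
        if cfg.enabled("meta") and cfg.replication_paths:
            t0 = stage("meta")
            cohorts = [a]
            for i, p in enumerate(cfg.replication_paths):
                rep = read_sumstats(p, trait_meta={
                    "trait_name": f"replication{i + 1}",
                    "trait_type": cfg.trait1_meta.get("trait_type", "binary")})
                _, rep = harmonize_pair(a, rep)
                cohorts.append(rep)
            snps = candidates if candidates else list(a.df.index[:0])
            rows = []
            for v in snps:
                betas = [float(c.df.loc[v, "beta"]) if v in c.df.index else np.nan
                         for c in cohorts]
                ses = [float(c.df.loc[v, "se"]) if v in c.df.index else np.nan
                       for c in cohorts]
                mr = ivw_meta(betas, ses, v)
                rows.append({"variant_id": v, "pooled_beta": mr.pooled_beta,
                             "pooled_se": mr.pooled_se, "or": mr.or_,
                             "ci95_low": mr.ci95[0], "ci95_high": mr.ci95[1],
                             "p_meta": mr.p_meta,
                             "direction": mr.direction_string,
                             "n_studies": mr.n_studies})
            meta_df = pd.DataFrame(rows)
            r = out / "meta.tsv"
            _write_tsv(meta_df, r)
            reports = [r]
            eligible = meta_df[meta_df["p_meta"] < 0.05] if len(meta_df) else meta_df
            if len(eligible) and not eligible["direction"].str.contains(r"\?").all():
                p_sign = sign_test(eligible["direction"].tolist(), len(cohorts))
                r2 = out / "signtest.json"
                r2.write_text(json.dumps(
                    {"n_variants": int(len(eligible)), "n_studies": len(cohorts),
                     "p_sign": p_sign}, indent=2) + "\n")
                reports.append(r2)
            done("meta", t0, *reports)

    except Exception as exc:
        (out / "FAILED").write_text(f"stage={current}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {current!r}: {exc}") from exc
    finally:
        root.removeHandler(log_fh)
        log_fh.close()

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
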