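"""GWAS summary-statistics containers, IO and allele harmonisation.

A :class:`SumStats` holds one trait's per-variant association evidence
(alleles, additive-scale effect, SE, Z, p, sample size) as a pandas
DataFrame indexed by variant id.  All downstream analyses assume the
two traits of a pair have been passed through :func:`harmonize_pair`
so their Z-scores refer to the same effect allele at every shared
variant.

Conventions
-----------
* Effects are on the additive scale: log-odds for binary traits
  (odds ratios are converted at read time), per-SD for quantitative.
* Variant identity is the variant id (rsID); chromosome/position are
  carried through for reporting and LD-block assignment only.
* For binary traits without an explicit per-SNP sample size, the
  effective sample size ``4 / (1/n_cases + 1/n_controls)`` is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

#: canonical column order used by :func:`write_sumstats`
COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue", "z", "n", "eaf", "info",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: relative tolerance for agreement between a stored p-value and the
#: two-sided normal tail implied by the stored Z-score
P_Z_RTOL = 1e-6


def effective_sample_size(n_cases: float, n_controls: float) -> float:
    """Effective n of a case-control study, ``4/(1/n_cases + 1/n_controls)``."""
    return 4.0 / (1.0 / n_cases + 1.0 / n_controls)


def p_from_z(z: np.ndarray | float) -> np.ndarray | float:
    """Two-sided normal-tail p-value of a Z-score."""
    return 2.0 * stats.norm.sf(np.abs(z))


class AssocRecord(NamedTuple):
    """One variant's association evidence for a single trait."""

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    z: float
    n: float
    eaf: float = np.nan
    info: float = np.nan


@dataclass
class SumStats:
    """A harmonisable collection of per-variant association records.

    ``df`` is indexed by variant id (unique) with the remaining
    :data:`COLUMNS` as columns.  ``qc_tally`` records how many input
    rows were dropped at read/harmonisation time and why.
    """

    trait_name: str
    trait_type: str  # "binary" | "quantitative"
    df: pd.DataFrame
    n_cases: int | None = None
    n_controls: int | None = None
    qc_tally: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "quantitative"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")
        if not self.df.index.is_unique:
            raise ValueError("variant_ids must be unique")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def variant_ids(self) -> pd.Index:
        return self.df.index

    def record(self, variant_id: str) -> AssocRecord:
        row = self.df.loc[variant_id]
        return AssocRecord(variant_id, str(row["chrom"]), int(row["pos"]),
                           row["effect_allele"], row["other_allele"],
                           float(row["beta"]), float(row["se"]),
                           float(row["pvalue"]), float(row["z"]),
                           float(row["n"]), float(row["eaf"]),
                           float(row["info"]))

    def iter_records(self) -> Iterator[AssocRecord]:
        for vid in self.df.index:
            yield self.record(vid)

    def subset(self, variant_ids) -> "SumStats":
        """Restrict to the given variants, preserving their order."""
        return SumStats(self.trait_name, self.trait_type,
                        self.df.loc[variant_ids].copy(),
                        self.n_cases, self.n_controls, dict(self.qc_tally))


def _valid_allele(a: pd.Series) -> pd.Series:
    return a.str.fullmatch(r"[ACGT]+").fillna(False)


def _tally(tally: dict, key: str, n: int) -> None:
    if n:
        tally[key] = tally.get(key, 0) + int(n)
        logger.info("sumstats QC: dropped/adjusted %d rows (%s)", n, key)


def read_sumstats(path, column_map: Mapping[str, str] | None = None,
                  trait_meta: Mapping | None = None) -> SumStats:
    """Read, validate and complete a summary-statistics table.

    Parameters
    ----------
    path
        Whitespace- or tab-delimited text file with a header row;
        ``.gz`` handled transparently.
    column_map
        Mapping from canonical field names (``variant_id``, ``chrom``,
        ``pos``, ``effect_allele``, ``other_allele``, ``beta``, ``or``
        (odds ratio, converted to log-odds), ``se``, ``pvalue``, ``z``,
        ``n``, ``eaf``, ``info``) to column names in the file.  ``None``
        means the file already uses canonical names.
    trait_meta
        Keys ``trait_name``, ``trait_type`` and optionally ``n``,
        ``n_cases``, ``n_controls``.

    Missing Z-scores are filled from beta/SE; missing p-values from Z.
    Rows failing validation are dropped and counted in ``qc_tally``.
    """
    meta = dict(trait_meta or {})
    trait_name = meta.get("trait_name", "trait")
    trait_type = meta.get("trait_type", "quantitative")

    raw = pd.read_csv(path, sep=r"\s+")
    cmap = dict(column_map) if column_map else {c: c for c in COLUMNS if c != "variant_id"}
    if column_map is None:
        cmap["variant_id"] = "variant_id"
    missing = [col for col in cmap.values() if col not in raw.columns]
    if missing:
        raise ValueError(f"{path}: mapped columns absent from header: {missing}")

    df = pd.DataFrame(index=raw.index)
    for canon, col in cmap.items():
        if col in raw.columns:
            df[canon] = raw[col]
    tally: dict = {}

    if "variant_id" not in df:
        raise ValueError("column_map must provide variant_id")
    for c in ("beta", "se", "pvalue", "z", "n", "eaf", "info", "or"):
        if c in df:
            df[c] = pd.to_numeric(df[c], errors="coerce")
    # odds ratios -> log-odds
    if "or" in df:
        or_beta = np.log(df.pop("or").where(lambda s: s > 0))
        df["beta"] = df["beta"] if "beta" in df else or_beta
        df["beta"] = df["beta"].fillna(or_beta)
    for c in COLUMNS:
        if c not in df:
            df[c] = np.nan

    df["effect_allele"] = df["effect_allele"].astype(str).str.upper()
    df["other_allele"] = df["other_allele"].astype(str).str.upper()

    keep = df["variant_id"].notna() & ~df["variant_id"].astype(str).duplicated()
    _tally(tally, "missing_or_duplicate_id", (~keep).sum())
    ok_alleles = (_valid_allele(df["effect_allele"]) & _valid_allele(df["other_allele"])
                  & (df["effect_allele"] != df["other_allele"]))
    _tally(tally, "invalid_alleles", (keep & ~ok_alleles).sum())
    keep &= ok_alleles

    bad_se = df["se"].notna() & (df["se"] <= 0)
    _tally(tally, "nonpositive_se", (keep & bad_se).sum())
    keep &= ~bad_se

    # resolve z: beta/se is authoritative when present
    z = pd.Series(np.nan, index=df.index)
    have_bs = df["beta"].notna() & df["se"].notna()
    z[have_bs] = df.loc[have_bs, "beta"] / df.loc[have_bs, "se"]
    z = z.fillna(df["z"])
    # p + effect direction as the last resort
    need = z.isna() & df["pvalue"].notna() & df["beta"].notna()
    p_clip = df["pvalue"].clip(lower=np.nextafter(0, 1), upper=1.0)
    z[need] = np.sign(df.loc[need, "beta"]) * stats.norm.isf(p_clip[need] / 2.0)
    # sign conflict between provided z and beta
    conflict = df["z"].notna() & df["beta"].notna() & (df["z"] * df["beta"] < 0)
    _tally(tally, "z_beta_sign_conflict", (keep & conflict).sum())
    keep &= ~conflict
    unresolved = z.isna()
    _tally(tally, "unresolvable_effect", (keep & unresolved).sum())
    keep &= ~unresolved
    df["z"] = z

    # p: keep a stored value only if consistent with z
    p_implied = pd.Series(p_from_z(df["z"].to_numpy()), index=df.index)
    stored = df["pvalue"]
    inconsistent = stored.notna() & (
        (stored <= 0) | (stored > 1)
        | ((stored - p_implied).abs() > P_Z_RTOL * p_implied)
    )
    _tally(tally, "pvalue_recomputed_from_z", (keep & inconsistent).sum())
    df.loc[inconsistent | stored.isna(), "pvalue"] = p_implied

    # sample size
    if df["n"].isna().any():
        n_default = meta.get("n")
        if n_default is None and meta.get("n_cases") and meta.get("n_controls"):
            n_default = effective_sample_size(meta["n_cases"], meta["n_controls"])
        if n_default is not None:
            df["n"] = df["n"].fillna(float(n_default))
    bad_n = df["n"].isna() | (df["n"] <= 0)
    _tally(tally, "missing_or_nonpositive_n", (keep & bad_n).sum())
    keep &= ~bad_n

    # back-fill beta/se from z on the standardised scale when absent
    fill = df["beta"].isna() | df["se"].isna()
    rt_n = np.sqrt(df.loc[fill, "n"])
    df.loc[fill, "beta"] = df.loc[fill, "z"] / rt_n
    df.loc[fill, "se"] = 1.0 / rt_n

    # optional fields sanitised, never a drop reason
    df.loc[df["eaf"].notna() & ~df["eaf"].between(0, 1, inclusive="neither"), "eaf"] = np.nan
    df.loc[df["info"].notna() & ~((df["info"] > 0) & (df["info"] <= 1)), "info"] = np.nan

    df = df[keep]
    if df.empty:
        raise ValueError(f"{path}: no valid rows after QC ({tally})")
    df = df.set_index(df["variant_id"].astype(str)).drop(columns=["variant_id"])
    df.index.name = "variant_id"
    df["chrom"] = df["chrom"].astype(str)
    df["pos"] = df["pos"].astype("int64")

    return SumStats(trait_name, trait_type, df[[c for c in COLUMNS if c != "variant_id"]],
                    meta.get("n_cases"), meta.get("n_controls"), tally)


def write_sumstats(s: SumStats, path) -> None:
    """Write in the canonical tab-delimited format (round-trips to 1e-12)."""
    if len(s) == 0:
        raise ValueError("refusing to write empty SumStats")
    out = s.df.reset_index()[COLUMNS]
    out.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def _complement(alleles: pd.Series) -> pd.Series:
    return alleles.str.translate(_COMPLEMENT)


def harmonize_pair(a: SumStats, b: SumStats,
                   drop_ambiguous: bool = True) -> tuple[SumStats, SumStats]:
    """Restrict two traits to shared variants with aligned effect alleles.

    ``b``'s records are re-oriented so its effect allele matches ``a``'s
    at every variant: allele swaps negate ``beta``/``z`` and complement
    ``eaf``; strand flips (A<->T, C<->G relabelling) are reconciled
    without a sign change.  Strand-ambiguous (A/T, C/G) variants are
    dropped when ``drop_ambiguous`` is set; unreconcilable allele pairs
    are always dropped and tallied.
    """
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both datasets must be non-empty")
    shared = a.df.index[a.df.index.isin(b.df.index)]
    if len(shared) == 0:
        raise ValueError("no shared variants between the two datasets")

    da = a.df.loc[shared].copy()
    db = b.df.loc[shared].copy()
    tally_a: dict = dict(a.qc_tally)
    tally_b: dict = dict(b.qc_tally)

    aea, aoa = da["effect_allele"], da["other_allele"]
    bea, boa = db["effect_allele"], db["other_allele"]
    cbea, cboa = _complement(bea), _complement(boa)

    ambiguous = aea == _complement(aoa)  # palindromic in a (and, if matched, in b)
    same = (bea == aea) & (boa == aoa)
    swap = (bea == aoa) & (boa == aea)
    flip = (cbea == aea) & (cboa == aoa)
    flipswap = (cbea == aoa) & (cboa == aea)

    # precedence: direct orientation first, then strand-flip readings
    negate = ~same & (swap | (~flip & flipswap))
    matched = same | swap | flip | flipswap
    keep = matched & ~(drop_ambiguous & ambiguous)

    _tally(tally_b, "allele_mismatch", (~matched).sum())
    if drop_ambiguous:
        _tally(tally_b, "strand_ambiguous", (matched & ambiguous).sum())

    db.loc[negate, "beta"] *= -1.0
    db.loc[negate, "z"] *= -1.0
    db.loc[negate, "eaf"] = 1.0 - db.loc[negate, "eaf"]
    db["effect_allele"] = aea
    db["other_allele"] = aoa

    da, db = da[keep.to_numpy()], db[keep.to_numpy()]
    if len(da) == 0:
        raise ValueError("empty intersection after allele reconciliation")
    out_a = SumStats(a.trait_name, a.trait_type, da, a.n_cases, a.n_controls, tally_a)
    out_b = SumStats(b.trait_name, b.trait_type, db, b.n_cases, b.n_controls, tally_b)
    return out_a, out_b
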