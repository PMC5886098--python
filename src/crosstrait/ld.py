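"""Linkage-disequilibrium model: approximately independent blocks,
per-block signed correlation matrices, and per-SNP LD scores.

Cross-block LD is defined to be exactly zero — that is what the
"approximately independent" block decomposition licenses, and it makes
pruning, the permutation engine and the simulator block-separable.
Block files follow the BED convention (0-based half-open); reports
print 1-based inclusive coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

PSD_TOL = 1e-8


@dataclass
class LDBlocks:
    """Ordered, non-overlapping genomic blocks plus a variant->block map."""

    blocks: pd.DataFrame  # columns: chrom, start, stop, block_id
    assignment: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        req = ["chrom", "start", "stop", "block_id"]
        if list(self.blocks.columns[:4]) != req:
            self.blocks = self.blocks[req]
        b = self.blocks
        if (b["start"] >= b["stop"]).any():
            raise ValueError("block start must be < stop")
        if b["block_id"].duplicated().any():
            raise ValueError("duplicate block_id")
        for _, grp in b.groupby("chrom", sort=False):
            g = grp.sort_values("start")
            if (g["start"].to_numpy()[1:] < g["stop"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping blocks on chrom {g['chrom'].iloc[0]}")

    def __len__(self) -> int:
        return len(self.blocks)

    @property
    def block_ids(self) -> list[str]:
        return list(self.blocks["block_id"])

    def assign(self, variant_ids, chroms, positions) -> int:
        """Assign variants to blocks by chrom/pos (half-open intervals).

        Returns the number of variants falling outside every block;
        those are left out of ``assignment``.
        """
        unplaced = 0
        by_chrom = {str(c): g.sort_values("start")
                    for c, g in self.blocks.groupby("chrom", sort=False)}
        for c in by_chrom:
            g = by_chrom[c]
            by_chrom[c] = (g["start"].to_numpy(), g["stop"].to_numpy(),
                           g["block_id"].to_numpy())
        for vid, chrom, pos in zip(variant_ids, chroms, positions):
            got = by_chrom.get(str(chrom))
            if got is None:
                unplaced += 1
                continue
            starts, stops, ids = got
            k = np.searchsorted(starts, pos, side="right") - 1
            if k >= 0 and pos < stops[k]:
                self.assignment[str(vid)] = str(ids[k])
            else:
                unplaced += 1
        return unplaced

    def block_of(self, variant_id: str) -> str:
        try:
            return self.assignment[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id} has no LD-block assignment") from None


def load_blocks(path) -> LDBlocks:
    """Read a BED-like block file (chrom, start, stop[, block_id]).

    Coordinates are 0-based half-open; blocks must not overlap within a
    chromosome.  A missing block_id column is synthesised as
    ``chrom_start_stop``.
    """
    df = pd.read_csv(path, sep=r"\s+", header=None, comment="#")
    if df.shape[1] < 3:
        raise ValueError(f"{path}: expected at least 3 columns")
    # tolerate a header row
    if not str(df.iloc[0, 1]).lstrip("-").isdigit():
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :4] if df.shape[1] >= 4 else df.iloc[:, :3]
    df.columns = ["chrom", "start", "stop", "block_id"][: df.shape[1]]
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype("int64")
    df["stop"] = df["stop"].astype("int64")
    if "block_id" not in df:
        df["block_id"] = [f"{c}_{a}_{b}" for c, a, b in
                          zip(df["chrom"], df["start"], df["stop"])]
    df = df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)
    return LDBlocks(df)


def write_blocks(blocks: LDBlocks, path) -> None:
    blocks.blocks.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class LDMatrix:
    """Signed LD (correlation) matrix for the variants of one block."""

    block_id: str
    variant_ids: list
    r: np.ndarray

    def __post_init__(self) -> None:
        self.variant_ids = [str(v) for v in self.variant_ids]
        r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if r.shape != (k, k):
            raise ValueError("LD matrix shape does not match variant count")
        if not np.allclose(r, r.T, atol=PSD_TOL):
            raise ValueError("LD matrix not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=PSD_TOL):
            raise ValueError("LD matrix diagonal must be 1")
        if np.abs(r).max() > 1 + PSD_TOL:
            raise ValueError("LD entries must lie in [-1, 1]")
        if k > 1 and np.linalg.eigvalsh(r).min() < -PSD_TOL:
            raise ValueError("LD matrix not positive semi-definite")
        self.r = r
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __len__(self) -> int:
        return len(self.variant_ids)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[str(variant_id)]
        except KeyError:
            raise KeyError(f"variant {variant_id} not in block {self.block_id}") from None

    def r2(self, i: str, j: str) -> float:
        """Squared correlation between two variants of this block."""
        return float(self.r[self.index_of(i), self.index_of(j)] ** 2)


def r2(ld: LDMatrix, i: str, j: str) -> float:
    """Module-level alias for :meth:`LDMatrix.r2`."""
    return ld.r2(i, j)


def ld_scores(mats) -> pd.Series:
    """Per-SNP LD scores: sum of r^2 with all block-mates, self included.

    Population LD is taken as known (the in-silico setting), so no
    finite-sample bias correction is applied.
    """
    pieces = []
    for mat in mats:
        pieces.append(pd.Series((mat.r ** 2).sum(axis=1),
                                index=pd.Index(mat.variant_ids, name="variant_id")))
    if not pieces:
        raise ValueError("no LD matrices supplied")
    out = pd.concat(pieces)
    if out.index.duplicated().any():
        dup = out.index[out.index.duplicated()][:5].tolist()
        raise ValueError(f"variant(s) appear in more than one block: {dup}")
    out.name = "ld_score"
    return out


def write_ld_scores(scores: pd.Series, path) -> None:
    scores.rename("ld_score").to_csv(path, sep="\t", float_format="%.10g")


def write_ld_matrix(mat: LDMatrix, path) -> None:
    """Plain-text square matrix; first line holds the variant ids."""
    with open(path, "w") as fh:
        fh.write("\t".join(mat.variant_ids) + "\n")
        np.savetxt(fh, mat.r, fmt="%.10g", delimiter="\t")


def read_ld_matrix(path, block_id: str | None = None) -> LDMatrix:
    path = Path(path)
    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        r = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if block_id is None:
        block_id = path.name.split(".")[0]
    return LDMatrix(block_id, ids, r)


def load_ld_dir(ld_dir, blocks: LDBlocks | None = None) -> dict:
    """Load every ``*.ld.txt`` matrix in a directory, keyed by block id."""
    mats = {}
    for p in sorted(Path(ld_dir).glob("*.ld.txt")):
        mat = read_ld_matrix(p, p.name[: -len(".ld.txt")])
        mats[mat.block_id] = mat
    if not mats:
        raise ValueError(f"no *.ld.txt files under {ld_dir}")
    if blocks is not None:
        missing = set(blocks.block_ids) - set(mats)
        if missing:
            raise ValueError(f"LD matrices missing for blocks: {sorted(missing)[:5]}")
    return mats


def ar1_matrix(k: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix r_ij = rho^|i-j| (identity when rho=0)."""
    if not -1 < rho < 1:
        raise ValueError("rho must be in (-1, 1)")
    idx = np.arange(k)
    return rho ** np.abs(idx[:, None] - idx[None, :])
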