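import numpy as np
import pandas as pd
import pytest

from crosstrait import LDBlocks, LDMatrix, SumStats


def make_sumstats(records, trait_name="t", trait_type="quantitative",
                  n=10_000.0):
    """Build a SumStats from (variant_id, chrom, pos, ea, oa, beta, se) tuples."""
    rows = []
    for vid, chrom, pos, ea, oa, beta, se in records:
        z = beta / se
        from scipy import stats
        rows.append({"variant_id": vid, "chrom": str(chrom), "pos": pos,
                     "effect_allele": ea, "other_allele": oa, "beta": beta,
                     "se": se, "pvalue": 2 * stats.norm.sf(abs(z)), "z": z,
                     "n": n, "eaf": np.nan, "info": np.nan})
    df = pd.DataFrame(rows).set_index("variant_id")
    return SumStats(trait_name, trait_type, df)


@pytest.fixture
def tiny_pair():
    a = make_sumstats([
        ("rs1", "1", 100, "A", "G", 0.10, 0.05),
        ("rs2", "1", 200, "C", "T", -0.20, 0.10),
        ("rs3", "1", 300, "A", "T", 0.05, 0.05),   # strand-ambiguous
        ("rs4", "2", 100, "G", "C", 0.15, 0.05),   # strand-ambiguous
        ("rs5", "2", 200, "T", "G", 0.00, 0.10),
    ], trait_name="OA", trait_type="binary")
    b = make_sumstats([
        ("rs1", "1", 100, "G", "A", -0.10, 0.05),  # swapped alleles
        ("rs2", "1", 200, "G", "A", -0.20, 0.10),  # strand-flipped
        ("rs3", "1", 300, "A", "T", 0.05, 0.05),
        ("rs4", "2", 100, "G", "C", 0.15, 0.05),
        ("rs5", "2", 200, "C", "A", 0.30, 0.10),   # flip + swap
    ], trait_name="BMD")
    return a, b


def identity_block(block_id, ids, chrom="1", start=0, stop=None):
    stop = stop if stop is not None else start + 1000 * len(ids)
    blocks = LDBlocks(pd.DataFrame(
        [(chrom, start, stop, block_id)],
        columns=["chrom", "start", "stop", "block_id"]))
    for v in ids:
        blocks.assignment[v] = block_id
    mat = LDMatrix(block_id, ids, np.eye(len(ids)))
    return blocks, {block_id: mat}


def stack_blocks(specs):
    """specs: list of (block_id, ids, r_matrix); all on chrom 1, adjacent."""
    rows, mats, assignment = [], {}, {}
    pos = 0
    for block_id, ids, r in specs:
        rows.append(("1", pos, pos + 1000 * len(ids), block_id))
        pos += 1000 * len(ids)
        mats[block_id] = LDMatrix(block_id, list(ids), np.asarray(r, dtype=float))
        for v in ids:
            assignment[v] = block_id
    blocks = LDBlocks(pd.DataFrame(
        rows, columns=["chrom", "start", "stop", "block_id"]))
    blocks.assignment = assignment
    return blocks, mats
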