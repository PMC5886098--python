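"""Generate a paired synthetic GWAS and harmonise the two tables.

Builds an OA-like case-control study and a BMD-like quantitative study
over a small shared variant panel with block LD, writes them to disk,
reads them back and allele-aligns them.
"""

from pathlib import Path
import tempfile

from crosstrait import SimConfig, harmonize_pair, make_fixture, read_sumstats

out = Path(tempfile.mkdtemp(prefix="crosstrait_"))
cfg = SimConfig(m_snps=2_000, block_size=40, seed=1)
paths = make_fixture(cfg, out)
print(f"fixture: {len(paths)} files under {out}")

a = read_sumstats(out / "trait1.sumstats.tsv",
                  trait_meta={"trait_name": "OA", "trait_type": "binary",
                              "n_cases": 7410, "n_controls": 11009})
b = read_sumstats(out / "trait2.sumstats.tsv",
                  trait_meta={"trait_name": "BMD",
                              "trait_type": "quantitative"})
a, b = harmonize_pair(a, b)

print(f"shared variants after harmonisation: {len(a)}")
print(f"effective n (OA): {a.df['n'].iloc[0]:.0f}   n (BMD): {b.df['n'].iloc[0]:.0f}")
print(a.df[["chrom", "pos", "effect_allele", "other_allele", "beta", "se",
            "pvalue"]].head(3))
# Each row is one variant's association evidence; effects are log-odds
# (OA) and per-SD (BMD), aligned to the same effect allele in both tables.
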