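# crosstrait

Cross-phenotype analysis of GWAS summary statistics, built around the
classic osteoarthritis (OA) / bone mineral density (BMD) setting: two
epidemiologically linked traits, one case-control and one
quantitative, studied only through per-variant summary statistics.
The package is aimed at statistical geneticists who want a tested,
seedable implementation of the standard cross-trait toolkit on
summary data:

* **Genetic correlation** by bivariate LD score regression.  For SNP
  *j* with LD score *l<sub>j</sub>* = Σ<sub>k</sub> r²<sub>jk</sub>,
  the regressions
  E[χ²<sub>j</sub>] = 1 + n h² l<sub>j</sub>/m and
  E[z<sub>1j</sub> z<sub>2j</sub>] = c + √(n₁n₂) ρ<sub>g</sub> l<sub>j</sub>/m
  yield heritabilities h², genetic covariance ρ<sub>g</sub>, and an
  intercept *c* that absorbs sample overlap; r<sub>g</sub> =
  ρ<sub>g</sub>/√(h₁²h₂²), with block-jackknife standard errors.
* **Signal overlap** with a permutation null: p-value-informed greedy
  LD pruning (r² > 0.05 removed), 2×2 contingency tables of variants
  below/above ten p-value thresholds in each trait, Pearson
  chi-square, and an empirical p from shuffling the second trait's
  p-values.
* **Bayesian colocalisation** per approximately independent LD block:
  posteriors over five hypotheses (H0 none, H1/H2 one trait only,
  H3 one shared causal variant, H4 two distinct causal variants) from
  Wakefield approximate Bayes factors
  log ABF = ½ log(V/(V+W)) + z²W/(2(V+W)), with an exact
  bivariate-normal shared-causal factor that accounts for sample
  overlap.
* **Cross-phenotype association**: S<sub>hom</sub> =
  (wᵀR⁻¹z)²/(wᵀR⁻¹w) with w = √n and a study correlation matrix R
  estimated from independent null SNPs; S<sub>het</sub> maximises the
  same statistic over |z| truncation levels with a Monte-Carlo null.
* **Replication**: fixed-effects inverse-variance-weighted
  meta-analysis and an exact binomial direction-of-effect sign test.

Because consortium summary statistics are access-controlled, the
package ships a first-class synthetic-data module that generates
paired summary statistics with known truth — block LD, bivariate
polygenic effects with tunable r<sub>g</sub>, per-region causal
configurations matching H0–H4, and overlap-correlated noise — so the
entire pipeline is testable end to end.

## Worked example

```python
from crosstrait import (SimConfig, bivariate_ldsc, build_panel, ld_scores,
                        simulate_polygenic_pair, z_correlation_overlap)

cfg = SimConfig(seed=2)          # OA/BMD-like defaults, rg = 0.18
blocks, mats = build_panel(cfg)
a, b, truth = simulate_polygenic_pair(cfg, (blocks, mats))
res = bivariate_ldsc(a, b, ld_scores(mats.values()))
print(res.rg, res.rg_se, res.p_rg)
```

Running `python examples/02_genetic_correlation.py` (the same code
with printing) gives:

```
rg   =  0.294 (se 0.088, p 0.000836) [generating value 0.18]
h2_1 =  0.245 (se 0.038) [true 0.2]
h2_2 =  0.288 (se 0.033) [true 0.25]
cross-trait intercept = -0.030 [sample-overlap c = 0.05]
null-SNP Z correlation estimate of overlap = 0.062
```

One seed's r̂<sub>g</sub> of 0.294 sits about 1.3 jackknife SEs from
the generating 0.18 — single-draw noise at m = 20,000 SNPs; averaged
over seeds the estimator centres on the truth (the acceptance script
below measures this).  The other `examples/*.py` scripts walk
through harmonisation, the overlap permutation test, colocalisation
and the CPASSOC/meta statistics, each printing what its numbers mean.

A thin CLI mirrors the library
(`crosstrait simulate|harmonize|rg|overlap|coloc|cpassoc|meta|run-all`),
with `run-all` driving the full pipeline from a YAML config and
writing per-stage TSV/JSON reports plus a reproducibility manifest.

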