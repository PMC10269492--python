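# rootniche

Analysis toolkit for root-associated microbiome studies along the
soil–rhizosphere–endosphere continuum. It re-implements, as a tested and
reusable pipeline, the statistical workflow used in amplicon surveys of
bulk soil, rhizosphere soil and root endosphere communities across host
cultivars:

* **Alpha/beta diversity** — bias-corrected Chao1
  (S_obs + F₁(F₁−1)/(2(F₂+1))), Shannon entropy (H = −Σ pᵢ ln pᵢ),
  Bray–Curtis dissimilarity, non-metric multidimensional scaling (Kruskal
  stress-1), ANOSIM and a two-way PERMANOVA partitioning marginal sums of
  squares for compartment niche and cultivar.
* **Biomarker discovery** — an LDA-effect-size (LEfSe-style) screen at
  phylum/class/order ranks: Kruskal–Wallis gate at P < 0.05 plus a
  bootstrap linear-discriminant effect size on the 10⁶ relative-abundance
  scale, reported as log₁₀ and thresholded at 4.0.
* **Community assembly null models** — abundance-weighted βMNTD with a
  taxa-shuffle null (999 randomizations) giving βNTI, a Bray–Curtis
  Raup–Crick index (RC_Bray) preserving per-sample richness and totals, and
  the five-way process classification: βNTI > +2 heterogeneous selection,
  βNTI < −2 homogeneous selection, |βNTI| < 2 with RC_Bray > 0.95 dispersal
  limitation, < −0.95 homogenizing dispersal, otherwise undominated.
* **Interkingdom co-occurrence networks** — Spearman |ρ| > 0.7 with jointly
  BH-adjusted P < 0.01 over taxa at > 0.5 % mean relative abundance;
  topology (average degree 2E/N, density, greedy modularity, clustering,
  sign balance, per-kingdom breakdown) and highest-degree keystone taxa;
  GraphML/TSV export.
* **Functional guilds** — a generic taxonomy→function mapping engine
  (FAPROTAX/FUNGuild-style, user-supplied mapping table) with per-sample
  guild abundances and cross-niche Kruskal–Wallis comparisons.
* **Synthetic data** — a seeded generator emulating the full study design
  (two kingdoms, 3 niches × 3 cultivars × 6 replicates, compartment effects
  stronger than cultivar effects, phylogenetically structured niche
  responses on a simulated pure-birth tree, planted intra- and interkingdom
  correlations and assembly regimes), so every stage is testable without
  any sequence data.

## Worked example

```python
from rootniche import SimulationParams, simulate_tree, simulate_community_design
from rootniche.diversity import bray_curtis, permanova_two_way, anosim

tree = simulate_tree(150, seed=1)
table, meta = simulate_community_design(SimulationParams(rng_seed=1), tree)
dist = bray_curtis(table)
res = permanova_two_way(dist, meta.niche(), meta.cultivar(),
                        n_perm=999, seed=1, names=("niche", "cultivar"))
print(res.summary())
print("ANOSIM R =", round(anosim(dist, meta.niche(), 999, 1).statistic, 3))
```

prints

```
          df      SS     R2       F      p
niche      2  4.5490 0.3912 16.5098 0.0010
cultivar   2  0.3294 0.0283  1.1957 0.2130
residual  49  6.7505 0.5805     NaN    NaN
total     53 11.6290 1.0000     NaN    NaN
ANOSIM R = 0.977
```

— the compartment niche explains over ten times more Bray–Curtis variance
(R² ≈ 0.39, P = 0.001) than the host cultivar (R² ≈ 0.028), mirroring the
dominance of the soil–root gradient over host genotype, and ANOSIM confirms
strong niche separation (R ≈ 0.98). The R² column is the fraction of total
distance-based variance attributed to each factor; P-values come from 999
permutations of the sample rows.

The same objects feed the other stages
(`rootniche.assembly.assembly_analysis`, `rootniche.networks.build_network`,
`rootniche.biomarkers.lefse_from_otus`,
`rootniche.functions.map_functions`), or run everything at once:

```sh
rootniche --seed 1 --outdir out run-all          # synthetic end-to-end run
rootniche --seed 1 --outdir fix simulate         # emit the fixture set only
```

`run-all` writes per-stage TSVs and a `manifest.json` with a config
snapshot and SHA-256 digests of all inputs and outputs; re-running with the
same seed reproduces every file byte for byte.

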