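# Methods

This note records the models, parameter choices and numerical conventions
behind `rootniche`, and what the synthetic-data tests do and do not show
about real amplicon data.

## Data model and normalisation

The universal input is an integer OTU count table (taxa × samples) with a
Greengenes-style lineage string and a kingdom tag per taxon, a per-sample
factor table (compartment niche ∈ {bulk, rhizosphere, endosphere}; cultivar
∈ {rabbiteye, northern_highbush, southern_highbush}) and, for the
phylogenetic null models, a rooted Newick tree whose tips are taxon IDs.

Counts are stored as integers; relative abundances are always derived by
total-sum scaling (each sample column divided by its total), never stored.
No rarefaction is applied by default — all group tests and distances work
on relative abundances, which makes every stage deterministic and
depth-invariant. A seeded rarefaction (`OtuTable.rarefy`, subsampling
without replacement) is available for users who prefer the subsampled
workflow; results in this package's own tests and acceptance runs use the
total-sum-scaled path.

The mean-relative-abundance filter used before network construction
averages over all samples of the table being networked and applies a strict
`>` comparison, so a taxon sitting exactly at the 0.5 % threshold is
removed.

## Diversity and ordination

* **Chao1** is the bias-corrected form S_obs + F₁(F₁−1)/(2(F₂+1)), defined
  even when no doubletons exist (F₂ = 0 reduces it to
  S_obs + F₁(F₁−1)/2).
* **Shannon** uses the natural logarithm. Tool chains differ on the base;
  fixing ln keeps H in nats with maximum ln S.
* **Bray–Curtis** is computed on relative abundances,
  d(x,y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), hence invariant to sequencing depth.
* **NMDS** minimises Kruskal stress-1 by isotonic-regression majorization
  from seeded random starts (20 restarts by default); the lowest-stress
  restart is returned and a non-convergence flag is set if the iteration
  cap is reached.
* **ANOSIM** uses average ranks of the condensed distance vector;
  R = (mean between-group rank − mean within-group rank)/(M/2) with
  M = n(n−1)/2, and a permutation p-value
  (1 + #{R_perm ≥ R_obs})/(n_perm+1).
* **Two-way PERMANOVA** partitions the Gower-centred squared-distance
  matrix G = −½ J D² J. For each factor the marginal (Type-II) sum of
  squares is the drop in tr(H G) when that factor leaves the two-factor
  hat matrix; pseudo-F uses the full-model residual, and p-values come from
  permutations of raw sample rows. No interaction term is fitted — the
  design is balanced and crossed, so factor and residual R² sum to one.
  With a constant second factor the procedure reduces exactly to the
  one-way test (verified against an independent implementation).
  Permutation counts default to 999.

## Biomarker screen (LDA effect size)

Features are per-rank aggregated tables (phylum, class, order) scaled to
per-sample totals of 10⁶. Two gates apply in series:

1. Kruskal–Wallis across niches at P < α (default 0.05, unadjusted, as in
   the standard LEfSe design).
2. An LDA effect size: over 30 bootstrap subsamples (2/3 of samples,
   class-stratified), a one-vs-rest linear discriminant (least-squares
   solver with Ledoit–Wolf shrinkage) is fitted per class; a feature's
   effect is 0.5 × (|unit-coefficient| × projected class separation +
   |raw class-mean difference|), maximised over classes, and the score is
   log₁₀(1 + mean bootstrap effect). Biomarkers need score ≥ 4.0, i.e. an
   effect around 10⁴ on the 10⁶ scale. The enriched class is the argmax of
   class means. All-zero features score 0 and sample order is canonicalised
   before bootstrapping, so scores are invariant to column permutations.

The exact effect-size blend is a documented package choice (the reference
combination is not uniquely defined); recovery of planted signals and the
null behaviour below do not hinge on its details. No subclass
(within-class) stage exists because the design has no subclass factor.

**Calibration caveat.** At desk scale the synthetic tables carry ~150 OTUs,
so a phylum aggregate contains ~19 OTUs (real surveys have hundreds per
phylum). Dominant phylum features then sit at 1–4 × 10⁵ with replicate
noise large enough that chance class-mean differences occasionally exceed
10⁴ — and because the KW and LDA gates are positively correlated (a feature
passing KW by chance has, by selection, an unusually large mean
difference), unstructured designs yield on average ~1–2 chance biomarkers
per run, concentrated in the largest aggregates. Order-rank features, whose
sizes match realistic scales, stay clean. Tests therefore assert a small
mean false-biomarker count rather than strictly zero; this is a property of
the LDA ≥ 4 gate under few large compositional features at n = 6–18 per
class, not of the implementation.

## Assembly null models

* **βMNTD** (abundance-weighted by default, matching standard practice):
  0.5 [Σ_{i∈k} f_ik min_{j∈l} Δ_ij + Σ_{j∈l} f_jl min_{i∈k} Δ_ij] with f the
  within-sample relative abundances over present taxa and Δ patristic
  distances.
* **βNTI** compares observed βMNTD with a null that shuffles the
  taxon↔tip assignment uniformly across the *whole* taxon pool of the table
  (not within clades), 999 randomizations by default;
  βNTI = (obs − mean_null)/sd_null. Zero-count taxa that are on the tree
  remain part of the shuffle pool — the regional pool provides the
  phylogenetic contrast that makes within-group selection detectable.
  Pairs with zero null spread (e.g. a star phylogeny, or two communities
  containing the whole pool) are reported as missing with a warning.
* **RC_Bray** draws, per pair, 999 null community pairs that preserve each
  sample's observed richness and total count: occurrences are sampled
  without replacement weighted by regional occupancy (Gumbel top-k), the
  remaining individuals multinomially weighted by regional relative
  abundance. RC_raw = (#{null BC < obs} + ½ #{ties})/999 with a 10⁻¹²
  tie tolerance, rescaled to 2(RC_raw − ½) ∈ [−1, 1].
* **Classification** follows the five-way rule set (±2 on βNTI, ±0.95 on
  RC_Bray, strict inequalities); values exactly on a threshold fall through
  to the stochastic branch, and pairs with undefined βNTI are labelled
  `undefined` and excluded from fractions with a warning.
* **Pair sets**: with metadata, pairs are within-niche comparisons pooled
  across cultivars, while the null models always operate on the full
  table's taxon pool. Per-niche process fractions report the five
  processes plus deterministic (both selection types) and stochastic
  (remainder) totals.
* **Seeding**: each sample pair draws from a counter-derived substream of
  the master seed, so results do not depend on pair iteration order.

## Co-occurrence networks

Spearman correlations (average ranks, two-sided t-approximation p-values;
exactness at these sample sizes was checked against explicit-loop oracles)
over abundance-filtered taxa; for interkingdom networks the two kingdom
tables are concatenated over an identical sample set. BH adjustment is
applied jointly to all pairs of the network being built. Edges require
p_adj < 0.01 **and** |ρ| > 0.7 (strict, as printed). Zero-variance taxa are
skipped with a warning; isolated nodes are dropped from the graph but
counted in the provenance record. Topology uses 2E/N for average degree,
2E/(N(N−1)) for density, greedy modularity maximisation (deterministic) for
community structure, and the mean local clustering coefficient. Keystone
taxa are the top-k (default 10) nodes by degree, ties broken by higher mean
relative abundance then lexical taxon ID.

## Functional guild mapping

The mapping engine is database-agnostic: a matcher is a taxon ID, a
whole-rank lineage prefix, or a single rank token (case-insensitive). A
taxon with m functions contributes its full relative abundance to each
(FAPROTAX-style); a `split` toggle divides by m instead, in which case
assigned + unassigned columns sum to one. Cross-niche comparisons use
Kruskal–Wallis with BH adjustment and the conventional star coding
(* P<0.05, ** P<0.01, *** P<0.001 on adjusted p).

## Synthetic data generator

The generator emulates the *processed outputs* of the study design, not
reads: two kingdom tables over 3 niches × 3 cultivars × 6 replicates.

* **Trees** are seeded pure-birth (Yule) trees, ultrametric by
  construction; tips are named OTU1..OTUn in traversal order.
* **Abundances**: log-normal baseline (σ = 1) + niche and cultivar
  log-fold shifts + per-sample log-normal noise (`dispersion`, default 1.0,
  a realistic OTU-level overdispersion for replicate field samples),
  softmax-normalised and drawn multinomially at `depth` (default 10,000)
  reads — every sample's counts sum exactly to `depth`.
* **Niche structure**: each niche owns a disjoint responsive taxon subset
  (10 % of taxa) shifted by `niche_effect` (default 2.0 natural-log-fold);
  with `trait_signal` λ ∈ [0,1] the shift blends the subset indicator with
  a standardized Brownian trait simulated on the tree, so closely related
  taxa share niche responses. Cultivar shifts work identically at
  `cultivar_effect` (default 0.4 < niche_effect, reproducing the
  compartment-dominates-cultivar ordering).
* **Assembly regimes** produce parameter-recovery material. *Selection*:
  taxa are exponentially down-weighted by squared Brownian-trait distance
  to a shared habitat optimum placed at the 0.95 trait quantile (a central
  optimum would equal the Brownian root state and admit convergent taxa
  from every clade), filter width 0.18 trait-sd; membership turnover comes
  from per-sample log-normal noise (σ = 2.0). *Drift*: the same turnover
  noise around a phylogenetically unstructured log-normal pool. Regime
  analyses use 768-taxon pools at depth 500 — βNTI's nearest-taxon contrast
  grows with pool size, and the study's real pools run to thousands of
  OTUs; 12-sample sets keep the pair count manageable. Zero-total taxa are
  retained as part of the regional pool.
* **Planted correlations** re-order a taxon's counts across samples to
  follow latent bivariate-normal ranks, preserving marginals exactly. The
  latent Pearson correlation is set by the Gaussian-copula relation
  2 sin(πs/6) at s = 1 − (1−strength)/4, above the nominal strength, so the
  realized Spearman still meets `strength` in expectation after rank
  quantization, finite-sample attenuation and compositional closure.
* **Function maps** assign 0–2 guilds per taxon from a vocabulary that
  includes ericoid mycorrhizae, soil saprotroph, plant pathogen,
  chemoheterotrophy, cellulolysis and nitrogen fixation.

**What passing tests show** — that each statistic is computed correctly
(closed forms, brute-force oracles), that the permutation machinery is
calibrated (type-I error, taxa-shuffle null), and that planted effects of
realistic magnitude are recovered at the published thresholds. **What they
do not show** — performance on real data with thousands of taxa, sequencing
artefacts, compositional correlation structure beyond the planted factors,
or database-quality guild annotations; the generator's noise is log-normal
and taxon-independent, which is simpler than real overdispersion.

## Numerical conventions and seeds

All randomness flows from one master seed through named substreams
(`_rng.substream`), so adding a stage never perturbs another stage's
results and per-pair null models are iteration-order independent. Null
standard deviations use ddof = 1. Bray–Curtis tie comparisons in RC_Bray
use a 10⁻¹² tolerance. Distance matrices are validated symmetric with zero
diagonals by the scikit-bio container. The end-to-end pipeline writes a
manifest with SHA-256 digests of every input and output; identical seeds
reproduce identical bytes.

## Problem sizes used in tests and the acceptance script

Unit and acceptance runs scale the study down to keep the suite quick while
preserving the statistical regime: community designs of 40–150 taxa with
2–6 replicates per niche × cultivar cell, assembly pools of 5 (oracles) to
768 taxa (regime recovery), 199–999 null-model randomizations, 199–999
permutations, 1000 datasets for the type-I calibration, and 50 seeded
replicates for recovery rates. These sizes are the package's own choices
and are reported alongside each value in `results/acceptance.json`.

## Known limitations

* The two-way PERMANOVA assumes a balanced crossed design for the R²
  partition identity; unbalanced designs still run (Type-II marginal SS)
  but R²s need not sum to one.
* LEfSe-style scores at coarse ranks are fragile for few, large
  compositional features (see calibration caveat above).
* RC_Bray's null assumes occupancy-weighted occurrence and
  abundance-weighted filling; other null choices (e.g. equiprobable
  occurrence) would shift RC magnitudes.
* NMDS stress depends on restarts; with 20 restarts stress differences
  below ~10⁻³ between runs of different seeds are not meaningful.
* The CLI's `network --mode inter` assumes the first table is bacterial
  and the second fungal.
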