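"""Synthetic OTU tables, trees, metadata and function maps.

The generator emulates the processed outputs of a soil-to-root amplicon
study: two kingdom tables (16S-style bacterial, ITS-style fungal taxonomy)
over a crossed design of 3 compartment niches x 3 host cultivars x 6
replicates, with compartment effects stronger than cultivar effects,
phylogenetically structured niche responses, and planted intra-/interkingdom
correlations serving as ground truth for network recovery.

Abundance model: a log-normal baseline per taxon, plus log-fold niche and
cultivar shifts, plus per-sample log-normal noise (the ``dispersion`` knob),
renormalised through a softmax and sampled multinomially at a fixed
sequencing depth. Niche responses can be phylogenetically conserved by
blending the niche indicator with a Brownian trait simulated on the tree
(``trait_signal`` interpolates between the two, Pagel-lambda style).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from . import io as rio
from ._rng import substream

GUILD_VOCABULARY = (
    "ericoid mycorrhizae",
    "soil saprotroph",
    "plant pathogen",
    "chemoheterotrophy",
    "cellulolysis",
    "nitrogen fixation",
)

_BACTERIAL_PHYLA = ("Proteobacteria", "Actinobacteria", "Acidobacteria",
                    "Chloroflexi", "Bacteroidota", "Firmicutes",
                    "Planctomycetes", "Verrucomicrobia")
_FUNGAL_PHYLA = ("Ascomycota", "Basidiomycota", "Mortierellomycota",
                 "Chytridiomycota", "Glomeromycota")
_FUNGAL_ORDERS = ("Helotiales", "Chaetothyriales", "Sebacinales",
                  "Hypocreales", "Pleosporales", "Agaricales",
                  "Mortierellales", "Eurotiales")


@dataclass
class SimulationParams:
    """Knobs of the synthetic community generator.

    ``niche_effect`` and ``cultivar_effect`` are log-fold shifts (natural
    log); the study design has the compartment effect dominating the cultivar
    effect, so the defaults keep ``cultivar_effect < niche_effect``.
    ``dispersion`` is the per-sample log-normal noise sigma; ``depth`` the
    multinomial sequencing depth per sample.
    """

    n_taxa: int = 150
    n_replicates: int = 6
    niche_effect: float = 2.0
    cultivar_effect: float = 0.4
    dispersion: float = 1.0
    depth: int = 10_000
    trait_signal: float = 0.5
    frac_responsive: float = 0.1
    planted_edges: list = field(default_factory=list)
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if self.niche_effect < 0 or self.cultivar_effect < 0:
            raise ValueError("effects must be >= 0")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.trait_signal <= 1:
            raise ValueError("trait_signal must be in [0, 1]")


# -- phylogeny ---------------------------------------------------------------

def simulate_tree(n_taxa: int, seed: int, birth_rate: float = 1.0) -> TreeNode:
    """A seeded pure-birth (Yule) ultrametric tree with tips OTU1..OTUn.

    Lineages split at exponential waiting times; all extant lineages are cut
    at the same final time, so every root-to-tip depth is identical.
    """
    if n_taxa < 2:
        raise ValueError("n_taxa must be >= 2")
    rng = substream(seed, "tree")
    root = TreeNode()
    t = 0.0
    active: list[tuple[TreeNode, float]] = []
    for _ in range(2):
        child = TreeNode()
        root.append(child)
        active.append((child, 0.0))
    while len(active) < n_taxa:
        k = len(active)
        t += rng.exponential(1.0 / (birth_rate * k))
        node, born = active.pop(int(rng.integers(k)))
        node.length = t - born
        for _ in range(2):
            child = TreeNode()
            node.append(child)
            active.append((child, t))
    t += rng.exponential(1.0 / (birth_rate * len(active)))
    for node, born in active:
        node.length = t - born
    for i, tip in enumerate(root.tips()):
        tip.name = f"OTU{i + 1}"
    return root


def brownian_trait(tree: TreeNode, rng: np.random.Generator,
                   standardize: bool = True) -> pd.Series:
    """Simulate a Brownian-motion trait along the tree (variance = path length)."""
    values: dict[int, float] = {}
    for node in tree.preorder(include_self=True):
        parent = 0.0 if node.parent is None else values[id(node.parent)]
        length = node.length or 0.0
        values[id(node)] = parent + rng.normal() * np.sqrt(length)
    trait = pd.Series({tip.name: values[id(tip)] for tip in tree.tips()})
    if standardize:
        sd = trait.std(ddof=0)
        trait = (trait - trait.mean()) / (sd if sd > 0 else 1.0)
    return trait


# -- taxonomy ----------------------------------------------------------------

def _assign_taxonomy(tip_names: list[str], kingdom: str) -> pd.Series:
    """Hierarchical synthetic lineages; contiguous blocks in tip-traversal
    order approximate clades, so taxonomy tracks the phylogeny."""
    n = len(tip_names)
    if kingdom == "bacteria":
        k_name, phyla = "Bacteria", _BACTERIAL_PHYLA
    else:
        k_name, phyla = "Fungi", _FUNGAL_PHYLA
    n_phyla = max(2, min(len(phyla), n // 12))
    lineages = {}
    blocks = np.array_split(np.asarray(tip_names, dtype=object), n_phyla)
    order_counter = 0
    for pi, block in enumerate(blocks):
        phylum = phyla[pi]
        class_blocks = np.array_split(block, max(1, len(block) // 12))
        for ci, cblock in enumerate(class_blocks):
            cls = f"{phylum}_cls{ci + 1}"
            ord_blocks = np.array_split(cblock, max(1, len(cblock) // 6))
            for oblock in ord_blocks:
                if kingdom == "fungi":
                    base = _FUNGAL_ORDERS[order_counter % len(_FUNGAL_ORDERS)]
                    rep = order_counter // len(_FUNGAL_ORDERS)
                    order = base if rep == 0 else f"{base}_{rep + 1}"
                else:
                    order = f"{phylum}_ord{order_counter + 1}"
                order_counter += 1
                for gi, name in enumerate(oblock):
                    lineages[name] = (
                        f"k__{k_name};p__{phylum};c__{cls};o__{order};"
                        f"f__{order}_fam;g__{order}_gen{gi // 3 + 1}")
    return pd.Series(lineages).reindex(tip_names)


# -- main community generator ------------------------------------------------

def simulate_community_design(params: SimulationParams, tree: TreeNode,
                              kingdom: str = "bacteria",
                              return_truth: bool = False):
    """Simulate the full niche x cultivar x replicate design.

    Each niche owns a disjoint responsive taxon subset shifted up by
    ``niche_effect`` in that niche; with ``trait_signal`` > 0 the shift is
    blended with a standardized Brownian trait so related taxa share niche
    responses. Cultivar shifts work the same way (no trait) at the smaller
    ``cultivar_effect``. Every sample's counts sum exactly to ``depth``.
    """
    taxa = [tip.name for tip in tree.tips()]
    n = len(taxa)
    if n != params.n_taxa:
        raise ValueError(f"tree has {n} tips, params.n_taxa={params.n_taxa}")
    rng = substream(params.rng_seed, "community", kingdom)

    base = rng.normal(0.0, 1.0, size=n)
    m = max(1, round(params.frac_responsive * n))
    shuffled = rng.permutation(n)
    niche_sets = {niche: shuffled[i * m:(i + 1) * m]
                  for i, niche in enumerate(rio.NICHES)}
    cult_sets = {cult: shuffled[(3 + i) * m:(4 + i) * m]
                 for i, cult in enumerate(rio.CULTIVARS)}

    lam = params.trait_signal
    niche_shift = {}
    for niche in rio.NICHES:
        indicator = np.zeros(n)
        indicator[niche_sets[niche]] = 1.0
        trait = brownian_trait(tree, rng).to_numpy()
        niche_shift[niche] = params.niche_effect * (
            (1 - lam) * indicator + lam * trait)
    cult_shift = {}
    for cult in rio.CULTIVARS:
        indicator = np.zeros(n)
        indicator[cult_sets[cult]] = 1.0
        cult_shift[cult] = params.cultivar_effect * indicator

    niche_codes = {"bulk": "BS", "rhizosphere": "RH", "endosphere": "EN"}
    cult_codes = {"rabbiteye": "RB", "northern_highbush": "NH",
                  "southern_highbush": "SH"}
    cols, meta_rows = {}, []
    for niche in rio.NICHES:
        for cult in rio.CULTIVARS:
            for rep in range(1, params.n_replicates + 1):
                sid = f"{niche_codes[niche]}_{cult_codes[cult]}_{rep}"
                log_ab = (base + niche_shift[niche] + cult_shift[cult]
                          + rng.normal(0.0, params.dispersion, size=n))
                p = np.exp(log_ab - log_ab.max())
                p /= p.sum()
                cols[sid] = rng.multinomial(params.depth, p)
                meta_rows.append((sid, niche, cult))
    counts = pd.DataFrame(cols, index=taxa)
    taxonomy = _assign_taxonomy(taxa, kingdom)
    table = rio.OtuTable(counts, taxonomy, kingdom)
    if params.planted_edges:
        table = plant_correlations(table, params.planted_edges,
                                   strength=0.9,
                                   seed=params.rng_seed)
    meta = rio.SampleMetadata(
        pd.DataFrame(meta_rows, columns=["sample_id", "niche", "cultivar"]
                     ).set_index("sample_id"))
    if return_truth:
        truth = {"niche_responsive": {n: [taxa[i] for i in idx]
                                      for n, idx in niche_sets.items()},
                 "cultivar_responsive": {c: [taxa[i] for i in idx]
                                         for c, idx in cult_sets.items()}}
        return table, meta, truth
    return table, meta


# -- assembly-regime generator -----------------------------------------------

def simulate_assembly_pair_set(regime: str, tree: TreeNode,
                               params: SimulationParams,
                               n_samples: int = 12,
                               kingdom: str = "bacteria") -> rio.OtuTable:
    """Communities assembled under a known ecological regime.

    ``selection``: every community is filtered on a phylogenetically
    conserved (Brownian) trait toward one shared optimum, producing
    phylogenetic clustering and hence strongly negative beta-NTI between
    pairs (homogeneous selection). ``drift``: stochastic resampling from a
    single phylogenetically unstructured regional pool, so |beta-NTI| < 2
    dominates. Both regimes add per-sample log-normal sampling noise
    (sigma = ``params.dispersion``) before the multinomial draw so that
    communities show realistic compositional turnover; without it every
    sample would contain essentially the whole pool and the nearest-taxon
    null would be degenerate.
    """
    if regime not in ("selection", "drift"):
        raise ValueError(f"unknown regime {regime!r}")
    taxa = [tip.name for tip in tree.tips()]
    if len(taxa) < 2:
        raise ValueError("regional pool must contain at least 2 taxa")
    rng = substream(params.rng_seed, "assembly", regime)
    turnover_sigma = 2.0  # per-sample membership turnover (log-normal)
    if regime == "selection":
        trait = brownian_trait(tree, rng).to_numpy()
        # the optimum sits in the upper tail of the trait so the filter
        # favours the few clades that drifted toward it; a central optimum
        # would admit convergent taxa from every clade (the root state).
        # The filter must dominate the turnover noise for taxa one trait-sd
        # away, hence the narrow width.
        optimum = float(np.quantile(trait, 0.95))
        filter_width = 0.18  # strong habitat filter
        base = -(trait - optimum) ** 2 / (2 * filter_width ** 2)
    else:
        base = rng.normal(0.0, params.dispersion, size=len(taxa))
    cols = {}
    for i in range(n_samples):
        field = base + rng.normal(0.0, turnover_sigma, size=len(taxa))
        p = np.exp(field - field.max())
        p /= p.sum()
        cols[f"P{i + 1}"] = rng.multinomial(params.depth, p)
    # zero-total taxa are kept: they are part of the regional pool and the
    # taxa-shuffle null of beta-NTI needs the full pool for contrast
    counts = pd.DataFrame(cols, index=taxa)
    taxonomy = _assign_taxonomy(taxa, kingdom)
    return rio.OtuTable(counts, taxonomy, kingdom)


# -- planted correlations ----------------------------------------------------

def plant_correlations(table: rio.OtuTable, edges, strength: float,
                       seed: int) -> rio.OtuTable:
    """Inject known pairwise associations as network ground truth.

    For each ``(taxon_i, taxon_j, sign)`` a latent bivariate-normal factor
    is drawn across samples and each taxon's existing counts are re-ordered
    across samples to follow the latent ranks — marginal count distributions
    are preserved exactly. ``strength`` is the association floor: the latent
    Pearson correlation is set via the Gaussian-copula Spearman relation
    ``2 sin(pi s/6)`` at ``s = 1 - (1 - strength)/4``, i.e. well above the
    nominal strength, so that after rank quantization, finite-sample
    attenuation and compositional closure the realized Spearman of the pair
    still reaches ``strength`` in expectation.
    """
    if not 0 < strength <= 1:
        raise ValueError("strength must be in (0, 1]")
    rng = substream(seed, "plant")
    counts = table.counts.copy()
    n = counts.shape[1]
    taxa = set(table.taxon_ids)
    s_target = 1.0 - (1.0 - strength) / 4.0
    rho = min(1.0, 2 * np.sin(np.pi * s_target / 6))
    for ti, tj, sign in edges:
        for t in (ti, tj):
            if t not in taxa:
                raise rio.ValidationError(f"planted edge names unknown taxon {t!r}")
        if sign not in ("positive", "negative"):
            raise ValueError(f"edge sign must be positive/negative, got {sign!r}")
        cov = np.array([[1.0, rho], [rho, 1.0]])
        uv = rng.multivariate_normal([0.0, 0.0], cov, size=n)
        u, v = uv[:, 0], uv[:, 1]
        if sign == "negative":
            v = -v
        for taxon, latent in ((ti, u), (tj, v)):
            vals = np.sort(counts.loc[taxon].to_numpy())
            new = np.empty(n, dtype=vals.dtype)
            new[np.argsort(latent)] = vals
            counts.loc[taxon] = new
    return rio.OtuTable(counts, table.taxonomy, table.kingdom)


# -- function map ------------------------------------------------------------

def simulate_function_map(table: rio.OtuTable, guilds=GUILD_VOCABULARY,
                          seed: int = 0) -> pd.DataFrame:
    """Assign 0..2 guilds per taxon, as a matcher/function/confidence table."""
    guilds = list(guilds)
    if not guilds:
        raise ValueError("guild list must be non-empty")
    rng = substream(seed, "functions")
    rows = []
    for taxon in table.taxon_ids:
        k = int(rng.integers(0, 3))
        chosen = rng.choice(len(guilds), size=k, replace=False)
        for g in sorted(chosen):
            rows.append((taxon, guilds[g], "simulated"))
    return pd.DataFrame(rows, columns=["matcher", "function", "confidence"])


# -- fixture emission --------------------------------------------------------

def generate_fixture_set(outdir, seed: int = 0,
                         params: SimulationParams | None = None) -> dict:
    """Emit the full synthetic fixture: two OTU tables, trees, metadata and
    function maps, with planted intra- and interkingdom correlations."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if params is None:
        params = SimulationParams(rng_seed=seed)
    objects = {}
    tables = {}
    planted: dict[str, list] = {}
    for kingdom in ("bacteria", "fungi"):
        kp = SimulationParams(**{**params.__dict__,
                                 "rng_seed": params.rng_seed,
                                 "planted_edges": []})
        tree = simulate_tree(kp.n_taxa, seed=substream(seed, kingdom, "treeseed"
                                                       ).integers(2 ** 31))
        table, meta = simulate_community_design(kp, tree, kingdom=kingdom)
        # intra-kingdom planted pairs among abundant taxa
        abundant = table.relative_abundance().mean(axis=1).nlargest(6).index
        planted[kingdom] = [(abundant[0], abundant[1], "positive"),
                            (abundant[2], abundant[3], "negative")]
        table = plant_correlations(
            table, planted[kingdom],
            strength=0.9, seed=substream(seed, kingdom, "plantseed"
                                         ).integers(2 ** 31))
        tables[kingdom] = (table, tree, meta)
    # interkingdom planted pair
    bact, btree, meta = tables["bacteria"]
    fung, ftree, _ = tables["fungi"]
    fung = rio.OtuTable(fung.counts.rename(index=lambda t: f"F{t}"),
                        fung.taxonomy.rename(index=lambda t: f"F{t}"),
                        fung.kingdom.rename(index=lambda t: f"F{t}"))
    ftree = ftree.copy()
    for tip in ftree.tips():
        tip.name = f"F{tip.name}"
    both = rio.concat_tables(bact, fung)
    ba = bact.relative_abundance().mean(axis=1).nlargest(6).index[4]
    fa = fung.relative_abundance().mean(axis=1).nlargest(6).index[4]
    both = plant_correlations(both, [(ba, fa, "positive")], strength=0.9,
                              seed=substream(seed, "inter", "plantseed"
                                             ).integers(2 ** 31))
    bact = rio.OtuTable(both.counts.loc[bact.taxon_ids], bact.taxonomy,
                        bact.kingdom)
    fung = rio.OtuTable(both.counts.loc[fung.taxon_ids], fung.taxonomy,
                        fung.kingdom)

    rio.write_metadata(meta, outdir / "metadata.tsv")
    objects["metadata"] = meta
    for kingdom, table, tree in (("bacteria", bact, btree),
                                 ("fungi", fung, ftree)):
        rio.write_otu_table(table, outdir / f"otu_{kingdom}.tsv")
        rio.write_tree(tree, outdir / f"tree_{kingdom}.nwk")
        fmap = simulate_function_map(
            table, seed=substream(seed, kingdom, "fmapseed").integers(2 ** 31))
        fmap.to_csv(outdir / f"function_map_{kingdom}.tsv", sep="\t",
                    index=False)
        objects[f"table_{kingdom}"] = table
        objects[f"tree_{kingdom}"] = tree
        objects[f"fmap_{kingdom}"] = fmap
    planted["fungi"] = [(f"F{a}", f"F{b}", s) for a, b, s in planted["fungi"]]
    planted["interkingdom"] = [(ba, fa, "positive")]
    objects["planted_edges"] = planted
    return objects
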