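"""Phylogenetic and taxonomic null models of community assembly.

Two turnover null models are combined to classify the ecological process
dominating each pair of communities:

* beta-MNTD / beta-NTI — the between-community mean nearest-taxon distance
  (abundance-weighted by default) is compared with a null distribution
  obtained by shuffling taxa across the tips of the whole tree; beta-NTI is
  the z-score (obs - mean_null) / sd_null.
* RC_Bray — the observed Bray-Curtis dissimilarity is compared with null
  communities that preserve each sample's richness and total count, drawing
  taxon occurrences weighted by regional occupancy and individuals weighted
  by regional relative abundance; the percentile is rescaled to [-1, 1].

Pairs are then labelled: beta-NTI > +2 heterogeneous selection; < -2
homogeneous selection; otherwise RC_Bray > +0.95 dispersal limitation,
< -0.95 homogenizing dispersal, else undominated. Values falling exactly on
a threshold go to the stochastic branch (the thresholds are strict as
printed).

Each sample pair draws from its own counter-derived random substream, so
results do not depend on pair iteration order.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._rng import substream
from .io import OtuTable, SampleMetadata, ValidationError, patristic_distances

PROCESSES = ("heterogeneous_selection", "homogeneous_selection",
             "dispersal_limitation", "homogenizing_dispersal", "undominated")

_MAX_NULL_BLOCK = 40_000_000  # elements per beta-MNTD null chunk


def _delta_matrix(table: OtuTable, tree):
    """Patristic distances over the table's taxon pool, in table row order.

    Every taxon with a positive count must be a tree tip (error otherwise);
    zero-count taxa that are on the tree stay in the pool, so the
    taxa-shuffle null spans the whole regional pool, not just the taxa the
    analysed samples happen to contain.
    """
    if isinstance(tree, TreeNode):
        dm = patristic_distances(tree)
    else:
        dm = pd.DataFrame(tree)
    present = table.counts.sum(axis=1) > 0
    missing = [t for t, p in zip(table.taxon_ids, present)
               if p and t not in dm.index]
    if missing:
        raise ValidationError(f"taxon missing from tree: {missing[0]!r}")
    keep = [t for t in table.taxon_ids if t in dm.index]
    return dm.loc[keep, keep].to_numpy(), keep


def _pair_bmntd(delta_kl: np.ndarray, f_k: np.ndarray,
                f_l: np.ndarray) -> float:
    return 0.5 * (float(f_k @ delta_kl.min(axis=1))
                  + float(f_l @ delta_kl.min(axis=0)))


def _community_profile(table: OtuTable, keep: list[str], weighted: bool):
    """Per-sample index arrays and weights over the pruned taxon set."""
    counts = table.counts.loc[keep].to_numpy(dtype=float)
    profiles = []
    for s in range(counts.shape[1]):
        col = counts[:, s]
        idx = np.flatnonzero(col > 0)
        if weighted:
            f = col[idx] / col[idx].sum()
        else:
            f = np.full(len(idx), 1.0 / len(idx))
        profiles.append((idx, f))
    return profiles


def beta_mntd(table: OtuTable, tree, weighted: bool = True) -> pd.DataFrame:
    """Observed between-community mean nearest-taxon distance matrix.

    bMNTD(k,l) = 0.5 [ sum_i f_ik min_j Delta_ij + sum_j f_jl min_i Delta_ij ]
    with f the within-sample relative abundances (weighted) or 1/S
    (unweighted).
    """
    delta, keep = _delta_matrix(table, tree)
    profiles = _community_profile(table, keep, weighted)
    s_ids = table.sample_ids
    n = len(s_ids)
    out = np.zeros((n, n))
    for k, l in combinations(range(n), 2):
        idx_k, f_k = profiles[k]
        idx_l, f_l = profiles[l]
        v = _pair_bmntd(delta[np.ix_(idx_k, idx_l)], f_k, f_l)
        out[k, l] = out[l, k] = v
    return pd.DataFrame(out, index=s_ids, columns=s_ids)


def beta_nti(table: OtuTable, tree, n_null: int = 999, seed: int = 0,
             weighted: bool = True,
             pairs=None) -> pd.DataFrame:
    """beta-NTI z-scores against the taxa-shuffle null.

    The null shuffles the taxon<->tip assignment uniformly over the whole
    tree (``n_null`` independent shuffles per sample pair, each pair on its
    own seed substream); pairs whose null distribution has zero spread are
    reported as NaN with a warning.
    """
    delta, keep = _delta_matrix(table, tree)
    nt = len(keep)
    profiles = _community_profile(table, keep, weighted)
    s_ids = table.sample_ids
    n = len(s_ids)
    out = np.full((n, n), np.nan)
    np.fill_diagonal(out, 0.0)
    pair_list = list(combinations(range(n), 2)) if pairs is None else pairs
    degenerate = 0
    for k, l in pair_list:
        idx_k, f_k = profiles[k]
        idx_l, f_l = profiles[l]
        obs = _pair_bmntd(delta[np.ix_(idx_k, idx_l)], f_k, f_l)
        rng = substream(seed, "bnti", min(k, l), max(k, l))
        null = np.empty(n_null)
        block = max(1, _MAX_NULL_BLOCK // max(1, len(idx_k) * len(idx_l)))
        done = 0
        while done < n_null:
            b = min(block, n_null - done)
            perms = np.array([rng.permutation(nt) for _ in range(b)])
            pk = perms[:, idx_k]
            pl = perms[:, idx_l]
            dn = delta[pk[:, :, None], pl[:, None, :]]
            null[done:done + b] = 0.5 * ((f_k * dn.min(axis=2)).sum(axis=1)
                                         + (f_l * dn.min(axis=1)).sum(axis=1))
            done += b
        sd = null.std(ddof=1)
        if sd <= 0:
            degenerate += 1
            continue
        z = (obs - null.mean()) / sd
        out[k, l] = out[l, k] = z
    if degenerate:
        warnings.warn(f"{degenerate} pair(s) had zero null spread; "
                      "beta-NTI undefined (NaN)", RuntimeWarning,
                      stacklevel=2)
    return pd.DataFrame(out, index=s_ids, columns=s_ids)


# -- RC_Bray -----------------------------------------------------------------

def _null_community_draws(rng, n_null: int, richness: int, total: int,
                          occ_logw: np.ndarray,
                          abundance_w: np.ndarray) -> np.ndarray:
    """Null counts (n_null x n_taxa): occurrences by weighted sampling
    without replacement (Gumbel top-k on occupancy weights), remaining
    individuals multinomially by regional relative abundance."""
    nt = len(occ_logw)
    keys = occ_logw[None, :] + rng.gumbel(size=(n_null, nt))
    chosen = np.argpartition(-keys, richness - 1, axis=1)[:, :richness]
    counts = np.zeros((n_null, nt), dtype=np.int64)
    rows = np.repeat(np.arange(n_null), richness)
    counts[rows, chosen.ravel()] = 1
    remaining = total - richness
    if remaining > 0:
        pmat = np.where(counts > 0, abundance_w[None, :], 0.0)
        pmat = pmat / pmat.sum(axis=1, keepdims=True)
        counts += rng.multinomial(remaining, pmat)
    return counts


def _bray_curtis_rows(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    num = np.abs(a - b).sum(axis=-1)
    den = (a + b).sum(axis=-1)
    return num / den


def rc_bray(table: OtuTable, n_null: int = 999, seed: int = 0,
            pairs=None, tie_tol: float = 1e-12) -> pd.DataFrame:
    """Bray-Curtis-based Raup-Crick index in [-1, 1].

    RC_raw = (#{null BC < obs BC} + 0.5 #{|null-obs| <= tie_tol}) / n_null,
    rescaled as 2 (RC_raw - 0.5). Null communities preserve each sample's
    observed richness and total count; taxon occurrences are weighted by
    regional occupancy and individuals by regional relative abundance.
    """
    counts = table.counts.to_numpy(dtype=np.int64)
    pool = counts.sum(axis=1) > 0
    if pool.sum() < 2:
        raise ValidationError("regional pool must contain >= 2 taxa")
    counts = counts[pool]
    occupancy = (counts > 0).sum(axis=1).astype(float)
    with np.errstate(divide="ignore"):
        occ_logw = np.log(occupancy / occupancy.sum())
    abundance_w = counts.sum(axis=1) / counts.sum()
    s_ids = table.sample_ids
    n = len(s_ids)
    out = np.zeros((n, n))
    pair_list = list(combinations(range(n), 2)) if pairs is None else pairs
    richness = (counts > 0).sum(axis=0)
    totals = counts.sum(axis=0)
    for k, l in pair_list:
        rng = substream(seed, "rcbray", min(k, l), max(k, l))
        obs = float(_bray_curtis_rows(counts[:, k].astype(float),
                                      counts[:, l].astype(float)))
        null_k = _null_community_draws(rng, n_null, int(richness[k]),
                                       int(totals[k]), occ_logw, abundance_w)
        null_l = _null_community_draws(rng, n_null, int(richness[l]),
                                       int(totals[l]), occ_logw, abundance_w)
        null_bc = _bray_curtis_rows(null_k.astype(float),
                                    null_l.astype(float))
        less = int((null_bc < obs - tie_tol).sum())
        ties = int((np.abs(null_bc - obs) <= tie_tol).sum())
        rc_raw = (less + 0.5 * ties) / n_null
        out[k, l] = out[l, k] = 2 * (rc_raw - 0.5)
    return pd.DataFrame(out, index=s_ids, columns=s_ids)


# -- classification ----------------------------------------------------------

def classify_assembly(beta_nti_value: float, rc_bray_value: float) -> str:
    """Five-way ecological-process label from (beta-NTI, RC_Bray)."""
    if np.isnan(beta_nti_value):
        return "undefined"
    if beta_nti_value > 2:
        return "heterogeneous_selection"
    if beta_nti_value < -2:
        return "homogeneous_selection"
    if np.isnan(rc_bray_value):
        return "undefined"
    if rc_bray_value > 0.95:
        return "dispersal_limitation"
    if rc_bray_value < -0.95:
        return "homogenizing_dispersal"
    return "undominated"


def assembly_analysis(table: OtuTable, tree, metadata: SampleMetadata = None,
                      n_null: int = 999, seed: int = 0,
                      weighted: bool = True) -> pd.DataFrame:
    """Per-pair beta-MNTD, beta-NTI, RC_Bray and process label.

    With metadata, pairs are restricted to within-niche comparisons (pooled
    across cultivars); without metadata all pairs of the table form one
    group. Either way the full table acts as the regional taxon pool for
    both null models, which is what gives within-group comparisons their
    phylogenetic contrast.
    """
    s_ids = table.sample_ids
    pos = {s: i for i, s in enumerate(s_ids)}
    if metadata is None:
        pair_groups = {"all": list(combinations(range(len(s_ids)), 2))}
    else:
        meta = metadata.require(s_ids)
        pair_groups = {}
        for niche in pd.unique(meta.niche()):
            sids = [s for s in s_ids if meta.niche()[s] == niche]
            if len(sids) >= 2:
                pair_groups[niche] = [(pos[a], pos[b])
                                      for a, b in combinations(sids, 2)]
    all_pairs = [p for pairs in pair_groups.values() for p in pairs]
    bm = beta_mntd(table, tree, weighted=weighted)
    bn = beta_nti(table, tree, n_null=n_null, seed=seed, weighted=weighted,
                  pairs=all_pairs)
    rc = rc_bray(table, n_null=n_null, seed=seed, pairs=all_pairs)
    rows = []
    for gname, pairs in pair_groups.items():
        for i, j in pairs:
            rows.append({
                "group": gname, "sample_i": s_ids[i], "sample_j": s_ids[j],
                "beta_mntd": bm.iloc[i, j], "beta_nti": bn.iloc[i, j],
                "rc_bray": rc.iloc[i, j],
                "process": classify_assembly(bn.iloc[i, j], rc.iloc[i, j]),
            })
    return pd.DataFrame(rows)


def process_fractions(results: pd.DataFrame,
                      group_col: str = "group") -> pd.DataFrame:
    """Per-group fractions of the five processes, plus the deterministic
    (both selection types) and stochastic (remainder) totals."""
    out = []
    for gname, sub in results.groupby(group_col, sort=False):
        classified = sub[sub["process"] != "undefined"]
        if classified.empty:
            raise ValidationError(f"group {gname!r} has no classified pairs")
        if len(classified) < len(sub):
            warnings.warn(f"group {gname!r}: "
                          f"{len(sub) - len(classified)} undefined pair(s) "
                          "excluded from fractions", RuntimeWarning,
                          stacklevel=2)
        frac = classified["process"].value_counts(normalize=True)
        row = {"group": gname}
        for p in PROCESSES:
            row[p] = float(frac.get(p, 0.0))
        row["deterministic"] = (row["heterogeneous_selection"]
                                + row["homogeneous_selection"])
        row["stochastic"] = 1.0 - row["deterministic"]
        out.append(row)
    return pd.DataFrame(out).set_index("group")
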