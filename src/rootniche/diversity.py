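"""Alpha diversity, Bray-Curtis beta diversity, NMDS ordination and
permutation group tests (ANOSIM, two-way PERMANOVA, Kruskal-Wallis).

Conventions fixed here: Shannon entropy uses the natural logarithm; Chao1 is
the bias-corrected estimator S_obs + F1(F1-1)/(2(F2+1)); Bray-Curtis is
computed on total-sum-scaled relative abundances, making it invariant to
per-sample sequencing depth; NMDS minimises Kruskal stress-1 over seeded
random restarts; the two-way PERMANOVA partitions marginal (each factor
adjusted for the other) sums of squares in Gower-centred distance space and
permutes raw sample rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import kruskal, mannwhitneyu, rankdata
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.stats.distance import DistanceMatrix
from sklearn.manifold import MDS
from statsmodels.stats.multitest import multipletests

from ._rng import substream
from .io import OtuTable, SampleMetadata, ValidationError


# -- alpha diversity ---------------------------------------------------------

def chao1(counts) -> float:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1))."""
    counts = np.asarray(counts)
    if counts.sum() <= 0:
        raise ValidationError("all-zero count vector")
    return float(_skbio_chao1(counts.astype(int), bias_corrected=True))


def shannon(counts) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log)."""
    counts = np.asarray(counts, dtype=float)
    if counts.sum() <= 0:
        raise ValidationError("all-zero count vector")
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon, samples as rows."""
    rows = {s: {"chao1": chao1(table.counts[s]),
                "shannon": shannon(table.counts[s])}
            for s in table.sample_ids}
    return pd.DataFrame(rows).T.loc[table.sample_ids]


# -- beta diversity ----------------------------------------------------------

def bray_curtis(table: OtuTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity on relative abundances."""
    if len(table.sample_ids) < 2:
        raise ValidationError("need >= 2 samples")
    rel = table.relative_abundance().to_numpy().T
    condensed = pdist(rel, metric="braycurtis")
    return DistanceMatrix(squareform(condensed), ids=table.sample_ids)


# -- NMDS --------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x k
    stress: float              # Kruskal stress-1 of the best restart
    n_restarts: int
    converged: bool = True


def nmds(dist: DistanceMatrix, k: int = 2, n_restarts: int = 20,
         seed: int = 0, max_iter: int = 300) -> OrdinationResult:
    """Non-metric MDS by monotone-regression majorization from seeded random
    starts; the restart with the lowest stress-1 is returned."""
    if k < 1:
        raise ValueError("k must be >= 1")
    rs = int(substream(seed, "nmds").integers(2 ** 31))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        model = MDS(n_components=k, metric_mds=False, metric="precomputed",
                    n_init=n_restarts, init="random", random_state=rs,
                    max_iter=max_iter, eps=1e-6, normalized_stress=True)
        coords = model.fit_transform(np.asarray(dist.data))
    converged = model.n_iter_ < max_iter
    if not converged:
        warnings.warn("NMDS did not converge; best-so-far returned",
                      RuntimeWarning, stacklevel=2)
    cols = [f"NMDS{i + 1}" for i in range(k)]
    return OrdinationResult(pd.DataFrame(coords, index=list(dist.ids),
                                         columns=cols),
                            float(model.stress_), n_restarts, converged)


# -- group tests -------------------------------------------------------------

@dataclass
class GroupTestResult:
    name: str                  # e.g. "ANOSIM", "Kruskal-Wallis"
    statistic: float
    p_value: float
    n_permutations: int = 0
    extra: dict = field(default_factory=dict)


def anosim(dist: DistanceMatrix, grouping, n_perm: int = 999,
           seed: int = 0) -> GroupTestResult:
    """Analysis of similarities.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2 pairwise distances ranked with average ranks; the p-value
    counts label permutations with R >= observed.
    """
    labels = pd.Series(grouping).loc[list(dist.ids)].to_numpy()
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValidationError("need >= 2 groups")
    if (counts < 2).any():
        raise ValidationError(
            f"group {uniq[counts < 2][0]!r} has fewer than 2 members")
    n = len(labels)
    iu, ju = np.triu_indices(n, k=1)
    ranks = rankdata(squareform(np.asarray(dist.data), checks=False))
    denom = len(ranks) / 2.0

    def r_stat(lab):
        within = lab[iu] == lab[ju]
        return (ranks[~within].mean() - ranks[within].mean()) / denom

    obs = r_stat(labels)
    rng = substream(seed, "anosim")
    hits = 0
    for _ in range(n_perm):
        if r_stat(rng.permutation(labels)) >= obs:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return GroupTestResult("ANOSIM", float(obs), float(p), n_perm)


# -- PERMANOVA ---------------------------------------------------------------

@dataclass
class PermanovaResult:
    """Anderson-style two-way PERMANOVA table (marginal sums of squares)."""

    table: pd.DataFrame  # rows: factors, residual, total; cols: df, SS, R2, F, p
    n_permutations: int

    def r2(self, factor: str) -> float:
        return float(self.table.loc[factor, "R2"])

    def p(self, factor: str) -> float:
        return float(self.table.loc[factor, "p"])

    def summary(self) -> str:
        return self.table.to_string(float_format=lambda x: f"{x:.4f}")


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _hat(x: np.ndarray) -> np.ndarray:
    # pseudo-inverse handles rank-deficient dummy codings
    return x @ np.linalg.pinv(x.T @ x) @ x.T


def _dummies(labels: np.ndarray) -> np.ndarray:
    levels = pd.unique(labels)
    if len(levels) < 2:
        return np.empty((len(labels), 0))
    return (labels[:, None] == levels[None, 1:]).astype(float)


def permanova_two_way(dist: DistanceMatrix, factor_a, factor_b,
                      n_perm: int = 999, seed: int = 0,
                      names: tuple[str, str] = ("A", "B")) -> PermanovaResult:
    """Two-way PERMANOVA with marginal SS per factor (no interaction).

    SS for a factor is the drop in explained trace when the factor is removed
    from the two-factor design; pseudo-F uses the residual of the full model;
    p-values come from permutations of raw sample rows.
    """
    ids = list(dist.ids)
    a = pd.Series(factor_a).loc[ids].to_numpy()
    b = pd.Series(factor_b).loc[ids].to_numpy()
    n = len(ids)
    g = _gower_center(np.asarray(dist.data))
    ones = np.ones((n, 1))
    xa, xb = _dummies(a), _dummies(b)
    df_a, df_b = xa.shape[1], xb.shape[1]
    x_full = np.hstack([ones, xa, xb])
    if np.linalg.matrix_rank(x_full) < 1 + df_a + df_b:
        raise ValidationError("factors are confounded (aliased design)")
    h_full = _hat(x_full)
    h_a = _hat(np.hstack([ones, xa]))
    h_b = _hat(np.hstack([ones, xb]))
    df_res = n - 1 - df_a - df_b

    def partition(gm):
        ss_total = np.trace(gm)
        ss_full = float(np.sum(h_full * gm))
        ss_a = ss_full - float(np.sum(h_b * gm))   # A adjusted for B
        ss_b = ss_full - float(np.sum(h_a * gm))   # B adjusted for A
        ss_res = ss_total - ss_full
        return ss_total, ss_a, ss_b, ss_res

    ss_total, ss_a, ss_b, ss_res = partition(g)
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    def f_of(ss, df):
        return (ss / df) / ms_res if df > 0 and ms_res > 0 else np.nan

    f_a, f_b = f_of(ss_a, df_a), f_of(ss_b, df_b)
    rng = substream(seed, "permanova")
    hits_a = hits_b = 0
    with np.errstate(divide="ignore", invalid="ignore"):
        for _ in range(n_perm):
            perm = rng.permutation(n)
            gp = g[np.ix_(perm, perm)]
            _, pa, pb, pr = partition(gp)
            msr = pr / df_res
            if df_a > 0 and (pa / df_a) / msr >= f_a:
                hits_a += 1
            if df_b > 0 and (pb / df_b) / msr >= f_b:
                hits_b += 1
    p_a = (1 + hits_a) / (n_perm + 1) if df_a > 0 else np.nan
    p_b = (1 + hits_b) / (n_perm + 1) if df_b > 0 else np.nan
    rows = pd.DataFrame(
        {"df": [df_a, df_b, df_res, n - 1],
         "SS": [ss_a, ss_b, ss_res, ss_total],
         "R2": [ss_a / ss_total, ss_b / ss_total, ss_res / ss_total, 1.0],
         "F": [f_a, f_b, np.nan, np.nan],
         "p": [p_a, p_b, np.nan, np.nan]},
        index=[names[0], names[1], "residual", "total"])
    return PermanovaResult(rows, n_perm)


def permanova_one_way(dist: DistanceMatrix, grouping, n_perm: int = 999,
                      seed: int = 0, name: str = "group") -> PermanovaResult:
    """One-way PERMANOVA via the same machinery (second factor constant)."""
    ids = list(dist.ids)
    const = pd.Series("all", index=ids)
    return permanova_two_way(dist, grouping, const, n_perm=n_perm, seed=seed,
                             names=(name, "_const"))


# -- alpha-diversity group tests --------------------------------------------

def significance_stars(p: float) -> str:
    """Figure-legend star coding: * P<0.05, ** P<0.01, *** P<0.001."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _kruskal_safe(groups) -> tuple[float, float]:
    flat = np.concatenate(groups)
    if np.allclose(flat, flat[0]):
        return 0.0, 1.0
    h, p = kruskal(*groups)
    return float(h), float(p)


def alpha_group_tests(alpha_table: pd.DataFrame, metadata: SampleMetadata,
                      factor: str = "niche") -> dict:
    """Kruskal-Wallis across niches per metric, plus pairwise two-sided
    Wilcoxon rank-sum tests with BH adjustment and star coding."""
    meta = metadata.require(alpha_table.index).table
    labels = meta[factor]
    levels = list(pd.unique(labels))
    if len(levels) < 2:
        raise ValidationError("need >= 2 groups")
    omnibus = {}
    pair_rows = []
    for metric in alpha_table.columns:
        vals = alpha_table[metric]
        groups = [vals[labels == lv].to_numpy() for lv in levels]
        h, p = _kruskal_safe(groups)
        omnibus[metric] = GroupTestResult("Kruskal-Wallis", h, p,
                                          extra={"factor": factor})
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                x, y = groups[i], groups[j]
                if np.allclose(np.concatenate([x, y]),
                               np.concatenate([x, y])[0]):
                    praw = 1.0
                else:
                    praw = float(mannwhitneyu(x, y,
                                              alternative="two-sided").pvalue)
                pair_rows.append((metric, levels[i], levels[j], praw))
    pairs = pd.DataFrame(pair_rows,
                         columns=["metric", "group1", "group2", "p_raw"])
    if len(pairs):
        pairs["p_adj"] = multipletests(pairs["p_raw"], method="fdr_bh")[1]
        pairs["stars"] = pairs["p_adj"].map(significance_stars)
    return {"omnibus": omnibus, "pairwise": pairs}
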