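from itertools import permutations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import squareform
from scipy.stats import rankdata
from skbio.stats.distance import DistanceMatrix
from skbio.stats.distance import anosim as skbio_anosim
from skbio.stats.distance import permanova as skbio_permanova

from rootniche import OtuTable, ValidationError
from rootniche.diversity import (alpha_diversity, alpha_group_tests, anosim,
                                 bray_curtis, chao1, nmds, permanova_one_way,
                                 permanova_two_way, shannon,
                                 significance_stars)


class TestAlphaDiversity:
    @pytest.mark.parametrize("counts,expected", [
        ([5, 3, 1, 1, 2], 5.5),        # S=5, F1=2, F2=1
        ([4, 4, 4], 3.0),              # no singletons -> S_obs
        ([1, 1, 3], 4.0),              # 3 + 2*1/(2*1)
    ])
    def test_chao1(self, counts, expected):
        assert chao1(counts) == pytest.approx(expected)

    @pytest.mark.parametrize("counts,expected", [
        ([1, 1, 1, 1], np.log(4)),     # maximum entropy
        ([7], 0.0),                    # single taxon
        ([1, 3], 0.5623351446),        # -(0.25 ln 0.25 + 0.75 ln 0.75)
    ])
    def test_shannon_natural_log(self, counts, expected):
        assert shannon(counts) == pytest.approx(expected, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(ValidationError):
            chao1([0, 0])
        with pytest.raises(ValidationError):
            shannon([0, 0])

    def test_alpha_table_shape(self, toy_table):
        out = alpha_diversity(toy_table)
        assert list(out.columns) == ["chao1", "shannon"]
        assert list(out.index) == toy_table.sample_ids


class TestBrayCurtis:
    def test_worked_cases(self):
        t = OtuTable(pd.DataFrame({"a": [1, 2], "b": [1, 2], "c": [3, 0],
                                   "d": [0, 3], "e": [1, 2], "f": [2, 1]},
                                  index=["x", "y"]))
        d = bray_curtis(t)
        assert d["a", "b"] == pytest.approx(0.0)        # identical
        assert d["c", "d"] == pytest.approx(1.0)        # disjoint
        assert d["e", "f"] == pytest.approx(1 / 3)      # |1-2|+|2-1| over 6

    def test_depth_invariance(self):
        a = OtuTable(pd.DataFrame({"s": [1, 2, 7], "t": [2, 2, 6]},
                                  index=list("xyz")))
        b = OtuTable(pd.DataFrame({"s": [10, 20, 70], "t": [1, 1, 3]},
                                  index=list("xyz")))
        np.testing.assert_allclose(np.asarray(bray_curtis(a).data),
                                   np.asarray(bray_curtis(b).data),
                                   atol=1e-12)


class TestNMDS:
    def test_perfect_embedding(self):
        pts = np.array([[0, 0], [1, 0], [0, 1], [1, 1]], dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=list("abcd"))
        res = nmds(dm, k=2, n_restarts=8, seed=0)
        assert res.stress < 0.01

    def test_deterministic(self, community):
        dm = bray_curtis(community["table"])
        r1 = nmds(dm, k=2, n_restarts=4, seed=3)
        r2 = nmds(dm, k=2, n_restarts=4, seed=3)
        assert r1.stress == r2.stress
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)

    def test_stress_decreases_with_k(self, community):
        dm = bray_curtis(community["table"])
        s1 = nmds(dm, k=1, n_restarts=8, seed=0).stress
        s2 = nmds(dm, k=2, n_restarts=8, seed=0).stress
        assert s2 <= s1


def _anosim_r(dist_condensed, labels):
    ranks = rankdata(dist_condensed)
    n = len(labels)
    iu, ju = np.triu_indices(n, 1)
    within = labels[iu] == labels[ju]
    return (ranks[~within].mean() - ranks[within].mean()) / (len(ranks) / 2)


class TestAnosim:
    def test_perfect_separation(self):
        d = np.zeros((4, 4))
        d[:2, 2:] = 1.0
        d[2:, :2] = 1.0
        dm = DistanceMatrix(d, ids=list("abcd"))
        g = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        assert anosim(dm, g, n_perm=99, seed=0).statistic == pytest.approx(1.0)

    def test_exhaustive_enumeration_oracle(self):
        """Permutation p matches exhaustive enumeration for n = 6."""
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(6, 2))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        ids = list("abcdef")
        dm = DistanceMatrix(d, ids=ids)
        labels = np.array(["x", "x", "x", "y", "y", "y"])
        cond = squareform(d, checks=False)
        obs = _anosim_r(cond, labels)
        stats = [_anosim_r(cond, np.array(perm))
                 for perm in permutations(labels)]
        p_exact = np.mean([s >= obs - 1e-12 for s in stats])
        res = anosim(dm, pd.Series(labels, index=ids), n_perm=50_000, seed=1)
        assert res.statistic == pytest.approx(obs)
        assert res.p_value == pytest.approx(p_exact, abs=0.01)

    def test_matches_skbio_statistic(self, community):
        dm = bray_curtis(community["table"])
        ours = anosim(dm, community["meta"].niche(), n_perm=9, seed=0)
        theirs = skbio_anosim(dm, community["meta"].niche().loc[list(dm.ids)],
                              permutations=9)
        assert ours.statistic == pytest.approx(theirs["test statistic"],
                                               abs=1e-12)

    def test_ties_finite(self):
        d = np.ones((4, 4)) - np.eye(4)
        dm = DistanceMatrix(d, ids=list("abcd"))
        g = pd.Series(["x", "x", "y", "y"], index=list("abcd"))
        res = anosim(dm, g, n_perm=19, seed=0)
        assert np.isfinite(res.statistic)

    def test_singleton_group_rejected(self):
        d = np.ones((3, 3)) - np.eye(3)
        dm = DistanceMatrix(d, ids=list("abc"))
        g = pd.Series(["x", "x", "y"], index=list("abc"))
        with pytest.raises(ValidationError):
            anosim(dm, g, n_perm=9, seed=0)


class TestPermanova:
    def test_constant_factor_reduces_to_one_way(self, community):
        """With factor B constant, factor A's pseudo-F equals the standard
        one-way PERMANOVA (independent implementation from scikit-bio)."""
        dm = bray_curtis(community["table"])
        niche = community["meta"].niche()
        const = pd.Series("all", index=niche.index)
        two = permanova_two_way(dm, niche, const, n_perm=9, seed=0,
                                names=("niche", "const"))
        ref = skbio_permanova(dm, niche.loc[list(dm.ids)], permutations=9)
        assert two.table.loc["niche", "F"] == pytest.approx(
            ref["test statistic"], abs=1e-6)

    def test_r2_partition_sums_to_one(self, community):
        dm = bray_curtis(community["table"])
        res = permanova_two_way(dm, community["meta"].niche(),
                                community["meta"].cultivar(), n_perm=9,
                                seed=0, names=("niche", "cultivar"))
        parts = res.table.loc[["niche", "cultivar", "residual"], "R2"].sum()
        assert parts == pytest.approx(1.0, abs=1e-10)

    def test_zero_within_spread_r2_one(self):
        ids = list("abcdef")
        d = np.zeros((6, 6))
        d[:3, 3:] = 1.0
        d[3:, :3] = 1.0
        dm = DistanceMatrix(d, ids=ids)
        a = pd.Series(["g1"] * 3 + ["g2"] * 3, index=ids)
        b = pd.Series("all", index=ids)
        res = permanova_two_way(dm, a, b, n_perm=9, seed=0)
        assert res.table.loc["A", "R2"] == pytest.approx(1.0, abs=1e-10)

    def test_confounded_factors_rejected(self):
        ids = list("abcd")
        dm = DistanceMatrix(np.ones((4, 4)) - np.eye(4), ids=ids)
        a = pd.Series(["x", "x", "y", "y"], index=ids)
        with pytest.raises(ValidationError, match="confounded"):
            permanova_two_way(dm, a, a, n_perm=9, seed=0)

    def test_one_way_wrapper(self, community):
        dm = bray_curtis(community["table"])
        res = permanova_one_way(dm, community["meta"].niche(), n_perm=9,
                                seed=0, name="niche")
        assert res.table.loc["niche", "R2"] > 0


class TestAlphaGroupTests:
    def test_star_coding(self):
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.004) == "**"
        assert significance_stars(0.0004) == "***"
        assert significance_stars(0.2) == ""

    def test_separated_groups_exact_p(self, metadata18):
        """Fully separated 6 vs 6 gives the minimal exact rank-sum p
        (2 / C(12,6) = 0.00216...), coded '**'."""
        alpha = pd.DataFrame(
            {"shannon": np.concatenate([np.arange(6), 10 + np.arange(6),
                                        100 + np.arange(6)])},
            index=metadata18.sample_ids)
        out = alpha_group_tests(alpha, metadata18)
        pair = out["pairwise"]
        np.testing.assert_allclose(pair["p_raw"], 2 / 924, rtol=1e-6)
        assert (pair["stars"] == "**").all()
        assert out["omnibus"]["shannon"].p_value < 0.001

    def test_identical_groups_no_stars(self, metadata18):
        alpha = pd.DataFrame({"chao1": np.ones(18)},
                             index=metadata18.sample_ids)
        out = alpha_group_tests(alpha, metadata18)
        assert out["omnibus"]["chao1"].p_value == 1.0
        assert (out["pairwise"]["stars"] == "").all()
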