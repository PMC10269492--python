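import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from skbio import TreeNode

from rootniche import (OtuTable, SimulationParams, ValidationError,
                       simulate_assembly_pair_set, simulate_tree)
from rootniche._rng import substream
from rootniche.assembly import (PROCESSES, assembly_analysis, beta_mntd,
                                beta_nti, classify_assembly,
                                process_fractions, rc_bray)


def _toy_tree():
    # ((A:1,B:1):2,(C:1.5,D:1.5):1.5):0  -> Delta(A,B)=2, Delta(A,C)=6 ...
    return TreeNode.read(["((A:1,B:1):2,(C:1.5,D:1.5):1.5):0;"])


def _brute_bmntd(counts: pd.DataFrame, delta: pd.DataFrame, k, l,
                 weighted=True):
    """Independent loop implementation of between-community MNTD."""
    taxa = list(counts.index)
    ck, cl = counts[k], counts[l]
    pk = [t for t in taxa if ck[t] > 0]
    pl = [t for t in taxa if cl[t] > 0]
    total = 0.0
    for side, (src, dst, vec) in enumerate(((pk, pl, ck), (pl, pk, cl))):
        ssum = sum(vec[t] for t in src)
        for t in src:
            f = vec[t] / ssum if weighted else 1.0 / len(src)
            total += f * min(delta.loc[t, u] for u in dst)
    return 0.5 * total


class TestBetaMNTD:
    def test_identical_communities_zero(self):
        tree = _toy_tree()
        counts = pd.DataFrame({"S1": [3, 1, 0, 2], "S2": [3, 1, 0, 2]},
                              index=list("ABCD"))
        bm = beta_mntd(OtuTable(counts), tree)
        assert bm.loc["S1", "S2"] == pytest.approx(0.0)

    def test_single_taxon_pair_is_patristic_distance(self):
        tree = _toy_tree()
        counts = pd.DataFrame({"S1": [5, 0, 0, 0], "S2": [0, 0, 7, 0]},
                              index=list("ABCD"))
        bm = beta_mntd(OtuTable(counts), tree)
        assert bm.loc["S1", "S2"] == pytest.approx(6.0)  # Delta(A, C)

    @pytest.mark.parametrize("weighted", [True, False])
    def test_matches_brute_force(self, weighted):
        tree = simulate_tree(5, seed=3)
        delta = tree.tip_tip_distances().to_data_frame()
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(rng.integers(0, 9, size=(5, 4)),
                              index=[t.name for t in tree.tips()],
                              columns=list("wxyz"))
        counts.iloc[0, :] += 1  # keep all columns positive
        table = OtuTable(counts)
        bm = beta_mntd(table, tree, weighted=weighted)
        for k, l in combinations(counts.columns, 2):
            assert bm.loc[k, l] == pytest.approx(
                _brute_bmntd(counts, delta, k, l, weighted), abs=1e-10)

    def test_missing_taxon_named(self):
        tree = _toy_tree()
        counts = pd.DataFrame({"S1": [1, 1], "S2": [1, 1]},
                              index=["A", "GHOST"])
        with pytest.raises(ValidationError, match="GHOST"):
            beta_mntd(OtuTable(counts), tree)


class TestBetaNTI:
    def test_matches_brute_force_null(self):
        """z-scores agree with an explicit-loop null using the identical
        seed substream, to 1e-10."""
        tree = simulate_tree(5, seed=11)
        delta = tree.tip_tip_distances().to_data_frame()
        taxa = [t.name for t in tree.tips()]
        counts = pd.DataFrame(
            [[4, 0, 2, 0],
             [1, 3, 0, 0],
             [0, 5, 1, 2],
             [0, 0, 6, 1],
             [2, 1, 0, 3]], index=taxa, columns=list("wxyz"))
        table = OtuTable(counts)
        n_null = 25
        result = beta_nti(table, tree, n_null=n_null, seed=9)
        for k, l in combinations(range(4), 2):
            sk, sl = counts.columns[k], counts.columns[l]
            obs = _brute_bmntd(counts, delta, sk, sl)
            stream = substream(9, "bnti", k, l)
            null = []
            for _ in range(n_null):
                perm = stream.permutation(len(taxa))
                shuffled = delta.to_numpy()[np.ix_(perm, perm)]
                sh = pd.DataFrame(shuffled, index=taxa, columns=taxa)
                null.append(_brute_bmntd(counts, sh, sk, sl))
            null = np.array(null)
            sd = null.std(ddof=1)
            if sd == 0:
                assert np.isnan(result.loc[sk, sl])
                continue
            expect = (obs - null.mean()) / sd
            assert result.loc[sk, sl] == pytest.approx(expect, abs=1e-10)

    def test_star_phylogeny_degenerate(self):
        """Equal pairwise distances make every shuffle identical: sd = 0,
        value reported missing with a warning."""
        star = TreeNode.read(["(A:1,B:1,C:1,D:1):0;"])
        counts = pd.DataFrame({"S1": [1, 2, 0, 0], "S2": [0, 0, 3, 4]},
                              index=list("ABCD"))
        with pytest.warns(RuntimeWarning, match="zero null spread"):
            bn = beta_nti(OtuTable(counts), star, n_null=19, seed=0)
        assert np.isnan(bn.loc["S1", "S2"])


class TestRCBray:
    def test_bounds(self):
        tree = simulate_tree(30, seed=4)
        p = SimulationParams(n_taxa=30, rng_seed=4, depth=300, dispersion=2.0)
        t = simulate_assembly_pair_set("drift", tree, p, n_samples=6)
        rc = rc_bray(t, n_null=49, seed=0).to_numpy()
        assert (rc >= -1).all() and (rc <= 1).all()

    def test_identical_samples_hit_lower_bound(self):
        """Identical compositions have BC = 0, below essentially every null
        draw from a diverse pool -> RC = -1."""
        rng = np.random.default_rng(1)
        base = rng.integers(1, 50, size=12)
        counts = pd.DataFrame({"S1": base, "S2": base},
                              index=[f"T{i}" for i in range(12)])
        rc = rc_bray(OtuTable(counts), n_null=99, seed=0)
        assert rc.loc["S1", "S2"] == pytest.approx(-1.0)

    def test_all_ties_midpoint_zero(self):
        """With a 2-taxon pool at richness 2 and totals 2 every null draw
        equals the observation, so the midpoint rule gives RC = 0."""
        counts = pd.DataFrame({"S1": [1, 1], "S2": [1, 1]}, index=["A", "B"])
        rc = rc_bray(OtuTable(counts), n_null=33, seed=0)
        assert rc.loc["S1", "S2"] == pytest.approx(0.0)

    def test_single_taxon_pool_rejected(self):
        counts = pd.DataFrame({"S1": [4], "S2": [2]}, index=["A"])
        with pytest.raises(ValidationError, match="pool"):
            rc_bray(OtuTable(counts), n_null=9, seed=0)


class TestClassification:
    @pytest.mark.parametrize("bnti,rc,expect", [
        (2.5, 0.0, "heterogeneous_selection"),
        (-2.5, 0.0, "homogeneous_selection"),
        (1.0, 0.96, "dispersal_limitation"),
        (1.0, -0.96, "homogenizing_dispersal"),
        (0.0, 0.0, "undominated"),
        (2.0, 0.99, "dispersal_limitation"),   # boundary -> stochastic branch
        (-2.0, 0.0, "undominated"),
        (0.0, 0.95, "undominated"),            # boundary RC not above 0.95
        (np.nan, 0.5, "undefined"),
    ])
    def test_rules(self, bnti, rc, expect):
        assert classify_assembly(bnti, rc) == expect


class TestProcessFractions:
    def test_all_selection_deterministic_one(self):
        df = pd.DataFrame({"group": ["bulk"] * 3,
                           "process": ["homogeneous_selection"] * 3})
        out = process_fractions(df)
        assert out.loc["bulk", "deterministic"] == pytest.approx(1.0)
        assert out.loc["bulk", "stochastic"] == pytest.approx(0.0)

    def test_fractions_sum_to_one(self):
        df = pd.DataFrame({
            "group": ["a"] * 5,
            "process": ["heterogeneous_selection", "homogeneous_selection",
                        "dispersal_limitation", "homogenizing_dispersal",
                        "undominated"]})
        out = process_fractions(df)
        assert out.loc["a", list(PROCESSES)].sum() == pytest.approx(1.0)
        assert (out.loc["a", "deterministic"] + out.loc["a", "stochastic"]
                ) == pytest.approx(1.0)

    def test_undefined_excluded_with_warning(self):
        df = pd.DataFrame({"group": ["a"] * 3,
                           "process": ["undominated", "undefined",
                                       "undominated"]})
        with pytest.warns(RuntimeWarning, match="undefined"):
            out = process_fractions(df)
        assert out.loc["a", "undominated"] == pytest.approx(1.0)

    def test_empty_group_rejected(self):
        df = pd.DataFrame({"group": ["a"], "process": ["undefined"]})
        with pytest.raises(ValidationError):
            process_fractions(df)


class TestRegimeRecovery:
    def test_selection_more_deterministic_than_drift(self):
        """A strong phylogenetically conserved habitat filter yields a larger
        deterministic fraction than neutral resampling."""
        tree = simulate_tree(256, seed=300)
        p = SimulationParams(n_taxa=256, rng_seed=3, depth=500,
                             dispersion=2.0)
        fracs = {}
        for regime in ("selection", "drift"):
            t = simulate_assembly_pair_set(regime, tree, p, n_samples=8)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                res = assembly_analysis(t, tree, n_null=99, seed=5)
            fracs[regime] = process_fractions(res).loc["all", "deterministic"]
        assert fracs["selection"] > fracs["drift"]

    def test_within_niche_pairs_only(self, community):
        res = assembly_analysis(community["table"], community["tree"],
                                community["meta"], n_null=19, seed=0)
        meta = community["meta"]
        for row in res.itertuples():
            assert meta.niche()[row.sample_i] == meta.niche()[row.sample_j]
            assert row.group == meta.niche()[row.sample_i]
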