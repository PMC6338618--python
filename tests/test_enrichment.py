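import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from revscreen import (
    GeneSignature,
    gsea,
    load_default_signature,
    permutation_p,
    rank_genes,
    read_gmt,
    score_compounds,
    weighted_es,
    write_gmt,
    wtcs,
)
from revscreen.enrichment import null_es


def brute_force_es(metric, member_flags, weight_p=1.0):
    """Independent running-sum enumeration (plain loops, no shared code)."""
    n = len(metric)
    n_hit = sum(member_flags)
    n_r = sum(abs(metric[i]) ** weight_p for i in range(n) if member_flags[i])
    running = []
    hit = miss = 0.0
    for i in range(n):
        if member_flags[i]:
            hit += abs(metric[i]) ** weight_p / n_r
        else:
            miss += 1.0 / (n - n_hit)
        running.append(hit - miss)
    pos = max(running)
    neg = min(running)
    if pos >= -neg - 1e-12:  # same magnitude-tie rule, same float slack
        return pos, running.index(pos)
    return neg, running.index(neg)


class TestWeightedES:
    def test_full_mass_at_top_and_bottom(self):
        genes = ["g1", "g2", "g3", "g4"]
        m = np.array([4.0, 3.0, 2.0, 1.0])
        assert weighted_es(genes, m, {"g1"}).es == pytest.approx(1.0)
        assert weighted_es(genes, m, {"g4"}).es == pytest.approx(-1.0)

    def test_tied_extrema_prefer_positive_earliest(self):
        genes = [f"g{i}" for i in range(1, 7)]
        m = np.array([3.0, 2.0, 1.0, -1.0, -2.0, -3.0])
        res = weighted_es(genes, m, {"g2", "g5"})
        assert res.es == pytest.approx(0.25)
        assert res.index == 1  # second position in the ranking

    def test_unweighted_equals_classical_ks(self):
        # top 3 of 20 at weight 0: ES = 1 - 0 = max of D statistic form
        genes = [f"g{i:02d}" for i in range(20)]
        m = np.linspace(10, 1, 20)
        res = weighted_es(genes, m, set(genes[:3]), weight_p=0.0)
        # classical unweighted KS running sum: 3 steps of 1/3 up, none down
        assert res.es == pytest.approx(1.0 - 0.0)
        assert res.index == 2

    def test_leading_edge_members(self):
        genes = ["a", "b", "c", "d", "e"]
        m = np.array([5.0, 4.0, 3.0, 2.0, 1.0])
        res = weighted_es(genes, m, {"a", "b", "e"})
        assert res.es > 0
        assert set(res.leading_edge) <= {"a", "b", "e"}
        assert "a" in res.leading_edge

    def test_errors(self):
        genes = ["a", "b"]
        m = np.array([1.0, 0.5])
        with pytest.raises(ValueError, match="intersect"):
            weighted_es(genes, m, {"zzz"})
        with pytest.raises(ValueError, match="whole profile"):
            weighted_es(genes, m, {"a", "b"})
        with pytest.raises(ValueError, match="zero"):
            weighted_es(["a", "b", "c"], np.array([0.0, 1.0, 1.0]), {"a"})

    def test_matches_bruteforce_on_random_profiles(self):
        rng = np.random.default_rng(5)
        for n in (3, 5, 8):
            genes = [f"g{i}" for i in range(n)]
            m = np.sort(rng.normal(0, 2, n))[::-1]
            for k in range(1, n):
                for members in itertools.combinations(genes, k):
                    flags = [g in members for g in genes]
                    es_bf, idx_bf = brute_force_es(list(m), flags)
                    res = weighted_es(genes, m, set(members))
                    assert res.es == pytest.approx(es_bf, abs=1e-12)
                    assert res.index == idx_bf

    def test_antisymmetry_under_list_reversal(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = rng.integers(4, 12)
            genes = [f"g{i}" for i in range(n)]
            m = np.sort(rng.normal(0, 1, n))[::-1]
            k = int(rng.integers(1, n))
            members = set(rng.choice(genes, size=k, replace=False).tolist())
            res_fwd = weighted_es(genes, m, members)
            dev = res_fwd.running
            if abs(dev.max() + dev.min()) < 1e-9:
                continue  # magnitude tie: the declared tie rule picks + on both sides
            rev = weighted_es(genes[::-1], -m[::-1], members).es
            assert rev == pytest.approx(-res_fwd.es, abs=1e-12)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(
        metric=st.lists(
            st.floats(-10, 10, allow_nan=False).filter(lambda v: abs(v) > 1e-3),
            min_size=3, max_size=12,
        ),
        pick=st.data(),
    )
    def test_es_always_bounded(self, metric, pick):
        genes = [f"g{i}" for i in range(len(metric))]
        m = np.sort(np.array(metric))[::-1]
        k = pick.draw(st.integers(1, len(genes) - 1))
        members = set(genes[:k])
        es = weighted_es(genes, m, members).es
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12


class TestWTCS:
    def test_opposite_signs_average(self):
        assert wtcs(0.6, -0.4) == pytest.approx(0.5)

    def test_concordant_signs_null(self):
        assert wtcs(0.6, 0.3) == 0.0
        assert wtcs(-0.2, -0.9) == 0.0

    def test_reversal_sign_convention(self):
        # up-half pushed to the bottom, down-half to the top => reversal +
        assert -wtcs(-0.8, 0.6) == pytest.approx(0.7)

    def test_bounds(self):
        assert abs(wtcs(1.0, -1.0)) <= 1.0


class TestPermutationP:
    def test_add_one_floor(self):
        nulls = np.zeros(999)
        assert permutation_p(5.0, nulls) == pytest.approx(1 / 1000)

    def test_zero_observed_gives_one(self):
        nulls = np.random.default_rng(0).normal(size=99)
        assert permutation_p(0.0, nulls) == 1.0

    def test_seeded_reproducibility(self):
        genes = [f"g{i}" for i in range(20)]
        m = np.linspace(3, -3, 20)
        a = null_es(genes, m, 4, 50, seed=42)
        b = null_es(genes, m, 4, 50, seed=42)
        assert np.array_equal(a, b)

    def test_requires_permutations(self):
        with pytest.raises(ValueError):
            permutation_p(1.0, np.array([]))
        genes = ["a", "b", "c"]
        with pytest.raises(ValueError):
            null_es(genes, np.array([3.0, 2.0, 1.0]), 1, 0)


class TestScoreCompounds:
    @staticmethod
    def _profile(metric: dict):
        return pd.DataFrame({"log2fc": pd.Series(metric)})

    def test_noise_free_reversal_scores_one(self):
        sig = GeneSignature("s", {"u1", "u2"}, {"d1", "d2"})
        metric = {"d1": 3.0, "d2": 2.5, "x1": 0.0, "x2": 0.0, "x3": 0.0,
                  "u1": -2.5, "u2": -3.0}
        ranked, skipped = score_compounds({"C": self._profile(metric)}, sig, n_perm=19, seed=0)
        assert not skipped
        assert ranked.loc[0, "reversal"] == pytest.approx(1.0)
        assert ranked.loc[0, "rank"] == 1

    def test_missing_signature_gene_skips_compound(self):
        sig = GeneSignature("s", {"u1"}, {"d1"})
        ok = self._profile({"u1": 1.0, "d1": -1.0, "x": 0.1})
        bad = self._profile({"u1": 1.0, "x": 0.1})
        ranked, skipped = score_compounds({"A": ok, "B": bad}, sig, n_perm=9, seed=0)
        assert skipped == ["B"]
        assert list(ranked["compound"]) == ["A"]

    def test_null_compounds_scores_symmetric_about_zero(self):
        rng = np.random.default_rng(12)
        genes = [f"g{i}" for i in range(40)]
        sig = GeneSignature("s", set(genes[:4]), set(genes[4:8]))
        profiles = {
            f"C{k:03d}": self._profile(dict(zip(genes, rng.normal(0, 1, 40))))
            for k in range(200)
        }
        ranked, _ = score_compounds(profiles, sig, n_perm=9, seed=1)
        assert abs(ranked["reversal"].mean()) <= 0.05

    def test_rank_ties_broken_by_compound_id(self):
        sig = GeneSignature("s", {"u1"}, {"d1"})
        prof = self._profile({"u1": 0.5, "d1": 0.4, "x": 0.0})
        ranked, _ = score_compounds({"B": prof, "A": prof}, sig, n_perm=9, seed=0)
        assert list(ranked["compound"]) == ["A", "B"]


class TestGSEA:
    def test_top_set_enriches_positively(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i:02d}" for i in range(30)]
        metric = pd.Series(np.linspace(4, -4, 30) + rng.normal(0, 0.1, 30), index=genes)
        res = gsea(metric, {"TOP": genes[:5]}, n_perm=99, seed=0)
        row = res.iloc[0]
        assert row["es"] > 0 and row["nes"] > 0

    def test_small_sets_skipped_and_empty_fails(self):
        metric = pd.Series(np.linspace(2, -2, 10), index=[f"g{i}" for i in range(10)])
        with pytest.raises(ValueError, match="minimum-intersection"):
            gsea(metric, {"TINY": ["g1", "g2"]}, n_perm=9, seed=0)

    def test_fdr_calibrated_under_null(self):
        rng = np.random.default_rng(7)
        genes = [f"g{i:03d}" for i in range(60)]
        metric = pd.Series(rng.normal(0, 1, 60), index=genes)
        sets = {
            f"S{k:02d}": rng.choice(genes, size=8, replace=False).tolist()
            for k in range(30)
        }
        res = gsea(metric, sets, n_perm=99, seed=3)
        assert (res["fdr"] < 0.25).mean() <= 0.40  # 25% + MC tolerance

    def test_results_deterministic_given_seed(self):
        metric = pd.Series(np.linspace(3, -3, 20), index=[f"g{i}" for i in range(20)])
        sets = {"A": [f"g{i}" for i in range(5)], "B": [f"g{i}" for i in range(10, 16)]}
        a = gsea(metric, sets, n_perm=49, seed=9)
        b = gsea(metric, sets, n_perm=49, seed=9)
        pd.testing.assert_frame_equal(a, b)


def test_gmt_roundtrip_and_signature(tmp_path):
    sets = {"SIG_UP": ["A", "B"], "SIG_DN": ["C"]}
    path = tmp_path / "sets.gmt"
    write_gmt(sets, path)
    assert read_gmt(path) == sets
    from revscreen import signature_from_gmt

    sig = signature_from_gmt(path, "SIG")
    assert sig.up == {"A", "B"} and sig.down == {"C"}
    with pytest.raises(ValueError):
        GeneSignature("x", {"A"}, {"A"})


def test_packaged_signature_core():
    sig = load_default_signature()
    assert sig.up == {"ANGPTL4", "MMP1", "PTGS2", "TNC"}
    assert sig.down == {"LY6E", "RARRES3"}


def test_rank_genes_orders_and_breaks_ties_stably():
    m = pd.Series({"b": 1.0, "a": 1.0, "c": 2.0})
    genes, vals = rank_genes(m)
    assert genes == ["c", "a", "b"]
    assert list(vals) == [2.0, 1.0, 1.0]
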