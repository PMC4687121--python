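"""Homolog collapse, top-list overlap and concordance-profile operations."""

import math

import numpy as np
import pandas as pd
import pytest

from crossde.crossmap import (
    RankedGeneList,
    collapse_to_homologs,
    concordance_profile,
    overlap_hypergeom,
    overlap_permutation,
)
from crossde.diffexpr import DEResults
from crossde.io import OrthologMap


def _ranked(ids, stats_=None, pvals=None):
    n = len(ids)
    return RankedGeneList(
        table=pd.DataFrame(
            {
                "id": list(ids),
                "signed_stat": stats_ if stats_ is not None else np.ones(n),
                "p": pvals if pvals is not None else np.linspace(0.001, 0.5, n),
                "rank": np.arange(1, n + 1),
            }
        )
    )


def _de_results(probes, genes, pvals, fcs):
    table = pd.DataFrame(
        {
            "gene_id": genes,
            "log2FC": fcs,
            "abs_fc": 2.0 ** np.abs(np.array(fcs)),
            "t": np.zeros(len(probes)),
            "p": pvals,
            "q": pvals,
        },
        index=pd.Index(probes, name="probeset_id"),
    )
    table["rank"] = table["p"].rank(method="first").astype(int)
    annotation = pd.Series(genes, index=table.index)
    return DEResults(table=table, d0=4.0, s0_sq=1.0), annotation


def _identity_map(genes):
    return OrthologMap(
        pairs=pd.DataFrame(
            {
                "gene_id_A": genes,
                "gene_id_B": [g + "_b" for g in genes],
                "homolog_group_id": genes,
            }
        )
    )


class TestCollapse:
    def test_best_p_collapse_keeps_smallest_p_sign(self):
        de, ann = _de_results(
            ["P1", "P2"], ["G1", "G1"], [0.01, 0.2], [0.5, -0.1]
        )
        out = collapse_to_homologs(de, ann, _identity_map(["G1"]), side="A")
        assert len(out) == 1
        row = out.table.iloc[0]
        assert row["id"] == "G1"
        assert row["p"] == pytest.approx(0.01)
        assert row["signed_stat"] == pytest.approx(0.5)

    def test_identity_map_preserves_order(self):
        genes = [f"G{i}" for i in range(6)]
        de, ann = _de_results(
            [f"P{i}" for i in range(6)], genes,
            np.linspace(0.001, 0.3, 6), np.ones(6),
        )
        out = collapse_to_homologs(de, ann, _identity_map(genes), side="A")
        assert list(out.table["id"]) == genes
        assert out.n_unmapped == 0

    def test_matches_bruteforce_groupby_min_oracle(self):
        rng = np.random.default_rng(17)
        n = 200
        probes = [f"P{i}" for i in range(n)]
        genes = [f"G{rng.integers(0, 60)}" for _ in range(n)]
        pvals = rng.random(n)
        fcs = rng.normal(0, 1, n)
        de, ann = _de_results(probes, genes, pvals, fcs)
        mapped_genes = sorted(set(genes))[:50]  # some genes unmapped
        out = collapse_to_homologs(de, ann, _identity_map(mapped_genes), side="A")

        # oracle: plain loops, best (p, -|fc|, probeset) per gene
        best = {}
        for pr, g, p, fc in zip(probes, genes, pvals, fcs):
            key = (p, -abs(fc), pr)
            if g not in best or key < best[g][0]:
                best[g] = (key, p, fc)
        expected = {
            g: (p, fc) for g, (_, p, fc) in best.items() if g in set(mapped_genes)
        }
        assert len(out) == len(expected)
        for row in out.table.itertuples():
            exp_p, exp_fc = expected[row.id]
            assert row.p == pytest.approx(exp_p)
            assert row.signed_stat == pytest.approx(exp_fc)
        assert out.n_unmapped == len(set(genes)) - len(expected)

    def test_empty_mappable_set_rejected(self):
        de, ann = _de_results(["P1"], ["G1"], [0.1], [1.0])
        with pytest.raises(ValueError, match="mapped"):
            collapse_to_homologs(de, ann, _identity_map(["OTHER"]), side="A")


class TestOverlapHypergeom:
    def test_full_overlap_small_universe(self):
        a = _ranked([f"g{i}" for i in range(10)])
        b = _ranked([f"g{i}" for i in range(10)][::-1])
        res = overlap_hypergeom(a, b, topA=5, topB=5)
        # P[X >= 5] with N=10, draws 5/5: overlap is 0..5, full overlap only
        # when the two 5-subsets coincide — p = 1 / C(10,5) = 1/252
        top_a = a.top(5)
        top_b = b.top(5)
        if top_a == top_b:
            assert res.p_hyper == pytest.approx(1 / 252, rel=1e-9)

    def test_exhaustive_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(25):
            N = int(rng.integers(5, 21))
            n1 = int(rng.integers(1, N + 1))
            n2 = int(rng.integers(1, N + 1))
            ids = [f"g{i}" for i in range(N)]
            a = _ranked(list(rng.permutation(ids)))
            b = _ranked(list(rng.permutation(ids)))
            if N < max(n1, n2):
                continue
            res = overlap_hypergeom(a, b, topA=n1, topB=n2)
            # oracle: tail mass by direct combinatorial enumeration
            p = sum(
                math.comb(n1, k) * math.comb(N - n1, n2 - k) / math.comb(N, n2)
                for k in range(res.k, min(n1, n2) + 1)
                if n2 - k <= N - n1
            )
            assert res.p_hyper == pytest.approx(p, abs=1e-12)

    def test_monotone_in_k(self):
        from scipy.stats import hypergeom

        N, n1, n2 = 40, 12, 15
        tails = [float(hypergeom.sf(k - 1, N, n1, n2)) for k in range(13)]
        assert all(a >= b - 1e-15 for a, b in zip(tails, tails[1:]))

    def test_universe_smaller_than_top_rejected(self):
        a = _ranked(["g1", "g2", "g3"])
        b = _ranked(["g1", "x1", "x2"])
        with pytest.raises(ValueError, match="universe"):
            overlap_hypergeom(a, b, topA=3, topB=3)


class TestOverlapPermutation:
    def test_floor_at_one_over_reps_plus_one(self):
        ids = [f"g{i}" for i in range(40)]
        a = _ranked(ids)
        b = _ranked(ids)
        res = overlap_permutation(a, b, topA=5, topB=5, reps=200, seed=1)
        assert res.p_perm >= 1 / 201

    def test_seed_determinism(self):
        rng = np.random.default_rng(4)
        ids = [f"g{i}" for i in range(60)]
        a = _ranked(list(rng.permutation(ids)))
        b = _ranked(list(rng.permutation(ids)))
        r1 = overlap_permutation(a, b, 10, 10, reps=300, seed=9).p_perm
        r2 = overlap_permutation(a, b, 10, 10, reps=300, seed=9).p_perm
        assert r1 == r2

    def test_agrees_with_hypergeometric_null(self):
        rng = np.random.default_rng(11)
        ids = [f"g{i}" for i in range(200)]
        a = _ranked(list(rng.permutation(ids)))
        b = _ranked(list(rng.permutation(ids)))
        res = overlap_permutation(a, b, 30, 30, reps=4000, seed=2)
        se = math.sqrt(res.p_hyper * (1 - res.p_hyper) / 4000)
        assert abs(res.p_perm - res.p_hyper) < 3 * se + 1 / 4001


class TestConcordanceProfile:
    def test_self_comparison_first_bin_fully_concordant(self):
        rng = np.random.default_rng(31)
        ids = [f"g{i}" for i in range(1500)]
        stats_ = rng.normal(0, 1, 1500)
        lst = _ranked(ids, stats_=stats_)
        profile = concordance_profile(lst, lst, K=200, bin_size=1000)
        assert profile.concordant_freq[0] == pytest.approx(1.0)
        assert profile.discordant_freq.sum() == 0.0
        assert profile.unmapped_fraction == 0.0

    def test_hand_walkthrough_toy(self):
        a = _ranked(["g1", "g2"], stats_=[1.0, -1.0])
        b = _ranked(["g1", "x", "g2", "y"], stats_=[0.5, 1.0, 0.7, -0.2])
        profile = concordance_profile(a, b, K=2, bin_size=2)
        np.testing.assert_allclose(profile.concordant_freq, [0.5, 0.0])
        np.testing.assert_allclose(profile.discordant_freq, [0.0, 0.5])
        assert profile.unmapped_fraction == 0.0

    def test_sign_negation_swaps_concordant_discordant(self):
        rng = np.random.default_rng(13)
        ids_a = [f"g{i}" for i in range(300)]
        a = _ranked(ids_a, stats_=rng.normal(0, 1, 300))
        ids_b = list(rng.permutation(ids_a))
        stats_b = rng.normal(0, 1, 300)
        b = _ranked(ids_b, stats_=stats_b)
        b_neg = _ranked(ids_b, stats_=-stats_b)
        p1 = concordance_profile(a, b, K=50, bin_size=100)
        p2 = concordance_profile(a, b_neg, K=50, bin_size=100)
        np.testing.assert_allclose(p1.concordant_freq, p2.discordant_freq)
        np.testing.assert_allclose(p1.discordant_freq, p2.concordant_freq)

    def test_conservation_invariant_with_unmapped(self):
        rng = np.random.default_rng(19)
        a = _ranked([f"a{i}" for i in range(100)], stats_=rng.normal(0, 1, 100))
        b = _ranked([f"a{i}" for i in range(0, 100, 2)],
                    stats_=rng.normal(0, 1, 50))
        profile = concordance_profile(a, b, K=80, bin_size=20)
        profile.validate()
        assert profile.unmapped_fraction > 0

    def test_disjoint_namespaces_fully_unmapped(self):
        a = _ranked([f"a{i}" for i in range(10)])
        b = _ranked([f"b{i}" for i in range(10)])
        profile = concordance_profile(a, b, K=10, bin_size=5)
        assert profile.unmapped_fraction == 1.0
        assert profile.concordant_freq.sum() == 0.0
        assert profile.discordant_freq.sum() == 0.0

    def test_k_exceeding_list_rejected(self):
        a = _ranked(["g1", "g2"])
        with pytest.raises(ValueError, match="K="):
            concordance_profile(a, a, K=5, bin_size=2)
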