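"""Conditional over-representation, gene-set similarity and term clustering."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats

from crossde.enrichment import (
    cluster_terms,
    conditional_enrich,
    enrichment_map_tables,
    term_similarity,
)
from crossde.io import GeneSetDAG


def _hyper_tail(count, n_universe, n_sig, n_term):
    """Oracle: upper-tail hypergeometric mass by direct enumeration."""
    return sum(
        math.comb(n_sig, k) * math.comb(n_universe - n_sig, n_term - k)
        / math.comb(n_universe, n_term)
        for k in range(count, min(n_sig, n_term) + 1)
        if n_term - k <= n_universe - n_sig
    )


class TestConditionalEnrich:
    def test_flat_dag_equals_plain_hypergeometric(self):
        rng = np.random.default_rng(2)
        universe = {f"g{i}" for i in range(60)}
        sig = set(rng.choice(sorted(universe), size=15, replace=False))
        names = {f"T{i}": f"t{i}" for i in range(5)}
        direct = {
            t: set(rng.choice(sorted(universe), size=12, replace=False))
            for t in names
        }
        dag = GeneSetDAG(names=names, parents={t: set() for t in names}, direct=direct)
        res = conditional_enrich(dag, sig, universe)
        for _, row in res.table.iterrows():
            expected = _hyper_tail(int(row["count"]), 60, 15, int(row["global"]))
            assert row["p"] == pytest.approx(expected, abs=1e-12)

    def test_significant_child_discounts_parent(self):
        # parent P = child C plus inert genes; all signal lives in C
        universe = {f"g{i}" for i in range(40)}
        child_genes = {f"g{i}" for i in range(8)}
        parent_extra = {f"g{i}" for i in range(8, 16)}
        sig = child_genes  # the 8 child genes are exactly the significant set
        dag = GeneSetDAG(
            names={"P": "parent", "C": "child"},
            parents={"P": set(), "C": {"P"}},
            direct={"P": set(parent_extra), "C": set(child_genes)},
        )
        res = conditional_enrich(dag, sig, universe, alpha_condition=0.05)
        table = res.table.set_index("term_id")

        p_child = _hyper_tail(8, 40, 8, 8)
        assert table.loc["C", "p"] == pytest.approx(p_child, abs=1e-12)
        # conditioning removes C's genes from P: only the 8 inert genes remain
        assert table.loc["P", "global"] == 8
        assert table.loc["P", "count"] == 0
        p_parent_conditional = _hyper_tail(0, 40, 8, 8)
        p_parent_plain = _hyper_tail(8, 40, 8, 16)
        assert table.loc["P", "p"] == pytest.approx(p_parent_conditional, abs=1e-12)
        assert table.loc["P", "p"] > p_parent_plain
        assert table.loc["P", "p"] > 0.05

    def test_sig_genes_outside_universe_rejected(self):
        dag = GeneSetDAG(names={"T": "t"}, parents={"T": set()}, direct={"T": {"g1"}})
        with pytest.raises(ValueError, match="universe"):
            conditional_enrich(dag, {"gX"}, {"g1", "g2"})

    def test_order_independence_of_term_insertion(self):
        rng = np.random.default_rng(8)
        universe = {f"g{i}" for i in range(50)}
        sig = set(rng.choice(sorted(universe), size=12, replace=False))
        names = {f"T{i}": f"t{i}" for i in range(6)}
        parents = {"T0": set(), "T1": {"T0"}, "T2": {"T0"}, "T3": {"T1"},
                   "T4": {"T1", "T2"}, "T5": set()}
        direct = {
            t: set(rng.choice(sorted(universe), size=10, replace=False))
            for t in names
        }
        fwd = conditional_enrich(
            GeneSetDAG(names=names, parents=parents, direct=direct), sig, universe
        )
        rev = conditional_enrich(
            GeneSetDAG(
                names=dict(reversed(list(names.items()))),
                parents={k: parents[k] for k in reversed(list(parents))},
                direct={k: direct[k] for k in reversed(list(direct))},
            ),
            sig,
            universe,
        )
        assert fwd.table.to_dict("records") == rev.table.to_dict("records")


class TestTermSimilarity:
    def test_identical_sets(self):
        assert term_similarity({"a", "b"}, {"a", "b"}) == 1.0

    def test_disjoint_sets(self):
        assert term_similarity({"a"}, {"b"}) == 0.0

    def test_partial_overlap(self):
        assert term_similarity({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(0.5)

    def test_two_empty_sets(self):
        assert term_similarity(set(), set()) == 0.0

    def test_overlap_coefficient_option(self):
        assert term_similarity({"a", "b"}, {"a", "b", "c", "d"},
                               method="overlap") == 1.0


class TestClusterTerms:
    def test_identical_sets_one_cluster(self):
        sets = {f"T{i}": {"a", "b", "c"} for i in range(4)}
        pvals = {f"T{i}": 0.01 * (i + 1) for i in range(4)}
        clusters = cluster_terms(sets, pvals, similarity_threshold=0.9)
        assert len(clusters) == 1
        assert clusters[0].representative == "T0"

    def test_two_disjoint_groups_two_clusters(self):
        sets = {"A1": {"a"}, "A2": {"a"}, "B1": {"b"}, "B2": {"b"}}
        pvals = {t: 0.01 for t in sets}
        clusters = cluster_terms(sets, pvals, similarity_threshold=0.9)
        assert len(clusters) == 2
        member_sets = sorted(tuple(c.terms) for c in clusters)
        assert member_sets == [("A1", "A2"), ("B1", "B2")]

    def test_matches_bruteforce_dendrogram_cut_oracle(self):
        from scipy.cluster import hierarchy
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(27)
        genes = [f"g{i}" for i in range(30)]
        for trial in range(10):
            n = int(rng.integers(2, 9))
            sets = {
                f"T{i}": set(rng.choice(genes, size=int(rng.integers(3, 10)),
                                        replace=False))
                for i in range(n)
            }
            pvals = {t: float(rng.random()) for t in sets}
            threshold = 0.3
            clusters = cluster_terms(sets, pvals, similarity_threshold=threshold)

            # oracle: rebuild linkage, enumerate every maxclust cut coarse->fine,
            # keep the first where all clusters meet the mean-similarity bar
            terms = sorted(sets)
            sim = np.ones((n, n))
            for i, j in itertools.combinations(range(n), 2):
                sim[i, j] = sim[j, i] = term_similarity(sets[terms[i]], sets[terms[j]])
            link = hierarchy.linkage(squareform(1 - sim, checks=False), "average")

            def mean_sim(members):
                if len(members) < 2:
                    return 1.0
                return np.mean([sim[i, j] for i, j in itertools.combinations(members, 2)])

            expected = None
            for k in range(1, n + 1):
                cand = hierarchy.fcluster(link, t=k, criterion="maxclust")
                groups = [list(np.flatnonzero(cand == lab)) for lab in np.unique(cand)]
                if all(mean_sim(g) >= threshold for g in groups):
                    expected = sorted(
                        tuple(sorted(terms[i] for i in g)) for g in groups
                    )
                    break
            got = sorted(tuple(c.terms) for c in clusters)
            assert got == expected

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            cluster_terms({}, {})


class TestEnrichmentMapTables:
    def test_edge_weights_equal_recomputed_similarity(self):
        rng = np.random.default_rng(6)
        universe = {f"g{i}" for i in range(40)}
        sig = set(rng.choice(sorted(universe), size=20, replace=False))
        names = {f"T{i}": f"t{i}" for i in range(4)}
        direct = {t: set(rng.choice(sorted(sig), size=10, replace=False)) for t in names}
        dag = GeneSetDAG(names=names, parents={t: set() for t in names}, direct=direct)
        res = conditional_enrich(dag, sig, universe)
        nodes, edges = enrichment_map_tables(res, dag.propagated, alpha=0.5)
        for row in edges.itertuples():
            expected = term_similarity(dag.propagated[row.term_a],
                                       dag.propagated[row.term_b])
            assert row.similarity == pytest.approx(expected)
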