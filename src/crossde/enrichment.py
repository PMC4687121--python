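"""Conditional over-representation analysis on a gene-set DAG.

Terms are tested children-before-parents with an upper-tail hypergeometric
test of the significant genes against the universe. When a term comes out
significant (unadjusted p below the conditioning threshold), its propagated
genes are removed from every ancestor's gene set before the ancestor is
tested, so a parent is only called significant on evidence beyond what its
significant children already explain. Reported ``count`` (significant genes
in the term) and ``global`` (term size in the universe) reflect the
post-conditioning sets; BH-FDR across terms is reported as "FDR p".

For enrichment-map style output, significant terms are clustered by
gene-set similarity (Jaccard by default) with average linkage.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .diffexpr import bh_adjust
from .io import GeneSetDAG

__all__ = [
    "EnrichmentResult",
    "conditional_enrich",
    "term_similarity",
    "cluster_terms",
    "TermCluster",
    "enrichment_map_tables",
]


@dataclass
class EnrichmentResult:
    """Per-term conditional over-representation results, sorted by p."""

    table: pd.DataFrame
    alpha_condition: float
    n_sig: int
    n_universe: int

    def significant(self, alpha: float = 0.05, use_fdr: bool = True) -> pd.DataFrame:
        col = "fdr_p" if use_fdr else "p"
        return self.table[self.table[col] < alpha]

    def to_frame(self) -> pd.DataFrame:
        out = self.table.rename(
            columns={
                "term_id": "ID", "name": "Term", "p": "p",
                "fdr_p": "FDR p", "count": "Count", "global": "Global",
            }
        )
        return out[["ID", "Term", "p", "FDR p", "Count", "Global"]]

    def summary(self) -> str:
        n_sig_terms = int((self.table["p"] < 0.05).sum())
        n_fdr = int((self.table["fdr_p"] < 0.05).sum())
        return "\n".join(
            [
                "Conditional gene-set over-representation",
                "=" * 48,
                f"terms tested:        {len(self.table)}",
                f"significant genes:   {self.n_sig} / universe {self.n_universe}",
                f"terms p < 0.05:      {n_sig_terms}",
                f"terms FDR p < 0.05:  {n_fdr}",
            ]
        )


def conditional_enrich(
    dag: GeneSetDAG,
    sig_genes: set[str],
    universe: set[str],
    alpha_condition: float = 0.05,
) -> EnrichmentResult:
    """Conditional hypergeometric over-representation over a term DAG.

    Parameters
    ----------
    sig_genes : set
        Significant genes; must be a subset of ``universe``.
    alpha_condition : float
        Unadjusted-p threshold below which a term's genes are removed from
        its ancestors before they are tested (single bottom-up pass).
    """
    sig_genes = set(sig_genes)
    universe = set(universe)
    if not sig_genes <= universe:
        extra = sorted(sig_genes - universe)[0]
        raise ValueError(f"significant gene {extra!r} not in universe")

    graph = dag.child_parent_graph()
    order = list(nx.lexicographical_topological_sort(graph))  # children first
    prop = {t: dag.propagated.get(t, set()) & universe for t in dag.names}
    removed: dict[str, set[str]] = {t: set() for t in dag.names}
    n_universe = len(universe)
    n_sig = len(sig_genes)

    rows = []
    for term in order:
        genes = prop[term] - removed[term]
        g = len(genes)
        c = len(genes & sig_genes)
        if g == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(c - 1, n_universe, n_sig, g))
        rows.append(
            {"term_id": term, "name": dag.names[term], "p": min(p, 1.0),
             "count": c, "global": g}
        )
        if p < alpha_condition:
            for anc in nx.descendants(graph, term):  # ancestors in child->parent graph
                removed[anc] |= prop[term]

    table = pd.DataFrame(rows)
    table["fdr_p"] = bh_adjust(table["p"].to_numpy())
    table = table.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    table = table[["term_id", "name", "p", "fdr_p", "count", "global"]]
    return EnrichmentResult(
        table=table, alpha_condition=alpha_condition,
        n_sig=n_sig, n_universe=n_universe,
    )


def term_similarity(set_a: set, set_b: set, method: str = "jaccard") -> float:
    """Gene-set similarity in [0, 1]: Jaccard |A∩B|/|A∪B| or overlap coefficient."""
    a, b = set(set_a), set(set_b)
    if not a and not b:
        return 0.0
    inter = len(a & b)
    if method == "jaccard":
        return inter / len(a | b)
    if method == "overlap":
        denom = min(len(a), len(b))
        return inter / denom if denom else 0.0
    raise ValueError(f"unknown similarity method {method!r}")


@dataclass
class TermCluster:
    """One cluster of terms with its most significant representative."""

    terms: list[str]
    representative: str
    mean_similarity: float


def _mean_pairwise(sim: np.ndarray, members: list[int]) -> float:
    if len(members) < 2:
        return 1.0
    pairs = list(itertools.combinations(members, 2))
    return float(np.mean([sim[i, j] for i, j in pairs]))


def cluster_terms(
    gene_sets: dict[str, set],
    pvals: dict[str, float],
    globals_: dict[str, int] | None = None,
    similarity_threshold: float = 0.9,
    method: str = "jaccard",
) -> list[TermCluster]:
    """Average-linkage clustering of terms cut at a mean within-cluster similarity.

    The dendrogram (average linkage on 1 - similarity) is cut at the coarsest
    level at which every cluster's mean pairwise similarity is at least
    ``similarity_threshold``; singletons trivially qualify. The
    representative of each cluster is its smallest-p term (tie: largest
    gene-set size, then term id).
    """
    terms = sorted(gene_sets)
    if not terms:
        raise ValueError("need at least one term to cluster")
    globals_ = globals_ or {t: len(gene_sets[t]) for t in terms}
    n = len(terms)
    sim = np.ones((n, n))
    for i, j in itertools.combinations(range(n), 2):
        sim[i, j] = sim[j, i] = term_similarity(gene_sets[terms[i]], gene_sets[terms[j]], method)

    if n == 1:
        labels = np.array([1])
    else:
        dist = squareform(1.0 - sim, checks=False)
        link = hierarchy.linkage(dist, method="average")
        # candidate cuts: coarsest (1 cluster) to finest (n singletons)
        labels = np.arange(1, n + 1)  # fallback: all singletons
        for n_clusters in range(1, n + 1):
            cand = hierarchy.fcluster(link, t=n_clusters, criterion="maxclust")
            ok = all(
                _mean_pairwise(sim, list(np.flatnonzero(cand == lab))) >= similarity_threshold
                for lab in np.unique(cand)
            )
            if ok:
                labels = cand
                break

    clusters = []
    for lab in np.unique(labels):
        members = [terms[i] for i in np.flatnonzero(labels == lab)]
        rep = min(members, key=lambda t: (pvals.get(t, 1.0), -globals_.get(t, 0), t))
        clusters.append(
            TermCluster(
                terms=sorted(members),
                representative=rep,
                mean_similarity=_mean_pairwise(sim, list(np.flatnonzero(labels == lab))),
            )
        )
    clusters.sort(key=lambda c: pvals.get(c.representative, 1.0))
    return clusters


def enrichment_map_tables(
    result: EnrichmentResult,
    gene_sets: dict[str, set],
    alpha: float = 0.05,
    min_edge_similarity: float = 0.1,
    method: str = "jaccard",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Node and edge tables for external enrichment-map rendering.

    Nodes: significant terms with p, count, global (node size ~ membership).
    Edges: term pairs with similarity >= ``min_edge_similarity``.
    """
    sig = result.table[result.table["p"] < alpha]
    nodes = sig[["term_id", "name", "p", "fdr_p", "count", "global"]].copy()
    ids = list(nodes["term_id"])
    edges = []
    for a, b in itertools.combinations(ids, 2):
        s = term_similarity(gene_sets.get(a, set()), gene_sets.get(b, set()), method)
        if s >= min_edge_similarity:
            edges.append({"term_a": a, "term_b": b, "similarity": s})
    edge_frame = pd.DataFrame(edges, columns=["term_a", "term_b", "similarity"])
    return nodes.reset_index(drop=True), edge_frame
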