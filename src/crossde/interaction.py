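"""Genotype x model interaction: genes whose mutant effect differs between models.

For every gene shared between two studies (matched through the ortholog map),
expression is regressed on genotype, model and their interaction with samples
of both studies pooled (all ages collapsed). The F test of the interaction
coefficient (1 numerator df, so equivalent to the squared t test of the
coefficient) asks whether the MUT - WT contrast differs between the two
models. Each study is median-centred per probeset before the joint fit to
absorb platform offsets; this is cosmetic, since any constant offset is
absorbed by the model main effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust, group_stats, moderated_t
from .io import ExpressionStudy, OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionResults",
    "ModelInteraction",
    "interaction_test",
    "rank_divergent",
]


@dataclass
class InteractionResults:
    """Per-gene genotype x model interaction results.

    ``table``: homolog_group (index), gene_A, gene_B, fc_A, fc_B (within-model
    MUT - WT log2 fold changes), abs_fc_diff = |fc_A - fc_B|, p_interaction, q.
    """

    table: pd.DataFrame
    n_excluded: int = 0
    labels: tuple[str, str] = ("A", "B")

    def to_frame(self) -> pd.DataFrame:
        return self.table.rename_axis("homolog_group_id").reset_index()

    def divergent(self, p_threshold: float = 0.05, min_abs_diff: float = 0.20) -> pd.DataFrame:
        return rank_divergent(self, p_threshold=p_threshold, min_abs_diff=min_abs_diff)

    def summary(self) -> str:
        n_sig = int((self.table["p_interaction"] < 0.05).sum())
        n_div = len(self.divergent())
        return "\n".join(
            [
                "Genotype x model interaction",
                "=" * 48,
                f"models compared:                 {self.labels[0]} vs {self.labels[1]}",
                f"shared genes tested:             {len(self.table)}",
                f"genes in one model only:         {self.n_excluded}",
                f"interaction p < 0.05:            {n_sig}",
                f"divergent (p<0.05, |dFC|>0.20):  {n_div}",
            ]
        )


def _representative_probesets(study: ExpressionStudy) -> pd.Series:
    """gene id -> representative probeset (smallest genotype-contrast p).

    Uses the ordinary pooled t (no moderation) since only the within-gene
    ordering matters here.
    """
    wt = study.samples_where(genotype="WT")
    mut = study.samples_where(genotype="MUT")
    gs = group_stats(study, (wt, mut))
    _, p = moderated_t(
        gs["log2FC"].to_numpy(), gs["s2"].to_numpy(), gs["df"].to_numpy(),
        d0=0.0, s0_sq=1.0, n1=len(wt), n2=len(mut),
    )
    tab = pd.DataFrame(
        {
            "probeset_id": gs.index,
            "gene_id": study.annotation.reindex(gs.index).to_numpy(),
            "p": p,
            "_abs": -gs["log2FC"].abs().to_numpy(),
        }
    ).dropna(subset=["gene_id"])
    tab = tab.sort_values(["gene_id", "p", "_abs", "probeset_id"], kind="mergesort")
    best = tab.drop_duplicates(subset="gene_id", keep="first")
    return best.set_index("gene_id")["probeset_id"]


def interaction_test(
    study_a: ExpressionStudy,
    study_b: ExpressionStudy,
    omap: OrthologMap,
) -> InteractionResults:
    """Joint genotype + model + genotype:model fit per shared gene.

    Genes are matched across studies through homolog groups; each gene is
    represented by its best genotype-contrast probeset within its study.
    Genes present in only one model are excluded and counted.
    """
    rep_a = _representative_probesets(study_a)
    rep_b = _representative_probesets(study_b)
    group_a = omap.group_of("A")
    group_b = omap.group_of("B")

    genes_a = pd.DataFrame({"gene": rep_a.index, "probeset": rep_a.to_numpy()})
    genes_a["group"] = group_a.reindex(genes_a["gene"]).to_numpy()
    genes_b = pd.DataFrame({"gene": rep_b.index, "probeset": rep_b.to_numpy()})
    genes_b["group"] = group_b.reindex(genes_b["gene"]).to_numpy()
    genes_a = genes_a.dropna(subset=["group"]).drop_duplicates(subset="group")
    genes_b = genes_b.dropna(subset=["group"]).drop_duplicates(subset="group")

    merged = genes_a.merge(genes_b, on="group", suffixes=("_A", "_B"))
    n_total = len(set(genes_a["group"]) | set(genes_b["group"]))
    n_excluded = n_total - len(merged)
    if n_excluded:
        logger.info("%d homolog groups present in only one model; excluded", n_excluded)
    if merged.empty:
        raise ValueError("no genes shared between the two models")

    # median-centre per probeset within each study, then stack samples
    ya = study_a.matrix.loc[merged["probeset_A"]].to_numpy(float)
    yb = study_b.matrix.loc[merged["probeset_B"]].to_numpy(float)
    ya = ya - np.median(ya, axis=1, keepdims=True)
    yb = yb - np.median(yb, axis=1, keepdims=True)
    y = np.hstack([ya, yb])

    geno = np.concatenate(
        [
            (study_a.design["genotype"] == "MUT").to_numpy(float),
            (study_b.design["genotype"] == "MUT").to_numpy(float),
        ]
    )
    model = np.concatenate(
        [np.zeros(study_a.matrix.shape[1]), np.ones(study_b.matrix.shape[1])]
    )
    ones = np.ones_like(geno)
    x_full = np.column_stack([ones, geno, model, geno * model])
    x_red = x_full[:, :3]

    def rss(x):
        q, _ = np.linalg.qr(x)
        proj = y @ q
        return np.maximum((y**2).sum(axis=1) - (proj**2).sum(axis=1), 0.0), x.shape[1]

    rss_full, k_full = rss(x_full)
    rss_red, _ = rss(x_red)
    df_den = y.shape[1] - k_full
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (rss_red - rss_full) / (rss_full / df_den)
    f = np.where(rss_full == 0, np.inf, f)
    p = stats.f.sf(f, 1, df_den)
    p = np.where(np.isinf(f), 0.0, p)

    wt_a = (geno == 0) & (model == 0)
    mut_a = (geno == 1) & (model == 0)
    wt_b = (geno == 0) & (model == 1)
    mut_b = (geno == 1) & (model == 1)
    fc_a = y[:, mut_a].mean(axis=1) - y[:, wt_a].mean(axis=1)
    fc_b = y[:, mut_b].mean(axis=1) - y[:, wt_b].mean(axis=1)

    table = pd.DataFrame(
        {
            "gene_A": merged["gene_A"].to_numpy(),
            "gene_B": merged["gene_B"].to_numpy(),
            "fc_A": fc_a,
            "fc_B": fc_b,
            "abs_fc_diff": np.abs(fc_a - fc_b),
            "p_interaction": p,
            "q": bh_adjust(p),
        },
        index=pd.Index(merged["group"], name="homolog_group_id"),
    )
    table = (
        table.rename_axis("homolog_group_id")
        .reset_index()
        .sort_values(["p_interaction", "homolog_group_id"], kind="mergesort")
        .set_index("homolog_group_id")
    )
    return InteractionResults(
        table=table,
        n_excluded=n_excluded,
        labels=(study_a.model_label, study_b.model_label),
    )


def rank_divergent(
    results: InteractionResults,
    p_threshold: float = 0.05,
    min_abs_diff: float = 0.20,
) -> pd.DataFrame:
    """Significant-interaction genes with |fc_A - fc_B| strictly above the cutoff.

    Sorted descending by abs_fc_diff (ties by homolog group id), the ordering
    used for divergent-gene tables.
    """
    tab = results.table
    keep = (tab["p_interaction"] < p_threshold) & (tab["abs_fc_diff"] > min_abs_diff)
    out = tab[keep].rename_axis("homolog_group_id").reset_index()
    out["homolog_group_id"] = out["homolog_group_id"].astype(str)
    out = out.sort_values(
        ["abs_fc_diff", "homolog_group_id"], ascending=[False, True], kind="mergesort"
    )
    return out.set_index("homolog_group_id")


class ModelInteraction:
    """statsmodels-style wrapper: ``ModelInteraction(a, b, omap).fit()``."""

    def __init__(self, study_a: ExpressionStudy, study_b: ExpressionStudy, omap: OrthologMap):
        self.study_a = study_a
        self.study_b = study_b
        self.omap = omap

    def fit(self) -> InteractionResults:
        return interaction_test(self.study_a, self.study_b, self.omap)
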