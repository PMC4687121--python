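"""Time-course analysis: genotype-dependent change over age and pattern calls.

Two stages mirror the screening-then-tagging workflow used for time-course
microarray studies of mouse models:

1. :func:`genotype_time_anova` — per-probeset two-way fixed-effects ANOVA with
   genotype, time (categorical) and their interaction. The reported p-value is
   the extra-sum-of-squares F test of all genotype-containing terms (genotype
   main effect + genotype:time interaction) against the time-only model, i.e.
   "does genotype affect the expression trajectory at all". BH-FDR follows.

2. :func:`classify_trajectory` — each significant probeset is tagged, per
   genotype, with the monotone template (up or down over the ordered time
   index) it correlates with most strongly, or "NC" (no change) when the
   amplitude or the correlation is too small. The 3x3 cross-tabulation of
   (WT pattern, MUT pattern), split by the direction of the genotype effect,
   is the :class:`PatternTable`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .io import ExpressionStudy

__all__ = [
    "genotype_time_anova",
    "classify_trajectory",
    "classify_study_trajectories",
    "build_pattern_table",
    "GenotypeTimeANOVA",
    "TemporalResults",
    "PatternTable",
    "PATTERNS",
]

PATTERNS = ("up", "NC", "down")


# ---------------------------------------------------------------------------
# ANOVA screen
# ---------------------------------------------------------------------------


def _design_matrices(design: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Reduced (time-only) and full (time + genotype + interaction) design matrices."""
    genotypes = sorted(design["genotype"].unique())
    times = sorted(design["time"].unique())
    if len(genotypes) < 2 or len(times) < 2:
        raise ValueError("need >=2 genotypes and >=2 time points")
    cells = design.groupby(["genotype", "time"], observed=True).size()
    if len(cells) < len(genotypes) * len(times):
        raise ValueError("empty genotype x time design cell")
    g = (design["genotype"] != genotypes[0]).to_numpy(float)  # 0 = reference
    t_dummies = np.column_stack(
        [(design["time"] == t).to_numpy(float) for t in times[1:]]
    )
    ones = np.ones((len(design), 1))
    x_red = np.column_stack([ones, t_dummies])
    x_full = np.column_stack([ones, t_dummies, g[:, None], t_dummies * g[:, None]])
    return x_red, x_full


def _rss(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, int]:
    """Row-wise residual sum of squares of Y (genes x samples) on X, and rank."""
    q, r = np.linalg.qr(x)
    rank = int(np.sum(np.abs(np.diag(r)) > 1e-10 * np.abs(r[0, 0])))
    proj = y @ q  # genes x k
    rss = (y**2).sum(axis=1) - (proj**2).sum(axis=1)
    return np.maximum(rss, 0.0), rank


def genotype_time_anova(study: ExpressionStudy) -> pd.DataFrame:
    """Per-probeset F test of genotype involvement over the time course.

    Returns a DataFrame indexed by probeset id with columns ``F``, ``p``,
    ``q`` (BH-FDR). The F statistic compares the full two-way model
    (genotype + time + genotype:time) against the time-only model.
    """
    x_red, x_full = _design_matrices(study.design)
    y = study.matrix.to_numpy(float)
    rss_red, rank_red = _rss(y, x_red)
    rss_full, rank_full = _rss(y, x_full)
    df_num = rank_full - rank_red
    df_den = y.shape[1] - rank_full
    if df_den <= 0:
        raise ValueError("no residual degrees of freedom in full model")
    with np.errstate(divide="ignore", invalid="ignore"):
        f = ((rss_red - rss_full) / df_num) / (rss_full / df_den)
    f = np.where(rss_full == 0, np.inf, f)
    p = stats.f.sf(f, df_num, df_den)
    p = np.where(np.isinf(f), 0.0, p)
    return pd.DataFrame(
        {"F": f, "p": p, "q": bh_adjust(p)}, index=study.probeset_ids
    )


# ---------------------------------------------------------------------------
# Trajectory classification
# ---------------------------------------------------------------------------


def _monotone_template(n_times: int) -> np.ndarray:
    """Standardized increasing template over the ordered time index."""
    t = np.arange(n_times, dtype=float)
    t -= t.mean()
    return t / np.sqrt((t**2).sum())


def classify_trajectory(
    means: np.ndarray, r_min: float = 0.8, min_amp: float = 0.1
) -> tuple[str, float, float]:
    """Classify a per-time mean profile as 'up', 'down' or 'NC'.

    The profile is correlated (Pearson) against the standardized monotone
    increasing template and its negation; the winner is the template with
    positive correlation. 'NC' (no change) is returned when the amplitude
    (max - min of the per-time means, log2 units) is below ``min_amp`` or the
    winning |r| is below ``r_min``. Constant profiles have undefined
    correlation, treated as r = 0, hence 'NC'.

    Returns (pattern, r, amplitude) with r signed towards the 'up' template.
    """
    means = np.asarray(means, float)
    if means.size < 3:
        raise ValueError("need >=3 time points for trajectory classification")
    amplitude = float(means.max() - means.min())
    centred = means - means.mean()
    denom = np.sqrt((centred**2).sum())
    if denom == 0:
        return "NC", 0.0, amplitude
    template = _monotone_template(means.size)
    r = float(centred @ template / denom)
    if amplitude < min_amp or abs(r) < r_min:
        return "NC", r, amplitude
    return ("up" if r > 0 else "down"), r, amplitude


def classify_study_trajectories(
    study: ExpressionStudy,
    probesets: pd.Index | list | None = None,
    r_min: float = 0.8,
    min_amp: float = 0.1,
) -> pd.DataFrame:
    """Per-probeset trajectory calls for both genotypes plus genotype direction.

    Returns a DataFrame indexed by probeset with columns ``gene_id``,
    ``pattern_<geno>``, ``r_<geno>``, ``amplitude_<geno>`` for each genotype
    (reference genotype first) and ``direction`` — the sign (+1 / -1) of the
    average MUT - WT difference across time points.
    """
    genotypes = sorted(study.design["genotype"].unique())
    if len(genotypes) != 2:
        raise ValueError("trajectory table requires exactly 2 genotypes")
    if "WT" in genotypes:  # wild-type is the reference; direction = sign(MUT - WT)
        genotypes = ["WT"] + [g for g in genotypes if g != "WT"]
    times = study.times
    ids = study.probeset_ids if probesets is None else pd.Index(probesets)
    mat = study.matrix.loc[ids]

    per_time_means = {}
    for geno in genotypes:
        cols = []
        for t in times:
            samp = study.samples_where(genotype=geno, time=t)
            cols.append(mat.loc[:, samp].mean(axis=1).to_numpy())
        per_time_means[geno] = np.column_stack(cols)  # probesets x times

    out = pd.DataFrame({"gene_id": study.annotation.reindex(ids)}, index=ids)
    for geno in genotypes:
        calls = [
            classify_trajectory(row, r_min=r_min, min_amp=min_amp)
            for row in per_time_means[geno]
        ]
        out[f"pattern_{geno}"] = [c[0] for c in calls]
        out[f"r_{geno}"] = [c[1] for c in calls]
        out[f"amplitude_{geno}"] = [c[2] for c in calls]
    # direction of the genotype effect: sign of mean (non-reference - reference)
    diff = per_time_means[genotypes[1]] - per_time_means[genotypes[0]]
    out["direction"] = np.where(diff.mean(axis=1) >= 0, 1, -1)
    out.attrs["genotypes"] = genotypes
    return out


# ---------------------------------------------------------------------------
# Pattern table
# ---------------------------------------------------------------------------


@dataclass
class PatternTable:
    """3x3 gene counts by (reference-genotype pattern, mutant pattern).

    Each cell also tallies the direction of the genotype effect (down / up in
    the mutant). Genes whose probesets disagree on the pattern pair are
    counted in the cell of their representative probeset but excluded from
    the direction tallies ("mixed pattern").
    """

    counts: pd.DataFrame            # rows = MUT pattern, cols = WT pattern
    down: pd.DataFrame
    up: pd.DataFrame
    n_mixed: int = 0
    genotypes: tuple[str, str] = ("WT", "MUT")

    @property
    def grand_total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def validate(self) -> None:
        assert self.grand_total == int(self.row_totals.sum()) == int(self.col_totals.sum())
        arrows = self.down.to_numpy() + self.up.to_numpy()
        assert (arrows <= self.counts.to_numpy()).all()

    def to_frame(self) -> pd.DataFrame:
        """Render as a publication-style table: 'count (down, up)' cells."""
        ref, mut = self.genotypes
        rows = []
        for mp in PATTERNS:
            row = {f"{mut}_pattern": mp}
            for wp in PATTERNS:
                c = int(self.counts.loc[mp, wp])
                d = int(self.down.loc[mp, wp])
                u = int(self.up.loc[mp, wp])
                row[f"{ref}_{wp}"] = f"{c} ({d}v,{u}^)"
            row["Total"] = int(self.row_totals[mp])
            rows.append(row)
        total_row = {f"{mut}_pattern": "Total"}
        for wp in PATTERNS:
            total_row[f"{ref}_{wp}"] = int(self.col_totals[wp])
        total_row["Total"] = self.grand_total
        rows.append(total_row)
        return pd.DataFrame(rows)


def build_pattern_table(calls: pd.DataFrame, rep_p: pd.Series | None = None) -> PatternTable:
    """Cross-tabulate per-probeset trajectory calls into a gene-level 3x3 table.

    Parameters
    ----------
    calls : DataFrame
        Output of :func:`classify_study_trajectories` (possibly subset to the
        significant probesets).
    rep_p : Series, optional
        Per-probeset p-values used to pick each gene's representative probeset
        (smallest p). Defaults to the first probeset per gene in input order.

    Genes with several probesets that disagree on the (WT, MUT) pattern pair
    or on the direction sign are counted in their representative cell but
    excluded from the down/up tallies.
    """
    genotypes = calls.attrs.get("genotypes")
    if genotypes is None:
        pattern_cols = [c for c in calls.columns if c.startswith("pattern_")]
        genotypes = [c[len("pattern_"):] for c in pattern_cols]
    ref, mut = genotypes

    zeros = lambda: pd.DataFrame(0, index=list(PATTERNS), columns=list(PATTERNS))
    counts, down, up = zeros(), zeros(), zeros()
    n_mixed = 0

    work = calls.copy()
    work["_p"] = rep_p.reindex(calls.index) if rep_p is not None else np.arange(len(calls))
    work["gene_id"] = work["gene_id"].fillna(work.index.to_series())

    for _, grp in work.groupby("gene_id", sort=True):
        rep = grp.sort_values("_p", kind="mergesort").iloc[0]
        wt_pat, mut_pat = rep[f"pattern_{ref}"], rep[f"pattern_{mut}"]
        counts.loc[mut_pat, wt_pat] += 1
        pattern_pairs = set(zip(grp[f"pattern_{ref}"], grp[f"pattern_{mut}"]))
        directions = set(grp["direction"])
        if len(pattern_pairs) > 1 or len(directions) > 1:
            n_mixed += 1
            continue
        if rep["direction"] < 0:
            down.loc[mut_pat, wt_pat] += 1
        else:
            up.loc[mut_pat, wt_pat] += 1

    table = PatternTable(
        counts=counts, down=down, up=up, n_mixed=n_mixed,
        genotypes=(str(ref), str(mut)),
    )
    table.validate()
    return table


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------


@dataclass
class TemporalResults:
    """Results of the genotype-over-time screen plus pattern classification."""

    anova: pd.DataFrame
    calls: pd.DataFrame
    pattern_table: PatternTable
    alpha: float
    r_min: float
    min_amp: float

    def to_frame(self) -> pd.DataFrame:
        merged = self.anova.join(self.calls.drop(columns=["gene_id"], errors="ignore"))
        merged.insert(0, "gene_id", self.calls["gene_id"].reindex(self.anova.index))
        return merged.rename_axis("probeset_id").reset_index()

    def summary(self) -> str:
        n_sig = int((self.anova["q"] < self.alpha).sum())
        lines = [
            "Genotype x time ANOVA screen",
            "=" * 48,
            f"probesets tested:         {len(self.anova)}",
            f"FDR q < {self.alpha:g}:             {n_sig}",
            f"genes in pattern table:   {self.pattern_table.grand_total}",
            f"mixed-pattern genes:      {self.pattern_table.n_mixed}",
            "",
            self.pattern_table.to_frame().to_string(index=False),
        ]
        return "\n".join(lines)


class GenotypeTimeANOVA:
    """Genotype-dependent time-course model with trajectory tagging.

    ``fit()`` runs the per-probeset two-way ANOVA screen, keeps probesets at
    FDR q < alpha, tags each with its per-genotype trajectory pattern, and
    builds the gene-level pattern table.
    """

    def __init__(
        self,
        study: ExpressionStudy,
        alpha: float = 0.05,
        r_min: float = 0.8,
        min_amp: float = 0.1,
    ):
        self.study = study
        self.alpha = alpha
        self.r_min = r_min
        self.min_amp = min_amp

    def fit(self) -> TemporalResults:
        anova = genotype_time_anova(self.study)
        sig = anova.index[anova["q"] < self.alpha]
        calls = classify_study_trajectories(
            self.study, probesets=sig, r_min=self.r_min, min_amp=self.min_amp
        )
        table = build_pattern_table(calls, rep_p=anova["p"])
        return TemporalResults(
            anova=anova,
            calls=calls,
            pattern_table=table,
            alpha=self.alpha,
            r_min=self.r_min,
            min_amp=self.min_amp,
        )
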