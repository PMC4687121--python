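"""Cross-dataset comparison of ranked differential-expression lists.

Probeset-level results are collapsed to genes (best p per gene) and then to
homolog groups so that two studies on different platforms or species can be
compared on a shared namespace. Three comparisons are provided:

* top-N overlap with an upper-tail hypergeometric p-value,
* the same overlap with a permutation p-value (resampling top lists from the
  shared universe),
* a direction-split rank-bin concordance profile: the fraction of one
  study's top-K changes that land in each rank bin of the other study's
  ordered list, split by whether the direction of change agrees.

A higher concordant than discordant frequency in the first bins indicates a
shared expression signature between the two datasets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import DEResults
from .io import OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "RankedGeneList",
    "OverlapResult",
    "ConcordanceProfile",
    "collapse_to_homologs",
    "overlap_hypergeom",
    "overlap_permutation",
    "concordance_profile",
    "plot_concordance_profile",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class RankedGeneList:
    """An ordered list of unique gene (or homolog-group) ids with signed stats.

    ``table`` has columns ``id``, ``signed_stat`` (signed log2FC), ``p`` and
    ``rank`` (1..n, no gaps), sorted by rank.
    """

    table: pd.DataFrame
    provenance: dict = field(default_factory=dict)
    n_unmapped: int = 0

    def __post_init__(self) -> None:
        n = len(self.table)
        ranks = self.table["rank"].to_numpy()
        if not np.array_equal(np.sort(ranks), np.arange(1, n + 1)):
            raise ValueError("ranks must be a gapless permutation of 1..n")
        if self.table["id"].duplicated().any():
            dup = self.table["id"][self.table["id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate id after collapse: {dup!r}")
        self.table = self.table.sort_values("rank", kind="mergesort").reset_index(drop=True)

    def ids(self) -> pd.Series:
        return self.table["id"]

    def top(self, n: int) -> set:
        return set(self.table["id"].iloc[:n])

    def sign_of(self) -> dict:
        return dict(zip(self.table["id"], np.sign(self.table["signed_stat"])))

    def rank_of(self) -> dict:
        return dict(zip(self.table["id"], self.table["rank"]))

    def __len__(self) -> int:
        return len(self.table)

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


@dataclass
class OverlapResult:
    """Top-list overlap between two ranked lists with its null p-value(s)."""

    k: int
    n1: int
    n2: int
    N: int
    p_hyper: float
    p_perm: float | None = None
    perm_reps: int | None = None
    universe_policy: str = "intersection"

    def to_dict(self) -> dict:
        return {
            "k": self.k, "n1": self.n1, "n2": self.n2, "N": self.N,
            "p_hyper": self.p_hyper, "p_perm": self.p_perm,
            "perm_reps": self.perm_reps, "universe_policy": self.universe_policy,
        }

    def summary(self) -> str:
        msg = (
            f"overlap {self.k}/{min(self.n1, self.n2)} "
            f"(universe {self.N}, policy {self.universe_policy}), "
            f"hypergeometric p = {self.p_hyper:.3g}"
        )
        if self.p_perm is not None:
            msg += f", permutation p = {self.p_perm:.3g} ({self.perm_reps} reps)"
        return msg


@dataclass
class ConcordanceProfile:
    """Direction-split rank-bin profile of one top-K list mapped into another.

    ``concordant_freq[b]`` (resp. ``discordant_freq[b]``) is the fraction of
    the K top genes of list A whose homolog lies in rank bin b of list B with
    agreeing (resp. opposing) sign of change. Together with
    ``unmapped_fraction`` the frequencies sum to 1.
    """

    concordant_freq: np.ndarray
    discordant_freq: np.ndarray
    unmapped_fraction: float
    K: int
    bin_size: int

    def validate(self, tol: float = 1e-12) -> None:
        total = self.concordant_freq.sum() + self.discordant_freq.sum() + self.unmapped_fraction
        if abs(total - 1.0) > tol:
            raise AssertionError(f"profile frequencies sum to {total}, not 1")

    @property
    def n_bins(self) -> int:
        return len(self.concordant_freq)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_index": np.arange(1, self.n_bins + 1),
                "concordant_freq": self.concordant_freq,
                "discordant_freq": self.discordant_freq,
            }
        )


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _collapse_best_p(frame: pd.DataFrame, by: str) -> pd.DataFrame:
    """Keep the best row per group: smallest p, tie larger |signed_stat|, then id."""
    work = frame.copy()
    work["_abs"] = -work["signed_stat"].abs()
    work = work.sort_values([by, "p", "_abs", "id"], kind="mergesort")
    out = work.drop_duplicates(subset=by, keep="first").drop(columns="_abs")
    return out


def collapse_to_homologs(
    de: DEResults,
    annotation: pd.Series,
    omap: OrthologMap,
    side: str = "A",
) -> RankedGeneList:
    """Collapse a probeset-level DE result to a ranked homolog-group list.

    Probesets are first collapsed to unique gene ids keeping the entry with
    the smallest p (tie: larger |log2FC|, then probeset id), then genes are
    mapped to homolog-group ids through ``omap`` (side 'A' or 'B'); genes of
    the same group are again collapsed to the best p within the species.
    Unmapped genes are recorded and excluded; the output is re-ranked.
    """
    tab = de.table.rename_axis("probeset_id").reset_index()
    tab["gene"] = annotation.reindex(tab["probeset_id"]).to_numpy()
    tab = tab.dropna(subset=["gene"])
    frame = pd.DataFrame(
        {
            "id": tab["probeset_id"],
            "gene": tab["gene"],
            "signed_stat": tab["log2FC"],
            "p": tab["p"],
        }
    )
    by_gene = _collapse_best_p(frame, "gene")
    group_of = omap.group_of(side)
    by_gene = by_gene.assign(group=group_of.reindex(by_gene["gene"]).to_numpy())
    n_unmapped = int(by_gene["group"].isna().sum())
    mapped = by_gene.dropna(subset=["group"])
    if mapped.empty:
        raise ValueError("no genes could be mapped to homolog groups")
    mapped = mapped.assign(id=mapped["group"])
    by_group = _collapse_best_p(mapped, "group")
    out = by_group[["id", "signed_stat", "p"]].copy()
    out = out.sort_values(["p", "signed_stat", "id"], kind="mergesort",
                          key=lambda s: -s.abs() if s.name == "signed_stat" else s)
    out["rank"] = np.arange(1, len(out) + 1)
    return RankedGeneList(
        table=out.reset_index(drop=True),
        provenance={
            "contrast": de.contrast,
            "collapse": omap.policy,
            "side": side,
        },
        n_unmapped=n_unmapped,
    )


def _universe(listA: RankedGeneList, listB: RankedGeneList, policy) -> set:
    ids_a, ids_b = set(listA.ids()), set(listB.ids())
    if policy == "intersection":
        return ids_a & ids_b
    if policy == "union":
        return ids_a | ids_b
    raise ValueError(f"unknown universe policy {policy!r}")


def overlap_hypergeom(
    listA: RankedGeneList,
    listB: RankedGeneList,
    topA: int = 1000,
    topB: int = 1000,
    universe_policy: str | int = "intersection",
) -> OverlapResult:
    """Upper-tail hypergeometric test of the top-list overlap.

    The universe defaults to the homolog groups present in BOTH collapsed
    lists ('intersection'); 'union' and a fixed integer N are alternatives.
    The policy is reported with the result because it is the dominant
    unstated degree of freedom in this kind of comparison.
    """
    if topA > len(listA) or topB > len(listB):
        raise ValueError("top size exceeds list length")
    if isinstance(universe_policy, int):
        universe = None
        n_universe = universe_policy
        policy_name = f"fixed:{universe_policy}"
        top_a = listA.top(topA)
        top_b = listB.top(topB)
    else:
        universe = _universe(listA, listB, universe_policy)
        n_universe = len(universe)
        policy_name = universe_policy
        top_a = listA.top(topA) & universe
        top_b = listB.top(topB) & universe
    if n_universe < max(topA, topB):
        raise ValueError(
            f"universe size {n_universe} smaller than requested top-list size "
            f"{max(topA, topB)}"
        )
    k = len(top_a & top_b)
    n1, n2 = len(top_a), len(top_b)
    p = float(stats.hypergeom.sf(k - 1, n_universe, n1, n2))
    return OverlapResult(
        k=k, n1=n1, n2=n2, N=n_universe, p_hyper=min(max(p, 0.0), 1.0),
        universe_policy=policy_name,
    )


def overlap_permutation(
    listA: RankedGeneList,
    listB: RankedGeneList,
    topA: int = 1000,
    topB: int = 1000,
    reps: int = 10_000,
    seed: int = 0,
    universe_policy: str = "intersection",
) -> OverlapResult:
    """Permutation p-value for the top-list overlap.

    Draws ``reps`` resamples of a topA-sized id set uniformly without
    replacement from the universe and counts overlaps with the observed top-B
    set; p = (1 + #{overlap >= observed}) / (reps + 1), floored at
    1/(reps+1).
    """
    if reps < 100:
        raise ValueError("need >=100 permutation replicates")
    base = overlap_hypergeom(listA, listB, topA, topB, universe_policy)
    universe = np.array(sorted(_universe(listA, listB, universe_policy)))
    top_b = listB.top(topB) & set(universe)
    b_mask = np.isin(universe, sorted(top_b))
    rng = np.random.default_rng(seed)
    n1 = base.n1
    count = 0
    for _ in range(reps):
        idx = rng.choice(len(universe), size=n1, replace=False)
        if b_mask[idx].sum() >= base.k:
            count += 1
    base.p_perm = (1 + count) / (reps + 1)
    base.perm_reps = reps
    return base


def concordance_profile(
    listA: RankedGeneList,
    listB: RankedGeneList,
    K: int = 200,
    bin_size: int = 1000,
) -> ConcordanceProfile:
    """Direction-split rank-bin profile of list A's top K genes in list B.

    List B is partitioned into consecutive rank bins of ``bin_size`` (the
    last bin may be short). Each of A's top-K genes found in B increments its
    bin's concordant count when the signs of change agree, discordant
    otherwise; genes absent from B make up the unmapped fraction.
    """
    if K > len(listA):
        raise ValueError(f"K={K} exceeds list A length {len(listA)}")
    n_bins = max(1, math.ceil(len(listB) / bin_size))
    conc = np.zeros(n_bins)
    disc = np.zeros(n_bins)
    rank_b = listB.rank_of()
    sign_b = listB.sign_of()
    top = listA.table.iloc[:K]
    unmapped = 0
    for gid, stat in zip(top["id"], top["signed_stat"]):
        if gid not in rank_b:
            unmapped += 1
            continue
        b = (rank_b[gid] - 1) // bin_size
        if np.sign(stat) == sign_b[gid]:
            conc[b] += 1
        else:
            disc[b] += 1
    profile = ConcordanceProfile(
        concordant_freq=conc / K,
        discordant_freq=disc / K,
        unmapped_fraction=unmapped / K,
        K=K,
        bin_size=bin_size,
    )
    profile.validate()
    return profile


def plot_concordance_profile(profile: ConcordanceProfile, ax=None, title: str | None = None):
    """Stacked-bar rendering of a concordance profile (concordant green on red)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    x = np.arange(1, profile.n_bins + 1)
    ax.bar(x, profile.concordant_freq, color="forestgreen", label="concordant")
    ax.bar(x, profile.discordant_freq, bottom=profile.concordant_freq,
           color="firebrick", label="discordant")
    ax.set_xlabel(f"rank bin ({profile.bin_size} genes per bin)")
    ax.set_ylabel(f"fraction of top {profile.K}")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False)
    return ax
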