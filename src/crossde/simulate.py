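"""Synthetic paired two-model expression studies with known ground truth.

The generator emulates the design of a paired mouse-model striatal time
course: two studies ("models") on disjoint probeset namespaces linked by an
ortholog map, each with 2 genotypes (WT, MUT) x 3 ages x a few replicates.
Expression follows the same linear model the analysis assumes,

    y_gs = mu_g + beta_g * I[MUT] + gamma_g * t_s + delta_g * I[MUT] * t_s + eps,
    eps ~ Normal(0, sigma_g^2),     sigma_g^2 ~ d0 * s0^2 / chi^2_{d0},

with time entering as the centred ordered index of the age (months spacing is
irrelevant to rank-based trajectory templates). beta_g carries the planted
genotype effect: a configurable fraction of genes is differentially expressed,
of which a tunable share is planted in BOTH models with the same sign (shared
signature) or opposite sign (discordant); the remainder is split between the
two models. gamma_g / delta_g encode per-genotype monotone trajectories (up /
flat / down). Gene-wise variances are drawn from a scaled inverse-chi-square
so the variance-moderation assumptions of the analysis hold by construction.

All randomness derives from a single seed through named substreams, so adding
a generator does not perturb the draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .io import ExpressionStudy, GeneSetDAG, OrthologMap

__all__ = [
    "SimulationConfig",
    "SimulatedTruth",
    "simulate_truth",
    "simulate_study",
    "simulate_paired_models",
    "simulate_enrichment",
]

_TRAJECTORIES = ("up", "flat", "down")


def _rng(seed: int, name: str) -> np.random.Generator:
    """Named substream: independent generator per (seed, component name)."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


@dataclass
class SimulationConfig:
    """Study-design and signal parameters of the paired-model generator.

    Defaults mirror a desk-scale version of a paired striatal time course:
    5000 genes, 2 genotypes x 3 ages x 5 replicates per cell, modest log2
    effect sizes, and gene variances from a scaled inverse-chi-square prior.
    """

    n_genes: int = 5000
    #: probability of a gene being measured by 1, 2, ... probesets
    probesets_per_gene: dict[int, float] = field(
        default_factory=lambda: {1: 0.8, 2: 0.15, 3: 0.05}
    )
    replicates_per_cell: int = 5
    times: tuple = (6, 12, 18)
    baseline_mean: float = 7.0
    #: magnitude distribution of the planted genotype log2FC: a float is a
    #: point mass; a (mean, sd) tuple draws Normal magnitudes clipped at 0.05
    genotype_effect_size: float | tuple[float, float] = (0.5, 0.15)
    de_fraction: float = 0.05
    shared_fraction: float = 0.6
    discordant_fraction: float = 0.1
    trajectory_mix: dict[str, float] = field(
        default_factory=lambda: {"up": 0.2, "flat": 0.6, "down": 0.2}
    )
    #: log2 change per time step for an 'up' trajectory (negated for 'down')
    trajectory_slope: float = 0.3
    #: (d0_true, s0_sq_true) of the scaled inverse-chi-square variance prior
    variance_prior: tuple[float, float] = (4.0, 0.05)
    mappable_fraction: float = 0.85
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.shared_fraction + self.discordant_fraction > 1.0 + 1e-12:
            raise ValueError("shared_fraction + discordant_fraction must be <= 1")
        if self.replicates_per_cell < 2:
            raise ValueError("replicates_per_cell must be >= 2")
        for dist in (self.probesets_per_gene, self.trajectory_mix):
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError("probability mixes must sum to 1")
        d0, s0 = self.variance_prior
        if d0 <= 0 or s0 <= 0:
            raise ValueError("variance prior parameters must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SimulatedTruth:
    """Planted per-gene ground truth for a paired simulation."""

    genes: pd.DataFrame
    #: term ids carrying planted enrichment signal (filled by simulate_enrichment)
    enriched_terms: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        g = self.genes
        if ((g["sign_A"] != 0) != g["is_de_A"]).any() or (
            (g["sign_B"] != 0) != g["is_de_B"]
        ).any():
            raise ValueError("signs must be nonzero exactly for DE genes")

    def de_genes(self, side: str) -> pd.Index:
        return self.genes.index[self.genes[f"is_de_{side}"]]


def _draw_effect_sizes(config: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    spec = config.genotype_effect_size
    if isinstance(spec, (int, float)):
        return np.full(n, float(spec))
    mean, sd = spec
    return np.maximum(rng.normal(mean, sd, size=n), 0.05)


def simulate_truth(config: SimulationConfig) -> SimulatedTruth:
    """Draw the planted per-gene truth shared by both simulated studies."""
    rng = _rng(config.seed, "truth")
    n = config.n_genes
    gene_ids = [f"HG{i:05d}" for i in range(n)]

    is_de_a = np.zeros(n, bool)
    is_de_b = np.zeros(n, bool)
    sign_a = np.zeros(n, int)
    sign_b = np.zeros(n, int)

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    n_shared = int(round(config.shared_fraction * n_de))
    n_disc = int(round(config.discordant_fraction * n_de))
    shared = de_idx[:n_shared]
    disc = de_idx[n_shared:n_shared + n_disc]
    rest = de_idx[n_shared + n_disc:]
    only_a = rest[: len(rest) // 2 + len(rest) % 2]
    only_b = rest[len(rest) // 2 + len(rest) % 2:]

    signs = rng.choice([-1, 1], size=n_de)
    sign_lookup = dict(zip(de_idx, signs))
    for idx in shared:
        is_de_a[idx] = is_de_b[idx] = True
        sign_a[idx] = sign_b[idx] = sign_lookup[idx]
    for idx in disc:
        is_de_a[idx] = is_de_b[idx] = True
        sign_a[idx] = sign_lookup[idx]
        sign_b[idx] = -sign_lookup[idx]
    for idx in only_a:
        is_de_a[idx] = True
        sign_a[idx] = sign_lookup[idx]
    for idx in only_b:
        is_de_b[idx] = True
        sign_b[idx] = sign_lookup[idx]

    # shared genes reuse one magnitude in both models so the planted
    # signature is concordant in size as well as sign
    beta_mag = _draw_effect_sizes(config, rng, n)

    # every gene gets a wild-type trajectory; the mutant trajectory differs
    # only for DE genes, so genotype-dependent temporal change is confined to
    # the dysregulated subset as in real studies
    traj_probs = [config.trajectory_mix[t] for t in _TRAJECTORIES]
    traj_wt = rng.choice(_TRAJECTORIES, size=n, p=traj_probs)
    traj_alt = rng.choice(_TRAJECTORIES, size=n, p=traj_probs)
    traj_mut = np.where(is_de_a | is_de_b, traj_alt, traj_wt)

    d0, s0 = config.variance_prior
    sigma_sq = d0 * s0 / rng.chisquare(d0, size=n)

    genes = pd.DataFrame(
        {
            "is_de_A": is_de_a,
            "is_de_B": is_de_b,
            "sign_A": sign_a,
            "sign_B": sign_b,
            "beta_magnitude": beta_mag,
            "trajectory_WT": traj_wt,
            "trajectory_MUT": traj_mut,
            "sigma_sq_true": sigma_sq,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )
    return SimulatedTruth(genes=genes)


def _slope(trajectory: np.ndarray, step: float) -> np.ndarray:
    return np.where(
        trajectory == "up", step, np.where(trajectory == "down", -step, 0.0)
    )


def simulate_study(
    config: SimulationConfig,
    model_label: str,
    truth: SimulatedTruth,
    side: str = "A",
) -> ExpressionStudy:
    """Generate one study (probeset matrix + design + annotation) from truth.

    Probeset namespaces are prefixed by the model label so paired studies are
    disjoint. The centred time index makes the pooled MUT - WT contrast equal
    beta_g exactly in expectation.
    """
    if config.replicates_per_cell < 2:
        raise ValueError("replicates_per_cell must be >= 2")
    rng = _rng(config.seed, f"study:{model_label}")
    genes = truth.genes
    n = len(genes)

    ks, probs = zip(*sorted(config.probesets_per_gene.items()))
    n_probes_per_gene = rng.choice(ks, size=n, p=probs)
    gene_idx = np.repeat(np.arange(n), n_probes_per_gene)
    n_probes = len(gene_idx)
    probeset_ids = [f"{model_label}:PS{i:06d}" for i in range(n_probes)]
    gene_names = np.array(
        [f"G{side}{i:05d}" for i in range(n)]
    )  # per-side gene namespace

    # design
    times = list(config.times)
    reps = config.replicates_per_cell
    rows = []
    for geno in ("WT", "MUT"):
        for t in times:
            for r in range(reps):
                rows.append(
                    {
                        "sample_id": f"{model_label}_{geno}_{t}m_r{r + 1}",
                        "genotype": geno,
                        "time": t,
                        "model": model_label,
                    }
                )
    design = pd.DataFrame(rows).set_index("sample_id")

    t_index = np.array([times.index(t) for t in design["time"]], float)
    t_centred = t_index - t_index.mean()
    is_mut = (design["genotype"] == "MUT").to_numpy(float)

    beta = genes["beta_magnitude"].to_numpy() * genes[f"sign_{side}"].to_numpy()
    gamma = _slope(genes["trajectory_WT"].to_numpy(), config.trajectory_slope)
    slope_mut = _slope(genes["trajectory_MUT"].to_numpy(), config.trajectory_slope)
    delta = slope_mut - gamma
    sigma = np.sqrt(genes["sigma_sq_true"].to_numpy())

    probe_offset = rng.normal(0.0, 0.5, size=n_probes)  # probe affinity
    mu = config.baseline_mean + probe_offset

    b = beta[gene_idx][:, None]
    g_ = gamma[gene_idx][:, None]
    d_ = delta[gene_idx][:, None]
    mean = (
        mu[:, None]
        + b * is_mut[None, :]
        + g_ * t_centred[None, :]
        + d_ * (is_mut * t_centred)[None, :]
    )
    noise = rng.normal(0.0, 1.0, size=mean.shape) * sigma[gene_idx][:, None]
    matrix = pd.DataFrame(
        mean + noise, index=pd.Index(probeset_ids, name="probeset_id"),
        columns=design.index,
    )
    annotation = pd.Series(
        gene_names[gene_idx], index=pd.Index(probeset_ids, name="probeset_id"),
        name="gene_id",
    )
    return ExpressionStudy(matrix=matrix, design=design, annotation=annotation)


def simulate_paired_models(
    config: SimulationConfig,
    labels: tuple[str, str] = ("A", "B"),
) -> tuple[ExpressionStudy, ExpressionStudy, OrthologMap, SimulatedTruth]:
    """Two linked studies on disjoint namespaces plus their ortholog map.

    A configurable fraction of genes (default 0.85) is mappable between the
    two gene namespaces; shared-signature genes are DE in both studies with
    concordant sign, discordant-fraction genes with opposite sign.
    """
    truth = simulate_truth(config)
    study_a = simulate_study(config, labels[0], truth, side="A")
    study_b = simulate_study(config, labels[1], truth, side="B")

    rng = _rng(config.seed, "orthomap")
    n = config.n_genes
    mappable = rng.random(n) < config.mappable_fraction
    pairs = pd.DataFrame(
        {
            "gene_id_A": [f"GA{i:05d}" for i in np.flatnonzero(mappable)],
            "gene_id_B": [f"GB{i:05d}" for i in np.flatnonzero(mappable)],
            "homolog_group_id": [truth.genes.index[i] for i in np.flatnonzero(mappable)],
        }
    )
    omap = OrthologMap(pairs=pairs)
    return study_a, study_b, omap, truth


def simulate_enrichment(
    config: SimulationConfig,
    n_terms: int = 50,
    planted_terms: int = 2,
    truth: SimulatedTruth | None = None,
    depth: int = 3,
    term_size_range: tuple[int, int] = (10, 50),
    odds_ratio: float = 8.0,
    side: str = "A",
) -> GeneSetDAG:
    """Random gene-set DAG with DE genes planted into a few terms.

    Terms are organised in ``depth`` levels; each non-root term has one or
    two parents from the level above. Direct annotations are sampled from the
    side's gene universe; in planted terms, DE genes are over-sampled at the
    stated odds ratio. Planted term ids are recorded in
    ``truth.enriched_terms``.
    """
    if planted_terms > n_terms:
        raise ValueError("planted_terms must be <= n_terms")
    if truth is None:
        truth = simulate_truth(config)
    rng = _rng(config.seed, "enrichment")
    n = config.n_genes
    gene_ids = np.array([f"G{side}{i:05d}" for i in range(n)])
    is_de = truth.genes[f"is_de_{side}"].to_numpy()

    levels = np.sort(rng.integers(0, depth, size=n_terms))
    levels[: max(1, n_terms // depth // 2)] = 0  # guarantee roots
    names = {f"T{i:04d}": f"synthetic term {i}" for i in range(n_terms)}
    term_ids = sorted(names)
    parents: dict[str, set[str]] = {t: set() for t in term_ids}
    for i, term in enumerate(term_ids):
        if levels[i] == 0:
            continue
        candidates = [term_ids[j] for j in range(n_terms) if levels[j] < levels[i]]
        k = int(rng.integers(1, 3))
        chosen = rng.choice(candidates, size=min(k, len(candidates)), replace=False)
        parents[term] = set(chosen.tolist())

    # planted terms: prefer leaf-most levels so conditioning is exercised
    order_by_depth = [t for _, t in sorted(zip(-levels, term_ids))]
    planted = sorted(order_by_depth[:planted_terms])

    weights_plain = np.ones(n)
    weights_planted = np.where(is_de, odds_ratio, 1.0)
    direct: dict[str, set[str]] = {}
    for term in term_ids:
        size = int(rng.integers(term_size_range[0], term_size_range[1] + 1))
        w = weights_planted if term in planted else weights_plain
        p = w / w.sum()
        chosen = rng.choice(n, size=size, replace=False, p=p)
        direct[term] = set(gene_ids[chosen])

    truth.enriched_terms = planted
    return GeneSetDAG(names=names, parents=parents, direct=direct)
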