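"""End-to-end orchestration of the paired-model analysis on simulated data.

``run_full_pipeline`` executes simulate → differential expression (per model)
→ temporal screen and pattern table → cross-model overlap and concordance →
conditional enrichment → genotype x model interaction, writing every stage's
TSV plus a JSON summary and a MANIFEST of artifact content hashes. All
randomness flows from the single configured seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from .crossmap import collapse_to_homologs, concordance_profile, overlap_permutation
from .diffexpr import DifferentialExpression
from .enrichment import conditional_enrich, enrichment_map_tables
from .interaction import ModelInteraction
from .io import write_expression_study, write_gene_sets, write_ortholog_map, write_table
from .simulate import SimulationConfig, simulate_enrichment, simulate_paired_models
from .temporal import GenotypeTimeANOVA

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "run_full_pipeline", "render_summary"]

STAGES = ("simulate", "de", "temporal", "concord", "enrich", "interaction")


@dataclass
class PipelineConfig:
    """Thresholds, sizes and output location for a full pipeline run."""

    out_dir: str = "crossde_out"
    seed: int = 0
    alpha: float = 0.05
    top_k: int = 200
    top_n: int = 1000
    bin_size: int = 1000
    r_min: float = 0.8
    min_amp: float = 0.1
    min_abs_diff: float = 0.20
    perm_reps: int = 2000
    n_terms: int = 50
    planted_terms: int = 2
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if isinstance(self.simulation, dict):
            self.simulation = SimulationConfig(**self.simulation)
        self.simulation.seed = self.seed
        for name in ("alpha",):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"{name} must be in (0, 1)")
        if min(self.top_k, self.top_n, self.bin_size, self.perm_reps) <= 0:
            raise ValueError("sizes must be positive")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _round6(x: float) -> float:
    return float(f"{float(x):.6g}")


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the report bundle (summary dict + paths)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": {}}
    artifacts: list[Path] = []
    completed: list[str] = []

    def finish_manifest(complete: bool) -> None:
        lines = [] if complete else ["# INCOMPLETE RUN — stages done: " + ",".join(completed)]
        for p in sorted(artifacts):
            lines.append(f"{_hash_file(p)}  {p.name}")
        (out / "MANIFEST").write_text("\n".join(lines) + "\n", encoding="utf-8")

    def stage(name):
        def wrap(fn):
            t0 = time.time()
            try:
                fn()
            except Exception as exc:  # pragma: no cover - error path
                finish_manifest(complete=False)
                raise PipelineError(name, exc) from exc
            completed.append(name)
            logger.info("stage %s done in %.2fs", name, time.time() - t0)
        return wrap

    state: dict = {}

    @stage("simulate")
    def _simulate():
        a, b, omap, truth = simulate_paired_models(config.simulation)
        dag = simulate_enrichment(
            config.simulation, n_terms=config.n_terms,
            planted_terms=config.planted_terms, truth=truth,
        )
        state.update(study_a=a, study_b=b, omap=omap, truth=truth, dag=dag)
        for label, study in (("A", a), ("B", b)):
            artifacts.extend(write_expression_study(study, out / f"study{label}").values())
        write_ortholog_map(omap, out / "ortholog_map.tsv")
        write_gene_sets(dag, out / "terms.tsv", out / "term_annotations.tsv")
        write_table(
            truth.genes.rename_axis("gene_id").reset_index(), out / "truth.tsv"
        )
        artifacts.extend(
            [out / "ortholog_map.tsv", out / "terms.tsv",
             out / "term_annotations.tsv", out / "truth.tsv"]
        )
        summary["stages"]["simulate"] = {
            "n_genes": config.simulation.n_genes,
            "n_probesets_A": len(a.probeset_ids),
            "n_probesets_B": len(b.probeset_ids),
            "n_mapped_groups": len(omap),
        }

    @stage("de")
    def _de():
        des = {}
        for label in ("A", "B"):
            res = DifferentialExpression(state[f"study_{label.lower()}"]).fit()
            des[label] = res
            write_table(res, out / f"de_{label}.tsv")
            artifacts.append(out / f"de_{label}.tsv")
            summary["stages"].setdefault("de", {})[label] = {
                "n_probesets": len(res.table),
                "n_nominal_p05": int((res.table["p"] < 0.05).sum()),
                "n_fdr_q05": int((res.table["q"] < 0.05).sum()),
                "d0": _round6(res.d0) if res.d0 != float("inf") else "inf",
                "s0_sq": _round6(res.s0_sq),
            }
        state["de"] = des

    @stage("temporal")
    def _temporal():
        res = GenotypeTimeANOVA(
            state["study_a"], alpha=config.alpha,
            r_min=config.r_min, min_amp=config.min_amp,
        ).fit()
        state["temporal"] = res
        write_table(res, out / "temporal_calls.tsv")
        write_table(res.pattern_table.to_frame(), out / "pattern_table.tsv")
        artifacts.extend([out / "temporal_calls.tsv", out / "pattern_table.tsv"])
        summary["stages"]["temporal"] = {
            "n_fdr_q05": int((res.anova["q"] < config.alpha).sum()),
            "pattern_table_total": res.pattern_table.grand_total,
            "n_mixed": res.pattern_table.n_mixed,
        }

    @stage("concord")
    def _concord():
        list_a = collapse_to_homologs(
            state["de"]["A"], state["study_a"].annotation, state["omap"], side="A"
        )
        list_b = collapse_to_homologs(
            state["de"]["B"], state["study_b"].annotation, state["omap"], side="B"
        )
        shared = set(list_a.ids()) & set(list_b.ids())
        top_n = min(config.top_n, len(list_a), len(list_b), len(shared))
        overlap = overlap_permutation(
            list_a, list_b, topA=top_n, topB=top_n,
            reps=config.perm_reps, seed=config.seed,
        )
        top_k = min(config.top_k, len(list_a))
        profile = concordance_profile(
            list_a, list_b, K=top_k, bin_size=config.bin_size
        )
        state["concord"] = (list_a, list_b, overlap, profile)
        write_table(profile, out / "concordance_profile.tsv")
        (out / "overlap.json").write_text(
            json.dumps(overlap.to_dict(), indent=2, sort_keys=True), encoding="utf-8"
        )
        artifacts.extend([out / "concordance_profile.tsv", out / "overlap.json"])
        summary["stages"]["concord"] = {
            "top_n": top_n,
            "overlap_k": overlap.k,
            "p_hyper": _round6(overlap.p_hyper),
            "p_perm": _round6(overlap.p_perm),
            "first_bin_concordant_freq": _round6(profile.concordant_freq[0]),
            "first_bin_discordant_freq": _round6(profile.discordant_freq[0]),
            "unmapped_fraction": _round6(profile.unmapped_fraction),
        }

    @stage("enrich")
    def _enrich():
        de_a = state["de"]["A"]
        genes = de_a.table.dropna(subset=["gene_id"])
        sig = set(genes.loc[genes["p"] < config.alpha, "gene_id"])
        universe = set(genes["gene_id"]) & state["dag"].universe()
        sig &= universe
        res = conditional_enrich(
            state["dag"], sig, universe, alpha_condition=config.alpha
        )
        state["enrich"] = res
        write_table(res, out / "enrichment.tsv")
        nodes, edges = enrichment_map_tables(
            res, state["dag"].propagated, alpha=config.alpha
        )
        write_table(nodes, out / "enrichment_nodes.tsv")
        write_table(edges, out / "enrichment_edges.tsv")
        artifacts.extend(
            [out / "enrichment.tsv", out / "enrichment_nodes.tsv",
             out / "enrichment_edges.tsv"]
        )
        planted = set(state["truth"].enriched_terms)
        top_terms = set(res.table.loc[res.table["p"] < config.alpha, "term_id"])
        summary["stages"]["enrich"] = {
            "n_terms": len(res.table),
            "n_sig_terms": len(top_terms),
            "planted_terms_recovered": len(planted & top_terms),
            "n_planted": len(planted),
        }

    @stage("interaction")
    def _interaction():
        res = ModelInteraction(state["study_a"], state["study_b"], state["omap"]).fit()
        state["interaction"] = res
        write_table(res, out / "interaction.tsv")
        div = res.divergent(p_threshold=config.alpha, min_abs_diff=config.min_abs_diff)
        write_table(div.reset_index(), out / "interaction_divergent.tsv")
        artifacts.extend([out / "interaction.tsv", out / "interaction_divergent.tsv"])
        summary["stages"]["interaction"] = {
            "n_shared_genes": len(res.table),
            "n_sig_interaction": int((res.table["p_interaction"] < config.alpha).sum()),
            "n_divergent": len(div),
        }

    summary_path = out / "summary.json"
    summary_path.write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    artifacts.append(summary_path)
    finish_manifest(complete=True)
    return {"summary": summary, "out_dir": out, "state": state}


def render_summary(bundle: dict) -> str:
    """Deterministic human-readable report, one section per pipeline stage."""
    summary = bundle["summary"]
    missing = [s for s in STAGES if s not in summary.get("stages", {})]
    if missing:
        raise ValueError(f"incomplete bundle; missing stage(s): {', '.join(missing)}")
    lines = [
        "crossde pipeline report",
        "=" * 48,
        f"seed: {summary['seed']}",
    ]
    for stage_name in STAGES:
        lines.append("")
        lines.append(f"[{stage_name}]")
        for key, val in sorted(summary["stages"][stage_name].items()):
            if isinstance(val, dict):
                for k2, v2 in sorted(val.items()):
                    lines.append(f"  {key}.{k2}: {v2}")
            else:
                lines.append(f"  {key}: {val}")
    return "\n".join(lines) + "\n"
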