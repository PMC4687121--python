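import numpy as np
import pandas as pd
import pytest

from crossde.io import ExpressionStudy


def build_study(
    n_probes: int = 20,
    genotypes=("WT", "MUT"),
    times=(6, 12, 18),
    reps: int = 2,
    seed: int = 0,
    matrix: np.ndarray | None = None,
    genes_per_probe: int = 1,
) -> ExpressionStudy:
    """Small dense study with deterministic ids, Gaussian noise by default."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in genotypes:
        for t in times:
            for r in range(reps):
                rows.append({"sample_id": f"{g}_{t}_{r}", "genotype": g,
                             "time": t, "model": "toy"})
    design = pd.DataFrame(rows).set_index("sample_id")
    n_samples = len(design)
    if matrix is None:
        matrix = rng.normal(7.0, 0.5, size=(n_probes, n_samples))
    probes = [f"PS{i:04d}" for i in range(n_probes)]
    genes = [f"G{i // genes_per_probe:04d}" for i in range(n_probes)]
    return ExpressionStudy(
        matrix=pd.DataFrame(matrix, index=pd.Index(probes, name="probeset_id"),
                            columns=design.index),
        design=design,
        annotation=pd.Series(genes, index=pd.Index(probes, name="probeset_id"),
                             name="gene_id"),
    )


@pytest.fixture
def small_study() -> ExpressionStudy:
    return build_study(n_probes=30, reps=3, seed=11)
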