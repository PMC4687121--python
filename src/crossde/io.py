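"""Readers, writers and in-memory containers for the pipeline's on-disk formats.

All downstream analysis consumes the domain types defined here:

* :class:`ExpressionStudy` — a log2 expression matrix (probesets × samples)
  together with its sample design (genotype, time, model) and a
  probeset → gene annotation.
* :class:`OrthologMap` — a cross-namespace gene → homolog-group relation used
  to compare ranked gene lists between platforms or species.
* :class:`GeneSetDAG` — gene-set terms with parent edges and true-path
  propagated annotations, supporting conditional over-representation tests.

Formats are TSV throughout (UTF-8, '.' decimal separator); flat gene sets may
also be read from GMT files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionStudy",
    "OrthologMap",
    "GeneSetDAG",
    "read_expression_study",
    "read_ortholog_map",
    "read_gene_sets",
    "write_table",
    "write_expression_study",
    "write_ortholog_map",
    "write_gene_sets",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class ExpressionStudy:
    """Post-normalisation log2 expression matrix plus sample design.

    Parameters
    ----------
    matrix : pandas.DataFrame
        Probesets (rows, index = probeset ids) × samples (columns, sample
        ids), log2 intensities, no missing values.
    design : pandas.DataFrame
        Indexed by sample id; columns ``genotype`` (e.g. WT / MUT), ``time``
        (ordered, e.g. months 6/12/18) and ``model`` (study label).
    annotation : pandas.Series
        probeset id → gene id (many probesets may map to one gene; each
        probeset maps to at most one gene).
    """

    matrix: pd.DataFrame
    design: pd.DataFrame
    annotation: pd.Series

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.matrix.index.has_duplicates:
            dup = self.matrix.index[self.matrix.index.duplicated()][0]
            raise ValueError(f"duplicate probeset id: {dup!r}")
        m_samples = set(self.matrix.columns)
        d_samples = set(self.design.index)
        if m_samples != d_samples:
            orphans = sorted(m_samples ^ d_samples)
            raise ValueError(
                "matrix and design disagree on sample ids; orphan sample(s): "
                + ", ".join(map(str, orphans))
            )
        for col in ("genotype", "time", "model"):
            if col not in self.design.columns:
                raise ValueError(f"design table lacks required column {col!r}")
            if self.design[col].isna().any():
                bad = self.design.index[self.design[col].isna()][0]
                raise ValueError(f"sample {bad!r} has incomplete design ({col} missing)")
        # canonical column order: design order
        self.matrix = self.matrix.loc[:, self.design.index]
        if not np.issubdtype(self.matrix.to_numpy().dtype, np.number):
            raise ValueError("expression matrix contains non-numeric values")
        if self.matrix.isna().to_numpy().any():
            r, c = np.argwhere(self.matrix.isna().to_numpy())[0]
            raise ValueError(
                f"missing expression value at probeset {self.matrix.index[r]!r}, "
                f"sample {self.matrix.columns[c]!r}"
            )
        cell_sizes = self.design.groupby(["genotype", "time"], observed=True).size()
        if (cell_sizes < 2).any():
            bad = cell_sizes[cell_sizes < 2].index[0]
            raise ValueError(
                f"design cell genotype={bad[0]!r}, time={bad[1]!r} has fewer "
                "than 2 samples; variance estimation impossible"
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def probeset_ids(self) -> pd.Index:
        return self.matrix.index

    @property
    def model_label(self) -> str:
        labels = self.design["model"].unique()
        return str(labels[0]) if len(labels) == 1 else ",".join(map(str, labels))

    @property
    def times(self) -> list:
        return sorted(self.design["time"].unique())

    def samples_where(self, **conditions) -> list[str]:
        """Sample ids matching equality conditions on design columns."""
        mask = pd.Series(True, index=self.design.index)
        for col, val in conditions.items():
            mask &= self.design[col] == val
        return list(self.design.index[mask])

    def subset_samples(self, sample_ids: list[str]) -> "ExpressionStudy":
        return ExpressionStudy(
            matrix=self.matrix.loc[:, sample_ids].copy(),
            design=self.design.loc[sample_ids].copy(),
            annotation=self.annotation,
        )


@dataclass
class OrthologMap:
    """Cross-namespace gene relation: (gene_id_A, gene_id_B, homolog_group_id).

    Homolog groups partition the mapped genes: a gene may not belong to two
    groups. Unmapped genes are simply absent from ``pairs``.
    """

    pairs: pd.DataFrame
    policy: str = "best_p_within_species"

    def __post_init__(self) -> None:
        required = {"gene_id_A", "gene_id_B", "homolog_group_id"}
        if not required.issubset(self.pairs.columns):
            raise ValueError(f"ortholog map needs columns {sorted(required)}")
        self.pairs = self.pairs.drop_duplicates().reset_index(drop=True)
        for side in ("A", "B"):
            col = f"gene_id_{side}"
            groups_per_gene = self.pairs.groupby(col)["homolog_group_id"].nunique()
            offenders = groups_per_gene[groups_per_gene > 1]
            if len(offenders):
                raise ValueError(
                    f"gene {offenders.index[0]!r} assigned to "
                    f"{offenders.iloc[0]} homolog groups (must be one)"
                )

    def group_of(self, side: str) -> pd.Series:
        """gene id → homolog group id for side 'A' or 'B'."""
        col = f"gene_id_{side}"
        sub = self.pairs[[col, "homolog_group_id"]].drop_duplicates()
        return sub.set_index(col)["homolog_group_id"]

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class GeneSetDAG:
    """Gene-set terms with parent edges and true-path propagated gene sets.

    ``direct`` holds the genes annotated straight to each term; ``propagated``
    additionally contains every gene annotated to any descendant term
    (true-path rule). A GMT file yields a flat DAG (all terms parentless,
    propagated == direct).
    """

    names: dict[str, str]
    parents: dict[str, set[str]]
    direct: dict[str, set[str]]
    propagated: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        graph = self.child_parent_graph()
        try:
            cycle = nx.find_cycle(graph)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[-1][1]}"
            raise ValueError(f"cycle in term parent graph: {path}")
        for term, genes in self.direct.items():
            if term not in self.names:
                raise ValueError(f"annotation references unknown term {term!r}")
        if not self.propagated:
            self.propagated = self._propagate()

    def child_parent_graph(self) -> nx.DiGraph:
        """Directed graph with an edge child → parent per parent relation."""
        g = nx.DiGraph()
        g.add_nodes_from(self.names)
        for child, ps in self.parents.items():
            for p in ps:
                if p not in self.names:
                    raise ValueError(f"term {child!r} names unknown parent {p!r}")
                g.add_edge(child, p)
        return g

    def _propagate(self) -> dict[str, set[str]]:
        graph = self.child_parent_graph()
        prop: dict[str, set[str]] = {t: set(self.direct.get(t, ())) for t in self.names}
        # children before parents: topological order on child→parent edges
        for term in nx.lexicographical_topological_sort(graph):
            for parent in graph.successors(term):
                prop[parent] |= prop[term]
        return prop

    @property
    def terms(self) -> list[str]:
        return sorted(self.names)

    def ancestors(self, term: str) -> set[str]:
        return set(nx.descendants(self.child_parent_graph(), term))

    def universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.direct.values():
            out |= genes
        return out


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, **kw)


def read_expression_study(
    matrix_path: str | Path,
    design_path: str | Path,
    annotation_path: str | Path,
) -> ExpressionStudy:
    """Load an expression study from matrix / design / annotation TSVs.

    The matrix TSV has a header row of sample ids and a first column of
    probeset ids. Sample order of matrix and design is reconciled by id, not
    by position. Multi-mapping probesets (one probeset, several genes) are
    dropped with a logged count.
    """
    raw = _read_tsv(matrix_path)
    probe_col = raw.columns[0]
    probes = raw[probe_col]
    if probes.duplicated().any():
        dup = probes[probes.duplicated()].iloc[0]
        raise ValueError(f"duplicate probeset id: {dup!r}")
    values = raw.drop(columns=[probe_col])
    numeric = values.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & (values != "")
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {values.iat[r, c]!r} at row "
            f"{probes.iloc[r]!r}, column {values.columns[c]!r}"
        )
    if numeric.isna().to_numpy().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing expression value at row {probes.iloc[r]!r}, "
            f"column {numeric.columns[c]!r}"
        )
    matrix = numeric.set_index(pd.Index(probes, name="probeset_id"))

    design = _read_tsv(design_path)
    for col in ("sample_id", "genotype", "time", "model"):
        if col not in design.columns:
            raise ValueError(f"design table lacks required column {col!r}")
    time_numeric = pd.to_numeric(design["time"], errors="coerce")
    if not time_numeric.isna().any():
        design["time"] = time_numeric
    design = design.set_index("sample_id")

    ann = _read_tsv(annotation_path)
    for col in ("probeset_id", "gene_id"):
        if col not in ann.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
    genes_per_probe = ann.groupby("probeset_id")["gene_id"].nunique()
    multi = genes_per_probe[genes_per_probe > 1].index
    if len(multi):
        logger.info("dropping %d multi-mapping probesets", len(multi))
        ann = ann[~ann["probeset_id"].isin(multi)]
    annotation = ann.drop_duplicates().set_index("probeset_id")["gene_id"]

    return ExpressionStudy(matrix=matrix, design=design, annotation=annotation)


def read_ortholog_map(path: str | Path, policy: str = "best_p_within_species") -> OrthologMap:
    """Load a cross-namespace ortholog map TSV.

    Columns: ``gene_id_A``, ``gene_id_B``, ``homolog_group_id``. Duplicated
    identical rows are collapsed; a gene assigned to two homolog groups is a
    hard error (the groups must partition the mapped genes).
    """
    pairs = _read_tsv(path)
    return OrthologMap(pairs=pairs, policy=policy)


def read_gene_sets(
    gmt_path: str | Path | None = None,
    term_path: str | Path | None = None,
    annotation_path: str | Path | None = None,
) -> GeneSetDAG:
    """Load gene sets either from a GMT file or from a two-file DAG dialect.

    GMT: one set per line, tab-separated ``set_id``, ``description``, gene
    ids. Yields a flat DAG (all terms parentless).

    DAG dialect: a term table (``term_id``, ``name``, ``parent_ids``
    semicolon-separated, empty for roots) plus an annotation table
    (``gene_id``, ``term_id``). Gene sets are propagated by the true-path
    rule: a gene annotated to a term belongs to all its ancestors.
    """
    if gmt_path is not None:
        names: dict[str, str] = {}
        direct: dict[str, set[str]] = {}
        with open(gmt_path, encoding="utf-8") as fh:
            for line in fh:
                line = line.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise ValueError(f"malformed GMT line: {line[:80]!r}")
                set_id, desc, *genes = fields
                names[set_id] = desc
                direct[set_id] = {g for g in genes if g}
        return GeneSetDAG(names=names, parents={t: set() for t in names}, direct=direct)

    if term_path is None or annotation_path is None:
        raise ValueError("provide either gmt_path or both term_path and annotation_path")
    terms = _read_tsv(term_path)
    for col in ("term_id", "name", "parent_ids"):
        if col not in terms.columns:
            raise ValueError(f"term table lacks required column {col!r}")
    names = dict(zip(terms["term_id"], terms["name"]))
    parents = {
        row.term_id: {p for p in str(row.parent_ids).split(";") if p}
        for row in terms.itertuples()
    }
    ann = _read_tsv(annotation_path)
    for col in ("gene_id", "term_id"):
        if col not in ann.columns:
            raise ValueError(f"annotation table lacks required column {col!r}")
    unknown = set(ann["term_id"]) - set(names)
    if unknown:
        raise ValueError(f"annotation references unknown term {sorted(unknown)[0]!r}")
    direct = {t: set() for t in names}
    for row in ann.itertuples():
        direct[row.term_id].add(row.gene_id)
    return GeneSetDAG(names=names, parents=parents, direct=direct)


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------

#: columns serialized as fixed 3-decimal log2 / linear fold quantities
_FC_COLUMNS = {
    "log2FC", "abs_fc", "AbsFC", "fc_A", "fc_B", "abs_fc_diff",
    "amplitude", "signed_stat",
}


def _format_value(col: str, val) -> str:
    if isinstance(val, (float, np.floating)):
        if col in _FC_COLUMNS:
            return f"{val:.3f}"
        return f"{val:.6g}"
    return str(val)


def write_table(result, path: str | Path) -> None:
    """Write a tabular result (DataFrame, or object with ``to_frame()``) as TSV.

    Column and row order are taken as given (every result type sorts itself
    deterministically before writing). Statistics are serialized with 6
    significant digits; fold-change columns with 3 decimal places.
    """
    frame = result if isinstance(result, pd.DataFrame) else result.to_frame()
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(map(str, frame.columns)) + "\n")
        for row in frame.itertuples(index=False):
            fh.write(
                "\t".join(_format_value(c, v) for c, v in zip(frame.columns, row)) + "\n"
            )


def write_expression_study(study: ExpressionStudy, prefix: str | Path) -> dict[str, Path]:
    """Write matrix/design/annotation TSVs under ``<prefix>_{matrix,design,annotation}.tsv``."""
    prefix = Path(prefix)
    paths = {
        "matrix": prefix.with_name(prefix.name + "_matrix.tsv"),
        "design": prefix.with_name(prefix.name + "_design.tsv"),
        "annotation": prefix.with_name(prefix.name + "_annotation.tsv"),
    }
    study.matrix.rename_axis("probeset_id").reset_index().to_csv(
        paths["matrix"], sep="\t", index=False, float_format="%.6g"
    )
    study.design.rename_axis("sample_id").reset_index().to_csv(
        paths["design"], sep="\t", index=False
    )
    study.annotation.rename_axis("probeset_id").reset_index().to_csv(
        paths["annotation"], sep="\t", index=False
    )
    return paths


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    omap.pairs.to_csv(path, sep="\t", index=False)


def write_gene_sets(dag: GeneSetDAG, term_path: str | Path, annotation_path: str | Path) -> None:
    """Write a GeneSetDAG in the two-file TSV dialect (direct annotations only)."""
    terms = pd.DataFrame(
        {
            "term_id": dag.terms,
            "name": [dag.names[t] for t in dag.terms],
            "parent_ids": [";".join(sorted(dag.parents.get(t, ()))) for t in dag.terms],
        }
    )
    terms.to_csv(term_path, sep="\t", index=False)
    rows = [
        {"gene_id": g, "term_id": t}
        for t in dag.terms
        for g in sorted(dag.direct.get(t, ()))
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(
        annotation_path, sep="\t", index=False
    )
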