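"""Readers and writers for the external formats the pipeline touches.

Formats: differential-expression tables (TSV/CSV), GMT gene-set
collections, TPM expression cohorts (TSV or MatrixMarket triplet with
sidecar name files), protein-interaction edge lists (TSV with columns
``node_a``, ``node_b``, ``score``).  All readers validate their input and
raise :class:`FormatError` / :class:`ValidationError` with enough context
to locate the offending record.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import mmread, mmwrite
from scipy.sparse import csr_matrix
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

VALID_STAGES = ("early", "late", "unknown")
GENOTYPE_FLAGS = ("LKB1_mut", "SMARCA4_mut", "TP53_mut", "KRAS_mut")

#: default column names of a DE table; overridable via ``column_map``
DE_COLUMNS = {"gene": "gene", "log2fc": "log2fc", "p_value": "p_value", "adj_p": "adj_p"}


class FormatError(ValueError):
    """A file does not conform to its declared format."""


class ValidationError(ValueError):
    """A parsed object violates a domain invariant."""


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Differential-expression tables
# ---------------------------------------------------------------------------

@dataclass
class DETable:
    """Per-gene log2 fold change and significance for one mutant-vs-WT contrast.

    Parameters
    ----------
    contrast_id
        Label of the contrast, conventionally ``"L"``, ``"S"`` or ``"LS"``
        (single and double tumor-suppressor mutants against the wild-type
        control line).
    data
        DataFrame indexed by unique ``gene_id`` with float columns
        ``log2fc`` (mutant over WT), ``p_value`` and ``adj_p``.
    provenance
        Free-form metadata, e.g. ``{"adj_p_derived": True}`` when the
        adjusted p-values were BH-computed by the reader.
    """

    contrast_id: str
    data: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        required = ["log2fc", "p_value", "adj_p"]
        missing = [c for c in required if c not in self.data.columns]
        if missing:
            raise ValidationError(f"DE table missing columns: {missing}")
        if self.data.index.has_duplicates:
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValidationError(f"duplicate gene_id in DE table: {dup!r}")
        vals = self.data[required].to_numpy(dtype=float)
        if not np.isfinite(vals[:, 0]).all():
            bad = self.data.index[~np.isfinite(vals[:, 0])][0]
            raise ValidationError(f"non-finite log2fc for gene {bad!r}")
        for j, col in ((1, "p_value"), (2, "adj_p")):
            col_vals = vals[:, j]
            if np.isnan(col_vals).any() or (col_vals <= 0).any() or (col_vals > 1).any():
                bad = self.data.index[~((col_vals > 0) & (col_vals <= 1))][0]
                raise ValidationError(f"{col} outside (0, 1] for gene {bad!r}")
        self.data = self.data.copy()
        self.data[required] = vals

    @property
    def genes(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)


def _read_delimited(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, dtype=str)


def read_de_table(
    path: str | Path,
    contrast_id: str,
    column_map: dict[str, str] | None = None,
) -> DETable:
    """Read a per-contrast differential-expression table from TSV/CSV.

    ``column_map`` maps the logical names ``gene``, ``log2fc``, ``p_value``,
    ``adj_p`` to the file's actual column headers.  If the adjusted-p column
    is absent, BH-adjusted values are computed from ``p_value`` and the
    table's provenance records ``adj_p_derived=True``.
    """
    cols = dict(DE_COLUMNS)
    if column_map:
        cols.update(column_map)
    raw = _read_delimited(path)

    for key in ("gene", "log2fc", "p_value"):
        if cols[key] not in raw.columns:
            raise FormatError(
                f"{path}: required column {cols[key]!r} (for {key}) not found; "
                f"available: {list(raw.columns)}"
            )

    genes = raw[cols["gene"]].astype(str)
    dupmask = genes.duplicated()
    if dupmask.any():
        raise ValidationError(f"{path}: duplicate gene_id {genes[dupmask].iloc[0]!r}")

    def _numeric(key: str) -> np.ndarray:
        col = raw[cols[key]]
        out = pd.to_numeric(col, errors="coerce")
        bad = out.isna() & col.notna()
        if bad.any():
            # +2: 1-based data rows after the header line
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
            raise FormatError(f"{path}: non-numeric {key} at line {row}: {col[bad].iloc[0]!r}")
        if out.isna().any():
            row = int(np.flatnonzero(out.isna().to_numpy())[0]) + 2
            raise FormatError(f"{path}: missing {key} at line {row}")
        return out.to_numpy(dtype=float)

    data = pd.DataFrame(
        {"log2fc": _numeric("log2fc"), "p_value": _numeric("p_value")},
        index=pd.Index(genes, name="gene"),
    )
    provenance: dict = {"source": str(path)}
    if cols["adj_p"] in raw.columns:
        data["adj_p"] = _numeric("adj_p")
    else:
        data["adj_p"] = bh_adjust(data["p_value"].to_numpy())
        provenance["adj_p_derived"] = True
        logger.info("%s: adj_p absent; computed BH adjustment from p_value", path)
    return DETable(contrast_id=contrast_id, data=data, provenance=provenance)


def write_de_table(table: DETable, path: str | Path) -> None:
    """Write a DE table as TSV with the default column names, genes sorted."""
    out = table.data.sort_index()
    out = out.rename_axis("gene").reset_index()
    out.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# Gene-set collections (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets keyed by term id (GO BP-style)."""

    sets: dict[str, set]
    names: dict[str, str]

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {term!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def term_ids(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: ``term_id <TAB> description <TAB> gene1 <TAB> ...``.

    Duplicate genes within a set are collapsed; empty sets are dropped with
    a logged warning.  A line with fewer than three fields is a format error.
    """
    sets: dict[str, set] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected >= 3 tab-separated fields")
            term, desc = parts[0], parts[1]
            if term in sets:
                raise FormatError(f"{path}: line {lineno}: duplicate term_id {term!r}")
            members = {g for g in parts[2:] if g}
            if not members:
                logger.warning("%s: line %d: term %r has no genes; dropped", path, lineno, term)
                continue
            sets[term] = members
            names[term] = desc
    return GeneSetCollection(sets=sets, names=names)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for term in sorted(collection.sets):
            genes = "\t".join(sorted(collection.sets[term]))
            fh.write(f"{term}\t{collection.names.get(term, term)}\t{genes}\n")


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------

@dataclass
class ExpressionCohort:
    """A samples x genes TPM matrix plus per-sample genotype/stage metadata.

    ``expression`` is indexed by sample id with gene ids as columns; all
    values are non-negative.  ``metadata`` is indexed by the same sample
    ids and carries boolean mutation flags (LKB1_mut, SMARCA4_mut,
    TP53_mut, KRAS_mut) and a ``stage`` column in {early, late, unknown}.
    """

    expression: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.expression.index.has_duplicates:
            raise ValidationError("duplicate sample_id in expression matrix")
        if self.expression.columns.has_duplicates:
            raise ValidationError("duplicate gene_id in expression matrix")
        missing = self.expression.index.difference(self.metadata.index)
        if len(missing):
            raise ValidationError(f"samples missing from metadata: {list(missing[:5])}")
        vals = self.expression.to_numpy(dtype=float)
        if np.isnan(vals).any() or (vals < 0).any():
            raise ValidationError("expression values must be finite and >= 0")
        bad_stage = set(self.metadata["stage"]) - set(VALID_STAGES)
        if bad_stage:
            raise ValidationError(f"unknown stage tokens: {sorted(bad_stage)}")
        # align metadata to the matrix's sample order
        self.metadata = self.metadata.loc[self.expression.index].copy()
        for flag in GENOTYPE_FLAGS:
            if flag in self.metadata.columns:
                self.metadata[flag] = self.metadata[flag].astype(bool)

    @property
    def samples(self) -> pd.Index:
        return self.expression.index

    @property
    def genes(self) -> pd.Index:
        return self.expression.columns

    def n_samples(self) -> int:
        return self.expression.shape[0]


def _parse_bool(series: pd.Series) -> pd.Series:
    mapping = {
        "true": True, "false": False, "1": True, "0": False,
        "yes": True, "no": False, "t": True, "f": False,
    }
    out = series.astype(str).str.strip().str.lower().map(mapping)
    if out.isna().any():
        bad = series[out.isna()].iloc[0]
        raise FormatError(f"cannot parse boolean flag value {bad!r}")
    return out.astype(bool)


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata TSV: sample_id, genotype flags, stage."""
    raw = _read_delimited(path)
    if "sample_id" not in raw.columns:
        raise FormatError(f"{path}: required column 'sample_id' not found")
    if "stage" not in raw.columns:
        raise FormatError(f"{path}: required column 'stage' not found")
    if raw["sample_id"].duplicated().any():
        dup = raw["sample_id"][raw["sample_id"].duplicated()].iloc[0]
        raise ValidationError(f"{path}: duplicate sample_id {dup!r}")
    meta = raw.set_index("sample_id")
    for flag in GENOTYPE_FLAGS:
        if flag in meta.columns:
            meta[flag] = _parse_bool(meta[flag])
        else:
            meta[flag] = False
            logger.info("%s: flag %s absent; defaulting to False", path, flag)
    meta["stage"] = meta["stage"].astype(str).str.strip().str.lower()
    bad = set(meta["stage"]) - set(VALID_STAGES)
    if bad:
        raise FormatError(f"{path}: unknown stage tokens {sorted(bad)}; expected {VALID_STAGES}")
    return meta[list(GENOTYPE_FLAGS) + ["stage"]]


def read_expression_cohort(matrix_path: str | Path, metadata_path: str | Path) -> ExpressionCohort:
    """Read an expression cohort from TSV or MatrixMarket plus metadata TSV.

    A TSV matrix may have samples in rows or genes in rows; orientation is
    auto-detected by overlap of its labels with the metadata sample ids.
    A ``.mtx`` matrix (genes x samples, per the common convention) requires
    sidecar files ``<path>.rows`` (gene ids) and ``<path>.cols`` (sample ids).
    """
    matrix_path = Path(matrix_path)
    meta = read_sample_metadata(metadata_path)

    if matrix_path.suffix == ".mtx":
        expr = _read_mtx_matrix(matrix_path)
    else:
        raw = pd.read_csv(matrix_path, sep="\t", index_col=0)
        row_overlap = raw.index.astype(str).isin(meta.index).mean()
        col_overlap = raw.columns.astype(str).isin(meta.index).mean()
        expr = raw if row_overlap >= col_overlap else raw.T
        expr.index = expr.index.astype(str)
        expr.columns = expr.columns.astype(str)

    missing = expr.index.difference(meta.index)
    if len(missing):
        raise ValidationError(
            f"{matrix_path}: samples missing from metadata: {sorted(missing)[:5]}"
        )
    return ExpressionCohort(expression=expr.astype(float), metadata=meta)


def _read_mtx_matrix(matrix_path: Path) -> pd.DataFrame:
    rows_path = matrix_path.with_suffix(".mtx.rows")
    cols_path = matrix_path.with_suffix(".mtx.cols")
    for sidecar in (rows_path, cols_path):
        if not sidecar.exists():
            raise FormatError(f"MTX sidecar file not found: {sidecar}")
    genes = rows_path.read_text(encoding="utf-8").split()
    samples = cols_path.read_text(encoding="utf-8").split()
    mat = np.asarray(mmread(str(matrix_path)).todense(), dtype=float)
    if mat.shape != (len(genes), len(samples)):
        raise FormatError(
            f"{matrix_path}: shape {mat.shape} does not match sidecars "
            f"({len(genes)} genes x {len(samples)} samples)"
        )
    # stored genes x samples; cohort convention is samples x genes
    return pd.DataFrame(mat.T, index=pd.Index(samples, name="sample_id"),
                        columns=pd.Index(genes, name="gene"))


def write_expression_cohort(
    cohort: ExpressionCohort,
    matrix_path: str | Path,
    metadata_path: str | Path,
) -> None:
    """Write a cohort as TSV (samples x genes) or MTX triplet, plus metadata TSV."""
    matrix_path = Path(matrix_path)
    expr = cohort.expression.sort_index(axis=0).sort_index(axis=1)
    if matrix_path.suffix == ".mtx":
        sparse = csr_matrix(expr.to_numpy().T)  # genes x samples on disk
        mmwrite(str(matrix_path), sparse)
        matrix_path.with_suffix(".mtx.rows").write_text(
            "\n".join(expr.columns) + "\n", encoding="utf-8")
        matrix_path.with_suffix(".mtx.cols").write_text(
            "\n".join(expr.index) + "\n", encoding="utf-8")
    else:
        expr.rename_axis("sample_id").to_csv(matrix_path, sep="\t", float_format="%.10g")
    meta = cohort.metadata.loc[expr.index].rename_axis("sample_id")
    meta.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# Interaction edge lists
# ---------------------------------------------------------------------------

@dataclass
class InteractionEdgeList:
    """Undirected interaction edges with integer confidence scores 0-1000."""

    edges: pd.DataFrame  # columns node_a, node_b, score

    def __post_init__(self) -> None:
        required = ["node_a", "node_b", "score"]
        missing = [c for c in required if c not in self.edges.columns]
        if missing:
            raise ValidationError(f"edge list missing columns: {missing}")
        scores = self.edges["score"].to_numpy()
        if ((scores < 0) | (scores > 1000)).any():
            raise ValidationError("edge confidence scores must lie in [0, 1000]")
        if (self.edges["node_a"] == self.edges["node_b"]).any():
            raise ValidationError("edge list contains self-loops")

    def __len__(self) -> int:
        return len(self.edges)

    def nodes(self) -> set:
        return set(self.edges["node_a"]) | set(self.edges["node_b"])


def read_edge_list(path: str | Path) -> InteractionEdgeList:
    """Read a STRING-export-style TSV edge list (node_a, node_b, score).

    Edges are undirected: pairs are canonicalized lexicographically and
    duplicates collapsed keeping the maximum score.  Self-loops are dropped
    with a logged count.
    """
    raw = _read_delimited(path)
    for col in ("node_a", "node_b", "score"):
        if col not in raw.columns:
            raise FormatError(f"{path}: required column {col!r} not found")
    score = pd.to_numeric(raw["score"], errors="coerce")
    if score.isna().any():
        row = int(np.flatnonzero(score.isna().to_numpy())[0]) + 2
        raise FormatError(f"{path}: non-numeric score at line {row}")
    a = raw["node_a"].astype(str)
    b = raw["node_b"].astype(str)
    loops = (a == b).sum()
    if loops:
        logger.warning("%s: dropped %d self-loop edge(s)", path, loops)
    edges = pd.DataFrame({
        "node_a": np.minimum(a, b),
        "node_b": np.maximum(a, b),
        "score": score.astype(int),
    })[a != b]
    edges = (edges.sort_values("score", ascending=False)
                  .drop_duplicates(["node_a", "node_b"])
                  .sort_values(["node_a", "node_b"])
                  .reset_index(drop=True))
    return InteractionEdgeList(edges=edges)


def write_edge_list(edges: InteractionEdgeList, path: str | Path) -> None:
    edges.edges.to_csv(path, sep="\t", index=False)
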