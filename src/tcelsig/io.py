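"""Expression matrices, sample annotations, gene sets, and group statistics.

The containers here are thin validated wrappers around pandas objects:

* :class:`ExpressionMatrix` — a genes x samples grid of log2 intensities.
* :class:`SampleAnnotation` — maps each sample to a class (T cell, non-T
  immune cell, healthy tissue, cell line, tumor) and a group label.
* :class:`GeneSignature` — an ordered, unique gene list with provenance.
* :class:`GroupMeanTable` — per-gene mean expression per sample group, plus
  the T-cell reference profile every downstream comparison uses.

All selection and scoring code consumes log2-scale values; the matrix carries
a ``scale`` tag so that linear-scale input cannot silently flow downstream.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SampleClass",
    "ExpressionMatrix",
    "SampleAnnotation",
    "GeneSignature",
    "GroupMeanTable",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_sets_gmt",
    "write_gene_sets_gmt",
    "signature_h",
    "trimmed_mean_normalize",
    "group_means",
    "write_run_metadata",
]


class SampleClass(str, Enum):
    """Sample classes the selection procedure distinguishes."""

    T_CELL = "T_CELL"
    IMMUNE_NON_T = "IMMUNE_NON_T"
    TISSUE = "TISSUE"
    CELL_LINE = "CELL_LINE"
    TUMOR = "TUMOR"


@dataclass
class ExpressionMatrix:
    """Genes x samples expression grid.

    Parameters
    ----------
    values
        DataFrame with gene symbols as the index and sample identifiers as
        columns. Every cell must be finite.
    scale
        Either ``"log2"`` (the working scale of all selection/scoring
        operations) or ``"linear"``.
    """

    values: pd.DataFrame
    scale: str = "log2"

    def __post_init__(self) -> None:
        if self.scale not in ("log2", "linear"):
            raise ValueError(f"scale must be 'log2' or 'linear', got {self.scale!r}")
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dups = sorted(idx[idx.duplicated()].unique().tolist())
            raise ValueError(f"duplicate gene identifiers: {dups}")
        if cols.has_duplicates:
            dups = sorted(cols[cols.duplicated()].unique().tolist())
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("expression values must be numeric")
        if not np.isfinite(arr).all():
            gi, si = np.argwhere(~np.isfinite(arr))[0]
            raise ValueError(
                f"non-finite expression value at gene {idx[gi]!r}, sample {cols[si]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def require_log2(self) -> None:
        if self.scale != "log2":
            raise ValueError("operation requires a log2-scale matrix")


@dataclass
class SampleAnnotation:
    """Per-sample class/group labels.

    ``table`` is indexed by sample_id with columns ``class`` (a
    :class:`SampleClass` value), ``group`` (free label: immune subset,
    tissue type, individual cell line, tumor type) and ``source_lineage``
    (parenchymal source or ``"immune"``; required for cell lines).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"class", "group"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        if self.table.index.has_duplicates:
            dups = sorted(self.table.index[self.table.index.duplicated()].unique())
            raise ValueError(f"duplicate sample_ids in annotation: {dups}")
        if "source_lineage" not in self.table.columns:
            self.table = self.table.assign(source_lineage="")
        self.table["source_lineage"] = self.table["source_lineage"].fillna("")
        self.table["class"] = self.table["class"].map(lambda c: SampleClass(c).value)
        bad = self.table[
            (self.table["class"] == SampleClass.CELL_LINE.value)
            & (self.table["source_lineage"].astype(str).str.len() == 0)
        ]
        if len(bad):
            raise ValueError(
                "CELL_LINE samples lack source_lineage: "
                f"{sorted(bad.index.tolist())}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def classes(self) -> set[SampleClass]:
        return {SampleClass(c) for c in self.table["class"].unique()}

    def samples_of_class(self, cls: SampleClass) -> pd.DataFrame:
        return self.table[self.table["class"] == cls.value]

    def restrict_to(self, sample_ids: Sequence[str]) -> "SampleAnnotation":
        missing = set(sample_ids) - set(self.table.index)
        if missing:
            raise ValueError(f"samples not annotated: {sorted(missing)}")
        return SampleAnnotation(self.table.loc[list(sample_ids)].copy())


@dataclass
class GeneSignature:
    """Ordered, unique gene list with a name and free-text provenance."""

    name: str
    genes: list[str]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"signature {self.name!r} has no genes")
        seen: set[str] = set()
        unique: list[str] = []
        for g in self.genes:
            if g in seen:
                warnings.warn(
                    f"signature {self.name!r}: duplicate gene {g!r} collapsed"
                )
                continue
            seen.add(g)
            unique.append(g)
        self.genes = unique

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class GroupMeanTable:
    """Per-gene mean log2 expression per sample group.

    Attributes
    ----------
    means
        genes x groups DataFrame of mean log2 expression; each column is the
        mean over the samples of that group only.
    group_class
        Maps each group label to its :class:`SampleClass`.
    t_ref
        Per-gene mean log2 expression over T-cell samples (the T-cell
        reference profile). ``None`` if the corpus has no T cells.
    source_lineage
        For CELL_LINE groups, the parenchymal source (or ``"immune"``).
    """

    means: pd.DataFrame
    group_class: dict[str, SampleClass]
    t_ref: pd.Series | None = None
    source_lineage: dict[str, str] = field(default_factory=dict)

    def groups_of_class(self, cls: SampleClass) -> list[str]:
        return [g for g, c in self.group_class.items() if c == cls]

    def means_of_class(self, cls: SampleClass) -> pd.DataFrame:
        return self.means[self.groups_of_class(cls)]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _sniff_sep(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_expression_matrix(
    path: str | Path,
    orientation: str = "genes_by_samples",
    scale: str = "log2",
) -> ExpressionMatrix:
    """Read a delimited genes x samples matrix (TSV by default, CSV by suffix).

    The first column holds gene symbols and the header row sample ids;
    ``orientation="samples_by_genes"`` reads the transposed layout.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), index_col=0)
    if orientation == "samples_by_genes":
        df = df.T
    elif orientation != "genes_by_samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    df.index.name = None
    df.columns.name = None
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        gi, si = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"non-numeric expression value {df.iat[gi, si]!r} at "
            f"gene {df.index[gi]!r}, sample {df.columns[si]!r}"
        )
    if numeric.isna().to_numpy().any():
        gi, si = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"missing expression value at gene {df.index[gi]!r}, "
            f"sample {df.columns[si]!r}"
        )
    return ExpressionMatrix(numeric.astype(float), scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    path = Path(path)
    out = matrix.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep=_sniff_sep(path), float_format="%.10g")


def read_annotation(path: str | Path) -> SampleAnnotation:
    """Read a sample annotation TSV (columns sample_id, class, group[, source_lineage])."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path), dtype=str).fillna("")
    if "sample_id" not in df.columns:
        raise ValueError("annotation file must have a 'sample_id' column")
    df = df.set_index("sample_id")
    return SampleAnnotation(df)


def write_annotation(annotation: SampleAnnotation, path: str | Path) -> None:
    out = annotation.table.copy()
    out.index.name = "sample_id"
    out.to_csv(Path(path), sep="\t")


def read_gene_sets_gmt(path: str | Path) -> list[GeneSignature]:
    """Read gene sets in GMT format (name, description, then genes, tab-separated)."""
    signatures: list[GeneSignature] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields; "
                    "GMT requires name, description and at least one gene"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            signatures.append(GeneSignature(name=name, genes=genes, provenance=desc))
    return signatures


def write_gene_sets_gmt(signatures: Iterable[GeneSignature], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sig in signatures:
            fh.write("\t".join([sig.name, sig.provenance or "-", *sig.genes]) + "\n")


def signature_h() -> GeneSignature:
    """The packaged 15-gene T-cell-restricted signature (signature-H)."""
    gmt = Path(__file__).parent / "data" / "signature_h.gmt"
    return read_gene_sets_gmt(gmt)[0]


# ---------------------------------------------------------------------------
# Normalization and group statistics
# ---------------------------------------------------------------------------

def trimmed_mean_normalize(
    matrix: ExpressionMatrix,
    target: float,
    trim_fraction: float = 0.05,
) -> ExpressionMatrix:
    """Shift a log2 matrix so its trimmed mean equals ``target``.

    The trimmed mean is the mean of all cell values after discarding the
    ``floor(trim_fraction * N)`` largest and smallest values (N = total cell
    count). The adjustment is a single additive shift in log2 space, i.e. a
    multiplicative rescale of linear intensities, so all within-matrix
    differences are preserved exactly. Idempotent for a fixed target.
    """
    matrix.require_log2()
    if not 0 <= trim_fraction < 0.5:
        raise ValueError("trim_fraction must be in [0, 0.5)")
    flat = np.sort(matrix.values.to_numpy().ravel())
    n = flat.size
    k = int(np.floor(trim_fraction * n))
    kept = flat[k : n - k] if k else flat
    if kept.size < 1:
        raise ValueError("trimming leaves no values to average")
    shift = target - float(kept.mean())
    return ExpressionMatrix(matrix.values + shift, scale="log2")


def group_means(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    pooling: str = "pooled_samples",
) -> GroupMeanTable:
    """Per-gene mean expression per sample group, plus the T-cell reference.

    ``pooling`` controls the T-cell reference ``t_ref``:

    * ``"pooled_samples"`` (default): mean over every T_CELL sample.
    * ``"mean_of_subgroup_means"``: unweighted mean of per-T-subset means,
      so small subsets weigh as much as large ones.
    """
    matrix.require_log2()
    if pooling not in ("pooled_samples", "mean_of_subgroup_means"):
        raise ValueError(f"unknown pooling {pooling!r}")
    ann = annotation.restrict_to(matrix.sample_ids)
    cols: dict[str, pd.Series] = {}
    group_class: dict[str, SampleClass] = {}
    lineage: dict[str, str] = {}
    for (cls, group), sub in ann.table.groupby(["class", "group"], sort=False):
        samples = list(sub.index)
        if not samples:
            raise ValueError(f"group {group!r} has zero samples")
        if group in group_class:
            raise ValueError(f"group label {group!r} appears in more than one class")
        cols[group] = matrix.values[samples].mean(axis=1)
        group_class[group] = SampleClass(cls)
        if cls == SampleClass.CELL_LINE.value:
            lineages = set(sub["source_lineage"])
            if len(lineages) > 1:
                raise ValueError(f"cell line {group!r} has mixed source lineages")
            lineage[group] = lineages.pop()
    means = pd.DataFrame(cols, index=matrix.values.index)

    t_groups = [g for g, c in group_class.items() if c == SampleClass.T_CELL]
    t_ref: pd.Series | None = None
    if t_groups:
        if pooling == "pooled_samples":
            t_samples = list(
                ann.table[ann.table["class"] == SampleClass.T_CELL.value].index
            )
            t_ref = matrix.values[t_samples].mean(axis=1)
        else:
            t_ref = means[t_groups].mean(axis=1)
        t_ref.name = "t_ref"
    return GroupMeanTable(
        means=means, group_class=group_class, t_ref=t_ref, source_lineage=lineage
    )


def write_run_metadata(
    path: str | Path,
    config: Mapping | None = None,
    seed: int | None = None,
) -> dict:
    """Write a small JSON run-metadata record (config hash, seed, version)."""
    from tcelsig import __version__

    payload = json.dumps(config or {}, sort_keys=True, default=str).encode()
    meta = {
        "version": __version__,
        "seed": seed,
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "config": config or {},
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2, default=str)
    return meta
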