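"""Core data containers and plain-text I/O.

Two containers travel through every stage of the toolkit:

``LabelledExpression``
    A normalized (log-scale) expression matrix of *n* samples by *m* genes,
    with a class label per sample and, optionally, a group label (e.g. the
    compound a sample was treated with) used for grouped cross-validation.

``PathwayCollection``
    An ordered mapping of pathway identifiers to gene sets, an optional
    source-database tag per pathway, and the gene *universe* — the genes
    eligible for membership (after restriction: the genes actually measured
    that map to at least one pathway).

File formats are deliberately minimal and text-based: expression matrices
and label tables are TSV, pathway collections are GMT (tab-separated:
name, source/description, member genes...). Gene identifiers are matched
as exact strings; no probe or symbol mapping is attempted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "LabelledExpression",
    "PathwayCollection",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "restrict_to_universe",
]


class DataError(ValueError):
    """Raised for malformed input files or inconsistent containers."""


@dataclass
class LabelledExpression:
    """Samples × genes expression matrix with per-sample labels.

    Parameters
    ----------
    values : ndarray, shape (n_samples, n_genes)
        Normalized expression, finite values only. Samples are rows.
    sample_ids, gene_ids : sequences of unique strings.
    class_labels : sequence of length n_samples
        Categorical outcome with at least two levels.
    group_labels : sequence of length n_samples, optional
        Grouping factor for leave-one-group-out cross-validation. Every
        group must map to exactly one class level.
    """

    values: np.ndarray
    sample_ids: list[str]
    gene_ids: list[str]
    class_labels: np.ndarray
    group_labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.class_labels = np.asarray(self.class_labels, dtype=object)
        if self.group_labels is not None:
            self.group_labels = np.asarray(self.group_labels, dtype=object)
        if self.values.ndim != 2:
            raise DataError("expression values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n:
            raise DataError(f"{len(self.sample_ids)} sample ids for {n} rows")
        if len(self.gene_ids) != m:
            raise DataError(f"{len(self.gene_ids)} gene ids for {m} columns")
        if len(set(self.sample_ids)) != n:
            raise DataError("sample ids are not unique")
        if len(set(self.gene_ids)) != m:
            raise DataError("gene ids are not unique")
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression matrix contains missing/non-finite values")
        if len(self.class_labels) != n:
            raise DataError("class_labels length does not match sample count")
        if len(np.unique(self.class_labels)) < 2:
            raise DataError("need at least two class levels")
        if self.group_labels is not None:
            if len(self.group_labels) != n:
                raise DataError("group_labels length does not match sample count")
            # a group is nested within a class: one class level per group
            tab = pd.crosstab(self.group_labels, self.class_labels)
            if ((tab > 0).sum(axis=1) > 1).any():
                bad = tab.index[(tab > 0).sum(axis=1) > 1].tolist()
                raise DataError(f"groups span multiple classes: {bad}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    @property
    def classes(self) -> np.ndarray:
        """Sorted unique class levels."""
        return np.unique(self.class_labels)

    def gene_index(self) -> dict[str, int]:
        return {g: j for j, g in enumerate(self.gene_ids)}

    def with_values(self, values: np.ndarray) -> "LabelledExpression":
        """Copy carrying new expression values with identical labels/ids."""
        return replace(self, values=np.asarray(values, dtype=float))

    def subset_genes(self, genes: list[str]) -> "LabelledExpression":
        idx = self.gene_index()
        cols = [idx[g] for g in genes]
        return replace(self, values=self.values[:, cols], gene_ids=list(genes))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.gene_ids)


@dataclass
class PathwayCollection:
    """Ordered pathway → gene-set mapping over a gene universe."""

    pathways: dict[str, frozenset]
    source_db: dict[str, str] = field(default_factory=dict)
    universe: frozenset = frozenset()

    def __post_init__(self) -> None:
        self.pathways = {str(k): frozenset(map(str, v)) for k, v in self.pathways.items()}
        if len(self.pathways) < 1:
            raise DataError("collection must contain at least one pathway")
        for name, genes in self.pathways.items():
            if not genes:
                raise DataError(f"pathway {name!r} is empty")
        if not self.universe:
            self.universe = frozenset().union(*self.pathways.values())
        else:
            self.universe = frozenset(map(str, self.universe))
            for name, genes in self.pathways.items():
                if not genes <= self.universe:
                    raise DataError(f"pathway {name!r} has members outside the universe")

    @property
    def n_pathways(self) -> int:
        return len(self.pathways)

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.pathways.items()}

    def subset(self, names: list[str]) -> "PathwayCollection":
        pw = {n: self.pathways[n] for n in names}
        src = {n: self.source_db[n] for n in names if n in self.source_db}
        return PathwayCollection(pathways=pw, source_db=src)

    def by_source(self) -> dict[str, "PathwayCollection"]:
        """Split the collection into one sub-collection per source tag."""
        if not self.source_db:
            raise DataError("collection has no source-database tags")
        out: dict[str, PathwayCollection] = {}
        for tag in dict.fromkeys(self.source_db.values()):
            names = [n for n in self.names if self.source_db.get(n) == tag]
            out[tag] = self.subset(names)
        return out


def read_gmt(path: str | Path, source_override: str | None = None) -> PathwayCollection:
    """Read a GMT file: one pathway per line, ``name<TAB>source<TAB>genes...``.

    The second field is stored as the pathway's source-database tag
    (ConsensusPathDB convention); pass ``source_override`` to replace it.
    Duplicate gene entries within a line are deduplicated; a duplicate
    pathway name is an error.
    """
    pathways: dict[str, frozenset] = {}
    source: dict[str, str] = {}
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise DataError(
                    f"{path}: line {lineno}: expected at least 3 tab-separated "
                    f"fields (name, source, genes...), got {len(fields)}"
                )
            name, desc, *genes = fields
            genes = [g for g in genes if g]
            if name in pathways:
                raise DataError(f"{path}: line {lineno}: duplicate pathway id {name!r}")
            if not genes:
                raise DataError(f"{path}: line {lineno}: pathway {name!r} has no genes")
            pathways[name] = frozenset(genes)
            source[name] = source_override if source_override is not None else desc
    if not pathways:
        raise DataError(f"{path}: no pathways")
    return PathwayCollection(pathways=pathways, source_db=source)


def write_gmt(coll: PathwayCollection, path: str | Path) -> None:
    """Write a collection as GMT; member genes are written sorted."""
    with open(path, "w") as fh:
        for name in coll.names:
            src = coll.source_db.get(name, "na")
            genes = "\t".join(sorted(coll.pathways[name]))
            fh.write(f"{name}\t{src}\t{genes}\n")


def read_expression(matrix_path: str | Path, labels_path: str | Path) -> LabelledExpression:
    """Read an expression TSV (samples in rows, header row of gene ids,
    first column sample ids) together with a 2–3 column labels TSV
    (``sample_id  class  [group]``, with a header row).

    Samples are aligned by id between the two files; a sample present in
    the matrix but absent from the labels file is an error.
    """
    raw = pd.read_csv(matrix_path, sep="\t", index_col=0, dtype=str)
    if raw.index.has_duplicates:
        raise DataError(f"{matrix_path}: duplicate sample ids")
    numeric = raw.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        bad = np.argwhere(numeric.isna().to_numpy())
        i, j = bad[0]
        raise DataError(
            f"{matrix_path}: non-numeric value {raw.iat[i, j]!r} at "
            f"sample {raw.index[i]!r}, gene {raw.columns[j]!r}"
        )
    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    if labels.shape[1] not in (2, 3):
        raise DataError(f"{labels_path}: expected 2 or 3 columns, got {labels.shape[1]}")
    labels = labels.set_index(labels.columns[0])
    missing = [s for s in numeric.index if s not in labels.index]
    if missing:
        raise DataError(f"{labels_path}: samples without labels: {missing}")
    labels = labels.loc[numeric.index]
    groups = labels.iloc[:, 1].to_numpy() if labels.shape[1] >= 2 else None
    # numpy's string->float conversion is correctly rounded (bit-exact
    # round trips); pandas' numeric parser can be one ulp off
    return LabelledExpression(
        values=raw.to_numpy(dtype=str).astype(float),
        sample_ids=list(numeric.index),
        gene_ids=list(numeric.columns),
        class_labels=labels.iloc[:, 0].to_numpy(),
        group_labels=groups,
    )


def write_expression(expr: LabelledExpression, matrix_path: str | Path,
                     labels_path: str | Path) -> None:
    """Write the matrix and labels as TSV in the layout ``read_expression`` reads."""
    expr.to_frame().to_csv(matrix_path, sep="\t", index_label="sample_id",
                           float_format="%.17g")
    lab = pd.DataFrame({"sample_id": expr.sample_ids, "class": expr.class_labels})
    if expr.group_labels is not None:
        lab["group"] = expr.group_labels
    lab.to_csv(labels_path, sep="\t", index=False)


def restrict_to_universe(expr: LabelledExpression, coll: PathwayCollection,
                         min_size: int = 2) -> tuple[LabelledExpression, PathwayCollection]:
    """Mutually restrict an expression matrix and a pathway collection.

    Genes not belonging to any pathway are dropped from the matrix; pathway
    members not measured in the matrix are dropped from the pathways; pathways
    left with fewer than ``min_size`` genes are dropped; the universe is reset
    to the retained genes. Idempotent. ``min_size`` defaults to 2 (a one-gene
    pathway score is a copy of that gene).
    """
    if min_size < 2:
        raise DataError("min_size must be >= 2")
    measured = set(expr.gene_ids)
    kept_pathways: dict[str, frozenset] = {}
    for name, genes in coll.pathways.items():
        retained = genes & measured
        if len(retained) >= min_size:
            kept_pathways[name] = frozenset(retained)
    if not kept_pathways:
        raise DataError("restriction leaves zero pathways")
    universe = frozenset().union(*kept_pathways.values())
    kept_genes = [g for g in expr.gene_ids if g in universe]
    if not kept_genes:
        raise DataError("restriction leaves zero genes")
    new_coll = PathwayCollection(
        pathways=kept_pathways,
        source_db={n: coll.source_db[n] for n in kept_pathways if n in coll.source_db},
        universe=universe,
    )
    return expr.subset_genes(kept_genes), new_coll
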