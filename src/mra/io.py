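"""Readers/writers for on-disk formats and normalization utilities.

Expression matrices are genes x samples tables (TSV/CSV, first column = gene
identifiers, header = sample identifiers). Gene sets use the GMT dialect.
Networks are 3-5 column TSV (regulator, target, weight[, mode[, confidence]]).
Phenotype labels are 2-column TSV (sample_id, label).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger("mra")

HIGH, MEDIUM, LOW = "HIGH", "MEDIUM", "LOW"
VALID_CLASSES = {HIGH, MEDIUM, LOW}
COHORT_GROUPS = {"ENABLED", "DISABLED", "NEUTRAL", "UNSPECIFIED"}


class MraError(ValueError):
    """Base error for malformed inputs."""


@dataclass
class ExpressionMatrix:
    """Genes x samples real-valued matrix (log2 expression units).

    ``data`` is a pandas DataFrame indexed by gene identifier with sample
    identifiers as columns. Identifiers must be unique; values finite.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        idx, cols = self.data.index, self.data.columns
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].unique().tolist()
            raise MraError(f"duplicate gene identifiers: {dups[:5]}")
        if cols.has_duplicates:
            dups = cols[cols.duplicated()].unique().tolist()
            raise MraError(f"duplicate sample identifiers: {dups[:5]}")
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise MraError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def zero_variance_genes(self) -> list[str]:
        v = self.data.to_numpy()
        flag = v.std(axis=1) == 0.0
        return [g for g, f in zip(self.data.index, flag) if f]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data[list(sample_ids)])


@dataclass
class PhenotypeLabels:
    """Per-sample class labels (HIGH/MEDIUM/LOW) for one cohort."""

    labels: pd.Series  # sample_id -> class
    cohort_id: str = "cohort"
    cohort_group: str = "UNSPECIFIED"

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - VALID_CLASSES
        if bad:
            raise MraError(f"invalid class labels: {sorted(bad)}")
        if self.cohort_group not in COHORT_GROUPS:
            raise MraError(f"invalid cohort group {self.cohort_group!r}")
        if self.labels.index.has_duplicates:
            raise MraError("duplicate sample identifiers in labels")

    def samples_of(self, cls: str) -> list[str]:
        return list(self.labels.index[self.labels == cls])

    @property
    def high_samples(self) -> list[str]:
        return self.samples_of(HIGH)

    @property
    def low_samples(self) -> list[str]:
        return self.samples_of(LOW)

    def validate_against(self, m: ExpressionMatrix) -> None:
        missing = set(self.labels.index) - set(m.sample_ids)
        if missing:
            raise MraError(f"labeled samples missing from matrix: {sorted(missing)[:5]}")

    def require_two_classes(self) -> None:
        if not self.high_samples or not self.low_samples:
            raise MraError("need at least one HIGH and one LOW sample")


@dataclass
class GeneSetCollection:
    """Named gene sets with optional descriptions (GMT-style)."""

    sets: dict[str, set[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, s in self.sets.items():
            if not s:
                raise MraError(f"empty gene set {name!r}")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_expression_matrix(path, delimiter: str = "\t", transpose: bool = False) -> ExpressionMatrix:
    """Read a genes x samples table; duplicate gene rows are mean-collapsed.

    Raises on non-numeric cells (naming row and column) and on duplicate
    sample headers.
    """
    # pandas mangles duplicate headers, so check the raw header line first
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split(delimiter)[1:]
    if not transpose and len(header) != len(set(header)):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise MraError(f"duplicate sample header(s): {dups}")
    df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, keep_default_na=False)
    if transpose:
        df = df.T
    if df.columns.has_duplicates:
        dups = df.columns[df.columns.duplicated()].unique().tolist()
        raise MraError(f"duplicate sample header(s): {dups}")
    try:
        num = df.apply(pd.to_numeric, errors="raise")
    except (ValueError, TypeError):
        for gene, row in df.iterrows():
            for sample, cell in row.items():
                try:
                    float(cell)
                except ValueError:
                    raise MraError(
                        f"non-numeric cell {cell!r} at gene {gene!r}, sample {sample!r}"
                    ) from None
        raise
    if not np.isfinite(num.to_numpy(dtype=float)).all():
        bad = np.argwhere(~np.isfinite(num.to_numpy(dtype=float)))[0]
        raise MraError(
            f"non-finite cell at gene {num.index[bad[0]]!r}, sample {num.columns[bad[1]]!r}"
        )
    if num.index.has_duplicates:
        dup_names = num.index[num.index.duplicated()].unique().tolist()
        warnings.warn(f"collapsing {len(dup_names)} duplicate gene row(s) by mean", stacklevel=2)
        num = num.groupby(level=0, sort=False).mean()
    return ExpressionMatrix(num.astype(float))


def write_expression_matrix(m: ExpressionMatrix, path, delimiter: str = "\t") -> None:
    m.data.to_csv(path, sep=delimiter, index_label="gene")


def quantile_normalize_log2(m: ExpressionMatrix, already_log: bool = True) -> ExpressionMatrix:
    """Quantile-normalize columns to a common distribution; optional log2(x+1).

    The reference distribution is the row-rank-wise mean of the sorted columns.
    Ties within a column receive the mean of the reference values they span,
    which makes the transform idempotent. When ``already_log`` is false the
    raw values must be non-negative and log2(x+1) is applied afterwards.
    """
    x = m.data.to_numpy(dtype=float)
    if not already_log and (x < 0).any():
        raise MraError("negative raw value with already_log=False")
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    for j in range(x.shape[1]):
        col = x[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # average the reference values over tied blocks so ties share one value
        sorted_vals = col[order]
        i = 0
        while i < len(sorted_vals):
            k = i
            while k + 1 < len(sorted_vals) and sorted_vals[k + 1] == sorted_vals[i]:
                k += 1
            if k > i:
                assigned[order[i : k + 1]] = ref[i : k + 1].mean()
            i = k + 1
        out[:, j] = assigned
    if not already_log:
        out = np.log2(out + 1.0)
    return ExpressionMatrix(pd.DataFrame(out, index=m.data.index, columns=m.data.columns))


def read_labels(path, cohort_id: str = "cohort", cohort_group: str = "UNSPECIFIED") -> PhenotypeLabels:
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise MraError("label file needs two columns: sample_id, label")
    ser = pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values)
    return PhenotypeLabels(ser, cohort_id=cohort_id, cohort_group=cohort_group)


def write_labels(labels: PhenotypeLabels, path) -> None:
    pd.DataFrame({"sample_id": labels.labels.index, "label": labels.labels.values}).to_csv(
        path, sep="\t", index=False
    )


def read_gmt(path) -> GeneSetCollection:
    sets: dict[str, set[str]] = {}
    desc: dict[str, str] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MraError(f"GMT line {ln}: fewer than 3 tab-separated fields")
            name = fields[0]
            if name in sets:
                raise MraError(f"GMT line {ln}: duplicate set name {name!r}")
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise MraError(f"GMT line {ln}: set {name!r} has no genes")
            sets[name] = genes
            desc[name] = fields[1]
    if not sets:
        raise MraError("empty GMT file")
    return GeneSetCollection(sets, desc)


def write_gmt(c: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, genes in c.sets.items():
            d = c.descriptions.get(name, "")
            fh.write("\t".join([name, d, *sorted(genes)]) + "\n")


NETWORK_COLUMNS = ["regulator", "target", "weight", "mode", "confidence"]


def read_network_edges(path) -> pd.DataFrame:
    """Read an edge table: regulator, target, weight [, mode, confidence]."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 3:
        raise MraError("network file needs >= 3 columns (regulator, target, weight)")
    df.columns = NETWORK_COLUMNS[: df.shape[1]]
    df["regulator"] = df["regulator"].astype(str)
    df["target"] = df["target"].astype(str)
    w = df["weight"].astype(float)
    if not np.isfinite(w).all() or (w <= 0).any():
        raise MraError("network weights must be finite and > 0")
    self_loops = df["regulator"] == df["target"]
    if self_loops.any():
        bad = df.loc[self_loops, "regulator"].iloc[0]
        raise MraError(f"self-loop edge on {bad!r}")
    if "mode" in df.columns and not df["mode"].isin([-1, 1]).all():
        raise MraError("mode column must be -1 or +1")
    return df


def write_network_edges(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
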