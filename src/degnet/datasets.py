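"""Expression-matrix containers and per-dataset preprocessing.

One study is held as an :class:`ExpressionDataset`: a genes × samples matrix of
log2-scale intensities with a case/control label per sample and a disease-group
tag (``LC`` lung cancer, ``BC`` breast cancer, ``LK`` leukemia, or ``OTHER``).
Matrices travel as TSV: first row sample ids, first column feature ids.

Preprocessing offered here is deliberately generic — probe-to-gene collapsing,
quantile normalization across samples within one dataset, and an optional
variance filter. No cross-dataset normalization is done: downstream consensus
compares per-dataset *calls*, never values across studies.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DISEASE_GROUPS = ("LC", "BC", "LK", "OTHER")
CLASSES = ("case", "control")

#: Values treated as missing when parsing expression TSVs.
NA_TOKENS = frozenset({"", "NA", "N/A", "NaN", "nan", "null", "NULL"})

#: log2 intensities above this are suspicious (matrix likely on linear scale).
LOG2_SCALE_GUARD = 30.0


class ExpressionParseError(ValueError):
    """A cell of an expression TSV could not be parsed as a number."""


class ValidationError(ValueError):
    """An ExpressionDataset invariant is violated."""


@dataclass
class ExpressionDataset:
    """One study's log2 expression matrix with sample labels.

    Parameters
    ----------
    dataset_id : str
        Study identifier (e.g. an accession).
    disease_group : str
        One of ``LC``, ``BC``, ``LK``, ``OTHER``.
    values : pandas.DataFrame
        Genes × samples, finite floats, unique row and column labels.
    sample_class : pandas.Series
        ``case`` / ``control`` per sample, indexed like ``values.columns``.
    """

    dataset_id: str
    disease_group: str
    values: pd.DataFrame
    sample_class: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if self.disease_group not in DISEASE_GROUPS:
            raise ValidationError(
                f"{self.dataset_id}: disease_group {self.disease_group!r} "
                f"not one of {DISEASE_GROUPS}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValidationError(f"{self.dataset_id}: duplicate gene ids {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValidationError(f"{self.dataset_id}: duplicate sample ids {dups[:5]}")
        missing = [s for s in self.values.columns if s not in self.sample_class.index]
        if missing:
            raise ValidationError(
                f"{self.dataset_id}: samples without class label: {missing[:5]}"
            )
        self.sample_class = self.sample_class.reindex(self.values.columns)
        bad = set(self.sample_class.unique()) - set(CLASSES)
        if bad:
            raise ValidationError(f"{self.dataset_id}: unknown class labels {bad}")
        arr = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"{self.dataset_id}: non-finite expression values")
        for cls in CLASSES:
            n = int((self.sample_class == cls).sum())
            if n < 2:
                raise ValidationError(
                    f"{self.dataset_id}: needs >=2 {cls} samples, found {n}"
                )
        if arr.size and np.nanmax(arr) > LOG2_SCALE_GUARD:
            logger.warning(
                "%s: max value %.3g exceeds %g — matrix may be on linear, "
                "not log2, scale (no transform applied)",
                self.dataset_id, float(np.nanmax(arr)), LOG2_SCALE_GUARD,
            )

    # -- convenience accessors -------------------------------------------------

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def case_ids(self) -> list[str]:
        return list(self.sample_class.index[self.sample_class == "case"])

    @property
    def control_ids(self) -> list[str]:
        return list(self.sample_class.index[self.sample_class == "control"])

    def case_matrix(self) -> np.ndarray:
        return self.values[self.case_ids].to_numpy(dtype=float)

    def control_matrix(self) -> np.ndarray:
        return self.values[self.control_ids].to_numpy(dtype=float)

    def with_values(self, values: pd.DataFrame) -> "ExpressionDataset":
        """Same metadata, new matrix (columns must be a subset of the old)."""
        return ExpressionDataset(
            dataset_id=self.dataset_id,
            disease_group=self.disease_group,
            values=values,
            sample_class=self.sample_class.loc[list(values.columns)],
        )


# -- TSV I/O -------------------------------------------------------------------

def read_class_labels(path: str | Path) -> pd.Series:
    """Read a two-column TSV ``sample_id<TAB>class`` into a Series."""
    df = pd.read_csv(path, sep="\t", header=None, names=["sample_id", "class"],
                     dtype=str, comment="#")
    if df["sample_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicate sample ids in label file")
    return pd.Series(df["class"].values, index=df["sample_id"].values)


def read_expression_matrix(
    path: str | Path,
    dataset_id: str,
    disease_group: str,
    class_labels: Mapping[str, str] | pd.Series | str | Path,
) -> ExpressionDataset:
    """Read, parse and validate one expression TSV.

    Rows containing any missing value (``NA`` and friends) are dropped and the
    drop count logged; any other non-numeric cell raises
    :class:`ExpressionParseError` naming the offending row and column.
    """
    if isinstance(class_labels, (str, Path)):
        class_labels = read_class_labels(class_labels)
    labels = pd.Series(dict(class_labels)) if not isinstance(class_labels, pd.Series) \
        else class_labels

    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dups = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"{path}: duplicate sample columns {dups[:5]}")

    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    parsed = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        stripped = raw[col].str.strip()
        numeric = pd.to_numeric(stripped, errors="coerce")
        bad = numeric.isna() & ~stripped.isin(NA_TOKENS)
        if bad.any():
            row = bad.idxmax()
            raise ExpressionParseError(
                f"{path}: cell ({row!r}, {col!r}) = {stripped[row]!r} is not numeric"
            )
        parsed[col] = numeric.to_numpy(dtype=float)
    keep = np.isfinite(parsed.to_numpy(dtype=float)).all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("%s: dropped %d rows with missing values", dataset_id, n_dropped)
    return ExpressionDataset(
        dataset_id=dataset_id,
        disease_group=disease_group,
        values=parsed.loc[keep],
        sample_class=labels,
    )


def write_expression_matrix(ds: ExpressionDataset, path: str | Path) -> None:
    """Write the matrix back in the same TSV dialect (full float precision)."""
    ds.values.to_csv(path, sep="\t", index_label="gene_id", float_format="%.12g")


def write_class_labels(ds: ExpressionDataset, path: str | Path) -> None:
    ds.sample_class.to_csv(path, sep="\t", header=False)


def read_probe_map(path: str | Path) -> dict[str, str]:
    """Read a two-column TSV ``probe_id<TAB>gene_id`` (many probes per gene)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["probe_id", "gene_id"],
                     dtype=str, comment="#")
    mapping = {}
    for probe, gene in zip(df["probe_id"], df["gene_id"]):
        if not gene or (isinstance(gene, float) and math.isnan(gene)):
            raise ValidationError(f"{path}: probe {probe!r} maps to empty gene id")
        mapping[probe] = gene
    return mapping


# -- preprocessing -------------------------------------------------------------

def collapse_probes(ds: ExpressionDataset, probe_map: Mapping[str, str]) -> ExpressionDataset:
    """Collapse probe-level rows to one row per gene.

    For genes measured by several probes the probe with the highest variance
    across samples is kept — this preserves dynamic range for the downstream
    correlation networks. Unmapped probes are dropped (logged).
    """
    for probe, gene in probe_map.items():
        if not gene:
            raise ValidationError(f"probe {probe!r} maps to empty gene id")
    mapped = [p for p in ds.gene_ids if p in probe_map]
    n_unmapped = ds.n_genes - len(mapped)
    if n_unmapped:
        logger.info("%s: dropped %d unmapped probes", ds.dataset_id, n_unmapped)
    if not mapped:
        raise ValidationError(f"{ds.dataset_id}: no probes left after mapping")

    sub = ds.values.loc[mapped]
    variances = sub.var(axis=1, ddof=1)
    genes = pd.Series([probe_map[p] for p in mapped], index=sub.index)
    # stable: first-seen probe wins variance ties, gene order = first appearance
    best_probe: dict[str, str] = {}
    for probe in mapped:
        g = genes[probe]
        if g not in best_probe or variances[probe] > variances[best_probe[g]]:
            best_probe[g] = probe
    out = sub.loc[list(best_probe.values())]
    out.index = pd.Index(list(best_probe.keys()), name="gene_id")
    return ds.with_values(out)


def quantile_normalize(ds: ExpressionDataset) -> ExpressionDataset:
    """Quantile-normalize columns so every sample shares one distribution.

    Each column's sorted values are replaced by the across-sample mean of the
    per-column sorted values; ties within a column receive the mean of the
    quantile values their rank range spans.
    """
    if ds.n_samples < 2:
        return ds
    X = ds.values.to_numpy(dtype=float)
    ref = np.sort(X, axis=0).mean(axis=1)  # mean quantile profile
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="stable")
        sorted_col = col[order]
        assigned = np.empty_like(sorted_col)
        i = 0
        n = len(sorted_col)
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            assigned[i:k + 1] = ref[i:k + 1].mean()  # tie group spans ranks i..k
            i = k + 1
        out[order, j] = assigned
    return ds.with_values(pd.DataFrame(out, index=ds.values.index,
                                       columns=ds.values.columns))


def variance_filter(ds: ExpressionDataset, keep_fraction: float = 1.0) -> ExpressionDataset:
    """Keep the ``ceil(keep_fraction * n_genes)`` most variable genes.

    Gene order of the retained rows is preserved. ``keep_fraction=1`` is the
    identity (the default: filtering off keeps tests deterministic).
    """
    if not (0.0 < keep_fraction <= 1.0):
        raise ValidationError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    if keep_fraction == 1.0:
        return ds
    n_keep = math.ceil(keep_fraction * ds.n_genes)
    variances = ds.values.var(axis=1, ddof=1).to_numpy()
    # highest-variance indices; stable sort so ties resolve to earlier rows
    ranked = np.argsort(-variances, kind="stable")[:n_keep]
    keep_idx = np.sort(ranked)
    return ds.with_values(ds.values.iloc[keep_idx])
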