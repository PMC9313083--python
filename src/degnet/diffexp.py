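"""Per-dataset differential expression: fold change, Welch t, BH, signed calls.

The effect scale is the log2 fold change, ``mean(case) − mean(control)`` on the
already-log2 matrix. Significance uses the Welch unequal-variance t test with
Satterthwaite degrees of freedom and step-up Benjamini–Hochberg correction over
the genes of one dataset. A gene is called ``up`` if ``fdr <= fdr_max`` and
``log2fc >= min_abs_log2fc``, ``down`` for the mirror condition, else ``ns``;
thresholds are inclusive.

Degenerate genes (zero variance in both arms) get ``t=0, p=1`` when the means
agree and ``p=0`` with a ``degenerate`` flag when they differ — a zero-noise
difference is evidence, but not of a kind the t test can quantify.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ExpressionDataset

DEG_COLUMNS = ["log2fc", "t_stat", "p_value", "fdr", "direction", "degenerate"]


@dataclass
class DEGTable:
    """Signed differential-expression calls for one dataset.

    ``records`` is a DataFrame indexed by gene_id with columns ``log2fc``,
    ``t_stat``, ``p_value``, ``fdr``, ``direction`` (up/down/ns) and
    ``degenerate`` (bool).
    """

    dataset_id: str
    disease_group: str
    records: pd.DataFrame = field(repr=False)

    @property
    def n_up(self) -> int:
        return int((self.records["direction"] == "up").sum())

    @property
    def n_down(self) -> int:
        return int((self.records["direction"] == "down").sum())

    def write(self, path) -> None:
        out = self.records.copy()
        for col in ("log2fc", "t_stat", "p_value", "fdr"):
            out[col] = out[col].map(lambda v: float(f"{v:.10g}"))
        out.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")

    @classmethod
    def read(cls, path, dataset_id: str, disease_group: str) -> "DEGTable":
        df = pd.read_csv(path, sep="\t", index_col="gene_id")
        if "degenerate" not in df.columns:
            df["degenerate"] = False
        return cls(dataset_id, disease_group, df)


def log2_fold_change(case_values, control_values) -> float:
    """mean(case) − mean(control) on the log2 scale."""
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size == 0 or control_values.size == 0:
        raise ValueError("log2_fold_change: both groups must be non-empty")
    return float(case_values.mean() - control_values.mean())


def welch_t(case_values, control_values) -> tuple[float, float, bool]:
    """Welch t statistic and two-sided p for one gene.

    Returns ``(t, p, degenerate)``; see module docstring for the zero-variance
    conventions.
    """
    case_values = np.asarray(case_values, dtype=float)
    control_values = np.asarray(control_values, dtype=float)
    if case_values.size < 2 or control_values.size < 2:
        raise ValueError("welch_t: need >=2 values per group")
    v1, v2 = case_values.var(ddof=1), control_values.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if case_values.mean() == control_values.mean():
            return 0.0, 1.0, False
        return np.inf, 0.0, True
    t, p = stats.ttest_ind(case_values, control_values, equal_var=False)
    return float(t), float(p), False


def welch_t_matrix(case: np.ndarray, control: np.ndarray):
    """Row-wise Welch t over genes × samples blocks.

    Returns arrays ``(t, p, degenerate)``; degenerate rows follow the scalar
    conventions.
    """
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    if case.shape[1] < 2 or control.shape[1] < 2:
        raise ValueError("welch_t_matrix: need >=2 samples per arm")
    v1 = case.var(axis=1, ddof=1)
    v2 = control.var(axis=1, ddof=1)
    both_zero = (v1 == 0.0) & (v2 == 0.0)
    with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
        # near-constant rows trip scipy's precision warning; those rows are
        # rewritten by the degenerate conventions below
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(case, control, axis=1, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    diff = case.mean(axis=1) - control.mean(axis=1)
    degen = both_zero & (diff != 0.0)
    t[both_zero & (diff == 0.0)] = 0.0
    p[both_zero & (diff == 0.0)] = 1.0
    t[degen] = np.where(diff[degen] > 0, np.inf, -np.inf)
    p[degen] = 0.0
    return t, p, degen


def bh_adjust(p_values) -> np.ndarray:
    """Step-up Benjamini–Hochberg adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("bh_adjust: p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_degs(records: pd.DataFrame, fdr_max: float = 0.05,
              min_abs_log2fc: float = 1.0) -> pd.DataFrame:
    """Attach the signed ``direction`` column (inclusive thresholds)."""
    if not (0.0 < fdr_max <= 1.0):
        raise ValueError(f"fdr_max must be in (0, 1], got {fdr_max}")
    if min_abs_log2fc < 0:
        raise ValueError(f"min_abs_log2fc must be >= 0, got {min_abs_log2fc}")
    out = records.copy()
    sig = out["fdr"] <= fdr_max
    out["direction"] = "ns"
    # the extra strict-sign clause only matters at min_abs_log2fc == 0
    out.loc[sig & (out["log2fc"] >= min_abs_log2fc) & (out["log2fc"] > 0),
            "direction"] = "up"
    out.loc[sig & (out["log2fc"] <= -min_abs_log2fc) & (out["log2fc"] < 0),
            "direction"] = "down"
    return out


def differential_expression(ds: ExpressionDataset, fdr_max: float = 0.05,
                            min_abs_log2fc: float = 1.0) -> DEGTable:
    """Full per-dataset DE: fold change, Welch t, BH, signed call per gene."""
    case = ds.case_matrix()
    control = ds.control_matrix()
    t, p, degen = welch_t_matrix(case, control)
    records = pd.DataFrame(
        {
            "log2fc": case.mean(axis=1) - control.mean(axis=1),
            "t_stat": t,
            "p_value": p,
            "fdr": bh_adjust(p),
            "degenerate": degen,
        },
        index=pd.Index(ds.gene_ids, name="gene_id"),
    )
    records = call_degs(records, fdr_max=fdr_max, min_abs_log2fc=min_abs_log2fc)
    return DEGTable(ds.dataset_id, ds.disease_group, records[DEG_COLUMNS])
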