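"""Direction-consistent consensus calling of winning genes across datasets.

The meta-analysis layer is pure vote counting: for every gene and disease
group (LC lung cancer, BC breast cancer, LK leukemia) we count in how many of
the group's datasets the gene was called up and in how many down. A gene is a

* **common winner** when its majority LC direction is called in at least
  ``common_lc_min`` LC datasets (default 8 of 10) *and* at least ``oc_min``
  (default 1) other-cancer datasets show it deregulated — in the same sense by
  default;
* **unique-LC winner** when the majority LC direction reaches ``unique_lc_min``
  LC datasets (default 7 of 10) and *no* other-cancer dataset shows it
  deregulated at all.

Ties between the up and down LC counts give direction ``mixed`` and can never
win. The group-presence pattern (which of LC/BC/LK have a nonzero deregulated
count, any direction) drives the descriptive categorization of winners.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .diffexp import DEGTable

logger = logging.getLogger(__name__)

GROUPS = ("LC", "BC", "LK")
GROUP_PATTERNS = ("LC_BC_LK", "LC_BC", "LC_LK", "LC_only", "none")

#: columns of a vote-tally frame, per disease group
TALLY_COLUMNS = [f"{kind}_{g}" for g in GROUPS for kind in ("up", "down", "n")]


@dataclass(frozen=True)
class ConsensusThresholds:
    """Winner-calling thresholds (absolute dataset counts, not fractions)."""

    common_lc_min: int = 8
    unique_lc_min: int = 7
    oc_min: int = 1
    oc_direction_mode: str = "same_sense"  # or "any_sense"

    def __post_init__(self) -> None:
        for name in ("common_lc_min", "unique_lc_min", "oc_min"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.oc_direction_mode not in ("same_sense", "any_sense"):
            raise ValueError(f"bad oc_direction_mode {self.oc_direction_mode!r}")


def tally_votes(tables: Sequence[DEGTable]) -> pd.DataFrame:
    """Count per-gene up/down calls per disease group.

    Returns a DataFrame indexed by gene_id with columns ``up_G``, ``down_G``,
    ``n_G`` for each group G; ``n_G`` is the number of datasets of that group
    containing the gene at all. Genes absent from a dataset contribute nothing
    there.
    """
    seen_ids = [t.dataset_id for t in tables]
    if len(set(seen_ids)) != len(seen_ids):
        dup = [d for d, c in Counter(seen_ids).items() if c > 1]
        raise ValueError(f"duplicate dataset ids: {dup}")

    universe: set[str] = set()
    for t in tables:
        universe.update(t.records.index)
    tally = pd.DataFrame(0, index=pd.Index(sorted(universe), name="gene_id"),
                         columns=TALLY_COLUMNS, dtype=int)
    for t in tables:
        g = t.disease_group
        if g not in GROUPS:
            logger.warning("dataset %s has group %s — ignored in tally",
                           t.dataset_id, g)
            continue
        direction = t.records["direction"]
        tally.loc[direction.index, f"n_{g}"] += 1
        for kind in ("up", "down"):
            hit = direction.index[direction == kind]
            tally.loc[hit, f"{kind}_{g}"] += 1
    return tally


def group_pattern(lc: int, bc: int, lk: int) -> str:
    """Presence pattern from any-direction deregulated-dataset counts."""
    if lc > 0 and bc > 0 and lk > 0:
        return "LC_BC_LK"
    if lc > 0 and bc > 0:
        return "LC_BC"
    if lc > 0 and lk > 0:
        return "LC_LK"
    if lc > 0:
        return "LC_only"
    return "none"


def classify_winner(tally_row: pd.Series,
                    thresholds: ConsensusThresholds = ConsensusThresholds()) -> dict:
    """Classify one gene's vote tally into a winner call.

    Returns a dict with keys ``status`` (common_winner / unique_lc_winner /
    none), ``direction`` (up / down / mixed / none), ``group_pattern``,
    ``lc``, ``bc``, ``lk``, ``total`` (any-direction deregulated counts).
    """
    up_lc, down_lc = int(tally_row["up_LC"]), int(tally_row["down_LC"])
    if up_lc == 0 and down_lc == 0:
        direction = "none"
        c_lc = 0
    elif up_lc == down_lc:
        direction = "mixed"
        c_lc = 0  # "same sense" is undefined for ties — never a winner
    else:
        direction = "up" if up_lc > down_lc else "down"
        c_lc = max(up_lc, down_lc)

    if thresholds.oc_direction_mode == "same_sense" and direction in ("up", "down"):
        oc = sum(int(tally_row[f"{direction}_{g}"]) for g in ("BC", "LK"))
    else:
        oc = sum(int(tally_row[f"up_{g}"]) + int(tally_row[f"down_{g}"])
                 for g in ("BC", "LK"))
    # the unique-LC rule demands no other-cancer deregulation in ANY sense
    oc_any = sum(int(tally_row[f"up_{g}"]) + int(tally_row[f"down_{g}"])
                 for g in ("BC", "LK"))

    if c_lc >= thresholds.common_lc_min and oc >= thresholds.oc_min:
        status = "common_winner"
    elif c_lc >= thresholds.unique_lc_min and oc_any == 0:
        status = "unique_lc_winner"
    else:
        status = "none"

    counts = {g.lower(): int(tally_row[f"up_{g}"]) + int(tally_row[f"down_{g}"])
              for g in GROUPS}
    return {
        "status": status,
        "direction": direction,
        "group_pattern": group_pattern(counts["lc"], counts["bc"], counts["lk"]),
        "lc": counts["lc"],
        "bc": counts["bc"],
        "lk": counts["lk"],
        "total": counts["lc"] + counts["bc"] + counts["lk"],
    }


def classify_winners(tally: pd.DataFrame,
                     thresholds: ConsensusThresholds = ConsensusThresholds()) -> pd.DataFrame:
    """Apply :func:`classify_winner` to every gene of a vote tally."""
    for g in GROUPS:
        n = int(tally[f"n_{g}"].max()) if len(tally) else 0
        need = thresholds.common_lc_min if g == "LC" else thresholds.oc_min
        if g == "LC" and n and need > n:
            logger.warning("LC threshold %d exceeds available LC datasets (%d)",
                           need, n)
    rows = {gene: classify_winner(row, thresholds) for gene, row in tally.iterrows()}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out


def categorize_table(calls: pd.DataFrame | Iterable[tuple[int, int, int]]) -> dict[str, int]:
    """Histogram of group-presence patterns.

    Accepts either a winner-call frame (with ``group_pattern``) or raw
    ``(lc, bc, lk)`` count triples.
    """
    counts = Counter()
    if isinstance(calls, pd.DataFrame):
        counts.update(calls["group_pattern"])
    else:
        for lc, bc, lk in calls:
            counts[group_pattern(lc, bc, lk)] += 1
    return {pat: counts.get(pat, 0) for pat in GROUP_PATTERNS}


def annotate_tf(calls: pd.DataFrame, tf_list: Iterable[str]) -> pd.DataFrame:
    """Set ``is_tf`` by membership in a transcription-factor list."""
    tfs = set(tf_list)
    if not tfs:
        raise ValueError("tf_list is empty")
    out = calls.copy()
    out["is_tf"] = out.index.isin(tfs)
    n_tf_winners = int((out["is_tf"] & (out["status"] != "none")).sum())
    logger.info("%d winner genes annotated as TFs", n_tf_winners)
    return out


def read_tf_list(path) -> set[str]:
    """One gene id per line; blank lines and '#' comments ignored."""
    with open(path, "r", encoding="utf-8") as fh:
        return {line.strip() for line in fh
                if line.strip() and not line.startswith("#")}


def write_winner_table(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index_label="gene_id")
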