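"""Over-representation analysis of a gene list against GMT gene sets.

The statistic is the plain hypergeometric upper tail: with a universe of N
genes of which K belong to a set, a query of n genes overlapping the set in k
gives ``P(X >= k)`` for X ~ Hypergeometric(N, K, n). P-values are corrected
across the tested sets with step-up Benjamini–Hochberg. This is a deliberately
fully specified statistic — it is not the EASE score of annotation web tools,
whose backend databases move over time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import pandas as pd
from scipy import stats

from .diffexp import bh_adjust

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named gene sets restricted to a universe.

    Members outside the universe are dropped (logged); sets left empty after
    restriction are removed (logged).
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.universe = frozenset(self.universe)
        restricted: dict[str, frozenset[str]] = {}
        n_dropped_members = 0
        for name, members in self.sets.items():
            members = frozenset(members)
            kept = members & self.universe
            n_dropped_members += len(members) - len(kept)
            if kept:
                restricted[name] = kept
            else:
                logger.warning("gene set %r empty after universe restriction", name)
        if n_dropped_members:
            logger.info("dropped %d set members outside the universe",
                        n_dropped_members)
        self.sets = restricted

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (set name, description, members, tab-separated).

    If ``universe`` is omitted it defaults to the union of all set members.
    """
    sets: dict[str, frozenset[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3 or not parts[0]:
                continue
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            sets[name] = frozenset(members)
            descriptions[name] = desc
    if universe is None:
        universe = frozenset().union(*sets.values()) if sets else frozenset()
    return GeneSetCollection(sets, frozenset(universe), descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """``P(X >= k)`` for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def ora(query: Iterable[str], collection: GeneSetCollection,
        fdr_max: float = 0.05) -> pd.DataFrame:
    """Test the query list against every set of the collection.

    Returns a DataFrame sorted by p ascending with columns ``set_name``,
    ``overlap`` (k), ``set_size`` (K), ``query_size`` (n), ``universe_size``
    (N), ``p_value``, ``fdr``, ``significant``.
    """
    query = frozenset(query)
    dropped = query - collection.universe
    if dropped:
        logger.info("dropped %d query genes outside the universe", len(dropped))
    query = query & collection.universe
    if not query:
        raise ValueError("query empty after restriction to the universe")
    N = len(collection.universe)
    n = len(query)
    rows = []
    for name, members in collection.sets.items():
        k = len(query & members)
        K = len(members)
        rows.append((name, k, K, n, N, hypergeometric_upper_tail(k, K, n, N)))
    out = pd.DataFrame(rows, columns=["set_name", "overlap", "set_size",
                                      "query_size", "universe_size", "p_value"])
    out["fdr"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["fdr"] <= fdr_max
    out = out.sort_values(["p_value", "set_name"], kind="stable",
                          ignore_index=True)
    return out
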