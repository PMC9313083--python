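"""Kaplan–Meier estimation and log-rank screening by expression dichotomy.

Overall survival is summarized with the product-limit estimator: at each
distinct event time t_i with d_i deaths among n_i subjects at risk,

    S(t_i) = S(t_{i-1}) * (1 - d_i / n_i).

Censored subjects leave the risk set after their time; when an event and a
censoring share a time, the event is counted first (the standard convention).

Two expression-defined groups are compared with the two-group log-rank test:
over the pooled distinct event times, the observed minus expected events in
group A with hypergeometric variance give ``chi2 = (O−E)² / V`` (1 df). The
reported hazard ratio is the Mantel–Haenszel-style ``(O_A/E_A)/(O_B/E_B)``.

Genes are screened by dichotomizing patients at the median expression
(default) or at the chi-square-maximizing cutpoint scanned over the 25th–75th
expression quantiles; the latter mimics auto-cutoff survival portals and its
p-value is flagged as cutoff-optimized (anti-conservative).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate: step values at the distinct event times."""

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): 1 before the first event, right-continuous steps after."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    chi2: float
    p_value: float
    hazard_ratio: float
    group_sizes: tuple[int, int]
    degenerate: bool = False
    cutoff: float | None = None
    cutoff_optimized: bool = False


def _clean(times, events) -> tuple[np.ndarray, np.ndarray]:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival group")
    if np.any(times <= 0):
        raise ValueError("survival times must be > 0")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("event indicators must be 0 or 1")
    return times, events


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimator for one group."""
    times, events = _clean(times, events)
    order = np.lexsort((1 - events, times))  # events first at tied times
    times, events = times[order], events[order]
    event_times = np.unique(times[events == 1])
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in event_times:
        n_i = int(np.sum(times >= t))  # events at t still at risk at t
        d_i = int(np.sum((times == t) & (events == 1)))
        s *= 1.0 - d_i / n_i
        surv.append(s)
        at_risk.append(n_i)
        n_ev.append(d_i)
    return KMCurve(event_times, np.asarray(surv), np.asarray(at_risk, dtype=int),
                   np.asarray(n_ev, dtype=int))


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """Two-group log-rank test with Mantel–Haenszel hazard ratio."""
    times_a, events_a = _clean(times_a, events_a)
    times_b, events_b = _clean(times_b, events_b)
    all_times = np.concatenate([times_a, times_b])
    all_events = np.concatenate([events_a, events_b])
    if all_events.sum() == 0:
        raise ValueError("no events in either group")

    event_times = np.unique(all_times[all_events == 1])
    O_a = E_a = V = 0.0
    O_b = E_b = 0.0
    for t in event_times:
        n_a = float(np.sum(times_a >= t))
        n_b = float(np.sum(times_b >= t))
        n = n_a + n_b
        d_a = float(np.sum((times_a == t) & (events_a == 1)))
        d_b = float(np.sum((times_b == t) & (events_b == 1)))
        d = d_a + d_b
        if n < 2 or d == 0:
            continue
        e_a = d * n_a / n
        O_a += d_a
        E_a += e_a
        O_b += d_b
        E_b += d - e_a
        V += d * (n_a / n) * (n_b / n) * (n - d) / (n - 1) if n > 1 else 0.0

    if V == 0.0:
        logger.warning("log-rank: zero variance — degenerate comparison")
        return LogRankResult(0.0, 1.0, np.nan,
                             (len(times_a), len(times_b)), degenerate=True)
    chi2 = (O_a - E_a) ** 2 / V
    p = float(stats.chi2.sf(chi2, df=1))
    if O_a > 0 and O_b > 0 and E_a > 0 and E_b > 0:
        hr = (O_a / E_a) / (O_b / E_b)
    else:
        hr = np.inf if (O_b == 0 or E_a == 0) else 0.0
    return LogRankResult(float(chi2), p, float(hr),
                         (len(times_a), len(times_b)))


def dichotomize(expression, mode: str = "median") -> tuple[np.ndarray, float]:
    """Split subjects into low/high expression groups.

    Returns ``(high_mask, cutoff)``: subjects with expression strictly above
    the cutoff are "high" (ties go to the low group). ``median`` uses the
    sample median; ``best_cutoff`` must be resolved against survival data via
    :func:`screen_gene`.
    """
    expression = np.asarray(expression, dtype=float)
    if expression.size < 4:
        raise ValueError("need >=4 records to dichotomize")
    if np.all(expression == expression[0]):
        raise ValueError("constant expression cannot be dichotomized")
    if mode != "median":
        raise ValueError("only 'median' resolves without survival data; "
                         "use screen_gene for best_cutoff")
    cutoff = float(np.median(expression))
    return expression > cutoff, cutoff


def _candidate_cutoffs(expression: np.ndarray) -> np.ndarray:
    lo, hi = np.quantile(expression, [0.25, 0.75])
    cands = np.unique(expression[(expression >= lo) & (expression <= hi)])
    # a cutoff equal to the max splits nothing off; drop it
    return cands[cands < expression.max()]


def screen_gene(times, events, expression, mode: str = "median") -> LogRankResult:
    """Log-rank screen of one gene by expression-dichotomized groups.

    ``mode='median'`` splits at the median; ``mode='best_cutoff'`` scans the
    observed expression values between the 25th and 75th quantiles and keeps
    the cutpoint maximizing chi2 (result flagged ``cutoff_optimized`` — the
    p-value is anti-conservative).
    """
    times, events = _clean(times, events)
    expression = np.asarray(expression, dtype=float)
    if mode == "median":
        high, cutoff = dichotomize(expression, "median")
        res = logrank_test(times[high], events[high], times[~high], events[~high])
        res.cutoff = cutoff
        return res
    if mode != "best_cutoff":
        raise ValueError(f"unknown mode {mode!r}")
    if np.all(expression == expression[0]):
        raise ValueError("constant expression cannot be dichotomized")
    best: LogRankResult | None = None
    for cut in _candidate_cutoffs(expression):
        high = expression > cut
        if high.sum() == 0 or (~high).sum() == 0:
            continue
        try:
            res = logrank_test(times[high], events[high],
                               times[~high], events[~high])
        except ValueError:
            continue
        if res.degenerate:
            continue
        if best is None or res.chi2 > best.chi2:
            res.cutoff = float(cut)
            best = res
    if best is None:
        raise ValueError("no usable cutoff in the 25th–75th quantile range")
    best.cutoff_optimized = True
    logger.info("best_cutoff split at %.4g: p-value is cutoff-optimized",
                best.cutoff)
    return best


def screen_genes(survival_df: pd.DataFrame, genes: list[str],
                 mode: str = "median") -> pd.DataFrame:
    """Screen several genes from a wide table.

    ``survival_df`` must have columns ``time`` and ``event`` plus one column
    per gene. Returns one row per gene: chi2, p_value, hazard_ratio, cutoff,
    n_high, n_low, cutoff_optimized.
    """
    rows = {}
    for gene in genes:
        res = screen_gene(survival_df["time"], survival_df["event"],
                          survival_df[gene], mode=mode)
        rows[gene] = {
            "chi2": res.chi2, "p_value": res.p_value,
            "hazard_ratio": res.hazard_ratio, "cutoff": res.cutoff,
            "n_high": res.group_sizes[0], "n_low": res.group_sizes[1],
            "cutoff_optimized": res.cutoff_optimized,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "gene_id"
    return out
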