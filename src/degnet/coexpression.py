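"""Coexpression networks with clustering-coefficient threshold selection.

The similarity between two genes is the absolute Pearson correlation of their
expression profiles, so the network is unsigned. A hard threshold τ turns the
similarity matrix into an undirected simple graph (edge iff ``S >= τ``); τ* is
chosen on a grid by comparing the observed clustering coefficient against the
Erdős–Rényi expectation for a random graph of the same size and edge count
(which is just the edge density). Two selection modes:

* ``first_local_max`` (default): smallest τ (with ≥ 1 edge and ``D > 0``)
  whose difference is not exceeded within the next ``patience`` grid steps —
  the first sustained local maximum of the difference curve. The global
  argmax always qualifies, so a selection always exists when any ``D > 0``.
* ``max_diff``: smallest τ attaining the global maximum of ``D`` among
  thresholds that leave at least one edge. On noisy data the global maximum
  tends to sit in the high-τ "crumble zone" where only a tiny sub-clique
  survives (its conditional clustering stays near 1 while the density term
  vanishes), which is why it is not the default.
* ``first_positive``: first τ where ``D(τ) > 0`` holds for ``k_sustain``
  consecutive grid points.

A common connectivity pattern (CCP) between two networks is a connected
component (≥ 2 nodes) of the graph of shared nodes and shared edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .datasets import ExpressionDataset

logger = logging.getLogger(__name__)

DEFAULT_GRID = np.round(np.arange(0.01, 1.00, 0.01), 2)

CURVE_COLUMNS = ["tau", "c_obs", "c_rand", "n_edges"]


@dataclass
class SimilarityMatrix:
    """Absolute-Pearson similarity over a gene list (symmetric, diag 1)."""

    gene_ids: list[str]
    S: np.ndarray = field(repr=False)
    constant_genes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = len(self.gene_ids)
        if self.S.shape != (n, n):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.S, self.S.T, atol=1e-12):
            raise ValueError("similarity matrix not symmetric")
        if self.S.min() < -1e-12 or self.S.max() > 1 + 1e-12:
            raise ValueError("similarities must lie in [0, 1]")


@dataclass
class CoexpressionNetwork:
    """Thresholded coexpression graph with its audit curves."""

    network_id: str
    gene_ids: list[str]
    tau_star: float
    graph: nx.Graph = field(repr=False)
    curves: pd.DataFrame | None = field(default=None, repr=False)
    degree_tier: dict[str, str] = field(default_factory=dict, repr=False)


def pearson_abs_similarity(ds: ExpressionDataset, genes: list[str] | None = None,
                           samples: str = "all") -> SimilarityMatrix:
    """|Pearson r| between all gene pairs over the selected samples.

    ``samples`` is ``all`` (default: cases + controls) or ``case``. Constant
    genes get similarity 0 to every other gene and are reported in
    ``constant_genes``.
    """
    if genes is None:
        genes = ds.gene_ids
    missing = [g for g in genes if g not in ds.values.index]
    if missing:
        raise KeyError(f"genes absent from {ds.dataset_id}: {missing[:5]}")
    cols = ds.sample_ids if samples == "all" else ds.case_ids
    if len(cols) < 3:
        raise ValueError("need >=3 samples for correlation")
    X = ds.values.loc[genes, cols].to_numpy(dtype=float)
    sd = X.std(axis=1)
    constant = sd == 0.0
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.abs(np.corrcoef(X))
    S[constant, :] = 0.0
    S[:, constant] = 0.0
    np.fill_diagonal(S, 1.0)
    S = np.clip((S + S.T) / 2.0, 0.0, 1.0)
    const_names = [g for g, c in zip(genes, constant) if c]
    if const_names:
        logger.warning("%d constant genes assigned zero similarity: %s",
                       len(const_names), const_names[:5])
    return SimilarityMatrix(list(genes), S, const_names)


def clustering_coefficient(graph: nx.Graph) -> float:
    """Mean local clustering over nodes of degree >= 2 (0 if there are none)."""
    cc = [c for node, c in nx.clustering(graph).items() if graph.degree(node) >= 2]
    return float(np.mean(cc)) if cc else 0.0


def random_expected_cc(n_nodes: int, n_edges: int) -> float:
    """Erdős–Rényi expected clustering: the edge density 2e / (n(n−1))."""
    if n_nodes < 2:
        raise ValueError("need n_nodes >= 2")
    return 2.0 * n_edges / (n_nodes * (n_nodes - 1))


def _curves_from_similarity(S: np.ndarray, grid: np.ndarray) -> pd.DataFrame:
    """Observed/random clustering and edge counts for every grid threshold.

    Vectorized via boolean adjacency powers: triangles through node i are
    ``(A @ A @ A)[i, i] / 2``.
    """
    n = S.shape[0]
    off = ~np.eye(n, dtype=bool)
    rows = []
    for tau in grid:
        A = (S >= tau) & off
        deg = A.sum(axis=1)
        n_edges = int(deg.sum() // 2)
        if n_edges == 0:
            rows.append((float(tau), 0.0, 0.0, 0))
            continue
        Af = A.astype(float)
        tri = np.diag(Af @ Af @ Af) / 2.0
        elig = deg >= 2
        if elig.any():
            local = 2.0 * tri[elig] / (deg[elig] * (deg[elig] - 1.0))
            c_obs = float(local.mean())
        else:
            c_obs = 0.0
        rows.append((float(tau), c_obs, random_expected_cc(n, n_edges), n_edges))
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def select_threshold(sim: SimilarityMatrix, grid: np.ndarray | None = None,
                     mode: str = "first_local_max", k_sustain: int = 3,
                     patience: int = 10) -> tuple[float, pd.DataFrame]:
    """Pick τ* on a grid by the clustering-coefficient criterion.

    Returns ``(tau_star, curves)`` with the full per-τ audit table. Raises if
    no grid threshold leaves at least one edge.
    """
    grid = DEFAULT_GRID if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("grid must lie inside (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly ascending")
    curves = _curves_from_similarity(sim.S, grid)
    has_edge = curves["n_edges"] > 0
    if not has_edge.any():
        raise ValueError("no threshold on the grid yields any edge")
    diff = curves["c_obs"] - curves["c_rand"]
    if mode == "first_local_max":
        d = diff.to_numpy()
        ok = has_edge.to_numpy()
        tau_star = None
        for i in range(len(d)):
            if not ok[i] or d[i] <= 0:
                continue
            window = d[i + 1:i + 1 + patience]
            if window.size == 0 or not np.any(window > d[i] + 1e-12):
                tau_star = float(curves.loc[i, "tau"])
                break
        if tau_star is None:  # no positive difference anywhere
            masked = diff.where(has_edge, -np.inf)
            tau_star = float(curves.loc[masked.idxmax(), "tau"])
    elif mode == "max_diff":
        masked = diff.where(has_edge, -np.inf)
        tau_star = float(curves.loc[masked.idxmax(), "tau"])  # idxmax → smallest tie
    elif mode == "first_positive":
        ok = ((diff > 0) & has_edge).to_numpy()
        run = 0
        tau_star = None
        for i, flag in enumerate(ok):
            run = run + 1 if flag else 0
            if run >= k_sustain:
                tau_star = float(curves.loc[i - k_sustain + 1, "tau"])
                break
        if tau_star is None:
            logger.warning("no sustained positive D(tau); falling back to max_diff")
            masked = diff.where(has_edge, -np.inf)
            tau_star = float(curves.loc[masked.idxmax(), "tau"])
    else:
        raise ValueError(f"unknown threshold mode {mode!r}")
    return tau_star, curves


def build_network(sim: SimilarityMatrix, tau_star: float,
                  network_id: str = "network",
                  curves: pd.DataFrame | None = None) -> CoexpressionNetwork:
    """Adjacency at τ* plus degree tiers.

    Tiers: ``most`` = degree at or above the 90th percentile of positive
    degrees, ``less`` = at or below the 10th percentile (isolated nodes are
    always ``less``), ``average`` otherwise.
    """
    n = len(sim.gene_ids)
    off = ~np.eye(n, dtype=bool)
    A = (sim.S >= tau_star) & off
    graph = nx.Graph()
    graph.add_nodes_from(sim.gene_ids)
    ii, jj = np.nonzero(np.triu(A, k=1))
    graph.add_weighted_edges_from(
        (sim.gene_ids[i], sim.gene_ids[j], float(sim.S[i, j]))
        for i, j in zip(ii, jj)
    )
    degrees = np.array([graph.degree(g) for g in sim.gene_ids])
    positive = degrees[degrees > 0]
    tier: dict[str, str] = {}
    if positive.size:
        hi = np.percentile(positive, 90)
        lo = np.percentile(positive, 10)
        for g, d in zip(sim.gene_ids, degrees):
            if d == 0 or d <= lo:
                tier[g] = "less"
            elif d >= hi:
                tier[g] = "most"
            else:
                tier[g] = "average"
    else:
        tier = {g: "less" for g in sim.gene_ids}
    return CoexpressionNetwork(network_id, list(sim.gene_ids), float(tau_star),
                               graph, curves, tier)


def coexpression_network(ds: ExpressionDataset, genes: list[str] | None = None,
                         grid: np.ndarray | None = None,
                         mode: str = "first_local_max",
                         samples: str = "all", tau: float | None = None
                         ) -> CoexpressionNetwork:
    """One-call network construction: similarity → τ* → graph."""
    present = [g for g in (genes or ds.gene_ids) if g in ds.values.index]
    sim = pearson_abs_similarity(ds, present, samples=samples)
    if tau is None:
        tau, curves = select_threshold(sim, grid=grid, mode=mode)
    else:
        curves = None
    return build_network(sim, tau, network_id=ds.dataset_id, curves=curves)


def find_ccps(net_a: CoexpressionNetwork, net_b: CoexpressionNetwork) -> list[list[str]]:
    """Common connectivity patterns between two networks.

    Connected components (size >= 2) of the shared-node, shared-edge graph,
    sorted by size descending then by lexicographically smallest member. Each
    component is returned as a sorted node list.
    """
    shared_nodes = set(net_a.graph.nodes) & set(net_b.graph.nodes)
    shared = nx.Graph()
    shared.add_nodes_from(shared_nodes)
    shared.add_edges_from(
        (u, v) for u, v in net_a.graph.edges
        if u in shared_nodes and v in shared_nodes and net_b.graph.has_edge(u, v)
    )
    comps = [sorted(c) for c in nx.connected_components(shared) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c[0]))
    return comps


# -- exports -------------------------------------------------------------------

def write_edge_list(net: CoexpressionNetwork, path) -> None:
    rows = [(u, v, f"{d.get('weight', 1.0):.10g}")
            for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "similarity"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(net: CoexpressionNetwork, path) -> None:
    g = net.graph.copy()
    nx.set_node_attributes(g, net.degree_tier, "degree_tier")
    nx.write_graphml(g, path)


def write_curves(curves: pd.DataFrame, path) -> None:
    curves.to_csv(path, sep="\t", index=False, float_format="%.10g")
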