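"""Small-world analysis of thresholded connectivity networks.

A connectivity matrix is binarized at a threshold T (edge iff value
strictly exceeds T), characterized by its mean clustering coefficient C
(functional segregation) and characteristic path length L (functional
integration), and compared against edge-count-matched uniform random
reference networks.  The small-world index is

    S = gamma / lambda,   gamma = C / Cr,   lambda = L / Lr,

with Cr, Lr averaged over 20 random references by default; S > 1 is the
usual indicator of small-world organization.

Conventions on degenerate cases (logged, not fatal, during sweeps):

* L is the mean shortest-path length over *connected* ordered pairs only;
  infinite distances in disconnected graphs are excluded.
* An edgeless graph has no defined L; clustering of a node with degree < 2
  is 0.
* At extreme thresholds Cr may be 0, leaving S undefined for that T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

#: threshold-grid step per connectivity metric
SWEEP_STEP = {"coherence": 0.025, "correlation": 0.025, "plv": 0.025, "pli": 0.005}


@dataclass
class BinaryGraph:
    """Undirected binary graph from thresholding a connectivity matrix."""

    adjacency: np.ndarray
    threshold: float
    metric: str = ""
    band: str = ""

    def __post_init__(self) -> None:
        a = np.asarray(self.adjacency)
        if a.ndim != 2 or a.shape[0] != a.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.array_equal(a, a.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(a) != 0):
            raise ValueError("self-loops are not allowed")
        self.adjacency = a.astype(np.uint8)

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2


@dataclass
class GraphMetrics:
    """Small-world metrics of one binarized network at one threshold."""

    C: float
    L: float
    Cr: float
    Lr: float
    gamma: float
    lam: float
    S: float
    node_clustering: np.ndarray
    threshold: float = np.nan


def binarize(m: ConnectivityMatrix | np.ndarray, T: float) -> BinaryGraph:
    """Edge iff connectivity strictly exceeds T; diagonal ignored."""
    if not 0.0 < T < 1.0:
        raise ValueError(f"threshold must satisfy 0 < T < 1, got {T}")
    if isinstance(m, ConnectivityMatrix):
        values, metric, band = m.values, m.metric, m.band.name
    else:
        values, metric, band = np.asarray(m, dtype=float), "", ""
    adj = (values > T).astype(np.uint8)
    np.fill_diagonal(adj, 0)
    return BinaryGraph(adj, threshold=T, metric=metric, band=band)


def _as_adj(g: BinaryGraph | np.ndarray) -> np.ndarray:
    return g.adjacency if isinstance(g, BinaryGraph) else np.asarray(g, dtype=np.uint8)


def clustering_coefficient(g: BinaryGraph | np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering coefficients and their mean.

    ``C_i = 2 t_i / (k_i (k_i - 1))`` where ``t_i`` counts edges among the
    neighbours of node i; nodes with degree < 2 have ``C_i = 0``.
    """
    a = _as_adj(g).astype(np.float64)
    k = a.sum(axis=1)
    triangles = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, 2.0 * triangles / denom, 0.0)
    return c, float(c.mean())


def characteristic_path_length(g: BinaryGraph | np.ndarray) -> float:
    """Mean shortest-path length over connected ordered node pairs."""
    a = _as_adj(g)
    if a.sum() == 0:
        raise ValueError("path length undefined for an edgeless graph")
    d = shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)
    off = ~np.eye(a.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    n_excluded = int(off.sum() - finite.sum())
    if n_excluded:
        logger.debug(
            "graph disconnected: %d ordered pairs excluded from L", n_excluded
        )
    return float(d[finite].mean())


def random_reference(
    g: BinaryGraph | np.ndarray, n_random: int = 20, seed: int | None = 0
) -> tuple[float, float]:
    """Mean C and L over uniform random graphs with matched node/edge counts.

    The reference model places the same number of edges uniformly at random
    among the same nodes (not degree-preserving rewiring).  Deterministic
    for a fixed seed.
    """
    a = _as_adj(g)
    n = a.shape[0]
    m = int(a.sum()) // 2
    if m < 1:
        raise ValueError("random reference needs at least one edge")
    total = comb(n, 2)
    iu = np.triu_indices(n, 1)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    for _ in range(n_random):
        pick = rng.choice(total, size=m, replace=False)
        adj = np.zeros((n, n), dtype=np.uint8)
        adj[iu[0][pick], iu[1][pick]] = 1
        adj |= adj.T
        _, c = clustering_coefficient(adj)
        cs.append(c)
        ls.append(characteristic_path_length(adj))
    return float(np.mean(cs)), float(np.mean(ls))


def small_world_index(C: float, L: float, Cr: float, Lr: float) -> tuple[float, float, float]:
    """``(gamma, lambda, S)`` = (C/Cr, L/Lr, gamma/lambda)."""
    if Cr <= 0 or Lr <= 0:
        raise ValueError("small-world index undefined: Cr and Lr must be positive")
    gamma = C / Cr
    lam = L / Lr
    return gamma, lam, gamma / lam


def graph_metrics(
    g: BinaryGraph | np.ndarray,
    n_random: int = 20,
    seed: int | None = 0,
    threshold: float = np.nan,
) -> GraphMetrics:
    """Full small-world characterization of one binary graph."""
    node_c, C = clustering_coefficient(g)
    L = characteristic_path_length(g)
    Cr, Lr = random_reference(g, n_random=n_random, seed=seed)
    gamma, lam, S = small_world_index(C, L, Cr, Lr)
    return GraphMetrics(C, L, Cr, Lr, gamma, lam, S, node_c, threshold)


def sweep_thresholds(metric: str) -> np.ndarray:
    """Interior threshold grid for a metric (step 0.025, or 0.005 for PLI)."""
    step = SWEEP_STEP[metric]
    n = int(round(1.0 / step))
    return np.round(np.arange(1, n) * step, 10)


def threshold_sweep(
    m: ConnectivityMatrix | np.ndarray,
    metric: str | None = None,
    n_random: int = 20,
    seed: int | None = 0,
) -> list[tuple[float, GraphMetrics | None]]:
    """Small-world metrics across the full threshold grid.

    Thresholds where the metrics are undefined (edgeless graph, Cr = 0)
    are recorded as ``None`` rather than aborting the sweep.
    """
    if metric is None:
        if not isinstance(m, ConnectivityMatrix):
            raise ValueError("metric name required for a bare array")
        metric = m.metric
    if metric not in SWEEP_STEP:
        raise ValueError(f"unknown metric {metric!r}")
    out: list[tuple[float, GraphMetrics | None]] = []
    for T in sweep_thresholds(metric):
        try:
            gm = graph_metrics(binarize(m, float(T)), n_random=n_random, seed=seed)
            gm.threshold = float(T)
            out.append((float(T), gm))
        except ValueError as e:
            logger.debug("threshold %.3f: metrics undefined (%s)", T, e)
            out.append((float(T), None))
    return out


def sweep_table(sweep: Sequence[tuple[float, GraphMetrics | None]]) -> pd.DataFrame:
    """Tidy one-row-per-threshold table of a sweep."""
    rows = []
    for T, gm in sweep:
        if gm is None:
            rows.append({"T": T})
        else:
            rows.append(
                {"T": T, "C": gm.C, "L": gm.L, "Cr": gm.Cr, "Lr": gm.Lr,
                 "gamma": gm.gamma, "lambda": gm.lam, "S": gm.S}
            )
    return pd.DataFrame(rows)


def group_node_ttest(
    group_a: np.ndarray, group_b: np.ndarray, node_labels: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-electrode two-sample t-tests on node clustering coefficients.

    Parameters
    ----------
    group_a, group_b
        ``subjects x nodes`` arrays of per-subject mean node clustering
        (each subject's trial-averaged network binarized at one threshold,
        conventionally T = 0.15).

    Returns a tidy frame with t, two-sided p, direction (sign of
    mean(A) - mean(B)) and a flag: ``"sig"`` for p < 0.05, ``"trend"`` for
    0.05 <= p < 0.1, ``""`` otherwise.
    """
    a = np.atleast_2d(np.asarray(group_a, dtype=float))
    b = np.atleast_2d(np.asarray(group_b, dtype=float))
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("each group needs at least 2 subjects for a t-test")
    if a.shape[1] != b.shape[1]:
        raise ValueError("groups must cover the same electrodes")
    t, p = stats.ttest_ind(a, b, axis=0)
    direction = np.sign(a.mean(axis=0) - b.mean(axis=0))
    flags = np.where(p < 0.05, "sig", np.where(p < 0.1, "trend", ""))
    labels = (
        list(node_labels)
        if node_labels is not None
        else [f"E{i + 1}" for i in range(a.shape[1])]
    )
    return pd.DataFrame(
        {"electrode": labels, "t": t, "p": p, "direction": direction, "flag": flags}
    )


def fdr_correct(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Optional Benjamini-Hochberg switch for the electrode-wise tests."""
    return stats.false_discovery_control(np.asarray(p, dtype=float))
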