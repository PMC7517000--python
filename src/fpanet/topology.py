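"""Topology statistics for undirected networks.

Everything needed for one summary row of a scale-free network study:
degree distribution and its cumulative (CCDF) power-law exponent beta,
the degree-correlation curve <k_nn(k)> and its exponent alpha,
average local clustering rho, average degree <k>, exact or estimated
diameter D, average shortest path length L, the maximum degree, and the
ultra-small-world reference value ln(N)/ln(ln(N)).

Exponents are measured the way they are usually read off log-log plots:
an ordinary least-squares line through log10 of the curve over a
configurable degree window.  Maximum-likelihood (Clauset-style) fitting
is deliberately out of scope.

Functions accept a :class:`~fpanet.generator.NetworkState`, a
:class:`networkx.Graph`, or an ``(n, edges)`` pair where ``edges`` is an
integer array of shape (E, 2) with 0-based node ids.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy import stats
from scipy.sparse.csgraph import connected_components, dijkstra

from .generator import NetworkState

__all__ = [
    "DegreeCurves",
    "PowerFit",
    "TopologySummary",
    "degree_curves",
    "fit_ccdf_exponent",
    "knn_curve",
    "fit_alpha",
    "clustering",
    "diameter",
    "avg_path_length",
    "ultra_small_reference",
    "summarize",
]

# Default lower cut of the CCDF fit window.  The head of the degree
# distribution (k of order the per-node link count) has not reached the
# asymptotic power law -- on the exact BA tree closed form the local
# log-log slope at k=1 is -1.5 versus the asymptotic -2 -- so fits start
# a little above it.  See fit_ccdf_exponent.
DEFAULT_KMIN = 6
# Default upper cut: degree at the 0.999 quantile of the degree
# distribution, excluding the extreme hub tail which visibly departs
# from the fitted line.
DEFAULT_CDF_QUANTILE = 0.999
# Degree classes entering the alpha fit need at least this many nodes.
DEFAULT_ALPHA_MIN_CLASS = 5
# Lower cut of the <k_nn(k)> fit: the low-degree classes of a growing
# tree saturate (every node keeps at least one link toward the core),
# so the power-law scaling regime is read off the k >= 10 tail.
DEFAULT_ALPHA_KMIN = 10
# Exact all-sources computations are attempted up to this many nodes.
EXACT_DIAMETER_LIMIT = 20_000
# Number of double-sweep roots for the large-graph diameter estimate.
DIAMETER_SWEEP_ROOTS = 20
# BFS sources sampled for the general-graph path-length estimate.
DEFAULT_LPL_SAMPLES = 1000


@dataclass
class DegreeCurves:
    """Degree distribution tabulated per observed degree k."""

    k: np.ndarray                     # sorted distinct degrees
    pdf: np.ndarray                   # p(k): fraction of nodes of degree k
    cdf: np.ndarray                   # P(k): fraction of nodes of degree >= k
    counts: np.ndarray                # node counts per degree class
    n_nodes: int
    knn: Optional[np.ndarray] = None  # <k_nn(k)>, aligned with k


@dataclass
class PowerFit:
    """Least-squares power-law fit on log-log scale."""

    exponent: float          # beta, alpha, or Df depending on context
    amplitude: float         # C in y = C * k^slope
    k_range: Tuple[float, float]
    stderr: float
    r_squared: float
    n_points: int


@dataclass
class TopologySummary:
    """One summary row: the standard topological parameters."""

    n_nodes: int
    n_edges: int
    alpha: float
    rho: float
    mean_degree: float
    diameter: int
    avg_path: float
    kmax: int
    beta: float
    diameter_exact: bool = True
    avg_path_exact: bool = True
    ultra_small_ref: float = float("nan")
    beta_fit: Optional[PowerFit] = None
    alpha_fit: Optional[PowerFit] = None
    m: Optional[int] = None
    f: Optional[float] = None
    seed: Optional[int] = None


# ---------------------------------------------------------------------------
# graph plumbing
# ---------------------------------------------------------------------------

def as_arrays(network) -> Tuple[int, np.ndarray]:
    """Coerce supported network containers to ``(n, edges)`` arrays."""
    if isinstance(network, NetworkState):
        return network.num_nodes, network.edges_array()
    if isinstance(network, tuple) and len(network) == 2:
        n, edges = network
        return int(n), np.asarray(edges, dtype=np.int64).reshape(-1, 2)
    try:
        import networkx as nx
    except ImportError:  # pragma: no cover
        nx = None
    if nx is not None and isinstance(network, nx.Graph):
        nodes = list(network.nodes())
        idx = {u: i for i, u in enumerate(nodes)}
        edges = np.asarray(
            [(idx[u], idx[v]) for u, v in network.edges()], dtype=np.int64
        ).reshape(-1, 2)
        return len(nodes), edges
    raise TypeError(f"unsupported network container: {type(network)!r}")


def _degrees(n: int, edges: np.ndarray) -> np.ndarray:
    return np.bincount(edges.ravel(), minlength=n).astype(np.int64)


def _adjacency(n: int, edges: np.ndarray) -> sp.csr_matrix:
    if edges.size == 0:
        return sp.csr_matrix((n, n), dtype=np.int8)
    row = np.concatenate([edges[:, 0], edges[:, 1]])
    col = np.concatenate([edges[:, 1], edges[:, 0]])
    data = np.ones(row.size, dtype=np.int8)
    return sp.csr_matrix((data, (row, col)), shape=(n, n))


def _require_connected(adj: sp.csr_matrix) -> None:
    ncomp, _ = connected_components(adj, directed=False)
    if ncomp != 1:
        raise ValueError(f"network is disconnected ({ncomp} components)")


def _bfs_dist(adj: sp.csr_matrix, source) -> np.ndarray:
    return dijkstra(adj, directed=False, unweighted=True, indices=source)


# ---------------------------------------------------------------------------
# degree distribution
# ---------------------------------------------------------------------------

def degree_curves(network) -> DegreeCurves:
    """Tabulate p(k) and the cumulative P(k) = #{i : k_i >= k} / N."""
    n, edges = as_arrays(network)
    if n == 0:
        raise ValueError("empty network")
    deg = _degrees(n, edges)
    counts = np.bincount(deg)
    k = np.nonzero(counts)[0]
    counts = counts[k]
    pdf = counts / n
    cdf = np.cumsum(pdf[::-1])[::-1]
    return DegreeCurves(k=k.astype(np.int64), pdf=pdf, cdf=cdf,
                        counts=counts, n_nodes=n)


def _loglog_fit(x: np.ndarray, y: np.ndarray) -> Tuple[float, float, float, float]:
    lx, ly = np.log10(x), np.log10(y)
    res = stats.linregress(lx, ly)
    return res.slope, 10.0 ** res.intercept, res.stderr, res.rvalue ** 2


def fit_ccdf_exponent(curves: DegreeCurves,
                      kmin: Optional[int] = None,
                      kmax_quantile: float = DEFAULT_CDF_QUANTILE) -> PowerFit:
    """Fit P(k) ~ k^-beta by OLS of log10 P(k) on log10 k.

    The window runs from ``kmin`` (default :data:`DEFAULT_KMIN`, clipped
    to the observed degrees) to the degree at the ``kmax_quantile`` of
    the degree distribution, i.e. the largest k with
    ``P(k) >= 1 - kmax_quantile``.  Returns beta as the negated slope.
    """
    if kmin is None:
        kmin = DEFAULT_KMIN
    k, cdf = curves.k, curves.cdf
    tail = 1.0 - kmax_quantile
    above = k[cdf >= tail - 1e-12]
    k_hi = int(above.max()) if above.size else int(k.max())
    mask = (k >= kmin) & (k <= k_hi) & (cdf > 0)
    if mask.sum() < 3:
        raise ValueError(
            f"need >= 3 degree points in [{kmin}, {k_hi}] to fit the CCDF")
    slope, amp, err, r2 = _loglog_fit(k[mask], cdf[mask])
    return PowerFit(exponent=-slope, amplitude=amp,
                    k_range=(float(kmin), float(k_hi)),
                    stderr=err, r_squared=r2, n_points=int(mask.sum()))


def knn_curve(network) -> DegreeCurves:
    """Mean degree of the neighbours of k-degree nodes, <k_nn(k)>.

    Per node i: k_nn(i) = (1/k_i) * sum over neighbours j of k_j;
    then averaged over all nodes in each degree class.  Isolated nodes
    are excluded (with a warning).
    """
    n, edges = as_arrays(network)
    deg = _degrees(n, edges)
    if (deg == 0).any():
        warnings.warn("isolated nodes excluded from the k_nn curve")
    s = np.zeros(n)
    np.add.at(s, edges[:, 0], deg[edges[:, 1]])
    np.add.at(s, edges[:, 1], deg[edges[:, 0]])
    ok = deg > 0
    knn_node = np.full(n, np.nan)
    knn_node[ok] = s[ok] / deg[ok]

    curves = degree_curves(network)
    sums = np.bincount(deg[ok], weights=knn_node[ok],
                       minlength=int(curves.k.max()) + 1)
    curves.knn = sums[curves.k] / curves.counts
    return curves


def fit_alpha(curves: DegreeCurves, kmin: int = DEFAULT_ALPHA_KMIN,
              min_class_size: int = DEFAULT_ALPHA_MIN_CLASS) -> PowerFit:
    """Fit <k_nn(k)> ~ k^alpha; alpha is the signed log-log slope.

    Negative alpha means disassortative mixing.  Degree classes with
    fewer than ``min_class_size`` nodes are dropped to suppress noise,
    and the fit reads the k >= ``kmin`` scaling regime (the low-degree
    head of a growing tree saturates).  Small networks that lack three
    usable classes above ``kmin`` fall back to the full degree range.
    """
    if curves.knn is None:
        raise ValueError("curves carry no k_nn component; call knn_curve")
    k, knn, cnt = curves.k, curves.knn, curves.counts
    usable = (cnt >= min_class_size) & np.isfinite(knn) & (knn > 0)
    mask = usable & (k >= kmin)
    if mask.sum() < 3:
        mask = usable                     # relax the window, keep the filter
    if mask.sum() < 3:
        raise ValueError("need >= 3 degree classes to fit alpha")
    slope, amp, err, r2 = _loglog_fit(k[mask], knn[mask])
    lo, hi = float(k[mask].min()), float(k[mask].max())
    return PowerFit(exponent=slope, amplitude=amp, k_range=(lo, hi),
                    stderr=err, r_squared=r2, n_points=int(mask.sum()))


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def clustering(network) -> Tuple[np.ndarray, float]:
    """Local clustering C_j = 2x / (k_j (k_j - 1)) and its average rho.

    ``x`` counts links among j's neighbours; nodes of degree < 2 have
    C_j = 0 and are included in the average, so a tree has rho = 0
    exactly.  Triangle counting is delegated to networkx.
    """
    import networkx as nx

    n, edges = as_arrays(network)
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(map(tuple, edges))
    cj_map = nx.clustering(g)
    cj = np.zeros(n)
    for v, c in cj_map.items():
        cj[v] = c
    return cj, float(cj.sum() / n)


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

def _double_sweep(adj: sp.csr_matrix, root: int) -> Tuple[int, int]:
    """One double-BFS sweep; returns (eccentricity found, far endpoint)."""
    d0 = _bfs_dist(adj, root)
    u = int(np.argmax(d0))
    d1 = _bfs_dist(adj, u)
    w = int(np.argmax(d1))
    return int(d1[w]), u


def diameter(network) -> int:
    """Longest shortest path.

    Exact for trees (double BFS) and for general graphs up to
    :data:`EXACT_DIAMETER_LIMIT` nodes (all-sources BFS).  Larger
    cyclic graphs get a double-sweep lower-bound estimate from the
    :data:`DIAMETER_SWEEP_ROOTS` highest-degree roots; ``summarize``
    labels that case as an estimate.
    """
    n, edges = as_arrays(network)
    adj = _adjacency(n, edges)
    _require_connected(adj)
    if n == 1:
        return 0
    if edges.shape[0] == n - 1:          # connected + N-1 edges => tree
        ecc, _ = _double_sweep(adj, 0)
        return ecc
    if n <= EXACT_DIAMETER_LIMIT:
        best = 0
        for lo in range(0, n, 512):
            d = _bfs_dist(adj, np.arange(lo, min(lo + 512, n)))
            best = max(best, int(d.max()))
        return best
    deg = _degrees(n, edges)
    roots = np.argsort(deg)[::-1][:DIAMETER_SWEEP_ROOTS]
    best = 0
    for r in roots:
        ecc, _ = _double_sweep(adj, int(r))
        best = max(best, ecc)
    return best


def _is_tree(n: int, edges: np.ndarray) -> bool:
    return edges.shape[0] == n - 1


def _tree_avg_path(n: int, edges: np.ndarray, adj: sp.csr_matrix,
                   network) -> float:
    """Exact tree path length via the edge-cut identity.

    Each edge e splits the tree into parts of size s_e and N - s_e and
    is crossed by exactly s_e (N - s_e) node pairs, so
    L = sum_e s_e (N - s_e) / C(N, 2).  Linear time.
    """
    if isinstance(network, NetworkState):
        parent = network.parent
        order = range(n - 1, 0, -1)      # children always arrive later
    else:
        from scipy.sparse.csgraph import breadth_first_order
        bfs_nodes, pred = breadth_first_order(adj, 0, directed=False,
                                              return_predecessors=True)
        parent = pred
        order = bfs_nodes[::-1]
    sizes = [1] * n
    total = 0
    for v in order:
        v = int(v)
        p = parent[v]
        if p < 0:
            continue
        sv = sizes[v]
        total += sv * (n - sv)
        sizes[p] += sv
    return total / (n * (n - 1) / 2)


def avg_path_length(network, rng=None,
                    n_samples: int = DEFAULT_LPL_SAMPLES) -> float:
    """Average shortest path length L.

    Trees are handled exactly in linear time via the edge-cut identity.
    For cyclic graphs L is estimated as the mean distance from
    ``min(N, n_samples)`` uniformly sampled BFS sources (seed-controlled
    through ``rng``); with ``n_samples >= N`` this is exact as well.
    """
    n, edges = as_arrays(network)
    adj = _adjacency(n, edges)
    _require_connected(adj)
    if n < 2:
        raise ValueError("average path length needs >= 2 nodes")
    if _is_tree(n, edges):
        return _tree_avg_path(n, edges, adj, network)
    if rng is None:
        rng = np.random.default_rng(0)
    k = min(n, n_samples)
    sources = np.arange(n) if k == n else rng.choice(n, size=k, replace=False)
    total, cnt = 0.0, 0
    for lo in range(0, k, 256):
        d = _bfs_dist(adj, sources[lo:lo + 256])
        total += d.sum()
        cnt += d.size - d.shape[0]       # drop the zero self-distances
    return total / cnt


def ultra_small_reference(n: int) -> float:
    """Ultra-small-world reference value ln(N) / ln(ln(N)).

    Defined (and monotone) only for N >= 16; smaller N is rejected to
    stay clear of the ln(ln(N)) singularity.
    """
    if n < 16:
        raise ValueError("ultra-small reference requires N >= 16")
    return math.log(n) / math.log(math.log(n))


# ---------------------------------------------------------------------------
# summary
# ---------------------------------------------------------------------------

def summarize(network,
              kmin: Optional[int] = None,
              cdf_quantile: float = DEFAULT_CDF_QUANTILE,
              alpha_min_class: int = DEFAULT_ALPHA_MIN_CLASS,
              lpl_samples: int = DEFAULT_LPL_SAMPLES,
              rng=None,
              m: Optional[int] = None,
              f: Optional[float] = None,
              seed: Optional[int] = None,
              include_clustering: bool = True) -> TopologySummary:
    """Compute one full summary row for a connected network."""
    n, edges = as_arrays(network)
    deg = _degrees(n, edges)
    curves = knn_curve((n, edges))
    beta_fit = fit_ccdf_exponent(curves, kmin=kmin, kmax_quantile=cdf_quantile)
    alpha_fit = fit_alpha(curves, min_class_size=alpha_min_class)
    if include_clustering:
        _, rho = clustering((n, edges))
    else:
        rho = float("nan")
    diam = diameter((n, edges))
    diam_exact = _is_tree(n, edges) or n <= EXACT_DIAMETER_LIMIT
    # pass the original container so a NetworkState keeps its parent info
    lpl = avg_path_length(network, rng=rng, n_samples=lpl_samples)
    lpl_exact = _is_tree(n, edges) or lpl_samples >= n
    return TopologySummary(
        n_nodes=n,
        n_edges=int(edges.shape[0]),
        alpha=alpha_fit.exponent,
        rho=rho,
        mean_degree=2.0 * edges.shape[0] / n,
        diameter=diam,
        avg_path=lpl,
        kmax=int(deg.max()),
        beta=beta_fit.exponent,
        diameter_exact=diam_exact,
        avg_path_exact=lpl_exact,
        ultra_small_ref=ultra_small_reference(n) if n >= 16 else float("nan"),
        beta_fit=beta_fit,
        alpha_fit=alpha_fit,
        m=m, f=f, seed=seed,
    )
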