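"""Graph-theoretic properties of binary brain networks.

All metrics are computed directly on 0/1 adjacency matrices (symmetric,
zero diagonal):

* global — average degree, mean clustering coefficient Cp, characteristic
  path length Lp, global efficiency Eglob, local efficiency Eloc, and the
  small-world triplet gamma = Cp / <Cp_rand>, lambda = Lp / <Lp_rand>,
  sigma = gamma / lambda, normalized against an ensemble of
  degree-preserving (Maslov–Sneppen) rewired graphs;
* nodal — degree centrality, betweenness centrality (Brandes), nodal
  clustering, nodal efficiency, and nodal local efficiency.

Disconnected graphs: Lp is the mean distance over *connected* ordered
pairs, with the infinite-pair fraction reported alongside; efficiency
metrics treat unreachable pairs as zero contribution and are the
disconnection-robust primary measures.

Metrics are aggregated across a sparsity grid by the trapezoidal rule
("AUC across thresholds"), the scale on which group comparisons and
classification features are defined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import BinaryGraphEnsemble

__all__ = [
    "nodal_degree", "clustering", "shortest_paths",
    "characteristic_path_length", "global_efficiency", "nodal_efficiency",
    "local_efficiency", "betweenness", "random_rewire", "small_world",
    "MetricSettings", "MetricTable", "metrics_over_ensemble",
    "cohort_metric_tables", "GLOBAL_METRICS", "NODAL_METRICS",
]

GLOBAL_METRICS = ("average_degree", "clustering_coefficient",
                  "characteristic_path_length", "global_efficiency",
                  "local_efficiency", "sigma", "lambda", "gamma")
NODAL_METRICS = ("degree", "betweenness", "nodal_clustering",
                 "nodal_efficiency", "nodal_local_efficiency")


def _validate(adj: np.ndarray) -> np.ndarray:
    adj = np.asarray(adj)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if not np.isin(adj, (0, 1)).all():
        raise ValueError("adjacency must be 0/1")
    if np.diag(adj).any():
        raise ValueError("adjacency diagonal must be zero")
    return adj.astype(np.int64)


def nodal_degree(adj: np.ndarray) -> np.ndarray:
    """Row sums of the adjacency (number of neighbors per node)."""
    return _validate(adj).sum(axis=1)


def clustering(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal clustering coefficients and their mean Cp.

    CC(v) = 2 * triangles(v) / (deg(v) * (deg(v) - 1)), zero for deg < 2.
    """
    a = _validate(adj)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2
    denom = deg * (deg - 1)
    cc = np.divide(2 * triangles, denom, out=np.zeros(len(a), dtype=float),
                   where=denom > 0)
    return cc, float(cc.mean()) if len(cc) else float("nan")


def shortest_paths(adj: np.ndarray) -> np.ndarray:
    """All-pairs hop distances by simultaneous BFS (boolean frontier
    expansion); unreachable pairs are +inf."""
    a = _validate(adj).astype(bool)
    r = a.shape[0]
    dist = np.full((r, r), np.inf)
    np.fill_diagonal(dist, 0.0)
    reached = np.eye(r, dtype=bool)
    frontier = np.eye(r, dtype=bool)
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier @ a) & ~reached
        dist[frontier] = d
        reached |= frontier
    return dist


def characteristic_path_length(dist: np.ndarray) -> tuple[float, bool, float]:
    """Mean finite off-diagonal distance.

    Returns ``(Lp, disconnected_flag, infinite_pair_fraction)``; Lp is NaN
    (and the flag set) when no pair is connected.
    """
    r = dist.shape[0]
    off = ~np.eye(r, dtype=bool)
    vals = dist[off]
    finite = np.isfinite(vals)
    frac_inf = float((~finite).mean()) if len(vals) else 0.0
    if not finite.any():
        return float("nan"), True, frac_inf
    return float(vals[finite].mean()), bool(frac_inf > 0), frac_inf


def global_efficiency(dist: np.ndarray) -> float:
    """Mean inverse distance over ordered pairs (0 for unreachable)."""
    r = dist.shape[0]
    if r < 2:
        return 0.0
    off = ~np.eye(r, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist[off]
    inv[~np.isfinite(inv)] = 0.0
    return float(inv.mean())


def nodal_efficiency(dist: np.ndarray) -> np.ndarray:
    """Per node: mean inverse distance to every other node."""
    r = dist.shape[0]
    if r < 2:
        return np.zeros(r)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (r - 1)


def local_efficiency(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Nodal local efficiency (Eglob of each node's neighbor-induced
    subgraph) and its mean Eloc."""
    a = _validate(adj)
    r = a.shape[0]
    out = np.zeros(r)
    for v in range(r):
        nb = np.flatnonzero(a[v])
        if len(nb) < 2:
            continue
        sub = a[np.ix_(nb, nb)]
        out[v] = global_efficiency(shortest_paths(sub))
    return out, float(out.mean()) if r else float("nan")


def betweenness(adj: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Brandes betweenness centrality over unordered pairs.

    Returns ``(raw, normalized)``: raw sums sigma_st(v)/sigma_st over
    unordered pairs {s, t} not containing v; normalized divides by
    (R-1)(R-2)/2, the number of such pairs.
    """
    a = _validate(adj)
    r = a.shape[0]
    neighbors = [np.flatnonzero(a[v]) for v in range(r)]
    bc = np.zeros(r)
    for s in range(r):
        # single-source BFS with path counting
        sigma = np.zeros(r)
        sigma[s] = 1.0
        dist = np.full(r, -1)
        dist[s] = 0
        order: list[int] = []
        queue = [s]
        preds: list[list[int]] = [[] for _ in range(r)]
        while queue:
            v = queue.pop(0)
            order.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(r)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    bc /= 2.0  # each unordered pair counted from both endpoints
    denom = (r - 1) * (r - 2) / 2
    norm = bc / denom if denom > 0 else np.zeros(r)
    return bc, norm


def random_rewire(adj: np.ndarray, n_swaps: int | None = None,
                  seed: int | np.random.Generator = 0,
                  max_tries_factor: int = 50) -> np.ndarray:
    """Degree-preserving randomization by Maslov–Sneppen double-edge swaps.

    Picks two edges (a, b) and (c, d) and rewires them to (a, d), (c, b)
    whenever that keeps the graph simple.  ``n_swaps`` defaults to
    10x the edge count.  If no valid swap can be found (e.g. a triangle),
    the input is returned unchanged with a warning.
    """
    a = _validate(adj).copy()
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    iu, ju = np.triu_indices(a.shape[0], k=1)
    mask = a[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    if len(edges) < 2:
        warnings.warn("fewer than 2 edges; graph returned unchanged",
                      RuntimeWarning)
        return a
    if n_swaps is None:
        n_swaps = 10 * len(edges)
    done = 0
    tries = 0
    max_tries = max_tries_factor * max(n_swaps, 1)
    while done < n_swaps and tries < max_tries:
        tries += 1
        e1, e2 = rng.integers(0, len(edges), size=2)
        if e1 == e2:
            continue
        x1, y1 = edges[e1]
        x2, y2 = edges[e2]
        if rng.random() < 0.5:
            x2, y2 = y2, x2
        # propose (x1, y2) and (x2, y1)
        if len({x1, y1, x2, y2}) < 4:
            continue
        if a[x1, y2] or a[x2, y1]:
            continue
        a[x1, y1] = a[y1, x1] = 0
        a[x2, y2] = a[y2, x2] = 0
        a[x1, y2] = a[y2, x1] = 1
        a[x2, y1] = a[y1, x2] = 1
        edges[e1] = (min(x1, y2), max(x1, y2))
        edges[e2] = (min(x2, y1), max(x2, y1))
        done += 1
    if done == 0:
        warnings.warn("no valid degree-preserving swap found; graph "
                      "returned unchanged", RuntimeWarning)
    return a


def small_world(adj: np.ndarray, n_random: int = 100,
                n_swaps: int | None = None,
                seed: int | np.random.Generator = 0) -> dict[str, float]:
    """Small-world coefficients against a rewired null ensemble.

    Returns gamma = Cp/<Cp_rand>, lambda = Lp/<Lp_rand>, sigma =
    gamma/lambda, plus the ensemble means and SDs.  With ``n_swaps=0`` the
    ensemble is the graph itself and all three ratios are exactly 1.
    Undefined ratios (zero ensemble mean, disconnected Lp) are NaN.
    """
    a = _validate(adj)
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    _, cp = clustering(a)
    lp, _, _ = characteristic_path_length(shortest_paths(a))
    cps, lps = [], []
    for _ in range(n_random):
        if n_swaps == 0:
            rnd = a
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                rnd = random_rewire(a, n_swaps=n_swaps, seed=rng)
        _, cp_r = clustering(rnd)
        lp_r, _, _ = characteristic_path_length(shortest_paths(rnd))
        cps.append(cp_r)
        lps.append(lp_r)
    cp_rand = float(np.mean(cps))
    lp_rand = float(np.nanmean(lps)) if np.isfinite(lps).any() else float("nan")
    gamma = cp / cp_rand if cp_rand > 0 else float("nan")
    lam = lp / lp_rand if lp_rand and np.isfinite(lp_rand) and lp_rand > 0 \
        else float("nan")
    sigma = gamma / lam if lam and np.isfinite(lam) and np.isfinite(gamma) \
        else float("nan")
    return {"sigma": sigma, "lambda": lam, "gamma": gamma,
            "cp": cp, "lp": lp, "cp_rand_mean": cp_rand,
            "lp_rand_mean": lp_rand,
            "cp_rand_sd": float(np.std(cps)),
            "lp_rand_sd": float(np.nanstd(lps))}


@dataclass
class MetricSettings:
    """Knobs for ensemble metric computation.

    ``n_random`` rewired graphs per threshold for small-world
    normalization; ``swaps_per_edge`` double-edge swaps per randomization;
    ``seed`` drives the rewiring RNG.
    """

    n_random: int = 100
    swaps_per_edge: int = 10
    seed: int = 0
    compute_small_world: bool = True


@dataclass
class MetricTable:
    """Per-subject metrics at every threshold plus grid-AUC aggregates."""

    subject_id: str
    sparsity_grid: np.ndarray
    global_metrics: pd.DataFrame                  # thresholds x metric
    nodal_metrics: dict[str, pd.DataFrame]        # metric -> thresholds x ROI
    auc_global: pd.Series = field(default=None)
    auc_nodal: pd.DataFrame = field(default=None)  # metric x ROI
    excluded_thresholds: dict[str, list[float]] = field(default_factory=dict)

    def nodal_auc_flat(self) -> pd.Series:
        """AUC nodal metrics as a flat series keyed 'metric.roi'."""
        out = {}
        for metric in self.auc_nodal.index:
            for roi in self.auc_nodal.columns:
                out[f"{metric}.{roi}"] = self.auc_nodal.loc[metric, roi]
        return pd.Series(out)


def _grid_auc(grid: np.ndarray, values: np.ndarray) -> tuple[float, list[float]]:
    """Trapezoidal AUC over the grid, skipping undefined thresholds."""
    valid = np.isfinite(values)
    excluded = [float(s) for s in grid[~valid]]
    if valid.sum() < 2:
        return float("nan"), excluded
    return float(np.trapezoid(values[valid], grid[valid])), excluded


def metrics_over_ensemble(ensemble: BinaryGraphEnsemble,
                          settings: MetricSettings | None = None) -> MetricTable:
    """All global and nodal metrics at every sparsity threshold, plus the
    trapezoid AUC of each metric across the grid."""
    settings = settings or MetricSettings()
    rng = np.random.default_rng(settings.seed)
    grid = ensemble.sparsity_grid
    rois = list(ensemble.roi_names)
    glob_rows = []
    nodal = {m: np.zeros((len(grid), len(rois))) for m in NODAL_METRICS}
    for k in range(len(grid)):
        a = ensemble.adjacency_stack[k].astype(np.int64)
        deg = nodal_degree(a)
        cc, cp = clustering(a)
        dist = shortest_paths(a)
        lp, _, _ = characteristic_path_length(dist)
        eglob = global_efficiency(dist)
        ne = nodal_efficiency(dist)
        nle, eloc = local_efficiency(a)
        bc, _ = betweenness(a)
        if settings.compute_small_world:
            n_swaps = settings.swaps_per_edge * max(int(a.sum() // 2), 1)
            sw = small_world(a, n_random=settings.n_random,
                             n_swaps=n_swaps, seed=rng)
        else:
            sw = {"sigma": np.nan, "lambda": np.nan, "gamma": np.nan}
        glob_rows.append({
            "average_degree": float(deg.mean()),
            "clustering_coefficient": cp,
            "characteristic_path_length": lp,
            "global_efficiency": eglob,
            "local_efficiency": eloc,
            "sigma": sw["sigma"], "lambda": sw["lambda"],
            "gamma": sw["gamma"],
        })
        nodal["degree"][k] = deg
        nodal["betweenness"][k] = bc
        nodal["nodal_clustering"][k] = cc
        nodal["nodal_efficiency"][k] = ne
        nodal["nodal_local_efficiency"][k] = nle
    global_df = pd.DataFrame(glob_rows, index=grid)
    nodal_dfs = {m: pd.DataFrame(v, index=grid, columns=rois)
                 for m, v in nodal.items()}

    excluded: dict[str, list[float]] = {}
    auc_g = {}
    for metric in global_df.columns:
        auc_g[metric], ex = _grid_auc(grid, global_df[metric].to_numpy())
        if ex:
            excluded[metric] = ex
    auc_n = pd.DataFrame(index=list(NODAL_METRICS), columns=rois, dtype=float)
    for metric, df in nodal_dfs.items():
        for roi in rois:
            auc_n.loc[metric, roi], ex = _grid_auc(grid,
                                                   df[roi].to_numpy())
            if ex:
                excluded[f"{metric}.{roi}"] = ex
    return MetricTable(subject_id=ensemble.subject_id, sparsity_grid=grid,
                       global_metrics=global_df, nodal_metrics=nodal_dfs,
                       auc_global=pd.Series(auc_g),
                       auc_nodal=auc_n, excluded_thresholds=excluded)


def cohort_metric_tables(ensembles: list[BinaryGraphEnsemble],
                         settings: MetricSettings | None = None,
                         ) -> tuple[pd.DataFrame, pd.DataFrame, list[MetricTable]]:
    """Metric tables for a cohort of ensembles.

    Returns ``(global_auc, nodal_auc, tables)`` where ``global_auc`` is a
    subjects x global-metric frame and ``nodal_auc`` a subjects x
    'metric.roi' frame, both on the AUC-across-thresholds scale.
    """
    tables = [metrics_over_ensemble(e, settings) for e in ensembles]
    global_auc = pd.DataFrame({t.subject_id: t.auc_global
                               for t in tables}).T
    nodal_auc = pd.DataFrame({t.subject_id: t.nodal_auc_flat()
                              for t in tables}).T
    return global_auc, nodal_auc, tables
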