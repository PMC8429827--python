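"""Twelve weighted graph measures on a connectivity matrix.

Conventions (standard for correlation-weighted brain networks, stated
here because weighted generalizations are not unique):

* edge length = 1 / weight; weight 0 means no edge;
* distances are weighted shortest-path lengths; infinite (unreachable)
  distances are excluded from node-level means, and contribute 0 to
  efficiency (1/inf = 0);
* per-node path length = mean finite distance to the other nodes;
  characteristic path length = mean of per-node path lengths;
* per-node eccentricity = max finite distance; the graph-level
  eccentricity scalar is the mean of node eccentricities, whose min and
  max are the radius and diameter;
* clustering is the Onnela geometric-mean triangle form with weights
  rescaled by the global maximum weight; transitivity is the matching
  ratio of summed triangle intensities to summed k(k-1);
* assortativity correlates the binary degrees at the two ends of each
  edge, using edge weights as frequencies; zero-variance endpoint
  degrees (e.g. regular graphs) give the undefined sentinel NaN, never
  a silent 0;
* modularity is the weighted Newman Q of the best of 10 seeded Louvain
  restarts at resolution 1;
* the small-worldness index is sigma = (C/C_rand) / (L/L_rand) against
  an ensemble of degree-preserving rewired references with the original
  weight multiset randomly reassigned to the rewired edges.

Functions accept a :class:`~scnet.network.ConnectivityMatrix` or a bare
symmetric non-negative weight array.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import shortest_path as _csgraph_shortest_path

from .errors import (
    NullDegenerateError,
    RewiringError,
    UndefinedMeasureError,
    ValidationError,
)
from .network import ConnectivityMatrix
from .seeds import derive_stage_seeds

MEASURE_NAMES = (
    "average_strength",
    "radius",
    "diameter",
    "eccentricity",
    "characteristic_path_length",
    "global_efficiency",
    "local_efficiency",
    "mean_clustering_coefficient",
    "transitivity",
    "modularity",
    "assortativity_coefficient",
    "small_worldness_index",
)


@dataclass(frozen=True)
class NullModelSpec:
    """Random-reference ensemble for the small-worldness index."""

    n_random: int = 100
    n_iter: int = 10  # rewiring iterations per edge
    seed: int | None = None

    def __post_init__(self):
        if self.n_random <= 0 or self.n_iter <= 0:
            raise ValidationError("null-model counts must be strictly positive")


def _weights(conn) -> np.ndarray:
    if isinstance(conn, ConnectivityMatrix):
        return conn.weights
    w = np.asarray(conn, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValidationError("weight matrix must be square")
    if np.abs(w - w.T).max(initial=0.0) > 1e-10:
        raise ValidationError("weight matrix must be symmetric")
    if w.min(initial=0.0) < 0:
        raise ValidationError("weights must be non-negative")
    return w


# ----------------------------------------------------------------- distances


def shortest_path_lengths(conn) -> np.ndarray:
    """Pairwise weighted shortest-path distances (edge length 1/weight).

    Unreachable pairs are ``inf``; the diagonal is 0.
    """
    w = _weights(conn)
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return _csgraph_shortest_path(lengths, method="D", directed=False)


def path_measures(conn) -> dict[str, float]:
    """Characteristic path length, eccentricity, radius, diameter and
    global efficiency from the distance matrix.

    Isolated nodes (no finite distance to any other node) are excluded
    from the node-level means; unreachable pairs contribute 0 to
    efficiency.
    """
    d = shortest_path_lengths(conn)
    n = d.shape[0]
    if n < 2:
        raise UndefinedMeasureError("path measures undefined on a singleton")
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    reached = finite.sum(axis=1)
    ok = reached > 0
    if not ok.any():
        raise UndefinedMeasureError("graph has no edges")
    dsum = np.where(finite, d, 0.0).sum(axis=1)
    node_pl = dsum[ok] / reached[ok]
    node_ecc = np.where(finite, d, -np.inf).max(axis=1)[ok]
    with np.errstate(divide="ignore"):
        inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
    return {
        "characteristic_path_length": float(node_pl.mean()),
        "eccentricity": float(node_ecc.mean()),
        "radius": float(node_ecc.min()),
        "diameter": float(node_ecc.max()),
        "global_efficiency": float(inv.sum() / (n * (n - 1))),
    }


def global_efficiency(conn) -> float:
    return path_measures(conn)["global_efficiency"]


def local_efficiency(conn) -> float:
    """Mean over nodes of the global efficiency of each node's
    neighborhood subgraph (neighbors of i, original weights)."""
    w = _weights(conn)
    n = w.shape[0]
    if n < 2:
        raise UndefinedMeasureError("local efficiency undefined on a singleton")
    effs = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i] > 0)
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = shortest_path_lengths(sub)
        m = nbrs.size
        off = ~np.eye(m, dtype=bool)
        finite = np.isfinite(d) & off
        with np.errstate(divide="ignore"):
            inv = np.where(finite, 1.0 / np.where(finite, d, 1.0), 0.0)
        effs[i] = inv.sum() / (m * (m - 1))
    return float(effs.mean())


# ------------------------------------------------------ triangles & strength


def clustering_and_transitivity(conn) -> tuple[float, float]:
    """Onnela weighted clustering (mean over nodes) and the matching
    weighted transitivity.

    Weights are rescaled by the global maximum before taking cube roots;
    nodes with binary degree < 2 have clustering 0 and are included in
    the mean.
    """
    w = _weights(conn)
    n = w.shape[0]
    wmax = w.max(initial=0.0)
    if wmax == 0 or n < 3:
        return 0.0, 0.0
    what = np.cbrt(w / wmax)
    tri = np.diag(what @ what @ what)  # 2 x summed triangle intensity per node
    k = (w > 0).sum(axis=1)
    denom = k * (k - 1)
    ci = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    total = denom.sum()
    transitivity = float(tri.sum() / total) if total > 0 else 0.0
    return float(ci.mean()), transitivity


def strength_and_assortativity(conn) -> tuple[float, float]:
    """Average node strength and the weighted degree assortativity.

    Strength is the row sum of weights.  Assortativity is the Pearson
    correlation of the binary degrees at the two endpoints of each edge,
    with edge weights as frequencies; it is NaN (undefined sentinel)
    when there are < 2 edges or the endpoint degrees have no variance.
    """
    w = _weights(conn)
    strength = float(w.sum(axis=1).mean()) if w.size else 0.0
    iu, ju = np.triu_indices(w.shape[0], k=1)
    mask = w[iu, ju] > 0
    ew = w[iu, ju][mask]
    if ew.size < 2:
        return strength, float("nan")
    deg = (w > 0).sum(axis=1).astype(float)
    x, y = deg[iu[mask]], deg[ju[mask]]
    wsum = ew.sum()
    mxy = (ew * (x + y)).sum() / (2 * wsum)
    var = (ew * (x**2 + y**2)).sum() / (2 * wsum) - mxy**2
    if var <= 1e-15:
        return strength, float("nan")
    cov = (ew * x * y).sum() / wsum - mxy**2
    return strength, float(cov / var)


# ------------------------------------------------------------------ modularity

_N_LOUVAIN_RESTARTS = 10


def modularity(conn, seed: int = 0) -> float:
    """Weighted Newman modularity of the best of 10 seeded Louvain
    restarts at resolution 1."""
    w = _weights(conn)
    if w.max(initial=0.0) <= 0:
        raise UndefinedMeasureError("modularity undefined without edges")
    g = nx.from_numpy_array(w)
    best = -np.inf
    for i in range(_N_LOUVAIN_RESTARTS):
        restart_seed = derive_stage_seeds(seed, f"louvain:{i}")
        parts = nx.community.louvain_communities(
            g, weight="weight", resolution=1.0, seed=restart_seed
        )
        q = nx.community.modularity(g, parts, weight="weight")
        best = max(best, q)
    return float(best)


# -------------------------------------------------------------- random nulls


def random_reference(conn, spec: NullModelSpec) -> np.ndarray:
    """Degree-preserving random reference: Maslov-Sneppen double-edge
    swaps on the binary topology, then random reassignment of the
    original weight multiset to the rewired edge set.

    Returns a weight array with the same binary degree sequence and the
    same weight multiset.  A complete graph admits no swap; its topology
    is returned unchanged with weights permuted.
    """
    w = _weights(conn)
    n = w.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = w[iu, ju] > 0
    edges = list(zip(iu[mask].tolist(), ju[mask].tolist()))
    weights_pool = w[iu, ju][mask]
    m = len(edges)
    if m < 4:
        raise RewiringError(f"need at least 4 edges to rewire, got {m}")
    rng = np.random.default_rng(spec.seed)
    if m < n * (n - 1) // 2:  # a complete graph cannot be rewired
        edge_set = {frozenset(e) for e in edges}
        target = spec.n_iter * m
        max_tries = 50 * target
        swaps = tries = 0
        while swaps < target and tries < max_tries:
            tries += 1
            e1, e2 = rng.integers(0, m, size=2)
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if rng.integers(0, 2):
                c, d = d, c
            if a == c or a == d or b == c or b == d:
                continue
            new1, new2 = frozenset((a, d)), frozenset((c, b))
            if new1 in edge_set or new2 in edge_set:
                continue
            edge_set.discard(frozenset((a, b)))
            edge_set.discard(frozenset((c, d)))
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = (a, d)
            edges[e2] = (c, b)
            swaps += 1
    shuffled = rng.permutation(weights_pool)
    out = np.zeros_like(w)
    for (a, b), wt in zip(edges, shuffled):
        out[a, b] = out[b, a] = wt
    return out


def small_worldness(conn, spec: NullModelSpec) -> float:
    """Small-worldness index sigma = (C/C_rand) / (L/L_rand).

    C is the mean Onnela clustering and L the characteristic path
    length; C_rand, L_rand are their means over the random-reference
    ensemble.
    """
    w = _weights(conn)
    c_obs, _ = clustering_and_transitivity(w)
    l_obs = path_measures(w)["characteristic_path_length"]
    seed = spec.seed if spec.seed is not None else 0
    c_rand = np.empty(spec.n_random)
    l_rand = np.empty(spec.n_random)
    for k in range(spec.n_random):
        ref = random_reference(
            w, NullModelSpec(1, spec.n_iter, derive_stage_seeds(seed, f"ref:{k}"))
        )
        c_rand[k], _ = clustering_and_transitivity(ref)
        l_rand[k] = path_measures(ref)["characteristic_path_length"]
    c_bar, l_bar = float(c_rand.mean()), float(l_rand.mean())
    if not (np.isfinite(c_bar) and np.isfinite(l_bar)) or c_bar <= 0 or l_bar <= 0:
        raise NullDegenerateError(
            f"degenerate null ensemble (C_rand={c_bar}, L_rand={l_bar})"
        )
    return float((c_obs / c_bar) / (l_obs / l_bar))


# ------------------------------------------------------------------- assembly


@dataclass(frozen=True)
class MeasureSet:
    """The twelve scalar graph measures of one network."""

    average_strength: float
    radius: float
    diameter: float
    eccentricity: float
    characteristic_path_length: float
    global_efficiency: float
    local_efficiency: float
    mean_clustering_coefficient: float
    transitivity: float
    modularity: float
    assortativity_coefficient: float
    small_worldness_index: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in MEASURE_NAMES}


def measure_set(conn, null_spec: NullModelSpec | None = None, seed: int = 0) -> MeasureSet:
    """Assemble all twelve measures; deterministic given ``seed``."""
    w = _weights(conn)
    null_spec = null_spec or NullModelSpec()
    pm = path_measures(w)
    strength, assort = strength_and_assortativity(w)
    clust, trans = clustering_and_transitivity(w)
    q = modularity(w, seed=derive_stage_seeds(seed, "modularity"))
    sw_spec = NullModelSpec(
        null_spec.n_random, null_spec.n_iter, derive_stage_seeds(seed, "null")
    )
    sigma = small_worldness(w, sw_spec)
    return MeasureSet(
        average_strength=strength,
        radius=pm["radius"],
        diameter=pm["diameter"],
        eccentricity=pm["eccentricity"],
        characteristic_path_length=pm["characteristic_path_length"],
        global_efficiency=pm["global_efficiency"],
        local_efficiency=local_efficiency(w),
        mean_clustering_coefficient=clust,
        transitivity=trans,
        modularity=q,
        assortativity_coefficient=assort,
        small_worldness_index=sigma,
    )
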