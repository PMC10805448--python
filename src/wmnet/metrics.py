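"""Graph-theoretic properties of structural brain networks.

Implements the metric set used throughout connectomics for 90-node structural
networks: shortest-path distance matrices, global efficiency (Eg), clustering
coefficient (Cp), local efficiency (Eloc), characteristic path length (Lp),
nodal efficiency (Enodal), nodal degree, degree-preserving (Maslov-Sneppen)
null ensembles, the small-world ratios gamma/lambda/sigma, and degree-based
hub detection.

Conventions
-----------
* Weighted shortest paths run over edge *lengths* derived from FA weights.
  The default mapping is ``length = 1/weight`` (a strong connection is a short
  link); ``one_minus`` (``length = 1 - weight``) is available as an option.
* Unreachable pairs are held as ``inf`` in the distance matrix but never enter
  arithmetic: efficiency-type metrics give them zero contribution (the harmonic
  convention) and Lp averages reachable pairs only, reporting the unreachable
  count alongside.
* Weighted clustering uses the Onnela geometric-mean formulation on weights
  normalised by the network maximum; binary graphs use the triangle-count
  formula 2 t_i / (k_i (k_i - 1)).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .network import ConnectivityMatrix

WEIGHT_TO_LENGTH_MODES = ("reciprocal", "one_minus")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """All-pairs shortest-path lengths; ``inf`` marks unreachable pairs."""

    values: np.ndarray = field(repr=False)
    mode: str = "binary"  # "binary" (hop counts) or "weighted"

    @property
    def n_unreachable_pairs(self) -> int:
        """Number of unordered unreachable pairs (diagonal excluded)."""
        off = ~np.eye(self.values.shape[0], dtype=bool)
        return int(np.isinf(self.values[off]).sum()) // 2


def _lengths(matrix: ConnectivityMatrix, weight_to_length: str) -> np.ndarray:
    w = matrix.values
    if (w < 0).any():
        raise ValueError("negative edge weights are not allowed")
    if weight_to_length not in WEIGHT_TO_LENGTH_MODES:
        raise ValueError(f"weight_to_length must be one of {WEIGHT_TO_LENGTH_MODES}")
    with np.errstate(divide="ignore"):
        if weight_to_length == "reciprocal":
            lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
        else:
            lengths = np.where(w > 0, 1.0 - w, 0.0)
            # a weight of exactly 1 would give a free (zero-length) edge
            lengths[(w > 0) & (lengths <= 0)] = np.finfo(float).tiny
    return lengths


def distance_matrix(
    matrix: ConnectivityMatrix, weight_to_length: str = "reciprocal"
) -> DistanceMatrix:
    """Shortest-path lengths for one network.

    Binary networks (FA_bin) give hop counts; weighted networks (FA_wei) give
    shortest paths over mapped edge lengths (default ``1/w``).
    """
    if matrix.is_weighted():
        lengths = _lengths(matrix, weight_to_length)
        d = shortest_path(lengths, method="D", directed=False, unweighted=False)
        return DistanceMatrix(d, "weighted")
    d = shortest_path(matrix.values != 0, method="D", directed=False, unweighted=True)
    return DistanceMatrix(d, "binary")


# ---------------------------------------------------------------------------
# global and nodal metrics
# ---------------------------------------------------------------------------

@dataclass
class GlobalMetrics:
    Eg: float
    Cp: float
    Eloc: float
    Lp: float  # NaN when no pair is reachable
    n_unreachable_pairs: int

    @property
    def lp_defined(self) -> bool:
        return not np.isnan(self.Lp)


@dataclass
class NodalMetrics:
    Enodal: np.ndarray = field(repr=False)  # (n,)
    degree: np.ndarray = field(repr=False)  # (n,) ints


def _inverse_distances(d: np.ndarray) -> np.ndarray:
    """1/d with zeros on the diagonal and for unreachable pairs."""
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    inv[np.eye(n, dtype=bool)] = 0.0
    return inv


def _subgraph_efficiency(sub: np.ndarray, weighted: bool,
                         weight_to_length: str) -> float:
    """Mean inverse shortest-path length over ordered pairs of a small subgraph."""
    m = sub.shape[0]
    if m < 2:
        return 0.0
    if weighted:
        with np.errstate(divide="ignore"):
            if weight_to_length == "reciprocal":
                lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
            else:
                lengths = np.where(sub > 0, 1.0 - sub, 0.0)
                lengths[(sub > 0) & (lengths <= 0)] = np.finfo(float).tiny
        d = shortest_path(lengths, method="D", directed=False, unweighted=False)
    else:
        d = shortest_path(sub != 0, method="D", directed=False, unweighted=True)
    inv = _inverse_distances(d)
    return float(inv.sum() / (m * (m - 1)))


def _clustering(matrix: ConnectivityMatrix) -> np.ndarray:
    """Per-node clustering coefficient; zero for degree < 2."""
    w = matrix.values
    k = (w != 0).sum(axis=1)
    denom = k * (k - 1)
    if matrix.is_weighted():
        wmax = w.max()
        if wmax <= 0:
            return np.zeros(w.shape[0])
        cbrt = np.cbrt(w / wmax)
        tri = np.diagonal(cbrt @ cbrt @ cbrt)
    else:
        a = (w != 0).astype(float)
        tri = np.diagonal(a @ a @ a)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return c


def global_metrics(
    matrix: ConnectivityMatrix,
    distances: DistanceMatrix | None = None,
    weight_to_length: str = "reciprocal",
) -> GlobalMetrics:
    """Eg, Cp, Eloc and Lp for one network.

    An all-zero (empty) network is not an error: it returns zero efficiencies
    and an undefined (NaN) characteristic path length.
    """
    if distances is None:
        distances = distance_matrix(matrix, weight_to_length)
    d = distances.values
    n = d.shape[0]
    inv = _inverse_distances(d)
    eg = float(inv.sum() / (n * (n - 1)))

    cp = float(_clustering(matrix).mean())

    # local efficiency: efficiency of each node's neighbour-induced subgraph
    w = matrix.values
    adj = w != 0
    eloc_terms = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(adj[i])
        if nbrs.size < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        eloc_terms[i] = _subgraph_efficiency(sub, matrix.is_weighted(),
                                             weight_to_length)
    eloc = float(eloc_terms.mean())

    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(d) & off
    lp = float(d[reachable].mean()) if reachable.any() else float("nan")
    return GlobalMetrics(eg, cp, eloc, lp, distances.n_unreachable_pairs)


def nodal_metrics(
    matrix: ConnectivityMatrix,
    distances: DistanceMatrix | None = None,
    weight_to_length: str = "reciprocal",
) -> NodalMetrics:
    """Nodal efficiency and binary degree per region.

    ``Enodal(i)`` is the mean of ``1/d(i, j)`` over the other n-1 nodes
    (unreachable j contribute zero), so the node-mean of Enodal equals Eg.
    """
    if distances is None:
        distances = distance_matrix(matrix, weight_to_length)
    inv = _inverse_distances(distances.values)
    n = inv.shape[0]
    enodal = inv.sum(axis=1) / (n - 1)
    return NodalMetrics(enodal, matrix.degrees())


# ---------------------------------------------------------------------------
# degree-preserving null ensemble and small-worldness
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    n_null: int
    seed: int | None
    per_null: list[GlobalMetrics] = field(repr=False)
    C_rand: float = 0.0
    L_rand: float = 0.0


class RewiringError(RuntimeError):
    """Raised when a graph cannot be rewired (too small, complete, degenerate)."""


def rewire_degree_preserving(
    values: np.ndarray, rng: np.random.Generator, swaps_per_edge: int = 10,
    max_attempt_factor: int = 100,
) -> np.ndarray:
    """One degree-preserving randomisation by double-edge swaps.

    Two edges (a, b) and (c, d) are replaced by (a, d) and (c, b), each edge
    carrying its weight along, so the degree sequence and the multiset of edge
    weights are preserved exactly.  The target is ``swaps_per_edge * n_edges``
    accepted swaps.
    """
    n = values.shape[0]
    iu, ju = np.nonzero(np.triu(values, 1))
    m = iu.size
    if m < 2:
        raise RewiringError("graph has fewer than two edges; nothing to rewire")
    if m == n * (n - 1) // 2:
        raise RewiringError("complete graph has no eligible double-edge swaps")
    edges = np.stack([iu, ju], axis=1)
    weights = values[iu, ju].copy()
    edge_set = {(int(a), int(b)) for a, b in edges}

    target = swaps_per_edge * m
    accepted = 0
    attempts = 0
    max_attempts = max_attempt_factor * target
    # draw proposal randomness in batches; apply sequentially
    batch = max(1024, target)
    while accepted < target:
        pick = rng.integers(0, m, size=(batch, 2))
        flip = rng.random(batch) < 0.5
        for (e1, e2), fl in zip(pick, flip):
            attempts += 1
            if attempts > max_attempts:
                raise RewiringError(
                    f"rewiring stalled after {attempts} attempts "
                    f"({accepted}/{target} swaps accepted)"
                )
            if e1 == e2:
                continue
            a, b = edges[e1]
            c, d = edges[e2]
            if fl:
                c, d = d, c
            # propose (a, d) and (c, b)
            if a == d or c == b:
                continue
            new1 = (min(a, d), max(a, d))
            new2 = (min(c, b), max(c, b))
            if new1 in edge_set or new2 in edge_set or new1 == new2:
                continue
            edge_set.discard((min(a, b), max(a, b)))
            edge_set.discard((min(edges[e2][0], edges[e2][1]),
                              max(edges[e2][0], edges[e2][1])))
            edge_set.add(new1)
            edge_set.add(new2)
            edges[e1] = new1
            edges[e2] = new2
            accepted += 1
            if accepted >= target:
                break

    out = np.zeros_like(values)
    out[edges[:, 0], edges[:, 1]] = weights
    out[edges[:, 1], edges[:, 0]] = weights
    return out


def null_ensemble(
    matrix: ConnectivityMatrix,
    n_null: int = 100,
    swaps_per_edge: int = 10,
    seed: int | None = None,
    weight_to_length: str = "reciprocal",
) -> NullEnsemble:
    """Ensemble of degree-matched random networks with their Cp and Lp.

    Every null preserves the empirical degree sequence exactly (and, for
    weighted input, the multiset of edge weights).  ``C_rand`` and ``L_rand``
    are the ensemble means used by the small-world ratios.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng(seed)
    per_null: list[GlobalMetrics] = []
    for _ in range(n_null):
        null_values = rewire_degree_preserving(matrix.values, rng, swaps_per_edge)
        null_matrix = ConnectivityMatrix(matrix.subject_id, matrix.kind, null_values)
        d = distance_matrix(null_matrix, weight_to_length)
        n = d.values.shape[0]
        inv = _inverse_distances(d.values)
        off = ~np.eye(n, dtype=bool)
        reachable = np.isfinite(d.values) & off
        lp = float(d.values[reachable].mean()) if reachable.any() else float("nan")
        cp = float(_clustering(null_matrix).mean())
        per_null.append(GlobalMetrics(float(inv.sum() / (n * (n - 1))), cp,
                                      float("nan"), lp, d.n_unreachable_pairs))
    c_rand = float(np.mean([g.Cp for g in per_null]))
    l_rand = float(np.nanmean([g.Lp for g in per_null]))
    return NullEnsemble(n_null, seed, per_null, c_rand, l_rand)


@dataclass
class SmallWorld:
    gamma: float  # Cp / C_rand
    lam: float    # Lp / L_rand
    sigma: float  # gamma / lam


def small_world(metrics: GlobalMetrics, ensemble: NullEnsemble) -> SmallWorld:
    """Small-world ratios against the degree-matched null ensemble.

    sigma > 1 indicates small-world organisation (clustering above random at
    near-random path length).
    """
    if not ensemble.C_rand > 0:
        raise ValueError("C_rand must be positive to form gamma")
    if not ensemble.L_rand > 0 or np.isnan(ensemble.L_rand):
        raise ValueError("L_rand must be positive to form lambda")
    if np.isnan(metrics.Lp):
        raise ValueError("Lp undefined (no reachable pairs); sigma is undefined")
    gamma = metrics.Cp / ensemble.C_rand
    lam = metrics.Lp / ensemble.L_rand
    return SmallWorld(gamma, lam, gamma / lam)


# ---------------------------------------------------------------------------
# hubs
# ---------------------------------------------------------------------------

@dataclass
class HubTable:
    """Group-level hub classification from mean nodal degree.

    A region is a hub when its group-mean degree exceeds the grand mean over
    regions by more than ``sd_multiplier`` standard deviations (taken over
    regions).
    """

    mean_degree: np.ndarray = field(repr=False)  # (n_regions,)
    grand_mean: float = 0.0
    sd_over_regions: float = 0.0
    sd_multiplier: float = 1.0
    is_hub: np.ndarray = field(default=None, repr=False)


def hub_detection(nodal_list: list[NodalMetrics], sd_multiplier: float = 1.0) -> HubTable:
    """Identify hubs from the per-subject nodal metrics of one group."""
    if len(nodal_list) < 2:
        raise ValueError("hub detection needs at least 2 subjects")
    degrees = np.stack([np.asarray(nm.degree, dtype=float) for nm in nodal_list])
    mean_degree = degrees.mean(axis=0)
    grand = float(mean_degree.mean())
    sd = float(mean_degree.std(ddof=1))
    is_hub = mean_degree > grand + sd_multiplier * sd
    return HubTable(mean_degree, grand, sd, sd_multiplier, is_hub)
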