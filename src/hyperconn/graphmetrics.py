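"""Global network measures with random/lattice surrogate normalization.

For every binary network the pipeline reports:

* ``G`` — normalized global efficiency.  The characteristic path length L
  (mean shortest-path distance over reachable ordered node pairs) is
  compared against degree-preserving surrogate ensembles; by the default
  ratio convention G = mean(L_random) / L_observed, so a random-like,
  short-path network scores near 1 and a lattice-like one near 0.
* ``C`` — normalized mean clustering coefficient, by the same convention
  C = C_observed / mean(C_lattice): lattice-like clustering scores near 1.
* ``SWI`` — small-world index, the product G * C, near 1 only when the
  network jointly shows random-like path lengths and lattice-like
  clustering.
* ``D`` — connection density, edges over possible edges (325 for a 26-node
  intra-brain network, 1326 for a 52-node hyperbrain network).
* ``IIR`` — intra-/inter-brain ratio, total intra-brain edges of both
  jugglers over inter-brain edges (hyperbrain networks only).

G and C are clipped to [0, 1]; an interpolation convention
(x - random) / (lattice - random) is available as an alternative.

Surrogates preserve the degree sequence via double-edge swaps
(Maslov-Sneppen); on hyperbrain inputs the swaps are restricted to edge
classes (intra-J1, intra-J2, inter), so intra- and inter-brain degree
sequences are preserved separately.  Lattice surrogates use the same move
set but accept a swap only when it lowers a ring-distance cost, driving
edges toward a band around the diagonal of the node ordering
(latticization); for the inter block the two 26-node orderings are aligned
on one ring.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import shortest_path

from .networks import AdjacencyMatrix

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# raw measures


def characteristic_path_length(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean shortest-path length over all ordered reachable node pairs.

    Unreachable pairs are excluded from the average so that fragmented
    thresholded networks still yield a finite value.  A graph with no edges
    has no defined path length and raises ``ValueError``.
    """
    m = adj.matrix if isinstance(adj, AdjacencyMatrix) else np.asarray(adj)
    if m.shape[0] < 2:
        raise ValueError("path length needs at least two nodes")
    if m.sum() == 0:
        raise ValueError("path length undefined for an edgeless graph")
    dist = shortest_path(m, method="D", unweighted=True, directed=False)
    mask = np.isfinite(dist) & ~np.eye(m.shape[0], dtype=bool)
    return float(dist[mask].mean())


def mean_clustering_coefficient(adj: AdjacencyMatrix | np.ndarray) -> float:
    """Mean over nodes of (links among neighbours) / (possible links).

    Nodes of degree < 2 contribute zero.
    """
    m = adj.matrix if isinstance(adj, AdjacencyMatrix) else np.asarray(adj)
    if m.shape[0] < 3:
        raise ValueError("clustering needs at least three nodes")
    a = m.astype(float)
    deg = a.sum(axis=1)
    triangles = np.diag(a @ a @ a) / 2.0
    possible = deg * (deg - 1) / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        ci = np.where(possible > 0, triangles / possible, 0.0)
    return float(ci.mean())


def connection_density(adj: AdjacencyMatrix) -> float:
    """Edges as a proportion of possible edges n(n-1)/2."""
    return adj.n_edges / adj.n_possible_edges


def intra_inter_ratio(adj: AdjacencyMatrix) -> float:
    """Total intra-brain edges of both jugglers over inter-brain edges.

    Returns NaN (with a warning) when there are no inter-brain edges, so
    session aggregation can skip the undefined value instead of propagating
    an infinity.
    """
    counts = adj.edge_counts_by_block()
    if counts["inter"] == 0:
        warnings.warn("IIR undefined: no inter-brain edges", stacklevel=2)
        return float("nan")
    return (counts["intra_J1"] + counts["intra_J2"]) / counts["inter"]


# ---------------------------------------------------------------------------
# degree-preserving surrogates


def _edge_classes(adj: AdjacencyMatrix) -> list[tuple[str, np.ndarray, np.ndarray]]:
    """(name, nodes_a, nodes_b) per rewiring class; a == b for intra blocks."""
    if adj.is_hyperbrain:
        n1, n2 = adj.brain_sizes
        i1 = np.arange(n1)
        i2 = np.arange(n1, n1 + n2)
        return [("intra_J1", i1, i1), ("intra_J2", i2, i2), ("inter", i1, i2)]
    nodes = np.arange(adj.n_nodes)
    return [("all", nodes, nodes)]


def _class_edges(
    m: np.ndarray, nodes_a: np.ndarray, nodes_b: np.ndarray
) -> list[tuple[int, int]]:
    if nodes_a is nodes_b or np.array_equal(nodes_a, nodes_b):
        sub = np.triu(m[np.ix_(nodes_a, nodes_a)], k=1)
        ii, jj = np.nonzero(sub)
        return [(int(nodes_a[i]), int(nodes_a[j])) for i, j in zip(ii, jj)]
    sub = m[np.ix_(nodes_a, nodes_b)]
    ii, jj = np.nonzero(sub)
    return [(int(nodes_a[i]), int(nodes_b[j])) for i, j in zip(ii, jj)]


def _ring_distance(i: int, j: int, n: int) -> int:
    d = abs(i - j) % n
    return min(d, n - d)


def _lattice_cost(
    u: int, v: int, classes_of: dict[int, int], offsets: list[int], sizes: list[int]
) -> int:
    """Ring-distance cost of one edge under the block node ordering."""
    bu, bv = classes_of[u], classes_of[v]
    pu = u - offsets[bu]
    pv = v - offsets[bv]
    n = max(sizes[bu], sizes[bv])
    return _ring_distance(pu, pv, n)


def _rewire(
    m: np.ndarray,
    adj: AdjacencyMatrix,
    rng: np.random.Generator,
    kind: str,
    swap_factor: int,
) -> np.ndarray:
    """Degree-preserving rewiring of one surrogate, class by class."""
    out = m.copy()
    if adj.is_hyperbrain:
        n1, n2 = adj.brain_sizes
        offsets, sizes = [0, n1], [n1, n2]
        classes_of = {u: (0 if u < n1 else 1) for u in range(n1 + n2)}
    else:
        offsets, sizes = [0], [adj.n_nodes]
        classes_of = {u: 0 for u in range(adj.n_nodes)}

    for name, na, nb in _edge_classes(adj):
        edges = _class_edges(out, na, nb)
        if len(edges) < 2:
            if len(edges) > 0:
                warnings.warn(
                    f"block {name} has too few edges to rewire; surrogate copies it",
                    stacklevel=2,
                )
            continue
        bipartite = name == "inter"
        n_attempts = swap_factor * len(edges)
        for _ in range(n_attempts):
            e1, e2 = rng.choice(len(edges), size=2, replace=False)
            a, b = edges[e1]
            c, d = edges[e2]
            if not bipartite and rng.random() < 0.5:
                c, d = d, c
            # proposed: (a, d), (c, b)
            # reject degenerate proposals: self-loops, shared endpoints
            if a == d or c == b or a == c or b == d:
                continue
            if out[a, d] or out[c, b]:
                continue
            if kind == "lattice":
                old = _lattice_cost(a, b, classes_of, offsets, sizes) + _lattice_cost(
                    c, d, classes_of, offsets, sizes
                )
                new = _lattice_cost(a, d, classes_of, offsets, sizes) + _lattice_cost(
                    c, b, classes_of, offsets, sizes
                )
                if new >= old:
                    continue
            out[a, b] = out[b, a] = 0
            out[c, d] = out[d, c] = 0
            out[a, d] = out[d, a] = 1
            out[c, b] = out[b, c] = 1
            edges[e1] = (a, d)
            edges[e2] = (c, b)
    return out


@dataclass
class SurrogateEnsemble:
    """Degree-preserving null networks with path-length/clustering summaries."""

    kind: str  # "random" | "lattice"
    matrices: list[np.ndarray]
    mean_path_length: float
    mean_clustering: float
    seed: int | None = None
    swap_factor: int = 10

    @property
    def n_surrogates(self) -> int:
        return len(self.matrices)


def generate_surrogates(
    adj: AdjacencyMatrix,
    kind: str,
    n_surrogates: int = 100,
    seed: int | np.random.Generator | None = None,
    swap_factor: int = 10,
) -> SurrogateEnsemble:
    """Generate a degree-preserving random or lattice surrogate ensemble.

    ``swap_factor`` sets the attempted double-edge swaps per surrogate as a
    multiple of the class edge count.  Every surrogate preserves the degree
    sequence of every edge class (intra-J1, intra-J2, inter separately on
    hyperbrain inputs).
    """
    if kind not in ("random", "lattice"):
        raise ValueError("kind must be 'random' or 'lattice'")
    if adj.n_edges == 0:
        raise ValueError("cannot build surrogates for an edgeless graph")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    mats, lengths, clusts = [], [], []
    for _ in range(n_surrogates):
        s = _rewire(adj.matrix, adj, rng, kind, swap_factor)
        mats.append(s)
        lengths.append(characteristic_path_length(s))
        clusts.append(mean_clustering_coefficient(s))
    return SurrogateEnsemble(
        kind=kind,
        matrices=mats,
        mean_path_length=float(np.mean(lengths)),
        mean_clustering=float(np.mean(clusts)),
        seed=seed if isinstance(seed, int) else None,
        swap_factor=swap_factor,
    )


# ---------------------------------------------------------------------------
# normalized measures


def normalized_global_efficiency(
    adj: AdjacencyMatrix | float,
    rand: SurrogateEnsemble,
    latt: SurrogateEnsemble | None = None,
    convention: str = "ratio",
) -> float:
    """Normalized global efficiency G in [0, 1].

    ``ratio`` (default): G = mean(L_random) / L_observed — equals 1 when the
    observed path length matches the random ensemble and decreases toward 0
    for lattice-like long paths.  ``interpolation``:
    G = (mean(L_lattice) - L_obs) / (mean(L_lattice) - mean(L_random)).
    Either result is clipped to [0, 1].
    """
    l_obs = (
        characteristic_path_length(adj)
        if isinstance(adj, AdjacencyMatrix)
        else float(adj)
    )
    if convention == "ratio":
        g = rand.mean_path_length / l_obs
    elif convention == "interpolation":
        if latt is None:
            raise ValueError("interpolation convention needs the lattice ensemble")
        denom = latt.mean_path_length - rand.mean_path_length
        if abs(denom) < 1e-12:
            raise ValueError("degenerate ensembles: L_lattice == L_random")
        g = (latt.mean_path_length - l_obs) / denom
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(np.clip(g, 0.0, 1.0))


def normalized_clustering(
    adj: AdjacencyMatrix | float,
    rand: SurrogateEnsemble | None,
    latt: SurrogateEnsemble,
    convention: str = "ratio",
) -> float:
    """Normalized clustering C in [0, 1].

    ``ratio`` (default): C = C_observed / mean(C_lattice) — equals 1 for
    lattice-like clustering.  ``interpolation``:
    C = (C_obs - mean(C_random)) / (mean(C_lattice) - mean(C_random)).
    Either result is clipped to [0, 1].
    """
    c_obs = (
        mean_clustering_coefficient(adj)
        if isinstance(adj, AdjacencyMatrix)
        else float(adj)
    )
    if convention == "ratio":
        if latt.mean_clustering <= 0:
            raise ValueError("lattice ensemble has zero clustering")
        c = c_obs / latt.mean_clustering
    elif convention == "interpolation":
        if rand is None:
            raise ValueError("interpolation convention needs the random ensemble")
        denom = latt.mean_clustering - rand.mean_clustering
        if abs(denom) < 1e-12:
            raise ValueError("degenerate ensembles: C_lattice == C_random")
        c = (c_obs - rand.mean_clustering) / denom
    else:
        raise ValueError(f"unknown convention {convention!r}")
    return float(np.clip(c, 0.0, 1.0))


def small_world_index(g: float, c: float) -> float:
    """SWI = G * C; 1 only when both normalized measures are 1."""
    if not (0.0 <= g <= 1.0 and 0.0 <= c <= 1.0):
        raise ValueError("G and C must lie in [0, 1]")
    return g * c


@dataclass
class NetworkMetrics:
    """Global measures of one binary network."""

    L: float
    C_raw: float
    G: float
    C: float
    SWI: float
    D: float
    IIR: float = float("nan")
    matrix_type: str = "intra"  # "intra" | "hyperbrain"
    trial_index: int | None = None

    def as_dict(self) -> dict[str, float]:
        out = {
            "L": self.L,
            "C_raw": self.C_raw,
            "G": self.G,
            "C": self.C,
            "SWI": self.SWI,
            "D": self.D,
        }
        if self.matrix_type == "hyperbrain":
            out["IIR"] = self.IIR
        return out


def compute_network_metrics(
    adj: AdjacencyMatrix,
    n_surrogates: int = 100,
    seed: int | np.random.Generator | None = None,
    convention: str = "ratio",
    swap_factor: int = 10,
) -> NetworkMetrics:
    """All global measures of one network, surrogate normalization included."""
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    rand = generate_surrogates(adj, "random", n_surrogates, rng, swap_factor)
    latt = generate_surrogates(adj, "lattice", n_surrogates, rng, swap_factor)
    l_obs = characteristic_path_length(adj)
    c_obs = mean_clustering_coefficient(adj)
    g = normalized_global_efficiency(l_obs, rand, latt, convention)
    c = normalized_clustering(c_obs, rand, latt, convention)
    return NetworkMetrics(
        L=l_obs,
        C_raw=c_obs,
        G=g,
        C=c,
        SWI=small_world_index(g, c),
        D=connection_density(adj),
        IIR=intra_inter_ratio(adj) if adj.is_hyperbrain else float("nan"),
        matrix_type="hyperbrain" if adj.is_hyperbrain else "intra",
    )
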