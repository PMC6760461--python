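"""Binarization of LPS matrices and hyperbrain network assembly.

Each trial's set of band-averaged LPS values (325 for a single brain, 1326
for a dyad) is thresholded independently at the median plus the (unscaled)
median absolute deviation of that set; values greater than or equal to the
threshold become edges.  The resulting binary adjacency matrix is treated
as a simple graph: the diagonal (self-connections) is stored as zero and
excluded from every count and metric.  Hyperbrain matrices are 52x52 with
block structure [intra-J1 | inter; inter^T | intra-J2], J1 being the less
experienced juggler.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import LPSMatrix


def mad_threshold(values: np.ndarray) -> float:
    """median(values) + median(|values - median|), MAD unscaled.

    No normal-consistency factor (1.4826) is applied.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("cannot threshold an empty value set")
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med + mad


@dataclass
class AdjacencyMatrix:
    """Binary symmetric network over labelled nodes.

    ``brain_sizes`` records the block structure: (26,) for a single brain,
    (26, 26) for a hyperbrain matrix whose first block is J1.
    """

    labels: list[str]
    matrix: np.ndarray  # (n, n) of 0/1, zero diagonal
    brain_sizes: tuple[int, ...]
    threshold_value: float | None = None
    source_set_size: int | None = None

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise ValueError("adjacency matrix must be square")
        if not np.array_equal(m, m.T):
            raise ValueError("adjacency matrix must be symmetric")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        m = m.astype(np.int8).copy()
        np.fill_diagonal(m, 0)
        self.matrix = m
        if sum(self.brain_sizes) != m.shape[0]:
            raise ValueError("brain_sizes inconsistent with matrix shape")

    @property
    def n_nodes(self) -> int:
        return self.matrix.shape[0]

    @property
    def is_hyperbrain(self) -> bool:
        return len(self.brain_sizes) == 2

    @property
    def n_edges(self) -> int:
        return int(self.matrix.sum()) // 2

    @property
    def n_possible_edges(self) -> int:
        n = self.n_nodes
        return n * (n - 1) // 2

    def block_slices(self) -> tuple[slice, slice]:
        if not self.is_hyperbrain:
            raise ValueError("block structure is defined only for hyperbrain matrices")
        n1, n2 = self.brain_sizes
        return slice(0, n1), slice(n1, n1 + n2)

    def edge_counts_by_block(self) -> dict[str, int]:
        """Edge counts for intra-J1, intra-J2, and inter blocks."""
        s1, s2 = self.block_slices()
        m = self.matrix
        return {
            "intra_J1": int(m[s1, s1].sum()) // 2,
            "intra_J2": int(m[s2, s2].sum()) // 2,
            "inter": int(m[s1, s2].sum()),
        }


def binarize(lps: LPSMatrix, threshold: float | None = None) -> AdjacencyMatrix:
    """Threshold one trial's LPS matrix into a binary adjacency matrix.

    By default the threshold is the median + MAD of that trial's full
    informative value set (all 325 values of a single-brain matrix; all
    1326 intra and inter values of a hyperbrain matrix jointly).  A pooled
    threshold computed elsewhere may be passed explicitly.  Ties at the
    threshold become edges.
    """
    vals = lps.pair_values()
    if np.isnan(vals).any():
        raise ValueError("LPS matrix contains undefined pair values")
    if vals.min() < 0 or vals.max() > 1:
        raise ValueError("LPS values must lie in [0, 1]")
    thr = mad_threshold(vals) if threshold is None else float(threshold)
    adj = (lps.values >= thr).astype(np.int8)
    np.fill_diagonal(adj, 0)
    adj = np.maximum(adj, adj.T)  # symmetric by construction; be explicit
    sizes = lps.brain_sizes if lps.brain_sizes else (lps.n_nodes,)
    return AdjacencyMatrix(
        labels=list(lps.labels),
        matrix=adj,
        brain_sizes=tuple(sizes),
        threshold_value=thr,
        source_set_size=vals.size,
    )


def assemble_hyperbrain(
    intra_j1: AdjacencyMatrix,
    intra_j2: AdjacencyMatrix,
    inter: np.ndarray,
    labels: list[str] | None = None,
) -> AdjacencyMatrix:
    """Compose a 52x52 hyperbrain matrix from its three blocks.

    ``inter`` is the (n1, n2) J1-by-J2 block; the lower-left block is its
    transpose.  J1 is by convention the less experienced juggler and comes
    first.
    """
    n1, n2 = intra_j1.n_nodes, intra_j2.n_nodes
    inter = np.asarray(inter)
    if inter.shape != (n1, n2):
        raise ValueError(
            f"inter block shape {inter.shape} does not match ({n1}, {n2})"
        )
    full = np.zeros((n1 + n2, n1 + n2), dtype=np.int8)
    full[:n1, :n1] = intra_j1.matrix
    full[n1:, n1:] = intra_j2.matrix
    full[:n1, n1:] = inter
    full[n1:, :n1] = inter.T
    labels = labels if labels is not None else intra_j1.labels + intra_j2.labels
    return AdjacencyMatrix(labels=labels, matrix=full, brain_sizes=(n1, n2))


def extract_blocks(
    adj: AdjacencyMatrix,
) -> tuple[AdjacencyMatrix, AdjacencyMatrix, np.ndarray]:
    """Split a hyperbrain matrix into (intra-J1, intra-J2, inter) blocks.

    The inter block is returned once as the (n1, n2) J1-by-J2 array (676
    unordered pairs for 26+26 ROIs).
    """
    s1, s2 = adj.block_slices()
    m = adj.matrix
    n1 = adj.brain_sizes[0]
    intra1 = AdjacencyMatrix(
        labels=adj.labels[:n1],
        matrix=m[s1, s1].copy(),
        brain_sizes=(adj.brain_sizes[0],),
        threshold_value=adj.threshold_value,
    )
    intra2 = AdjacencyMatrix(
        labels=adj.labels[n1:],
        matrix=m[s2, s2].copy(),
        brain_sizes=(adj.brain_sizes[1],),
        threshold_value=adj.threshold_value,
    )
    return intra1, intra2, m[s1, s2].copy()
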