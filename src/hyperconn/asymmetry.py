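"""Hemispheric lateralization and regional asymmetry indices.

Edge-count based indices in [-1, +1] describing how connections distribute
over partial ROI sets:

* ``Lat_intra``: (R - L) / (R + L) over intra-brain edges whose two
  endpoints lie in the same hemisphere (R = both right, L = both left);
  +1 means all classified connections are right-hemispheric.
* ``RA_intra``: the same contrast between fronto-limbic and
  occipito-parietal regions (+1 = only fronto-limbic connections).
* ``Lat_inter`` / ``RA_inter``: for hyperbrain networks, computed per
  juggler over inter-brain edges only, counting each edge by the
  hemisphere (or regional class) of its endpoint in that juggler's brain.

Edges straddling the two classes (inter-hemispheric, or one fronto-limbic
and one occipito-parietal endpoint) do not classify as either side and are
excluded from both counts; an option to split them half/half exists for
sensitivity analysis.  When no edge classifies, the index is 0 and the
result is flagged so session aggregation remains total.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .networks import AdjacencyMatrix, extract_blocks
from .trials import DEFAULT_REGION_CLASSES, ROIAtlas


@dataclass(frozen=True)
class AsymmetryValue:
    """An index in [-1, 1] plus a flag for the no-classified-edges case."""

    value: float
    n_positive: int  # edges counted toward +1 (right / fronto-limbic)
    n_negative: int
    defined: bool

    def __float__(self) -> float:
        return self.value


def load_region_classes(path: str | Path | None = None) -> dict[str, str]:
    """Load a label -> region-class map from YAML, or the built-in default."""
    if path is None:
        return dict(DEFAULT_REGION_CLASSES)
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise ValueError("region-class file must map ROI labels to classes")
    return {str(k): str(v) for k, v in mapping.items()}


def _index(pos: int, neg: int, split_cross: float = 0.0) -> AsymmetryValue:
    p = pos + split_cross
    n = neg + split_cross
    if p + n == 0:
        return AsymmetryValue(0.0, pos, neg, defined=False)
    return AsymmetryValue((p - n) / (p + n), pos, neg, defined=True)


def _side_of(roi, mode: str) -> str:
    if mode == "hemisphere":
        return "pos" if roi.hemisphere == "right" else "neg"
    return "pos" if roi.region_class == "fronto-limbic" else "neg"


def _intra_index(
    adj: AdjacencyMatrix, atlas: ROIAtlas, mode: str, split_cross_edges: bool
) -> AsymmetryValue:
    if len(atlas) != adj.n_nodes:
        raise ValueError("atlas does not match adjacency matrix")
    iu, ju = np.triu_indices(adj.n_nodes, k=1)
    edges = adj.matrix[iu, ju] > 0
    pos = neg = cross = 0
    for i, j in zip(iu[edges], ju[edges]):
        si, sj = _side_of(atlas[int(i)], mode), _side_of(atlas[int(j)], mode)
        if si != sj:
            cross += 1
        elif si == "pos":
            pos += 1
        else:
            neg += 1
    return _index(pos, neg, 0.5 * cross if split_cross_edges else 0.0)


def lateralization_intra(
    adj: AdjacencyMatrix,
    atlas: ROIAtlas,
    split_cross_edges: bool = False,
) -> AsymmetryValue:
    """Right-vs-left asymmetry of within-hemisphere intra-brain edges."""
    return _intra_index(adj, atlas, "hemisphere", split_cross_edges)


def regional_asymmetry_intra(
    adj: AdjacencyMatrix,
    atlas: ROIAtlas,
    split_cross_edges: bool = False,
) -> AsymmetryValue:
    """Fronto-limbic vs occipito-parietal asymmetry of intra-brain edges."""
    for roi in atlas:
        if roi.region_class not in ("fronto-limbic", "occipito-parietal"):
            raise ValueError(
                f"ROI {roi.full_label} has unknown region class {roi.region_class!r}"
            )
    return _intra_index(adj, atlas, "region", split_cross_edges)


def _inter_index(
    adj: AdjacencyMatrix, atlas: ROIAtlas, which_juggler: str, mode: str
) -> AsymmetryValue:
    if not adj.is_hyperbrain:
        raise ValueError("inter-brain indices need a hyperbrain matrix")
    if which_juggler not in atlas.brain_ids:
        raise ValueError(f"juggler {which_juggler!r} not in atlas")
    _, _, inter = extract_blocks(adj)
    n1 = adj.brain_sizes[0]
    j1_rois = [atlas[i] for i in range(n1)]
    j2_rois = [atlas[i] for i in range(n1, adj.n_nodes)]
    rows, cols = np.nonzero(inter)
    pos = neg = 0
    for r, c in zip(rows, cols):
        roi = j1_rois[int(r)] if which_juggler == "J1" else j2_rois[int(c)]
        if _side_of(roi, mode) == "pos":
            pos += 1
        else:
            neg += 1
    return _index(pos, neg)


def lateralization_inter(
    adj: AdjacencyMatrix, atlas: ROIAtlas, which_juggler: str
) -> AsymmetryValue:
    """Right-vs-left attachment asymmetry of one juggler's inter-brain edges."""
    return _inter_index(adj, atlas, which_juggler, "hemisphere")


def regional_asymmetry_inter(
    adj: AdjacencyMatrix, atlas: ROIAtlas, which_juggler: str
) -> AsymmetryValue:
    """Regional attachment asymmetry of one juggler's inter-brain edges."""
    return _inter_index(adj, atlas, which_juggler, "region")
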