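"""File formats: HDF5 trial containers, CSV matrices/tables, GraphML.

Trials live in an HDF5 container with layout
``/session/<id>/<CONDITION>/<juggler>/trial<k>`` (dataset of shape
ROI x 3 x samples, attributes ``sampling_rate`` and ``labels``); the
session design table and all matrices and results are CSV so they stay
diffable and language-neutral.  Every writer embeds the configuration hash
and seed it was produced under.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import networkx as nx
import numpy as np
import pandas as pd
import yaml

from .connectivity import ALPHA_BAND, LPSMatrix
from .networks import AdjacencyMatrix
from .trials import ROIAtlas, SourceTrial, default_atlas

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """End-to-end pipeline parameters; the defaults reproduce the standard
    analysis: alpha band 8.5-12 Hz, 2 s windows stepped by 1 s over the
    central 10 s, per-trial median+MAD thresholding, ratio normalization
    against 100 surrogates."""

    band: tuple[float, float] = ALPHA_BAND
    window: float = 2.0
    step: float = 1.0
    trim_duration: float = 10.0
    threshold_mode: str = "per-trial"  # | "pooled"
    convention: str = "ratio"  # | "interpolation"
    n_surrogates: int = 100
    swap_factor: int = 10
    calibrate: bool = True
    region_class_path: str | None = None
    seed: int = 0
    input_path: str | None = None
    output_path: str | None = None

    def __post_init__(self) -> None:
        self.band = (float(self.band[0]), float(self.band[1]))
        if self.band[0] >= self.band[1]:
            raise ValueError(f"band must be increasing, got {self.band}")
        if self.threshold_mode not in ("per-trial", "pooled"):
            raise ValueError("threshold_mode must be 'per-trial' or 'pooled'")
        if self.convention not in ("ratio", "interpolation"):
            raise ValueError("convention must be 'ratio' or 'interpolation'")
        if self.window <= 0 or self.step <= 0:
            raise ValueError("window and step must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        data = (
            json.loads(text)
            if str(path).endswith(".json")
            else yaml.safe_load(text)
        )
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        data = asdict(self)
        data["band"] = list(self.band)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @property
    def config_hash(self) -> str:
        data = asdict(self)
        data["band"] = list(self.band)
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _provenance(config: PipelineConfig | None) -> str:
    if config is None:
        return ""
    return f"# config_hash={config.config_hash} seed={config.seed}\n"


# ---------------------------------------------------------------------------
# HDF5 trials


def write_trials_hdf5(
    path: str | Path,
    trials: list[SourceTrial],
    config: PipelineConfig | None = None,
) -> None:
    """Write trials into the /session/<id>/<cond>/<juggler>/trial<k> layout."""
    with h5py.File(path, "w") as fh:
        if config is not None:
            fh.attrs["config_hash"] = config.config_hash
            fh.attrs["seed"] = config.seed
        for t in trials:
            grp = fh.require_group(
                f"session/{t.session_id}/{t.condition}/{t.juggler_id}"
            )
            ds = grp.create_dataset(f"trial{t.trial_index}", data=t.data)
            ds.attrs["sampling_rate"] = t.sampling_rate
            ds.attrs["labels"] = [r.full_label for r in t.atlas]


def read_trials(path: str | Path, atlas_factory=None) -> list[SourceTrial]:
    """Read every trial in the container, attaching a matching atlas.

    ROI labels stored with each dataset are checked against the default
    atlas of the recorded juggler; a custom ``atlas_factory(brain_id)`` may
    be supplied for non-standard atlases.
    """
    factory = atlas_factory if atlas_factory is not None else default_atlas
    out: list[SourceTrial] = []
    with h5py.File(path, "r") as fh:
        if "session" not in fh:
            return out
        for sid, sgrp in fh["session"].items():
            for cond, cgrp in sgrp.items():
                for jug, jgrp in cgrp.items():
                    for name, ds in jgrp.items():
                        if not name.startswith("trial"):
                            raise ValueError(f"unexpected dataset {name!r}")
                        data = np.asarray(ds)
                        if data.ndim != 3 or data.shape[1] != 3:
                            raise ValueError(
                                f"dataset {sid}/{cond}/{jug}/{name} has shape "
                                f"{data.shape}; expected (rois, 3, samples)"
                            )
                        if "sampling_rate" not in ds.attrs:
                            raise ValueError(
                                f"dataset {sid}/{cond}/{jug}/{name} lacks a "
                                "sampling_rate attribute"
                            )
                        atlas = factory(jug)
                        stored = [s.decode() if isinstance(s, bytes) else str(s)
                                  for s in ds.attrs.get("labels", [])]
                        if stored and stored != atlas.labels:
                            raise ValueError(
                                f"ROI labels in {sid}/{cond}/{jug}/{name} do "
                                "not match the atlas"
                            )
                        out.append(
                            SourceTrial(
                                data=data,
                                sampling_rate=float(ds.attrs["sampling_rate"]),
                                atlas=atlas,
                                session_id=sid,
                                juggler_id=jug,
                                condition=cond,
                                trial_index=int(name.removeprefix("trial")),
                            )
                        )
    return out


# ---------------------------------------------------------------------------
# CSV / GraphML


def write_lps_csv(
    lps: LPSMatrix, path: str | Path, config: PipelineConfig | None = None
) -> None:
    df = pd.DataFrame(lps.values, index=lps.labels, columns=lps.labels)
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        fh.write(f"# band={lps.band[0]}-{lps.band[1]}Hz "
                 f"segments={lps.n_trial_segments}\n")
        df.to_csv(fh)


def read_lps_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", index_col=0)


def write_adjacency_csv(
    adj: AdjacencyMatrix, path: str | Path, config: PipelineConfig | None = None
) -> None:
    df = pd.DataFrame(adj.matrix, index=adj.labels, columns=adj.labels)
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        if adj.threshold_value is not None:
            fh.write(f"# threshold={adj.threshold_value!r}\n")
        df.to_csv(fh)


def write_adjacency_graphml(adj: AdjacencyMatrix, path: str | Path) -> None:
    g = nx.from_numpy_array(adj.matrix)
    nx.relabel_nodes(g, dict(enumerate(adj.labels)), copy=False)
    if adj.threshold_value is not None:
        g.graph["threshold"] = float(adj.threshold_value)
    nx.write_graphml(g, path)


def write_table(
    df: pd.DataFrame, path: str | Path, config: PipelineConfig | None = None
) -> None:
    with open(path, "w") as fh:
        fh.write(_provenance(config))
        df.to_csv(fh, index=False)
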