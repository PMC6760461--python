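"""ROI atlas and source-level trial handling.

The analysis operates on region-of-interest (ROI) current-density time
series: for each of 26 cortical ROIs per brain (13 anatomical labels x 2
hemispheres) a 3-dimensional dipole-moment series sampled at a fixed rate.
This module defines the atlas, the trial container, and the three
preparatory operations every trial passes through before connectivity
estimation: validation, central trimming to the steady 10 s of juggling,
and segmentation into overlapping analysis windows.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Anatomical labels, Brodmann area, and MNI centroid (x, y, z in mm) of the
#: 13 per-hemisphere ROIs.  Left-hemisphere coordinates; right hemisphere
#: mirrors the sign of x.
ROI_DEFINITIONS: tuple[tuple[str, str, int, tuple[int, int, int]], ...] = (
    ("SMA", "SensoriMotor Area", 3, (-40, -25, 50)),
    ("SPL", "Superior Parietal Lobule", 7, (-15, -60, 50)),
    ("SPFC", "Superior PreFrontal Cortex", 6, (-25, 0, 50)),
    ("OFC", "OrbitoFrontal Cortex", 11, (-25, 35, -15)),
    ("APFC", "Anterior PreFrontal Cortex", 10, (-25, 45, 25)),
    ("LPFC", "Lateral PreFrontal Cortex", 45, (-50, 20, 15)),
    ("ACC", "Anterior Cingulate Cortex", 24, (-5, 20, 25)),
    ("PCC", "Posterior Cingulate Cortex", 30, (-5, -50, 20)),
    ("PHG", "ParaHippocampal Gyrus", 28, (-20, -20, -20)),
    ("IPC", "Inferior Parietal Cortex", 40, (-45, -45, 35)),
    ("FUS", "Fusiform cortex", 37, (-40, -65, 0)),
    ("PVC", "Primary Visual Cortex", 17, (-15, -85, 0)),
    ("INS", "INSULA", 13, (-40, -10, 10)),
)

#: Default split of the 13 labels into the two regional classes used by the
#: regional-asymmetry index.  The split is configurable (see
#: :func:`hyperconn.asymmetry.load_region_classes`); this default groups the
#: frontal and limbic structures against the parietal/occipital ones.
DEFAULT_REGION_CLASSES: dict[str, str] = {
    "SPFC": "fronto-limbic",
    "OFC": "fronto-limbic",
    "APFC": "fronto-limbic",
    "LPFC": "fronto-limbic",
    "ACC": "fronto-limbic",
    "INS": "fronto-limbic",
    "PHG": "fronto-limbic",
    "SPL": "occipito-parietal",
    "IPC": "occipito-parietal",
    "PVC": "occipito-parietal",
    "FUS": "occipito-parietal",
    "PCC": "occipito-parietal",
    "SMA": "occipito-parietal",
}


@dataclass(frozen=True)
class ROI:
    """A single region of interest."""

    label: str
    hemisphere: str  # "left" | "right"
    brain_id: str  # "J1" | "J2"
    region_class: str
    mni: tuple[float, float, float]

    @property
    def full_label(self) -> str:
        hemi = "L" if self.hemisphere == "left" else "R"
        return f"{self.brain_id}_{self.label}_{hemi}"


@dataclass(frozen=True)
class ROIAtlas:
    """An ordered collection of ROIs for one brain (26) or a dyad (52).

    Ordering convention: all ROIs of one brain are contiguous, with the 13
    labels in :data:`ROI_DEFINITIONS` order, left hemisphere before right.
    For a dyad J1 (the less experienced juggler) precedes J2.
    """

    rois: tuple[ROI, ...]

    def __post_init__(self) -> None:
        labels = [r.full_label for r in self.rois]
        if len(set(labels)) != len(labels):
            raise ValueError("duplicate ROI labels in atlas")

    def __len__(self) -> int:
        return len(self.rois)

    def __iter__(self):
        return iter(self.rois)

    def __getitem__(self, i: int) -> ROI:
        return self.rois[i]

    @property
    def labels(self) -> list[str]:
        return [r.full_label for r in self.rois]

    @property
    def brain_ids(self) -> list[str]:
        seen: list[str] = []
        for r in self.rois:
            if r.brain_id not in seen:
                seen.append(r.brain_id)
        return seen

    def indices_of_brain(self, brain_id: str) -> np.ndarray:
        idx = np.array([i for i, r in enumerate(self.rois) if r.brain_id == brain_id])
        if idx.size == 0:
            raise KeyError(f"brain {brain_id!r} not in atlas")
        return idx

    def subset(self, brain_id: str) -> "ROIAtlas":
        return ROIAtlas(tuple(r for r in self.rois if r.brain_id == brain_id))

    def index_of(self, full_label: str) -> int:
        for i, r in enumerate(self.rois):
            if r.full_label == full_label:
                return i
        raise KeyError(f"unknown ROI label {full_label!r}")


def default_atlas(
    brain_id: str = "J1", region_classes: dict[str, str] | None = None
) -> ROIAtlas:
    """The 26-ROI single-brain atlas (13 labels x 2 hemispheres)."""
    classes = DEFAULT_REGION_CLASSES if region_classes is None else region_classes
    missing = [lab for lab, *_ in ROI_DEFINITIONS if lab not in classes]
    if missing:
        raise ValueError(f"region-class map misses labels: {missing}")
    rois = []
    for label, _ext, _ba, (x, y, z) in ROI_DEFINITIONS:
        for hemi in ("left", "right"):
            mni = (float(-x if hemi == "right" else x), float(y), float(z))
            rois.append(ROI(label, hemi, brain_id, classes[label], mni))
    return ROIAtlas(tuple(rois))


def dyad_atlas(region_classes: dict[str, str] | None = None) -> ROIAtlas:
    """The 52-ROI hyperbrain atlas: J1's 26 ROIs followed by J2's."""
    j1 = default_atlas("J1", region_classes)
    j2 = default_atlas("J2", region_classes)
    return ROIAtlas(j1.rois + j2.rois)


@dataclass
class SourceTrial:
    """One trial's 3D current-density time series for a set of ROIs.

    data has shape (n_rois, 3, n_samples): per ROI the dipole moment along
    the three spatial dimensions.
    """

    data: np.ndarray
    sampling_rate: float
    atlas: ROIAtlas
    session_id: str = "S1"
    juggler_id: str = "J1"
    condition: str = "SOLO"
    trial_index: int = 0

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


@dataclass
class SegmentSet:
    """Equal-length analysis windows cut from a trimmed trial."""

    windows: list[np.ndarray]  # each (n_rois, 3, window_samples)
    window_duration: float
    step: float
    sampling_rate: float

    def __len__(self) -> int:
        return len(self.windows)


def validate_trial(trial: SourceTrial, atlas: ROIAtlas | None = None) -> SourceTrial:
    """Check a trial's shape, labels, finiteness and duration.

    Returns the trial unchanged when well-formed; raises ``ValueError``
    otherwise.  A duration below 10 s marks an unsuccessful trial, which the
    caller is expected to exclude.
    """
    atlas = atlas if atlas is not None else trial.atlas
    if trial.data.ndim != 3 or trial.data.shape[1] != 3:
        raise ValueError(
            f"trial data must have shape (n_rois, 3, n_samples); got {trial.data.shape}"
        )
    if trial.data.shape[0] != len(atlas):
        raise ValueError(
            f"trial has {trial.data.shape[0]} ROIs but atlas defines {len(atlas)}"
        )
    if trial.sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if not np.all(np.isfinite(trial.data)):
        raise ValueError("trial contains non-finite samples")
    if trial.duration < 10.0 - 1e-9:
        raise ValueError(
            f"trial duration {trial.duration:.3f} s < 10 s (unsuccessful trial)"
        )
    return trial


def trim_trial(trial: SourceTrial, target_duration: float = 10.0) -> SourceTrial:
    """Retain the central ``target_duration`` seconds of a trial.

    Equal amounts are removed from both ends (a 20 s trial loses its first
    and last 5 s), keeping only the steady portion of the juggling bout.
    """
    target_samples = int(round(target_duration * trial.sampling_rate))
    n = trial.n_samples
    if n < target_samples:
        raise ValueError(
            f"trial of {trial.duration:.3f} s shorter than target "
            f"{target_duration} s (unsuccessful trial)"
        )
    start = (n - target_samples) // 2
    data = trial.data[:, :, start : start + target_samples]
    return replace(trial, data=data)


def segment_trial(
    trial: SourceTrial, window: float = 2.0, step: float = 1.0
) -> SegmentSet:
    """Cut a trimmed trial into equal overlapping windows.

    Windows are half-open sample ranges starting at multiples of ``step``
    from time zero.  With the defaults (2 s windows, 1 s step) a 10 s trial
    yields exactly nine segments whose union covers the whole trial.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    fs = trial.sampling_rate
    wsamp = window * fs
    if abs(wsamp - round(wsamp)) > 1e-9:
        raise ValueError(f"window of {window} s is not a whole number of samples")
    wsamp = int(round(wsamp))
    if wsamp > trial.n_samples:
        raise ValueError("window longer than trial")
    n_windows = math.floor((trial.n_samples - wsamp) / (step * fs)) + 1
    windows = []
    for k in range(n_windows):
        start = math.floor(k * step * fs)
        windows.append(trial.data[:, :, start : start + wsamp])
    logger.debug(
        "segmented trial into %d windows of %g s (step %g s)", n_windows, window, step
    )
    return SegmentSet(windows, window, step, fs)
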