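"""Core in-memory containers for component time courses and motion traces."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class TimeCoursePanel:
    """A single subject's intrinsic-connectivity-network (ICN) time courses.

    Parameters
    ----------
    data : ndarray, shape (T, C)
        One column per component, one row per acquired volume.
    tr_seconds : float
        Sampling interval (repetition time) in seconds.
    component_ids : list of str
        Column labels, e.g. ``ic01 .. ic42``.
    subnetwork_labels : list of str
        Sub-network membership of each component (e.g. visual, default-mode).
    subject_id : str
    """

    data: np.ndarray
    tr_seconds: float
    component_ids: list[str]
    subnetwork_labels: list[str]
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time-course data must be a 2-D (T, C) array")
        T, C = self.data.shape
        if T < 1 or C < 1:
            raise ValueError("time-course data must have positive T and C")
        if len(self.component_ids) != C:
            raise ValueError(
                f"{len(self.component_ids)} component ids for {C} columns"
            )
        if len(self.subnetwork_labels) != C:
            raise ValueError(
                f"{len(self.subnetwork_labels)} sub-network labels for {C} columns"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_components(self) -> int:
        return self.data.shape[1]

    def with_data(self, data: np.ndarray) -> "TimeCoursePanel":
        """Return a copy of the panel carrying new values, same metadata."""
        if data.shape != self.data.shape:
            raise ValueError("replacement data must preserve (T, C)")
        return replace(self, data=np.asarray(data, dtype=float))


@dataclass
class MotionParams:
    """Rigid-body head motion: 3 translations (mm) and 3 rotations (radians)."""

    data: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ValueError("motion parameters must be a (T, 6) array")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]


def default_subnetwork_labels(n_components: int = 42,
                              n_blocks: int = 7) -> list[str]:
    """Partition components into contiguous labelled sub-networks.

    Mirrors a typical resting-state decomposition into seven intrinsic
    systems; block sizes differ by at most one when n_components is not a
    multiple of n_blocks.
    """
    names = ["subcortical", "auditory", "visual", "somatomotor",
             "cognitive-control", "default-mode", "cerebellar"]
    if n_blocks > len(names):
        names = names + [f"network-{i}" for i in range(len(names), n_blocks)]
    sizes = np.full(n_blocks, n_components // n_blocks, dtype=int)
    sizes[: n_components % n_blocks] += 1
    labels: list[str] = []
    for name, size in zip(names[:n_blocks], sizes):
        labels.extend([name] * int(size))
    return labels
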