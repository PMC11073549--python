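"""Shared in-memory containers for parcellated runs.

A parcellated run is a frames x regions table of BOLD signal averaged
within atlas regions, together with the repetition time (TR), region
identifiers and (optionally) the intrinsic-system label of each region.
Confounds carry the fMRIPrep-style nuisance series (6 rigid-body motion
parameters, mean white-matter, CSF and whole-brain signals).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["ParcelSeries", "Confounds", "SubjectRun"]


@dataclass
class ParcelSeries:
    """Frames x regions signal table with acquisition metadata.

    Parameters
    ----------
    data : ndarray, shape (n_frames, n_regions)
    tr : float
        Repetition time in seconds.
    region_ids : sequence of str, optional
        One identifier per region; defaults to ``"r001", "r002", ...``.
    systems : sequence of str, optional
        Intrinsic-system label per region (e.g. "default-mode").
    """

    data: np.ndarray
    tr: float
    region_ids: Optional[Sequence[str]] = None
    systems: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("parcel data must be 2-D (frames x regions)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        if self.region_ids is None:
            self.region_ids = [f"r{i + 1:03d}" for i in range(self.n_regions)]
        self.region_ids = list(map(str, self.region_ids))
        if len(self.region_ids) != self.n_regions:
            raise ValueError("region_ids length does not match data")
        if self.systems is not None:
            self.systems = list(map(str, self.systems))
            if len(self.systems) != self.n_regions:
                raise ValueError("systems length does not match data")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def n_regions(self) -> int:
        return self.data.shape[1]

    @property
    def frame_times(self) -> np.ndarray:
        """Acquisition time of each frame in seconds (frame_index * tr)."""
        return np.arange(self.n_frames) * self.tr

    def with_data(self, data: np.ndarray) -> "ParcelSeries":
        """Copy of this series with ``data`` replaced, metadata kept."""
        return replace(self, data=np.asarray(data, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, columns=self.region_ids)


@dataclass
class Confounds:
    """Nuisance series for one run: motion (frames x 6), tissue and global.

    Column order of ``motion`` is (trans_x, trans_y, trans_z,
    rot_x, rot_y, rot_z); rotations in radians.
    """

    motion: np.ndarray
    white_matter: np.ndarray
    csf: np.ndarray
    global_signal: np.ndarray

    def __post_init__(self) -> None:
        self.motion = np.asarray(self.motion, dtype=float)
        if self.motion.ndim != 2 or self.motion.shape[1] != 6:
            raise ValueError("motion must have exactly 6 columns")
        for name in ("white_matter", "csf", "global_signal"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if v.shape[0] != self.motion.shape[0]:
                raise ValueError(f"{name} length does not match motion")
            setattr(self, name, v)

    @property
    def n_frames(self) -> int:
        return self.motion.shape[0]

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "trans_x": self.motion[:, 0],
            "trans_y": self.motion[:, 1],
            "trans_z": self.motion[:, 2],
            "rot_x": self.motion[:, 3],
            "rot_y": self.motion[:, 4],
            "rot_z": self.motion[:, 5],
            "white_matter": self.white_matter,
            "csf": self.csf,
            "global_signal": self.global_signal,
        }
        return pd.DataFrame(cols)


@dataclass
class SubjectRun:
    """One acquisition of one subject: parcels + task design + confounds.

    ``design`` is None for resting-state runs.
    """

    parcels: ParcelSeries
    confounds: Confounds
    design: Optional["TaskDesign"] = None  # noqa: F821 - forward ref
    subject_id: str = "sub-01"
    run_id: str = "run-01"

    def __post_init__(self) -> None:
        if self.confounds.n_frames != self.parcels.n_frames:
            raise ValueError("confound frame count does not match parcels")
        if self.design is not None:
            if self.design.n_frames != self.parcels.n_frames:
                raise ValueError("design frame count does not match parcels")
            if abs(self.design.tr - self.parcels.tr) > 1e-9:
                raise ValueError("design TR does not match parcels")

    @property
    def is_rest(self) -> bool:
        return self.design is None
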