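"""Shared in-memory containers."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError


@dataclass
class VoxelTimeSeries:
    """Voxels × scans signal for one run.

    ``data`` is a 2-D real matrix (arbitrary units or percent signal
    change), ``tr_s`` the repetition time, ``run`` a run identifier and
    ``voxel_ids`` unique voxel labels aligned with the rows.
    """

    data: np.ndarray
    tr_s: float
    run: int | str = 0
    voxel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValidationError("data must be voxels x scans (2-D)")
        if not np.all(np.isfinite(self.data)):
            raise ValidationError("data contains missing/non-finite values")
        if self.tr_s <= 0:
            raise ValidationError("tr_s must be positive")
        if self.voxel_ids is None:
            self.voxel_ids = np.array([f"v{i:05d}" for i in range(self.data.shape[0])])
        else:
            self.voxel_ids = np.asarray(self.voxel_ids)
            if len(np.unique(self.voxel_ids)) != self.data.shape[0]:
                raise ValidationError("voxel_ids must be unique and match data rows")

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_scans(self) -> int:
        return self.data.shape[1]

    def scan_times(self) -> np.ndarray:
        return np.arange(self.n_scans) * self.tr_s
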