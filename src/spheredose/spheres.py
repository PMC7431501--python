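"""Per-microsphere position/activity table shared across the pipeline.

A :class:`SphereTable` is the bridge between simulation (ground truth),
detection (measured locations) and dosimetry (sources to convolve): N rows
of 3-D world coordinates (mm) with a per-sphere activity (Bq) referenced to
a stated time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SphereTable:
    positions_mm: np.ndarray              # (N, 3)
    activities_bq: np.ndarray             # (N,)
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions_mm = np.atleast_2d(np.asarray(self.positions_mm, dtype=float))
        if self.positions_mm.size == 0:
            self.positions_mm = np.empty((0, 3))
        if self.positions_mm.shape[1] != 3:
            raise ValueError("positions must be (N, 3)")
        self.activities_bq = np.asarray(self.activities_bq, dtype=float).ravel()
        if len(self.activities_bq) != len(self.positions_mm):
            raise ValueError("positions and activities must have equal length")
        if np.any(self.activities_bq < 0):
            raise ValueError("activities must be >= 0")

    def __len__(self) -> int:
        return len(self.positions_mm)

    @property
    def total_activity_bq(self) -> float:
        return float(self.activities_bq.sum())

    def with_activities(self, activities_bq: np.ndarray, **prov) -> "SphereTable":
        p = dict(self.provenance)
        p.update(prov)
        return SphereTable(self.positions_mm.copy(), activities_bq, p)


def assign_sphere_activity(table: SphereTable, total_activity_gbq: float,
                           reference_time: str | None = None) -> SphereTable:
    """Split a total activity uniformly over the spheres (ideal equal loading).

    The sum of the assigned activities equals the total exactly.
    """
    if total_activity_gbq < 0:
        raise ValueError("total activity must be >= 0")
    n = len(table)
    if n == 0:
        if total_activity_gbq > 0:
            raise ValueError("cannot assign positive activity to an empty sphere table")
        return table.with_activities(np.empty(0))
    per = np.full(n, total_activity_gbq * 1e9 / n)
    # force exact conservation against accumulated rounding
    per[-1] += total_activity_gbq * 1e9 - per.sum()
    return table.with_activities(per, activity_reference_time=reference_time,
                                 total_activity_gbq=total_activity_gbq)
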