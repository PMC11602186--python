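"""The Session container: one recording's schedule, cells, spikes, and behavior.

A session is the unit of analysis: a stimulus schedule, a table of cells with
atlas-like anatomical positions, per-cell spike trains, lick times, a pupil
radius trace (nominally 60 fps), and a whisker mean-angle trace (nominally
125 fps).  All times are seconds from session start.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .task_schedule import StimulusSchedule

SCHEMA_VERSION = 1

#: columns of the cells table
CELL_COLUMNS = ["cell_id", "region", "ap_um", "dv_um", "ml_um", "dist_to_boundary_um"]


class SessionValidationError(ValueError):
    """A session bundle violates a structural invariant."""

    def __init__(self, code: str, message: str):
        self.code = code
        super().__init__(f"[{code}] {message}")


@dataclass
class Session:
    schedule: StimulusSchedule
    cells: pd.DataFrame
    spikes: dict[str, np.ndarray]
    licks: np.ndarray
    pupil_t: np.ndarray
    pupil_r: np.ndarray
    whisk_t: np.ndarray
    whisk_angle: np.ndarray
    pupil_fs: float = 60.0
    whisk_fs: float = 125.0
    seed: int | None = None
    sync_offsets: dict[str, float] = field(default_factory=dict)
    schema_version: int = SCHEMA_VERSION

    @property
    def conditioning(self) -> str:
        return self.schedule.conditioning

    @property
    def duration(self) -> float:
        return self.schedule.session_duration

    def cell_ids(self) -> list[str]:
        return list(self.cells["cell_id"])

    def validate(self) -> "Session":
        """Check structural invariants; raise SessionValidationError on failure."""
        missing = [c for c in CELL_COLUMNS if c not in self.cells.columns]
        if missing:
            raise SessionValidationError("bad-header", f"cells table missing columns {missing}")
        known = set(self.cells["cell_id"])
        orphans = set(self.spikes) - known
        if orphans:
            raise SessionValidationError(
                "orphan-id", f"spike trains reference unknown cells: {sorted(orphans)[:5]}"
            )
        for cid, st in self.spikes.items():
            if np.any(np.diff(st) < 0):
                raise SessionValidationError("unsorted-times", f"spikes of {cid} are not sorted")
            if st.size and (st[0] < 0 or st[-1] > self.duration):
                raise SessionValidationError(
                    "time-range", f"spikes of {cid} fall outside [0, {self.duration}]"
                )
        if self.licks.size and (
            np.any(np.diff(self.licks) < 0)
            or self.licks[0] < 0
            or self.licks[-1] > self.duration
        ):
            raise SessionValidationError("time-range", "lick times unsorted or out of range")
        for ev in self.schedule.events:
            if ev.onset < 0 or ev.onset > self.duration:
                raise SessionValidationError(
                    "time-range", f"event onset {ev.onset} outside [0, {self.duration}]"
                )
        if np.any(self.pupil_r <= 0) or not np.all(np.isfinite(self.pupil_r)):
            raise SessionValidationError("bad-value", "pupil radius must be positive and finite")
        return self
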