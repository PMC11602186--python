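"""Session bundle I/O: plain CSV + JSON, deterministic and diff-able.

A session bundle is a directory with ``session.json`` (metadata),
``events.csv``, ``cells.csv``, ``spikes.csv``, ``licks.csv``, ``pupil.csv``,
``whisker.csv``, and optionally ``ground_truth.json``.  All times are seconds
as decimals; writing is byte-deterministic (fixed column order and decimal
formatting) so a fixed seed reproduces identical files.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .session import CELL_COLUMNS, SCHEMA_VERSION, Session, SessionValidationError
from .synthetic_data import GroundTruth
from .task_schedule import ISIParams, StimulusEvent, StimulusSchedule

logger = logging.getLogger(__name__)

TABLES = ("events", "cells", "spikes", "licks", "pupil", "whisker")

_HEADERS = {
    "events": ["modality", "onset_s", "duration_s", "rewarded"],
    "cells": CELL_COLUMNS,
    "spikes": ["cell_id", "time_s"],
    "licks": ["time_s"],
    "pupil": ["time_s", "radius_px"],
    "whisker": ["time_s", "angle_deg"],
}


def write_session(session: Session, path: str | Path, truth: GroundTruth | None = None) -> Path:
    """Write a session bundle; returns the bundle directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "schema_version": session.schema_version,
        "conditioning": session.conditioning,
        "duration_s": session.duration,
        "pupil_fs": session.pupil_fs,
        "whisk_fs": session.whisk_fs,
        "seed": session.seed,
        "sync_offsets": session.sync_offsets,
        "isi_params": {
            m: vars(p).copy() for m, p in session.schedule.params.items()
        },
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1, sort_keys=True) + "\n")

    ev = pd.DataFrame(
        {
            "modality": [e.modality for e in session.schedule.events],
            "onset_s": [f"{e.onset:.3f}" for e in session.schedule.events],
            "duration_s": [f"{e.duration:.3f}" for e in session.schedule.events],
            "rewarded": [int(e.rewarded) for e in session.schedule.events],
        }
    )
    ev.to_csv(path / "events.csv", index=False)
    session.cells.to_csv(path / "cells.csv", index=False, float_format="%.1f")

    cid = np.concatenate(
        [np.repeat(c, session.spikes[c].size) for c in session.cell_ids()]
    ) if session.spikes else np.array([], dtype=str)
    times = np.concatenate(
        [session.spikes[c] for c in session.cell_ids()]
    ) if session.spikes else np.array([])
    pd.DataFrame({"cell_id": cid, "time_s": [f"{t:.6f}" for t in times]}).to_csv(
        path / "spikes.csv", index=False
    )
    pd.DataFrame({"time_s": [f"{t:.6f}" for t in session.licks]}).to_csv(
        path / "licks.csv", index=False
    )
    pd.DataFrame(
        {"time_s": [f"{t:.6f}" for t in session.pupil_t],
         "radius_px": [f"{r:.6f}" for r in session.pupil_r]}
    ).to_csv(path / "pupil.csv", index=False)
    pd.DataFrame(
        {"time_s": [f"{t:.6f}" for t in session.whisk_t],
         "angle_deg": [f"{a:.6f}" for a in session.whisk_angle]}
    ).to_csv(path / "whisker.csv", index=False)
    if truth is not None:
        (path / "ground_truth.json").write_text(truth.to_json() + "\n")
    return path


def _read_table(path: Path, name: str) -> pd.DataFrame:
    f = path / f"{name}.csv"
    if not f.exists():
        raise SessionValidationError("missing-table", f"bundle lacks {f.name}")
    df = pd.read_csv(f)
    missing = [c for c in _HEADERS[name] if c not in df.columns]
    if missing:
        raise SessionValidationError("bad-header", f"{f.name} missing columns {missing}")
    return df


def read_session(path: str | Path) -> tuple[Session, GroundTruth | None]:
    """Read and validate a session bundle."""
    path = Path(path)
    meta_file = path / "session.json"
    if not meta_file.exists():
        raise SessionValidationError("missing-table", f"bundle lacks {meta_file.name}")
    meta = json.loads(meta_file.read_text())
    if meta.get("schema_version") != SCHEMA_VERSION:
        raise SessionValidationError(
            "schema-version",
            f"unsupported schema_version {meta.get('schema_version')!r}",
        )
    ev = _read_table(path, "events")
    try:
        events = [
            StimulusEvent(
                modality=str(r.modality),
                onset=float(r.onset_s),
                duration=float(r.duration_s),
                rewarded=bool(int(r.rewarded)),
            )
            for r in ev.itertuples()
        ]
    except ValueError as e:
        raise SessionValidationError("bad-value", f"events.csv: {e}") from e
    params = {
        m: ISIParams(**p) for m, p in meta.get("isi_params", {}).items()
    } or {"tactile": ISIParams(), "visual": ISIParams()}
    schedule = StimulusSchedule(
        events=events,
        session_duration=float(meta["duration_s"]),
        params=params,
        conditioning=meta["conditioning"],
    )
    cells = _read_table(path, "cells")
    cells["cell_id"] = cells["cell_id"].astype(str)
    sp = _read_table(path, "spikes")
    spikes = {
        str(cid): np.sort(g["time_s"].to_numpy(float))
        for cid, g in sp.groupby("cell_id")
    }
    for cid in cells["cell_id"]:
        spikes.setdefault(cid, np.array([]))
    licks = _read_table(path, "licks")["time_s"].to_numpy(float)
    pupil = _read_table(path, "pupil")
    whisker = _read_table(path, "whisker")
    truth = None
    gt_file = path / "ground_truth.json"
    if gt_file.exists():
        truth = GroundTruth.from_json(gt_file.read_text())
    session = Session(
        schedule=schedule,
        cells=cells,
        spikes=spikes,
        licks=licks,
        pupil_t=pupil["time_s"].to_numpy(float),
        pupil_r=pupil["radius_px"].to_numpy(float),
        whisk_t=whisker["time_s"].to_numpy(float),
        whisk_angle=whisker["angle_deg"].to_numpy(float),
        pupil_fs=float(meta.get("pupil_fs", 60.0)),
        whisk_fs=float(meta.get("whisk_fs", 125.0)),
        seed=meta.get("seed"),
        sync_offsets=meta.get("sync_offsets", {}),
        schema_version=int(meta["schema_version"]),
    ).validate()
    return session, truth


def write_outputs(
    df: pd.DataFrame, path: str | Path, config: AnalysisConfig = AnalysisConfig()
) -> Path:
    """Write an analysis table with a config-hash header line.

    Deterministic: fixed column order (as given), 6-significant-digit
    floats, and a ``#``-prefixed header carrying the config hash so outputs
    from different configs never silently mix.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        f.write(f"# secothal config={config.hash()}\n")
        df.to_csv(f, index=False, float_format="%.6g")
    logger.info("wrote %s (%d rows)", path, len(df))
    return path


def read_outputs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
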