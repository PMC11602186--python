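"""Pupil and whisking signal extraction, and alignment to a 1 kHz timebase.

Pupil radius is the geometric mean of the semi-axes of an ellipse fitted to a
binary pupil mask (image second moments).  The radius trace is repaired for
blinks (points far from a 3-s running median) and smoothed over five frames
(83 ms at 60 fps).

Whisking is quantified from the mean whisker angle: the angle is band-passed
4-30 Hz, the Hilbert transform gives the whisk-cycle phase, and the upper /
lower envelopes are the unfiltered angle sampled where phase crosses 0 (most
protracted) and +/-pi (most retracted).  Whisking amplitude is the difference
of the two envelopes.

All behavioral series are finally linearly interpolated onto a common 1 kHz
grid; lick times are binarized per millisecond and spike times rounded to the
nearest millisecond.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal
from skimage import measure

from .session import Session
from .task_schedule import ParameterError

_MS = 0.001


@dataclass
class PupilTrace:
    time: np.ndarray
    raw: np.ndarray
    clean: np.ndarray
    blink: np.ndarray   # boolean per frame
    fs: float


@dataclass
class WhiskTrace:
    time: np.ndarray
    angle: np.ndarray
    bandpassed: np.ndarray
    phase: np.ndarray
    upper: np.ndarray
    lower: np.ndarray
    amplitude: np.ndarray
    flagged: np.ndarray  # spans without whisk-cycle crossings for > 0.5 s
    fs: float


def pupil_radius_from_mask(mask: np.ndarray) -> float:
    """Ellipse-equivalent pupil radius (pixels) from a binary mask.

    The ellipse comes from the mask's second-order moments; the radius is
    sqrt(a*b) with a, b the semi-major and semi-minor axes.  Returns NaN for
    masks with fewer than 5 foreground pixels (flagged missing frame).
    """
    mask = np.asarray(mask).astype(bool)
    if mask.sum() < 5:
        return float("nan")
    props = measure.regionprops(mask.astype(np.uint8))[0]
    a = props.axis_major_length / 2.0
    b = props.axis_minor_length / 2.0
    return float(np.sqrt(a * b))


def clean_pupil(
    time: np.ndarray,
    raw: np.ndarray,
    fs: float,
    median_span: float = 3.0,
    k_mad: float = 5.0,
    smooth_frames: int = 5,
) -> PupilTrace:
    """Blink-repair and smooth a raw pupil radius trace.

    Frames where |raw - running median(3 s)| exceeds ``k_mad`` times the MAD
    of that residual (or that are non-finite) are flagged as blinks and
    linearly interpolated, then the trace is smoothed with a
    ``smooth_frames``-point moving average.
    """
    raw = np.asarray(raw, dtype=float)
    time = np.asarray(time, dtype=float)
    size = max(3, int(round(median_span * fs)) | 1)
    finite = np.isfinite(raw)
    if not finite.any():
        raise ParameterError("pupil trace contains no valid frames")
    filled = raw.copy()
    if not finite.all():
        filled[~finite] = np.interp(time[~finite], time[finite], raw[finite])
    med = ndimage.median_filter(filled, size=size, mode="nearest")
    resid = filled - med
    mad = np.median(np.abs(resid - np.median(resid)))
    # the running median tracks a smooth noise-free trace exactly, making the
    # MAD degenerate; sub-percent deviations are never blinks, so floor the
    # scale at 1% of the typical radius
    scale = max(mad, 0.01 * float(np.median(np.abs(filled))))
    blink = ~finite | (np.abs(resid) > k_mad * scale)
    if blink.all():
        raise ParameterError("every pupil frame flagged as blink; trace unusable")
    repaired = filled.copy()
    if blink.any():
        repaired[blink] = np.interp(time[blink], time[~blink], filled[~blink])
    clean = ndimage.uniform_filter1d(repaired, size=smooth_frames, mode="nearest")
    return PupilTrace(time=time, raw=raw, clean=clean, blink=blink, fs=fs)


def _phase_crossings(phase: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sample indices of phase-0 (protracted) and +/-pi (retracted) crossings."""
    # phase 0: sign change without wrap (|phase| small on both sides)
    up = np.nonzero((phase[:-1] < 0) & (phase[1:] >= 0) & (np.abs(phase[:-1]) < np.pi / 2))[0]
    # +/-pi: wrap from +pi side to -pi side
    wrap = np.nonzero((phase[:-1] > np.pi / 2) & (phase[1:] < -np.pi / 2))[0]
    return up, wrap


def whisking_amplitude(
    time: np.ndarray,
    angle: np.ndarray,
    fs: float,
    band: tuple[float, float] = (4.0, 30.0),
    gap: float = 0.5,
) -> WhiskTrace:
    """Whisking amplitude from the mean whisker angle.

    Zero-phase Butterworth band-pass (order 2 per pass), Hilbert phase, and
    envelopes from the unfiltered angle at phase crossings, linearly
    interpolated between whisk cycles.  Spans more than ``gap`` seconds from
    any crossing are flagged and their amplitude decayed toward zero.
    """
    angle = np.asarray(angle, dtype=float)
    time = np.asarray(time, dtype=float)
    if angle.size < fs:
        raise ParameterError("whisker trace shorter than 1 s")
    if fs <= 2 * band[1]:
        raise ParameterError(f"sampling rate {fs} too low for band {band}")
    sos = signal.butter(2, band, btype="bandpass", fs=fs, output="sos")
    bp = signal.sosfiltfilt(sos, angle)
    analytic = signal.hilbert(bp)
    phase = np.angle(analytic)

    up, wrap = _phase_crossings(phase)
    n = angle.size
    if up.size >= 2 and wrap.size >= 2:
        upper = np.interp(np.arange(n), up, angle[up])
        lower = np.interp(np.arange(n), wrap, angle[wrap])
        amplitude = np.maximum(upper - lower, 0.0)
    else:
        upper = np.full(n, angle.mean())
        lower = upper.copy()
        amplitude = np.zeros(n)

    crossings = np.sort(np.concatenate([up, wrap]))
    flagged = np.ones(n, dtype=bool)
    if crossings.size:
        idx = np.arange(n)
        pos = np.searchsorted(crossings, idx)
        left = crossings[np.clip(pos - 1, 0, crossings.size - 1)]
        right = crossings[np.clip(pos, 0, crossings.size - 1)]
        dist = np.minimum(np.abs(idx - left), np.abs(idx - right)) / fs
        flagged = dist > gap
        amplitude = np.where(flagged, amplitude * np.exp(-(dist - gap) / gap), amplitude)
    return WhiskTrace(
        time=time, angle=angle, bandpassed=bp, phase=phase,
        upper=upper, lower=lower, amplitude=amplitude, flagged=flagged, fs=fs,
    )


def round_spikes_ms(spikes: np.ndarray) -> np.ndarray:
    """Spike times rounded to the nearest millisecond."""
    return np.round(np.asarray(spikes, dtype=float), 3)


def _check_gaps(time: np.ndarray, name: str, max_gap: float = 1.0) -> None:
    if time.size >= 2 and np.max(np.diff(time)) > max_gap:
        raise ParameterError(f"gap longer than {max_gap} s in source trace {name!r}")


def align_1khz(session: Session) -> pd.DataFrame:
    """All behavioral series on one 1 kHz grid.

    Columns: ``time_ms`` (integer), ``pupil`` (cleaned radius, px),
    ``whisk_amp`` (degrees), ``lick`` (0/1 per ms).  Per-trace sync offsets
    from session metadata are applied before interpolation.
    """
    dur = session.duration
    off = session.sync_offsets
    t_p = session.pupil_t + off.get("pupil", 0.0)
    t_w = session.whisk_t + off.get("whisker", 0.0)
    _check_gaps(t_p, "pupil")
    _check_gaps(t_w, "whisker")
    pupil = clean_pupil(t_p, session.pupil_r, session.pupil_fs)
    whisk = whisking_amplitude(t_w, session.whisk_angle, session.whisk_fs)

    n = int(round(dur / _MS))
    grid = np.arange(n) * _MS
    out = pd.DataFrame(
        {
            "time_ms": np.arange(n, dtype=np.int64),
            "pupil": np.interp(grid, t_p, pupil.clean),
            "whisk_amp": np.interp(grid, t_w, whisk.amplitude),
            "lick": np.zeros(n, dtype=np.int8),
        }
    )
    licks = session.licks + off.get("lick", 0.0)
    if licks.size:
        idx = np.round(licks / _MS).astype(np.int64)
        out.loc[idx[(idx >= 0) & (idx < n)], "lick"] = 1
    return out
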