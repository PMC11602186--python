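"""Stimulus timing model of the cross-modal conditioning task.

The full version of the task presents 2-s stimuli of two modalities (an air
puff to the whiskers and a drifting grating) as two independent renewal
processes.  Each inter-stimulus interval (ISI) is drawn as an exponential
variate (mean 10 s) plus a uniform offset (8-12 s), capped at 55 s and
quantized to whole seconds, for a mean ISI of 20 s.  Beyond the offset the
hazard rate of the next stimulus is flat, so a stimulus gives the animal no
information about the timing of the next one.

This module generates such schedules for the simulator and provides the
hazard-rate estimator used to audit the design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

MODALITIES = ("tactile", "visual")


class ParameterError(ValueError):
    """Invalid task or generator parameter."""


@dataclass(frozen=True)
class ISIParams:
    """Parameters of the shifted-exponential ISI distribution.

    ISI = min(cap, Exp(exp_mean) + U(offset_lo, offset_hi)), quantized to
    the nearest multiple of ``bin``.  Defaults are the full-task values.
    """

    exp_mean: float = 10.0
    offset_lo: float = 8.0
    offset_hi: float = 12.0
    cap: float = 55.0
    bin: float = 1.0

    def __post_init__(self) -> None:
        if not self.exp_mean > 0:
            raise ParameterError(f"exp_mean must be > 0, got {self.exp_mean}")
        if not 0 <= self.offset_lo <= self.offset_hi:
            raise ParameterError(
                f"need 0 <= offset_lo <= offset_hi, got ({self.offset_lo}, {self.offset_hi})"
            )
        if not self.cap > self.offset_hi:
            raise ParameterError(f"cap must exceed offset_hi, got cap={self.cap}")
        if not self.bin > 0:
            raise ParameterError(f"bin must be > 0, got {self.bin}")

    @property
    def mean(self) -> float:
        """Nominal mean ISI ignoring the cap (exp_mean + mid-offset)."""
        return self.exp_mean + 0.5 * (self.offset_lo + self.offset_hi)


@dataclass(frozen=True)
class StimulusEvent:
    """One stimulus presentation; the stimulus occupies [onset, onset+duration)."""

    modality: str
    onset: float
    duration: float = 2.0
    rewarded: bool = False

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ParameterError(f"unknown modality {self.modality!r}")
        if self.onset < 0:
            raise ParameterError(f"onset must be >= 0, got {self.onset}")
        if not self.duration > 0:
            raise ParameterError(f"duration must be > 0, got {self.duration}")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass
class StimulusSchedule:
    """Interleaved two-modality event stream with the reward contingency."""

    events: list[StimulusEvent]
    session_duration: float
    params: dict[str, ISIParams]
    conditioning: str

    def __post_init__(self) -> None:
        if self.conditioning not in MODALITIES:
            raise ParameterError(f"unknown conditioning {self.conditioning!r}")
        self.events = sorted(self.events, key=lambda e: (e.onset, e.modality))

    def onsets(self, modality: str | None = None) -> np.ndarray:
        evs = self.events if modality is None else self.by_modality(modality)
        return np.array([e.onset for e in evs], dtype=float)

    def by_modality(self, modality: str) -> list[StimulusEvent]:
        if modality not in MODALITIES:
            raise ParameterError(f"unknown modality {modality!r}")
        return [e for e in self.events if e.modality == modality]

    def rewarded_events(self) -> list[StimulusEvent]:
        return [e for e in self.events if e.rewarded]

    def reward_times(self) -> np.ndarray:
        """Reward delivery times: the offset of each conditioned stimulus."""
        return np.array([e.offset for e in self.rewarded_events()], dtype=float)


@dataclass
class HazardCurve:
    """Estimated conditional probability of a stimulus per elapsed-time bin."""

    t: np.ndarray
    hazard: np.ndarray
    at_risk: np.ndarray
    bin: float = field(default=1.0)


def _as_rng(seed: int | np.random.Generator) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def draw_isis(n: int, params: ISIParams, seed: int | np.random.Generator) -> np.ndarray:
    """Draw ``n`` inter-stimulus intervals from the task distribution.

    Each ISI is min(cap, Exp(exp_mean) + U(offset_lo, offset_hi)); the cap is
    applied before quantization, and quantization rounds to the nearest
    multiple of ``params.bin`` (mean-preserving).
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ParameterError(f"n must be a positive integer, got {n!r}")
    rng = _as_rng(seed)
    raw = rng.exponential(params.exp_mean, size=n) + rng.uniform(
        params.offset_lo, params.offset_hi, size=n
    )
    capped = np.minimum(raw, params.cap)
    return np.round(capped / params.bin) * params.bin


def draw_shaping_isis(
    n: int, lo: float = 8.0, hi: float = 12.0, seed: int | np.random.Generator = 0
) -> np.ndarray:
    """ISIs of the shaping (trial-based) task: uniform 8-12 s."""
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ParameterError(f"n must be a positive integer, got {n!r}")
    if not 0 <= lo <= hi:
        raise ParameterError(f"need 0 <= lo <= hi, got ({lo}, {hi})")
    rng = _as_rng(seed)
    return rng.uniform(lo, hi, size=n)


def _event_onsets(duration: float, params: ISIParams, rng: np.random.Generator) -> np.ndarray:
    """Onsets of one modality stream: cumulative ISIs from session start."""
    # first event one ISI from t=0 keeps the process stationary
    n_guess = max(int(duration / params.mean * 1.5) + 10, 10)
    onsets: list[float] = []
    t = 0.0
    while True:
        isis = draw_isis(n_guess, params, rng)
        for isi in isis:
            t += isi
            if t >= duration:
                return np.array(onsets)
            onsets.append(t)


def build_schedule(
    duration: float,
    params_tactile: ISIParams | None = None,
    params_visual: ISIParams | None = None,
    conditioning: str = "tactile",
    seed: int | np.random.Generator = 0,
    stim_duration: float = 2.0,
    shaping: bool = False,
) -> StimulusSchedule:
    """Build a two-modality schedule with independent ISI streams.

    With ``shaping=True`` the trial-based shaping task is generated instead:
    a single alternating stream with uniform 8-12 s ISIs and random modality
    per trial (balanced 50:50 in expectation).
    """
    params_tactile = params_tactile or ISIParams()
    params_visual = params_visual or ISIParams()
    if conditioning not in MODALITIES:
        raise ParameterError(f"unknown conditioning {conditioning!r}")
    if duration <= 0:
        raise ParameterError(f"duration must be > 0, got {duration}")
    rng = _as_rng(seed)

    events: list[StimulusEvent] = []
    if shaping:
        t = 0.0
        lo, hi = params_tactile.offset_lo, params_tactile.offset_hi
        while True:
            t += rng.uniform(lo, hi) + stim_duration
            if t >= duration:
                break
            modality = MODALITIES[int(rng.integers(2))]
            events.append(
                StimulusEvent(modality, round(t, 6), stim_duration, modality == conditioning)
            )
    else:
        for modality, params in (("tactile", params_tactile), ("visual", params_visual)):
            for onset in _event_onsets(duration, params, rng):
                events.append(
                    StimulusEvent(modality, round(onset, 6), stim_duration, modality == conditioning)
                )

    if not events:
        warnings.warn(
            f"duration {duration} s is shorter than one mean ISI; schedule is empty",
            stacklevel=2,
        )
    return StimulusSchedule(
        events=events,
        session_duration=duration,
        params={"tactile": params_tactile, "visual": params_visual},
        conditioning=conditioning,
    )


def estimate_hazard(isis: np.ndarray, bin: float = 1.0) -> HazardCurve:
    """Discrete hazard of the ISI distribution.

    hazard(t) = (# ISIs in [t, t+bin)) / (# ISIs >= t).  The at-risk counts
    are monotonically non-increasing; bins with nobody at risk are dropped.
    """
    isis = np.asarray(isis, dtype=float)
    if isis.size == 0:
        raise ParameterError("cannot estimate a hazard from no ISIs")
    if not bin > 0:
        raise ParameterError(f"bin must be > 0, got {bin}")
    edges = np.arange(0.0, isis.max() + 2 * bin, bin)
    counts, _ = np.histogram(isis, bins=edges)
    at_risk = counts[::-1].cumsum()[::-1]
    keep = at_risk > 0
    hazard = np.zeros_like(counts, dtype=float)
    hazard[keep] = counts[keep] / at_risk[keep]
    return HazardCurve(t=edges[:-1][keep], hazard=hazard[keep], at_risk=at_risk[keep], bin=bin)


def hazard_slope(
    curve: HazardCurve, t_lo: float, t_hi: float, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Slope of a linear fit to the hazard over [t_lo, t_hi], with its CI.

    A flat hazard (the design goal of the task) has a slope CI containing 0.
    """
    sel = (curve.t >= t_lo) & (curve.t <= t_hi)
    if sel.sum() < 3:
        raise ParameterError("fewer than 3 hazard bins in the requested range")
    fit = stats.linregress(curve.t[sel], curve.hazard[sel])
    half = stats.t.ppf(0.5 + conf / 2, sel.sum() - 2) * fit.stderr
    return fit.slope, (fit.slope - half, fit.slope + half)
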