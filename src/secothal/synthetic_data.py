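"""Synthetic session generator with known ground truth.

Generates complete sessions — flat-hazard stimulus schedules, inhomogeneous-
Poisson spike trains, anticipatory/consummatory licking, slow pupil dynamics,
and oscillatory whisker angle — so that every downstream analysis stage can be
tested by parameter recovery, without any recorded data.

The generative model mirrors the structure the analyses assume:

* Each cell has a baseline rate plus stimulus-locked kernels (a brief onset
  step at a true latency, a sustained component for the 2-s stimulus, and an
  offset/consumption component for 2 s after the rewarded stimulus) and
  linear couplings to the realized whisking amplitude, pupil radius, and lick
  rate.  The instantaneous rate is rectified at zero and spikes are drawn by
  Poisson thinning, so spikes are conditioned on the realized behavior —
  the same direction the movement regression assumes.
* The pupil is a mean-reverting Ornstein-Uhlenbeck process (tau ~ 2 s) plus
  per-event constriction (visual, a luminance reflex) and dilation (arousal)
  kernels.
* The whisker angle is an ~8 Hz carrier whose peak-to-trough envelope is a
  rectified slow OU process plus event-triggered increments; the envelope is
  the ground-truth whisking amplitude.
* Licks are an inhomogeneous point process: low baseline, an anticipatory
  ramp during the conditioned stimulus, and a consumption burst for 2 s after
  reward.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.signal import lfilter

from .session import Session
from .task_schedule import (
    ISIParams,
    MODALITIES,
    ParameterError,
    StimulusSchedule,
    build_schedule,
)

_MS = 0.001


# ---------------------------------------------------------------------------
# configuration and ground truth
# ---------------------------------------------------------------------------

#: axis-aligned anatomical boxes (µm, atlas-like): (ap, dv, ml) ranges.
#: LP sits dorsal to POm; the shared boundary is the dv = 2800 µm plane.
REGION_BOXES = {
    "POm": {"ap": (-2300.0, -1400.0), "dv": (2800.0, 3600.0), "ml": (1000.0, 1700.0)},
    "LP": {"ap": (-2300.0, -1400.0), "dv": (2000.0, 2800.0), "ml": (1200.0, 2000.0)},
}
BOUNDARY_DV_UM = 2800.0


@dataclass
class SessionConfig:
    """Study conditions of one simulated session.

    Defaults emulate the recording sessions the pipeline targets: ~33 min of
    the full task (mean ISI 20 s per modality, hence ~100 presentations of
    each stimulus), 30 simultaneously recorded cells, two-thirds in POm.
    """

    duration: float = 2000.0
    n_cells: int = 30
    frac_pom: float = 2 / 3
    conditioning: str = "tactile"
    stim_duration: float = 2.0
    isi_tactile: ISIParams = field(default_factory=ISIParams)
    isi_visual: ISIParams = field(default_factory=ISIParams)
    pupil_fs: float = 60.0
    whisk_fs: float = 125.0

    # cell population
    baseline_range_pom: tuple[float, float] = (6.0, 18.0)
    baseline_range_lp: tuple[float, float] = (3.0, 12.0)
    p_responsive: float = 0.5      # per modality: any stimulus kernel at all
    p_step: float = 0.5            # responsive cells with a sharp onset step
    onset_amp_range: tuple[float, float] = (18.0, 30.0)   # spikes/s, 100 ms
    sustained_amp_range: tuple[float, float] = (4.0, 12.0)
    p_suppressed: float = 0.1      # sustained component is negative instead
    suppressed_amp_range: tuple[float, float] = (-6.0, -3.0)
    p_offset: float = 0.4
    offset_amp_range: tuple[float, float] = (4.0, 12.0)
    latency_range: tuple[float, float] = (0.01, 0.1)      # s, rounded to 1 ms
    onset_kernel_width: float = 0.1                       # s

    # movement coupling (spikes/s per predictor unit)
    p_coupled: float = 0.7
    beta_whisk_range: tuple[float, float] = (0.1, 0.4)    # per degree
    beta_pupil_range: tuple[float, float] = (0.1, 0.5)    # per pixel
    beta_lick_range: tuple[float, float] = (0.2, 0.8)     # per (licks/s)

    # pupil (pixels); spontaneous arousal fluctuations dominate the evoked
    # kernels, as in awake mice
    pupil_setpoint: float = 20.0
    pupil_tau: float = 2.0
    pupil_sigma: float = 2.0
    pupil_constrict_amp: float = 1.5      # visual events (luminance reflex)
    pupil_dilate_amp: float = 2.5         # conditioned stimulus (arousal)
    pupil_dilate_amp_uncond_tactile: float = 1.0   # the air puff stays salient

    # whisker (degrees); spontaneous whisking bouts span a wide amplitude
    # range, with a modest evoked increment on top
    whisk_carrier_hz: float = 8.0
    whisk_angle_offset: float = 70.0
    whisk_env_mean: float = 10.0
    whisk_env_sigma: float = 5.0
    whisk_env_tau: float = 1.0
    whisk_amp_tactile: float = 6.0        # evoked envelope increment, air puff
    whisk_amp_visual_cs: float = 3.0      # grating when it is the CS+
    whisk_amp_visual_uncond: float = 0.5

    # licking (events/s)
    lick_base_rate: float = 0.3
    lick_ramp_peak: float = 3.5           # anticipatory ramp at CS+ offset
    lick_ramp_delay: float = 0.3          # s after CS+ onset before ramping
    lick_consumption_rate: float = 7.0    # free parameter; see methods note
    lick_consumption_dur: float = 2.0
    lick_rate_bin: float = 0.25           # grain of the lick-rate signal cells follow

    # optional linear dependence of the tactile sustained kernel on ML
    # position (spikes/s per mm), applied in visually conditioned sessions to
    # emulate an anatomical selectivity gradient
    si_gradient: float = 0.0

    def validate(self) -> "SessionConfig":
        bad = []
        if self.duration <= 0:
            bad.append("duration")
        if self.n_cells < 0:
            bad.append("n_cells")
        if not 0 <= self.frac_pom <= 1:
            bad.append("frac_pom")
        if self.conditioning not in MODALITIES:
            bad.append("conditioning")
        for name in ("p_responsive", "p_step", "p_suppressed", "p_offset", "p_coupled"):
            if not 0 <= getattr(self, name) <= 1:
                bad.append(name)
        if self.pupil_setpoint <= 0 or self.pupil_tau <= 0 or self.pupil_sigma < 0:
            bad.append("pupil parameters")
        if bad:
            raise ParameterError(f"invalid SessionConfig fields: {', '.join(bad)}")
        return self


@dataclass
class CellSpec:
    """Generative parameters of one cell (per-modality kernels + couplings)."""

    cell_id: str
    region: str
    ap_um: float
    dv_um: float
    ml_um: float
    dist_to_boundary_um: float
    baseline_rate: float
    onset_amp: dict[str, float]
    sustained_amp: dict[str, float]
    offset_amp: float
    latency_true: dict[str, float]
    beta_whisk: float = 0.0
    beta_pupil: float = 0.0
    beta_lick: float = 0.0

    def is_step(self, modality: str) -> bool:
        """Sharp-onset cell: suitable for latency-recovery checks."""
        return self.onset_amp[modality] > 0


@dataclass
class GroundTruth:
    """Everything needed to regenerate a session and score recovery."""

    seed: int
    config: SessionConfig
    cells: list[CellSpec]
    si_true: dict[str, float] = field(default_factory=dict)
    signal_means: dict[str, dict[str, float]] = field(default_factory=dict)

    def cell(self, cell_id: str) -> CellSpec:
        for c in self.cells:
            if c.cell_id == cell_id:
                return c
        raise KeyError(cell_id)

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "config": asdict(self.config),
            "cells": [asdict(c) for c in self.cells],
            "si_true": self.si_true,
            "signal_means": self.signal_means,
        }
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        cfg = d["config"]
        cfg["isi_tactile"] = ISIParams(**cfg["isi_tactile"])
        cfg["isi_visual"] = ISIParams(**cfg["isi_visual"])
        for k in ("baseline_range_pom", "baseline_range_lp", "onset_amp_range",
                  "sustained_amp_range", "suppressed_amp_range", "offset_amp_range",
                  "latency_range", "beta_whisk_range", "beta_pupil_range",
                  "beta_lick_range"):
            cfg[k] = tuple(cfg[k])
        return cls(
            seed=d["seed"],
            config=SessionConfig(**cfg),
            cells=[CellSpec(**c) for c in d["cells"]],
            si_true=d["si_true"],
            signal_means=d["signal_means"],
        )


# ---------------------------------------------------------------------------
# point processes
# ---------------------------------------------------------------------------

def generate_spike_train(
    rate_fn,
    duration: float,
    seed: int | np.random.Generator,
    rate_max: float | None = None,
) -> np.ndarray:
    """Inhomogeneous-Poisson spike times on [0, duration) by thinning.

    Candidates are drawn at ``rate_max`` and accepted with probability
    rate_fn(t)/rate_max.  ``rate_fn`` must accept a vector of times; if
    ``rate_max`` is omitted it is probed on a 1-ms grid (and the draw fails
    loudly if the probe underestimated the true bound).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if duration <= 0:
        raise ParameterError(f"duration must be > 0, got {duration}")
    if rate_max is None:
        probe = np.asarray(rate_fn(np.arange(0.0, duration, _MS)), dtype=float)
        if not np.all(np.isfinite(probe)):
            raise ParameterError("rate_fn is unbounded or non-finite on [0, duration)")
        rate_max = float(probe.max()) * 1.0 + 1e-12
    if not np.isfinite(rate_max) or rate_max < 0:
        raise ParameterError(f"rate_max must be finite and >= 0, got {rate_max}")
    n = rng.poisson(rate_max * duration)
    if n == 0:
        return np.empty(0)
    t = rng.uniform(0.0, duration, size=n)
    r = np.asarray(rate_fn(t), dtype=float)
    if np.any(r > rate_max * (1 + 1e-9)):
        raise ParameterError("rate_fn exceeds rate_max; thinning bound violated")
    keep = rng.uniform(size=n) < r / rate_max
    return np.sort(t[keep])


def _spikes_from_grid(rate: np.ndarray, dt: float, rng: np.random.Generator) -> np.ndarray:
    """Thinning specialized to a piecewise-constant rate sampled on a grid."""
    rate_max = float(rate.max())
    duration = rate.size * dt
    if rate_max <= 0:
        return np.empty(0)
    n = rng.poisson(rate_max * duration)
    if n == 0:
        return np.empty(0)
    t = rng.uniform(0.0, duration, size=n)
    idx = np.minimum((t / dt).astype(np.int64), rate.size - 1)
    keep = rng.uniform(size=n) < rate[idx] / rate_max
    return np.sort(t[keep])


# ---------------------------------------------------------------------------
# behavior signals
# ---------------------------------------------------------------------------

def _ou(n: int, dt: float, tau: float, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary zero-mean OU samples via its exact AR(1) discretization."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    a = np.exp(-dt / tau)
    w = rng.standard_normal(n) * sigma * np.sqrt(1 - a * a)
    w[0] = rng.standard_normal() * sigma
    return lfilter([1.0], [1.0, -a], w)


def _alpha_kernel(t: np.ndarray, peak_t: float) -> np.ndarray:
    """Unit-peak alpha function (t/tp)·exp(1 − t/tp), zero for t < 0."""
    out = np.zeros_like(t)
    pos = t >= 0
    x = t[pos] / peak_t
    out[pos] = x * np.exp(1.0 - x)
    return out


def _add_events(sig: np.ndarray, t: np.ndarray, onsets: np.ndarray, kernel: np.ndarray) -> None:
    """Add a causal kernel (sampled on the grid of t) at each onset, in place."""
    dt = t[1] - t[0] if t.size > 1 else 1.0
    k = kernel.size
    for onset in onsets:
        i0 = int(np.ceil((onset - t[0]) / dt))
        if i0 >= sig.size:
            continue
        i0 = max(i0, 0)
        span = min(k, sig.size - i0)
        sig[i0 : i0 + span] += kernel[:span]


def _pupil_kernels(config: SessionConfig, fs: float) -> dict[str, np.ndarray]:
    """Single-event pupil kernels (pixels) per modality, on the pupil grid."""
    t = np.arange(0.0, 8.0, 1.0 / fs)
    constrict = -config.pupil_constrict_amp * _alpha_kernel(t, 0.4) * (t < 2.5)
    dilate = _alpha_kernel(t, 1.5)
    cs = config.conditioning
    out = {"tactile": np.zeros_like(t), "visual": constrict.copy()}
    out[cs] = out[cs] + config.pupil_dilate_amp * dilate
    if cs == "visual":
        out["tactile"] = out["tactile"] + config.pupil_dilate_amp_uncond_tactile * dilate
    return out


def _whisk_kernels(config: SessionConfig, fs: float) -> dict[str, np.ndarray]:
    """Single-event whisking-envelope increments (degrees) per modality."""
    t = np.arange(0.0, 4.0, 1.0 / fs)
    shape = _alpha_kernel(t, 0.5)
    amp_vis = (
        config.whisk_amp_visual_cs
        if config.conditioning == "visual"
        else config.whisk_amp_visual_uncond
    )
    return {"tactile": config.whisk_amp_tactile * shape, "visual": amp_vis * shape}


def _lick_kernels(config: SessionConfig, fs: float) -> dict[str, np.ndarray]:
    """Single-event additions to the lick intensity (licks/s) per modality."""
    t = np.arange(0.0, config.stim_duration + config.lick_consumption_dur + 0.5, 1.0 / fs)
    ramp = np.clip(
        (t - config.lick_ramp_delay) / (config.stim_duration - config.lick_ramp_delay), 0, 1
    )
    ramp[t >= config.stim_duration] = 0.0
    consume = ((t >= config.stim_duration)
               & (t < config.stim_duration + config.lick_consumption_dur)).astype(float)
    cs_kernel = config.lick_ramp_peak * ramp + config.lick_consumption_rate * consume
    out = {m: np.zeros_like(t) for m in MODALITIES}
    out[config.conditioning] = cs_kernel
    return out


def generate_behavior_signals(
    schedule: StimulusSchedule,
    config: SessionConfig,
    seed: int | np.random.Generator,
) -> tuple[np.ndarray, tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Realize licks, pupil, and whisker angle for a schedule.

    Returns ``(licks, (pupil_t, pupil_r), (whisk_t, whisk_angle, whisk_env))``
    where ``whisk_env`` is the ground-truth peak-to-trough whisking amplitude.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    dur = schedule.session_duration

    # pupil at pupil_fs
    fs_p = config.pupil_fs
    t_p = np.round(np.arange(int(np.floor(dur * fs_p))) / fs_p, 6)
    radius = config.pupil_setpoint + _ou(t_p.size, 1 / fs_p, config.pupil_tau,
                                         config.pupil_sigma, rng)
    for mod, kern in _pupil_kernels(config, fs_p).items():
        _add_events(radius, t_p, schedule.onsets(mod), kern)
    np.maximum(radius, 0.5, out=radius)   # physical floor, pixels

    # whisker envelope + carrier at whisk_fs
    fs_w = config.whisk_fs
    t_w = np.round(np.arange(int(np.floor(dur * fs_w))) / fs_w, 6)
    env = config.whisk_env_mean + _ou(t_w.size, 1 / fs_w, config.whisk_env_tau,
                                      config.whisk_env_sigma, rng)
    np.maximum(env, 0.0, out=env)
    for mod, kern in _whisk_kernels(config, fs_w).items():
        _add_events(env, t_w, schedule.onsets(mod), kern)
    phase0 = rng.uniform(0, 2 * np.pi)
    angle = config.whisk_angle_offset + 0.5 * env * np.sin(
        2 * np.pi * config.whisk_carrier_hz * t_w + phase0
    )

    # licks as an inhomogeneous point process (100 Hz intensity grid)
    fs_l = 100.0
    t_l = np.arange(int(np.floor(dur * fs_l))) / fs_l
    intensity = np.full(t_l.size, config.lick_base_rate)
    for mod, kern in _lick_kernels(config, fs_l).items():
        _add_events(intensity, t_l, schedule.onsets(mod), kern)
    licks = _spikes_from_grid(intensity, 1 / fs_l, rng)

    return (
        np.round(licks, 6),
        (t_p, np.round(radius, 6)),
        (t_w, np.round(angle, 6), env),
    )


# ---------------------------------------------------------------------------
# cells and spikes
# ---------------------------------------------------------------------------

def _draw_cells(config: SessionConfig, rng: np.random.Generator) -> list[CellSpec]:
    n_pom = int(round(config.n_cells * config.frac_pom))
    regions = ["POm"] * n_pom + ["LP"] * (config.n_cells - n_pom)
    cells = []
    for i, region in enumerate(regions):
        box = REGION_BOXES[region]
        ap = rng.uniform(*box["ap"])
        dv = rng.uniform(*box["dv"])
        ml = rng.uniform(*box["ml"])
        lo, hi = (config.baseline_range_pom if region == "POm"
                  else config.baseline_range_lp)
        onset, sustained, latency = {}, {}, {}
        for mod in MODALITIES:
            if rng.uniform() < config.p_responsive:
                if rng.uniform() < config.p_suppressed:
                    sustained[mod] = rng.uniform(*config.suppressed_amp_range)
                    onset[mod] = 0.0
                else:
                    sustained[mod] = rng.uniform(*config.sustained_amp_range)
                    onset[mod] = (
                        rng.uniform(*config.onset_amp_range)
                        if rng.uniform() < config.p_step
                        else 0.0
                    )
                latency[mod] = round(float(rng.uniform(*config.latency_range)), 3)
            else:
                sustained[mod] = 0.0
                onset[mod] = 0.0
                latency[mod] = 0.0
        if config.si_gradient != 0.0 and config.conditioning == "visual":
            ml_mid = 0.5 * sum(box["ml"])
            if sustained["tactile"] != 0.0 or onset["tactile"] != 0.0:
                sustained["tactile"] = max(
                    0.0, sustained["tactile"] + config.si_gradient * (ml - ml_mid) / 1000.0
                )
        coupled = rng.uniform() < config.p_coupled
        cells.append(
            CellSpec(
                cell_id=f"c{i:03d}",
                region=region,
                ap_um=round(ap, 1),
                dv_um=round(dv, 1),
                ml_um=round(ml, 1),
                dist_to_boundary_um=round(abs(dv - BOUNDARY_DV_UM), 1),
                baseline_rate=round(float(rng.uniform(lo, hi)), 3),
                onset_amp=onset,
                sustained_amp=sustained,
                offset_amp=(round(float(rng.uniform(*config.offset_amp_range)), 3)
                            if rng.uniform() < config.p_offset else 0.0),
                latency_true=latency,
                beta_whisk=round(float(rng.uniform(*config.beta_whisk_range)), 4) if coupled else 0.0,
                beta_pupil=round(float(rng.uniform(*config.beta_pupil_range)), 4) if coupled else 0.0,
                beta_lick=round(float(rng.uniform(*config.beta_lick_range)), 4) if coupled else 0.0,
            )
        )
    return cells


def _kernel_track(
    cell: CellSpec, schedule: StimulusSchedule, grid_n: int, config: SessionConfig
) -> np.ndarray:
    """Stimulus-locked rate component of one cell on the 1-ms grid."""
    track = np.zeros(grid_n, dtype=np.float64)
    stim_ms = int(round(config.stim_duration / _MS))
    for mod in MODALITIES:
        on_amp = cell.onset_amp[mod]
        sus_amp = cell.sustained_amp[mod]
        if on_amp == 0.0 and sus_amp == 0.0:
            continue
        lat_ms = int(round(cell.latency_true[mod] / _MS))
        width_ms = int(round(config.onset_kernel_width / _MS))
        for onset in schedule.onsets(mod):
            i0 = int(round(onset / _MS))
            a = min(i0 + lat_ms, grid_n)
            track[a : min(i0 + lat_ms + width_ms, grid_n)] += on_amp
            track[a : min(i0 + stim_ms, grid_n)] += sus_amp
    if cell.offset_amp != 0.0:
        off_ms = int(round(config.lick_consumption_dur / _MS))
        for ev in schedule.rewarded_events():
            i0 = int(round(ev.offset / _MS))
            track[min(i0, grid_n) : min(i0 + off_ms, grid_n)] += cell.offset_amp
    return track


def _expected_signal_changes(config: SessionConfig) -> dict[str, dict[str, float]]:
    """Mean event-triggered excursion of each signal over [0, 1) s, per modality.

    These are the movement-mediated contributions to a cell's expected
    stimulus-period rate change; computed from the same kernel templates the
    generator adds to the signals.
    """
    out: dict[str, dict[str, float]] = {}
    win = 1.0
    for name, kernels, fs in (
        ("whisk", _whisk_kernels(config, config.whisk_fs), config.whisk_fs),
        ("pupil", _pupil_kernels(config, config.pupil_fs), config.pupil_fs),
        ("lick", _lick_kernels(config, 100.0), 100.0),
    ):
        n_win = int(round(win * fs))
        out[name] = {m: float(kernels[m][:n_win].mean()) for m in MODALITIES}
    return out


def true_selectivity(cell: CellSpec, config: SessionConfig,
                     sig: dict[str, dict[str, float]] | None = None) -> float:
    """Ground-truth selectivity index of a cell.

    Expected rate change in the 1-s stimulus window combines the direct
    kernels with the movement-mediated pathway (coupling betas times the
    expected event-triggered signal excursions).  NaN when both expected
    responses are zero.
    """
    sig = sig or _expected_signal_changes(config)
    delta = {}
    for mod in MODALITIES:
        lat = cell.latency_true[mod]
        direct = cell.onset_amp[mod] * min(config.onset_kernel_width, max(0.0, 1.0 - lat)) \
            + cell.sustained_amp[mod] * max(0.0, 1.0 - lat)
        mediated = (
            cell.beta_whisk * sig["whisk"][mod]
            + cell.beta_pupil * sig["pupil"][mod]
            + cell.beta_lick * sig["lick"][mod]
        )
        delta[mod] = direct + mediated
    num = abs(delta["tactile"]) - abs(delta["visual"])
    den = abs(delta["tactile"]) + abs(delta["visual"])
    return float(num / den) if den > 0 else float("nan")


def generate_session(
    config: SessionConfig | None = None, seed: int = 0
) -> tuple[Session, GroundTruth]:
    """Generate one synthetic session and its ground truth."""
    config = (config or SessionConfig()).validate()
    rng = np.random.default_rng(seed)

    schedule = build_schedule(
        config.duration,
        config.isi_tactile,
        config.isi_visual,
        conditioning=config.conditioning,
        seed=rng,
        stim_duration=config.stim_duration,
    )
    licks, (t_p, radius), (t_w, angle, env) = generate_behavior_signals(schedule, config, rng)
    cells = _draw_cells(config, rng)

    # predictors on the 1-ms grid the spikes are conditioned on
    grid_n = int(round(config.duration / _MS))
    grid = np.arange(grid_n) * _MS
    whisk_1k = np.interp(grid, t_w, env)
    pupil_dev_1k = np.interp(grid, t_p, radius) - config.pupil_setpoint
    # the lick-rate signal cells follow: piecewise-constant counts per
    # lick_rate_bin (licks/s), i.e. the instantaneous rate at that grain
    lick_bin_ms = int(round(config.lick_rate_bin / _MS))
    n_lick_bins = grid_n // lick_bin_ms
    lick_counts = np.histogram(
        licks, bins=np.arange(n_lick_bins + 1) * config.lick_rate_bin
    )[0]
    lick_rate_1k = np.zeros(grid_n)
    lick_rate_1k[: n_lick_bins * lick_bin_ms] = np.repeat(
        lick_counts / config.lick_rate_bin, lick_bin_ms
    )

    spikes: dict[str, np.ndarray] = {}
    for cell in cells:
        rate = cell.baseline_rate + _kernel_track(cell, schedule, grid_n, config)
        if cell.beta_whisk:
            rate += cell.beta_whisk * whisk_1k
        if cell.beta_pupil:
            rate += cell.beta_pupil * pupil_dev_1k
        if cell.beta_lick:
            rate += cell.beta_lick * lick_rate_1k
        np.maximum(rate, 0.0, out=rate)
        spikes[cell.cell_id] = np.round(_spikes_from_grid(rate, _MS, rng), 6)

    cells_df = pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "region": [c.region for c in cells],
            "ap_um": [c.ap_um for c in cells],
            "dv_um": [c.dv_um for c in cells],
            "ml_um": [c.ml_um for c in cells],
            "dist_to_boundary_um": [c.dist_to_boundary_um for c in cells],
        }
    )
    session = Session(
        schedule=schedule,
        cells=cells_df,
        spikes=spikes,
        licks=licks,
        pupil_t=t_p,
        pupil_r=radius,
        whisk_t=t_w,
        whisk_angle=angle,
        pupil_fs=config.pupil_fs,
        whisk_fs=config.whisk_fs,
        seed=seed,
    ).validate()

    sig = _expected_signal_changes(config)
    truth = GroundTruth(
        seed=seed,
        config=config,
        cells=cells,
        si_true={c.cell_id: true_selectivity(c, config, sig) for c in cells},
        signal_means=sig,
    )
    return session, truth


def ellipse_mask(
    semi_major: float, semi_minor: float, rotation_deg: float = 0.0, supersample: int = 8
) -> np.ndarray:
    """Fair (area-preserving) rasterization of a filled ellipse.

    A pixel is foreground when at least half its area lies inside the
    ellipse, estimated by supersampling.  Exists to test the moment-based
    pupil radius estimator against a known shape.
    """
    if semi_major <= 0 or semi_minor <= 0:
        raise ParameterError("semi-axes must be positive")
    n = int(2 * max(semi_major, semi_minor)) + 5
    yy, xx = np.mgrid[-n : n + 1, -n : n + 1].astype(float)
    th = np.deg2rad(rotation_deg)
    cov = np.zeros(yy.shape)
    offs = (np.arange(supersample) + 0.5) / supersample - 0.5
    for dy in offs:
        for dx in offs:
            y, x = yy + dy, xx + dx
            yr = y * np.cos(th) - x * np.sin(th)
            xr = y * np.sin(th) + x * np.cos(th)
            cov += (yr / semi_major) ** 2 + (xr / semi_minor) ** 2 <= 1
    return cov / supersample**2 >= 0.5


def regenerate(truth: GroundTruth) -> tuple[Session, GroundTruth]:
    """Rebuild the exact session a GroundTruth came from (same config, seed)."""
    return generate_session(replace(truth.config), truth.seed)
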