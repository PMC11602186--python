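"""Movement and arousal models of firing.

Firing, licking, whisking amplitude, and pupil radius are binned into 250-ms
bins.  Each cell's binned rate is fit by ordinary least squares on whisking
amplitude, pupil radius, and lick rate (optionally plus air-puff, grating,
and reward indicator columns).  The residual series is a baseline-subtracted,
movement-corrected firing rate that can be event-aligned exactly like a
PSTH.  Lagged Pearson cross-correlations between rate and each behavioral
signal complete the picture; negative lags mean the rate precedes the signal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .config import AnalysisConfig
from .session import Session
from .signals import align_1khz
from .task_schedule import ParameterError

_MS = 0.001

MOVEMENT_PREDICTORS = ("whisk", "pupil", "lick")
STIMULUS_PREDICTORS = ("puff", "grating", "reward")


@dataclass
class BinnedSession:
    """All session series on one regular bin grid (default 250 ms)."""

    time: np.ndarray                 # bin midpoints, seconds
    bin: float
    rates: pd.DataFrame              # per-cell spikes/s per bin
    predictors: pd.DataFrame         # whisk, pupil, lick (+ indicators)

    @property
    def n_bins(self) -> int:
        return self.time.size


def bin_session(
    session: Session,
    bin: float = 0.25,
    aligned: pd.DataFrame | None = None,
    config: AnalysisConfig = AnalysisConfig(),
) -> BinnedSession:
    """Bin rates, movement signals, and stimulus indicators onto one grid.

    The bin must be a whole number of milliseconds.  Indicator columns are 1
    where the bin midpoint lies inside a stimulus window (or within the 2-s
    reward window following a conditioned stimulus).
    """
    n_ms = bin / _MS
    if abs(n_ms - round(n_ms)) > 1e-9:
        raise ParameterError(f"bin {bin} s is not a whole number of milliseconds")
    n_ms = int(round(n_ms))
    if aligned is None:
        aligned = align_1khz(session)
    n_bins = len(aligned) // n_ms
    edges = np.arange(n_bins + 1) * bin
    mid = edges[:-1] + bin / 2

    def _binmean(col: np.ndarray) -> np.ndarray:
        return col[: n_bins * n_ms].reshape(n_bins, n_ms).mean(axis=1)

    predictors = pd.DataFrame(
        {
            "whisk": _binmean(aligned["whisk_amp"].to_numpy(float)),
            "pupil": _binmean(aligned["pupil"].to_numpy(float)),
            "lick": _binmean(aligned["lick"].to_numpy(float)) / _MS,  # licks/s
        }
    )
    for name, windows in (
        ("puff", [(e.onset, e.offset) for e in session.schedule.by_modality("tactile")]),
        ("grating", [(e.onset, e.offset) for e in session.schedule.by_modality("visual")]),
        ("reward", [(t, t + config.reward_window) for t in session.schedule.reward_times()]),
    ):
        ind = np.zeros(n_bins)
        for a, b in windows:
            ind[(mid >= a) & (mid < b)] = 1.0
        predictors[name] = ind

    rates = pd.DataFrame(
        {
            cid: np.histogram(st, bins=edges)[0] / bin
            for cid, st in session.spikes.items()
        }
    )
    return BinnedSession(time=mid, bin=bin, rates=rates, predictors=predictors)


@dataclass
class MovementResult:
    """Fitted movement model of one cell."""

    cell_id: str
    params: pd.Series
    pvalues: pd.Series
    bse: pd.Series
    residuals: np.ndarray        # spikes/s per bin, observed - fitted
    time: np.ndarray
    include_stimuli: bool
    results: object              # underlying statsmodels OLSResults

    def tuning(self, alpha: float = 0.05) -> "TuningLabel":
        return tuning_classification(self, alpha)

    def summary(self):
        return self.results.summary()


@dataclass(frozen=True)
class TuningLabel:
    cell_id: str
    movement_tuned: bool
    stimulus_tuned: bool


class MovementModel:
    """OLS model of one cell's binned rate on movement (and stimulus) predictors.

    Fit over all session bins; residuals are event-aligned afterwards, which
    identifies the movement coupling from spontaneous epochs as well as
    trials.
    """

    def __init__(self, binned: BinnedSession, cell_id: str, include_stimuli: bool = False):
        if binned.n_bins < 100:
            raise ParameterError("need at least 100 bins for the movement regression")
        cols = list(MOVEMENT_PREDICTORS) + (
            list(STIMULUS_PREDICTORS) if include_stimuli else []
        )
        X = binned.predictors[cols]
        constant = [c for c in cols if np.ptp(X[c].to_numpy()) == 0]
        if constant:
            raise ParameterError(f"constant predictor column(s): {', '.join(constant)}")
        Xc = sm.add_constant(X)
        if np.linalg.matrix_rank(Xc.to_numpy()) < Xc.shape[1]:
            corr = X.corr().abs()
            np.fill_diagonal(corr.values, 0)
            i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
            raise ParameterError(
                f"rank-deficient design; most collinear columns: {corr.index[i]}, {corr.columns[j]}"
            )
        self.binned = binned
        self.cell_id = cell_id
        self.include_stimuli = include_stimuli
        self.exog = Xc
        self.endog = binned.rates[cell_id].to_numpy(float)

    def fit(self) -> MovementResult:
        # least-squares point estimates; heteroscedasticity-robust (HC1)
        # covariance, since binned count-derived rates have variance that
        # grows with the rate itself
        res = sm.OLS(self.endog, self.exog).fit(cov_type="HC1")
        return MovementResult(
            cell_id=self.cell_id,
            params=res.params,
            pvalues=res.pvalues,
            bse=res.bse,
            residuals=np.asarray(res.resid),
            time=self.binned.time,
            include_stimuli=self.include_stimuli,
            results=res,
        )


def movement_regression(
    binned: BinnedSession, cell_id: str, include_stimuli: bool = False
) -> MovementResult:
    return MovementModel(binned, cell_id, include_stimuli).fit()


def tuning_classification(result: MovementResult, alpha: float = 0.05) -> TuningLabel:
    """'Movement tuned' and/or 'stimulus tuned' from coefficient significance."""
    if not result.include_stimuli:
        raise ParameterError("tuning classification needs the model with stimulus predictors")
    p = result.pvalues
    return TuningLabel(
        cell_id=result.cell_id,
        movement_tuned=bool(any(p[c] < alpha for c in MOVEMENT_PREDICTORS)),
        stimulus_tuned=bool(any(p[c] < alpha for c in ("puff", "grating"))),
    )


def corrected_event_average(
    residuals: np.ndarray,
    time: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float] = (-2.0, 4.0),
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Event-aligned mean +/- SEM of a residual series.

    Returns ``(t_rel, mean, sem)`` on the residual bin grid relative to onset.
    Events whose window falls outside the residual span are skipped.
    """
    onsets = np.asarray(onsets, dtype=float)
    bin_ = time[1] - time[0]
    lo = int(np.round(window[0] / bin_))
    hi = int(np.round(window[1] / bin_))
    n_rel = hi - lo
    traces = []
    for on in onsets:
        i0 = int(np.round((on - time[0]) / bin_)) + lo
        if i0 < 0 or i0 + n_rel > residuals.size:
            continue
        traces.append(residuals[i0 : i0 + n_rel])
    if not traces:
        raise ParameterError("no events with a full residual window")
    tr = np.array(traces)
    t_rel = (np.arange(lo, hi) + 0.5) * bin_
    sem = tr.std(axis=0, ddof=1) / np.sqrt(len(traces)) if len(traces) > 1 else np.zeros(n_rel)
    return t_rel, tr.mean(axis=0), sem


def crosscorr(
    rate: np.ndarray, sig: np.ndarray, bin: float, max_lag: float = 2.0
) -> pd.DataFrame:
    """Pearson correlation at integer-bin lags in [-max_lag, +max_lag].

    r(lag) = corr(rate(t + lag), signal(t)): a peak at a negative lag means
    the rate precedes the signal.
    """
    rate = np.asarray(rate, dtype=float)
    sig = np.asarray(sig, dtype=float)
    if rate.size != sig.size:
        raise ParameterError("rate and signal must share one grid")
    if rate.size < 200:
        raise ParameterError("need at least 200 bins for a cross-correlation")
    if np.ptp(rate) == 0 or np.ptp(sig) == 0:
        return pd.DataFrame({"lag_s": [np.nan], "r": [np.nan], "undefined": [True]})
    x = rate - rate.mean()
    y = sig - sig.mean()
    max_k = int(round(max_lag / bin))
    lags, rs = [], []
    for k in range(-max_k, max_k + 1):
        if k >= 0:
            a, b = x[k:], y[: y.size - k] if k else y
        else:
            a, b = x[: x.size + k], y[-k:]
        denom = np.sqrt((a - a.mean()) @ (a - a.mean()) * ((b - b.mean()) @ (b - b.mean())))
        rs.append(float((a - a.mean()) @ (b - b.mean()) / denom) if denom > 0 else np.nan)
        lags.append(k * bin)
    return pd.DataFrame({"lag_s": lags, "r": rs, "undefined": False})
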