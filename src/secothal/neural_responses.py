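"""Event-triggered firing-rate analyses.

This module classifies each cell's stimulus responsiveness, measures response
latencies, and relates stimulus selectivity to anatomical position:

* PSTHs: per-event spike counts in half-open bins relative to stimulus onset.
* Responsiveness: per-event spike counts in a 1-s baseline ([-1, 0) s) and a
  1-s stimulus window ([0, 1) s), after excluding any event with a
  different-modality onset within +/-6 s.  A one-way ANOVA over {pooled
  baselines, air-puff-period counts, grating-period counts} is
  Holm-Bonferroni corrected across the cells of each region family; cells
  passing the corrected ANOVA are then tested per stimulus with a paired
  Wilcoxon signed-rank against their own baselines.
* Latency: the mean 10-ms-binned rate across events leaves the baseline
  confidence band (mean +/- 2.576 SD for two consecutive bins, or +/- 3.891
  SD for one bin, whichever is earlier), with the baseline taken over the 2 s
  before onset.
* Selectivity: SI = (|FR_A - FR_B| - |FR_G - FR_B|) / (|FR_A - FR_B| + |FR_G - FR_B|),
  +1 for a purely tactile response, -1 purely visual.  A linear model relates
  SI to anatomical position (DV, ML, AP) and conditioning type with
  position-by-conditioning interactions.
* Spontaneous rate: mean rate over quiet spans (no stimuli, licks, or
  rewards for at least 2 s, remaining span at least 6 s).

Cells within 50 um of the POm/LP boundary are excluded from all outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import AnalysisConfig
from .session import Session
from .task_schedule import MODALITIES, ParameterError, StimulusEvent

logger = logging.getLogger(__name__)

LABELS = ("puff", "grating", "both", "none")


# ---------------------------------------------------------------------------
# PSTHs
# ---------------------------------------------------------------------------

@dataclass
class PSTH:
    edges: np.ndarray      # bin edges, seconds relative to onset
    counts: np.ndarray     # (n_events, n_bins) spike counts
    rate: np.ndarray       # mean spikes/s per bin
    sem: np.ndarray

    @property
    def bin(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])


def event_triggered_rates(
    spikes: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float] = (-2.0, 4.0),
    bin: float = 0.25,
) -> PSTH:
    """Per-event binned spike counts and the mean +/- SEM rate across events."""
    onsets = np.asarray(onsets, dtype=float)
    spikes = np.asarray(spikes, dtype=float)
    if onsets.size == 0:
        raise ParameterError("no events to align to")
    t0, t1 = window
    n_bins = (t1 - t0) / bin
    if abs(n_bins - round(n_bins)) > 1e-9:
        raise ParameterError(f"bin {bin} does not divide window {window}")
    edges = t0 + np.arange(round(n_bins) + 1) * bin
    counts = np.empty((onsets.size, edges.size - 1), dtype=np.int64)
    for i, on in enumerate(onsets):
        counts[i] = np.histogram(spikes, bins=edges + on)[0]
    rates = counts / bin
    return PSTH(
        edges=edges,
        counts=counts,
        rate=rates.mean(axis=0),
        sem=rates.std(axis=0, ddof=1) / np.sqrt(onsets.size) if onsets.size > 1
        else np.zeros(edges.size - 1),
    )


# ---------------------------------------------------------------------------
# event exclusion and counting
# ---------------------------------------------------------------------------

def non_overlapping_events(
    schedule, exclusion: float = 6.0
) -> dict[str, list[StimulusEvent]]:
    """Events with no different-modality onset within +/-``exclusion`` s."""
    out: dict[str, list[StimulusEvent]] = {}
    for mod in MODALITIES:
        own = schedule.by_modality(mod)
        other = schedule.onsets("visual" if mod == "tactile" else "tactile")
        kept = [
            ev for ev in own
            if not (other.size and np.min(np.abs(other - ev.onset)) < exclusion)
        ]
        logger.info(
            "overlap exclusion (%s): kept %d of %d events", mod, len(kept), len(own)
        )
        out[mod] = kept
    return out


def _window_counts(spikes: np.ndarray, onsets: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Spike counts in [onset+lo, onset+hi) per event."""
    spikes = np.asarray(spikes, dtype=float)
    return np.searchsorted(spikes, onsets + hi) - np.searchsorted(spikes, onsets + lo)


# ---------------------------------------------------------------------------
# responsiveness classification
# ---------------------------------------------------------------------------

def _paired_wilcoxon(a: np.ndarray, b: np.ndarray) -> float:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.all(d == 0):
        return 1.0
    return float(stats.wilcoxon(d, zero_method="zsplit").pvalue)


def cell_response_stats(
    spikes: np.ndarray,
    events: dict[str, list[StimulusEvent]],
    config: AnalysisConfig = AnalysisConfig(),
) -> dict:
    """Raw (uncorrected) response statistics of one cell.

    Returns FR_B/FR_A/FR_G (spikes/s), the one-way ANOVA p over {pooled
    baselines, puff counts, grating counts}, and per-stimulus paired
    Wilcoxon p-values; `insufficient` is set when either modality has fewer
    than ``config.min_events`` usable events.
    """
    on_t = np.array([e.onset for e in events["tactile"]])
    on_v = np.array([e.onset for e in events["visual"]])
    if on_t.size < config.min_events or on_v.size < config.min_events:
        return {
            "fr_b": np.nan, "fr_a": np.nan, "fr_g": np.nan,
            "anova_p": np.nan, "p_puff": np.nan, "p_grating": np.nan,
            "insufficient": True,
        }
    bw, sw = config.baseline_window, config.stim_window
    base_t = _window_counts(spikes, on_t, -bw, 0.0) / bw
    base_v = _window_counts(spikes, on_v, -bw, 0.0) / bw
    stim_t = _window_counts(spikes, on_t, 0.0, sw) / sw
    stim_v = _window_counts(spikes, on_v, 0.0, sw) / sw
    baselines = np.concatenate([base_t, base_v])
    groups = (baselines, stim_t, stim_v)
    if all(np.ptp(g) == 0 for g in groups) and len({g.mean() for g in groups}) == 1:
        anova_p = 1.0
    else:
        anova_p = float(stats.f_oneway(*groups).pvalue)
        if np.isnan(anova_p):
            anova_p = 1.0
    return {
        "fr_b": float(baselines.mean()),
        "fr_a": float(stim_t.mean()),
        "fr_g": float(stim_v.mean()),
        "anova_p": anova_p,
        "p_puff": _paired_wilcoxon(stim_t, base_t),
        "p_grating": _paired_wilcoxon(stim_v, base_v),
        "insufficient": False,
    }


def selectivity_index(fr_a: float, fr_g: float, fr_b: float) -> float:
    """Stimulus selectivity index; NaN when both absolute responses are 0."""
    if min(fr_a, fr_g, fr_b) < 0:
        raise ParameterError("firing rates must be non-negative")
    da, dg = abs(fr_a - fr_b), abs(fr_g - fr_b)
    return (da - dg) / (da + dg) if (da + dg) > 0 else float("nan")


def classify_responses(
    session: Session, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Per-cell responsiveness table for one session.

    Holm-Bonferroni correction of the ANOVA p-values is applied within each
    region family (conditioning is constant within a session, so the family
    is the region's cell set).  A cell is labeled 'puff'/'grating'/'both'
    only if its corrected ANOVA p < alpha and the per-stimulus test p < alpha.
    SI is reported for significantly responding cells.
    """
    events = non_overlapping_events(session.schedule, config.overlap_exclusion)
    cells = session.cells
    near = cells["dist_to_boundary_um"] < config.boundary_exclusion_um
    if near.any():
        logger.info("boundary exclusion: dropped %d of %d cells", near.sum(), len(cells))
    cells = cells.loc[~near].reset_index(drop=True)

    rows = []
    for _, c in cells.iterrows():
        st = cell_response_stats(session.spikes[c["cell_id"]], events, config)
        rows.append({"cell_id": c["cell_id"], "region": c["region"], **st})
    df = pd.DataFrame(rows)
    if df.empty:
        return df.assign(anova_p_corr=[], label=[], si=[])

    df["anova_p_corr"] = np.nan
    for region, idx in df.groupby("region").groups.items():
        sub = df.loc[idx]
        ok = ~sub["anova_p"].isna()
        if ok.any():
            df.loc[sub.index[ok], "anova_p_corr"] = multipletests(
                sub.loc[ok, "anova_p"], alpha=config.alpha, method="holm"
            )[1]

    labels, sis = [], []
    for _, r in df.iterrows():
        if r["insufficient"] or not (r["anova_p_corr"] < config.alpha):
            labels.append("none")
            sis.append(np.nan)
            continue
        puff = r["p_puff"] < config.alpha
        grat = r["p_grating"] < config.alpha
        label = "both" if (puff and grat) else "puff" if puff else "grating" if grat else "none"
        labels.append(label)
        sis.append(
            selectivity_index(r["fr_a"], r["fr_g"], r["fr_b"]) if label != "none" else np.nan
        )
    df["label"] = labels
    df["si"] = sis
    return df


# ---------------------------------------------------------------------------
# response latency
# ---------------------------------------------------------------------------

@dataclass
class LatencyResult:
    cell_id: str
    modality: str
    latency: float | None      # seconds, multiple of the latency bin; None if no crossing
    rule: str                  # 'two-bin-99', 'one-bin-9999', or 'none'
    direction: str             # 'increase', 'decrease', or 'none'
    sigma_floored: bool = False


def response_latency(
    spikes: np.ndarray,
    onsets: np.ndarray,
    config: AnalysisConfig = AnalysisConfig(),
    cell_id: str = "",
    modality: str = "",
) -> LatencyResult:
    """First confidence-interval crossing of the event-aligned mean rate.

    The mean rate per 10-ms bin across events is compared with the baseline
    mean and SD (2-s pre-onset bins).  The latency is the left edge of the
    first bin outside mean +/- 2.576 SD for two consecutive bins, or outside
    mean +/- 3.891 SD for one bin, whichever comes first.  A silent baseline
    has its SD floored at the Poisson expectation for the bin estimator
    (flagged).
    """
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size < 20:
        raise ParameterError("need at least 20 events for a stable latency estimate")
    span, bin_ = config.latency_baseline_span, config.latency_bin
    psth = event_triggered_rates(spikes, onsets, window=(-span, config.latency_search), bin=bin_)
    pre = psth.centers < 0
    mu = float(psth.rate[pre].mean())
    sd = float(psth.rate[pre].std(ddof=1))
    floored = False
    if sd == 0.0:
        mu_hat = max(mu, 1.0 / (onsets.size * span))   # at least one expected spike overall
        sd = float(np.sqrt(mu_hat / (onsets.size * bin_)))
        floored = True
    post = psth.rate[~pre]
    z = (post - mu) / sd
    lat2 = lat1 = None
    hits2 = np.abs(z) > config.z_two_bin
    for i in range(hits2.size - 1):
        if hits2[i] and hits2[i + 1]:
            lat2 = i
            break
    hits1 = np.nonzero(np.abs(z) > config.z_one_bin)[0]
    if hits1.size:
        lat1 = int(hits1[0])
    if lat2 is None and lat1 is None:
        return LatencyResult(cell_id, modality, None, "none", "none", floored)
    if lat1 is not None and (lat2 is None or lat1 < lat2):
        idx, rule = lat1, "one-bin-9999"
    else:
        idx, rule = lat2, "two-bin-99"
    direction = "increase" if z[idx] > 0 else "decrease"
    return LatencyResult(cell_id, modality, round(idx * bin_, 10), rule, direction, floored)


def latency_table(
    session: Session, config: AnalysisConfig = AnalysisConfig()
) -> pd.DataFrame:
    """Latency of every analyzable cell for each modality."""
    cells = session.cells
    cells = cells.loc[cells["dist_to_boundary_um"] >= config.boundary_exclusion_um]
    rows = []
    for _, c in cells.iterrows():
        for mod in MODALITIES:
            onsets = session.schedule.onsets(mod)
            if onsets.size < 20:
                continue
            r = response_latency(session.spikes[c["cell_id"]], onsets, config,
                                 cell_id=c["cell_id"], modality=mod)
            rows.append(
                {
                    "cell_id": r.cell_id,
                    "modality": r.modality,
                    "latency_s": np.nan if r.latency is None else r.latency,
                    "rule": r.rule,
                    "direction": r.direction,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# window rate changes and spontaneous rate
# ---------------------------------------------------------------------------

def window_rate_change(
    spikes: np.ndarray,
    onsets: np.ndarray,
    window: tuple[float, float],
    config: AnalysisConfig = AnalysisConfig(),
) -> tuple[float, float]:
    """Mean rate in ``window`` minus the 1-s baseline rate, with its SEM."""
    onsets = np.asarray(onsets, dtype=float)
    if onsets.size == 0:
        raise ParameterError("no events")
    lo, hi = window
    w = hi - lo
    in_win = _window_counts(spikes, onsets, lo, hi) / w
    base = _window_counts(spikes, onsets, -config.baseline_window, 0.0) / config.baseline_window
    diff = in_win - base
    sem = float(diff.std(ddof=1) / np.sqrt(onsets.size)) if onsets.size > 1 else float("nan")
    return float(diff.mean()), sem


def spontaneous_rate(
    session: Session, cell_id: str, config: AnalysisConfig = AnalysisConfig()
) -> float:
    """Mean rate over quiet spans; NaN if the session has none.

    Quiet spans are maximal intervals free of stimuli (their 2-s windows),
    licks, and reward windows; the first 2 s of each is dropped and the
    remainder must be at least 6 s long.
    """
    dur = session.duration
    occupied: list[tuple[float, float]] = []
    for ev in session.schedule.events:
        occupied.append((ev.onset, ev.offset))
        if ev.rewarded:
            occupied.append((ev.offset, ev.offset + config.reward_window))
    occupied.extend((t, t) for t in session.licks)
    occupied.sort()
    free: list[tuple[float, float]] = []
    t = 0.0
    for a, b in occupied:
        if a > t:
            free.append((t, min(a, dur)))
        t = max(t, b)
        if t >= dur:
            break
    if t < dur:
        free.append((t, dur))
    spans = [(a + 2.0, b) for a, b in free if (b - (a + 2.0)) >= 6.0]
    if not spans:
        logger.info("spontaneous rate: no qualifying quiet span")
        return float("nan")
    spikes = session.spikes[cell_id]
    total_t = sum(b - a for a, b in spans)
    total_n = sum(
        int(np.searchsorted(spikes, b) - np.searchsorted(spikes, a)) for a, b in spans
    )
    return total_n / total_t


# ---------------------------------------------------------------------------
# selectivity vs anatomical position
# ---------------------------------------------------------------------------

class SelectivityPositionModel:
    """Linear model of selectivity index against anatomical position.

    Design: SI ~ 1 + DV + ML + AP + CT + CT:DV + CT:ML + CT:AP, where CT is
    the conditioning type.  Built from a table with columns
    ``si, ap_um, dv_um, ml_um, conditioning``; rows with undefined SI are
    dropped.  With a single conditioning level the CT terms are dropped with
    a warning.
    """

    FORMULA = "si ~ dv_mm + ml_mm + ap_mm + C(ct) + C(ct):dv_mm + C(ct):ml_mm + C(ct):ap_mm"
    FORMULA_SINGLE = "si ~ dv_mm + ml_mm + ap_mm"

    def __init__(self, table: pd.DataFrame):
        t = table.dropna(subset=["si"]).copy()
        if len(t) < 30:
            raise ParameterError(
                f"need at least 30 cells with defined SI, got {len(t)}"
            )
        # millimetre scale keeps coefficients O(1)
        for ax in ("ap", "dv", "ml"):
            t[f"{ax}_mm"] = t[f"{ax}_um"] / 1000.0
        t["ct"] = t["conditioning"]
        self.table = t
        self.single_ct = t["ct"].nunique() < 2

    def fit(self):
        """OLS fit; returns the statsmodels results object."""
        if self.single_ct:
            import warnings

            warnings.warn(
                "single conditioning label: conditioning terms dropped", stacklevel=2
            )
            return smf.ols(self.FORMULA_SINGLE, data=self.table).fit()
        return smf.ols(self.FORMULA, data=self.table).fit()


def selectivity_position_model(
    sis: pd.DataFrame | None = None, positions: pd.DataFrame | None = None,
    conditioning: pd.Series | None = None, table: pd.DataFrame | None = None,
):
    """Fit the SI-vs-position model; accepts a prepared table or the pieces."""
    if table is None:
        table = sis.merge(positions, on="cell_id")
        table["conditioning"] = np.asarray(conditioning)
    return SelectivityPositionModel(table).fit()
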