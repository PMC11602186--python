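"""Anticipatory-licking metrics and training-stage criteria.

Learning in the conditioning task is scored by the lick index (LI) of each
stimulus presentation:

    LI = (licks_stimulus - licks_baseline) / (licks_stimulus + licks_baseline)

with licks_stimulus counted over the 2-s stimulus window (licks within 50 ms
of onset excluded, since they cannot be reactions to the stimulus) and
licks_baseline over the 2 s before onset.  A positive LI means anticipatory
licking, a negative LI withheld licking; a trial with no licks in either
window carries no preference information and is flagged undefined rather
than set to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .session import Session
from .task_schedule import MODALITIES, ParameterError, StimulusEvent

MIN_DEFINED_LI = 5   # rank test needs at least this many defined LIs


@dataclass(frozen=True)
class LickIndexResult:
    event: StimulusEvent
    licks_stimulus: int
    licks_baseline: int
    li: float          # NaN when undefined (0/0)

    @property
    def defined(self) -> bool:
        return not np.isnan(self.li)


@dataclass
class ModalityBehavior:
    modality: str
    n_events: int
    n_defined: int
    mean_li: float
    sem_li: float
    p_signedrank: float        # two-sided vs 0; NaN with "insufficient" flag
    insufficient: bool
    first_lick_latency: np.ndarray = field(default_factory=lambda: np.empty(0))

    @property
    def median_first_lick(self) -> float:
        return float(np.median(self.first_lick_latency)) if self.first_lick_latency.size else float("nan")


@dataclass
class SessionBehavior:
    per_modality: dict[str, ModalityBehavior]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mod in MODALITIES:
            b = self.per_modality[mod]
            rows.append(
                {
                    "modality": mod,
                    "n_events": b.n_events,
                    "n_defined": b.n_defined,
                    "mean_li": b.mean_li,
                    "sem_li": b.sem_li,
                    "p_signedrank": b.p_signedrank,
                    "median_first_lick_s": b.median_first_lick,
                }
            )
        return pd.DataFrame(rows)


def lick_index(
    licks: np.ndarray,
    event: StimulusEvent,
    stim_dur: float = 2.0,
    exclusion: float = 0.05,
) -> LickIndexResult:
    """LI of one stimulus presentation (half-open count windows)."""
    licks = np.asarray(licks, dtype=float)
    on = event.onset
    n_base = int(np.count_nonzero((licks >= on - stim_dur) & (licks < on)))
    n_stim = int(np.count_nonzero((licks >= on + exclusion) & (licks < on + stim_dur)))
    total = n_stim + n_base
    li = (n_stim - n_base) / total if total > 0 else float("nan")
    return LickIndexResult(event=event, licks_stimulus=n_stim, licks_baseline=n_base, li=li)


def _signed_rank_vs_zero(values: np.ndarray, alternative: str = "two-sided") -> float:
    """Wilcoxon signed-rank p of values against 0 (ties at 0 split)."""
    values = values[~np.isnan(values)]
    if values.size < MIN_DEFINED_LI or np.all(values == 0):
        return float("nan")
    return float(stats.wilcoxon(values, zero_method="zsplit", alternative=alternative).pvalue)


def first_lick_latencies(licks: np.ndarray, events: list[StimulusEvent]) -> np.ndarray:
    """Latency from stimulus onset to the first lick after reward availability.

    Reward becomes available at stimulus offset; only rewarded events with a
    subsequent lick contribute.
    """
    licks = np.asarray(licks, dtype=float)
    out = []
    for ev in events:
        if not ev.rewarded:
            continue
        idx = np.searchsorted(licks, ev.offset)
        if idx < licks.size:
            out.append(licks[idx] - ev.onset)
    return np.array(out)


def session_behavior(
    session: Session, stim_dur: float = 2.0, exclusion: float = 0.05
) -> SessionBehavior:
    """Per-modality LI summary, signed-rank test vs 0, and first-lick latencies."""
    per = {}
    for mod in MODALITIES:
        events = session.schedule.by_modality(mod)
        lis = np.array(
            [lick_index(session.licks, ev, stim_dur, exclusion).li for ev in events]
        )
        defined = lis[~np.isnan(lis)]
        p = _signed_rank_vs_zero(lis)
        per[mod] = ModalityBehavior(
            modality=mod,
            n_events=len(events),
            n_defined=defined.size,
            mean_li=float(defined.mean()) if defined.size else float("nan"),
            sem_li=float(defined.std(ddof=1) / np.sqrt(defined.size))
            if defined.size > 1
            else float("nan"),
            p_signedrank=p,
            insufficient=np.isnan(p),
            first_lick_latency=first_lick_latencies(session.licks, events),
        )
    return SessionBehavior(per_modality=per)


def assess_criterion(history: list[SessionBehavior], stage: str, conditioning: str,
                     alpha: float = 0.05) -> bool:
    """Training-stage criterion over a chronological session history.

    shaping: the CS+ mean LI of the latest session is significantly greater
    than 0 (one-sided signed rank) and at least 3 sessions have been run.
    full: the distractor LI of the latest session is not significantly
    different from 0 (two-sided) and at least 4 sessions have been run.
    """
    if not history:
        raise ParameterError("empty training history")
    if stage not in ("shaping", "full"):
        raise ParameterError(f"unknown stage {stage!r}")
    distractor = "visual" if conditioning == "tactile" else "tactile"
    latest = history[-1]
    if stage == "shaping":
        if len(history) < 3:
            return False
        b = latest.per_modality[conditioning]
        if b.insufficient:
            return False
        # one-sided "greater than 0": half the two-sided p when the shift is positive
        return b.mean_li > 0 and b.p_signedrank / 2 < alpha
    if len(history) < 4:
        return False
    b = latest.per_modality[distractor]
    return (not b.insufficient) and b.p_signedrank >= alpha
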