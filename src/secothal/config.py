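"""Analysis tunables, with defaults matching the study design they audit."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass


@dataclass(frozen=True)
class AnalysisConfig:
    """All analysis-stage constants in one serializable place.

    Every default traces to the task/analysis design: 1-s baseline and
    stimulus windows, the 2-s offset (consumption) window starting at
    stimulus offset, 10-ms latency bins searched over 1 s against a 2-s
    pre-onset baseline, two-sided normal z-thresholds for 99% (2.576, two
    consecutive bins) and 99.99% (3.891, one bin) coverage, symmetric 6-s
    cross-modality overlap exclusion, 50 um anatomical boundary exclusion,
    250-ms regression bins, and alpha = 0.05 throughout.
    """

    baseline_window: float = 1.0
    stim_window: float = 1.0
    offset_window: tuple[float, float] = (2.0, 4.0)   # s relative to onset
    psth_bin: float = 0.25
    latency_bin: float = 0.01
    latency_search: float = 1.0
    latency_baseline_span: float = 2.0                # config switch: 1.0 also used upstream
    z_two_bin: float = 2.576
    z_one_bin: float = 3.891
    overlap_exclusion: float = 6.0
    boundary_exclusion_um: float = 50.0
    alpha: float = 0.05
    regression_bin: float = 0.25
    reward_window: float = 2.0
    max_lag: float = 2.0
    lick_window: float = 2.0
    lick_exclusion: float = 0.05
    min_events: int = 5

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha1(text.encode()).hexdigest()[:12]
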