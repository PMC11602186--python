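"""End-to-end analysis of one session bundle and a headline-summary report."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior import session_behavior
from .config import AnalysisConfig
from .movement_models import bin_session, movement_regression
from .neural_responses import classify_responses, latency_table
from .session import Session
from .signals import align_1khz


def movement_table(
    session: Session, config: AnalysisConfig = AnalysisConfig(), include_stimuli: bool = True
) -> pd.DataFrame:
    """Per-cell movement-regression coefficients, p-values, and tuning flags."""
    binned = bin_session(session, config.regression_bin, config=config)
    rows = []
    for cid in session.cell_ids():
        res = movement_regression(binned, cid, include_stimuli=include_stimuli)
        tun = res.tuning(config.alpha) if include_stimuli else None
        rows.append(
            {
                "cell_id": cid,
                "beta0": res.params["const"],
                "beta_whisk": res.params["whisk"],
                "beta_pupil": res.params["pupil"],
                "beta_lick": res.params["lick"],
                "p_whisk": res.pvalues["whisk"],
                "p_pupil": res.pvalues["pupil"],
                "p_lick": res.pvalues["lick"],
                "movement_tuned": int(tun.movement_tuned) if tun else np.nan,
                "stimulus_tuned": int(tun.stimulus_tuned) if tun else np.nan,
            }
        )
    return pd.DataFrame(rows)


def report(session: Session, config: AnalysisConfig = AnalysisConfig()) -> dict:
    """One JSON-able summary of the headline statistics of a session."""
    beh = session_behavior(session, config.lick_window, config.lick_exclusion)
    responses = classify_responses(session, config)
    latencies = latency_table(session, config)
    moves = movement_table(session, config)

    responsive = responses[responses["label"] != "none"]
    early = latencies.dropna(subset=["latency_s"])
    early = early[early["latency_s"] <= 0.5]
    out = {
        "conditioning": session.conditioning,
        "duration_s": session.duration,
        "n_cells": len(session.cells),
        "n_cells_analyzed": len(responses),
        "behavior": {
            m: {
                "mean_li": b.mean_li,
                "sem_li": b.sem_li,
                "p_signedrank": b.p_signedrank,
                "median_first_lick_s": b.median_first_lick,
            }
            for m, b in beh.per_modality.items()
        },
        "responsive": {
            "fraction": len(responsive) / len(responses) if len(responses) else float("nan"),
            "by_label": responses["label"].value_counts().to_dict(),
            "median_si": float(responsive["si"].median()) if len(responsive) else float("nan"),
        },
        "latency": {
            m: {
                "n_early": int((early["modality"] == m).sum()),
                "median_s": float(early.loc[early["modality"] == m, "latency_s"].median())
                if (early["modality"] == m).any()
                else float("nan"),
            }
            for m in ("tactile", "visual")
        },
        "movement": {
            "frac_movement_tuned": float(moves["movement_tuned"].mean()),
            "frac_stimulus_tuned": float(moves["stimulus_tuned"].mean()),
        },
        "config_hash": config.hash(),
    }
    return out


__all__ = ["movement_table", "report", "align_1khz"]
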