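"""Small plotting helpers for the standard figures of the pipeline."""

from __future__ import annotations

import numpy as np

from .neural_responses import PSTH


def plot_psth(psth: PSTH, ax=None, color="k", label=None):
    """Mean +/- SEM event-triggered rate with the 2-s stimulus window shaded."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = psth.centers
    ax.fill_between(t, psth.rate - psth.sem, psth.rate + psth.sem, alpha=0.3, color=color)
    ax.plot(t, psth.rate, color=color, label=label)
    ax.axvspan(0, 2, color="0.85", zorder=0)
    ax.set_xlabel("time from stimulus onset (s)")
    ax.set_ylabel("rate (spikes/s)")
    return ax


def plot_learning_curve(histories, conditioning, ax=None):
    """Mean lick index per session for the CS+ and the distractor."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    distractor = "visual" if conditioning == "tactile" else "tactile"
    for mod, color in ((conditioning, "C3"), (distractor, "C0")):
        m = [h.per_modality[mod].mean_li for h in histories]
        s = [h.per_modality[mod].sem_li for h in histories]
        x = np.arange(1, len(m) + 1)
        ax.errorbar(x, m, yerr=s, color=color, label=f"{mod} ({'CS+' if mod == conditioning else 'distractor'})")
    ax.axhline(0, color="0.5", lw=0.5)
    ax.set_xlabel("session")
    ax.set_ylabel("lick index")
    ax.legend()
    return ax


def plot_crosscorr(xc, ax=None, **kwargs):
    """Correlation by lag; negative lags mean the rate precedes the signal."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.plot(xc["lag_s"], xc["r"], **kwargs)
    ax.axvline(0, color="0.5", lw=0.5)
    ax.set_xlabel("lag (s)")
    ax.set_ylabel("r")
    return ax
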