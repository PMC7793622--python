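"""Ratiometric dF/F computation and epoch summaries for imaging trials.

Each channel's dF/F is (F - F_base) / F_base with F_base the mean over the
first 5 s of the trial; the motion-corrected signal is the green dF/F
minus the red dF/F, which cancels fluctuations (e.g. Z-plane brain
movement) common to both channels. Epoch summaries average the corrected
signal over the trial's five epochs (pre, airflow, airflow+odor, airflow,
post) and aggregate across the five repetition blocks per direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_imaging import TwoChannelSeries, EPOCHS

BASELINE_WINDOW_S = (0.0, 5.0)


@dataclass
class DffTrace:
    """Per-channel and corrected fractional fluorescence change."""

    t: np.ndarray
    dff_green: np.ndarray
    dff_red: np.ndarray
    dff_corrected: np.ndarray  # green - red, pointwise
    direction: float
    fs: float


def dff(series: TwoChannelSeries, baseline_window=BASELINE_WINDOW_S) -> DffTrace:
    """Compute dF/F per channel and the channel-subtracted correction.

    The baseline is per-trial (mean over the first 5 s); non-positive
    baseline means are rejected.
    """
    i0 = int(round(baseline_window[0] * series.fs))
    i1 = int(round(baseline_window[1] * series.fs))
    if not (0 <= i0 < i1 <= len(series.green)):
        raise ValueError("baseline window outside trial")

    out = {}
    for name, f in (("green", series.green), ("red", series.red)):
        f = np.asarray(f, dtype=float)
        f0 = f[i0:i1].mean()
        if f0 <= 0:
            raise ValueError(f"non-positive baseline mean in {name} channel")
        out[name] = (f - f0) / f0
    return DffTrace(t=series.t, dff_green=out["green"], dff_red=out["red"],
                    dff_corrected=out["green"] - out["red"],
                    direction=series.direction, fs=series.fs)


def epoch_summary(trace: DffTrace, epochs=EPOCHS) -> dict:
    """Mean corrected dF/F per trial epoch."""
    n = len(trace.dff_corrected)
    out = {}
    for name, t0, t1 in epochs:
        i0 = int(round(t0 * trace.fs))
        i1 = int(round(t1 * trace.fs))
        if not (0 <= i0 < i1 <= n):
            raise ValueError(f"epoch {name} outside trace")
        out[name] = float(trace.dff_corrected[i0:i1].mean())
    return out


def epoch_table(trials, epochs=EPOCHS) -> pd.DataFrame:
    """Tidy epoch summary across trials: one row per (trial, epoch), with
    per-direction aggregation left to the caller (or `groupby`)."""
    rows = []
    for i, series in enumerate(trials):
        tr = dff(series)
        for name, value in epoch_summary(tr, epochs).items():
            rows.append({"trial_id": i, "direction": tr.direction,
                         "epoch": name, "mean_dff": value})
    return pd.DataFrame(rows)


def direction_means(trials, epoch="airflow_1") -> pd.Series:
    """Mean corrected dF/F in one epoch, averaged across the repetition
    blocks, per direction."""
    tab = epoch_table(trials)
    sel = tab[tab["epoch"] == epoch]
    return sel.groupby("direction")["mean_dff"].mean()
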