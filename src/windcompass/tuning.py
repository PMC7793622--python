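"""Circular tuning statistics and response dynamics for single cells.

The mean tuning vector converts each direction's baseline-subtracted mean
response into a vector (angle = airflow direction, magnitude = response)
and takes the resultant; its angle is the cell's preferred direction and
its length (normalized by the summed response magnitudes) measures tuning
sharpness. Response dynamics are summarized by the cumulative normalized
PSTH over the 4 s stimulus and the time at which it reaches half of the
total response (short times = transient cells, ~2 s = tonic cells).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._angles import wrap_deg


@dataclass
class TuningCurve:
    """Per-direction baseline-subtracted mean responses for one cell."""

    directions: np.ndarray   # degrees, unique, >= 2 of them
    responses: np.ndarray    # spikes/s (or mV); may be negative
    sem: np.ndarray | None = None
    n_trials: np.ndarray | None = None

    def __post_init__(self):
        self.directions = np.asarray(self.directions, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(self.directions) < 2:
            raise ValueError("need at least 2 directions")
        if len(np.unique(wrap_deg(self.directions))) != len(self.directions):
            raise ValueError("directions must be unique")
        if len(self.responses) != len(self.directions):
            raise ValueError("responses and directions differ in length")


@dataclass(frozen=True)
class VectorTuning:
    """Resultant of response-weighted direction vectors."""

    angle: float      # degrees, fly-centered; NaN when undefined
    length: float     # [0, 1], normalized by sum of |response|
    defined: bool = True


def mean_vector(curve: TuningCurve, signed: bool = True) -> VectorTuning:
    """Mean tuning vector of a curve.

    Each direction contributes a vector with its (signed) mean response as
    magnitude; the resultant length is normalized by the summed absolute
    responses so it lies in [0, 1]. With ``signed=False`` responses are
    rectified first (non-default variant). An all-zero curve has no defined
    angle and is flagged as such.
    """
    r = curve.responses if signed else np.abs(curve.responses)
    theta = np.deg2rad(curve.directions)
    x = float(np.sum(r * np.cos(theta)))
    y = float(np.sum(r * np.sin(theta)))
    norm = float(np.sum(np.abs(curve.responses)))
    if norm == 0:
        return VectorTuning(angle=np.nan, length=0.0, defined=False)
    length = float(np.hypot(x, y)) / norm
    if length < 1e-12:
        return VectorTuning(angle=np.nan, length=0.0, defined=False)
    angle = float(wrap_deg(np.rad2deg(np.arctan2(y, x))))
    return VectorTuning(angle=angle, length=length)


@dataclass
class DynamicsProfile:
    """Cumulative normalized response over the stimulus and its half-max time."""

    t: np.ndarray                 # s from stimulus onset
    cumulative: np.ndarray        # normalized, endpoint 1 when defined
    time_to_half_max: float       # s in [0, stimulus length]; NaN if undefined
    defined: bool = True


def dynamics(psth, fs, stim_window=(4.0, 8.0)) -> DynamicsProfile:
    """Cumulative normalized response during the stimulus.

    The PSTH is integrated over the stimulus window and divided by its
    total integral over that window; the half-max time is the first
    crossing of 0.5, located by linear interpolation between samples. A
    zero or negative total (possible for inhibited cells) yields an
    undefined profile.
    """
    psth = np.asarray(psth, dtype=float)
    i0 = int(round(stim_window[0] * fs))
    i1 = int(round(stim_window[1] * fs))
    if not (0 <= i0 < i1 <= len(psth)):
        raise ValueError("stimulus window outside PSTH support")
    seg = psth[i0:i1]
    dt = 1.0 / fs
    cum = np.cumsum(seg) * dt
    total = cum[-1]
    t = (np.arange(len(seg)) + 1) * dt
    if total <= 0:
        return DynamicsProfile(t=t, cumulative=np.full_like(seg, np.nan),
                               time_to_half_max=np.nan, defined=False)
    c = cum / total
    above = np.flatnonzero(c >= 0.5)
    k = above[0]
    if k == 0:
        t_half = t[0] * (0.5 / c[0]) if c[0] > 0 else t[0]
    else:
        # linear interpolation between the straddling samples
        t_half = t[k - 1] + (0.5 - c[k - 1]) / (c[k] - c[k - 1]) * dt
    return DynamicsProfile(t=t, cumulative=c, time_to_half_max=float(t_half))


def tuning_table(cells) -> pd.DataFrame:
    """Per-cell tuning summary table.

    ``cells`` is an iterable of dicts with keys ``cell``, ``curve``
    (TuningCurve), optionally ``column`` and ``dynamics``
    (DynamicsProfile). Emits one tidy row per cell.
    """
    rows = []
    for c in cells:
        vt = mean_vector(c["curve"])
        row = {
            "cell": c["cell"],
            "column": c.get("column"),
            "mean_angle_deg": vt.angle,
            "vector_length": vt.length,
            "angle_defined": vt.defined,
        }
        dyn = c.get("dynamics")
        row["time_to_half_max_s"] = dyn.time_to_half_max if dyn is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)
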