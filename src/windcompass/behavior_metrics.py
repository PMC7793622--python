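"""Behavioral statistics from closed-loop flight sessions.

Fixation metrics treat each 50 Hz orientation sample as a unit vector: the
circular mean gives the fly's preferred orientation, the resultant length
its fixation strength (1 = perfect fixation, 0 = no preference), and the
toward fraction is the probability mass in the quadrant facing the airflow
source ([-45, +45) deg; 0.25 under uniform orienting). Perturbation
responses are dWBA timecourses in a 6 s window around each manipulation
(1 s pre, 5 s post); slip responses are additionally integrated over the
5 s post-slip period, and the correction fraction converts that integral
into orientation degrees through the closed-loop gain and divides by the
negative slip magnitude (1 = the turn undoes the slip, 0 = no response,
negative = turning with the slip). Pause responses are sign-adjusted so
turns toward the source are positive regardless of which side it is on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._angles import wrap_deg
from .closed_loop_sim import (
    BehaviorRecord, PAUSE_DURATIONS_S, SLIP_SAMPLES, SLIP_SIGNS, apply_slip,
)

logger = logging.getLogger(__name__)

PRE_WINDOW_S = 1.0
POST_WINDOW_S = 5.0


@dataclass(frozen=True)
class FixationMetrics:
    mean_orientation: float   # degrees; NaN when strength ~ 0
    fixation_strength: float  # [0, 1]
    toward_fraction: float    # [0, 1]


def fixation_metrics(orientation) -> FixationMetrics:
    """Circular-mean summary of an orientation series (degrees)."""
    theta = np.deg2rad(np.asarray(orientation, dtype=float))
    if theta.size == 0:
        raise ValueError("empty orientation series")
    z = np.exp(1j * theta).mean()
    strength = float(np.abs(z))
    mean_ang = float(wrap_deg(np.rad2deg(np.angle(z)))) if strength > 1e-12 else np.nan
    wrapped = wrap_deg(orientation)
    toward = float(np.mean((wrapped >= -45.0) & (wrapped < 45.0)))
    return FixationMetrics(mean_ang, strength, toward)


@dataclass
class PerturbationResponse:
    """Windowed dWBA responses to one perturbation type."""

    trial_type: str
    t: np.ndarray                  # s relative to onset, -1 .. +5
    timecourses: np.ndarray        # trials x samples
    integrated: np.ndarray         # per-trial integral, deg*s (slips: 5 s post;
                                   # long pauses: the 2 s pause)
    n_dropped: int = 0

    @property
    def mean_timecourse(self):
        return self.timecourses.mean(axis=0)

    @property
    def sem_timecourse(self):
        n = self.timecourses.shape[0]
        return self.timecourses.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else \
            np.zeros(self.timecourses.shape[1])


def _windowed(record: BehaviorRecord, types, signal, integrate_window):
    """Collect per-trial windows of ``signal`` around onsets of the given
    perturbation types. ``integrate_window`` maps type -> (t0, t1) relative
    to onset for the per-trial integral."""
    fs = record.fs
    n_pre = int(round(PRE_WINDOW_S * fs))
    n_post = int(round(POST_WINDOW_S * fs))
    rel_t = np.arange(-n_pre, n_post + 1) / fs
    out = {}
    for typ in types:
        rows, integrals, dropped = [], [], 0
        for entry_type, onset in record.schedule.entries:
            if entry_type != typ:
                continue
            i_on = int(round(onset * fs))
            i0, i1 = i_on - n_pre, i_on + n_post + 1
            if i0 < 0 or i1 > len(signal):
                dropped += 1
                continue
            rows.append(signal[i0:i1])
            w0, w1 = integrate_window[typ]
            j0 = i_on + int(round(w0 * fs))
            j1 = i_on + int(round(w1 * fs))
            integrals.append(signal[j0:j1].sum() / fs)
        if dropped:
            logger.info("dropped %d truncated %s windows", dropped, typ)
        out[typ] = PerturbationResponse(
            trial_type=typ, t=rel_t,
            timecourses=np.asarray(rows, dtype=float),
            integrated=np.asarray(integrals, dtype=float),
            n_dropped=dropped)
    return out


def slip_responses(record: BehaviorRecord):
    """Per-slip-type windowed dWBA responses (raw sign: + = rightward).

    The integrated response is the dWBA integral over the 5 s following
    slip onset, in deg*s.
    """
    slip_types = tuple(SLIP_SAMPLES)
    window = {typ: (0.0, POST_WINDOW_S) for typ in slip_types}
    return _windowed(record, slip_types, np.asarray(record.dwba, float), window)


def pause_responses(record: BehaviorRecord):
    """Per-pause-type windowed responses with direction-invariant sign.

    dWBA is sign-flipped sample by sample so turns toward the airflow
    source (at 0 deg) are positive on both sides of the arena. Long-pause
    integrals cover the 2 s pause period.
    """
    toward_sign = -np.sign(wrap_deg(record.orientation))
    adjusted = np.asarray(record.dwba, float) * toward_sign
    window = {
        "pause_long": (0.0, PAUSE_DURATIONS_S["pause_long"]),
        "pause_short": (0.0, PAUSE_DURATIONS_S["pause_short"]),
    }
    return _windowed(record, tuple(window), adjusted, window)


def dwba_integral_to_orientation_deg(integrated, record: BehaviorRecord):
    """Convert a dWBA time-integral (deg*s) to the orientation change it
    produces through the closed loop (gain per 50 Hz tick)."""
    return record.arena.gain * record.arena.fs * np.asarray(integrated, float)


def correction_fraction(integrated_responses, slip_deg, record: BehaviorRecord):
    """Fraction of a slip undone by the fly's subsequent turning.

    The mean integrated slip response (converted to orientation degrees
    through the closed-loop mapping) divided by the negative slip
    magnitude: 1 = full correction, 0 = none, negative = anti-corrective
    turning. Ratio-of-means, i.e. the mean response is divided once.
    """
    if slip_deg == 0:
        raise ValueError("slip magnitude must be nonzero")
    converted = dwba_integral_to_orientation_deg(integrated_responses, record)
    return float(np.mean(converted) / (-slip_deg))


def correction_fractions(record: BehaviorRecord):
    """Correction fraction per slip type for one session."""
    resp = slip_responses(record)
    out = {}
    for typ, r in resp.items():
        slip = apply_slip(SLIP_SAMPLES[typ], SLIP_SIGNS[typ], record.arena)
        out[typ] = correction_fraction(r.integrated, slip, record)
    return out


def response_histogram(values, bin_width=20.0, slip_signs=None):
    """Probability histogram of integrated slip responses.

    Responses to leftward slips are sign-flipped before pooling
    ("collapsed across slip direction") when ``slip_signs`` is given (an
    array of +1/-1 per value). Bins are ``bin_width`` wide and centered on
    zero; counts are normalized to probabilities.
    """
    if bin_width <= 0:
        raise ValueError("bin width must be > 0")
    values = np.asarray(values, dtype=float)
    if slip_signs is not None:
        values = values * np.asarray(slip_signs, dtype=float)
    lo = np.floor((values.min() - bin_width / 2) / bin_width) if values.size else 0
    hi = np.ceil((values.max() + bin_width / 2) / bin_width) if values.size else 1
    edges = np.arange(lo * bin_width - bin_width / 2,
                      hi * bin_width + bin_width, bin_width)
    counts, edges = np.histogram(values, bins=edges)
    probs = counts / counts.sum() if counts.sum() else counts.astype(float)
    return edges, probs


def fly_summary(records) -> pd.DataFrame:
    """Per-fly metric table: fixation metrics and correction fractions
    (stick-and-ball export: angle + strength per fly)."""
    rows = []
    for rec in records:
        fm = fixation_metrics(rec.orientation)
        cf = correction_fractions(rec)
        rows.append({
            "fly_id": rec.fly_id, "genotype": rec.genotype_label,
            "mean_orientation_deg": fm.mean_orientation,
            "fixation_strength": fm.fixation_strength,
            "toward_fraction": fm.toward_fraction,
            **{f"correction_{k}": v for k, v in cf.items()},
        })
    return pd.DataFrame(rows)
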