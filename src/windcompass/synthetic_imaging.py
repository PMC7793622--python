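"""Two-channel ROI fluorescence generator with shared motion artifacts.

Emulates calcium imaging of LAL-to-noduli (LNa) neurites at 5.0 frames/s
with an activity channel (GCaMP, green) and a structural channel (tdTomato,
red). Each 47 s trial is 5 s pre-stimulus, 10 s airflow, 10 s airflow plus
odor, 10 s airflow, and 12 s post-stimulus. Both channels share a smooth
multiplicative artifact a(t) emulating slow Z-drift of the brain, so the
ratiometric correction (green dF/F minus red dF/F) cancels it:

    green(t) = B_g * (1 + response(t)) * a(t) + noise
    red(t)   = B_r * a(t) + noise

The tuned response uses the same circular-Gaussian direction-tuning family
as the electrophysiology generator; a flag inverts the preferred side,
matching LNa tuning being sign-inverted relative to ventral P-FN activity.
Odor leaves the response unchanged by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._angles import circular_gaussian, ang_diff_deg

FS_IMAGING = 5.0  # frames/s

# trial structure, seconds from trial start
EPOCHS = (
    ("pre", 0.0, 5.0),
    ("airflow_1", 5.0, 15.0),
    ("airflow_odor", 15.0, 25.0),
    ("airflow_2", 25.0, 35.0),
    ("post", 35.0, 47.0),
)
TRIAL_LEN_S = 47.0
IMAGING_DIRECTIONS = (-90.0, -45.0, 0.0, 45.0, 90.0)  # 5-direction manifold


@dataclass(frozen=True)
class RoiModel:
    """Generative parameters for one imaged ROI."""

    baseline_green: float = 200.0  # a.u.
    baseline_red: float = 150.0
    amp: float = 0.6               # peak dF/F of the tuned response
    pref_dir: float = 90.0         # degrees
    tuning_width: float = 60.0
    sign_invert: bool = False      # mirror tuning across the midline
    odor_gain: float = 1.0         # 1 = odor leaves the response unchanged
    noise_sd: float = 1.0          # a.u., per channel
    response_tau: float = 1.5      # s, indicator-like rise/decay smoothing

    def __post_init__(self):
        if self.baseline_green <= 0 or self.baseline_red <= 0:
            raise ValueError("channel baselines must be positive")

    def tuning(self, direction):
        d = -direction if self.sign_invert else direction
        return circular_gaussian(ang_diff_deg(d, self.pref_dir), self.tuning_width)


@dataclass
class TwoChannelSeries:
    """One trial's green/red ROI fluorescence at 5 frames/s."""

    t: np.ndarray
    green: np.ndarray
    red: np.ndarray
    direction: float
    seed: int
    fs: float = FS_IMAGING

    def __post_init__(self):
        if len(self.green) != len(self.red):
            raise ValueError("channel lengths differ")


_ARTIFACT_SIGMA_S = 2.0  # smoothness of the shared motion artifact


def simulate_two_channel(roi: RoiModel, direction, artifact_amp, seed,
                         trial_len=TRIAL_LEN_S) -> TwoChannelSeries:
    """Simulate one trial of two-channel ROI fluorescence.

    ``artifact_amp`` is the standard deviation of the shared multiplicative
    artifact (0 disables it). Deterministic under seed.
    """
    if artifact_amp < 0:
        raise ValueError("artifact_amp must be >= 0")
    rng = np.random.default_rng(seed)
    n = int(round(trial_len * FS_IMAGING))
    t = np.arange(n) / FS_IMAGING

    # stimulus envelope: airflow on 5-35 s, smoothed with an indicator-like
    # time constant; odor epoch scales the response by odor_gain
    stim = np.zeros(n)
    stim[(t >= 5.0) & (t < 35.0)] = 1.0
    stim[(t >= 15.0) & (t < 25.0)] = roi.odor_gain
    sigma = roi.response_tau * FS_IMAGING
    stim = gaussian_filter1d(stim, sigma, mode="constant")
    response = roi.amp * roi.tuning(direction) * stim

    if artifact_amp > 0:
        z = gaussian_filter1d(rng.normal(0.0, 1.0, n), _ARTIFACT_SIGMA_S * FS_IMAGING,
                              mode="reflect")
        z *= np.sqrt(2.0 * _ARTIFACT_SIGMA_S * FS_IMAGING * np.sqrt(np.pi))
        artifact = np.clip(1.0 + artifact_amp * z, 0.1, None)
    else:
        artifact = np.ones(n)

    green = roi.baseline_green * (1.0 + response) * artifact
    red = roi.baseline_red * artifact
    if roi.noise_sd > 0:
        green = green + rng.normal(0.0, roi.noise_sd, n)
        red = red + rng.normal(0.0, roi.noise_sd, n)

    try:
        seed_int = int(seed)
    except (TypeError, ValueError):
        seed_int = 0
    return TwoChannelSeries(t=t, green=green, red=red,
                            direction=float(direction), seed=seed_int)


def export_trials_csv(path, trials) -> None:
    """Delimited-text export: t, green, red, direction, trial_id."""
    frames = []
    for i, tr in enumerate(trials):
        frames.append(pd.DataFrame({
            "t": tr.t, "green": tr.green, "red": tr.red,
            "direction": tr.direction, "trial_id": i,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def load_trials_csv(path):
    """Read trials written by :func:`export_trials_csv`."""
    df = pd.read_csv(path)
    trials = []
    for tid, g in df.groupby("trial_id"):
        trials.append(TwoChannelSeries(
            t=g["t"].to_numpy(), green=g["green"].to_numpy(),
            red=g["red"].to_numpy(), direction=float(g["direction"].iloc[0]),
            seed=0))
    return trials
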