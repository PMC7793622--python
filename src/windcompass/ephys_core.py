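"""From raw membrane voltage to spikes, rates, and windowed responses.

Spike times are rising-edge threshold crossings of the high-pass-filtered
trace (second-order Butterworth, 40 Hz cutoff, applied forward-backward so
spike times are not shifted). PSTHs are spike trains convolved with a
unit-area 1 s Hanning window. Trial responses are response-window means
minus baseline-window means (each window 1 s, flanking stimulus onset by
500 ms). Input resistance comes from the -2 pA test pulse at the start of
each trial, and the baseline profile summarizes the pre-stimulus membrane
state (resting potential, distribution width, oscillation frequency).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .synthetic_ephys import VoltageTrace, TrialSpec, FS_EPHYS


@dataclass(frozen=True)
class WindowSpec:
    """Baseline and response analysis windows around stimulus onset.

    Defaults: baseline = [onset - 1.5, onset - 0.5] s and response =
    [onset + 0.5, onset + 1.5] s, i.e. 1 s segments ending/starting 500 ms
    before/after onset.
    """

    baseline: tuple = (2.5, 3.5)
    response: tuple = (4.5, 5.5)

    @classmethod
    def around_onset(cls, stim_onset: float) -> "WindowSpec":
        return cls(baseline=(stim_onset - 1.5, stim_onset - 0.5),
                   response=(stim_onset + 0.5, stim_onset + 1.5))


@dataclass(frozen=True)
class ThresholdConfig:
    """Spike-detection settings.

    ``threshold`` is in mV on the high-pass-filtered trace; when None it is
    set per recording to ``mad_factor`` times the median absolute deviation
    of the filtered trace (robust, self-scaling stand-in for the
    cell-type-specific thresholds used with real recordings).
    """

    cutoff_hz: float = 40.0
    order: int = 2
    threshold: float | None = None
    mad_factor: float = 5.0


def highpass_vm(samples, fs, cutoff_hz=40.0, order=2):
    """Zero-phase second-order Butterworth high-pass of a voltage trace."""
    if not 0 < cutoff_hz < fs / 2:
        raise ValueError("cutoff must be in (0, fs/2)")
    sos = signal.butter(order, cutoff_hz, btype="highpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def detect_spikes(trace: VoltageTrace, config: ThresholdConfig | None = None):
    """Detect spike times as rising-edge crossings of the filtered trace.

    Returns spike times in seconds. One spike per suprathreshold excursion,
    timed at the upward crossing sample.
    """
    config = config or ThresholdConfig()
    filt = highpass_vm(trace.samples, trace.fs, config.cutoff_hz, config.order)
    if config.threshold is None:
        mad = np.median(np.abs(filt - np.median(filt)))
        # floor guards the noiseless case, where the MAD is numerically zero
        thr = max(config.mad_factor * mad, 1e-6)
    else:
        thr = config.threshold
    if not np.isfinite(thr):
        raise ValueError("spike threshold must be finite")
    above = filt > thr
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    return rising / trace.fs


def psth(spike_trains, duration, fs_out=1000.0, kernel_width=1.0):
    """Trial-averaged firing-rate timecourse (spikes/s).

    Each train is binned at ``fs_out`` and convolved with a unit-area
    Hanning window of length ``kernel_width``; the result is averaged across
    trains. Kernel mass falling outside the trial is folded back at the
    edges so the integral of the PSTH equals the mean spike count.
    """
    if kernel_width <= 0:
        raise ValueError("kernel width must be > 0")
    trains = list(spike_trains)
    if not trains:
        raise ValueError("no spike trains supplied")
    n = int(round(duration * fs_out))
    k = int(round(kernel_width * fs_out))
    kernel = np.hanning(k + 2)[1:-1]
    kernel = kernel / kernel.sum() * fs_out  # unit area in time units
    half = (len(kernel) - 1) // 2

    out = np.zeros(n)
    for st in trains:
        st = np.asarray(st, dtype=float)
        counts = np.zeros(n)
        if st.size:
            idx = np.clip((st * fs_out).astype(int), 0, n - 1)
            np.add.at(counts, idx, 1.0)
        full = np.convolve(counts, kernel, mode="full")
        y = full[half:half + n].copy()
        left = full[:half]
        right = full[half + n:]
        if left.size:
            y[:left.size] += left[::-1]
        if right.size:
            y[-right.size:] += right[::-1]
        out += y
    return out / len(trains)


def trial_response(series, fs, windows: WindowSpec):
    """Windowed response: response-window mean minus baseline-window mean.

    Works on any per-trial series (a PSTH in spikes/s or a Vm trace in mV).
    """
    series = np.asarray(series, dtype=float)
    n = len(series)

    def _mean(window):
        i0 = int(round(window[0] * fs))
        i1 = int(round(window[1] * fs))
        if not (0 <= i0 < i1 <= n):
            raise ValueError(f"window {window} outside trace")
        return series[i0:i1].mean()

    return _mean(windows.response) - _mean(windows.baseline)


_PULSE_GUARD_S = 0.05  # settle time excluded at pulse edges


def input_resistance(trace: VoltageTrace) -> float:
    """Input resistance (GOhm) from the trial's test pulse, ΔV / I.

    The pulse steady state is the mean over its second half; the reference
    level is the mean of the first-second baseline samples outside the
    pulse (with 50 ms guard bands), since the default pulse starts at t=0
    and leaves no pre-pulse segment.
    """
    onset, dur, current = trace.trial.pulse
    if current == 0:
        raise ValueError("pulse current is zero")
    fs = trace.fs
    t = trace.t
    ss_mask = (t >= onset + dur / 2) & (t < onset + dur - _PULSE_GUARD_S / 2)
    ref_mask = (t < 1.0) & ((t < onset - _PULSE_GUARD_S) | (t >= onset + dur + _PULSE_GUARD_S))
    if not ss_mask.any() or not ref_mask.any():
        raise ValueError("pulse epoch not within trace")
    delta_v = trace.samples[ss_mask].mean() - trace.samples[ref_mask].mean()
    return delta_v / current  # mV / pA = GOhm


@dataclass
class BaselineProfile:
    """Pre-stimulus membrane-state summary for one cell."""

    resting_potential: float      # mV, mode of the baseline Vm distribution
    vm_width: float               # mV, 5th-95th percentile range
    osc_freq: float | None        # Hz, dominant 0.5-10 Hz peak or None
    r_in: float | None            # GOhm, mean across trials


# rhythmic cell types oscillate at 2-4 Hz; the 1 Hz low edge keeps the
# two-period requirement within the 3 s pulse-free baseline segment
_OSC_BAND = (1.0, 10.0)
_OSC_PROMINENCE_FACTOR = 4.0


def oscillation_frequency(segment, fs, band=_OSC_BAND,
                          prominence_factor=_OSC_PROMINENCE_FACTOR):
    """Dominant baseline oscillation frequency, or None.

    Welch periodogram of the segment; the peak in ``band`` counts only if
    its power is at least ``prominence_factor`` times the median in-band
    power (rhythmic cell types oscillate at roughly 2-4 Hz; noise-only
    baselines should return None).
    """
    segment = np.asarray(segment, dtype=float)
    min_len = 2.0 / band[0]
    if len(segment) / fs < min_len:
        raise ValueError("segment shorter than two periods at the low band edge")
    nperseg = min(len(segment), int(fs * min_len))
    f, pxx = signal.welch(segment - segment.mean(), fs=fs, nperseg=nperseg)
    in_band = (f >= band[0]) & (f <= band[1])
    if not in_band.any():
        return None
    peak_i = np.argmax(pxx[in_band])
    if pxx[in_band][peak_i] < prominence_factor * np.median(pxx[in_band]):
        return None
    return float(f[in_band][peak_i])


def baseline_profile(traces, baseline_end=None) -> BaselineProfile:
    """Summarize the baseline membrane state across a cell's trials.

    Uses each trial's pre-stimulus segment after the test pulse (pulse
    second excluded). Resting potential is the mode of the pooled Vm
    histogram; width is the 5th-95th percentile range.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("need at least one trace")
    segments = []
    for tr in traces:
        end = baseline_end if baseline_end is not None else tr.trial.stim_onset
        i0 = int(round(1.0 * tr.fs))  # skip the pulse second
        i1 = int(round(end * tr.fs))
        segments.append(tr.samples[i0:i1])
    pooled = np.concatenate(segments)

    # histogram mode with Freedman-Diaconis-style bins, floor 0.1 mV
    q75, q25 = np.percentile(pooled, [75, 25])
    bw = max(2 * (q75 - q25) / max(len(pooled), 1) ** (1 / 3), 0.1)
    edges = np.arange(pooled.min(), pooled.max() + bw, bw)
    if len(edges) < 2:
        mode = float(pooled.mean())
    else:
        counts, edges = np.histogram(pooled, bins=edges)
        mode = float((edges[np.argmax(counts)] + edges[np.argmax(counts) + 1]) / 2)

    width = float(np.percentile(pooled, 95) - np.percentile(pooled, 5))
    osc = oscillation_frequency(segments[0], traces[0].fs)
    try:
        r_in = float(np.mean([input_resistance(tr) for tr in traces]))
    except ValueError:
        r_in = None
    return BaselineProfile(resting_potential=mode, vm_width=width,
                           osc_freq=osc, r_in=r_in)


def strongest_direction_response(responses_by_direction) -> float:
    """Mean |response| at the direction with the largest-magnitude mean.

    ``responses_by_direction`` maps direction -> iterable of per-trial
    responses. Signed per-trial responses are averaged first, then the
    absolute value is taken, so strong inhibition can win. Ties (including
    the all-zero case) resolve to the first direction in mapping order.
    """
    if not responses_by_direction:
        raise ValueError("no directions supplied")
    best = None
    for direction, vals in responses_by_direction.items():
        m = abs(float(np.mean(list(vals))))
        if best is None or m > best:
            best = m
    return best


def response_table(traces, detect_config=None, windows=None,
                   rate_fs=1000.0) -> pd.DataFrame:
    """Tidy per-trial response table: one row per trial with spiking and
    membrane-potential responses (baseline-subtracted window means)."""
    rows = []
    for i, tr in enumerate(traces):
        w = windows or WindowSpec.around_onset(tr.trial.stim_onset)
        spikes = detect_spikes(tr, detect_config)
        rate = psth([spikes], tr.trial.duration, fs_out=rate_fs)
        rows.append({
            "trial_id": i, "fly_id": tr.fly_id, "neuron_id": tr.neuron_id,
            "direction": tr.trial.direction, "condition": tr.trial.condition,
            "response_hz": trial_response(rate, rate_fs, w),
            "vm_response_mv": trial_response(tr.samples, tr.fs, w),
            "n_spikes": len(spikes),
        })
    return pd.DataFrame(rows)
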