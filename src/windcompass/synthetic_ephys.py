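"""Ground-truth generator for whole-cell recording sessions.

Emulates 12 s patch-clamp trials from central-complex columnar neurons: a
4 s pre-stimulus baseline (with a -2 pA test pulse in the first second),
4 s of directional stimulation (stripe, airflow, odorized airflow, or
combinations), and 4 s of post-stimulus time, sampled at 10 kHz. Spiking is
an inhomogeneous Poisson process whose rate follows a circular-Gaussian
direction tuning with configurable multisensory integration (summation or
single-modality dominance); the membrane potential carries a resting level,
an optional baseline oscillation, smoothed noise, a subthreshold stimulus
deflection, the Ohmic pulse response, and stereotyped rendered spikes.

Parameter ranges (resting potential, input resistance, oscillation
frequency) are anchored to the intrinsic properties measured across the
surveyed cell types (roughly -40 to -18 mV, 1.5-10 GOhm, 2-4 Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import h5py
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from ._angles import circular_gaussian, ang_diff_deg, wrap_deg

FS_EPHYS = 10_000.0
"""Acquisition rate of the voltage traces, Hz."""

CONDITIONS = (
    "stripe",
    "airflow",
    "stripe+airflow",
    "airflow+odor",
    "stripe+airflow+odor",
)

SURVEY_DIRECTIONS = (-90.0, 0.0, 90.0, 180.0)
EIGHT_DIRECTIONS = (-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0)


def _parse_condition(condition: str) -> frozenset:
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition label: {condition!r}")
    return frozenset(condition.split("+"))


@dataclass(frozen=True)
class TrialSpec:
    """One 12 s trial: 4 s baseline, 4 s stimulus, 4 s post.

    The first second of baseline contains a 500 ms, -2 pA current injection
    used to track input resistance.
    """

    direction: float
    condition: str
    t_baseline: float = 4.0
    t_stim: float = 4.0
    t_post: float = 4.0
    pulse: tuple = (0.0, 0.5, -2.0)  # (onset s, duration s, current pA)

    def __post_init__(self):
        _parse_condition(self.condition)
        object.__setattr__(self, "direction", float(wrap_deg(self.direction)))
        onset, dur, _ = self.pulse
        if not (0.0 <= onset and onset + dur <= min(1.0, self.t_baseline)):
            raise ValueError("test pulse must lie within the first 1 s of baseline")

    @property
    def duration(self) -> float:
        return self.t_baseline + self.t_stim + self.t_post

    @property
    def stim_onset(self) -> float:
        return self.t_baseline

    @property
    def stim_offset(self) -> float:
        return self.t_baseline + self.t_stim


@dataclass(frozen=True)
class SessionDesign:
    """Block-pseudorandom trial order.

    Every (direction, condition) pair appears exactly once per block of
    ``len(directions) * len(conditions)`` trials, and all pairs are shown
    before any repeats (the paper-style 'set' structure).
    """

    trials: tuple
    directions: tuple
    conditions: tuple
    reps: int
    iti: float = 9.0

    def __len__(self):
        return len(self.trials)


def build_survey_session(directions, conditions, reps, seed,
                         trial_kwargs=None) -> SessionDesign:
    """Build a pseudorandom session: each of the |directions| x |conditions|
    pairs occurs once per block, ``reps`` blocks in total.

    The survey design is 4 directions x 5 conditions x 4 reps = 80 trials;
    the eight-direction airflow-only design is 8 x 1 x 5 = 40 trials.
    """
    directions = tuple(float(wrap_deg(d)) for d in directions)
    conditions = tuple(conditions)
    if not directions or not conditions:
        raise ValueError("directions and conditions must be non-empty")
    if len(set(directions)) != len(directions):
        raise ValueError("duplicate directions")
    if len(set(conditions)) != len(conditions):
        raise ValueError("duplicate conditions")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    for c in conditions:
        _parse_condition(c)

    rng = np.random.default_rng(seed)
    pairs = [(d, c) for d in directions for c in conditions]
    trial_kwargs = trial_kwargs or {}
    trials = []
    for _ in range(reps):
        order = rng.permutation(len(pairs))
        for idx in order:
            d, c = pairs[idx]
            trials.append(TrialSpec(direction=d, condition=c, **trial_kwargs))
    return SessionDesign(trials=tuple(trials), directions=directions,
                         conditions=conditions, reps=int(reps))


@dataclass(frozen=True)
class NeuronModel:
    """Generative parameters of a direction-tuned columnar neuron.

    Tuning is a circular Gaussian peaked at ``pref_dir`` with half-width at
    half-max ``tuning_width``; ``inhib_frac`` > 0 lets the tuning dip below
    zero opposite the preferred direction (contralateral inhibition: spiking
    is floored at 0 while the membrane potential hyperpolarizes).
    ``integration_mode`` selects how modality amplitudes combine during
    multimodal stimuli; odor multiplies the airflow term by ``a_odor_gain``
    (values < 1 emulate olfactory suppression of the airflow response).
    The stripe response carries its own preferred direction, offset from
    the airflow one by ``stripe_pref_offset`` (visual and airflow tuning
    need not align in a given cell; distinct tuning is also what lets the
    similarity analysis tell summation from single-modality dominance).
    """

    v_rest: float = -30.0           # mV
    osc_freq: float = 0.0           # Hz; 0 = tonic
    osc_amp: float = 0.0            # mV
    noise_sd: float = 0.5           # mV
    r_in: float = 5.0               # GOhm
    baseline_rate: float = 5.0      # spikes/s
    pref_dir: float = 90.0          # degrees
    tuning_width: float = 60.0      # degrees, half-width at half-max
    a_air: float = 15.0             # spikes/s at preferred direction
    a_stripe: float = 4.0
    a_odor_gain: float = 1.0        # multiplicative, on the airflow term
    integration_mode: str = "summation"
    temporal_profile: str = "tonic"  # or "transient"
    tau: float = 1.0                # s, decay constant when transient
    inhib_frac: float = 0.0         # anti-preferred dip as fraction of peak
    stripe_pref_offset: float = 0.0  # stripe pref_dir minus airflow pref_dir
    spike_amp: float = 40.0         # mV
    spike_threshold_true: float = -20.0  # mV
    vm_drive_gain: float = 0.2      # mV of subthreshold deflection per spikes/s

    def __post_init__(self):
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be >= 0")
        if self.tuning_width <= 0:
            raise ValueError("tuning_width must be > 0")
        if self.a_odor_gain <= 0:
            raise ValueError("a_odor_gain must be > 0")
        if self.temporal_profile == "transient" and self.tau <= 0:
            raise ValueError("tau must be > 0 for transient profile")
        if self.integration_mode not in ("summation", "airflow_dominant",
                                         "stripe_dominant"):
            raise ValueError(f"unknown integration_mode: {self.integration_mode}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def tuning(self, direction, modality="airflow"):
        """Direction tuning, peak 1 at the modality's preferred direction,
        possibly dipping to -inhib_frac opposite it."""
        pref = self.pref_dir + (self.stripe_pref_offset
                                if modality == "stripe" else 0.0)
        delta = ang_diff_deg(direction, pref)
        g = circular_gaussian(delta, self.tuning_width)
        return (1.0 + self.inhib_frac) * g - self.inhib_frac

    def stimulus_drive(self, condition: str, direction) -> float:
        """Tuned rate increment for a condition and direction, per the
        integration mode (spikes/s, before the temporal profile)."""
        parts = _parse_condition(condition)
        air = stripe = 0.0
        if "airflow" in parts:
            air = (self.a_air * (self.a_odor_gain if "odor" in parts else 1.0)
                   * self.tuning(direction, "airflow"))
        if "stripe" in parts:
            stripe = self.a_stripe * self.tuning(direction, "stripe")
        if self.integration_mode == "summation":
            return air + stripe
        if self.integration_mode == "airflow_dominant":
            return air if "airflow" in parts else stripe
        return stripe if "stripe" in parts else air


# cell-type presets: intrinsic values (resting potential, input resistance,
# oscillation) follow the measured cross-fly means; response amplitudes are
# set to the magnitudes the respective cell types show in the recordings
# (ventral P-FNs: strong, tens of spikes/s airflow responses; P-EN2:
# moderate summating responses; P-F3N2d: diverse, single-modality-dominated)
CELL_PRESETS = {
    "P-F1N3": dict(v_rest=-18.0, r_in=6.21, osc_freq=4.0, osc_amp=2.0,
                   baseline_rate=5.0, a_air=25.0, a_stripe=3.0,
                   a_odor_gain=0.5, pref_dir=90.0, tuning_width=60.0),
    "P-F2N3": dict(v_rest=-22.0, r_in=4.86, osc_freq=2.0, osc_amp=2.0,
                   baseline_rate=5.0, a_air=30.0, a_stripe=3.0,
                   pref_dir=90.0, tuning_width=60.0, inhib_frac=0.2),
    "P-EN2": dict(v_rest=-30.1, r_in=3.30, osc_freq=3.0, osc_amp=2.0,
                  baseline_rate=8.0, a_air=10.0, a_stripe=8.0,
                  integration_mode="summation", stripe_pref_offset=-90.0),
    "P-F3N2d": dict(v_rest=-30.9, r_in=2.58, baseline_rate=8.0,
                    a_air=12.0, a_stripe=8.0,
                    integration_mode="airflow_dominant",
                    stripe_pref_offset=-90.0),
}


def make_neuron(cell_type: str, **overrides) -> NeuronModel:
    """NeuronModel from a named cell-type preset, with overrides."""
    if cell_type not in CELL_PRESETS:
        raise ValueError(f"unknown cell type {cell_type!r}; "
                         f"have {sorted(CELL_PRESETS)}")
    params = dict(CELL_PRESETS[cell_type])
    params.update(overrides)
    return NeuronModel(**params)


def expected_rate(neuron: NeuronModel, trial: TrialSpec, t):
    """Ground-truth instantaneous firing rate (spikes/s) at time(s) t.

    Baseline rate outside the stimulus window; during the stimulus the
    tuned, integration-mode-combined drive is added (scaled by the temporal
    profile) and the total is floored at zero.
    """
    t = np.asarray(t, dtype=float)
    if np.any((t < 0) | (t > trial.duration)):
        raise ValueError("t outside trial")
    drive = neuron.stimulus_drive(trial.condition, trial.direction)
    in_stim = (t >= trial.stim_onset) & (t < trial.stim_offset)
    if neuron.temporal_profile == "transient":
        profile = np.exp(-(t - trial.stim_onset) / neuron.tau)
    else:
        profile = np.ones_like(t)
    rate = neuron.baseline_rate + drive * profile * in_stim
    return np.maximum(rate, 0.0)


@dataclass
class VoltageTrace:
    """One trial's membrane potential at 10 kHz plus generator ground truth."""

    samples: np.ndarray          # mV
    trial: TrialSpec
    fs: float = FS_EPHYS
    neuron_id: str = "cell0"
    fly_id: str = "fly0"
    seed: int = 0
    spike_times: np.ndarray | None = None  # ground truth, s

    @property
    def t(self):
        return np.arange(len(self.samples)) / self.fs

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("voltage trace contains non-finite values")


# spike rendering: 2 ms triangular depolarization peaking 1 ms after the
# Poisson event; the event time is the ground-truth spike time
_SPIKE_RISE_S = 1e-3
_SPIKE_FALL_S = 1e-3

# membrane-noise smoothing time constant (Gaussian kernel sigma)
_NOISE_SIGMA_S = 2e-3

# absolute refractory period of the generated point process
_T_REFRACTORY_S = 3e-3

# membrane-like smoothing of deterministic Vm deflections (pulse, drive)
_VM_SMOOTH_S = 10e-3


def _spike_kernel(fs: float, amp: float) -> np.ndarray:
    n_rise = int(round(_SPIKE_RISE_S * fs))
    n_fall = int(round(_SPIKE_FALL_S * fs))
    up = np.linspace(0.0, amp, n_rise + 1)
    down = np.linspace(amp, 0.0, n_fall + 1)[1:]
    return np.concatenate([up, down])


def simulate_trial_vm(neuron: NeuronModel, trial: TrialSpec, seed,
                      fs: float = FS_EPHYS, neuron_id: str = "cell0",
                      fly_id: str = "fly0") -> VoltageTrace:
    """Simulate one trial's membrane potential.

    Vm = v_rest + oscillation + smoothed Gaussian noise + subthreshold
    stimulus deflection + Ohmic pulse response + rendered spikes, with spike
    times drawn from an inhomogeneous Poisson process at ``expected_rate``.
    Identical (model, trial, seed) gives an identical trace.
    """
    rng = np.random.default_rng(seed)
    n = int(round(trial.duration * fs))
    t = np.arange(n) / fs

    vm = np.full(n, neuron.v_rest)
    if neuron.osc_amp != 0.0 and neuron.osc_freq != 0.0:
        vm += neuron.osc_amp * np.sin(2 * np.pi * neuron.osc_freq * t)

    if neuron.noise_sd > 0:
        sigma = _NOISE_SIGMA_S * fs
        noise = gaussian_filter1d(rng.normal(0.0, 1.0, n), sigma, mode="reflect")
        # restore unit variance after smoothing (white noise in, the filter
        # reduces the variance by 1 / (2 sigma sqrt(pi)))
        noise *= np.sqrt(2.0 * sigma * np.sqrt(np.pi))
        vm += neuron.noise_sd * noise

    # subthreshold deflection tracks the (signed) stimulus drive, so
    # contralateral inhibition hyperpolarizes even when spiking floors at 0
    rate = expected_rate(neuron, trial, t)
    drive_signed = rate - neuron.baseline_rate  # 0 outside stimulus
    deterministic = neuron.vm_drive_gain * drive_signed

    onset, dur, current = trial.pulse
    pulse_mask = (t >= onset) & (t < onset + dur)
    deterministic = deterministic + pulse_mask * (current * neuron.r_in)  # pA*GOhm = mV

    # membrane low-pass: smooth step edges so they do not masquerade as
    # spikes after high-pass filtering (10 ms, ~ a membrane time constant)
    vm += gaussian_filter1d(deterministic, _VM_SMOOTH_S * fs, mode="nearest")

    # inhomogeneous Poisson spikes with a short absolute refractory period.
    # The per-sample hazard is dead-time-corrected, h = r / (1 - r * t_ref),
    # so the delivered rate equals expected_rate in steady state (renewal
    # process with dead time: rate = h / (1 + h * t_ref)).
    hazard = rate / np.maximum(1.0 - rate * _T_REFRACTORY_S, 0.2)
    events = rng.random(n) < hazard / fs
    candidates = np.flatnonzero(events)
    n_ref = int(round(_T_REFRACTORY_S * fs))
    spike_idx = []
    last = -n_ref - 1
    for i in candidates:
        if i - last > n_ref:
            spike_idx.append(i)
            last = i
    spike_idx = np.asarray(spike_idx, dtype=int)
    kernel = _spike_kernel(fs, 1.0)
    n_rise = int(round(_SPIKE_RISE_S * fs))
    for i in spike_idx:
        start = i - n_rise
        k0 = max(0, -start)
        k1 = min(len(kernel), n - start)
        # peak reaches spike_amp above local Vm, crossing threshold_true
        amp = max(neuron.spike_amp, neuron.spike_threshold_true - vm[i] + 5.0)
        vm[start + k0:start + k1] += amp * kernel[k0:k1]

    try:
        seed_int = int(seed)
    except (TypeError, ValueError):
        seed_int = 0
    return VoltageTrace(samples=vm, trial=trial, fs=fs, neuron_id=neuron_id,
                        fly_id=fly_id, seed=seed_int, spike_times=spike_idx / fs)


def simulate_session(neuron: NeuronModel, design: SessionDesign, seed,
                     neuron_id: str = "cell0", fly_id: str = "fly0"):
    """Simulate all trials of a session with per-trial seeds derived from
    ``seed``. Returns a list of VoltageTrace."""
    rng = np.random.default_rng(seed)
    trial_seeds = rng.integers(0, 2**31 - 1, size=len(design))
    return [
        simulate_trial_vm(neuron, trial, int(s), neuron_id=neuron_id, fly_id=fly_id)
        for trial, s in zip(design.trials, trial_seeds)
    ]


def save_session(path, traces) -> None:
    """Write a session to one HDF5 container: per-trial voltage arrays plus a
    JSON metadata table (fly, cell, direction, condition, seed)."""
    meta = []
    with h5py.File(path, "w") as f:
        grp = f.create_group("trials")
        for i, tr in enumerate(traces):
            d = grp.create_dataset(f"trial{i:03d}", data=tr.samples)
            d.attrs["fs"] = tr.fs
            if tr.spike_times is not None:
                grp.create_dataset(f"trial{i:03d}_spikes", data=tr.spike_times)
            meta.append({
                "trial_id": i, "fly_id": tr.fly_id, "neuron_id": tr.neuron_id,
                "direction": tr.trial.direction, "condition": tr.trial.condition,
                "seed": tr.seed,
            })
        f.attrs["metadata"] = json.dumps(meta)


def load_session(path):
    """Read a session container written by :func:`save_session`."""
    traces = []
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        for m in meta:
            key = f"trial{m['trial_id']:03d}"
            samples = f["trials"][key][...]
            spikes = None
            if f"{key}_spikes" in f["trials"]:
                spikes = f["trials"][f"{key}_spikes"][...]
            trial = TrialSpec(direction=m["direction"], condition=m["condition"])
            traces.append(VoltageTrace(
                samples=samples, trial=trial, fs=float(f["trials"][key].attrs["fs"]),
                neuron_id=m["neuron_id"], fly_id=m["fly_id"], seed=int(m["seed"]),
                spike_times=spikes))
    return traces


def export_session_csv(path, traces) -> None:
    """Delimited-text export, one row per sample (interoperability format)."""
    frames = []
    for i, tr in enumerate(traces):
        frames.append(pd.DataFrame({
            "trial_id": i, "t": tr.t, "vm_mv": tr.samples,
            "direction": tr.trial.direction, "condition": tr.trial.condition,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
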