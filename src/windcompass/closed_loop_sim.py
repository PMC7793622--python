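"""Closed-loop tethered-flight arena simulator.

A fly agent steers a virtual orientation relative to a fixed airflow
source at 0 deg (world frame). Every control tick (50 Hz) the difference
in wingbeat angles (dWBA, positive = rightward turn) is multiplied by a
static gain (0.04) and applied as the orientation increment, capped at the
motor's maximum speed (144 deg/s). Sessions are divided into 20 s trials,
each carrying one open-loop perturbation: a pause in airflow (2 s or
150 ms) or a "slip" of the airflow source driven at full motor speed for
5 samples (14.4 deg) or 22 samples (63.36 deg), left or right. During a
slip the fly's input is ignored; during a pause the loop stays closed but
the agent switches to its airflow-off policy.

The agent is a phenomenological controller, not a biomechanical model: it
produces dWBA proportional to the error between its preferred
flow-relative orientation (downwind, 180 deg, by default) and its current
orientation, with motor noise, reaction latency, and an optional bias
toward the source while the airflow is off.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._angles import wrap_deg, ang_diff_deg

logger = logging.getLogger(__name__)

PERTURBATION_TYPES = (
    "pause_long", "pause_short",
    "slip_right_short", "slip_right_long",
    "slip_left_short", "slip_left_long",
)

PAUSE_DURATIONS_S = {"pause_long": 2.0, "pause_short": 0.15}
SLIP_SAMPLES = {"slip_right_short": 5, "slip_right_long": 22,
                "slip_left_short": 5, "slip_left_long": 22}
SLIP_SIGNS = {"slip_right_short": +1, "slip_right_long": +1,
              "slip_left_short": -1, "slip_left_long": -1}

# manipulation onset within each trial; 1 s in, so the 1 s pre-stimulus
# analysis window of the first trial lies inside the session
TRIAL_ONSET_S = 1.0


@dataclass(frozen=True)
class ArenaConfig:
    """Rig constants of the flight simulator."""

    fs: float = 50.0          # control-loop rate, Hz
    gain: float = 0.04        # deg of rotation per unit dWBA per sample
    motor_max: float = 144.0  # deg/s
    source_angle0: float = 0.0

    def __post_init__(self):
        if self.fs <= 0 or self.gain < 0 or self.motor_max <= 0:
            raise ValueError("invalid arena configuration")

    @property
    def max_step_deg(self) -> float:
        """Largest per-sample orientation change the motor can produce."""
        return self.motor_max / self.fs


@dataclass(frozen=True)
class PerturbationSchedule:
    """Ordered open-loop manipulations, one per 20 s trial."""

    entries: tuple            # of (type, onset s)
    trial_len: float = 20.0

    def __post_init__(self):
        onsets = [o for _, o in self.entries]
        if sorted(onsets) != list(onsets):
            raise ValueError("trial onsets must be sorted")
        for typ, _ in self.entries:
            if typ not in PERTURBATION_TYPES:
                raise ValueError(f"unknown perturbation type {typ!r}")

    @property
    def duration(self) -> float:
        return self.trial_len * len(self.entries)


def make_schedule(reps_per_type, seed, trial_len=20.0) -> PerturbationSchedule:
    """Pseudorandom perturbation schedule: the six types, ``reps_per_type``
    times each, shuffled blockwise (all six appear once per block of six
    trials). Ten reps gives the 60-trial, 20-minute session."""
    if reps_per_type < 1:
        raise ValueError("reps_per_type must be >= 1")
    rng = np.random.default_rng(seed)
    order = []
    for _ in range(reps_per_type):
        order.extend(rng.permutation(len(PERTURBATION_TYPES)))
    entries = tuple(
        (PERTURBATION_TYPES[t], i * trial_len + TRIAL_ONSET_S)
        for i, t in enumerate(order)
    )
    return PerturbationSchedule(entries=entries, trial_len=trial_len)


def apply_slip(n_samples, direction_sign, arena: ArenaConfig = ArenaConfig()):
    """Open-loop displacement of the airflow source, degrees.

    The source is driven at full motor speed for ``n_samples`` control
    ticks: 5 samples -> 14.4 deg, 22 samples -> 63.36 deg.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    return direction_sign * arena.motor_max * n_samples / arena.fs


@dataclass(frozen=True)
class FlyAgent:
    """Phenomenological steering policy.

    dWBA = k * wrapped(theta_goal - orientation) + noise while airflow is
    on; while airflow is off, a fixed-magnitude offset ``pause_bias``
    directed toward the source (plus noise). ``latency`` delays the
    orientation the policy sees by that many samples.
    """

    theta_goal: float = 180.0   # downwind
    k: float = 0.05             # dWBA units per degree of error
    noise_sd: float = 0.0
    pause_bias: float = 0.0     # dWBA offset toward source during pauses
    latency: int = 0            # samples

    def __post_init__(self):
        if self.k < 0 or self.latency < 0 or self.noise_sd < 0:
            raise ValueError("invalid agent parameters")


@dataclass
class BehaviorRecord:
    """One session: 50 Hz dWBA and virtual orientation plus the schedule."""

    t: np.ndarray
    dwba: np.ndarray          # degrees; positive = rightward turn
    orientation: np.ndarray   # degrees, wrapped to (-180, 180]
    airflow_on: np.ndarray    # bool
    schedule: PerturbationSchedule
    arena: ArenaConfig
    fly_id: str = "fly0"
    genotype_label: str = "control"
    seed: int = 0
    orientation0: float = 0.0

    @property
    def fs(self) -> float:
        return self.arena.fs

    def trial_type(self, i):
        """Perturbation type of the trial containing sample i."""
        trial = int(self.t[i] // self.schedule.trial_len)
        return self.schedule.entries[trial][0]

    def to_frame(self) -> pd.DataFrame:
        trial_id = (self.t // self.schedule.trial_len).astype(int)
        trial_type = [self.schedule.entries[j][0] for j in trial_id]
        return pd.DataFrame({
            "t": self.t, "dwba": self.dwba, "orientation": self.orientation,
            "airflow_on": self.airflow_on.astype(int),
            "trial_id": trial_id, "trial_type": trial_type,
        })

    def save(self, csv_path, sidecar_path=None):
        """Write the record as delimited text plus a JSON config sidecar."""
        self.to_frame().to_csv(csv_path, index=False)
        sidecar_path = sidecar_path or str(csv_path) + ".json"
        with open(sidecar_path, "w") as f:
            json.dump({
                "arena": asdict(self.arena),
                "schedule": {"entries": list(self.schedule.entries),
                             "trial_len": self.schedule.trial_len},
                "fly_id": self.fly_id, "genotype_label": self.genotype_label,
                "seed": self.seed, "orientation0": self.orientation0,
            }, f)


def load_record(csv_path, sidecar_path=None, validate=True) -> BehaviorRecord:
    """Read a saved BehaviorRecord; by default re-derives the orientation
    from dWBA + schedule and checks it matches the stored series."""
    sidecar_path = sidecar_path or str(csv_path) + ".json"
    df = pd.read_csv(csv_path)
    with open(sidecar_path) as f:
        meta = json.load(f)
    rec = BehaviorRecord(
        t=df["t"].to_numpy(), dwba=df["dwba"].to_numpy(),
        orientation=df["orientation"].to_numpy(),
        airflow_on=df["airflow_on"].to_numpy().astype(bool),
        schedule=PerturbationSchedule(
            entries=tuple((e[0], float(e[1])) for e in meta["schedule"]["entries"]),
            trial_len=meta["schedule"]["trial_len"]),
        arena=ArenaConfig(**meta["arena"]),
        fly_id=meta["fly_id"], genotype_label=meta["genotype_label"],
        seed=meta["seed"], orientation0=meta["orientation0"],
    )
    if validate:
        recon = reconstruct_orientation(rec)
        if not np.allclose(recon, rec.orientation, atol=1e-8):
            raise ValueError("stored orientation violates the closed-loop "
                             "update rule")
    return rec


def _perturbation_arrays(schedule: PerturbationSchedule, arena: ArenaConfig, n):
    """Per-sample slip increments (deg) and airflow-on flags."""
    slip_inc = np.zeros(n)
    airflow_on = np.ones(n, dtype=bool)
    fs = arena.fs
    for typ, onset in schedule.entries:
        i0 = int(round(onset * fs))
        if typ in PAUSE_DURATIONS_S:
            i1 = i0 + int(round(PAUSE_DURATIONS_S[typ] * fs))
            airflow_on[i0:min(i1, n)] = False
        else:
            k = SLIP_SAMPLES[typ]
            slip_inc[i0:min(i0 + k, n)] = SLIP_SIGNS[typ] * arena.max_step_deg
    return slip_inc, airflow_on


def step(agent: FlyAgent, arena: ArenaConfig, orientation, delayed_orientation,
         airflow_on, slip_increment, noise=0.0):
    """One control tick: returns (dwba, next_orientation).

    The agent's dWBA is computed from the (possibly delayed) orientation;
    the orientation update is clamp(gain * dWBA) per sample, unless this
    sample is inside an open-loop slip, in which case the slip increment
    applies and the fly's input is ignored.
    """
    if airflow_on:
        err = float(ang_diff_deg(agent.theta_goal, delayed_orientation))
        dwba = agent.k * err + noise
    else:
        # fixed-magnitude offset toward the source at 0 deg
        toward = -np.sign(wrap_deg(delayed_orientation))
        dwba = agent.pause_bias * toward + noise
    if slip_increment != 0.0:
        delta = slip_increment
    else:
        delta = np.clip(arena.gain * dwba, -arena.max_step_deg, arena.max_step_deg)
    return dwba, float(wrap_deg(orientation + delta))


def run_session(agent: FlyAgent, arena: ArenaConfig,
                schedule: PerturbationSchedule, seed,
                orientation0=0.0, fly_id="fly0",
                genotype_label="control") -> BehaviorRecord:
    """Simulate a full session; reproducible under seed."""
    fs = arena.fs
    n = int(round(schedule.duration * fs))
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, agent.noise_sd, n) if agent.noise_sd > 0 else np.zeros(n)
    slip_inc, airflow_on = _perturbation_arrays(schedule, arena, n)

    dwba = np.zeros(n)
    orientation = np.zeros(n)
    theta = float(wrap_deg(orientation0))
    history = [theta] * (agent.latency + 1)
    for i in range(n):
        delayed = history[0]
        dwba[i], theta = step(agent, arena, theta, delayed,
                              airflow_on[i], slip_inc[i], noise[i])
        orientation[i] = theta
        history.append(theta)
        history.pop(0)

    try:
        seed_int = int(seed)
    except (TypeError, ValueError):
        seed_int = 0
    return BehaviorRecord(
        t=np.arange(n) / fs, dwba=dwba, orientation=orientation,
        airflow_on=airflow_on, schedule=schedule, arena=arena,
        fly_id=fly_id, genotype_label=genotype_label, seed=seed_int,
        orientation0=float(wrap_deg(orientation0)),
    )


def reconstruct_orientation(record: BehaviorRecord) -> np.ndarray:
    """Replay the closed-loop update rule from dWBA + schedule.

    Exactly reproduces the stored orientation series of any record
    generated by :func:`run_session` (the closed-loop consistency
    invariant).
    """
    arena = record.arena
    n = len(record.dwba)
    slip_inc, _ = _perturbation_arrays(record.schedule, arena, n)
    out = np.zeros(n)
    theta = record.orientation0
    for i in range(n):
        if slip_inc[i] != 0.0:
            delta = slip_inc[i]
        else:
            delta = np.clip(arena.gain * record.dwba[i],
                            -arena.max_step_deg, arena.max_step_deg)
        theta = float(wrap_deg(theta + delta))
        out[i] = theta
    return out
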