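"""Angle conventions and small circular helpers.

All angles are fly-centered degrees on (-180, 180]: 0 is directly in front,
+90 ipsilateral, 180 behind, -90 contralateral (for behavior, 0 is the
airflow source in the world frame).
"""

from __future__ import annotations

import numpy as np


def wrap_deg(angle):
    """Wrap angle(s) in degrees to (-180, 180]."""
    wrapped = -np.mod(-np.asarray(angle, dtype=float) + 180.0, 360.0) + 180.0
    return wrapped


def ang_diff_deg(a, b):
    """Signed circular difference a - b in degrees, on (-180, 180]."""
    return wrap_deg(np.asarray(a, dtype=float) - np.asarray(b, dtype=float))


def circular_gaussian(delta_deg, width_deg):
    """Von-Mises-shaped bump, peak 1 at delta = 0.

    ``width_deg`` is the half-width at half maximum: the concentration is
    chosen so the bump equals 0.5 at |delta| = width_deg.
    """
    if width_deg <= 0:
        raise ValueError("tuning width must be positive")
    kappa = np.log(2.0) / (1.0 - np.cos(np.deg2rad(width_deg)))
    return np.exp(kappa * (np.cos(np.deg2rad(delta_deg)) - 1.0))
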