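"""Multisensory integration metrics: summation and response similarity.

Two complementary views of how a cell combines a visual stripe with
airflow. The summation view plots the observed multimodal response per
direction against the sum of the unimodal means; points on the diagonal
indicate linear summation. The similarity view concatenates per-direction
mean response timecourses (stimulus and offset periods, seconds 4-12 of
each trial) and correlates the multimodal timecourse with each unimodal
one, yielding the pair (rho_a, rho_s); equal coefficients are the hallmark
of summation, while one dominant modality pulls the pair off the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

DIRECTION_ORDER = (-90.0, 0.0, 90.0, 180.0)
TRUNCATE_WINDOW = (4.0, 12.0)  # stimulus response + offset periods, s


@dataclass(frozen=True)
class SimilarityResult:
    """Correlations of a multimodal timecourse with each unimodal one."""

    rho_air: float
    rho_stripe: float
    n_points: int
    degenerate: bool = False  # a zero-variance series made rho undefined


def summation_points(stripe_means, airflow_means, multi_means):
    """Per-direction (predicted, observed) pairs for the summation plot.

    ``predicted`` = mean stripe-alone + mean airflow-alone response for a
    direction; ``observed`` = the mean multimodal response from the same
    direction. For the trimodal variant pass the airflow+odor means as
    ``airflow_means`` and the trimodal means as ``multi_means``.
    """
    dirs = set(stripe_means)
    if dirs != set(airflow_means) or dirs != set(multi_means):
        raise ValueError("direction sets differ across conditions")
    return [
        (float(stripe_means[d]) + float(airflow_means[d]), float(multi_means[d]))
        for d in stripe_means
    ]


def _concat(psths_by_direction, order, fs, window, baseline_window):
    segs = []
    i0 = int(round(window[0] * fs))
    i1 = int(round(window[1] * fs))
    for d in order:
        seg = np.asarray(psths_by_direction[d], dtype=float)
        if baseline_window is not None:
            b0 = int(round(baseline_window[0] * fs))
            b1 = int(round(baseline_window[1] * fs))
            seg = seg - seg[b0:b1].mean()
        segs.append(seg[i0:i1])
    return np.concatenate(segs)


def similarity_coefficients(multi, airflow, stripe, fs,
                            order=DIRECTION_ORDER,
                            window=TRUNCATE_WINDOW,
                            baseline_window=(2.5, 3.5)) -> SimilarityResult:
    """Cross-condition correlation pair (rho_a, rho_s).

    Each argument maps direction -> full-trial mean PSTH sampled at ``fs``.
    Segments are baseline-subtracted (set ``baseline_window=None`` for raw),
    truncated to ``window`` (seconds 4-12 by default) and concatenated in a
    fixed direction order; Pearson correlations are computed point by point
    on the concatenations. A zero-variance series yields an explicit
    degenerate result (NaN coefficients), never a silent 0.
    """
    for m in (multi, airflow, stripe):
        missing = set(order) - set(m)
        if missing:
            raise ValueError(f"missing directions: {sorted(missing)}")
    cm = _concat(multi, order, fs, window, baseline_window)
    ca = _concat(airflow, order, fs, window, baseline_window)
    cs = _concat(stripe, order, fs, window, baseline_window)
    if not (len(cm) == len(ca) == len(cs)):
        raise ValueError("PSTHs have unequal lengths")

    degenerate = any(np.std(x) == 0 for x in (cm, ca, cs))
    if degenerate:
        return SimilarityResult(np.nan, np.nan, len(cm), degenerate=True)
    rho_a = float(np.corrcoef(cm, ca)[0, 1])
    rho_s = float(np.corrcoef(cm, cs)[0, 1])
    return SimilarityResult(rho_a, rho_s, len(cm))


def similarity_table(results_by_cell) -> pd.DataFrame:
    """Tidy per-cell (rho_a, rho_s) table from a {cell: SimilarityResult}
    mapping, for export alongside the summation point lists."""
    rows = [
        {"cell": cell, "rho_air": r.rho_air, "rho_stripe": r.rho_stripe,
         "n_points": r.n_points, "degenerate": r.degenerate}
        for cell, r in results_by_cell.items()
    ]
    return pd.DataFrame(rows)


def session_similarity(traces, fs_out=1000.0, order=DIRECTION_ORDER,
                       detect_config=None) -> SimilarityResult:
    """Similarity coefficients straight from a session's voltage traces.

    Groups trials by (condition, direction), computes trial-mean PSTHs for
    the airflow-alone, stripe-alone, and stripe+airflow conditions, and
    runs :func:`similarity_coefficients` on them.
    """
    from . import ephys_core  # deferred: analysis layer above this module

    by_key: dict = {}
    for tr in traces:
        key = (tr.trial.condition, tr.trial.direction)
        by_key.setdefault(key, []).append(ephys_core.detect_spikes(tr, detect_config))
    duration = traces[0].trial.duration
    psths = {
        cond: {
            d: ephys_core.psth(by_key[(cond, d)], duration, fs_out=fs_out)
            for d in order
        }
        for cond in ("stripe+airflow", "airflow", "stripe")
    }
    return similarity_coefficients(psths["stripe+airflow"], psths["airflow"],
                                   psths["stripe"], fs=fs_out, order=order)
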