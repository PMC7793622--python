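"""Nonparametric tests, Bonferroni correction, and summary reports.

Paired comparisons use the Wilcoxon signed-rank test (exact null by
enumeration for n <= 12 nonzero differences, normal approximation above),
unpaired comparisons the Mann-Whitney U test (exact for small samples
without ties), and distribution comparisons the two-sample
Kolmogorov-Smirnov test. All tests are two-sided by default with ties
mid-ranked; families of comparisons are corrected with the Bonferroni
method (per-test threshold alpha / m).
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    p: float
    n: tuple
    method: str = ""
    degenerate: bool = False


@dataclass(frozen=True)
class BonferroniResult:
    threshold: float          # per-test alpha
    adjusted_p: tuple
    reject: tuple
    m: int


def paired_rank_test(x, y, alternative="two-sided") -> TestResult:
    """Wilcoxon signed-rank test on paired samples.

    Zero differences are discarded (the classic treatment); if every
    difference is zero the result is flagged degenerate with p = 1. The
    null distribution is exact for n <= 12 nonzero differences and a
    continuity-corrected normal approximation above.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be non-empty and equal-length")
    d = x - y
    nz = np.count_nonzero(d)
    if nz == 0:
        return TestResult("signed-rank", 0.0, 1.0, (x.size,), "degenerate",
                          degenerate=True)
    method = "exact" if nz <= 12 else "approx"
    res = stats.wilcoxon(x, y, alternative=alternative, method=method,
                         zero_method="wilcox", correction=(method == "approx"))
    return TestResult("signed-rank", float(res.statistic), float(res.pvalue),
                      (x.size,), method)


def unpaired_rank_test(x, y, alternative="two-sided") -> TestResult:
    """Mann-Whitney U test on independent samples.

    Exact enumeration when min(n) <= 8, n + m <= 16, and there are no
    ties; otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = min(x.size, y.size) <= 8 and x.size + y.size <= 16 and not has_ties
    method = "exact" if exact else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return TestResult("rank-sum", float(res.statistic), float(res.pvalue),
                      (x.size, y.size), method)


def ks_test(x, y) -> TestResult:
    """Two-sample Kolmogorov-Smirnov test (statistic = max ECDF gap)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y)
    return TestResult("ks", float(res.statistic), float(res.pvalue),
                      (x.size, y.size))


def bonferroni(pvals, alpha=0.05) -> BonferroniResult:
    """Bonferroni correction for a family of m comparisons."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    pvals = np.asarray(pvals, dtype=float)
    m = pvals.size
    if m == 0:
        raise ValueError("no p values")
    threshold = alpha / m
    adjusted = np.minimum(pvals * m, 1.0)
    return BonferroniResult(threshold=threshold,
                            adjusted_p=tuple(adjusted),
                            reject=tuple(pvals < threshold), m=m)


# ---------------------------------------------------------------------------
# report generation

def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def plot_rho_scatter(results, path):
    """rho_s vs rho_a scatter with the summation diagonal."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ra = [r.rho_air for r in results if not r.degenerate]
    rs = [r.rho_stripe for r in results if not r.degenerate]
    ax.plot([-1, 1], [-1, 1], "k--", lw=0.8)
    ax.scatter(ra, rs, s=18)
    ax.set_xlabel(r"$\rho_a$ (airflow)")
    ax.set_ylabel(r"$\rho_s$ (stripe)")
    ax.set_xlim(-1, 1); ax.set_ylim(-1, 1)
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)


def plot_stick_and_ball(summary: pd.DataFrame, path):
    """Polar stick-and-ball plot of per-fly mean orientation and fixation
    strength (airflow source at 0 deg)."""
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
    for _, row in summary.iterrows():
        th = np.deg2rad(row["mean_orientation_deg"])
        r = row["fixation_strength"]
        ax.plot([th, th], [0, r], "-", color="0.4", lw=1)
        ax.plot(th, r, "o", ms=5)
    ax.set_rmax(1.0)
    ax.set_theta_zero_location("N")
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)


def plot_perturbation_timecourses(responses, path):
    """Mean +/- SEM dWBA timecourses per perturbation type."""
    fig, axes = plt.subplots(1, len(responses), figsize=(3 * len(responses), 3),
                             sharey=True, squeeze=False)
    for ax, (typ, r) in zip(axes[0], responses.items()):
        m, s = r.mean_timecourse, r.sem_timecourse
        ax.fill_between(r.t, m - s, m + s, alpha=0.3)
        ax.plot(r.t, m)
        ax.axvline(0, color="k", lw=0.6, ls=":")
        ax.set_title(typ, fontsize=9)
        ax.set_xlabel("time from onset (s)")
    axes[0][0].set_ylabel(r"$\Delta$WBA (deg)")
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)


def plot_tuning_curve(curve, path, vector=None):
    fig, ax = plt.subplots(figsize=(4, 3))
    order = np.argsort(curve.directions)
    ax.axhline(0, color="k", lw=0.6)
    ax.plot(curve.directions[order], curve.responses[order], "o-")
    if curve.sem is not None:
        ax.errorbar(curve.directions[order], curve.responses[order],
                    yerr=np.asarray(curve.sem)[order], fmt="none", ecolor="0.5")
    if vector is not None and vector.defined:
        ax.axvline(vector.angle, color="C3", ls="--", lw=1)
    ax.set_xlabel("airflow direction (deg)")
    ax.set_ylabel("response (spikes/s)")
    fig.tight_layout(); fig.savefig(path, dpi=120); plt.close(fig)
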