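"""Method-agreement and cohort statistics for TUG durations.

Covers the validation toolkit for comparing duration measurements between
methods (e.g., IMU-derived vs stopwatch): Pearson correlation, ordinary
least-squares calibration, Bland-Altman bias and limits of agreement, a gamma
fit for the right-tailed duration distribution, Wilcoxon signed-rank
comparison of paired conditions, and distance normalization of episodes so
walks of different lengths become comparable as seconds per meter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "TUG_DISTANCE_M",
    "CHAIR_CHANGE_RANGE_M",
    "CHAIR_CHANGE_DISTANCE_M",
    "AgreementReport",
    "NormalizedEpisode",
    "PairedComparison",
    "agreement",
    "fit_gamma",
    "mean_walk_distance",
    "normalize_episode",
    "compare_paired",
    "plot_agreement",
    "plot_bland_altman",
]

#: assumed walking distance of the standard test (3 m out + 3 m back)
TUG_DISTANCE_M = 6.0
#: observed chair-to-chair distances in the naturalistic setting
CHAIR_CHANGE_RANGE_M = (3.0, 4.1)


def mean_walk_distance(min_m: float, max_m: float) -> float:
    """Assumed mean walking distance: the midpoint of an observed range."""
    if not (0 < min_m <= max_m):
        raise ValueError("need 0 < min_m <= max_m")
    return (min_m + max_m) / 2.0


CHAIR_CHANGE_DISTANCE_M = mean_walk_distance(*CHAIR_CHANGE_RANGE_M)


@dataclass(frozen=True)
class AgreementReport:
    """Paired-method statistics for durations measured by two methods.

    The regression predicts method B from method A (``b ~ slope*a +
    intercept``); Bland-Altman ``bias`` is ``mean(b - a)`` with limits of
    agreement at ``bias +/- 1.96`` sample standard deviations of the
    differences.  ``pearson_r`` and ``p_value`` are NaN when either input is
    constant (correlation undefined).
    """

    n: int
    pearson_r: float
    p_value: float
    slope: float
    intercept: float
    bias: float
    loa_low: float
    loa_high: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "slope": self.slope,
            "intercept": self.intercept,
            "bias": self.bias,
            "loa_low": self.loa_low,
            "loa_high": self.loa_high,
        }


def agreement(a, b) -> AgreementReport:
    """Full agreement analysis between two equal-length duration vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    n = a.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        r, p = math.nan, math.nan
        if np.std(a) == 0.0:
            slope, intercept = math.nan, math.nan
        else:
            fit = stats.linregress(a, b)
            slope, intercept = float(fit.slope), float(fit.intercept)
    else:
        r_res = stats.pearsonr(a, b)
        r, p = float(r_res.statistic), float(r_res.pvalue)
        fit = stats.linregress(a, b)
        slope, intercept = float(fit.slope), float(fit.intercept)
    d = b - a
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1)) if n > 1 else 0.0
    return AgreementReport(
        n=n,
        pearson_r=r,
        p_value=p,
        slope=slope,
        intercept=intercept,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def fit_gamma(durations) -> tuple[float, float]:
    """Maximum-likelihood gamma fit (location fixed at 0) of durations.

    Returns ``(shape, scale)``.  Durations must be strictly positive and
    non-degenerate; a constant sample has no ML gamma fit and raises.
    """
    x = np.asarray(durations, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 durations")
    if np.any(x <= 0):
        raise ValueError("durations must be strictly positive")
    if np.all(x == x[0]):
        raise ValueError("gamma fit is degenerate for a constant sample")
    shape, _, scale = stats.gamma.fit(x, floc=0.0)
    return float(shape), float(scale)


@dataclass(frozen=True)
class NormalizedEpisode:
    """A walking episode's duration normalized by its assumed distance, in
    seconds per meter (larger = slower)."""

    raw_duration_s: float
    distance_m: float
    normalized_duration: float


def normalize_episode(duration_s: float, distance_m: float) -> NormalizedEpisode:
    """Normalize an episode duration by walking distance (seconds per meter)."""
    if distance_m <= 0:
        raise ValueError("distance_m must be positive")
    return NormalizedEpisode(
        raw_duration_s=float(duration_s),
        distance_m=float(distance_m),
        normalized_duration=float(duration_s) / float(distance_m),
    )


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank + correlation summary of two paired conditions."""

    n: int
    wilcoxon_statistic: float
    wilcoxon_p: float
    pearson_r: float
    pearson_p: float
    median_a: float
    median_b: float

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "wilcoxon_statistic": self.wilcoxon_statistic,
            "wilcoxon_p": self.wilcoxon_p,
            "pearson_r": self.pearson_r,
            "pearson_p": self.pearson_p,
            "median_a": self.median_a,
            "median_b": self.median_b,
        }


def compare_paired(a, b) -> PairedComparison:
    """Compare paired (normalized) durations between two conditions.

    Two-sided Wilcoxon signed-rank with zero differences dropped; the exact
    null distribution is used up to n=25 pairs and the normal approximation
    beyond.  Identical vectors are the degenerate no-difference case and are
    reported with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("a and b must be equal-length 1-D vectors")
    d = b - a
    nz = d[d != 0]
    if nz.size == 0:
        w_stat, w_p = math.nan, 1.0
    else:
        method = "exact" if nz.size <= 25 else "approx"
        res = stats.wilcoxon(nz, alternative="two-sided", method=method)
        w_stat, w_p = float(res.statistic), float(res.pvalue)
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        r, rp = math.nan, math.nan
    else:
        rr = stats.pearsonr(a, b)
        r, rp = float(rr.statistic), float(rr.pvalue)
    return PairedComparison(
        n=int(a.size),
        wilcoxon_statistic=w_stat,
        wilcoxon_p=w_p,
        pearson_r=r,
        pearson_p=rp,
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
    )


def _pyplot():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def plot_agreement(a, b, report: AgreementReport, path) -> None:
    """Scatter of paired durations with the fitted regression line."""
    plt = _pyplot()
    a = np.asarray(a, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(a, b, s=14, alpha=0.7)
    xs = np.linspace(a.min(), a.max(), 50)
    ax.plot(xs, report.slope * xs + report.intercept, "k--", lw=1)
    ax.set_xlabel("method A duration (s)")
    ax.set_ylabel("method B duration (s)")
    ax.set_title(f"r = {report.pearson_r:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_bland_altman(a, b, report: AgreementReport, path) -> None:
    """Bland-Altman plot: per-pair difference against per-pair mean."""
    plt = _pyplot()
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter((a + b) / 2, b - a, s=14, alpha=0.7)
    for y, style in ((report.bias, "-"), (report.loa_low, "--"), (report.loa_high, "--")):
        ax.axhline(y, color="k", ls=style, lw=1)
    ax.set_xlabel("mean of methods (s)")
    ax.set_ylabel("difference B - A (s)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
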