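"""Clinical assay-validation statistics for the LP-X test.

Implements the standard validation battery: replicate imprecision (mean, SD,
%CV), limit of blank, lower limit of quantitation at the 20 %-CV point of the
precision profile, Deming errors-in-both-variables linearity, refrigerated /
freeze–thaw stability against a 10 % bias rule (two consecutive excursions),
interference screening at a 10 % bias threshold, and population screening
frequency.

Conventions: sample SD uses the n−1 denominator; bias thresholds compare
|bias| (interference can push results either way); reporting precision
follows clinical-table practice (%CV to 1 decimal, screening frequency to 2
decimals) while internal arithmetic is full precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PrecisionSummary",
    "DemingFit",
    "StabilityAssessment",
    "LloqEstimate",
    "LinearityReport",
    "InterferenceReport",
    "precision_summary",
    "cv_percent",
    "percent_bias",
    "limit_of_blank",
    "lloq_from_profile",
    "deming_fit",
    "linearity_assess",
    "stability_assess",
    "interference_assess",
    "detection_frequency",
]


# ---------------------------------------------------------------------------
# Imprecision
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PrecisionSummary:
    n: int
    mean: float  # mg/dL
    sd: float  # mg/dL
    cv_percent: float  # %


def precision_summary(values: Sequence[float]) -> PrecisionSummary:
    """Sample mean, SD (n−1) and %CV of a replicate series."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need ≥ 2 replicates, got {v.size}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    if mean <= 0:
        raise ValueError(f"CV undefined for mean {mean} ≤ 0")
    return PrecisionSummary(n=int(v.size), mean=mean, sd=sd, cv_percent=cv_percent(mean, sd))


def cv_percent(mean: float, sd: float) -> float:
    """Coefficient of variation, 100·SD/mean, reported to 1 decimal."""
    if mean <= 0:
        raise ValueError(f"CV undefined for mean {mean} ≤ 0")
    if sd < 0:
        raise ValueError("SD must be nonnegative")
    return round(100.0 * sd / mean, 1)


def percent_bias(baseline: float, value: float, ndigits: int | None = 1) -> float:
    """100·(value − baseline)/baseline.

    ``ndigits`` sets reporting precision (1 decimal by default; pass 0 for
    integer reporting as used for freeze–thaw tables, None for full
    precision).
    """
    if baseline <= 0:
        raise ValueError(f"baseline must be positive, got {baseline}")
    bias = 100.0 * (value - baseline) / baseline
    if ndigits is None:
        return bias
    bias = round(bias, ndigits)
    return int(bias) if ndigits == 0 else bias


# ---------------------------------------------------------------------------
# Limits
# ---------------------------------------------------------------------------

def limit_of_blank(
    blank_replicate_sets: Sequence[Sequence[float]], mode: str = "mean"
) -> float:
    """Limit of blank from replicate measurements of blank pools.

    ``mode="mean"`` (default): grand mean of all blank measurements.
    ``mode="parametric"``: mean + 1.645·SD over all blank measurements
    (one-sided 95th percentile under normality).
    """
    if not blank_replicate_sets:
        raise ValueError("need at least one blank replicate set")
    allv = np.concatenate([np.asarray(s, dtype=float).ravel() for s in blank_replicate_sets])
    if allv.size == 0:
        raise ValueError("blank replicate sets are empty")
    if mode == "mean":
        return float(allv.mean())
    if mode == "parametric":
        sd = float(allv.std(ddof=1)) if allv.size > 1 else 0.0
        return float(allv.mean() + 1.645 * sd)
    raise ValueError(f"unknown LOB mode {mode!r}")


@dataclass(frozen=True)
class LloqEstimate:
    value: float  # mg/dL
    status: str  # "interpolated" | "at-node" | "below-profile" | "above-profile"


def lloq_from_profile(
    pool_concentrations: Sequence[float],
    pool_cvs: Sequence[float],
    target_cv: float = 20.0,
) -> LloqEstimate:
    """Concentration at which the precision profile crosses ``target_cv``.

    Pools are sorted by concentration; the crossing between the bracketing
    pools is located by log-log linear interpolation (exact for a power-law
    CV(c) profile).  If every pool CV is below target the lowest pool is
    returned with status ``below-profile``; if every CV is above, the highest
    pool with ``above-profile``.
    """
    c = np.asarray(pool_concentrations, dtype=float)
    cv = np.asarray(pool_cvs, dtype=float)
    if c.size != cv.size or c.size < 2:
        raise ValueError("need ≥ 2 pools with matching CVs")
    if np.any(c <= 0) or np.any(cv <= 0):
        raise ValueError("pool concentrations and CVs must be positive")
    order = np.argsort(c)
    c, cv = c[order], cv[order]
    for i in range(c.size):
        if math.isclose(cv[i], target_cv, rel_tol=0, abs_tol=1e-12):
            return LloqEstimate(float(c[i]), "at-node")
    if np.all(cv < target_cv):
        return LloqEstimate(float(c[0]), "below-profile")
    if np.all(cv > target_cv):
        return LloqEstimate(float(c[-1]), "above-profile")
    # find the last downward crossing: cv above target at i, below at i+1
    for i in range(c.size - 1):
        hi, lo = cv[i], cv[i + 1]
        if (hi - target_cv) * (lo - target_cv) < 0:
            t = (math.log(target_cv) - math.log(hi)) / (math.log(lo) - math.log(hi))
            logc = math.log(c[i]) + t * (math.log(c[i + 1]) - math.log(c[i]))
            return LloqEstimate(float(math.exp(logc)), "interpolated")
    # CVs not monotone around target with no sign change between neighbours
    raise ValueError("precision profile never crosses the target CV between pools")


# ---------------------------------------------------------------------------
# Deming regression and linearity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DemingFit:
    slope: float
    intercept: float  # mg/dL
    lam: float = 1.0  # ratio of y- to x-error variance

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(x, dtype=float) + self.intercept


def deming_fit(x: Sequence[float], y: Sequence[float], lam: float = 1.0) -> DemingFit:
    """Closed-form Deming errors-in-variables regression.

    With sample (co)variances s_xx, s_yy, s_xy and error-variance ratio λ:

        slope = [s_yy − λ·s_xx + √((s_yy − λ·s_xx)² + 4λ·s_xy²)] / (2·s_xy)
        intercept = ȳ − slope·x̄
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need paired vectors with n ≥ 3")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    xm, ym = x.mean(), y.mean()
    sxx = float(np.sum((x - xm) ** 2))
    syy = float(np.sum((y - ym) ** 2))
    sxy = float(np.sum((x - xm) * (y - ym)))
    if sxx == 0:
        raise ValueError("variance of x must be positive")
    if sxy == 0:
        raise ValueError("degenerate data: s_xy = 0")
    d = syy - lam * sxx
    slope = (d + math.sqrt(d * d + 4 * lam * sxy * sxy)) / (2 * sxy)
    return DemingFit(slope=float(slope), intercept=float(ym - slope * xm), lam=lam)


@dataclass(frozen=True)
class LinearityReport:
    fit: DemingFit
    flagged: tuple[int, ...]  # indices (by ascending expected) outside tolerance
    linear_range: tuple[float, float]  # widest contiguous clean span (expected units)
    tolerance_percent: float


def linearity_assess(
    measured: Sequence[float], expected: Sequence[float], tolerance: float = 10.0
) -> LinearityReport:
    """Deming fit of measured on expected plus a point-wise deviation screen.

    A point is flagged when its measured value deviates from the fitted line
    by more than ``tolerance`` percent of the line value; the claimed linear
    range is the widest contiguous run of unflagged points (in expected
    concentration).
    """
    m = np.asarray(measured, dtype=float)
    e = np.asarray(expected, dtype=float)
    if m.shape != e.shape or m.size < 3:
        raise ValueError("need paired vectors with n ≥ 3")
    order = np.argsort(e)
    m, e = m[order], e[order]
    fit = deming_fit(e, m)
    line = fit.predict(e)
    with np.errstate(divide="ignore", invalid="ignore"):
        dev = 100.0 * np.abs(m - line) / np.abs(line)
    flagged = tuple(int(i) for i in np.nonzero(dev > tolerance)[0])
    # widest contiguous unflagged run
    best_lo = best_hi = None
    best_len = 0
    i = 0
    n = m.size
    flagged_set = set(flagged)
    while i < n:
        if i in flagged_set:
            i += 1
            continue
        j = i
        while j + 1 < n and (j + 1) not in flagged_set:
            j += 1
        if j - i + 1 > best_len:
            best_len, best_lo, best_hi = j - i + 1, i, j
        i = j + 1
    if best_lo is None:
        raise ValueError("no unflagged points; linearity cannot be claimed")
    return LinearityReport(
        fit=fit,
        flagged=flagged,
        linear_range=(float(e[best_lo]), float(e[best_hi])),
        tolerance_percent=float(tolerance),
    )


# ---------------------------------------------------------------------------
# Stability and interference
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StabilityAssessment:
    #: (timepoint label, value mg/dL, % bias vs baseline; baseline bias 0)
    series: tuple[tuple[str, float, float], ...]
    claimed_stable_through: str
    threshold_percent: float


def stability_assess(
    series: Sequence[tuple[str, float]],
    baseline_label: str | None = None,
    threshold: float = 10.0,
    bias_ndigits: int | None = None,
) -> StabilityAssessment:
    """Apply the two-consecutive-excursions stability rule.

    Bias of each point is computed against the baseline value.  Stability is
    claimed through the last point before the first run of ≥ 2 consecutive
    points with |bias| > threshold; a single isolated excursion does not
    break stability.  If the run starts at the first post-baseline point,
    stability is claimed through baseline only.
    """
    if not series:
        raise ValueError("empty series")
    labels = [str(lab) for lab, _ in series]
    if baseline_label is None:
        baseline_label = labels[0]
    if baseline_label not in labels:
        raise ValueError(f"baseline label {baseline_label!r} not in series")
    b_idx = labels.index(baseline_label)
    baseline = float(series[b_idx][1])
    rest = [(lab, float(v)) for i, (lab, v) in enumerate(series) if i != b_idx]
    if not rest:
        raise ValueError("need at least one non-baseline point")
    rows = [(baseline_label, baseline, 0.0)]
    biases = []
    for lab, v in rest:
        bias = percent_bias(baseline, v, ndigits=bias_ndigits)
        rows.append((lab, v, float(bias)))
        biases.append(float(bias))
    exceed = [abs(b) > threshold for b in biases]
    fail_at = None
    for i in range(len(exceed) - 1):
        if exceed[i] and exceed[i + 1]:
            fail_at = i
            break
    if fail_at is None:
        claimed = rest[-1][0]
    elif fail_at == 0:
        claimed = baseline_label
    else:
        claimed = rest[fail_at - 1][0]
    return StabilityAssessment(
        series=tuple(rows),
        claimed_stable_through=claimed,
        threshold_percent=float(threshold),
    )


@dataclass(frozen=True)
class InterferenceReport:
    #: (substance concentration, mean LP-X, % bias vs control)
    rows: tuple[tuple[float, float, float], ...]
    lowest_interfering_concentration: float | None
    max_tested_concentration: float
    threshold_percent: float

    @property
    def interferes(self) -> bool:
        return self.lowest_interfering_concentration is not None


def interference_assess(
    control_mean: float,
    spiked_means: Sequence[tuple[float, float]],
    threshold: float = 10.0,
) -> InterferenceReport:
    """Lowest interferent concentration with |bias| > threshold vs control."""
    if control_mean <= 0:
        raise ValueError("control mean must be positive")
    if not spiked_means:
        raise ValueError("need at least one spiked level")
    rows = []
    for conc, mean in sorted((float(c), float(m)) for c, m in spiked_means):
        rows.append((conc, mean, percent_bias(control_mean, mean, ndigits=None)))
    lowest = next((c for c, _, b in rows if abs(b) > threshold), None)
    return InterferenceReport(
        rows=tuple(rows),
        lowest_interfering_concentration=lowest,
        max_tested_concentration=rows[-1][0],
        threshold_percent=float(threshold),
    )


def detection_frequency(n_flagged: int, n_total: int) -> float:
    """Percentage of screened spectra flagged positive, to 2 decimals."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_flagged <= n_total:
        raise ValueError("require 0 ≤ n_flagged ≤ n_total")
    return round(100.0 * n_flagged / n_total, 2)
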