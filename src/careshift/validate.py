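"""Reference-device indices and group statistics.

The seat-sensor indices are validated against two conventional devices:

* a force plate under the wheelchair, whose centre-of-pressure shift
  ``dCoP`` between the pre-contact baseline and the post-seating stable
  state measures where the recipient ended up on the seat, and
* a head marker tracked by motion capture, whose third downward-velocity
  peak during the transfer, ``v_z`` (mm/s), measures how fast the recipient
  was lowered onto the seat.

The group comparisons mirror the original study design: simple linear
regression (r, t, p) between a sensor index and its reference, a two-sided
Mann-Whitney test between the inexperienced and expert groups, and Tukey
box summaries.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import signal, stats

from .errors import AnalysisError, ContactError, ParameterError, PeakError
from .seatpos import _check_uniform

#: Seconds from seat contact (t1) to the declared stable state (t2).
STABLE_DELAY_S = 5.0
#: Length of the averaging window after t2, seconds.
AVERAGE_WINDOW_S = 0.5

_T_TOL = 1e-6


@dataclass
class CoPSeries:
    """Force-plate centre-of-pressure stream (mm), uniform at fs (600 Hz)."""

    fs: float
    t: np.ndarray
    cop_x: np.ndarray
    cop_y: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.cop_x = np.asarray(self.cop_x, dtype=float)
        self.cop_y = np.asarray(self.cop_y, dtype=float)
        if not (self.t.shape == self.cop_x.shape == self.cop_y.shape):
            raise ParameterError("CoPSeries arrays must share one shape")
        if not (np.all(np.isfinite(self.cop_x)) and np.all(np.isfinite(self.cop_y))):
            raise ParameterError("CoPSeries values must be finite")
        _check_uniform(self.t, self.fs, "CoPSeries")


@dataclass
class MarkerTrajectory:
    """Head-marker height stream z (mm), uniform at fs (120 Hz)."""

    fs: float
    t: np.ndarray
    z: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.z = np.asarray(self.z, dtype=float)
        if self.t.shape != self.z.shape:
            raise ParameterError("MarkerTrajectory arrays must share one shape")
        _check_uniform(self.t, self.fs, "MarkerTrajectory")


@dataclass
class DeltaCoP:
    """CoP shift (mm) from pre-contact baseline to the stable state."""

    dx: float
    dy: float
    t1: float
    t2: float
    baseline_window: tuple[float, float]
    averaging_window: tuple[float, float]


@dataclass
class RegressionResult:
    """Ordinary least squares of y on x with Pearson r and its t test."""

    n: int
    slope: float
    intercept: float
    r: float
    t_value: float
    p_value: float
    flagged: bool = False
    note: str = ""


@dataclass
class BoxSummary:
    """Tukey five-number box summary (linear-interpolation quantiles)."""

    n: int
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: list = field(default_factory=list)


@dataclass
class GroupComparison:
    """Two-sided Mann-Whitney comparison with per-group box summaries."""

    n_a: int
    n_b: int
    u_statistic: float
    p_value: float
    method: str
    summary_a: BoxSummary
    summary_b: BoxSummary


def detect_contact(
    cop: CoPSeries,
    threshold_mm: float = 5.0,
    hold_s: float = 0.1,
    baseline_s: float = 1.0,
) -> float:
    """First time the CoP deviates from its pre-trial baseline.

    The baseline is the mean CoP over the first ``baseline_s`` seconds; seat
    contact t1 is the first sample whose deviation magnitude exceeds
    ``threshold_mm`` and stays above it for ``hold_s`` seconds.

    Raises
    ------
    ContactError
        If no sustained crossing exists.
    """
    if cop.t[-1] - cop.t[0] < baseline_s:
        raise ParameterError(
            f"need >= {baseline_s} s of pre-motion data for the baseline"
        )
    base = cop.t < cop.t[0] + baseline_s
    dev = np.hypot(cop.cop_x - cop.cop_x[base].mean(), cop.cop_y - cop.cop_y[base].mean())
    above = dev > threshold_mm
    hold_n = max(1, int(round(hold_s * cop.fs)))
    if above.size >= hold_n:
        run = np.convolve(above.astype(int), np.ones(hold_n, dtype=int), mode="valid")
        hits = np.flatnonzero(run == hold_n)
        if hits.size:
            return float(cop.t[hits[0]])
    raise ContactError(
        f"no CoP deviation > {threshold_mm} mm sustained for {hold_s} s"
    )


def delta_cop(cop: CoPSeries, t1: float, baseline_s: float = 1.0) -> DeltaCoP:
    """CoP shift between baseline and the stable seated state.

    The stable state t2 is 5 s after contact; the index is the mean CoP over
    the half-open window (t2, t2 + 0.5 s] minus the pre-motion baseline mean.
    Adding any constant vector to the whole stream leaves the result
    unchanged.
    """
    t2 = t1 + STABLE_DELAY_S
    if cop.t[-1] + _T_TOL < t2 + AVERAGE_WINDOW_S:
        raise AnalysisError(
            f"recording ends at {cop.t[-1]:.3f} s, before the averaging window "
            f"({t2:.3f}, {t2 + AVERAGE_WINDOW_S:.3f}] s"
        )
    base = cop.t < cop.t[0] + baseline_s
    win = (cop.t > t2 + _T_TOL) & (cop.t <= t2 + AVERAGE_WINDOW_S + _T_TOL)
    return DeltaCoP(
        dx=float(cop.cop_x[win].mean() - cop.cop_x[base].mean()),
        dy=float(cop.cop_y[win].mean() - cop.cop_y[base].mean()),
        t1=float(t1),
        t2=float(t2),
        baseline_window=(float(cop.t[0]), float(cop.t[0] + baseline_s)),
        averaging_window=(float(t2), float(t2 + AVERAGE_WINDOW_S)),
    )


def seating_velocity_vz(
    marker: MarkerTrajectory,
    prominence_mm_s: float = 5.0,
    min_separation_s: float = 0.5,
) -> float:
    """Seating velocity v_z: the third downward-velocity peak (mm/s).

    dz/dt is taken by central differences; downward (negative-velocity)
    excursions are accepted as peaks if they exceed the prominence floor and
    are separated by at least ``min_separation_s``.  The transfer's three
    phases (stand-up, lateral move, descent to the seat) produce three such
    excursions, and v_z is the magnitude of the third in time order.

    Raises
    ------
    PeakError
        If fewer than three downward peaks are found (count reported).
    """
    v = np.gradient(marker.z, marker.t)
    peaks, _ = signal.find_peaks(
        -v,
        height=prominence_mm_s,
        prominence=prominence_mm_s,
        distance=max(1, int(round(min_separation_s * marker.fs))),
    )
    if peaks.size < 3:
        raise PeakError(
            f"found {peaks.size} downward velocity peak(s), need 3 "
            f"(prominence >= {prominence_mm_s} mm/s)"
        )
    return float(-v[peaks[2]])


def t_from_correlation(r: float, n: int) -> float:
    """t statistic of a Pearson correlation: t = r sqrt(n-2) / sqrt(1-r^2)."""
    if n <= 2:
        raise ParameterError(f"need n > 2, got {n}")
    if not -1 < r < 1:
        raise ParameterError(f"need |r| < 1, got {r}")
    return r * math.sqrt(n - 2) / math.sqrt(1.0 - r * r)


def simple_regression(x, y) -> RegressionResult:
    """OLS of y on x with the correlation's t test (two-sided, n-2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ParameterError(f"need n >= 3 observations, got {n}")
    if np.ptp(x) == 0:
        raise ParameterError("explanatory variable is constant")
    if np.ptp(y) == 0:
        return RegressionResult(
            n=n, slope=0.0, intercept=float(y[0]), r=float("nan"),
            t_value=float("nan"), p_value=float("nan"),
            flagged=True, note="response variable is constant; r undefined",
        )
    fit = stats.linregress(x, y)
    r = float(fit.rvalue)
    if abs(r) >= 1.0 - 1e-12:
        return RegressionResult(
            n=n, slope=float(fit.slope), intercept=float(fit.intercept), r=r,
            t_value=float("nan"), p_value=float("nan"),
            flagged=True, note="perfect collinearity; t undefined",
        )
    t = t_from_correlation(r, n)
    p = 2.0 * float(stats.t.sf(abs(t), n - 2))
    return RegressionResult(
        n=n, slope=float(fit.slope), intercept=float(fit.intercept),
        r=r, t_value=t, p_value=p,
    )


def _u_statistic(ranks_a: np.ndarray, n_a: int) -> float:
    return float(ranks_a.sum() - n_a * (n_a + 1) / 2.0)


#: Largest number of group-label permutations enumerated on the tied path.
_MAX_ENUMERATION = 50_000


def _exact_tied_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group splits (midranks)."""
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    n_a = a.size
    n = pooled.size
    mu = n_a * b.size / 2.0
    obs = abs(_u_statistic(ranks[:n_a], n_a) - mu)
    count = 0
    total = 0
    for idx in itertools.combinations(range(n), n_a):
        u = _u_statistic(ranks[list(idx)], n_a)
        count += abs(u - mu) >= obs - 1e-9
        total += 1
    return count / total


def mann_whitney(a, b) -> GroupComparison:
    """Two-sided Mann-Whitney U comparison of two independent samples.

    Method selection, recorded in the result:

    * ``exact`` — exact null distribution (no ties, n_a * n_b <= 400);
    * ``exact-enumeration`` — full enumeration of group splits with
      midranks, used for small tied samples;
    * ``normal-approximation`` — tie- and continuity-corrected otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    u = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").statistic)
    if not has_ties and a.size * b.size <= 400:
        method = "exact"
        p = float(
            stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        )
    elif has_ties and math.comb(pooled.size, a.size) <= _MAX_ENUMERATION:
        method = "exact-enumeration"
        p = _exact_tied_p(a, b)
    else:
        method = "normal-approximation"
        p = float(
            stats.mannwhitneyu(
                a, b, alternative="two-sided", method="asymptotic", use_continuity=True
            ).pvalue
        )
    return GroupComparison(
        n_a=int(a.size),
        n_b=int(b.size),
        u_statistic=u,
        p_value=min(1.0, p),
        method=method,
        summary_a=group_summary(a),
        summary_b=group_summary(b),
    )


def group_summary(values) -> BoxSummary:
    """Tukey box summary: linear-interpolation quartiles, 1.5 IQR whiskers."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ParameterError("cannot summarise an empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_fence) & (v <= hi_fence)]
    outliers = sorted(float(x) for x in v[(v < lo_fence) | (v > hi_fence)])
    return BoxSummary(
        n=int(v.size),
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
    )


# ---------------------------------------------------------------------------
# report assembly

_METRICS = ("cog_x_bar", "cog_y_bar", "alpha", "dcop_x", "dcop_y", "v_z")


@dataclass
class TrialRecord:
    """Per-trial skill indices for the report assembler.

    Reference-device indices may be absent (None) when only the seat sensor
    was recorded.
    """

    participant: str
    group: str
    trial: int = 1
    cog_x_bar: float | None = None
    cog_y_bar: float | None = None
    alpha: float | None = None
    dcop_x: float | None = None
    dcop_y: float | None = None
    v_z: float | None = None


def _box_dict(summary: BoxSummary) -> dict:
    return {
        "n": summary.n,
        "median": summary.median,
        "q1": summary.q1,
        "q3": summary.q3,
        "whisker_low": summary.whisker_low,
        "whisker_high": summary.whisker_high,
        "outliers": summary.outliers,
    }


def _regression_dict(res: RegressionResult) -> dict:
    return {
        "n": res.n, "slope": res.slope, "intercept": res.intercept,
        "r": res.r, "t_value": res.t_value, "p_value": res.p_value,
        "flagged": res.flagged, "note": res.note,
    }


def _comparison_dict(res: GroupComparison) -> dict:
    return {
        "n_a": res.n_a, "n_b": res.n_b, "u_statistic": res.u_statistic,
        "p_value": res.p_value, "method": res.method,
        "summary_a": _box_dict(res.summary_a), "summary_b": _box_dict(res.summary_b),
    }


def skill_report(records: list[TrialRecord]) -> dict:
    """Assemble per-trial indices into the study-style report.

    Produces, as one JSON-serialisable document: per-group observation and
    participant counts, per-group box summaries of every available metric,
    regressions of each sensor index on its reference (CoG on dCoP
    componentwise, alpha on v_z), and — when exactly two groups are present —
    two-sided Mann-Whitney comparisons of v_z and alpha.
    """
    if not records:
        raise ParameterError("no trial records supplied")
    groups: dict[str, list[TrialRecord]] = {}
    for rec in records:
        groups.setdefault(rec.group, []).append(rec)

    report: dict = {"groups": {}, "totals": {}, "regressions": {}, "group_tests": {}}
    for name, recs in groups.items():
        entry: dict = {
            "n_observations": len(recs),
            "n_participants": len({r.participant for r in recs}),
            "metrics": {},
        }
        for metric in _METRICS:
            vals = [getattr(r, metric) for r in recs if getattr(r, metric) is not None]
            if vals:
                entry["metrics"][metric] = _box_dict(group_summary(vals))
        report["groups"][name] = entry
    report["totals"] = {
        "n_observations": len(records),
        "n_participants": len({r.participant for r in records}),
        "n_groups": len(groups),
    }

    for yname, xname in (("cog_x_bar", "dcop_x"), ("cog_y_bar", "dcop_y"), ("alpha", "v_z")):
        pairs = [
            (getattr(r, xname), getattr(r, yname))
            for r in records
            if getattr(r, xname) is not None and getattr(r, yname) is not None
        ]
        if len(pairs) >= 3:
            x, y = zip(*pairs)
            try:
                report["regressions"][f"{yname}_on_{xname}"] = _regression_dict(
                    simple_regression(x, y)
                )
            except ParameterError as exc:
                report["regressions"][f"{yname}_on_{xname}"] = {"error": str(exc)}

    if len(groups) == 2:
        (name_a, recs_a), (name_b, recs_b) = sorted(groups.items())
        for metric in ("v_z", "alpha", "cog_y_bar"):
            va = [getattr(r, metric) for r in recs_a if getattr(r, metric) is not None]
            vb = [getattr(r, metric) for r in recs_b if getattr(r, metric) is not None]
            if va and vb:
                report["group_tests"][metric] = {
                    "group_a": name_a,
                    "group_b": name_b,
                    **_comparison_dict(mann_whitney(va, vb)),
                }
    return report
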