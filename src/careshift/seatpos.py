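"""Seating-position analysis from the count streams.

The seating-position index is the count-weighted centroid ("CoG") of the
sensor array:

    CoG_x(t) = sum_i cnt_i(t) x_i / sum_i cnt_i(t)      (likewise for y)

so a recipient seated dead-centre gives (0, 0).  Seating is considered
complete five seconds after CoG_y reaches its maximum, and the reported
index is the summary (mean by default) of the CoG over the ten seconds
ending at completion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError, ParameterError, WindowError
from .geometry import SensorLayout

#: Seconds between the CoG_y maximum and declared seating completion.
COMPLETION_DELAY_S = 5.0
#: Length of the evaluation window ending at completion, seconds.
INDEX_WINDOW_S = 10.0

_T_TOL = 1e-6  # tolerance on timestamp uniformity / window bounds, seconds


def _check_uniform(t: np.ndarray, fs: float, what: str):
    if t.ndim != 1 or t.size < 2:
        raise ParameterError(f"{what}: need at least 2 samples")
    dt = np.diff(t)
    if np.any(dt <= 0) or np.any(np.abs(dt - 1.0 / fs) > _T_TOL):
        bad = int(np.argmax(np.abs(dt - 1.0 / fs)))
        raise ParameterError(
            f"{what}: timestamps not uniform at {fs} Hz near sample {bad + 1}"
        )


@dataclass
class CountSeries:
    """Timestamped multi-channel count matrix at a uniform rate.

    ``counts`` is (n_samples, n_channels), non-negative; ``t`` is strictly
    increasing and uniform at 1/fs.
    """

    fs: float
    t: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.t.size:
            raise ParameterError(
                f"counts must be (n_samples, n_channels) matching t; got "
                f"{self.counts.shape} vs {self.t.size} timestamps"
            )
        if np.any(self.counts < 0):
            raise ParameterError("counts must be non-negative")
        _check_uniform(self.t, self.fs, "CountSeries")

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def n_channels(self) -> int:
        return self.counts.shape[1]


@dataclass
class CoGTrajectory:
    """Per-sample weighted-centroid trajectory (mm).

    Samples with zero total count have no defined centroid: they are NaN in
    ``cog_x``/``cog_y`` and False in ``valid``.
    """

    t: np.ndarray
    cog_x: np.ndarray
    cog_y: np.ndarray
    valid: np.ndarray
    fs: float = 62.0


@dataclass
class SeatingEvent:
    """Seating-completion event derived from the CoG_y maximum."""

    t_peak_cogy: float
    completion: float
    valid: bool = True
    reason: str = ""


@dataclass
class CoGIndex:
    """Windowed seating-position index (mm)."""

    cog_x_bar: float
    cog_y_bar: float
    window: tuple[float, float]
    statistic: str = "mean"


def compute_cog(counts: CountSeries, layout: SensorLayout) -> CoGTrajectory:
    """Count-weighted centroid per sample.

    Homogeneous of degree zero in the counts (any overall rescaling leaves
    the trajectory unchanged) and equivariant under translating the layout.
    All-zero samples are marked invalid and excluded from downstream windows.
    """
    if counts.n_channels != layout.n_channels:
        raise ParameterError(
            f"count series has {counts.n_channels} channels, layout has "
            f"{layout.n_channels}"
        )
    total = counts.counts.sum(axis=1)
    valid = total > 0
    cog_x = np.full(counts.n_samples, np.nan)
    cog_y = np.full(counts.n_samples, np.nan)
    cog_x[valid] = counts.counts[valid] @ layout.x / total[valid]
    cog_y[valid] = counts.counts[valid] @ layout.y / total[valid]
    return CoGTrajectory(t=counts.t, cog_x=cog_x, cog_y=cog_y, valid=valid, fs=counts.fs)


def _moving_average(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x
    if width % 2 == 0:
        raise ParameterError(f"smoothing width must be odd, got {width}")
    kernel = np.ones(width)
    # normalise by the actual kernel overlap so edges are plain shorter means
    return np.convolve(x, kernel, mode="same") / np.convolve(
        np.ones_like(x), kernel, mode="same"
    )


def detect_completion(cog: CoGTrajectory, smooth_width: int = 1) -> SeatingEvent:
    """Locate the CoG_y maximum and declare completion 5 s later.

    Ties at the maximum resolve to the first qualifying sample.  If the
    trajectory does not extend 5 s beyond the maximum the event is returned
    invalid with a diagnostic rather than raising, so batch pipelines can
    flag the trial.
    """
    if not np.any(cog.valid):
        return SeatingEvent(np.nan, np.nan, valid=False, reason="no defined CoG samples")
    y = np.where(cog.valid, cog.cog_y, -np.inf)
    y = _moving_average(y, smooth_width) if smooth_width > 1 else y
    idx = int(np.argmax(y))  # first occurrence on exact ties
    t_peak = float(cog.t[idx])
    completion = t_peak + COMPLETION_DELAY_S
    if cog.t[-1] + _T_TOL < completion:
        return SeatingEvent(
            t_peak,
            completion,
            valid=False,
            reason=(
                f"trajectory ends at {cog.t[-1]:.3f} s, {completion - cog.t[-1]:.3f} s "
                f"before completion"
            ),
        )
    return SeatingEvent(t_peak, completion)


def cog_index(
    cog: CoGTrajectory, event: SeatingEvent, statistic: str = "mean"
) -> CoGIndex:
    """Summarise the CoG over the 10 s ending at seating completion.

    The window is [completion - 10 s, completion]; a truncated window or any
    undefined sample inside it invalidates the trial (no silent shortening or
    interpolation).
    """
    if not event.valid:
        raise AnalysisError(f"invalid seating event: {event.reason}")
    if statistic not in ("mean", "median"):
        raise ParameterError(f"statistic must be 'mean' or 'median', got {statistic!r}")
    start = event.completion - INDEX_WINDOW_S
    if cog.t[0] > start + _T_TOL:
        raise WindowError(
            f"evaluation window starts at {start:.3f} s but data begin at "
            f"{cog.t[0]:.3f} s"
        )
    mask = (cog.t >= start - _T_TOL) & (cog.t <= event.completion + _T_TOL)
    if not np.all(cog.valid[mask]):
        n_bad = int(np.sum(~cog.valid[mask]))
        raise AnalysisError(
            f"{n_bad} undefined CoG sample(s) inside the evaluation window"
        )
    reduce = np.mean if statistic == "mean" else np.median
    return CoGIndex(
        cog_x_bar=float(reduce(cog.cog_x[mask])),
        cog_y_bar=float(reduce(cog.cog_y[mask])),
        window=(start, event.completion),
        statistic=statistic,
    )
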