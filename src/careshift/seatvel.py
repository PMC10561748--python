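"""Seating-velocity analysis: the exponential velocity coefficient alpha.

The two central-region channels are averaged into one waveform; the fit
window is the one second of data (62 samples at the native 62 Hz) ending at
the maximum first difference of that waveform — i.e. the steepest part of
the count rise as the recipient descends.  The window is fitted with

    c(t) = exp(alpha * (t - beta)) + gamma

where alpha (1/s) is the growth rate of the rise and serves as the seating
velocity coefficient, beta is the time the exponential term reaches unity,
and gamma is the count offset below the rise.  A faster descent steepens
the rise and increases alpha.

The fit is nonlinear least squares in the reparameterisation
exp(alpha (t - beta)) = A exp(alpha t) with A = exp(-alpha beta) > 0, which
removes the alpha-beta coupling from the positivity constraint; beta is
reported as -ln(A)/alpha.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import FitError, ParameterError, WindowError
from .seatpos import CountSeries, _moving_average

#: Default central-region channel pair whose mean drives the fit.
DEFAULT_CHANNELS = (8, 13)
#: Upper bound on alpha, 1/s; fits at a bound are flagged, not accepted.
ALPHA_MAX = 100.0
_ALPHA_MIN = 1e-8


@dataclass
class VelocityFit:
    """Fitted (alpha, beta, gamma) with window metadata and diagnostics."""

    alpha: float | None
    beta: float | None
    gamma: float | None
    window: tuple[int, int]
    n_samples: int
    residual_ss: float
    converged: bool
    message: str = ""


def average_channels(counts: CountSeries, channels=DEFAULT_CHANNELS) -> np.ndarray:
    """Per-sample arithmetic mean of the named (1-based) channels."""
    channels = tuple(int(c) for c in channels)
    if not channels:
        raise ParameterError("need at least one channel")
    for c in channels:
        if not 1 <= c <= counts.n_channels:
            raise ParameterError(
                f"channel {c} out of range 1..{counts.n_channels}"
            )
    idx = [c - 1 for c in channels]
    return counts.counts[:, idx].mean(axis=1)


def find_fit_window(
    series: np.ndarray,
    fs: float,
    mode: str = "smoothed",
    smooth_width: int = 5,
) -> tuple[int, int]:
    """Place the 1-s fit window ending at the maximum first difference.

    Returns inclusive sample indices (start, end) with end - start + 1 =
    round(fs) — exactly 62 samples at the native 62 Hz.  The first
    difference is taken on a moving-average smoothed copy by default
    (``mode="raw"`` disables smoothing); ties resolve to the first
    occurrence.  The window indices always refer to the raw series.

    Raises
    ------
    WindowError
        If the series is too short or the maximum derivative falls within
        the first second (window would be truncated).
    """
    series = np.asarray(series, dtype=float)
    win = int(round(fs))
    if series.size <= win:
        raise WindowError(
            f"series of {series.size} samples cannot hold a {win}-sample window"
        )
    if mode not in ("raw", "smoothed"):
        raise ParameterError(f"mode must be 'raw' or 'smoothed', got {mode!r}")
    work = _moving_average(series, smooth_width) if mode == "smoothed" else series
    diff = work[1:] - work[:-1]
    end = int(np.argmax(diff)) + 1  # sample where the steepest rise lands
    start = end - win + 1
    if start < 0:
        raise WindowError(
            f"maximum derivative at sample {end} is within the first second; "
            "fit window would be truncated"
        )
    return start, end


def fit_exponential(
    series: np.ndarray,
    t: np.ndarray,
    window: tuple[int, int] = (0, -1),
    max_restarts: int = 5,
    seed: int = 0,
    alpha_max: float = ALPHA_MAX,
) -> VelocityFit:
    """Least-squares fit of c(t) = exp(alpha (t - beta)) + gamma.

    Optimises (alpha, ln A', gamma) with A' the amplitude at the window
    start, which keeps the exponential well scaled for any time origin.
    Initialisation: gamma from the window minimum, (alpha, A') from a
    log-linear regression; up to ``max_restarts`` seeded jittered restarts
    on failure.  Fits that do not converge, or converge onto the alpha
    bounds, are flagged (``converged=False``) with alpha reported but not
    accepted by :func:`velocity_coefficient`.
    """
    series = np.asarray(series, dtype=float)
    t = np.asarray(t, dtype=float)
    if series.shape != t.shape or series.ndim != 1:
        raise ParameterError("series and t must be 1-D arrays of equal length")
    if not np.all(np.isfinite(series)):
        raise ParameterError("window contains non-finite counts")
    win = (window[0], window[1] if window[1] >= 0 else series.size - 1)
    n = series.size
    if np.ptp(series) == 0:
        return VelocityFit(
            alpha=None, beta=None, gamma=float(series[0]), window=win,
            n_samples=n, residual_ss=0.0, converged=False,
            message="degenerate window of constant counts",
        )

    u = t - t[0]
    gamma0 = float(series.min())
    y = np.log(series - gamma0 + 1.0)
    slope, intercept = np.polyfit(u, y, 1)
    alpha0 = float(np.clip(slope, 1e-3, alpha_max * 0.9))
    la0 = float(np.clip(intercept, -50.0, 50.0))

    def residual(p):
        a, la, g = p
        return np.exp(np.clip(la + a * u, -700.0, 700.0)) + g - series

    lower = np.array([_ALPHA_MIN, -700.0, -np.inf])
    upper = np.array([alpha_max, 700.0, np.inf])
    rng = np.random.default_rng(seed)
    best = None
    x0 = np.array([alpha0, la0, gamma0])
    for attempt in range(max_restarts + 1):
        try:
            res = least_squares(
                residual, np.clip(x0, lower + 1e-12, upper - 1e-12),
                bounds=(lower, upper), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except Exception:  # pragma: no cover - solver-internal failures
            res = None
        if res is not None and res.success and (best is None or res.cost < best.cost):
            best = res
        if best is not None and _ALPHA_MIN * 10 < best.x[0] < alpha_max * (1.0 - 1e-9):
            break  # converged to an interior alpha; no further restarts
        jitter = rng.normal(0.0, 0.5, size=3)
        x0 = np.array([alpha0 * math.exp(jitter[0]), la0 + jitter[1],
                       gamma0 * (1.0 + 0.1 * jitter[2])])

    if best is None:
        return VelocityFit(
            alpha=None, beta=None, gamma=None, window=win, n_samples=n,
            residual_ss=float("nan"), converged=False,
            message=f"solver failed to converge after {max_restarts} restarts",
        )
    a, la, g = best.x
    at_bound = a <= _ALPHA_MIN * 10 or a >= alpha_max * (1.0 - 1e-9)
    beta = float(t[0] - la / a)
    return VelocityFit(
        alpha=float(a), beta=beta, gamma=float(g), window=win, n_samples=n,
        residual_ss=float(np.sum(best.fun ** 2)),
        converged=not at_bound,
        message="alpha at bound; fit rejected" if at_bound else "",
    )


def velocity_coefficient(
    counts: CountSeries,
    channels=DEFAULT_CHANNELS,
    mode: str = "smoothed",
    smooth_width: int = 5,
    seed: int = 0,
) -> VelocityFit:
    """Full pipeline: channel average -> fit window -> exponential fit.

    Returns the accepted :class:`VelocityFit` (``fit.alpha`` is the seating
    velocity coefficient).

    Raises
    ------
    WindowError
        If the fit window cannot be placed.
    FitError
        If the fit is flagged (non-convergence, degenerate window or a
        bound-hitting alpha); the flagged fit travels on the exception.
    """
    series = average_channels(counts, channels)
    start, end = find_fit_window(series, counts.fs, mode=mode, smooth_width=smooth_width)
    fit = fit_exponential(
        series[start : end + 1], counts.t[start : end + 1],
        window=(start, end), seed=seed,
    )
    if not fit.converged:
        raise FitError(f"velocity fit rejected: {fit.message}", fit=fit)
    return fit
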