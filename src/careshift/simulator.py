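"""Physics-based synthetic transfer trials with known ground truth.

A sit-down transfer is emulated in three phases.  Before ``approach_start``
the recipient is away from the seat and every electrode sits at its
parasitic baseline count.  During the approach the body descends toward the
seat at ``descent_velocity`` until only the clothing layer separates body
and electrodes; after contact the clothing compresses exponentially toward
the minimum gap, so the counts rise rapidly and then plateau.  The buttock
footprint finally settles at ``seat_offset`` — during the approach it is
displaced by ``settle_overshoot`` (the body lands slightly forward and
slides back), which is what gives the CoG_y trace its interior maximum.

Alongside the 62 Hz count streams the simulator produces the two reference
streams used for validation: a 600 Hz force-plate CoP trace whose designed
post-seating shift is proportional to the seat offset, and a 120 Hz
head-marker height trace containing exactly three downward-velocity
excursions whose third (the descent to the seat) peaks at a configurable
v_z.  Every trial carries its ground truth so analyses can be checked by
round trip.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import special

from .errors import ParameterError
from .geometry import CapacitanceParams, SensorLayout, capacitance, default_layout
from .seatpos import CountSeries
from .validate import CoPSeries, MarkerTrajectory

COUNT_FS_HZ = 62.0
COP_FS_HZ = 600.0
MARKER_FS_HZ = 120.0


@dataclass(frozen=True)
class MotionProfile:
    """Parameterised seating motion.

    Lengths in mm, times in s, velocities in mm/s.  ``trial_duration=None``
    sizes the trial automatically to contact + 8 s, enough for the
    completion rule (CoG_y peak + 5 s) and the force-plate stable state.
    """

    seat_offset: tuple[float, float] = (0.0, 0.0)
    descent_velocity: float = 50.0
    approach_start: float = 5.0
    footprint: tuple[float, float] = (300.0, 300.0)
    start_height: float = 200.0
    clothing_thickness: float = 5.0
    compression_tau: float = 0.3
    trial_duration: float | None = None
    lateral_drift: float = 0.0
    settle_overshoot: tuple[float, float] = (0.0, 15.0)
    settle_tau: float = 0.6
    approach_entry_y: float = 300.0
    sweep_height: float = 100.0
    edge_softness: float = 40.0
    head_peak_velocity: float | None = None

    def __post_init__(self):
        if not self.descent_velocity > 0:
            raise ParameterError("descent_velocity must be > 0")
        if not 0 < self.clothing_thickness < self.start_height:
            raise ParameterError(
                "need 0 < clothing_thickness < start_height "
                f"(got {self.clothing_thickness}, {self.start_height})"
            )
        if self.footprint[0] <= 0 or self.footprint[1] <= 0:
            raise ParameterError("footprint dimensions must be > 0")
        if not self.compression_tau > 0 or not self.settle_tau > 0:
            raise ParameterError("time constants must be > 0")
        if not self.clothing_thickness < self.sweep_height < self.start_height:
            raise ParameterError(
                "need clothing_thickness < sweep_height < start_height "
                f"(got {self.sweep_height})"
            )
        if self.approach_start < 0:
            raise ParameterError("approach_start must be >= 0")

    @property
    def contact_time(self) -> float:
        """Time the gap first equals the clothing thickness (seat contact)."""
        return self.approach_start + (
            self.start_height - self.clothing_thickness
        ) / self.descent_velocity

    @property
    def duration(self) -> float:
        return (
            self.trial_duration
            if self.trial_duration is not None
            else self.contact_time + 8.0
        )

    @property
    def vz(self) -> float:
        """Peak downward head velocity of the seating descent."""
        return (
            self.head_peak_velocity
            if self.head_peak_velocity is not None
            else self.descent_velocity
        )


@dataclass(frozen=True)
class TransductionParams:
    """Affine capacitance-to-count transduction with noise and saturation.

    The measurement chain counts oscillator pulses whose rate grows with
    capacitance; it is modelled as the simplest monotone map: counts =
    clip(round(baseline + gain * C_body + noise), 0, saturation), where
    ``baseline_count`` is the parasitic-capacitance response of an electrode
    in open space.
    """

    gain_counts_per_f: float = 1e11
    baseline_count: float = 200.0
    saturation_count: float = 20000.0
    noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if not self.saturation_count > self.baseline_count >= 0:
            raise ParameterError("need saturation_count > baseline_count >= 0")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if not self.gain_counts_per_f > 0:
            raise ParameterError("gain must be > 0")


@dataclass(frozen=True)
class TrialTruth:
    """Ground truth echoed from the motion profile."""

    seat_offset: tuple[float, float]
    descent_velocity: float
    contact_time: float
    head_peak_velocity: float
    designed_delta_cop: tuple[float, float]


@dataclass
class TrialRecording:
    """One complete synthetic trial: all three streams plus the truth."""

    counts: CountSeries
    cop: CoPSeries
    marker: MarkerTrajectory
    truth: TrialTruth


def _axis_coverage(a, b, lo, hi, softness: float):
    """Mean occupancy of interval [a, b] under a footprint edge-softened
    indicator of [lo, hi]; reduces to fractional overlap at softness 0."""
    if softness <= 0:
        return np.clip(np.minimum(b, hi) - np.maximum(a, lo), 0.0, None) / (b - a)
    k = softness * math.sqrt(2.0)

    def antideriv(u, c):
        w = (u - c) / k
        return (u - c) * special.erf(w) + k / math.sqrt(math.pi) * np.exp(-(w ** 2))

    integral = 0.5 * (
        (antideriv(b, lo) - antideriv(a, lo)) - (antideriv(b, hi) - antideriv(a, hi))
    )
    return np.clip(integral / (b - a), 0.0, 1.0)


def footprint_weights(
    layout: SensorLayout,
    center: tuple[float, float],
    footprint: tuple[float, float],
    edge_softness: float = 0.0,
) -> np.ndarray:
    """Per-channel coverage weight in [0, 1] of the buttock footprint.

    With the default hard edge this is the fractional area overlap of the
    footprint rectangle with each electrode square; ``edge_softness`` (mm)
    Gaussian-blurs the footprint boundary, modelling the tapering pressure
    at the body edge.
    """
    if footprint[0] <= 0 or footprint[1] <= 0:
        raise ParameterError("footprint dimensions must be > 0")
    half = layout.electrode_side_mm / 2.0
    wx = _axis_coverage(
        layout.x - half, layout.x + half,
        center[0] - footprint[0] / 2.0, center[0] + footprint[0] / 2.0,
        edge_softness,
    )
    wy = _axis_coverage(
        layout.y - half, layout.y + half,
        center[1] - footprint[1] / 2.0, center[1] + footprint[1] / 2.0,
        edge_softness,
    )
    return np.asarray(wx * wy)


def gap_profile(t, profile: MotionProfile, l_min: float = 0.5):
    """Body-electrode gap L(t) in mm.

    Constant at ``start_height`` before the approach, linear descent at
    ``descent_velocity`` until the gap equals the clothing thickness, then
    first-order exponential compression toward ``l_min``.  Continuous,
    non-increasing after the approach starts, bounded below by ``l_min``.
    """
    t = np.asarray(t, dtype=float)
    t1 = profile.contact_time
    linear = profile.start_height - profile.descent_velocity * (t - profile.approach_start)
    compressed = l_min + (profile.clothing_thickness - l_min) * np.exp(
        -np.clip(t - t1, 0.0, None) / profile.compression_tau
    )
    out = np.where(
        t < profile.approach_start,
        profile.start_height,
        np.where(t < t1, linear, compressed),
    )
    out = np.maximum(out, l_min)
    return float(out) if out.ndim == 0 else out


def _footprint_center(t: np.ndarray, profile: MotionProfile) -> np.ndarray:
    """(n, 2) footprint centre along the seating path.

    The buttocks sweep in over the front edge of the seat: during the
    approach the centre moves from ``approach_entry_y`` to the contact
    point (final offset plus overshoot) in step with the descent, and after
    contact the overshoot decays with ``settle_tau`` as the recipient
    settles back into the final position.  This is what gives the CoG_y
    trace its characteristic rise-then-settle shape with an interior
    maximum.
    """
    t1 = profile.contact_time
    decay = np.where(t < t1, 1.0, np.exp(-np.clip(t - t1, 0.0, None) / profile.settle_tau))
    # the forward sweep finishes while the body is still at sweep_height,
    # after which the final descent is vertical
    t_sweep_end = profile.approach_start + (
        profile.start_height - profile.sweep_height
    ) / profile.descent_velocity
    progress = np.clip(
        (t - profile.approach_start) / (t_sweep_end - profile.approach_start), 0.0, 1.0
    )
    y_contact = profile.seat_offset[1] + profile.settle_overshoot[1]
    cy = np.where(
        t < t1,
        profile.approach_entry_y + (y_contact - profile.approach_entry_y) * progress,
        profile.seat_offset[1] + profile.settle_overshoot[1] * decay,
    )
    cx = (
        profile.seat_offset[0]
        + profile.settle_overshoot[0] * decay
        + profile.lateral_drift * np.minimum(t - t1, 0.0)
    )
    return np.column_stack([cx, cy])


def simulate_counts(
    profile: MotionProfile,
    layout: SensorLayout | None = None,
    cap_params: CapacitanceParams | None = None,
    trans_params: TransductionParams | None = None,
) -> CountSeries:
    """Synthesise the 62 Hz 20-channel count stream for one trial.

    Per channel, counts(t) = clip(round(baseline + gain * w_i(t) * C(L(t))
    + noise), 0, saturation): covered channels rise monotonically during the
    descent (before noise) and plateau once compression settles, while
    uncovered channels stay at the parasitic baseline.
    """
    layout = layout if layout is not None else default_layout()
    cap_params = cap_params if cap_params is not None else CapacitanceParams()
    trans_params = trans_params if trans_params is not None else TransductionParams()
    if profile.duration < profile.contact_time + 6.0:
        raise ParameterError(
            f"trial_duration {profile.duration:.2f} s too short: need >= "
            f"{profile.contact_time + 6.0:.2f} s to contain the completion window"
        )
    n = int(math.floor(profile.duration * COUNT_FS_HZ)) + 1
    t = np.arange(n) / COUNT_FS_HZ
    L = gap_profile(t, profile, l_min=cap_params.l_min_mm)
    centers = _footprint_center(t, profile)

    half = layout.electrode_side_mm / 2.0
    hw, hd = profile.footprint[0] / 2.0, profile.footprint[1] / 2.0
    wx = _axis_coverage(
        layout.x[None, :] - half, layout.x[None, :] + half,
        centers[:, 0:1] - hw, centers[:, 0:1] + hw, profile.edge_softness,
    )
    wy = _axis_coverage(
        layout.y[None, :] - half, layout.y[None, :] + half,
        centers[:, 1:2] - hd, centers[:, 1:2] + hd, profile.edge_softness,
    )
    weights = wx * wy

    body = trans_params.gain_counts_per_f * weights * capacitance(L, cap_params)[:, None]
    det = trans_params.baseline_count + body
    rng = np.random.default_rng(trans_params.seed)
    noise = rng.normal(0.0, trans_params.noise_sd, det.shape) if trans_params.noise_sd else 0.0
    counts = np.clip(np.rint(det + noise), 0.0, trans_params.saturation_count)
    return CountSeries(fs=COUNT_FS_HZ, t=t, counts=counts)


def simulate_force_plate(
    profile: MotionProfile,
    cop_gain: float = 1.0,
    noise_sd: float = 0.3,
    damping_rate: float = 2.0,
    osc_freq_hz: float = 1.2,
    seed: int | None = 0,
) -> CoPSeries:
    """Synthesise the 600 Hz force-plate CoP stream.

    Baseline (0, 0) before contact; after contact the CoP relaxes with a
    damped oscillation toward ``cop_gain * seat_offset`` and is stable well
    before contact + 5 s, so the extracted dCoP equals the designed value up
    to noise.
    """
    n = int(math.floor(profile.duration * COP_FS_HZ)) + 1
    t = np.arange(n) / COP_FS_HZ
    dt = np.clip(t - profile.contact_time, 0.0, None)
    step = np.where(
        t < profile.contact_time,
        0.0,
        1.0 - np.exp(-damping_rate * dt) * np.cos(2.0 * math.pi * osc_freq_hz * dt),
    )
    delta = designed_delta_cop(profile, cop_gain)
    rng = np.random.default_rng(seed)
    noise = (
        rng.normal(0.0, noise_sd, (n, 2)) if noise_sd else np.zeros((n, 2))
    )
    return CoPSeries(
        fs=COP_FS_HZ,
        t=t,
        cop_x=delta[0] * step + noise[:, 0],
        cop_y=delta[1] * step + noise[:, 1],
    )


def designed_delta_cop(profile: MotionProfile, cop_gain: float = 1.0) -> tuple[float, float]:
    """The dCoP the force-plate stream is designed to settle at."""
    return (cop_gain * profile.seat_offset[0], cop_gain * profile.seat_offset[1])


def simulate_marker(
    profile: MotionProfile,
    noise_sd: float = 0.0,
    start_z: float = 1600.0,
    seed: int | None = 0,
) -> MarkerTrajectory:
    """Synthesise the 120 Hz head-marker height stream.

    z(t) is the analytic integral of three Gaussian downward-velocity
    pulses: two fixed-size excursions (the stand-up adjustment and the
    lateral move) followed by the seating descent centred at contact,
    whose peak downward velocity is exactly ``profile.vz``.
    """
    n = int(math.floor(profile.duration * MARKER_FS_HZ)) + 1
    t = np.arange(n) / MARKER_FS_HZ
    t1 = profile.contact_time
    vz = profile.vz
    # the stand-up adjustment and lateral move have their own typical
    # speeds; only the third excursion tracks the seating descent
    pulses = (
        (max(1.0, t1 - 4.0), 20.0, 0.30),
        (max(2.0, t1 - 2.0), 30.0, 0.30),
        (t1, vz, 0.40),
    )
    z = np.full(n, start_z, dtype=float)
    for center, amp, sigma in pulses:
        k = sigma * math.sqrt(2.0)
        # integral of amp * exp(-(t-c)^2 / (2 sigma^2)) from 0 to t
        z -= (
            amp
            * sigma
            * math.sqrt(math.pi / 2.0)
            * (special.erf((t - center) / k) - special.erf((0.0 - center) / k))
        )
    if noise_sd:
        z = z + np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return MarkerTrajectory(fs=MARKER_FS_HZ, t=t, z=z)


def simulate_trial(
    profile: MotionProfile | None = None,
    layout: SensorLayout | None = None,
    cap_params: CapacitanceParams | None = None,
    trans_params: TransductionParams | None = None,
    seed: int = 0,
    cop_noise_sd: float = 0.3,
    marker_noise_sd: float = 0.0,
    cop_gain: float = 1.0,
) -> TrialRecording:
    """Generate one complete trial; all randomness flows from ``seed``.

    Identical arguments give bit-identical recordings.
    """
    profile = profile if profile is not None else MotionProfile()
    trans_params = trans_params if trans_params is not None else TransductionParams()
    child = np.random.default_rng(seed).integers(0, 2**31 - 1, size=3)
    trans_params = replace(trans_params, seed=int(child[0]))
    counts = simulate_counts(profile, layout, cap_params, trans_params)
    cop = simulate_force_plate(
        profile, cop_gain=cop_gain, noise_sd=cop_noise_sd, seed=int(child[1])
    )
    marker = simulate_marker(profile, noise_sd=marker_noise_sd, seed=int(child[2]))
    truth = TrialTruth(
        seat_offset=profile.seat_offset,
        descent_velocity=profile.descent_velocity,
        contact_time=profile.contact_time,
        head_peak_velocity=profile.vz,
        designed_delta_cop=designed_delta_cop(profile, cop_gain),
    )
    return TrialRecording(counts=counts, cop=cop, marker=marker, truth=truth)
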