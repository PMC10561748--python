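"""Sensor-array geometry and the parallel-plate proximity model.

The seat sensor is a grid of square conductive-fabric electrodes embroidered
onto the wheelchair seat.  All coordinates are millimetres in the seat frame:
origin at the seat centre, x positive to the right, y positive forward
(z would be up).  Channels are numbered row-major from the rear-left corner,
1-based; the numbering is stored with the layout so any alternative map from
channel index to grid cell remains recoverable through configuration.

Each electrode forms a parallel-plate capacitor with the approaching body:

    C = eps0 * kappa * S / L

with ``eps0`` the permittivity constant (8.854e-12 F/mm as used by the
measurement chain), ``kappa`` the relative permittivity of the clothing
layer, ``S`` the electrode area (mm^2) and ``L`` the body-electrode gap (mm).
As the body descends, L shrinks and C grows; after contact the clothing is
compressed and C keeps rising toward its pressure-dependent plateau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ParameterError

#: Permittivity constant of the capacitance model, F/mm.
EPSILON0_F_PER_MM = 8.854e-12


@dataclass(frozen=True)
class CapacitanceParams:
    """Parameters of the parallel-plate proximity model.

    Parameters
    ----------
    kappa : relative permittivity of the clothing layer (>= 1).
    area_mm2 : electrode area S in mm^2 (20 mm squares -> 400).
    l_min_mm : smallest admissible body-electrode gap; callers clamp L here
        once the clothing is fully compressed.
    epsilon0 : permittivity constant in F/mm.
    """

    kappa: float = 3.0
    area_mm2: float = 400.0
    l_min_mm: float = 2.5
    epsilon0: float = EPSILON0_F_PER_MM

    def __post_init__(self):
        if not self.kappa >= 1:
            raise ParameterError(f"kappa must be >= 1, got {self.kappa}")
        if not self.area_mm2 > 0:
            raise ParameterError(f"electrode area must be > 0, got {self.area_mm2}")
        if not self.l_min_mm > 0:
            raise ParameterError(f"l_min must be > 0, got {self.l_min_mm}")


@dataclass(frozen=True)
class SensorLayout:
    """Electrode grid geometry with per-channel seat coordinates.

    ``positions[i]`` is the centre (x, y) of channel ``i + 1`` (channels are
    1-based, row-major from the rear-left corner: row 1 is the rearmost row,
    column 1 the leftmost column).
    """

    rows: int
    cols: int
    pitch_mm: float
    electrode_side_mm: float
    positions: np.ndarray = field(repr=False)

    @property
    def n_channels(self) -> int:
        return self.rows * self.cols

    @property
    def x(self) -> np.ndarray:
        """Per-channel x coordinates (mm)."""
        return self.positions[:, 0]

    @property
    def y(self) -> np.ndarray:
        """Per-channel y coordinates (mm)."""
        return self.positions[:, 1]

    @property
    def extent(self) -> tuple[float, float]:
        """(width, depth) of the populated grid including electrode bodies."""
        return (
            (self.cols - 1) * self.pitch_mm + self.electrode_side_mm,
            (self.rows - 1) * self.pitch_mm + self.electrode_side_mm,
        )

    def channel_position(self, channel: int) -> tuple[float, float]:
        """Centre of a 1-based channel index."""
        if not 1 <= channel <= self.n_channels:
            raise ParameterError(
                f"channel {channel} out of range 1..{self.n_channels}"
            )
        x, y = self.positions[channel - 1]
        return float(x), float(y)

    def translated(self, dx: float, dy: float) -> "SensorLayout":
        """Layout with every electrode shifted by (dx, dy) mm."""
        return SensorLayout(
            rows=self.rows,
            cols=self.cols,
            pitch_mm=self.pitch_mm,
            electrode_side_mm=self.electrode_side_mm,
            positions=self.positions + np.array([dx, dy]),
        )


def build_layout(
    rows: int,
    cols: int,
    pitch: float = 80.0,
    electrode_side: float = 20.0,
) -> SensorLayout:
    """Build a centred rows x cols electrode grid.

    The grid is centred on the seat origin (the mean of all electrode
    positions is exactly (0, 0)); channel numbering is row-major from the
    rear-left corner, 1-based.  The default 5 x 4 grid at 80 mm pitch spans
    260 mm x 340 mm of electrode centres plus the 20 mm electrode bodies.

    Raises
    ------
    ParameterError
        On non-positive dimensions or pitch smaller than the electrode side.
    """
    if rows < 1 or cols < 1:
        raise ParameterError(f"rows and cols must be >= 1, got {rows}x{cols}")
    if not electrode_side > 0:
        raise ParameterError(f"electrode_side must be > 0, got {electrode_side}")
    if pitch < electrode_side:
        raise ParameterError(
            f"pitch ({pitch}) must be >= electrode_side ({electrode_side})"
        )
    xs = (np.arange(cols) - (cols - 1) / 2.0) * pitch
    ys = (np.arange(rows) - (rows - 1) / 2.0) * pitch
    # row-major: iterate columns within each row, rear row (smallest y) first
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    positions = np.column_stack([gx.ravel(), gy.ravel()])
    return SensorLayout(
        rows=rows,
        cols=cols,
        pitch_mm=float(pitch),
        electrode_side_mm=float(electrode_side),
        positions=positions,
    )


def default_layout() -> SensorLayout:
    """The default 20-channel seat array (5 rows x 4 columns, 80 mm pitch)."""
    return build_layout(rows=5, cols=4, pitch=80.0, electrode_side=20.0)


def capacitance(L, params: CapacitanceParams):
    """Parallel-plate capacitance (F) at gap ``L`` (mm).

    Accepts a scalar or array gap; strictly decreasing in L, linear in both
    the electrode area and the clothing permittivity.

    Raises
    ------
    DomainError
        If any gap is <= 0 (callers clamp to ``params.l_min_mm`` instead).
    """
    L = np.asarray(L, dtype=float)
    if np.any(L <= 0):
        raise DomainError("gap L must be > 0")
    out = params.epsilon0 * params.kappa * params.area_mm2 / L
    return float(out) if out.ndim == 0 else out
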