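"""Root phenotypes from traced polylines, pixel skeletons, and tip-angle time series.

Two families of traits are computed here:

* **Long-term root angle** — the net angle of the vector from the
  root–hypocotyl junction to the root tip, measured against the downward
  vertical (``avg_abs_angle``), together with its signed variant and a sign
  test for growth handedness.
* **Short-term gravitropism** — the kinetics of the root tip angle after a
  90° plate rotation, sampled at 34 timepoints spaced 3.75 min apart.  The
  per-timepoint rate of change of tip angle is the *swing rate*; roots are
  classed as rotating "through" or "away from" the gravity vector by the
  sign of their starting angle.

Coordinate conventions (fixed throughout the package):

* Trace points are ``(x, y)`` pixels with **y increasing downward** (image
  rows).  The downward vertical is ``(0, +1)``.
* Skeleton pixels are ``(row, col)`` with rows increasing downward.
* Tip angles use 0° = horizontal to the right, positive clockwise, so a tip
  bending downward moves toward +90°.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

#: Sampling interval of the rotation time course, minutes.
DT_MINUTES = 3.75
#: Number of images recorded per rotated plate.
N_TIMEPOINTS = 34

#: Per-step directional weights for the direction index.
DIRECTION_WEIGHTS = {
    "down": 0,
    "diagonal-down": 1,
    "horizontal": 2,
    "diagonal-up": 3,
    "up": 4,
}


class DegenerateGeometryError(ValueError):
    """Raised when an angle is requested for coincident endpoints."""


@dataclass
class RootTrace:
    """An ordered polyline from the root–hypocotyl junction to the tip.

    ``points`` is an (n, 2) array of (x, y) pixel coordinates, y downward.
    """

    points: np.ndarray
    scale: float = 1.0  # mm per pixel
    genotype: str | None = None
    plate_id: str | None = None
    germ_age: int | None = None
    plate_date: str | None = None
    collide: bool = False
    along: bool = False

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise ValueError("trace points must be an (n, 2) array of (x, y)")
        if len(self.points) < 2:
            raise ValueError("a root trace needs at least 2 points")

    @property
    def junction(self) -> np.ndarray:
        return self.points[0]

    @property
    def tip(self) -> np.ndarray:
        return self.points[-1]


@dataclass
class TipAngleSeries:
    """Tip angle at fixed 3.75-min intervals after a 90° rotation."""

    angles: np.ndarray
    dt: float = DT_MINUTES
    root_id: str | None = None
    genotype: str | None = None
    rotation_class: str = "unknown"

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        if self.angles.ndim != 1 or len(self.angles) != N_TIMEPOINTS:
            raise ValueError(f"a tip-angle series has exactly {N_TIMEPOINTS} timepoints")
        if not np.all(np.isfinite(self.angles)):
            raise ValueError("tip angles must be finite")


@dataclass
class SwingRateSeries:
    """Rate of change of tip angle, degrees per minute, labelled T1..T33."""

    rates: np.ndarray
    labels: tuple[str, ...] = field(default=())
    root_id: str | None = None
    genotype: str | None = None

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if not self.labels:
            self.labels = tuple(f"T{k}" for k in range(1, len(self.rates) + 1))
        if len(self.labels) != len(self.rates):
            raise ValueError("one label per rate")


@dataclass
class Skeleton:
    """Ordered 8-connected pixel path from junction toward tip, (row, col)."""

    pixels: np.ndarray

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        if self.pixels.ndim != 2 or self.pixels.shape[1] != 2:
            raise ValueError("skeleton pixels must be an (n, 2) array of (row, col)")
        if len(self.pixels) >= 2:
            steps = np.diff(self.pixels, axis=0)
            if np.any(np.abs(steps) > 1):
                raise ValueError("skeleton must be 8-connected (steps of at most 1)")
            if np.any(np.all(steps == 0, axis=1)):
                raise ValueError("skeleton must not repeat a pixel")


def _angle_to_down(vec: np.ndarray) -> float:
    """Angle in degrees between ``vec`` (in a y-downward frame) and straight down."""
    norm = float(np.hypot(vec[0], vec[1]))
    if norm == 0.0:
        raise DegenerateGeometryError("junction and tip coincide; angle undefined")
    cos = np.clip(vec[1] / norm, -1.0, 1.0)
    return float(np.degrees(np.arccos(cos)))


def avg_abs_angle(trace: RootTrace) -> float:
    """Absolute net angle (degrees, in [0, 180]) between the junction→tip vector
    and the downward vertical.

    This is the long-term root-angle trait: a perfectly plumb root scores 0°,
    a horizontally growing root 90°.
    """
    return _angle_to_down(trace.tip - trace.junction)


def signed_net_angle(trace: RootTrace) -> float:
    """Like :func:`avg_abs_angle` but signed: + for rightward deviation
    (tip x > junction x), − for leftward.  A tip directly below (or above)
    the junction is reported as +."""
    mag = avg_abs_angle(trace)
    dx = trace.tip[0] - trace.junction[0]
    return mag if dx >= 0 else -mag


def handedness_test(signed_angles: Sequence[float]) -> float:
    """Two-sided exact binomial sign test of P(rightward) = 0.5.

    Zero angles carry no handedness information and are dropped.  Returns the
    p-value; under no left/right preference it is uniform-ish, and a perfectly
    balanced sample gives 1.0.
    """
    signs = np.sign(np.asarray(signed_angles, dtype=float))
    signs = signs[signs != 0]
    if len(signs) == 0:
        raise ValueError("handedness test needs at least one nonzero angle")
    k = int(np.sum(signs > 0))
    return float(stats.binomtest(k, len(signs), 0.5, alternative="two-sided").pvalue)


def swing_rate(series: TipAngleSeries) -> SwingRateSeries:
    """First differences of tip angle divided by the sampling interval
    (degrees per minute); rate at Tk = (angle_k − angle_{k−1}) / dt."""
    rates = np.diff(series.angles) / series.dt
    return SwingRateSeries(rates, root_id=series.root_id, genotype=series.genotype)


def net_tip_angle_change(series: TipAngleSeries) -> float:
    """Total tip-angle change over the time course, degrees.

    Computed as the swing rate integrated over time (Σ rate·dt), which equals
    the difference between the final and initial angle.
    """
    r = swing_rate(series)
    return float(np.sum(r.rates) * series.dt)


def deviation_from_vertical(tip_angle: float) -> float:
    """Convert a tip angle (0° = horizontal right, + clockwise/downward) to
    the deviation from the downward vertical: 90° − angle."""
    return 90.0 - float(tip_angle)


def classify_rotation(series: TipAngleSeries) -> str:
    """Class a rotated root by its starting angle: initial angle > 0 means the
    plate rotation carried the tip *through* the gravity vector (below
    horizontal); < 0 means it rotated *away* (above horizontal).  An exact 0
    is assigned to "through"."""
    return "through" if series.angles[0] >= 0 else "away"


def _step_weight(drow: int, dcol: int) -> int:
    if drow > 0:
        return 0 if dcol == 0 else 1
    if drow == 0:
        return 2
    return 4 if dcol == 0 else 3


def direction_index(skel: Skeleton) -> float:
    """Mean per-step directional weight along a root skeleton.

    Each pixel-to-pixel step is weighted by its direction relative to gravity
    (straight down 0, diagonal down 1, horizontal 2, diagonal up 3, straight
    up 4); the sum is divided by the number of steps.  A root growing
    perfectly plumb scores 0; one growing straight upward scores 4.
    """
    if len(skel.pixels) < 2:
        raise ValueError("direction index needs at least 2 pixels")
    steps = np.diff(skel.pixels, axis=0)
    weights = [_step_weight(int(dr), int(dc)) for dr, dc in steps]
    return float(np.mean(weights))


def root_angle_vs_vertical(skel: Skeleton) -> float:
    """Angle (degrees, [0, 180]) between the first→last skeleton pixel vector
    and the downward vertical (the assumed gravity vector)."""
    if len(skel.pixels) < 2:
        raise ValueError("root angle needs at least 2 pixels")
    first, last = skel.pixels[0], skel.pixels[-1]
    drow = float(last[0] - first[0])
    dcol = float(last[1] - first[1])
    # (col, row) maps onto the (x, y)-downward frame used for traces
    return _angle_to_down(np.array([dcol, drow]))


def growth_rate(lengths: Sequence[float], dt: float = DT_MINUTES) -> np.ndarray:
    """Root growth rate series (mm/min) from per-timepoint root lengths (mm)."""
    lengths = np.asarray(lengths, dtype=float)
    if len(lengths) < 2:
        raise ValueError("growth rate needs at least 2 length measurements")
    return np.diff(lengths) / dt


# ---------------------------------------------------------------------------
# tabular I/O

def traces_from_frame(df: pd.DataFrame) -> list[RootTrace]:
    """Build traces from a long table with columns root_id, x, y (ordered),
    plus optional per-root metadata columns (genotype, collide, ...)."""
    meta_cols = {"genotype", "plate_id", "germ_age", "plate_date", "collide", "along"}
    traces = []
    for root_id, grp in df.groupby("root_id", sort=False):
        kwargs = {c: grp[c].iloc[0] for c in meta_cols & set(grp.columns)}
        traces.append(RootTrace(grp[["x", "y"]].to_numpy(), **kwargs))
    return traces


def tip_angle_table(series_list: Sequence[TipAngleSeries]) -> pd.DataFrame:
    """Wide table of tip-angle series: one row per root, columns T0..T33."""
    rows = []
    for s in series_list:
        row = {"root_id": s.root_id, "genotype": s.genotype,
               "rotation_class": s.rotation_class}
        row.update({f"T{k}": a for k, a in enumerate(s.angles)})
        rows.append(row)
    return pd.DataFrame(rows)


def swing_rate_table(series_list: Sequence[TipAngleSeries]) -> pd.DataFrame:
    """Wide table of swing rates (deg/min): one row per root, columns T1..T33."""
    rows = []
    for s in series_list:
        r = swing_rate(s)
        row = {"root_id": s.root_id, "genotype": s.genotype}
        row.update(dict(zip(r.labels, r.rates)))
        rows.append(row)
    return pd.DataFrame(rows)
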