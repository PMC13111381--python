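"""Stride segmentation, plate-geometry frame selection, 20/60/20 normalization.

The supporting-leg period is bounded by four blade events and split into
three phases:

* contact        — analyzed blade on .. one frame before opposite blade off
* single_support — opposite blade off .. one frame before opposite blade on
* push_off       — opposite blade on .. one frame before analyzed blade off

For cross-trial comparison each phase is mapped onto a fixed share of a
0-100% grid (contact 0-20%, single support 20-80%, push-off 80-100%) by
per-phase cubic-spline resampling at 1% steps, so strides of different
absolute durations line up point-for-point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import EventOrderError, GeometryError, InvalidParameterError

PHASES = ("contact", "single_support", "push_off")
#: percent band occupied by each phase on the normalized grid
PHASE_BANDS = {"contact": (0.0, 20.0), "single_support": (20.0, 80.0), "push_off": (80.0, 100.0)}
GRID = np.arange(101, dtype=float)  # 0..100 % at 1% steps


@dataclass
class BladeEvents:
    """Blade on/off times (s) bounding the supporting-leg period."""

    analyzed_on: float
    opposite_off: float
    opposite_on: float
    analyzed_off: float

    def __post_init__(self) -> None:
        order = (
            ("analyzed_on", "opposite_off", self.analyzed_on < self.opposite_off),
            ("opposite_off", "opposite_on", self.opposite_off <= self.opposite_on),
            ("opposite_on", "analyzed_off", self.opposite_on < self.analyzed_off),
        )
        for a, b, ok in order:
            if not ok:
                raise EventOrderError(f"event order violated: {a} !< {b}")

    @property
    def duration(self) -> float:
        return self.analyzed_off - self.analyzed_on


@dataclass
class PhaseSegmentation:
    """Per-frame phase label plus the defining events and time base."""

    labels: np.ndarray  # (n,) str: contact|single_support|push_off|outside
    events: BladeEvents
    time: np.ndarray  # (n,) s

    def frames_in(self, phase: str) -> np.ndarray:
        return np.nonzero(self.labels == phase)[0]


@dataclass
class NormalizedSeries:
    """Series resampled to the 101-point percent grid with a validity mask."""

    values: np.ndarray  # (101,)
    valid: np.ndarray  # (101,) bool
    n: np.ndarray | None = None  # per-point trial count when aggregated


def segment_phases(events: BladeEvents, time: np.ndarray) -> PhaseSegmentation:
    """Label each frame with its stride phase (half-open intervals).

    The half-open convention implements the "one frame before" boundary
    rule: a frame exactly at an off/on event belongs to the following phase.
    """
    time = np.asarray(time, dtype=float)
    labels = np.full(time.shape, "outside", dtype=object)
    labels[(time >= events.analyzed_on) & (time < events.opposite_off)] = "contact"
    labels[(time >= events.opposite_off) & (time < events.opposite_on)] = "single_support"
    labels[(time >= events.opposite_on) & (time < events.analyzed_off)] = "push_off"
    return PhaseSegmentation(labels=np.asarray(labels), events=events, time=time)


def _inside_rect(xy: np.ndarray, rect: tuple[float, float, float, float]) -> np.ndarray:
    xmin, xmax, ymin, ymax = rect
    return (
        (xy[..., 0] >= xmin) & (xy[..., 0] <= xmax)
        & (xy[..., 1] >= ymin) & (xy[..., 1] <= ymax)
    )


def analyzable_mask(
    analyzed_blade_xy: np.ndarray,
    opposite_blade_xy: np.ndarray,
    opposite_airborne: np.ndarray,
    plate: tuple[float, float, float, float] = (0.0, 0.6, 0.0, 5.4),
) -> np.ndarray:
    """Select frames whose force-plate signal belongs to the analyzed blade only.

    A frame is analyzable iff both analyzed-blade endpoints lie on the plate
    (closed rectangle ``(xmin, xmax, ymin, ymax)`` in course coordinates) and
    the opposite blade contributes no force to it — either airborne or fully
    grounded off the plate. Frames with the analyzed blade straddling a
    plate edge, or with both blades on the plate, are rejected.

    Blade endpoint arrays have shape (n, 2, 2): frame x endpoint x (x, y).
    """
    xmin, xmax, ymin, ymax = plate
    if not (xmax > xmin and ymax > ymin):
        raise GeometryError("plate rectangle is degenerate")
    analyzed = np.asarray(analyzed_blade_xy, dtype=float)
    opposite = np.asarray(opposite_blade_xy, dtype=float)
    airborne = np.asarray(opposite_airborne, dtype=bool)

    analyzed_on_plate = _inside_rect(analyzed, plate).all(axis=1)
    opposite_inside = _inside_rect(opposite, plate)
    opposite_clear = airborne | (~opposite_inside).all(axis=1)
    return analyzed_on_plate & opposite_clear


def phase_normalize(
    series: np.ndarray,
    seg: PhaseSegmentation,
    mask: np.ndarray | None = None,
    gap_pct: float = 2.0,
) -> NormalizedSeries:
    """Resample a per-frame series onto the 20/60/20 percent grid.

    Each phase is fitted separately (phase boundaries are knots, so no
    leakage across support transitions) on its masked-valid frames and
    evaluated at the 1% grid points of its band. A grid point is invalid if
    its phase has fewer than two valid frames, if its nearest raw frame is
    masked out, or if no valid frame lies within ``gap_pct`` percent of
    stride of its source time.
    """
    series = np.asarray(series, dtype=float)
    if mask is None:
        mask = np.ones(series.shape, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if series.shape != mask.shape or series.shape != seg.time.shape:
        raise InvalidParameterError("series, mask and segmentation lengths differ")

    ev = seg.events
    spans = {
        "contact": (ev.analyzed_on, ev.opposite_off),
        "single_support": (ev.opposite_off, ev.opposite_on),
        "push_off": (ev.opposite_on, ev.analyzed_off),
    }
    values = np.full(GRID.shape, np.nan)
    valid = np.zeros(GRID.shape, dtype=bool)
    gap_s = gap_pct / 100.0 * ev.duration

    for phase in PHASES:
        lo, hi = PHASE_BANDS[phase]
        t0, t1 = spans[phase]
        # boundary ownership: 20% and 80% belong to single support,
        # the interior phase, so they survive masking of either double-
        # support phase; push_off owns (80, 100]
        if phase == "contact":
            own = (GRID >= lo) & (GRID < hi)
        elif phase == "single_support":
            own = (GRID >= lo) & (GRID <= hi)
        else:
            own = GRID > lo
        if t1 <= t0:
            continue  # zero-length phase: its points stay invalid
        idx = seg.frames_in(phase)
        # knots include the closing boundary frame so band edges are
        # interpolated, not extrapolated; validity still follows the
        # owning phase's frames
        in_span = np.nonzero((seg.time >= t0 - 1e-12) & (seg.time <= t1 + 1e-12))[0]
        good = in_span[mask[in_span]]
        tg = t0 + (GRID[own] - lo) / (hi - lo) * (t1 - t0)
        if good.size < 2:
            continue
        tk, vk = seg.time[good], series[good]
        if good.size >= 4:
            interp = CubicSpline(tk, vk)
            vals = interp(tg)
        else:
            vals = np.interp(tg, tk, vk)
        values[own] = vals
        # validity: nearest raw frame masked-in, and a valid frame nearby
        if idx.size:
            nearest = idx[np.argmin(np.abs(seg.time[idx][None, :] - tg[:, None]), axis=1)]
            near_ok = mask[nearest]
        else:
            near_ok = np.zeros(tg.shape, dtype=bool)
        gap_ok = np.min(np.abs(tk[None, :] - tg[:, None]), axis=1) <= gap_s + 1e-12
        valid[own] = near_ok & gap_ok

    return NormalizedSeries(values=values, valid=valid)


def aggregate_normalized(series_list: list[NormalizedSeries]) -> dict[str, np.ndarray]:
    """Pointwise mean, sd and n over trials, honoring each trial's validity.

    Mirrors the varying per-percent sample size of plate-limited recordings:
    n at a grid point counts only the trials valid there.
    """
    if not series_list:
        raise InvalidParameterError("no series to aggregate")
    vals = np.stack([s.values for s in series_list])
    ok = np.stack([s.valid for s in series_list])
    n = ok.sum(axis=0)
    with np.errstate(invalid="ignore"):
        masked = np.where(ok, vals, np.nan)
        mean = np.nanmean(np.where(n > 0, masked, np.nan), axis=0)
        sd = np.full(mean.shape, np.nan)
        enough = n > 1
        sd[enough] = np.nanstd(masked[:, enough], axis=0, ddof=1)
    return {"mean": mean, "sd": sd, "n": n}
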