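"""Raw-trial preprocessing: filtering, synchronization, local frame, BW scaling.

The pipeline works in a course-fixed global frame (Z up, meters) and a
per-frame *local* frame derived from the skater's center-of-mass (CM)
velocity: the horizontal CM velocity direction is the Y' axis (travel),
vertically up is Z', and X' = Y' x Z' completes a right-handed triad
pointing to the skater's right when moving forward. All forces are reported
dimensionless, as multiples of body weight (BW).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy import signal

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    NearStationaryError,
    ResamplingError,
)

Side = Literal["left", "right"]

#: Cutoff range (Hz) to which per-coordinate residual-method cutoffs are
#: clipped for marker smoothing.
MARKER_CUTOFF_RANGE = (9.0, 15.0)


@dataclass
class RawTrial:
    """Synchronized-or-not raw streams for one supporting-leg period.

    Marker trajectories are in meters in the global frame at ``fs_m`` Hz;
    the force vector is in newtons at ``fs_f`` Hz. Both streams share t=0.
    """

    markers: dict[str, np.ndarray]  # each (n, 3), meters
    cm: np.ndarray  # (n, 3), meters
    force: np.ndarray  # (m, 3), newtons, global frame
    fs_m: float
    fs_f: float
    body_weight: float  # newtons
    side: Side = "right"

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise InvalidParameterError("body_weight must be > 0 N")
        n = len(self.cm)
        for name, tr in self.markers.items():
            if len(tr) != n:
                raise InvalidParameterError(
                    f"marker {name!r} has {len(tr)} frames, CM has {n}"
                )

    @property
    def n_frames(self) -> int:
        return len(self.cm)

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fs_m


@dataclass
class LocalFrame:
    """Per-frame right-handed orthonormal triad (X', Y', Z'), Z' = global up."""

    X_axis: np.ndarray  # (n, 3)
    Y_axis: np.ndarray
    Z_axis: np.ndarray

    def __len__(self) -> int:
        return len(self.Y_axis)


@dataclass
class ForceSeries:
    """Force-plate output in the local frame, body-weight units."""

    components_local: np.ndarray  # (n, 3) in (X', Y', Z'), BW
    resultant: np.ndarray  # (n,), BW
    time: np.ndarray  # seconds

    def __post_init__(self) -> None:
        norm = np.linalg.norm(self.components_local, axis=1)
        if not np.allclose(norm, self.resultant, atol=1e-9):
            raise InvalidParameterError(
                "resultant must equal the norm of components_local"
            )


def butterworth_lowpass(series: np.ndarray, fc: float, fs: float) -> np.ndarray:
    """Zero-phase 4th-order Butterworth low-pass (dual-pass 2nd order).

    The forward-backward pass doubles the effective order and cancels phase
    lag, the convention for marker-trajectory smoothing. Edge transients are
    limited by even (reflective) padding.
    """
    if not 0 < fc < fs / 2:
        raise InvalidParameterError(
            f"cutoff {fc} Hz must lie in (0, Nyquist={fs / 2} Hz)"
        )
    series = np.asarray(series, dtype=float)
    if series.shape[0] < 12:
        raise InsufficientDataError(
            f"need >= 12 samples to filter, got {series.shape[0]}"
        )
    b, a = signal.butter(2, fc / (fs / 2))
    padlen = min(series.shape[0] - 1, 12)
    return signal.filtfilt(b, a, series, axis=0, padtype="even", padlen=padlen)


def residual_cutoff(
    series: np.ndarray,
    fs: float,
    grid: np.ndarray | None = None,
    r2_min: float = 0.5,
    floor_tol: float = 0.02,
) -> float:
    """Select a low-pass cutoff by residual analysis.

    For each candidate cutoff the RMS residual between the raw and filtered
    series is computed. The high-frequency tail of the residual-vs-cutoff
    curve (top third of the grid), where only noise is being removed, is fit
    with a line and extrapolated to 0 Hz to estimate the noise floor; the
    chosen cutoff is the lowest grid frequency whose residual falls at or
    below that floor. The 0-Hz extrapolation is itself only a percent-level
    estimate, so the floor carries a ``floor_tol`` relative tolerance (a
    pure-noise series then selects the grid minimum, as it should: there is
    no signal to preserve).

    Raises :class:`DegenerateSignalError` when the tail has no meaningful
    linear region (fit R^2 < ``r2_min``, non-negative slope, or non-positive
    intercept) — e.g. for a noiseless signal.
    """
    from .errors import DegenerateSignalError

    series = np.asarray(series, dtype=float)
    if series.shape[0] < 100:
        raise InsufficientDataError("residual method needs >= 100 samples")
    if grid is None:
        grid = np.arange(1.0, 30.0 + 1e-9, 0.5)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) <= 0) or grid[-1] >= fs / 2:
        raise InvalidParameterError("grid must ascend and stay below Nyquist")

    # evaluate residuals on the central 80% so filter edge transients do
    # not masquerade as a noise floor
    edge = max(series.shape[0] // 10, 1)
    core = slice(edge, -edge)
    resid = np.array(
        [
            np.sqrt(
                np.mean((series - butterworth_lowpass(series, fc, fs))[core] ** 2)
            )
            for fc in grid
        ]
    )
    n_tail = max(len(grid) // 3, 3)
    fx, ry = grid[-n_tail:], resid[-n_tail:]
    slope, intercept = np.polyfit(fx, ry, 1)
    pred = slope * fx + intercept
    ss_res = np.sum((ry - pred) ** 2)
    ss_tot = np.sum((ry - ry.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    rms_total = np.sqrt(np.mean(series**2)) + 1e-300
    # a true noise floor is near-flat across the tail; a residual still
    # decaying steeply there (e.g. pure passband droop of a noiseless
    # signal) means there is no floor to extrapolate
    plateau = ry[-1] >= 0.5 * ry[0]
    if (
        slope >= 0
        or intercept <= 1e-9 * rms_total
        or r2 < r2_min
        or not plateau
    ):
        raise DegenerateSignalError(
            "residual curve has no linear noise region "
            f"(slope={slope:.3g}, intercept={intercept:.3g}, R2={r2:.3f})"
        )
    floor = intercept * (1.0 + floor_tol)
    below = np.nonzero(resid <= floor)[0]
    if below.size:
        return float(grid[below[0]])
    # No candidate crosses the floor: take the closest approach.
    return float(grid[int(np.argmin(np.abs(resid - floor)))])


def synchronize(raw: RawTrial, antialias: bool = True) -> RawTrial:
    """Decimate the force stream to the marker rate, aligning time bases.

    With ``antialias`` (default) the force is zero-phase low-pass filtered at
    0.4x the target Nyquist (8th-order Butterworth) before every k-th sample
    is kept. Disable it only when the force content is known band-limited and
    sample-exact pass-through is required.
    """
    k_float = raw.fs_f / raw.fs_m
    k = int(round(k_float))
    if abs(k_float - k) > 1e-9 or k < 1:
        raise ResamplingError(
            f"force rate {raw.fs_f} Hz is not an integer multiple of "
            f"marker rate {raw.fs_m} Hz"
        )
    force = np.asarray(raw.force, dtype=float)
    if antialias and k > 1:
        fc = 0.4 * (raw.fs_m / 2)
        sos = signal.butter(4, fc / (raw.fs_f / 2), output="sos")
        force = signal.sosfiltfilt(sos, force, axis=0)
    force = force[::k][: raw.n_frames]
    return replace(raw, force=force, fs_f=raw.fs_m)


def cm_velocity(cm: np.ndarray, fs: float) -> np.ndarray:
    """CM velocity by central differences; one-sided at the endpoints."""
    cm = np.asarray(cm, dtype=float)
    if len(cm) < 2:
        raise InsufficientDataError("need >= 2 CM samples for velocity")
    v = np.empty_like(cm)
    v[1:-1] = (cm[2:] - cm[:-2]) * (fs / 2.0)
    v[0] = (cm[1] - cm[0]) * fs
    v[-1] = (cm[-1] - cm[-2]) * fs
    return v


def local_frame(cm_vel: np.ndarray, eps: float = 0.1) -> LocalFrame:
    """Build the travel-aligned local frame from per-frame CM velocity.

    Y' is the unit horizontal CM velocity, Z' = (0, 0, 1), X' = Y' x Z'.
    Frames with horizontal speed <= ``eps`` m/s are rejected: the travel
    direction is undefined for a (near-)stationary skater.
    """
    v = np.atleast_2d(np.asarray(cm_vel, dtype=float))
    horiz = v.copy()
    horiz[:, 2] = 0.0
    speed = np.linalg.norm(horiz, axis=1)
    if np.any(speed <= eps):
        bad = int(np.argmax(speed <= eps))
        raise NearStationaryError(
            f"horizontal CM speed {speed[bad]:.3g} m/s <= eps={eps} "
            f"at frame {bad}: local frame undefined"
        )
    y = horiz / speed[:, None]
    z = np.zeros_like(y)
    z[:, 2] = 1.0
    x = np.cross(y, z)
    return LocalFrame(X_axis=x, Y_axis=y, Z_axis=z)


def to_local(vec_global: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Express global vectors in the local frame: (v.X', v.Y', v.Z')."""
    v = np.atleast_2d(np.asarray(vec_global, dtype=float))
    out = np.stack(
        [
            np.einsum("ij,ij->i", v, np.broadcast_to(frame.X_axis, v.shape)),
            np.einsum("ij,ij->i", v, np.broadcast_to(frame.Y_axis, v.shape)),
            np.einsum("ij,ij->i", v, np.broadcast_to(frame.Z_axis, v.shape)),
        ],
        axis=1,
    )
    return out[0] if np.asarray(vec_global).ndim == 1 else out


def to_global(vec_local: np.ndarray, frame: LocalFrame) -> np.ndarray:
    """Inverse of :func:`to_local` (the frame matrix is orthonormal)."""
    v = np.atleast_2d(np.asarray(vec_local, dtype=float))
    out = (
        v[:, 0:1] * frame.X_axis
        + v[:, 1:2] * frame.Y_axis
        + v[:, 2:3] * frame.Z_axis
    )
    return out[0] if np.asarray(vec_local).ndim == 1 else out


def normalize_by_bw(force_N: np.ndarray | float, body_weight: float):
    """Convert newtons to dimensionless body-weight (BW) units."""
    if body_weight <= 0:
        raise InvalidParameterError("body_weight must be > 0 N")
    return np.asarray(force_N, dtype=float) / body_weight


def force_series(
    force_N: np.ndarray, frame: LocalFrame, body_weight: float, fs: float
) -> ForceSeries:
    """Package a synchronized global force stream as a local-frame ForceSeries."""
    comp = to_local(normalize_by_bw(force_N, body_weight), frame)
    comp = np.atleast_2d(comp)
    return ForceSeries(
        components_local=comp,
        resultant=np.linalg.norm(comp, axis=1),
        time=np.arange(len(comp)) / fs,
    )


def filter_markers(
    raw: RawTrial,
    cutoff_policy: str = "residual",
) -> RawTrial:
    """Smooth marker and CM trajectories per the configured cutoff policy.

    ``"residual"`` picks one cutoff per coordinate by :func:`residual_cutoff`
    and clips it to the 9.0-15.0 Hz marker range; ``"fixed:<Hz>"`` applies a
    single cutoff; ``"none"`` returns the trial untouched.
    """
    if cutoff_policy == "none":
        return raw

    def _filter(tr: np.ndarray) -> np.ndarray:
        out = np.empty_like(tr, dtype=float)
        for j in range(tr.shape[1]):
            if cutoff_policy == "residual":
                from .errors import DegenerateSignalError

                try:
                    fc = residual_cutoff(tr[:, j], raw.fs_m)
                except (InsufficientDataError, DegenerateSignalError):
                    # noiseless or too-short coordinate: keep the most signal
                    fc = MARKER_CUTOFF_RANGE[1]
                fc = float(np.clip(fc, *MARKER_CUTOFF_RANGE))
            elif cutoff_policy.startswith("fixed:"):
                fc = float(cutoff_policy.split(":", 1)[1])
            else:
                raise InvalidParameterError(
                    f"unknown cutoff policy {cutoff_policy!r}"
                )
            out[:, j] = butterworth_lowpass(tr[:, j], fc, raw.fs_m)
        return out

    markers = {name: _filter(tr) for name, tr in raw.markers.items()}
    return replace(raw, markers=markers, cm=_filter(raw.cm))
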