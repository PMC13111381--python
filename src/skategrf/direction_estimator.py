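"""Sole-normal GRF direction estimators (Est1 / Est2) and linear correction.

Both estimators assume the ground reaction force acts perpendicular to the
shoe sole. The sole plane is reconstructed from three points of the
supporting leg: the rear and front ends of the skate blade plus one joint
center — the ankle for Est1, the knee for Est2. An orthogonal triad is built
as

    y_b = unit(front - rear)            (blade axis)
    x_b = unit(y_b x lever),  lever = joint - rear
    z_b = unit(y_b x x_b)               (sole normal, flipped upward)

and the estimated GRF components are the measured resultant magnitude
F_sigma times the local-frame components of z_b. Marker error tilts z_b by
roughly (noise / lever length), which is why the longer knee lever (Est2)
is more stable than the ankle lever (Est1).

Sign convention: the literal cross-product order yields a z_b pointing away
from the joint (into the ground); this module flips the sign so that
z_b . (0,0,1) > 0, matching the upward reaction-force direction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .errors import (
    ConfigurationError,
    ContractError,
    FitError,
    GeometryError,
    InsufficientDataError,
    InvalidParameterError,
)
from .preprocess import (
    LocalFrame,
    RawTrial,
    cm_velocity,
    filter_markers,
    local_frame,
    normalize_by_bw,
    synchronize,
    to_local,
)

Method = Literal["Est1", "Est2"]

#: Canonical marker names the trial pipeline expects.
BLADE_REAR, BLADE_FRONT, ANKLE, KNEE = "blade_rear", "blade_front", "ankle", "knee"

COMPONENTS = ("X", "Y", "Z")


@dataclass
class DirectionEstimate:
    """Per-frame estimated sole-normal, globally and in the local frame."""

    method: Method
    z_b_global: np.ndarray  # (n, 3) unit vectors
    e_local: np.ndarray  # (n, 3): (e_X', e_Y', e_Z')


@dataclass
class EstimatedGRF:
    """Estimated GRF components in BW units on the local frame."""

    components: np.ndarray  # (n, 3): (F_estX', F_estY', F_estZ')
    method: Method
    corrected: bool = False


@dataclass
class CorrectionModel:
    """Per-component linear recalibration: true = slope * estimate + intercept.

    ``fitted_for`` records the motion condition the coefficients were fitted
    on; applying a model to a different motion requires an explicit override.
    """

    slopes: np.ndarray  # (3,) for (X', Y', Z')
    intercepts: np.ndarray  # (3,)
    fitted_for: str | None = None

    def __post_init__(self) -> None:
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.intercepts = np.asarray(self.intercepts, dtype=float)
        if not (np.all(np.isfinite(self.slopes)) and np.all(self.slopes != 0)):
            raise ConfigurationError("correction slopes must be finite and nonzero")
        if not np.all(np.isfinite(self.intercepts)):
            raise ConfigurationError("correction intercepts must be finite")

    def to_dict(self) -> dict:
        return {
            c: {"slope": float(s), "intercept": float(i)}
            for c, s, i in zip(COMPONENTS, self.slopes, self.intercepts)
        }

    @classmethod
    def from_dict(cls, d: dict, fitted_for: str | None = None) -> "CorrectionModel":
        try:
            slopes = [d[c]["slope"] for c in COMPONENTS]
            intercepts = [d[c]["intercept"] for c in COMPONENTS]
        except KeyError as exc:
            raise ConfigurationError(f"missing correction component: {exc}") from exc
        return cls(np.array(slopes), np.array(intercepts), fitted_for=fitted_for)


def default_correction() -> CorrectionModel:
    """Published curve-left recalibration of Est2 components."""
    return CorrectionModel(
        slopes=np.array([0.847, 0.596, 0.987]),
        intercepts=np.array([-0.029, -0.025, 0.030]),
        fitted_for="curve-left",
    )


def estimate_direction(
    rear: np.ndarray,
    front: np.ndarray,
    joint: np.ndarray,
    method: Method = "Est2",
) -> np.ndarray:
    """Estimated sole-normal unit vector(s) from blade ends and a joint center.

    ``joint`` is the ankle center for Est1, the knee center for Est2; the
    triad construction is identical, only the lever differs. Accepts single
    points (3,) or stacked frames (n, 3); returns matching shape.
    """
    single = np.ndim(rear) == 1
    rear = np.atleast_2d(np.asarray(rear, dtype=float))
    front = np.atleast_2d(np.asarray(front, dtype=float))
    joint = np.atleast_2d(np.asarray(joint, dtype=float))

    blade = front - rear
    blade_len = np.linalg.norm(blade, axis=1)
    if np.any(blade_len <= 1e-6):
        raise GeometryError("blade ends coincide: blade axis undefined")
    y_b = blade / blade_len[:, None]

    lever = joint - rear
    lever_len = np.linalg.norm(lever, axis=1)
    cross1 = np.cross(y_b, lever)
    sin_angle = np.linalg.norm(cross1, axis=1) / np.maximum(lever_len, 1e-300)
    if np.any(lever_len <= 1e-6) or np.any(sin_angle <= 1e-4):
        raise GeometryError(
            "joint center (nearly) collinear with blade axis: sole plane undefined"
        )
    x_b = cross1 / np.linalg.norm(cross1, axis=1)[:, None]

    z_b = np.cross(y_b, x_b)
    z_b /= np.linalg.norm(z_b, axis=1)[:, None]
    # enforce the upward reaction-force convention
    flip = z_b[:, 2] < 0
    z_b[flip] *= -1.0
    return z_b[0] if single else z_b


def grf_components(F_sigma: np.ndarray, e_local: np.ndarray, method: Method = "Est2") -> EstimatedGRF:
    """Scale the unit direction by the measured resultant: F_est = F_sigma * e."""
    F_sigma = np.atleast_1d(np.asarray(F_sigma, dtype=float))
    e_local = np.atleast_2d(np.asarray(e_local, dtype=float))
    if np.any(F_sigma < 0):
        raise InvalidParameterError("resultant force must be >= 0")
    norms = np.linalg.norm(e_local, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-6):
        raise ContractError("e_local must be unit vectors (within 1e-6)")
    return EstimatedGRF(components=F_sigma[:, None] * e_local, method=method)


def mirror_left(series: np.ndarray) -> np.ndarray:
    """Reflect local-frame vectors left<->right by negating the X' component.

    Straight skating is bilaterally symmetric, so left-leg trials are mapped
    to right-leg convention before pooling. Involutive; apply only to
    straight-motion left-side data.
    """
    out = np.array(series, dtype=float, copy=True)
    out[..., 0] *= -1.0
    return out


def apply_correction(
    est: EstimatedGRF,
    model: CorrectionModel | None = None,
    motion: str | None = None,
    override: bool = False,
) -> EstimatedGRF:
    """Apply the per-component linear recalibration (Est2 -> Est2C).

    The default model was fitted on curve-left data only; passing a
    different ``motion`` without ``override=True`` is a configuration error.
    The corrected component vector no longer has norm F_sigma.
    """
    import warnings

    if model is None:
        model = default_correction()
    if est.method != "Est2":
        warnings.warn(
            f"correction model was developed for Est2, got {est.method}",
            stacklevel=2,
        )
    if (
        model.fitted_for is not None
        and motion is not None
        and motion != model.fitted_for
        and not override
    ):
        raise ConfigurationError(
            f"model fitted for {model.fitted_for!r} applied to {motion!r}; "
            "pass override=True to force"
        )
    comp = est.components * model.slopes + model.intercepts
    return EstimatedGRF(components=comp, method=est.method, corrected=True)


def fit_correction(
    true_series: np.ndarray,
    est_series: np.ndarray,
    fitted_for: str | None = None,
) -> CorrectionModel:
    """Least-squares recalibration per component, true regressed on estimate.

    The regression orientation matters: the true (plate) value is the
    response and the estimate the predictor, so the fitted line maps future
    estimates onto the plate scale.
    """
    true_series = np.atleast_2d(np.asarray(true_series, dtype=float))
    est_series = np.atleast_2d(np.asarray(est_series, dtype=float))
    if true_series.shape != est_series.shape:
        raise InvalidParameterError("true/estimated series shapes differ")
    if true_series.shape[0] < 3:
        raise InsufficientDataError("need >= 3 paired frames per component")
    slopes, intercepts = np.empty(3), np.empty(3)
    for j in range(3):
        x, y = est_series[:, j], true_series[:, j]
        if np.var(x) <= 0:
            raise FitError(f"zero variance in estimated {COMPONENTS[j]}' component")
        slopes[j], intercepts[j] = np.polyfit(x, y, 1)
    return CorrectionModel(slopes, intercepts, fitted_for=fitted_for)


def estimate_trial(
    raw: RawTrial,
    method: Method = "Est2",
    motion: str = "straight",
    cutoff_policy: str = "residual",
    antialias: bool = True,
    correction: CorrectionModel | None = None,
    override_correction_motion: bool = False,
) -> tuple[DirectionEstimate, EstimatedGRF, LocalFrame, np.ndarray]:
    """Full per-trial pipeline: filter, synchronize, estimate, project, scale.

    Returns the direction estimate, the estimated GRF (mirrored for left-leg
    straight trials), the per-frame local frame, and the resultant F_sigma
    (BW). Set ``cutoff_policy="none"`` and ``antialias=False`` for an exact
    pass-through of band-limited synthetic data.
    """
    raw = filter_markers(raw, cutoff_policy)
    raw = synchronize(raw, antialias=antialias)

    frame = local_frame(cm_velocity(raw.cm, raw.fs_m))
    joint_name = ANKLE if method == "Est1" else KNEE
    z_b = estimate_direction(
        raw.markers[BLADE_REAR], raw.markers[BLADE_FRONT], raw.markers[joint_name],
        method=method,
    )
    z_b = np.atleast_2d(z_b)
    e_local = to_local(z_b, frame)

    F_sigma = np.linalg.norm(normalize_by_bw(raw.force, raw.body_weight), axis=1)
    est = grf_components(F_sigma, e_local, method=method)

    if raw.side == "left" and motion == "straight":
        est = EstimatedGRF(mirror_left(est.components), method, est.corrected)
        e_local = mirror_left(e_local)

    if correction is not None:
        est = apply_correction(
            est, correction, motion=motion, override=override_correction_motion
        )
    return DirectionEstimate(method, z_b, e_local), est, frame, F_sigma
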