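"""Synthetic skating-stride generator with known ground truth.

Produces the full set of streams a real trial would provide — blade and
joint marker trajectories, CM path, force-plate vectors, blade events, and
plate geometry — plus the ground-truth GRF direction and components that a
real recording cannot give. The model is geometric, not dynamic:

* the CM travels a straight line or an arc (radius 26 m, the inner-lane
  radius of a standard track) at constant speed and height;
* the supporting blade glides on the course plane under the CM with a
  constant steering (yaw) angle relative to the travel direction;
* the shank leans from vertical following a half-sine "push" profile on
  top of a constant centripetal lean on the curve; ankle and knee sit in
  the blade-shank plane, so at zero noise the sole-normal reconstructed
  from the markers is exact by construction;
* the resultant force is a raised-cosine bump (0 at blade-on and -off),
  directed along the sole normal optionally rotated about the blade axis
  by a configurable perturbation;
* observed markers are the exact ones plus isotropic i.i.d. Gaussian noise.

The generator claims geometric and statistical structure only, not
waveform fidelity to any particular skater.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
import pandas as pd

from .direction_estimator import (
    ANKLE,
    BLADE_FRONT,
    BLADE_REAR,
    COMPONENTS,
    KNEE,
    CorrectionModel,
    estimate_trial,
    mirror_left,
)
from .errors import ConfigurationError, InvalidParameterError
from .preprocess import RawTrial, local_frame, to_local
from .stride_phases import (
    BladeEvents,
    analyzable_mask,
    phase_normalize,
    segment_phases,
)

Motion = Literal["straight", "curve-right", "curve-left"]

#: Table-style mean phase durations (s): contact, single support, push-off.
PHASE_DURATIONS = {
    "straight": (0.16, 0.60, 0.16),
    "curve-right": (0.15, 0.48, 0.14),
    "curve-left": (0.14, 0.56, 0.15),
}
CM_SPEEDS = {"straight": 9.79, "curve-right": 8.87, "curve-left": 8.87}

GRAVITY = 9.81  # m/s^2

# blade/leg geometry (m): realistic inline-skate proportions
BLADE_LENGTH = 0.30
ANKLE_ALONG, ANKLE_UP = 0.15, 0.11  # ankle offset from blade rear, along/up
SHANK_LENGTH = 0.40  # ankle to knee along the shank


@dataclass
class SimulationConfig:
    """Study-condition parameters of one simulated stride."""

    motion: Motion = "straight"
    curve_radius: float = 26.0
    cm_speed: float | None = None  # m/s; default per motion
    phase_durations: tuple[float, float, float] | None = None  # s
    side: Literal["left", "right"] = "right"
    marker_noise_sd: float = 0.003  # m, isotropic per frame
    direction_perturbation_deg: float = 0.0  # truth tilt about blade axis
    force_peak: float = 1.8  # BW
    fs_m: float = 300.0
    fs_f: float = 900.0
    body_weight: float = 65.0 * GRAVITY  # N
    blade_yaw_deg: float = 12.0  # steering angle vs travel direction
    push_lean_deg: float = 30.0  # peak half-sine shank lean
    cm_height: float = 0.85  # m
    opposite_lateral_offset: float = 0.45  # m, keeps the other blade off-plate
    plate: tuple[float, float, float, float] = (0.0, 0.6, 0.0, 5.4)
    blade_start_y: float = 0.05  # rear blade end at blade-on, course y (m)
    force_on_plate: bool = False  # error if the stride leaves the plate
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cm_speed is None:
            self.cm_speed = CM_SPEEDS[self.motion]
        if self.phase_durations is None:
            self.phase_durations = PHASE_DURATIONS[self.motion]
        if min(self.phase_durations) < 0 or sum(self.phase_durations) <= 0:
            raise InvalidParameterError("phase durations must be positive")
        if self.curve_radius <= 0 or self.marker_noise_sd < 0:
            raise InvalidParameterError("radius must be > 0 and noise sd >= 0")


@dataclass
class SyntheticTrial:
    """One simulated supporting-leg period with ground truth attached."""

    raw: RawTrial
    events: BladeEvents
    truth_markers: dict[str, np.ndarray]
    truth_dir_global: np.ndarray  # (n, 3) unit truth GRF direction
    truth_components_local: np.ndarray  # (n, 3) BW
    truth_resultant: np.ndarray  # (n,) BW
    analyzed_blade_xy: np.ndarray  # (n, 2, 2)
    opposite_blade_xy: np.ndarray
    opposite_airborne: np.ndarray  # (n,) bool
    plate: tuple[float, float, float, float]
    motion: Motion
    config: SimulationConfig
    participant: str = "P00"
    trial: int = 0

    @property
    def analyzable(self) -> np.ndarray:
        return analyzable_mask(
            self.analyzed_blade_xy,
            self.opposite_blade_xy,
            self.opposite_airborne,
            self.plate,
        )


def _rotate_about_axis(vec: np.ndarray, axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rodrigues rotation of row vectors about per-row unit axes."""
    if angle_rad == 0.0:
        return vec
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    cross = np.cross(axis, vec)
    dot = np.einsum("ij,ij->i", axis, vec)[:, None]
    return vec * c + cross * s + axis * dot * (1 - c)


def _kinematics(cfg: SimulationConfig, t: np.ndarray) -> dict[str, np.ndarray]:
    """Closed-form truth kinematics evaluated at arbitrary times."""
    d1, d2, d3 = cfg.phase_durations
    total = d1 + d2 + d3
    v = cfg.cm_speed
    arclen = v * t

    if cfg.motion == "straight":
        tangent = np.tile([0.0, 1.0, 0.0], (len(t), 1))
        xy = np.column_stack([np.full_like(t, 0.3), cfg.blade_start_y + arclen])
    else:
        # arc tangent to +Y at (0.3, blade_start_y); center to the turn side
        turn = 1.0 if cfg.motion == "curve-right" else -1.0
        R = cfg.curve_radius
        theta = arclen / R
        cx = 0.3 + turn * R
        xy = np.column_stack(
            [
                cx - turn * R * np.cos(theta),
                cfg.blade_start_y + R * np.sin(theta),
            ]
        )
        tangent = np.column_stack(
            [turn * np.sin(theta), np.cos(theta), np.zeros_like(t)]
        )

    cm = np.column_stack([xy[:, 0], xy[:, 1], np.full_like(t, cfg.cm_height)])
    cm_vel = v * tangent

    # blade direction: tangent yawed by the steering angle (toward lateral)
    yaw = np.deg2rad(cfg.blade_yaw_deg) * (1.0 if cfg.side == "right" else -1.0)
    cy, sy = np.cos(yaw), np.sin(yaw)
    u = np.column_stack(
        [
            tangent[:, 0] * cy + tangent[:, 1] * sy,
            -tangent[:, 0] * sy + tangent[:, 1] * cy,
            np.zeros_like(t),
        ]
    )
    n = np.column_stack([-u[:, 1], u[:, 0], np.zeros_like(t)])  # z x u

    # shank lean: centripetal base (curve) + half-sine push profile
    base = 0.0
    if cfg.motion != "straight":
        base = np.arctan((v**2 / cfg.curve_radius) / GRAVITY)
    tau = np.clip(t / total, 0.0, 1.0)
    lean = base + np.deg2rad(cfg.push_lean_deg) * np.sin(np.pi / 2 * tau) ** 2
    lean_sign = 1.0 if cfg.side == "left" else -1.0

    w = (
        lean_sign * np.sin(lean)[:, None] * n
        + np.cos(lean)[:, None] * np.column_stack([np.zeros_like(t), np.zeros_like(t), np.ones_like(t)])
    )

    mid = np.column_stack([xy, np.zeros_like(t)])
    rear = mid - 0.5 * BLADE_LENGTH * u
    front = mid + 0.5 * BLADE_LENGTH * u
    ankle = rear + ANKLE_ALONG * u + ANKLE_UP * w
    knee = ankle + SHANK_LENGTH * w

    # exact sole normal: perpendicular to the blade in the blade-shank plane
    z_up = np.zeros_like(u)
    z_up[:, 2] = 1.0
    sole = np.cos(lean)[:, None] * z_up + (lean_sign * np.sin(lean))[:, None] * n

    # raised-cosine resultant, zero outside the support period
    frac = np.clip(t / total, 0.0, 1.0)
    F_sigma = cfg.force_peak * 0.5 * (1 - np.cos(2 * np.pi * frac))
    F_sigma[(t < 0) | (t > total)] = 0.0

    truth_dir = _rotate_about_axis(
        sole, u, np.deg2rad(cfg.direction_perturbation_deg)
    )
    return {
        "cm": cm,
        "cm_vel": cm_vel,
        "rear": rear,
        "front": front,
        "ankle": ankle,
        "knee": knee,
        "truth_dir": truth_dir,
        "F_sigma": F_sigma,
        "n_lat": n,
        "u": u,
    }


def simulate_stride(config: SimulationConfig) -> SyntheticTrial:
    """Generate one stride trial per the configured study conditions."""
    cfg = config
    d1, d2, d3 = cfg.phase_durations
    total = d1 + d2 + d3
    n_m = int(round(total * cfg.fs_m))
    t_m = np.arange(n_m) / cfg.fs_m
    t_f = np.arange(int(round(total * cfg.fs_f))) / cfg.fs_f

    kin = _kinematics(cfg, t_m)
    kin_f = _kinematics(cfg, t_f)

    force_N = kin_f["F_sigma"][:, None] * kin_f["truth_dir"] * cfg.body_weight

    rng = np.random.default_rng(cfg.seed)
    truth_markers = {
        BLADE_REAR: kin["rear"],
        BLADE_FRONT: kin["front"],
        ANKLE: kin["ankle"],
        KNEE: kin["knee"],
    }
    markers = {
        name: tr + rng.normal(0.0, cfg.marker_noise_sd, tr.shape)
        for name, tr in truth_markers.items()
    }

    raw = RawTrial(
        markers=markers,
        cm=kin["cm"],
        force=force_N,
        fs_m=cfg.fs_m,
        fs_f=cfg.fs_f,
        body_weight=cfg.body_weight,
        side=cfg.side,
    )
    events = BladeEvents(0.0, d1, d1 + d2, total)

    # truth components in the analytic (tangent-aligned) local frame
    frame = local_frame(kin["cm_vel"])
    truth_local = to_local(kin["truth_dir"], frame) * kin["F_sigma"][:, None]
    if cfg.side == "left" and cfg.motion == "straight":
        truth_local = mirror_left(truth_local)

    # opposite blade: grounded laterally off the path during double support
    opp_side = -1.0 if cfg.side == "right" else 1.0
    opp_mid = (
        np.column_stack([kin["cm"][:, 0], kin["cm"][:, 1], np.zeros(n_m)])
        + opp_side * cfg.opposite_lateral_offset * kin["n_lat"]
    )
    opp_rear = opp_mid - 0.5 * BLADE_LENGTH * kin["u"]
    opp_front = opp_mid + 0.5 * BLADE_LENGTH * kin["u"]
    airborne = (t_m >= d1) & (t_m < d1 + d2)

    analyzed_xy = np.stack(
        [kin["rear"][:, :2], kin["front"][:, :2]], axis=1
    )
    opposite_xy = np.stack([opp_rear[:, :2], opp_front[:, :2]], axis=1)

    trial = SyntheticTrial(
        raw=raw,
        events=events,
        truth_markers=truth_markers,
        truth_dir_global=kin["truth_dir"],
        truth_components_local=truth_local,
        truth_resultant=kin["F_sigma"],
        analyzed_blade_xy=analyzed_xy,
        opposite_blade_xy=opposite_xy,
        opposite_airborne=airborne,
        plate=cfg.plate,
        motion=cfg.motion,
        config=cfg,
    )
    if cfg.force_on_plate and not trial.analyzable.any():
        raise ConfigurationError(
            "stride footprint never lies cleanly on the plate"
        )
    if cfg.force_on_plate and not trial.analyzable.all():
        raise ConfigurationError(
            "stride footprint exceeds the plate bounds with force_on_plate=True"
        )
    return trial


def make_cohort(
    n_participants: int,
    trials_per: int,
    config: SimulationConfig | None = None,
    seed: int = 0,
) -> list[SyntheticTrial]:
    """Simulate a cohort with per-participant random effects.

    Speed and push-lean amplitude get multiplicative normal effects (sd 5%
    of nominal); each participant also carries a small systematic direction
    bias (sd 0.5 deg about the blade axis). Fully reproducible per seed.
    """
    if n_participants < 1 or trials_per < 1:
        raise InvalidParameterError("need >= 1 participant and >= 1 trial")
    base = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    trials: list[SyntheticTrial] = []
    for p in range(n_participants):
        speed_mult = rng.normal(1.0, 0.05)
        lean_mult = rng.normal(1.0, 0.05)
        dir_bias = rng.normal(0.0, 0.5)
        for k in range(trials_per):
            dur_mult = rng.normal(1.0, 0.05)
            cfg = replace(
                base,
                cm_speed=base.cm_speed * speed_mult,
                push_lean_deg=base.push_lean_deg * lean_mult,
                direction_perturbation_deg=base.direction_perturbation_deg + dir_bias,
                phase_durations=tuple(
                    d * max(dur_mult, 0.5) for d in base.phase_durations
                ),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            trial = simulate_stride(cfg)
            trial.participant = f"P{p:02d}"
            trial.trial = k
            trials.append(trial)
    return trials


def paired_dataset(
    trials: list[SyntheticTrial],
    method: str = "Est2",
    grid: tuple[int, ...] = tuple(range(5, 100, 10)),
    cutoff_policy: str = "none",
    antialias: bool = False,
) -> pd.DataFrame:
    """Long-format (true, estimated) pairs at normalized-grid checkpoints.

    Runs the estimation pipeline per trial, phase-normalizes truth and
    estimate with the plate-analyzability mask, and emits one row per
    (trial, component, grid point) where both are valid — reproducing the
    varying per-checkpoint sample sizes of plate-limited recordings.
    """
    rows = []
    grid_idx = np.asarray(grid, dtype=int)
    for trial in trials:
        _, est, _, _ = estimate_trial(
            trial.raw,
            method=method,
            motion=trial.motion,
            cutoff_policy=cutoff_policy,
            antialias=antialias,
        )
        seg = segment_phases(trial.events, trial.raw.time)
        mask = trial.analyzable
        for j, comp in enumerate(COMPONENTS):
            norm_true = phase_normalize(trial.truth_components_local[:, j], seg, mask)
            norm_est = phase_normalize(est.components[:, j], seg, mask)
            ok = norm_true.valid[grid_idx] & norm_est.valid[grid_idx]
            for g, use in zip(grid_idx, ok):
                if not use:
                    continue
                rows.append(
                    {
                        "participant": trial.participant,
                        "trial": trial.trial,
                        "motion": trial.motion,
                        "component": comp,
                        "pct": int(g),
                        "true_bw": float(norm_true.values[g]),
                        "est_bw": float(norm_est.values[g]),
                    }
                )
    return pd.DataFrame(rows)


def cohort_rmse(
    trials: list[SyntheticTrial],
    method: str = "Est2",
    cutoff_policy: str = "none",
    antialias: bool = False,
) -> dict[str, float]:
    """Pooled per-component RMSE of a method over analyzable frames."""
    diffs: dict[str, list[np.ndarray]] = {c: [] for c in COMPONENTS}
    for trial in trials:
        _, est, _, _ = estimate_trial(
            trial.raw,
            method=method,
            motion=trial.motion,
            cutoff_policy=cutoff_policy,
            antialias=antialias,
        )
        mask = trial.analyzable
        delta = est.components[mask] - trial.truth_components_local[mask]
        for j, comp in enumerate(COMPONENTS):
            diffs[comp].append(delta[:, j])
    return {
        c: float(np.sqrt(np.mean(np.concatenate(d) ** 2))) for c, d in diffs.items()
    }


def inject_distortion(
    dataset: pd.DataFrame,
    model: CorrectionModel,
    residual_sd: float = 0.005,
    seed: int = 0,
) -> pd.DataFrame:
    """Rebuild the truth column as a linear distortion of the estimates.

    Sets true = slope_c * est + intercept_c + N(0, residual_sd) per
    component, producing a dataset whose true-on-estimate regression has
    known coefficients — the ground truth for correction-recovery checks.
    """
    rng = np.random.default_rng(seed)
    out = dataset.copy()
    comp_idx = out["component"].map({c: j for j, c in enumerate(COMPONENTS)})
    est = out["est_bw"].to_numpy(float)
    out["true_bw"] = (
        model.slopes[comp_idx.to_numpy()] * est
        + model.intercepts[comp_idx.to_numpy()]
        + rng.normal(0.0, residual_sd, est.shape)
    )
    return out
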