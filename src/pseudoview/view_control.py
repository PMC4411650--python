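"""Interactive viewpoint control law.

A 2-axis input device (joystick) drives incremental rotations of the
virtual viewpoint. Raw samples q ∈ R² are referenced to a neutral
position q₀ (the mean of the first frames after start-up), mapped to a
rotation increment by a 3×2 matrix Ω(γ), and integrated with a
sign-preserving power law

    θᵢ ← θᵢ + αᵢ · sign(Δθᵢ) · |Δθᵢ|^r

so that r > 1 gives fine control near the neutral position and fast
sweeps at full deflection, while r = 1 is exactly linear. A press of the
device's switch resets θ to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .warp_engine import PivotPose

__all__ = [
    "ControlConfig",
    "ViewpointState",
    "omega_from_gamma",
    "rate_to_gain",
    "calibrate_neutral",
    "map_input",
    "update_viewpoint",
    "reset_viewpoint",
    "replay_trace",
]

#: fastest rotation at full deflection, degrees/second
DEFAULT_MAX_RATE = 28.2
#: control-loop update rate, updates/second
DEFAULT_UPDATE_RATE = 16.0


def omega_from_gamma(gamma_deg: float) -> np.ndarray:
    """Input-direction mapping matrix Ω(γ).

    γ sets the correspondence between the joystick deflection direction
    and the direction of viewpoint rotation; the third row is zero so a
    2-axis device never commands roll (Δθz = 0).
    """
    g = np.deg2rad(gamma_deg)
    c, s = np.cos(g), np.sin(g)
    return np.array([[c, s], [s, c], [0.0, 0.0]])


def rate_to_gain(max_rate: float, update_rate: float, r: float = 1.0) -> float:
    """Per-update gain α realizing a given peak rotation rate.

    At full deflection |Δθ| = 1, so |Δθ|^r = 1 for any r and the gain is
    simply max_rate / update_rate (degrees per update).
    """
    if max_rate <= 0 or update_rate <= 0:
        raise ValueError("rates must be positive")
    if r < 1:
        raise ValueError("power coefficient r must be >= 1")
    return max_rate / update_rate


@dataclass(frozen=True)
class ControlConfig:
    """Parameters of the control law.

    Defaults reproduce the single-axis clinical configuration: only the
    elevation axis is active (αy = αz = 0), r = 2 for fine centering, and
    the x gain realizes a 28.2°/s sweep at a 16 Hz update rate.
    """

    gamma: float = 0.0
    omega: np.ndarray | None = None
    alpha: np.ndarray = field(
        default_factory=lambda: np.array(
            [rate_to_gain(DEFAULT_MAX_RATE, DEFAULT_UPDATE_RATE), 0.0, 0.0]
        )
    )
    r: float = 2.0
    q_neutral: np.ndarray = field(default_factory=lambda: np.zeros(2))
    theta_limit: float = 90.0
    n_neutral_frames: int = 10

    def __post_init__(self) -> None:
        om = omega_from_gamma(self.gamma) if self.omega is None else np.asarray(self.omega, dtype=float)
        if om.shape != (3, 2):
            raise ValueError("omega must be a 3x2 matrix")
        a = np.asarray(self.alpha, dtype=float).reshape(3)
        if not np.all(np.isfinite(a)):
            raise ValueError("alpha must be finite")
        if self.r < 1:
            raise ValueError("power coefficient r must be >= 1")
        if self.theta_limit <= 0:
            raise ValueError("theta_limit must be positive")
        if self.n_neutral_frames < 1:
            raise ValueError("n_neutral_frames must be >= 1")
        object.__setattr__(self, "omega", om)
        object.__setattr__(self, "alpha", a)
        object.__setattr__(self, "q_neutral", np.asarray(self.q_neutral, dtype=float).reshape(2))


@dataclass(frozen=True)
class ViewpointState:
    """Accumulated viewpoint rotation θ = (θx, θy, θz), degrees, plus pivot."""

    theta: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pivot: PivotPose = field(default_factory=lambda: PivotPose.from_point((0.0, 0.0, 120.0)))

    def __post_init__(self) -> None:
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float).reshape(3))


def calibrate_neutral(q_samples, cfg: ControlConfig) -> ControlConfig:
    """Set the neutral position from start-up samples.

    q_neutral becomes the per-component mean of the first
    ``cfg.n_neutral_frames`` samples; raises if too few are supplied.
    """
    q = np.atleast_2d(np.asarray(q_samples, dtype=float))
    if len(q) < cfg.n_neutral_frames:
        raise ValueError(
            f"need at least {cfg.n_neutral_frames} samples for neutral calibration, got {len(q)}"
        )
    return replace(cfg, q_neutral=q[: cfg.n_neutral_frames].mean(axis=0))


def map_input(q, cfg: ControlConfig) -> np.ndarray:
    """Map one raw input sample to a rotation increment Δθ (degrees).

    Raw values are clamped to [−1, 1] per axis, referenced to the neutral
    position and multiplied by Ω. With the default Ω, Δθz is always 0.
    """
    qc = np.clip(np.asarray(q, dtype=float).reshape(2), -1.0, 1.0)
    return cfg.omega @ (qc - cfg.q_neutral)


def update_viewpoint(state: ViewpointState, dtheta, cfg: ControlConfig) -> ViewpointState:
    """Integrate one increment through the sign-preserving power law."""
    d = np.asarray(dtheta, dtype=float).reshape(3)
    step = cfg.alpha * np.sign(d) * np.abs(d) ** cfg.r
    theta = np.clip(state.theta + step, -cfg.theta_limit, cfg.theta_limit)
    return replace(state, theta=theta)


def reset_viewpoint(state: ViewpointState) -> ViewpointState:
    """Joystick-press reset: θ back to zero, pivot unchanged."""
    return replace(state, theta=np.zeros(3))


def replay_trace(q_trace, cfg: ControlConfig, state: ViewpointState | None = None) -> np.ndarray:
    """Run a recorded input trace through the full control loop.

    The first ``cfg.n_neutral_frames`` samples calibrate the neutral
    position (and do not move the viewpoint); every later sample is mapped
    and integrated. Returns the θ trajectory, one row per input sample.
    """
    q = np.atleast_2d(np.asarray(q_trace, dtype=float))
    cfg = calibrate_neutral(q, cfg)
    st = ViewpointState() if state is None else state
    traj = np.zeros((len(q), 3))
    for i, sample in enumerate(q):
        if i >= cfg.n_neutral_frames:
            st = update_viewpoint(st, map_input(sample, cfg), cfg)
        traj[i] = st.theta
    return traj
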