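"""EMG-driven Hill-type muscle force and joint torque.

The chain is: rectified-smoothed EMG u(t) in [0, 1] -> nonlinear neural
activation a(t) = (e^(A*u) - 1)/(e^A - 1) -> Hill-type muscle force
F = (f_l(l_m) * f_v(v_m) * a + f_p(l_m)) * F0 * cos(phi) -> joint torque
T_J = sum_i r_i * F_i (scalar moment arms, sagittal-plane convention).

The active/passive curve shapes f_l, f_v, f_p are standard phenomenological
defaults (Gaussian force-length, Hill hyperbola with a 1.4 eccentric
plateau, exponential passive element zero at optimal length); all are
swappable through :class:`HillParams`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

__all__ = [
    "HillParams",
    "MuscleAction",
    "emg_envelope",
    "activation_from_emg",
    "force_length",
    "force_velocity",
    "passive_force",
    "muscle_force",
    "joint_torque",
]


@dataclass
class HillParams:
    """Hill-model constants for one muscle.

    A_sh: nonlinear EMG-to-activation shape factor (nonzero; negative
    values give the usual concave recruitment curve). F0 in newtons,
    pennation in radians, optimal fiber length in mm, max shortening
    velocity in optimal lengths per second.
    """

    A_sh: float = -2.0
    F0: float = 600.0
    pennation: float = 0.0
    l_opt: float = 80.0
    fl_width: float = 0.45
    fv_af: float = 0.25
    fv_eccentric_plateau: float = 1.4
    fp_exponent: float = 10.0
    v_max_rel: float = 10.0

    def __post_init__(self) -> None:
        if self.A_sh == 0:
            raise ValueError("A_sh must be nonzero")
        if self.F0 <= 0:
            raise ValueError("F0 must be positive")
        if not 0 <= self.pennation < np.pi / 2:
            raise ValueError("pennation must be in [0, pi/2)")

    @property
    def v_max(self) -> float:
        """Maximum shortening velocity, mm/s."""
        return self.v_max_rel * self.l_opt


@dataclass
class MuscleAction:
    """State of one muscle at one instant: normalized EMG drive u in
    [0, 1], fiber length (mm), fiber velocity (mm/s, positive =
    lengthening) and scalar moment arm (m, signed by flexor/extensor
    convention)."""

    u: float
    l_m: float
    v_m: float = 0.0
    moment_arm: float = 0.04


def emg_envelope(emg: np.ndarray, fs: float, lowpass: float = 4.0,
                 order: int = 4) -> np.ndarray:
    """Normalized EMG drive u(t): rectify, zero-phase low-pass (4 Hz),
    scale to peak 1. Returns values in [0, 1]."""
    sos = sps.butter(order, lowpass, btype="lowpass", fs=fs, output="sos")
    env = sps.sosfiltfilt(sos, np.abs(np.asarray(emg, dtype=float)), axis=-1)
    env = np.clip(env, 0.0, None)
    peak = env.max()
    if peak == 0:
        raise ValueError("zero EMG envelope cannot be normalized")
    return env / peak


def activation_from_emg(u, A_sh: float):
    """Neural activation (e^(A_sh*u) - 1)/(e^A_sh - 1); a bijection of
    [0, 1] onto [0, 1] for any nonzero A_sh."""
    if A_sh == 0:
        raise ValueError("A_sh must be nonzero")
    u = np.asarray(u, dtype=float)
    if np.any((u < 0) | (u > 1)):
        raise ValueError("u must lie in [0, 1]")
    out = np.expm1(A_sh * u) / np.expm1(A_sh)
    return float(out) if out.ndim == 0 else out


def force_length(l_m, params: HillParams):
    """Active force-length curve exp(-((l/l_opt - 1)/width)^2), peak 1 at
    the optimal length."""
    l_rel = np.asarray(l_m, dtype=float) / params.l_opt
    out = np.exp(-(((l_rel - 1.0) / params.fl_width) ** 2))
    return float(out) if out.ndim == 0 else out


def force_velocity(v_m, params: HillParams):
    """Hill force-velocity factor, 1 at isometric (v=0).

    Shortening (v < 0): the classic hyperbola, reaching 0 at -v_max.
    Lengthening (v > 0): saturating rise to the eccentric plateau.
    """
    v = np.asarray(v_m, dtype=float)
    vmax, af = params.v_max, params.fv_af
    plateau = params.fv_eccentric_plateau
    shortening = np.clip((1.0 + v / vmax) / (1.0 - v / (af * vmax)), 0.0, None)
    lengthening = 1.0 + (plateau - 1.0) * v / (v + af * vmax)
    out = np.where(v < 0, shortening, lengthening)
    return float(out) if out.ndim == 0 else out


def passive_force(l_m, params: HillParams):
    """Parallel elastic force, zero at (and below) the optimal length."""
    l_rel = np.asarray(l_m, dtype=float) / params.l_opt
    k = params.fp_exponent
    out = np.clip(np.expm1(k * (l_rel - 1.0)), 0.0, None) / np.expm1(k / 2.0)
    return float(out) if out.ndim == 0 else out


def muscle_force(a, l_m, v_m, params: HillParams):
    """Hill-type force (N): (f_l*f_v*a + f_p) * F0 * cos(pennation)."""
    a = np.asarray(a, dtype=float)
    if np.any((a < 0) | (a > 1)):
        raise ValueError("activation must lie in [0, 1]")
    out = (
        force_length(l_m, params) * force_velocity(v_m, params) * a
        + passive_force(l_m, params)
    ) * params.F0 * np.cos(params.pennation)
    return float(out) if out.ndim == 0 else out


def joint_torque(actions: list[tuple[MuscleAction, HillParams]]):
    """Net joint torque sum_i r_i * F_i (N*m); additive over muscles."""
    total = 0.0
    for action, params in actions:
        f = muscle_force(activation_from_emg(action.u, params.A_sh),
                         action.l_m, action.v_m, params)
        total += action.moment_arm * f
    return total
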