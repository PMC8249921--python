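"""Coupled neural-mass simulation of motor-cortex EEG.

Three Jansen/Wendling-type neural mass models run in parallel — a low (L),
medium (M) and high (H) frequency rhythm generator — each describing four
interacting populations of a cortical column: pyramidal cells, excitatory
interneurons, slow (dendritic) inhibitory interneurons and fast (somatic)
inhibitory interneurons. Each population converts its mean membrane
potential into a firing rate through a sigmoid and feeds the others through
second-order synaptic impulse responses ``gain * rate * t * exp(-rate*t)``.
The summed pyramidal membrane potential is the simulated EEG.

A voluntary-movement intention enters as the stochastic drive P(t) (Gaussian
rate noise); around the intention onset a readiness-potential (RP) transient
— the slow pre-movement negativity of the motor cortex — is superimposed as
a ramp-and-recover kernel.

The fast-inhibitory population is integrated in the standard Wendling form
(rate constant g1 in its second-order term; membrane potential
v3 = C5*y0 - C6*y2); the model family's published equations are followed
where the source material's typography is internally inconsistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .signals import TimeSeriesSignal

__all__ = [
    "NMMParams",
    "RPConfig",
    "IntentionSchedule",
    "sigmoid_rate",
    "psp_kernel",
    "rp_kernel",
    "simulate_single_nmm",
    "simulate_cortex",
]

#: Connectivity constants shared by the L/M/H rhythm generators.
CONNECTIVITY = {
    "C1": 135.0,
    "C2": 108.0,
    "C3": 33.75,
    "C4": 33.75,
    "C5": 40.5,
    "C6": 13.5,
    "C7": 108.0,
}

_STATE_BOUND = 1e6  # mV; beyond this the integration is declared divergent


@dataclass
class NMMParams:
    """Parameters of one neural mass (one rhythm generator).

    Gains are in mV, rate constants in 1/s, the input drive P(t) is a
    firing rate in 1/s with mean ``m`` and variance ``sigma2``.
    """

    A: float          # excitatory synaptic gain (mV)
    B: float          # slow inhibitory synaptic gain (mV)
    G: float          # fast inhibitory synaptic gain (mV)
    a1: float         # excitatory rate constant (1/s)
    b1: float         # slow inhibitory rate constant (1/s)
    g1: float         # fast inhibitory rate constant (1/s)
    m: float          # mean of the drive P(t) (1/s)
    sigma2: float     # variance of the drive P(t) ((1/s)^2)
    C: dict = field(default_factory=lambda: dict(CONNECTIVITY))
    s0: float = 6.0   # sigmoid half-activation potential (mV)
    e0: float = 2.5   # half of the maximum population firing rate (1/s)
    r: float = 0.56   # sigmoid steepness (1/mV)

    def __post_init__(self) -> None:
        for name in ("a1", "b1", "g1", "e0", "r"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for key, val in self.C.items():
            if val < 0:
                raise ValueError(f"connectivity {key} must be non-negative")

    # Default parameter columns of the three rhythm generators.
    @classmethod
    def low(cls) -> "NMMParams":
        return cls(A=2.7, B=3.2, G=20.8, a1=40.0, b1=20.0, g1=300.0,
                   m=60.1, sigma2=61.0)

    @classmethod
    def medium(cls) -> "NMMParams":
        return cls(A=4.5, B=4.5, G=35.7, a1=85.0, b1=30.0, g1=350.0,
                   m=-20.6, sigma2=30.5)

    @classmethod
    def high(cls) -> "NMMParams":
        return cls(A=6.7, B=5.7, G=66.2, a1=140.0, b1=38.0, g1=790.0,
                   m=115.9, sigma2=69.0)


@dataclass
class RPConfig:
    """Readiness-potential transient: linear negative ramp of depth
    ``amplitude`` over ``rise_duration`` ending at the intention onset,
    then exponential recovery with ``recovery_time_constant``."""

    amplitude: float = -8.0            # mV (negative deflection depth)
    rise_duration: float = 1.5         # s
    recovery_time_constant: float = 0.5  # s
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.rise_duration <= 0:
            raise ValueError("rise_duration must be positive")
        if self.recovery_time_constant <= 0:
            raise ValueError("recovery_time_constant must be positive")


@dataclass
class IntentionSchedule:
    """Time course of the intention drive P(t).

    Outside the task window every model uses its own resting (m, sigma2);
    inside it the mean is multiplied by ``task_gain`` (default doubling).
    Explicit ``rest_input`` / ``task_input`` (m, sigma2) tuples override
    the per-model values for all models when given.
    """

    total_duration: float
    task_window: tuple[float, float]
    task_gain: float = 2.0
    rest_input: tuple[float, float] | None = None
    task_input: tuple[float, float] | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        start, end = self.task_window
        if not 0 <= start < end <= self.total_duration:
            raise ValueError(
                f"task window {self.task_window} must satisfy "
                f"0 <= start < end <= {self.total_duration}")


def sigmoid_rate(v, params: NMMParams):
    """Population firing rate 2*e0 / (1 + exp(r*(s0 - v))), in 1/s.

    Strictly increasing in the membrane potential ``v`` (mV) and bounded
    in (0, 2*e0).
    """
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("membrane potential must be finite")
    out = 2.0 * params.e0 / (1.0 + np.exp(params.r * (params.s0 - v)))
    return float(out) if out.ndim == 0 else out


def psp_kernel(kind: str, gain: float, rate: float, t):
    """Synaptic impulse response gain*rate*t*exp(-rate*t) for t > 0, else 0.

    ``kind`` is "excitatory" or "inhibitory" (the functional form is shared;
    the label is kept for config readability). Peaks at t = 1/rate with
    value gain/e and integrates to gain/rate.
    """
    if kind not in ("excitatory", "inhibitory"):
        raise ValueError(f"unknown kernel kind {kind!r}")
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, gain * rate * t * np.exp(-rate * np.clip(t, 0, None)), 0.0)
    return float(out) if out.ndim == 0 else out


def rp_kernel(t, rp: RPConfig):
    """Readiness-potential waveform, time-locked so the minimum is at t=0."""
    t = np.asarray(t, dtype=float)
    ramp = rp.amplitude * (t + rp.rise_duration) / rp.rise_duration
    rec = rp.amplitude * np.exp(-np.clip(t, 0, None) / rp.recovery_time_constant)
    out = np.where(t < -rp.rise_duration, 0.0, np.where(t < 0, ramp, rec))
    return float(out) if out.ndim == 0 else out


def _rhs(y, p_val, par: NMMParams):
    """Time derivative of the 8-dim state [y0..y3, y5..y8]."""
    C = par.C
    y0, y1, y2, y3, y5, y6, y7, y8 = y
    v0 = C["C2"] * y1 - C["C4"] * y2 - C["C7"] * y3
    v1 = C["C1"] * y0
    v2 = C["C3"] * y0
    v3 = C["C5"] * y0 - C["C6"] * y2
    two_e0, r, s0 = 2.0 * par.e0, par.r, par.s0

    def sig(v: float) -> float:
        arg = r * (s0 - v)
        if arg > 700.0:  # exp would overflow; the rate is numerically 0
            return 0.0
        return two_e0 / (1.0 + math.exp(arg))

    z0, z1, z2, z3 = sig(v0), sig(v1), sig(v2), sig(v3)
    a1, b1, g1 = par.a1, par.b1, par.g1
    return (
        y5,
        y6,
        y7,
        y8,
        par.A * a1 * z0 - 2.0 * a1 * y5 - a1 * a1 * y0,
        par.A * a1 * (z1 + p_val / C["C2"]) - 2.0 * a1 * y6 - a1 * a1 * y1,
        par.B * b1 * z2 - 2.0 * b1 * y7 - b1 * b1 * y2,
        par.G * g1 * z3 - 2.0 * g1 * y8 - g1 * g1 * y3,
    )


def simulate_single_nmm(params: NMMParams, p_series, fs: float,
                        initial=None, substeps: int = 1) -> np.ndarray:
    """Integrate one neural mass and return the pyramidal potential v0(t).

    The four-population second-order system is advanced with fixed-step
    RK4 at 1/fs; the drive sample p_series[k] is held constant over step k
    (and over its ``substeps`` refinements, so refining the step keeps the
    input realization fixed — the basis of the convergence check).

    Parameters
    ----------
    params : NMMParams
    p_series : array of drive values (1/s), one per output sample.
    fs : sampling rate, >= 500 Hz.
    initial : optional 8-vector [y0..y3, y5..y8]; zeros by default.
    substeps : integration substeps per output sample.

    Returns
    -------
    ndarray of v0 = C2*y1 - C4*y2 - C7*y3 per sample (mV).
    """
    if fs < 500:
        raise ValueError(f"fs must be >= 500 Hz, got {fs}")
    p_series = np.asarray(p_series, dtype=float)
    if p_series.ndim != 1 or p_series.size < 1:
        raise ValueError("p_series must be a non-empty 1-d sequence")
    y = tuple(float(v) for v in (initial if initial is not None else np.zeros(8)))
    if len(y) != 8:
        raise ValueError("initial state must have 8 entries")
    h = 1.0 / (fs * substeps)
    C = params.C
    out = np.empty(p_series.size)
    for k, p_val in enumerate(p_series):
        out[k] = C["C2"] * y[1] - C["C4"] * y[2] - C["C7"] * y[3]
        for _ in range(substeps):
            k1 = _rhs(y, p_val, params)
            k2 = _rhs(tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k1)), p_val, params)
            k3 = _rhs(tuple(yi + 0.5 * h * ki for yi, ki in zip(y, k2)), p_val, params)
            k4 = _rhs(tuple(yi + h * ki for yi, ki in zip(y, k3)), p_val, params)
            y = tuple(
                yi + (h / 6.0) * (a + 2.0 * b + 2.0 * c + d)
                for yi, a, b, c, d in zip(y, k1, k2, k3, k4)
            )
        if not all(abs(v) < _STATE_BOUND for v in y):
            raise FloatingPointError(
                f"neural mass integration diverged at sample {k} "
                f"(t={k / fs:.3f} s) with params A={params.A}, B={params.B}, "
                f"G={params.G}")
    return out


def _drive_series(params: NMMParams, schedule: IntentionSchedule, fs: float,
                  rng: np.random.Generator) -> np.ndarray:
    n = int(round(schedule.total_duration * fs))
    t = np.arange(n) / fs
    rest_m, rest_s2 = (schedule.rest_input if schedule.rest_input is not None
                       else (params.m, params.sigma2))
    task_m, task_s2 = (schedule.task_input if schedule.task_input is not None
                       else (schedule.task_gain * params.m, params.sigma2))
    start, end = schedule.task_window
    in_task = (t >= start) & (t < end)
    mean = np.where(in_task, task_m, rest_m)
    sd = np.sqrt(np.where(in_task, task_s2, rest_s2))
    return mean + sd * rng.standard_normal(n)


def simulate_cortex(models: dict[str, NMMParams] | None = None,
                    schedule: IntentionSchedule | None = None,
                    rp: RPConfig | None = None,
                    fs: float = 1000.0,
                    weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                    seed: int | None = None,
                    channel_label: str = "Cz") -> TimeSeriesSignal:
    """Simulate one motor-cortex EEG channel from the parallel L/M/H masses.

    Each rhythm generator receives its own seeded Gaussian drive P(t)
    (mean/variance from its parameters, modulated by the intention
    schedule); outputs are combined with ``weights`` and, if enabled, the
    readiness-potential kernel is added time-locked to the task-window
    start. A trigger marks the onset.
    """
    if models is None:
        models = {"L": NMMParams.low(), "M": NMMParams.medium(),
                  "H": NMMParams.high()}
    if schedule is None:
        schedule = IntentionSchedule(total_duration=10.0, task_window=(5.0, 8.0))
    if rp is None:
        rp = RPConfig()
    seeds = np.random.SeedSequence(seed if seed is not None else schedule.seed)
    children = seeds.spawn(len(models))
    n = int(round(schedule.total_duration * fs))
    total = np.zeros(n)
    for (name, par), w, child in zip(models.items(), weights, children):
        if w == 0.0:
            continue
        rng = np.random.default_rng(child)
        p = _drive_series(par, schedule, fs, rng)
        total += w * simulate_single_nmm(par, p, fs)
    onset = schedule.task_window[0]
    if rp.enabled:
        t = np.arange(n) / fs
        total += rp_kernel(t - onset, rp)
    onset_idx = int(round(onset * fs))
    triggers = [(onset_idx, "onset")] if 0 <= onset_idx < n else []
    return TimeSeriesSignal(data=total[np.newaxis, :], fs=fs,
                            channel_labels=[channel_label], unit="mV",
                            triggers=triggers)
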