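"""Ionic circuit model of the neuromuscular junction (NMJ).

The endplate membrane is a two-node circuit: four parallel ionic branches
(K+, Na+, Cl-, Ca2+), each an equilibrium-potential battery in series with
a conductance, shunted by the membrane capacitance. Equilibrium potentials
come from the Nernst relation; the resting potential is the
conductance-weighted mean of the branch potentials (zero net current); the
multi-ion steady state is also available through a
Goldman-Hodgkin-Katz-style voltage equation. Driving the membrane with a
raised-cosine stimulus (a smooth surrogate for the incoming nerve action
potential) reproduces the endplate-potential time course, whose peak lags
the stimulus peak because the capacitance must charge — the synaptic
conversion delay this model is built to expose.

Units: potentials mV, conductances mS/cm^2, capacitance uF/cm^2,
concentrations mM, stimulus current uA/cm^2 (so I/g is in mV), time s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .signals import TimeSeriesSignal

__all__ = [
    "IonBranch",
    "MembraneModel",
    "nernst",
    "resting_potential",
    "ghk_voltage",
    "stimulus_waveform",
    "simulate_endplate",
    "default_membrane",
]

GAS_CONSTANT = 8.314       # J/(mol K)
FARADAY = 96485.0          # C/mol

_VALENCE = {"K": 1, "Na": 1, "Cl": -1, "Ca": 2}


def nernst(z: int, conc_out: float, conc_in: float, temperature: float = 310.0) -> float:
    """Single-ion equilibrium potential (R*T)/(z*F) * ln(Co/Ci), in mV."""
    if conc_out <= 0 or conc_in <= 0:
        raise ValueError("concentrations must be positive")
    if z == 0:
        raise ValueError("valence must be nonzero")
    return 1e3 * GAS_CONSTANT * temperature / (z * FARADAY) * np.log(conc_out / conc_in)


@dataclass
class IonBranch:
    """One ionic branch: species, trans-membrane concentrations (mM),
    conductance (mS/cm^2) and relative permeability (dimensionless).

    ``equilibrium_potential`` (mV) is derived from the Nernst relation
    unless fixed explicitly.
    """

    species: str
    conc_out: float
    conc_in: float
    conductance: float
    permeability: float = 0.0
    equilibrium_potential: float | None = None

    def __post_init__(self) -> None:
        if self.species not in _VALENCE:
            raise ValueError(f"unknown species {self.species!r}")
        if self.conc_out <= 0 or self.conc_in <= 0:
            raise ValueError("concentrations must be positive")
        if self.conductance < 0 or self.permeability < 0:
            raise ValueError("conductance and permeability must be >= 0")

    @property
    def valence(self) -> int:
        return _VALENCE[self.species]

    def potential(self, temperature: float = 310.0) -> float:
        if self.equilibrium_potential is not None:
            return self.equilibrium_potential
        return nernst(self.valence, self.conc_out, self.conc_in, temperature)


@dataclass
class MembraneModel:
    """Parallel-conductance endplate membrane."""

    branches: list[IonBranch]
    capacitance: float = 1.0     # uF/cm^2
    temperature: float = 310.0   # K

    def __post_init__(self) -> None:
        if self.capacitance <= 0 or self.temperature <= 0:
            raise ValueError("capacitance and temperature must be positive")
        if not self.branches:
            raise ValueError("need at least one ionic branch")

    def branch(self, species: str) -> IonBranch:
        for b in self.branches:
            if b.species == species:
                return b
        raise KeyError(species)

    @property
    def total_conductance(self) -> float:
        return sum(b.conductance for b in self.branches)


def default_membrane() -> MembraneModel:
    """Default endplate membrane.

    Concentrations are a calibration table, not measured physiology: they
    are chosen (at 310 K, with physiological intracellular anchors) so the
    Nernst potentials reproduce E_K = -91.2, E_Na = +75.8, E_Cl = -123.8
    and E_Ca = +123.1 mV to within 1 mV. Conductance ratios
    g_K:g_Na:g_Cl:g_Ca = 1.0:0.04:0.45:0.01 mS/cm^2 are resting-state
    defaults, exposed through the config.
    """
    return MembraneModel(
        branches=[
            IonBranch("K", conc_out=4.60, conc_in=140.0, conductance=1.0,
                      permeability=1.0),
            IonBranch("Na", conc_out=170.8, conc_in=10.0, conductance=0.04,
                      permeability=0.04),
            IonBranch("Cl", conc_out=123.6, conc_in=1.2, conductance=0.45,
                      permeability=0.45),
            IonBranch("Ca", conc_out=2.01, conc_in=0.0002, conductance=0.01,
                      permeability=0.01),
        ],
        capacitance=1.0,
        temperature=310.0,
    )


def resting_potential(model: MembraneModel) -> float:
    """Zero-net-current membrane potential sum(Ei*gi)/sum(gi), in mV.

    A convex combination of the branch equilibrium potentials, hence always
    within [min Ei, max Ei] and invariant to uniform conductance scaling.
    """
    g = np.array([b.conductance for b in model.branches])
    if g.sum() <= 0:
        raise ValueError("all conductances are zero")
    e = np.array([b.potential(model.temperature) for b in model.branches])
    return float(np.dot(e, g) / g.sum())


def ghk_voltage(model: MembraneModel, strict_mode: bool = False) -> float:
    """Multi-ion steady-state potential from permeability-weighted
    concentrations.

    The default evaluates the constant-field expression with every species
    entered with the same (cation) orientation, divalent Ca2+ included in
    the monovalent form — the formulation this simulator is built around.
    ``strict_mode=True`` instead applies the textbook GHK convention, where
    the anion (Cl-) enters with inside/outside concentrations swapped.
    """
    perms = [b.permeability for b in model.branches]
    if any(p < 0 for p in perms) or not any(p > 0 for p in perms):
        raise ValueError("need non-negative permeabilities, at least one > 0")
    num = 0.0
    den = 0.0
    for b in model.branches:
        if strict_mode and b.valence < 0:
            num += b.permeability * b.conc_in
            den += b.permeability * b.conc_out
        else:
            num += b.permeability * b.conc_out
            den += b.permeability * b.conc_in
    if den == 0:
        raise ValueError("zero denominator in GHK expression")
    return float(1e3 * GAS_CONSTANT * model.temperature / FARADAY * np.log(num / den))


def stimulus_waveform(t, onset: float, duration: float, peak: float):
    """Raised-cosine stimulus pulse (smooth action-potential surrogate).

    peak * 0.5 * (1 - cos(2*pi*(t-onset)/duration)) inside
    [onset, onset+duration], zero outside; continuous everywhere and
    integrating to peak*duration/2.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    t = np.asarray(t, dtype=float)
    phase = (t - onset) / duration
    inside = (phase >= 0) & (phase <= 1)
    out = np.where(inside, 0.5 * peak * (1.0 - np.cos(2.0 * np.pi * phase)), 0.0)
    return float(out) if out.ndim == 0 else out


def simulate_endplate(model: MembraneModel, stimulus, fs: float) -> TimeSeriesSignal:
    """Endplate potential under a stimulus current series.

    Integrates Cm * dVm/dt = -sum_i gi*(Vm - Ei) + I(t) from
    Vm(0) = resting potential. The ODE is linear, so each step uses the
    exact exponential update (stimulus held constant over the step):
    Vm <- Vinf + (Vm - Vinf) * exp(-dt/tau) with tau = Cm/sum(g) and
    Vinf = resting + I/sum(g). Bit-stable; with zero stimulus the
    trajectory is constant at the resting potential.
    """
    if fs < 1000:
        raise ValueError(f"fs must be >= 1 kHz, got {fs}")
    stimulus = np.asarray(stimulus, dtype=float)
    g_total = model.total_conductance
    v_rest = resting_potential(model)
    # tau in seconds: (uF/cm^2) / (mS/cm^2) = ms
    tau = model.capacitance / g_total * 1e-3
    decay = np.exp(-1.0 / (fs * tau))
    vm = np.empty(stimulus.size)
    v = v_rest
    for k, i_stim in enumerate(stimulus):
        vm[k] = v
        v_inf = v_rest + i_stim / g_total
        v = v_inf + (v - v_inf) * decay
        if not np.isfinite(v) or abs(v) > 1e6:
            raise FloatingPointError(f"endplate integration diverged at step {k}")
    return TimeSeriesSignal(data=vm[np.newaxis, :], fs=fs,
                            channel_labels=["Vm"], unit="mV")
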