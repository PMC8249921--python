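# Methods

This note documents the models, their parameters and the numerical and
design choices behind `cmcsim`. Nothing here states an empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Cortical EEG: coupled neural masses

Each rhythm generator is a four-population neural mass (pyramidal cells,
excitatory, slow-inhibitory and fast-inhibitory interneurons). Population
firing follows the sigmoid `z(v) = 2 e0 / (1 + exp(r (s0 − v)))` with
`e0 = 2.5 s⁻¹`, `s0 = 6 mV`, `r = 0.56 mV⁻¹`; synapses are second-order
kernels `gain · rate · t · e^{−rate·t}` (excitatory A/a1, slow inhibitory
B/b1, fast inhibitory G/g1). The state equations are, with connectivities
C1–C7 (C1 = 135, C2 = C7 = 108, C3 = C4 = 33.75, C5 = 40.5, C6 = 13.5):

    y0'' = A a1 z(v0) − 2 a1 y0' − a1² y0        v0 = C2 y1 − C4 y2 − C7 y3
    y1'' = A a1 (z(v1) + P/C2) − 2 a1 y1' − a1² y1   v1 = C1 y0
    y2'' = B b1 z(v2) − 2 b1 y2' − b1² y2        v2 = C3 y0
    y3'' = G g1 z(v3) − 2 g1 y3' − g1² y3        v3 = C5 y0 − C6 y2

The fast-inhibitory population uses the standard Wendling form (g1² in its
second-order term, membrane potential v3 = C5 y0 − C6 y2); the `P/C2`
scaling of the external drive makes the system algebraically identical to
the classic Jansen formulation once the connectivities are moved into the
v-definitions. The simulated EEG is v0, summed over the three generators
L/M/H with unit weights (configurable):

| parameter | L | M | H |
|---|---|---|---|
| A (mV) | 2.7 | 4.5 | 6.7 |
| B (mV) | 3.2 | 4.5 | 5.7 |
| G (mV) | 20.8 | 35.7 | 66.2 |
| a1 (s⁻¹) | 40 | 85 | 140 |
| b1 (s⁻¹) | 20 | 30 | 38 |
| g1 (s⁻¹) | 300 | 350 | 790 |
| m (s⁻¹) | 60.1 | −20.6 | 115.9 |
| σ² (s⁻²) | 61 | 30.5 | 69 |

The M generator's mean drive is negative as printed in the reference
parameterization; it is implemented as printed. P(t) is white Gaussian rate
noise N(m, σ²) per sample, held constant across integrator substeps. The
intention schedule multiplies each generator's mean by `task_gain`
(default 2) inside the task window — the time-varying activation that
distinguishes movement intention from rest.

**Readiness potential.** The RP generator behind the reference model is not
available in closed form, so the package ships a surrogate kernel: a linear
negative ramp of depth −8 mV over 1.5 s ending at the intention onset,
followed by exponential recovery with a 0.5 s time constant. These defaults
produce the qualitative drop-and-recover morphology; they are surrogates,
not fitted values (see Limitations).

**Integration.** Fixed-step RK4 at the EEG sampling rate (1 kHz), states
initialized to zero, divergence guard at |state| > 10⁶ mV. Convergence is
verified in the tests: refining the step 2× or 10× changes a 2 s
M-parameter run by < 10⁻³ mV RMS. With constant drive the simulation
settles onto the algebraic fixed point of the state equations (verified
against `scipy.optimize.fsolve` root-finding), and the classic
alpha-rhythm parameterization (A = 3.25, B = 22, a = 100, b = 50, C = 135,
constant drive 220 s⁻¹, fast loop disabled) oscillates at 8–12 Hz.

## Neuromuscular junction

Four ionic branches (K⁺, Na⁺, Cl⁻, Ca²⁺) in parallel with a 1 µF/cm²
membrane capacitance. Equilibrium potentials come from the Nernst relation
at 310 K. The shipped concentration table is a *calibration*, not measured
physiology: intracellular anchors are physiological (140 mM K, 10 mM Na,
1.2 mM Cl, 0.2 µM Ca) and the extracellular values are set so the Nernst
potentials reproduce the reference equilibria E_K = −91.2, E_Na = +75.8,
E_Cl = −123.8, E_Ca = +123.1 mV within 1 mV. Branch conductances
(1.0 : 0.04 : 0.45 : 0.01 mS/cm² for K:Na:Cl:Ca) are resting-state
defaults standing in for I–V-derived values that are not published;
all are exposed in the config.

The GHK voltage equation is provided in two forms: the default enters every
species with cation orientation (divalent Ca²⁺ inside the monovalent
expression), matching the formulation this simulator is built around;
`strict_mode=True` applies the textbook convention with the anion's
concentrations swapped.

The endplate ODE `Cm V' = −Σ gᵢ(V − Eᵢ) + I(t)` is linear, so each step
uses the exact exponential update (stimulus held constant over the step) —
bit-stable, with the RC constant τ = Cm/Σg reproduced within 2% in the
step-response test. The stimulus surrogate for the arriving nerve action
potential is a raised-cosine pulse; the simulated endplate peak lags the
stimulus peak for any Cm > 0, which is the synaptic conversion delay the
model exposes.

## Surface EMG

The muscle is a 45 mm-diameter cylinder at 80 fibers/mm² (127,235 fibers,
the unique round density consistent with the reference geometry),
partitioned uniformly at random into 120 motor units. Each fiber is a line
source of length 120 mm with its innervation point at mid-fiber ± 5 mm
(uniform); the intracellular action potential is the Rosenfalck waveform
`e(u) = 96 u³ e^{−u} − 90` mV with u = v_scale·t and v_scale defaulting to
the conduction velocity in mm/ms, so the travelling spatial profile is the
millimetre-scale Rosenfalck shape. The extracellular potential is

    V_f(t) = s σi/(4π σm) ∫ ∂e/∂z · ∂(1/r_a)/∂z dz,
    r_a = √((σz/σx) ρ² + (z − z_e)²)

discretized by the trapezoid rule at dz = 0.5 mm (the dz/10 refinement
changes waveforms by < 1% peak-to-peak), with bidirectional propagation at
4 m/s. Defaults: s = 2,300 µm², σi = 1.01, σm = σx = 0.1, σz = 0.5 S/m;
electrode at (0, 5, 30) mm in a frame centred on the innervation-zone
centre on the muscle axis (5 mm radial, 30 mm along the fibers), with a
0.5 mm minimum fiber–electrode clearance enforced at placement.

Per-unit MUAP templates are computed once by grouping a unit's fibers by
their grid-snapped innervation offset (half-step 0.25 mm accuracy) and
summing their distance-weighting profiles — this turns 127k line-source
integrals into ~21 small matrix products per unit. Unit mean rates are
drawn from a Poisson distribution truncated to [8, 50] Hz whose rate
parameter is calibrated numerically (λ ≈ 11.24) so the truncated mean is
exactly 12 Hz — naive truncation of Poisson(12) would inflate the mean.
Spike trains are Poisson renewal processes (no refractory period) inside
the burst window; recruitment is all-units-on. The synthesis is linear:
disjoint unit subsets sum exactly to the full trace under a shared seed.

## EMG → torque

The drive u(t) is the rectified, 4 Hz zero-phase low-passed, peak-normalized
EMG. Activation is `(e^{A u} − 1)/(e^A − 1)` (default A = −2), a bijection
of [0, 1] for any A ≠ 0. The Hill curves are standard phenomenological
defaults, all swappable: Gaussian force–length
`exp(−((l/l_opt − 1)/0.45)²)`; Hill hyperbola force–velocity normalized to
1 at isometric with a 1.4 eccentric plateau; exponential passive element
zero at and below the optimal length. Torque is the scalar moment-arm sum
(sagittal-plane convention).

## Wavelet coherence

Morlet mother with ω0 = 6 in the L²-normalized convention
(W(a,b) = a^{−1/2} ∫ x ψ*((t−b)/a) dt); the geometric scale grid has 12
voices per octave covering 0.5–45 Hz (the grid contains 1.000 Hz exactly),
with the standard mapping f = (ω0 + √(2+ω0²))/(4π a). The CWT is an FFT
convolution of the sampled, ±5-scale-truncated kernel; the test suite
checks it against a literal O(N²) time-domain convolution to 10⁻⁸ relative
error. Smoothing is a Gaussian along time with width equal to the scale
(kernel ∝ exp(−t²/2a²)) followed by a boxcar along scale of width 0.6 a;
both kernels are renormalized to unit *local* mass so a constant field is
unchanged everywhere including the record edges, and the coherence

    Wco = |S(W_x W_y*)| / √(S(|W_x|²) S(|W_y|²))

lies in [0, 1] by Cauchy–Schwarz (zero-power cells are flagged and set to
0, never NaN). The cross-spectrum is conjugated (W_x W_y*) so a positive
phase means the first signal leads. Edge handling is zero padding plus a
cone of influence at the √2·a e-folding time.

Two estimator details matter in practice. First, the scale grid is
internally extended by half a boxcar width beyond both band edges (record
length permitting) and trimmed after smoothing: without this the edge rows
receive a truncated scale-smoothing window, carry a higher small-sample
coherence bias, and spuriously attract the argmax. Second, significance
contours are available as an optional Monte-Carlo AR(1)-surrogate test
(300 repetitions, α = 0.05); the reference analysis method is not
published, so this is an add-on, not a reproduction.

## Homology experiments and the synthetic session

In a homology scenario the cortical intention keeps a fixed mid-record
onset (5 s: task drive and RP) while only the EMG burst onset moves —
2 s (early), 5 s (middle) or 7 s (late) with a 3 s duration inside a 10 s
record. The EMG burst is z-scored, padded with resting noise (1% of task
RMS) to the full record, and polyphase-resampled from 2 kHz to the common
1 kHz grid. Coherence is computed between the EEG and the **rectified**
standardized EMG: a zero-mean broadband burst carries its movement-locked
structure in its amplitude envelope, and rectification is what exposes that
envelope to the ≤2 Hz scales (this is also standard practice in
corticomuscular-coherence analysis). The phase summary flips the EEG sign
first, because the movement-related EEG component is a negativity while the
rectified muscle drive is positive; with matched polarity, positive phase
= cortex leads.

Under these conditions the middle scenario shows strong (≈0.8–0.9)
EEG-leading coherence confined to the ≤2 Hz scales in the 5–7 s window,
while the early scenario's strongest low-frequency coherence misses the
burst window (< 0.5 overlap) and the late scenario's begins before its
burst — coherence inconsistent with the EMG response time, as expected
when the muscle response is placed against the wrong intention time.

**Where the peak lands.** The argmax frequency of the window-averaged
coherence is bimodal across seeds (≈0.63 Hz or ≈1.1–1.4 Hz). Both ridges
are spectral lobes of the deterministic movement-locked transients, whose
positions follow directly from the RP surrogate's time constants (1.5 s
ramp → lobes around 0.6–0.7 and 1.1–1.3 Hz). The qualitative statement —
coherence concentrated near 1 Hz at movement onset — is robust; the exact
winning grid bin is not, and should not be over-interpreted for any RP
waveform that is itself a surrogate.

The synthetic session generator emulates the recording protocol: 8
motor-cortex EEG channels and 2 tibialis-anterior EMG channels at 1 kHz,
15 sessions × 5 repetitions with ≥10 s breaks (enforced), triggers at each
onset. One latent intention drive per repetition expresses itself twice:
as the RP negativity in every EEG channel (one shared coupled-NMM cortical
source plus independent per-channel sensor noise at 0.5× source SD), and —
`delay` seconds later (default 100 ms, the order of corticomuscular
conduction) — as the *intensity envelope* of a motor-unit EMG burst, on a
resting floor of 5% burst RMS. The envelope is the mirrored RP kernel, so
the two low-frequency transients are shape-matched and the coherence phase
at the dominant low-frequency scale encodes exactly the planted delay;
with unmatched shapes the phase estimate would carry a waveform-dependent
bias of the order of the transient asymmetry (hundreds of ms), swamping a
100 ms delay. Consequently the envelope *peaks* (rather than starts) Δ
after the RP minimum. `recover_delay` inverts the construction blind:
epoch ±3 s around triggers, coherence of the polarity-flipped channel-mean
EEG against the rectified standardized EMG per epoch, dominant scale below
2 Hz within ±1 s of onset, circular-mean phase over epochs divided by 2πf.

## What the synthetic data does and does not show

The generators reproduce the mechanistic structure of a real recording —
rhythmic EEG background with an onset-locked negativity, broadband EMG
bursts with physiologic amplitude (≤10 mV) and bandwidth (95% of power
below ~300–400 Hz), trigger jitter-free session layout — but not volume
conduction across scalp channels, artifacts (EOG, motion, line noise
beyond a test tone), fatigue or rate-coding changes within bursts, ordered
recruitment by motor-unit size, or inter-subject variability. Passing
tests therefore certify the algorithms (simulators, coherence estimator,
delay recovery) under known ground truth, not performance on any
particular human dataset.

## Problem sizes used by the test suite

Simulation lengths are chosen to make each check statistically decisive at
desk scale: 2–10 s neural-mass runs; the full 127k-fiber muscle for the
amplitude/bandwidth checks (10 seeds) and a reduced 8–10 mm muscle
(~1.6–5k fibers, 16–25 units) for superposition/recruitment properties;
sessions of 2 × 5 repetitions (10 epochs) for delay recovery at 3 seeds
per planted delay; 20-seed surrogate batches for the envelope-coupling
delay check. These sizes are the package's chosen defaults for its own
verification and are stated here so they can be scaled up.

## Known limitations

- The RP waveform and the L/M/H coupling ("deployed in parallel") are
  under-specified upstream; unit-weight summation and the piecewise RP
  kernel are this package's choices, exposed in config.
- NMJ branch conductances and concentrations are calibrations, not
  measurements; the GHK default deliberately keeps a non-standard anion
  orientation for fidelity, with `strict_mode` for the textbook form.
- EMG amplitude depends strongly on electrode geometry; with the default
  5 mm radial offset the simulated maxima (~1–2 mV) sit at the low end of
  the 0–10 mV physiologic envelope.
- EDF files can be read (via `mne`) but not written; CSV is the canonical
  interchange format.
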