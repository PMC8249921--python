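"""End-to-end homology experiments: simulated EEG/EMG coherence and
synthetic recording sessions.

``run_homology_simulation`` reproduces the desk-scale homology study: a
10 s motor-cortex EEG from the coupled L/M/H neural masses (with the
readiness potential at the intention onset), a 3 s surface-EMG burst whose
onset is placed early (2 s), middle (5 s) or late (7 s), normalization and
rest-padding of the EMG, and the wavelet coherence of the pair. The
summary statistics are the frequency of maximal time-averaged coherence in
the post-onset window and the EEG-vs-EMG phase there.

``generate_synthetic_session`` emulates a recording session (8 motor-cortex
EEG channels + 2 tibialis-anterior EMG channels at 1 kHz, repeated
movements with >= 10 s breaks) with a *known* cortico-muscular delay: one
latent intention drive per repetition expresses itself as an RP negativity
in the EEG and, ``delay`` seconds later, as the intensity envelope of a
motor-unit EMG burst. ``recover_delay`` estimates that delay back from the
data through the coherence phase at the dominant low-frequency scale —
the parameter-recovery loop that certifies the phase-lead analysis.

Coherence is always computed between the EEG and the *rectified*
standardized EMG: a zero-mean broadband burst carries its movement-locked
low-frequency structure in its amplitude envelope, and rectification is
what exposes that envelope to the 1 Hz wavelet scales.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import emg as emg_mod
from . import nmm as nmm_mod
from .coherence import (CoherenceMap, WaveletParams, peak_coherence_frequency,
                        phase_lead, wavelet_coherence)
from .signals import TimeSeriesSignal, epoch, normalize_and_pad, resample_to

__all__ = [
    "HomologyScenario",
    "SessionLayout",
    "SyntheticSession",
    "run_homology_simulation",
    "generate_synthetic_session",
    "recover_delay",
    "write_summary",
]

EEG_CHANNELS = ["FC1", "FC2", "C1", "C2", "CP1", "CP2", "Cz", "FCz"]
EMG_CHANNELS = ["TA_L", "TA_R"]


@dataclass
class HomologyScenario:
    """One homology simulation: EMG burst onset within a 10 s EEG record."""

    eeg_duration: float = 10.0
    emg_onset: float = 5.0        # early 2 s / middle 5 s / late 7 s
    emg_duration: float = 3.0
    intention_onset: float = 5.0  # EEG intention (RP, task drive) is fixed
    fs_common: float = 1000.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.emg_onset + self.emg_duration > self.eeg_duration:
            raise ValueError("EMG burst must end within the EEG record")
        if self.emg_onset < 0:
            raise ValueError("emg_onset must be non-negative")
        if not 0 <= self.intention_onset < self.eeg_duration:
            raise ValueError("intention_onset must lie inside the record")

    @classmethod
    def early(cls, **kw) -> "HomologyScenario":
        return cls(emg_onset=2.0, **kw)

    @classmethod
    def middle(cls, **kw) -> "HomologyScenario":
        return cls(emg_onset=5.0, **kw)

    @classmethod
    def late(cls, **kw) -> "HomologyScenario":
        return cls(emg_onset=7.0, **kw)


def run_homology_simulation(scenario: HomologyScenario,
                            models: dict | None = None,
                            rp: nmm_mod.RPConfig | None = None,
                            muscle: emg_mod.MuscleModel | None = None,
                            firing: emg_mod.FiringModel | None = None,
                            electrode: emg_mod.ElectrodePoint | None = None,
                            wavelet: WaveletParams | None = None,
                            emg_fs: float = 2000.0) -> dict:
    """Simulate EEG + EMG for one scenario and measure their coherence.

    Returns a dict with the coherence map, the post-onset peak frequency
    and phase (positive = EEG leads), and the resampled input signals.
    """
    ss = np.random.SeedSequence(scenario.seed)
    eeg_seed, emg_seed, pad_seed = [s.generate_state(1)[0] % (2 ** 31)
                                    for s in ss.spawn(3)]
    onset = scenario.emg_onset
    # The cortical intention keeps its own time course; only the EMG onset
    # moves between scenarios. The early/late placements are therefore
    # deliberately inconsistent with the EEG response.
    schedule = nmm_mod.IntentionSchedule(
        total_duration=scenario.eeg_duration,
        task_window=(scenario.intention_onset,
                     min(scenario.intention_onset + scenario.emg_duration,
                         scenario.eeg_duration)))
    eeg = nmm_mod.simulate_cortex(models=models, schedule=schedule, rp=rp,
                                  fs=scenario.fs_common, seed=int(eeg_seed))
    burst = emg_mod.surface_emg(muscle=muscle, firing=firing,
                                electrode=electrode, fs=emg_fs,
                                duration=scenario.emg_duration,
                                seed=int(emg_seed))
    padded = normalize_and_pad(
        burst, pad_pre=onset,
        pad_post=scenario.eeg_duration - onset - scenario.emg_duration,
        seed=int(pad_seed))
    emg_common = resample_to(padded, scenario.fs_common)
    n = min(eeg.n_samples, emg_common.n_samples)
    emg_rect = np.abs(emg_common.data[0, :n])
    # Polarity: the movement-related EEG component is a negativity, the
    # rectified EMG drive a positivity; the phase of the lead/lag is read
    # with matched polarity (EEG sign flipped). Coherence magnitude is
    # unaffected.
    cmap = wavelet_coherence(-eeg.data[0, :n], emg_rect, wavelet,
                             fs=scenario.fs_common)
    window = (onset, min(onset + 2.0, scenario.eeg_duration))
    peak_f = peak_coherence_frequency(cmap, window)
    phase = phase_lead(cmap, peak_f, window)
    return {
        "map": cmap,
        "peak_frequency": peak_f,
        "phase": phase,
        "window": window,
        "eeg": eeg,
        "emg": emg_common,
    }


def write_summary(result: dict, path) -> None:
    """One-row CSV with the scenario's homology statistics."""
    import pandas as pd

    pd.DataFrame([{
        "window_start_s": result["window"][0],
        "window_end_s": result["window"][1],
        "peak_coherence_frequency_hz": result["peak_frequency"],
        "phase_lead_rad": result["phase"],
    }]).to_csv(path, index=False)


# ------------------------------------------------------------------ sessions

@dataclass
class SessionLayout:
    """Timing of the synthetic experiment: repetitions within sessions,
    separated by rest breaks (>= 10 s, as in the protocol)."""

    n_sessions: int = 15
    reps_per_session: int = 5
    break_s: float = 10.0
    movement_s: float = 2.5
    inter_session_rest_s: float = 10.0
    lead_in_s: float = 5.0

    def __post_init__(self) -> None:
        if self.break_s < 10.0:
            raise ValueError("break between repetitions must be >= 10 s")
        if self.n_sessions < 1 or self.reps_per_session < 1:
            raise ValueError("need at least one session and one repetition")

    def onsets(self) -> np.ndarray:
        """Movement-onset times (s) for every repetition."""
        t = self.lead_in_s
        out = []
        for s in range(self.n_sessions):
            for _ in range(self.reps_per_session):
                t += self.break_s
                out.append(t)
                t += self.movement_s
            t += self.inter_session_rest_s
        return np.asarray(out)

    def total_duration(self) -> float:
        return float(self.onsets()[-1] + self.movement_s + self.break_s)


@dataclass
class SyntheticSession:
    """A generated recording: 8-channel EEG + 2-channel EMG at 1 kHz with
    movement-onset triggers and the known planted delay."""

    eeg: TimeSeriesSignal
    emg: TimeSeriesSignal
    planted_delay: float
    layout: SessionLayout


def _envelope(t, rp: nmm_mod.RPConfig, delay: float) -> np.ndarray:
    """EMG intensity envelope: the mirrored RP kernel, ``delay`` s later.

    One latent drive, two expressions: the cortical negativity peaks at the
    onset, the muscle drive peaks ``delay`` later with the same waveform,
    so the coherence phase at low frequencies encodes exactly the delay.
    """
    return -nmm_mod.rp_kernel(np.asarray(t) - delay, rp) / abs(rp.amplitude)


def generate_synthetic_session(delay: float = 0.1,
                               layout: SessionLayout | None = None,
                               muscle: emg_mod.MuscleModel | None = None,
                               firing: emg_mod.FiringModel | None = None,
                               rp: nmm_mod.RPConfig | None = None,
                               models: dict | None = None,
                               fs: float = 1000.0,
                               eeg_channel_noise: float = 0.5,
                               emg_rest_level: float = 0.05,
                               rp_gain: float = 1.0,
                               seed: int | None = None) -> SyntheticSession:
    """Generate one synchronized EEG/EMG recording with a planted delay.

    EEG: one coupled-NMM cortical source (stationary drive, RP disabled)
    shared by the 8 channels, plus independent per-channel sensor noise
    (``eeg_channel_noise`` x source SD), plus the RP kernel at every onset.
    EMG: per channel, motor-unit burst noise under the delayed-drive
    envelope on a resting floor of ``emg_rest_level`` x burst RMS.
    """
    if delay < 0:
        raise ValueError("delay must be non-negative")
    layout = layout if layout is not None else SessionLayout()
    rp = rp if rp is not None else nmm_mod.RPConfig()
    muscle = muscle if muscle is not None else emg_mod.MuscleModel()
    firing = firing if firing is not None else emg_mod.FiringModel()
    ss = np.random.SeedSequence(seed)
    s_cortex, s_chan, s_emg = ss.spawn(3)

    duration = layout.total_duration()
    onsets = layout.onsets()
    n = int(round(duration * fs))
    t = np.arange(n) / fs

    schedule = nmm_mod.IntentionSchedule(
        total_duration=duration, task_window=(0.0, duration), task_gain=1.0)
    source = nmm_mod.simulate_cortex(
        models=models, schedule=schedule, rp=nmm_mod.RPConfig(enabled=False),
        fs=fs, seed=int(s_cortex.generate_state(1)[0] % (2 ** 31))).data[0]
    source = source - source.mean()

    rp_trace = np.zeros(n)
    for t0 in onsets:
        lo = int((t0 - rp.rise_duration) * fs)
        hi = min(int((t0 + 8 * rp.recovery_time_constant) * fs), n)
        rp_trace[lo:hi] += nmm_mod.rp_kernel(t[lo:hi] - t0, rp)
    rng_ch = np.random.default_rng(s_chan)
    eeg_data = np.empty((len(EEG_CHANNELS), n))
    for c in range(len(EEG_CHANNELS)):
        noise = eeg_channel_noise * source.std() * rng_ch.standard_normal(n)
        eeg_data[c] = source + noise + rp_gain * rp_trace

    # EMG: unit templates once per channel, spike bursts under the envelope
    env_lo, env_hi = -rp.rise_duration, 8 * rp.recovery_time_constant
    emg_data = np.zeros((len(EMG_CHANNELS), n))
    electrodes = [emg_mod.ElectrodePoint(0.0, 5.0, 30.0),
                  emg_mod.ElectrodePoint(0.0, -5.0, 30.0)]
    lam = emg_mod.calibrate_firing_lambda(firing.rate_mean, firing.rate_min,
                                          firing.rate_max)
    emg_children = s_emg.spawn(len(electrodes))
    for c, electrode in enumerate(electrodes):
        rng = np.random.default_rng(emg_children[c])
        templates = emg_mod._unit_templates(muscle, electrode, fs, rng)
        n_tpl = templates.shape[1]
        trace = np.zeros(n + n_tpl)
        for t0 in onsets:
            w0, w1 = t0 + delay + env_lo, min(t0 + delay + env_hi, duration)
            for u in range(muscle.n_motor_units):
                rate = emg_mod._draw_unit_rate(rng, lam, firing.rate_min,
                                               firing.rate_max)
                spikes = emg_mod.firing_times(firing, rate, (w0, w1), rng)
                idx = np.round(spikes * fs).astype(int)
                for i in idx:
                    trace[i:i + n_tpl] += templates[u]
        trace = trace[:n]
        env = np.zeros(n)
        for t0 in onsets:
            lo = max(int((t0 + delay + env_lo) * fs), 0)
            hi = min(int((t0 + delay + env_hi) * fs), n)
            env[lo:hi] = np.maximum(env[lo:hi],
                                    _envelope(t[lo:hi] - t0, rp, delay))
        burst = trace * env
        rms = burst[env > 0.1].std() if (env > 0.1).any() else 1.0
        rest = emg_rest_level * rms * rng.standard_normal(n)
        emg_data[c] = burst + rest

    triggers = [(int(round(t0 * fs)), "onset") for t0 in onsets]
    eeg = TimeSeriesSignal(eeg_data, fs, list(EEG_CHANNELS), "mV",
                           list(triggers))
    emg = TimeSeriesSignal(emg_data, fs, list(EMG_CHANNELS), "mV",
                           list(triggers))
    return SyntheticSession(eeg=eeg, emg=emg, planted_delay=delay,
                            layout=layout)


def recover_delay(session: SyntheticSession,
                  window_pre: float = 3.0, window_post: float = 3.0,
                  max_frequency: float = 2.0,
                  wavelet: WaveletParams | None = None) -> float:
    """Estimate the planted cortico-muscular delay (s) from the session.

    Per movement epoch, the coherence between the polarity-flipped EEG
    (channel average; the RP is a negativity, the muscle drive positive)
    and the rectified standardized EMG is computed; the scale of maximal
    epoch-averaged coherence below ``max_frequency`` is selected inside
    +/-1 s of onset, and the coherence-weighted circular-mean phase there,
    divided by 2*pi*f, is the delay. Positive values certify the EEG lead.
    """
    if len(session.eeg.triggers) < 10:
        raise ValueError("need at least 10 triggers to estimate the delay")
    wavelet = wavelet if wavelet is not None else WaveletParams(fmax=8.0)
    eeg_mean = session.eeg.copy()
    eeg_mean.data = -session.eeg.data.mean(axis=0, keepdims=True)
    eeg_mean.channel_labels = ["EEGavg"]
    eeg_ep = epoch(eeg_mean, window_pre, window_post)
    emg_one = session.emg.copy()
    emg_one.data = session.emg.data[:1]
    emg_one.channel_labels = session.emg.channel_labels[:1]
    emg_ep = epoch(emg_one, window_pre, window_post)

    maps: list[CoherenceMap] = []
    for k in range(eeg_ep.n_epochs):
        a = eeg_ep.epochs[k, 0]
        b = np.abs(emg_ep.epochs[k, 0])
        a = (a - a.mean()) / (a.std() or 1.0)
        b = (b - b.mean()) / (b.std() or 1.0)
        maps.append(wavelet_coherence(a, b, wavelet, fs=session.eeg.fs))
    if not maps:
        raise ValueError("no usable epochs for coherence")
    mean_coh = np.mean([m.coherence for m in maps], axis=0)
    ref = maps[0]
    window = (window_pre - 1.0, window_pre + 1.0)
    tsel = (ref.times >= window[0]) & (ref.times <= window[1])
    fsel = ref.frequencies <= max_frequency
    valid = ~ref.coi_mask[:, tsel]
    scores = np.where(valid, mean_coh[:, tsel], 0.0).sum(axis=1) / np.maximum(
        valid.sum(axis=1), 1)
    scores[~fsel] = -np.inf
    j = int(np.argmax(scores))
    f_peak = float(ref.frequencies[j])
    phases = []
    weights = []
    for m in maps:
        try:
            ph = phase_lead(m, f_peak, window)
        except ValueError:
            continue
        phases.append(ph)
        weights.append(1.0)
    if not phases:
        raise ValueError("insufficient coherent epochs for a phase estimate")
    vec = np.sum(np.exp(1j * np.asarray(phases)))
    return float(np.angle(vec) / (2.0 * np.pi * f_peak))
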