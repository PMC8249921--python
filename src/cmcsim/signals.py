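"""Multichannel time-series container, I/O and preprocessing.

The :class:`TimeSeriesSignal` is the shared currency of the package: every
simulator emits one and every analysis step consumes one. Preprocessing
follows the standard EEG/EMG pipeline: zero-phase Butterworth band-pass
(0.5-45 Hz for EEG, 20-200 Hz for EMG), 50 Hz notch, trigger-based epoching
centred on movement onset, and pointwise ERP averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

logger = logging.getLogger(__name__)

__all__ = [
    "TimeSeriesSignal",
    "EpochSet",
    "bandpass",
    "notch",
    "epoch",
    "erp_average",
    "normalize_and_pad",
    "resample_to",
    "read_edf",
]


@dataclass
class TimeSeriesSignal:
    """Uniformly sampled multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Sample values in physical units.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One label per channel (e.g. ``["FC1", "FC2", ...]``).
    unit : str
        Physical unit of ``data`` (default millivolt).
    triggers : list of (int, str)
        Event markers as (sample index, label) pairs.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str] = field(default_factory=list)
    unit: str = "mV"
    triggers: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i}" for i in range(self.data.shape[0])]
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("channel_labels length does not match data rows")
        for idx, _ in self.triggers:
            if not 0 <= idx < self.n_samples:
                raise ValueError(f"trigger sample {idx} out of bounds")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self, **changes) -> "TimeSeriesSignal":
        out = replace(self, **changes)
        out.data = np.array(out.data, copy=True)
        out.triggers = list(out.triggers)
        return out

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(self.data.T, columns=self.channel_labels)
        frame.insert(0, "time_s", self.times)
        return frame

    def to_csv(self, path, trigger_path=None) -> None:
        """Write ``time_s,<ch1>,<ch2>,...`` CSV, triggers to a side file."""
        self.to_frame().to_csv(path, index=False)
        if trigger_path is not None:
            rows = [(idx / self.fs, label) for idx, label in self.triggers]
            pd.DataFrame(rows, columns=["onset_s", "label"]).to_csv(
                trigger_path, index=False
            )

    @classmethod
    def from_csv(cls, path, trigger_path=None, unit: str = "mV") -> "TimeSeriesSignal":
        frame = pd.read_csv(path)
        if "time_s" not in frame.columns:
            raise ValueError(f"{path}: expected a 'time_s' column")
        times = frame["time_s"].to_numpy()
        if len(times) < 2:
            raise ValueError(f"{path}: need at least two samples")
        dt = np.diff(times)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
            raise ValueError(f"{path}: non-uniform sampling")
        fs = 1.0 / dt[0]
        labels = [c for c in frame.columns if c != "time_s"]
        data = frame[labels].to_numpy().T
        triggers: list[tuple[int, str]] = []
        if trigger_path is not None:
            tf = pd.read_csv(trigger_path)
            for _, row in tf.iterrows():
                triggers.append((int(round(row["onset_s"] * fs)), str(row["label"])))
        return cls(data=data, fs=fs, channel_labels=labels, unit=unit,
                   triggers=triggers)


def read_edf(path) -> TimeSeriesSignal:
    """Read an EDF recording via MNE (optional dependency)."""
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    data = raw.get_data() * 1e3  # MNE returns volts; store millivolts
    triggers = []
    for onset, _, desc in zip(
        raw.annotations.onset, raw.annotations.duration, raw.annotations.description
    ):
        triggers.append((int(round(onset * raw.info["sfreq"])), str(desc)))
    return TimeSeriesSignal(
        data=data,
        fs=float(raw.info["sfreq"]),
        channel_labels=list(raw.ch_names),
        unit="mV",
        triggers=triggers,
    )


@dataclass
class EpochSet:
    """Trigger-aligned trials: ``epochs`` has shape (trials, channels, samples).

    Time 0 of every epoch is the trigger (movement onset); the window spans
    ``[-pre, +post]`` seconds around it.
    """

    epochs: np.ndarray
    fs: float
    pre: float
    post: float
    channel_labels: list[str] = field(default_factory=list)
    alignment: str = "onset"

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    @property
    def times(self) -> np.ndarray:
        n = self.epochs.shape[2]
        return np.arange(n) / self.fs - self.pre


# ----------------------------------------------------------------- filters

def _validate_band(low: float, high: float, fs: float) -> None:
    if not 0 < low < high:
        raise ValueError(f"need 0 < low < high, got ({low}, {high})")
    if high >= fs / 2:
        raise ValueError(f"band edge {high} Hz at or above Nyquist ({fs / 2} Hz)")


def bandpass(signal: TimeSeriesSignal, low: float, high: float,
             order: int = 4) -> TimeSeriesSignal:
    """Zero-phase Butterworth band-pass (applied forward-backward)."""
    _validate_band(low, high, signal.fs)
    sos = sps.butter(order, [low, high], btype="bandpass", fs=signal.fs,
                     output="sos")
    out = signal.copy()
    out.data = sps.sosfiltfilt(sos, signal.data, axis=-1)
    return out


def notch(signal: TimeSeriesSignal, f0: float = 50.0, q: float = 30.0) -> TimeSeriesSignal:
    """Zero-phase IIR notch (power-line removal)."""
    if not 0 < f0 < signal.fs / 2:
        raise ValueError(f"notch frequency {f0} Hz outside (0, Nyquist)")
    b, a = sps.iirnotch(f0, q, fs=signal.fs)
    out = signal.copy()
    out.data = sps.filtfilt(b, a, signal.data, axis=-1)
    return out


# ---------------------------------------------------------------- epoching

def epoch(signal: TimeSeriesSignal, window_pre: float = 3.0,
          window_post: float = 3.0) -> EpochSet:
    """Cut one trial per trigger; trials whose window spills over an edge
    are dropped (their count is logged)."""
    if not signal.triggers:
        raise ValueError("signal has no triggers to epoch on")
    n_pre = int(round(window_pre * signal.fs))
    n_post = int(round(window_post * signal.fs))
    trials = []
    dropped = 0
    for idx, _ in signal.triggers:
        if idx - n_pre < 0 or idx + n_post > signal.n_samples:
            dropped += 1
            continue
        trials.append(signal.data[:, idx - n_pre:idx + n_post])
    if dropped:
        logger.info("epoch: dropped %d/%d out-of-bounds triggers", dropped,
                    len(signal.triggers))
    if not trials:
        raise ValueError("no trigger window fits inside the recording")
    return EpochSet(
        epochs=np.stack(trials),
        fs=signal.fs,
        pre=window_pre,
        post=window_post,
        channel_labels=list(signal.channel_labels),
    )


def erp_average(epochs: EpochSet, baseline: tuple[float, float] | None = None
                ) -> np.ndarray:
    """Pointwise mean across trials, shape (channels, samples).

    ``baseline=(t0, t1)`` (seconds, epoch time) subtracts the mean of that
    interval per channel before averaging.
    """
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    data = epochs.epochs
    if baseline is not None:
        t = epochs.times
        mask = (t >= baseline[0]) & (t <= baseline[1])
        if not mask.any():
            raise ValueError("baseline interval outside the epoch window")
        data = data - data[:, :, mask].mean(axis=2, keepdims=True)
    return data.mean(axis=0)


# ----------------------------------------------------- normalization / pads

def normalize_and_pad(emg: TimeSeriesSignal, pad_pre: float, pad_post: float,
                      seed: int | None = None,
                      rest_amplitude: float = 0.01) -> TimeSeriesSignal:
    """Z-score the task segment and flank it with resting-state noise.

    The task burst is standardized per channel (mean 0, SD 1) and padded
    with white rest noise of SD ``rest_amplitude`` (fraction of the task
    RMS, i.e. of 1 after standardization).
    """
    if pad_pre < 0 or pad_post < 0:
        raise ValueError("pads must be non-negative")
    std = emg.data.std(axis=1, keepdims=True)
    if np.any(std == 0):
        raise ValueError("zero-variance channel cannot be normalized")
    task = (emg.data - emg.data.mean(axis=1, keepdims=True)) / std
    rng = np.random.default_rng(seed)
    n_pre = int(round(pad_pre * emg.fs))
    n_post = int(round(pad_post * emg.fs))
    pre = rest_amplitude * rng.standard_normal((emg.n_channels, n_pre))
    post = rest_amplitude * rng.standard_normal((emg.n_channels, n_post))
    out = emg.copy()
    out.data = np.concatenate([pre, task, post], axis=1)
    out.unit = "a.u."
    out.triggers = [(idx + n_pre, label) for idx, label in emg.triggers]
    return out


def resample_to(signal: TimeSeriesSignal, fs_new: float) -> TimeSeriesSignal:
    """Polyphase resampling onto a common grid (exact rational ratios only)."""
    from fractions import Fraction

    frac = Fraction(fs_new / signal.fs).limit_denominator(1000)
    if abs(frac.numerator / frac.denominator - fs_new / signal.fs) > 1e-9:
        raise ValueError(f"cannot express {signal.fs} -> {fs_new} Hz as a "
                         "small rational ratio")
    out = signal.copy()
    out.data = sps.resample_poly(signal.data, frac.numerator, frac.denominator,
                                 axis=-1)
    out.fs = fs_new
    scale = fs_new / signal.fs
    out.triggers = [(int(round(idx * scale)), label)
                    for idx, label in signal.triggers
                    if int(round(idx * scale)) < out.n_samples]
    return out
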