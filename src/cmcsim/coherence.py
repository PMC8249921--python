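"""Morlet wavelet coherence between EEG and EMG.

The continuous wavelet transform uses the analytic Morlet mother
``psi(t) = pi^(-1/4) exp(i*omega0*t) exp(-t^2/2)`` with the L2-normalized
convention W(a, b) = 1/sqrt(a) * int x(t) psi*((t-b)/a) dt on a geometric
scale grid (12 voices per octave covering 0.5-45 Hz by default). Wavelet
coherence is the smoothed, normalized cross-spectrum

    Wco = |S(Wx * conj(Wy))| / sqrt(S(|Wx|^2) * S(|Wy|^2)),

where S applies a Gaussian time smoothing of width equal to the scale
followed by a boxcar scale smoothing of width 0.6*a; both kernels are
renormalized to unit local mass, so a constant field is left unchanged and
the coherence lies in [0, 1] by Cauchy-Schwarz. The phase of S(Wxy) gives
the lead/lag between the signals (positive = first signal leads); the
cone of influence marks cells within sqrt(2)*a of an edge, where
zero-padding bleeds in.

Scale-to-frequency mapping is the standard Morlet relation
f = (omega0 + sqrt(2 + omega0^2)) / (4*pi*a).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .signals import TimeSeriesSignal

__all__ = [
    "WaveletParams",
    "CWTResult",
    "CoherenceMap",
    "cwt",
    "cross_wavelet",
    "smooth_spectrum",
    "wavelet_coherence",
    "peak_coherence_frequency",
    "phase_lead",
    "significance_threshold",
]


@dataclass
class WaveletParams:
    """Morlet CWT and smoothing configuration."""

    omega0: float = 6.0
    fmin: float = 0.5
    fmax: float = 45.0
    voices_per_octave: int = 12
    scale_smoothing_factor: float = 0.6
    kernel_halfwidth: float = 5.0   # wavelet truncation, in scales

    def __post_init__(self) -> None:
        if self.omega0 < 5:
            raise ValueError("omega0 must be >= 5 for practical admissibility")
        if not 0 < self.fmin < self.fmax:
            raise ValueError("need 0 < fmin < fmax")

    @property
    def fourier_factor(self) -> float:
        """Frequency * scale product: f = fourier_factor / a."""
        return (self.omega0 + np.sqrt(2.0 + self.omega0 ** 2)) / (4.0 * np.pi)

    def frequencies(self) -> np.ndarray:
        """Geometric frequency grid fmin * 2^(k/voices), ascending, <= fmax."""
        n = int(np.floor(self.voices_per_octave
                         * np.log2(self.fmax / self.fmin))) + 1
        return self.fmin * 2.0 ** (np.arange(n) / self.voices_per_octave)

    def scales(self) -> np.ndarray:
        """Wavelet scales (seconds), descending along the frequency grid."""
        return self.fourier_factor / self.frequencies()


@dataclass
class CWTResult:
    """Complex Morlet coefficients on a (scale x time) grid."""

    coeffs: np.ndarray          # (n_scales, n_samples), complex
    frequencies: np.ndarray     # Hz, one per row
    scales: np.ndarray          # s, one per row
    fs: float

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.coeffs.shape[1]) / self.fs


@dataclass
class CoherenceMap:
    """Time-frequency wavelet coherence with phase and cone of influence."""

    times: np.ndarray
    frequencies: np.ndarray
    coherence: np.ndarray        # in [0, 1]
    phase: np.ndarray            # radians, first signal minus second
    coi_mask: np.ndarray         # True where edge effects are non-negligible
    coi_frequency: np.ndarray    # per-time lowest trustworthy frequency (Hz)
    zero_power: np.ndarray = field(default=None)  # flagged degenerate cells

    def to_frame(self):
        """Long-format (time, frequency, coherence, phase, in_coi) table."""
        import pandas as pd

        tt, ff = np.meshgrid(self.times, self.frequencies)
        return pd.DataFrame({
            "time_s": tt.ravel(),
            "frequency_hz": ff.ravel(),
            "coherence": self.coherence.ravel(),
            "phase_rad": self.phase.ravel(),
            "in_coi": self.coi_mask.ravel(),
        })


def _as_array(x) -> tuple[np.ndarray, float | None]:
    if isinstance(x, TimeSeriesSignal):
        if x.n_channels != 1:
            raise ValueError("wavelet analysis expects a single channel")
        return x.data[0], x.fs
    return np.asarray(x, dtype=float), None


def _morlet_kernel(scale: float, fs: float, params: WaveletParams) -> np.ndarray:
    half = int(np.ceil(params.kernel_halfwidth * scale * fs))
    t = np.arange(-half, half + 1) / fs
    u = t / scale
    psi = np.pi ** -0.25 * np.exp(1j * params.omega0 * u - 0.5 * u ** 2)
    return psi / np.sqrt(scale) / fs  # includes the dt of the CWT integral


def cwt(signal, params: WaveletParams | None = None,
        fs: float | None = None) -> CWTResult:
    """Morlet CWT of a uniformly sampled signal.

    ``signal`` may be a single-channel :class:`TimeSeriesSignal` (carrying
    its own fs) or a plain array with ``fs`` given. The record must be at
    least twice the largest scale long.
    """
    params = params if params is not None else WaveletParams()
    x, fs_sig = _as_array(signal)
    fs = fs_sig if fs_sig is not None else fs
    if fs is None:
        raise ValueError("fs required for array input")
    scales = params.scales()
    freqs = params.frequencies()
    n = x.size
    worst = scales.max()
    if n < 2 * worst * fs:
        raise ValueError(
            f"signal of {n} samples is shorter than twice the largest scale "
            f"({worst:.3g} s at {fs} Hz); raise fmin or lengthen the record")
    coeffs = np.empty((scales.size, n), dtype=complex)
    for j, a in enumerate(scales):
        kern = _morlet_kernel(a, fs, params)
        coeffs[j] = fftconvolve(x, kern, mode="same")
    return CWTResult(coeffs=coeffs, frequencies=freqs, scales=scales, fs=fs)


def cross_wavelet(wx: CWTResult, wy: CWTResult) -> np.ndarray:
    """Cross-wavelet spectrum Wx * conj(Wy); swapping arguments conjugates
    the result, so the magnitude is symmetric and the phase antisymmetric."""
    if wx.coeffs.shape != wy.coeffs.shape or not np.allclose(wx.scales, wy.scales):
        raise ValueError("cross_wavelet requires identical scale/time grids")
    return wx.coeffs * np.conj(wy.coeffs)


def _smooth_time(field_: np.ndarray, scales: np.ndarray, fs: float) -> np.ndarray:
    """Per-scale Gaussian time smoothing, kernel exp(-t^2/(2*a^2)),
    renormalized to unit local mass (edges included)."""
    out = np.empty_like(field_)
    ones = np.ones(field_.shape[-1])
    for j, a in enumerate(scales):
        half = int(np.ceil(4.0 * a * fs))
        t = np.arange(-half, half + 1) / fs
        kern = np.exp(-0.5 * (t / a) ** 2)
        kern /= kern.sum()
        mass = fftconvolve(ones, kern, mode="same")
        out[j] = fftconvolve(field_[j], kern, mode="same") / mass
    return out


def _smooth_scale(field_: np.ndarray, scales: np.ndarray,
                  factor: float) -> np.ndarray:
    """Boxcar smoothing along the scale axis, width ``factor * a`` around
    each scale (|a_k - a_j| <= factor*a_j/2), unit-normalized."""
    out = np.empty_like(field_)
    for j, a in enumerate(scales):
        sel = np.abs(scales - a) <= 0.5 * factor * a
        out[j] = field_[sel].mean(axis=0)
    return out


def smooth_spectrum(field_: np.ndarray, params: WaveletParams, fs: float,
                    scales: np.ndarray | None = None) -> np.ndarray:
    """The smoothing operator S: Gaussian along time (width = scale), then
    boxcar along scale (width 0.6*a). Both kernels have unit local mass,
    so a constant field passes through unchanged."""
    scales = scales if scales is not None else params.scales()
    if np.iscomplexobj(field_):
        real = _smooth_scale(_smooth_time(field_.real, scales, fs), scales,
                             params.scale_smoothing_factor)
        imag = _smooth_scale(_smooth_time(field_.imag, scales, fs), scales,
                             params.scale_smoothing_factor)
        return real + 1j * imag
    return _smooth_scale(_smooth_time(field_, scales, fs), scales,
                         params.scale_smoothing_factor)


def wavelet_coherence(x, y, params: WaveletParams | None = None,
                      fs: float | None = None) -> CoherenceMap:
    """Wavelet coherence magnitude and phase of two equal-length signals.

    Degenerate zero-power cells yield coherence 0 and are flagged in
    ``zero_power`` rather than returned as NaN.
    """
    params = params if params is not None else WaveletParams()
    xa, fsx = _as_array(x)
    ya, fsy = _as_array(y)
    fs = fsx if fsx is not None else fs
    if fsy is not None and fs is not None and not np.isclose(fsy, fs):
        raise ValueError("signals must share a sampling rate")
    if xa.size != ya.size:
        raise ValueError("signals must have equal length")
    # Extend the scale grid past both band edges (by half the scale-smoothing
    # window, record length permitting) so every reported row receives the
    # full boxcar support; edge rows would otherwise carry a higher
    # small-sample coherence bias. Trimmed back after smoothing.
    voices = params.voices_per_octave
    pad = int(np.ceil(voices * np.log2(1.0 + 0.5 * params.scale_smoothing_factor))) + 1
    fmin_ext = params.fmin * 2.0 ** (-pad / voices)
    limit = params.fourier_factor * 2.0 * fs / xa.size  # lowest usable freq
    fmin_ext = max(fmin_ext, min(params.fmin, limit))
    work = WaveletParams(
        omega0=params.omega0, fmin=fmin_ext,
        fmax=params.fmax * 2.0 ** (pad / voices),
        voices_per_octave=voices,
        scale_smoothing_factor=params.scale_smoothing_factor,
        kernel_halfwidth=params.kernel_halfwidth)
    wx = cwt(xa, work, fs=fs)
    wy = cwt(ya, work, fs=fs)
    sxy = smooth_spectrum(cross_wavelet(wx, wy), work, fs, wx.scales)
    sxx = smooth_spectrum(np.abs(wx.coeffs) ** 2, work, fs, wx.scales)
    syy = smooth_spectrum(np.abs(wy.coeffs) ** 2, work, fs, wx.scales)
    keep = (wx.frequencies >= params.fmin * (1 - 1e-9)) & (
        wx.frequencies <= params.fmax * (1 + 1e-9))
    wx = CWTResult(wx.coeffs[keep], wx.frequencies[keep], wx.scales[keep], fs)
    sxy, sxx, syy = sxy[keep], sxx[keep], syy[keep]
    denom2 = sxx * syy
    floor = 1e-300
    zero_power = denom2 <= floor
    coh = np.zeros_like(sxx)
    np.divide(np.abs(sxy), np.sqrt(np.clip(denom2, floor, None)), out=coh,
              where=~zero_power)
    coh[zero_power] = 0.0
    phase = np.angle(sxy)
    times = wx.times
    duration = times[-1] if times.size > 1 else 0.0
    edge = np.minimum(times, duration - times)
    # e-folding time sqrt(2)*a: cells closer to an edge are inside the cone
    coi_mask = (np.sqrt(2.0) * wx.scales[:, np.newaxis]) > edge[np.newaxis, :]
    with np.errstate(divide="ignore"):
        coi_frequency = np.sqrt(2.0) * params.fourier_factor / edge
    return CoherenceMap(times=times, frequencies=wx.frequencies,
                        coherence=coh, phase=phase, coi_mask=coi_mask,
                        coi_frequency=coi_frequency, zero_power=zero_power)


def peak_coherence_frequency(cmap: CoherenceMap,
                             window: tuple[float, float]) -> float:
    """Frequency maximizing the time-averaged coherence over ``window``
    (seconds); cone-of-influence cells are excluded from the average."""
    t0, t1 = window
    sel = (cmap.times >= t0) & (cmap.times <= t1)
    if not sel.any():
        raise ValueError(f"window {window} does not overlap the map times")
    valid = ~cmap.coi_mask[:, sel]
    counts = valid.sum(axis=1)
    sums = np.where(valid, cmap.coherence[:, sel], 0.0).sum(axis=1)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), -np.inf)
    if not np.isfinite(means).any():
        raise ValueError("all cells in the window are inside the cone of influence")
    return float(cmap.frequencies[int(np.argmax(means))])


def phase_lead(cmap: CoherenceMap, frequency: float,
               window: tuple[float, float]) -> float:
    """Coherence-weighted circular-mean phase (radians) at the scale
    nearest ``frequency`` over ``window``. Positive values mean the first
    signal leads."""
    j = int(np.argmin(np.abs(cmap.frequencies - frequency)))
    t0, t1 = window
    sel = (cmap.times >= t0) & (cmap.times <= t1)
    if not sel.any():
        raise ValueError(f"window {window} does not overlap the map times")
    valid = ~cmap.coi_mask[j, sel]
    if not valid.any():
        raise ValueError("all cells at this scale/window are masked")
    w = cmap.coherence[j, sel][valid]
    ph = cmap.phase[j, sel][valid]
    vec = np.sum(w * np.exp(1j * ph))
    if np.abs(vec) == 0:
        raise ValueError("no coherence mass to average")
    return float(np.angle(vec))


def significance_threshold(x, y, params: WaveletParams | None = None,
                           fs: float | None = None, n_surrogates: int = 300,
                           alpha: float = 0.05,
                           seed: int | None = None) -> np.ndarray:
    """Per-scale Monte-Carlo coherence threshold from AR(1) surrogates.

    Fits an AR(1) to each input, simulates ``n_surrogates`` independent
    pairs, and returns the (1-alpha) quantile of coherence per scale
    (outside the cone of influence).
    """
    params = params if params is not None else WaveletParams()
    xa, fsx = _as_array(x)
    ya, fsy = _as_array(y)
    fs = fsx if fsx is not None else fs
    rng = np.random.default_rng(seed)

    def ar1_fit(v):
        v = v - v.mean()
        phi = np.dot(v[:-1], v[1:]) / np.dot(v[:-1], v[:-1])
        phi = np.clip(phi, -0.999, 0.999)
        sig = np.sqrt(np.var(v) * (1 - phi ** 2))
        return phi, sig

    def ar1_sim(phi, sig, n):
        out = np.empty(n)
        out[0] = rng.normal(0, sig / np.sqrt(1 - phi ** 2))
        eps = rng.normal(0, sig, n)
        for i in range(1, n):
            out[i] = phi * out[i - 1] + eps[i]
        return out

    (phix, sigx), (phiy, sigy) = ar1_fit(xa), ar1_fit(ya)
    n = xa.size
    maxima = np.zeros((n_surrogates, params.frequencies().size))
    for s in range(n_surrogates):
        cm = wavelet_coherence(ar1_sim(phix, sigx, n), ar1_sim(phiy, sigy, n),
                               params, fs=fs)
        vals = np.where(~cm.coi_mask, cm.coherence, np.nan)
        maxima[s] = np.nanquantile(vals, 0.95, axis=1)
    return np.quantile(maxima, 1 - alpha, axis=0)
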