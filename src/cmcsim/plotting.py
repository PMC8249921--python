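"""Coherence-map and signal panels (matplotlib)."""

from __future__ import annotations

import numpy as np

from .coherence import CoherenceMap
from .signals import TimeSeriesSignal

__all__ = ["plot_coherence_map", "plot_signals"]


def plot_coherence_map(cmap: CoherenceMap, ax=None, phase_arrows: bool = True,
                       arrow_stride: tuple[int, int] = (6, 500)):
    """Time-frequency coherence panel with the cone of influence shaded and
    (optionally) phase arrows: rightward = in phase, upward = first signal
    leading by a quarter cycle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    mesh = ax.pcolormesh(cmap.times, cmap.frequencies, cmap.coherence,
                         cmap="viridis", vmin=0.0, vmax=1.0, shading="auto")
    ax.set_yscale("log")
    ax.set_ylabel("frequency (Hz)")
    ax.set_xlabel("time (s)")
    masked = np.where(cmap.coi_mask, 1.0, np.nan)
    ax.pcolormesh(cmap.times, cmap.frequencies, masked, cmap="gray_r",
                  vmin=0, vmax=2, alpha=0.4, shading="auto")
    if phase_arrows:
        fstep, tstep = arrow_stride
        ff = cmap.frequencies[::fstep]
        tt = cmap.times[::tstep]
        ph = cmap.phase[::fstep, ::tstep]
        coh = cmap.coherence[::fstep, ::tstep]
        show = coh > 0.6
        ax.quiver(np.meshgrid(tt, ff)[0][show], np.meshgrid(tt, ff)[1][show],
                  np.cos(ph)[show], np.sin(ph)[show],
                  angles="xy", scale=40, width=0.002, color="white")
    ax.figure.colorbar(mesh, ax=ax, label="wavelet coherence")
    return ax


def plot_signals(signals: list[TimeSeriesSignal], labels=None, axes=None):
    """Stacked signal traces with trigger marks."""
    import matplotlib.pyplot as plt

    if axes is None:
        _, axes = plt.subplots(len(signals), 1, sharex=True,
                               figsize=(8, 2 * len(signals)))
        axes = np.atleast_1d(axes)
    for ax, sig, label in zip(axes, signals,
                              labels or [s.channel_labels[0] for s in signals]):
        ax.plot(sig.times, sig.data[0], lw=0.5)
        for idx, _ in sig.triggers:
            ax.axvline(idx / sig.fs, color="r", ls="--", lw=0.7)
        ax.set_ylabel(f"{label} ({sig.unit})")
    axes[-1].set_xlabel("time (s)")
    return axes
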