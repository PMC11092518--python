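"""Figure helpers: trajectory/spike overlay, rate map, autocorrelogram,
sweep heat maps.  All functions return the matplotlib Figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .spatial import Autocorrelogram, RateMap
from .stimulus import Trajectory
from .sweep import SweepResult

__all__ = ["plot_triptych", "plot_sweep", "plot_psd"]


def plot_triptych(
    traj: Trajectory,
    spike_times_s: np.ndarray,
    rmap: RateMap,
    ac: Autocorrelogram,
    title: str = "",
):
    """Trajectory + spike overlay, rate map, and autocorrelogram panels."""
    fig, axes = plt.subplots(1, 3, figsize=(12, 4))
    ax = axes[0]
    ax.plot(traj.x, traj.y, color="k", lw=0.3)
    pos = traj.position_at(spike_times_s)
    ax.plot(pos[..., 0], pos[..., 1], "r.", ms=2)
    ax.set_aspect("equal")
    ax.set_title("trajectory + spikes")
    extent = [0, rmap.rate.shape[1] * rmap.bin_cm, 0, rmap.rate.shape[0] * rmap.bin_cm]
    im = axes[1].imshow(rmap.rate, origin="lower", extent=extent, cmap="jet")
    fig.colorbar(im, ax=axes[1], label="spikes/s")
    axes[1].set_title("rate map")
    im = axes[2].imshow(ac.corr, origin="lower", cmap="jet", vmin=-1, vmax=1)
    fig.colorbar(im, ax=axes[2], label="correlation")
    axes[2].set_title("autocorrelogram")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig


def plot_sweep(result: SweepResult, title: str = ""):
    """Score heat map with threshold (black) and realism (teal) contours."""
    fig, ax = plt.subplots(figsize=(5.5, 4.5))
    im = ax.pcolormesh(result.values_x, result.values_y, result.scores, shading="nearest")
    fig.colorbar(im, ax=ax, label="grid score")
    for mask, color in ((result.threshold_mask, "black"), (result.realism_mask, "teal")):
        ax.contour(
            result.values_x,
            result.values_y,
            mask.astype(float),
            levels=[0.5],
            colors=color,
        )
    ax.set_xlabel(result.spec_params[0])
    ax.set_ylabel(result.spec_params[1])
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig


def plot_psd(freqs: np.ndarray, power: np.ndarray, title: str = ""):
    fig, ax = plt.subplots(figsize=(5, 3.5))
    m = (freqs >= 1) & (freqs <= 100)
    ax.semilogy(freqs[m], power[m])
    for edge in (4, 12, 25):
        ax.axvline(edge, color="gray", lw=0.5, ls="--")
    ax.set_xlabel("frequency (Hz)")
    ax.set_ylabel("power")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    return fig
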