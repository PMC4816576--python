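"""Minimal rendering helpers (condition ERPs, ERP images, montage scatter)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .epochs import Epochs
from .erp_stats import erp_image
from .montage import Montage

__all__ = ["plot_condition_erps", "plot_erp_image", "plot_montage_values"]


def plot_condition_erps(erps: dict, channel: str, path) -> Path:
    """Overlay the per-condition averages at one channel."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for (task, response), erp in sorted(erps.items()):
        ax.plot(erp.times, erp.channel(channel), label=f"{task}-{response}")
    ax.axvline(0, color="k", lw=0.5)
    ax.set_xlabel("time relative to response (ms)")
    ax.set_ylabel("amplitude (μV)")
    ax.set_title(channel)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_erp_image(epochs: Epochs, channel: str, path, ma_window: int = 40) -> Path:
    """RT-sorted smoothed single-trial image at one channel."""
    matrix, order = erp_image(epochs, channel, ma_window=ma_window)
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(
        matrix,
        aspect="auto",
        origin="lower",
        extent=(epochs.times[0], epochs.times[-1], 0, matrix.shape[0]),
        cmap="RdBu_r",
        vmin=-1,
        vmax=1,
    )
    rts = np.sort(epochs.rts)[: matrix.shape[0]]
    ax.plot(np.zeros_like(rts), np.arange(len(rts)), color="k", lw=0.8)
    ax.set_xlabel("time relative to response (ms)")
    ax.set_ylabel("trials (RT-sorted, smoothed)")
    ax.set_title(channel)
    fig.colorbar(im, ax=ax, label="normalised amplitude")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_montage_values(montage: Montage, values, path, title: str = "") -> Path:
    """Scatter per-channel values on the schematic head layout."""
    values = np.asarray(values, float)
    fig, ax = plt.subplots(figsize=(5, 5))
    sc = ax.scatter(montage.positions[:, 0], montage.positions[:, 1], c=values, s=120, cmap="RdBu_r")
    for name, (x, y) in zip(montage.channel_names, montage.positions):
        ax.annotate(name, (x, y), fontsize=6, ha="center", va="center")
    circle = plt.Circle((0, 0), 1.0, fill=False, color="k", lw=0.8)
    ax.add_patch(circle)
    ax.set_aspect("equal")
    ax.axis("off")
    ax.set_title(title)
    fig.colorbar(sc, ax=ax, shrink=0.7, label="μV")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
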