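"""Filtering, re-referencing, segmentation, and statistical artifact rejection.

The artifact-rejection stage implements an automated outlier criterion:
pool every data point (all trials, scalp channels, samples), estimate mean
and SD, flag trials containing any point beyond ``z_criterion`` SDs, and
remove at most ``max_reject_fraction`` of the trials (the worst offenders
first).  Ocular-artifact removal by ICA is deliberately not implemented;
:func:`ica_hook` is the seam where an external cleaner can be plugged in.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve, firwin, freqz

from .epochs import Epochs
from .montage import MASTOIDS, Montage

__all__ = [
    "FilterSpec",
    "RejectionConfig",
    "design_fir",
    "bandpass_filter",
    "rereference_linked_mastoids",
    "segment_epochs",
    "reject_artifact_trials",
    "ica_hook",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FilterSpec:
    """Zero-phase FIR band-pass specification."""

    highpass_hz: float = 0.5
    lowpass_hz: float = 25.0
    kind: str = "fir"
    n_taps: int | None = None  # odd; default ~0.8 s of taps

    def validate(self, sampling_rate: float) -> None:
        if not 0 < self.highpass_hz < self.lowpass_hz < sampling_rate / 2:
            raise ValueError(
                "band edges must satisfy 0 < highpass < lowpass < Nyquist"
            )
        if self.kind != "fir":
            raise ValueError("only FIR filtering is supported")


@dataclass(frozen=True)
class RejectionConfig:
    """Statistical outlier-trial rejection parameters."""

    z_criterion: float = 3.0
    max_reject_fraction: float = 0.05

    def validate(self) -> None:
        if self.z_criterion <= 0:
            raise ValueError("z_criterion must be > 0")
        if not 0 <= self.max_reject_fraction <= 1:
            raise ValueError("max_reject_fraction must be in [0, 1]")


def design_fir(spec: FilterSpec, sampling_rate: float) -> np.ndarray:
    """Linear-phase FIR band-pass taps (Hamming window design)."""
    spec.validate(sampling_rate)
    n_taps = spec.n_taps if spec.n_taps is not None else int(round(0.8 * sampling_rate)) | 1
    if n_taps % 2 == 0:
        raise ValueError("n_taps must be odd for a type-I linear-phase filter")
    return firwin(
        n_taps,
        [spec.highpass_hz, spec.lowpass_hz],
        pass_zero=False,
        fs=sampling_rate,
        window="hamming",
    )


def filter_response_db(spec: FilterSpec, sampling_rate: float, freqs_hz) -> np.ndarray:
    """Magnitude response of the designed filter in dB at the given frequencies."""
    taps = design_fir(spec, sampling_rate)
    _, h = freqz(taps, worN=np.atleast_1d(np.asarray(freqs_hz, float)), fs=sampling_rate)
    return 20.0 * np.log10(np.maximum(np.abs(h), 1e-300))


def bandpass_filter(epochs: Epochs, spec: FilterSpec = FilterSpec()) -> Epochs:
    """Zero-phase band-pass filter applied per channel and trial.

    The symmetric (linear-phase) kernel is applied centred, which compensates
    the group delay exactly; epoch edges are reflection-padded.
    """
    taps = design_fir(spec, epochs.sampling_rate)
    pad = len(taps) // 2
    x = np.pad(epochs.data, ((0, 0), (0, 0), (pad, pad)), mode="reflect")
    y = fftconvolve(x, taps[None, None, :], mode="same")[..., pad:-pad]
    return replace(epochs, data=y, trial_meta=epochs.trial_meta.copy())


def rereference_linked_mastoids(
    epochs: Epochs, mastoid_channels: tuple[str, str] = MASTOIDS
) -> Epochs:
    """Subtract the mean of the two mastoid channels from every channel."""
    idx = [epochs.channel_index(c) for c in mastoid_channels]
    ref = epochs.data[:, idx, :].mean(axis=1, keepdims=True)
    return replace(epochs, data=epochs.data - ref, trial_meta=epochs.trial_meta.copy())


def segment_epochs(
    continuous: np.ndarray,
    events: pd.DataFrame,
    window_ms: tuple[float, float],
    *,
    montage: Montage,
    sampling_rate: float,
    lock: str = "response",
) -> Epochs:
    """Cut a continuous ``channel x sample`` record into event-locked epochs.

    ``events`` needs a ``sample`` column (lock-event sample index) plus the
    trial metadata columns (``subject_id``, ``task``, ``response``, ``rt``).
    Events whose window falls outside the recording are dropped with a
    logged warning.
    """
    continuous = np.asarray(continuous, dtype=float)
    if continuous.ndim != 2 or continuous.shape[0] != len(montage):
        raise ValueError("continuous must be (n_channels, n_samples) matching the montage")
    step = 1000.0 / sampling_rate
    start_off = int(round(window_ms[0] / step))
    n_samp = int(round((window_ms[1] - window_ms[0]) / step)) + 1
    times = window_ms[0] + step * np.arange(n_samp)

    keep, slabs = [], []
    for i, ev in events.reset_index(drop=True).iterrows():
        lo = int(ev["sample"]) + start_off
        hi = lo + n_samp
        if lo < 0 or hi > continuous.shape[1]:
            logger.warning("event %d at sample %d too close to recording edge; dropped", i, ev["sample"])
            continue
        keep.append(i)
        slabs.append(continuous[:, lo:hi])
    data = np.stack(slabs) if slabs else np.empty((0, len(montage), n_samp))
    meta = events.reset_index(drop=True).iloc[keep].drop(columns=["sample"]).reset_index(drop=True)
    return Epochs(
        data=data, montage=montage, sampling_rate=sampling_rate,
        times=times, trial_meta=meta, lock=lock,
    )


def reject_artifact_trials(
    epochs: Epochs,
    cfg: RejectionConfig = RejectionConfig(),
    exclude_channels: tuple[str, ...] = MASTOIDS,
) -> tuple[Epochs, np.ndarray]:
    """Remove statistical outlier trials, capped at a fraction of all trials.

    Mean and SD are pooled over every data point of the scalp channels
    (auxiliary channels in ``exclude_channels`` are ignored).  A trial is
    flagged if any of its points exceeds ``mean ± z_criterion * SD``.  If
    more trials are flagged than ``floor(max_reject_fraction * n_trials)``,
    only that many are removed, ranked by their maximum absolute z-score
    (ties broken towards the earlier trial index).  A zero pooled SD rejects
    nothing.  Returns the surviving epochs and the removed trial indices.
    """
    cfg.validate()
    if epochs.n_trials < 2:
        raise ValueError("artifact rejection needs at least 2 trials")
    scalp = [i for i, c in enumerate(epochs.montage.channel_names) if c not in exclude_channels]
    x = epochs.data[:, scalp, :]
    mean, sd = float(x.mean()), float(x.std())
    if sd == 0.0:
        return epochs, np.array([], dtype=int)
    max_abs_z = np.abs(x - mean).reshape(epochs.n_trials, -1).max(axis=1) / sd
    flagged = np.flatnonzero(max_abs_z > cfg.z_criterion)
    cap = int(np.floor(cfg.max_reject_fraction * epochs.n_trials))
    if len(flagged) > cap:
        order = sorted(flagged, key=lambda i: (-max_abs_z[i], i))
        flagged = np.sort(np.array(order[:cap], dtype=int))
    if len(flagged):
        logger.info("rejected %d/%d trials (cap %d)", len(flagged), epochs.n_trials, cap)
    keep = np.setdiff1d(np.arange(epochs.n_trials), flagged)
    return epochs.subset(keep), flagged


def ica_hook(epochs: Epochs, cleaner=None) -> Epochs:
    """Hook point for an external ocular-artifact cleaner (e.g. an ICA tool).

    The pipeline itself performs no ICA; pass a callable ``Epochs -> Epochs``
    to plug one in.  With no cleaner this is the identity.
    """
    return cleaner(epochs) if cleaner is not None else epochs
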