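"""Persistence: the internal epoch container and optional EEG-format readers.

The internal container is one ``.npy`` voltage array plus a ``.json``
metadata sidecar (montage, sampling rate, time axis, trial table, lock
event); the round trip is lossless.  Readers for BrainVision and EEGLAB
files delegate to :mod:`mne` (lazily imported) and normalise voltages to
microvolts.
"""

from __future__ import annotations

import json
import os
from pathlib import Path

import numpy as np
import pandas as pd

from .epochs import TRIAL_META_COLUMNS, Epochs
from .montage import Montage

__all__ = ["save_epochs", "load_epochs", "export_trial_table", "read_epochs"]

_SIDE_CAR_SUFFIX = ".json"
_ARRAY_SUFFIX = ".npy"


def _paths(path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in (_ARRAY_SUFFIX, _SIDE_CAR_SUFFIX):
        base = base.with_suffix("")
    return base.with_suffix(_ARRAY_SUFFIX), base.with_suffix(_SIDE_CAR_SUFFIX)


def save_epochs(epochs: Epochs, path) -> tuple[Path, Path]:
    """Write ``<path>.npy`` (voltages, μV) and ``<path>.json`` (metadata)."""
    arr_path, meta_path = _paths(path)
    arr_path.parent.mkdir(parents=True, exist_ok=True)
    np.save(arr_path, epochs.data)
    meta = {
        "format": "erpdecode-epochs",
        "version": 1,
        "montage": epochs.montage.to_dict(),
        "sampling_rate": epochs.sampling_rate,
        "times_ms": epochs.times.tolist(),
        "lock": epochs.lock,
        "trial_meta": epochs.trial_meta.to_dict(orient="list"),
    }
    meta_path.write_text(json.dumps(meta))
    return arr_path, meta_path


def load_epochs(path) -> Epochs:
    """Read an internal-container epoch set written by :func:`save_epochs`."""
    arr_path, meta_path = _paths(path)
    try:
        meta = json.loads(meta_path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"corrupt metadata sidecar {meta_path}: {exc}") from exc
    if meta.get("format") != "erpdecode-epochs":
        raise ValueError(f"{meta_path} is not an epoch container sidecar")
    try:
        data = np.load(arr_path, allow_pickle=False)
    except ValueError as exc:
        size = os.path.getsize(arr_path)
        raise ValueError(f"corrupt voltage array {arr_path} ({size} bytes): {exc}") from exc
    trial_meta = pd.DataFrame(meta["trial_meta"])
    missing = [c for c in TRIAL_META_COLUMNS if c not in trial_meta.columns]
    if missing:
        raise ValueError(f"container lacks trial annotations: {missing}")
    return Epochs(
        data=data,
        montage=Montage.from_dict(meta["montage"]),
        sampling_rate=float(meta["sampling_rate"]),
        times=np.asarray(meta["times_ms"], float),
        trial_meta=trial_meta,
        lock=meta["lock"],
    )


def export_trial_table(epochs: Epochs, path) -> Path:
    """Write the per-trial metadata table as TSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    epochs.trial_meta.to_csv(path, sep="\t", index=False)
    return path


def _epochs_from_mne(mne_epochs, montage_names=None) -> Epochs:
    """Convert an mne.Epochs with metadata into the internal container (μV)."""
    meta = mne_epochs.metadata
    if meta is None or any(c not in meta.columns for c in TRIAL_META_COLUMNS):
        raise ValueError(
            f"per-trial metadata with columns {TRIAL_META_COLUMNS} is required"
        )
    names = montage_names or mne_epochs.ch_names
    picked = mne_epochs.copy().pick(names)
    pos2d = np.array(
        [picked.info["chs"][i]["loc"][:2] for i in range(len(names))], dtype=float
    )
    if not np.all(np.isfinite(pos2d)):
        raise ValueError("channel positions missing; set a montage before reading")
    return Epochs(
        data=picked.get_data() * 1e6,  # volts -> μV
        montage=Montage(tuple(names), pos2d),
        sampling_rate=float(picked.info["sfreq"]),
        times=picked.times * 1000.0,
        trial_meta=meta.reset_index(drop=True),
        lock="response",
    )


def read_epochs(path, format: str = "container") -> Epochs:
    """Read epochs from the internal container or a standard EEG format.

    ``format`` is one of ``container``, ``eeglab-set`` (epoched .set file)
    or ``brainvision`` (.vhdr; requires events already epoched via mne).
    External formats require :mod:`mne` and per-trial metadata carrying
    subject/task/response/RT annotations.
    """
    if format == "container":
        return load_epochs(path)
    try:
        import mne  # noqa: PLC0415 — optional dependency
    except ImportError as exc:
        raise ImportError("reading EEG file formats requires the 'mne' package") from exc
    if format == "eeglab-set":
        return _epochs_from_mne(mne.io.read_epochs_eeglab(path))
    if format == "brainvision":
        raw = mne.io.read_raw_brainvision(path, preload=True)
        raise ValueError(
            "BrainVision data are continuous; segment them with "
            "erpdecode.preprocess.segment_epochs using your event table "
            f"(loaded {len(raw.ch_names)} channels)"
        )
    raise ValueError(f"unknown format {format!r}")
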