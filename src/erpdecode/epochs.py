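"""Single-trial epoch container.

An :class:`Epochs` holds a ``trial x channel x sample`` voltage array in
microvolts together with the montage, the sampling rate, a millisecond time
axis relative to the lock event, and a per-trial metadata table (subject,
task, response label, reaction time).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .montage import Montage

__all__ = ["Epochs", "TRIAL_META_COLUMNS"]

TRIAL_META_COLUMNS = ("subject_id", "task", "response", "rt")
RESPONSE_LABELS = ("error", "correct")


@dataclass
class Epochs:
    """Response- or stimulus-locked single-trial EEG segments (μV)."""

    data: np.ndarray  # (n_trials, n_channels, n_samples), μV
    montage: Montage
    sampling_rate: float
    times: np.ndarray  # ms relative to the lock event
    trial_meta: pd.DataFrame = field(repr=False)
    lock: str = "response"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("data must be (n_trials, n_channels, n_samples)")
        n_trials, n_ch, n_samp = self.data.shape
        if n_ch != len(self.montage):
            raise ValueError("channel dimension does not match montage")
        if n_samp != len(self.times):
            raise ValueError("sample dimension does not match time axis")
        if self.lock not in ("response", "stimulus"):
            raise ValueError(f"unknown lock event {self.lock!r}")
        meta = self.trial_meta.reset_index(drop=True)
        missing = [c for c in TRIAL_META_COLUMNS if c not in meta.columns]
        if missing:
            raise ValueError(f"trial_meta lacks columns {missing}")
        if len(meta) != n_trials:
            raise ValueError("trial_meta length does not match trial count")
        bad = set(meta["response"]) - set(RESPONSE_LABELS)
        if bad:
            raise ValueError(f"unknown response labels {sorted(bad)}")
        if np.isnan(self.data).any():
            raise ValueError("epoch data contain NaN")
        self.trial_meta = meta

    # ------------------------------------------------------------------ basics
    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def channel_index(self, name: str) -> int:
        return self.montage.index(name)

    def get_channel(self, name: str) -> np.ndarray:
        """(n_trials, n_samples) voltages of one channel."""
        return self.data[:, self.channel_index(name), :]

    @property
    def labels(self) -> np.ndarray:
        return self.trial_meta["response"].to_numpy()

    @property
    def rts(self) -> np.ndarray:
        return self.trial_meta["rt"].to_numpy(dtype=float)

    # --------------------------------------------------------------- selection
    def subset(self, index) -> "Epochs":
        """New Epochs restricted to the given trial indices or boolean mask."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        index = index.astype(int, copy=False)
        return replace(
            self,
            data=self.data[index],
            trial_meta=self.trial_meta.iloc[index].reset_index(drop=True),
        )

    def where(self, **conditions) -> "Epochs":
        """Subset by metadata equality, e.g. ``epochs.where(response="error")``."""
        mask = np.ones(self.n_trials, dtype=bool)
        for col, val in conditions.items():
            mask &= (self.trial_meta[col] == val).to_numpy()
        return self.subset(mask)

    def copy(self) -> "Epochs":
        return replace(self, data=self.data.copy(), trial_meta=self.trial_meta.copy())

    def time_mask(self, start_ms: float, end_ms: float) -> np.ndarray:
        """Boolean sample mask for start <= t <= end (endpoints inclusive)."""
        return (self.times >= start_ms) & (self.times <= end_ms)
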