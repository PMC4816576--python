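"""Single-trial feature sets for Ne/Pe decoding.

A feature is the windowed mean voltage of one trial at one electrode: the
Ne set uses five fronto-central electrodes in 20–100 ms, the Pe set five
centro-parietal electrodes in 180–250 ms, and the combined set concatenates
both (10 features).  Features are min-max scaled to [0, 1] with parameters
learned from a fitting (training) partition, and classes are balanced by
randomly subsampling correct trials to the error count.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .epochs import Epochs
from .montage import NE_ELECTRODES, PE_ELECTRODES

__all__ = [
    "FeatureSetSpec",
    "FeatureMatrix",
    "ScalerParams",
    "extract_features",
    "fit_scaler",
    "apply_scaler",
    "balance_classes",
]

NE_FEATURE_WINDOW = (20.0, 100.0)
PE_FEATURE_WINDOW = (180.0, 250.0)


@dataclass(frozen=True)
class FeatureSetSpec:
    """Which component windows/electrodes constitute the feature set."""

    name: str  # "ne", "pe" or "combined"

    def __post_init__(self) -> None:
        if self.name not in ("ne", "pe", "combined"):
            raise ValueError(f"unknown feature set {self.name!r}")

    @property
    def blocks(self) -> list[tuple[str, tuple[str, ...], tuple[float, float]]]:
        ne = ("Ne", NE_ELECTRODES, NE_FEATURE_WINDOW)
        pe = ("Pe", PE_ELECTRODES, PE_FEATURE_WINDOW)
        return {"ne": [ne], "pe": [pe], "combined": [ne, pe]}[self.name]

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(f"{comp}:{el}" for comp, els, _ in self.blocks for el in els)


FEATURE_SETS = tuple(FeatureSetSpec(n) for n in ("ne", "pe", "combined"))


@dataclass
class FeatureMatrix:
    """Trials x features table with labels and a scaling flag."""

    values: np.ndarray  # (n_trials, n_features)
    feature_names: tuple[str, ...]
    labels: np.ndarray  # per-trial "error"/"correct"
    scaled: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D")
        if len(self.labels) != self.values.shape[0]:
            raise ValueError("labels length must match number of rows")
        if np.isnan(self.values).any():
            raise ValueError("feature values contain NaN")

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, index) -> "FeatureMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return replace(self, values=self.values[index], labels=self.labels[index])

    def class_counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))


@dataclass(frozen=True)
class ScalerParams:
    """Per-feature min/max learned from a fitting set."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "mins", np.asarray(self.mins, float))
        object.__setattr__(self, "maxs", np.asarray(self.maxs, float))
        if self.mins.shape != self.maxs.shape or self.mins.ndim != 1:
            raise ValueError("mins/maxs must be matching 1-D arrays")
        if np.any(self.maxs < self.mins):
            raise ValueError("max must be >= min per feature")


def extract_features(epochs: Epochs, spec: FeatureSetSpec) -> FeatureMatrix:
    """Windowed mean voltage per trial and electrode (μV, unscaled)."""
    times = epochs.times
    cols = []
    for _, electrodes, (lo, hi) in spec.blocks:
        if lo < times[0] or hi > times[-1]:
            raise ValueError(f"feature window ({lo}, {hi}) outside the epoch time axis")
        mask = epochs.time_mask(lo, hi)
        for el in electrodes:
            cols.append(epochs.get_channel(el)[:, mask].mean(axis=1))
    return FeatureMatrix(
        values=np.column_stack(cols),
        feature_names=spec.feature_names,
        labels=epochs.labels.copy(),
        scaled=False,
    )


def fit_scaler(train: FeatureMatrix) -> ScalerParams:
    """Learn per-feature min/max from the fitting rows."""
    if train.n_trials < 2:
        raise ValueError("need at least 2 rows to fit the scaler")
    return ScalerParams(train.values.min(axis=0), train.values.max(axis=0))


def apply_scaler(fm: FeatureMatrix, params: ScalerParams) -> FeatureMatrix:
    """Map features linearly into [0, 1]; out-of-range values are clipped.

    Constant training features (max == min) map to 0.5.
    """
    if fm.n_features != len(params.mins):
        raise ValueError("feature count does not match scaler parameters")
    span = params.maxs - params.mins
    degenerate = span == 0
    safe_span = np.where(degenerate, 1.0, span)
    scaled = (fm.values - params.mins) / safe_span
    scaled[:, degenerate] = 0.5
    return replace(fm, values=np.clip(scaled, 0.0, 1.0), scaled=True)


def balance_classes(fm: FeatureMatrix, seed) -> FeatureMatrix:
    """Keep all error trials and an equal-size random sample of correct trials.

    Sampling is uniform without replacement; the balanced rows are then
    shuffled deterministically with the same seed.
    """
    errors = np.flatnonzero(fm.labels == "error")
    corrects = np.flatnonzero(fm.labels == "correct")
    if len(errors) == 0 or len(corrects) == 0:
        raise ValueError("both classes must be present")
    if len(corrects) < len(errors):
        raise ValueError(
            "fewer correct than error trials; swap the roles of the classes"
        )
    rng = np.random.default_rng(seed)
    sampled = rng.choice(corrects, size=len(errors), replace=False)
    idx = np.concatenate([errors, sampled])
    return fm.subset(rng.permutation(idx))
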