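"""Electrode montage: channel labels plus schematic 2-D head coordinates.

Coordinates live on a unit head circle (Cz at the origin, nose towards +y).
They are built programmatically from the extended 10-10 naming convention:
rim electrodes sit on the circle at fixed polar angles, inner electrodes are
placed by linear interpolation between the midline electrode of their row and
the rim electrode of the same row.  Mastoids (M1/M2) and PO9/PO10 sit just
outside the head circle.  The layout is schematic — it drives the simulator's
spatial falloff and scatter plots, not any quantitative geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Montage",
    "standard_montage",
    "analysis_montage",
    "NE_ELECTRODES",
    "PE_ELECTRODES",
    "MASTOIDS",
]

#: electrodes around the fronto-central Ne/ERN peak
NE_ELECTRODES = ("Fz", "FCz", "FC1", "FC2", "Cz")
#: electrodes around the centro-parietal Pe peak
PE_ELECTRODES = ("Cz", "FCz", "CPz", "C1", "C2")
MASTOIDS = ("M1", "M2")


@dataclass(frozen=True)
class Montage:
    """An ordered set of EEG channels with 2-D head-surface positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray = field(repr=False)  # (n_channels, 2)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        object.__setattr__(self, "channel_names", names)
        pos = np.asarray(self.positions, dtype=float)
        object.__setattr__(self, "positions", pos)
        if len(set(names)) != len(names):
            raise ValueError("channel names must be unique")
        if pos.shape != (len(names), 2):
            raise ValueError(f"positions must be ({len(names)}, 2), got {pos.shape}")
        if not np.all(np.isfinite(pos)):
            raise ValueError("positions must be finite")
        missing = [c for c in set(NE_ELECTRODES + PE_ELECTRODES) if c not in names]
        if missing:
            raise ValueError(f"montage lacks required Ne/Pe electrodes: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self.channel_names.index(name)
        except ValueError:
            raise KeyError(f"channel {name!r} not in montage") from None

    def __contains__(self, name: str) -> bool:
        return name in self.channel_names

    def distances_from(self, name: str) -> np.ndarray:
        """Euclidean distance of every channel from the named channel."""
        ref = self.positions[self.index(name)]
        return np.linalg.norm(self.positions - ref, axis=1)

    def subset(self, names) -> "Montage":
        idx = [self.index(n) for n in names]
        return Montage(tuple(names), self.positions[idx])

    def to_dict(self) -> dict:
        return {
            "channel_names": list(self.channel_names),
            "positions": self.positions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Montage":
        return cls(tuple(d["channel_names"]), np.asarray(d["positions"], float))


# rim electrodes: polar angle in degrees on the unit circle (0° = right ear,
# counter-clockwise), optionally with a radius > 1 for below-rim sites
_RIM = {
    "FPz": 90, "FP1": 108, "FP2": 72,
    "AF7": 126, "AF8": 54,
    "F7": 144, "F8": 36,
    "FT7": 162, "FT8": 18,
    "T7": 180, "T8": 0,
    "TP7": 198, "TP8": 342,
    "P7": 216, "P8": 324,
    "PO7": 234, "PO8": 306,
    "O1": 252, "Oz": 270, "O2": 288,
}
_BELOW_RIM = {"PO9": (240, 1.15), "PO10": (300, 1.15), "M1": (200, 1.15), "M2": (340, 1.15)}

# midline y-coordinate per row (x = 0)
_MIDLINE = {
    "FPz": 1.0, "AFz": 0.8, "Fz": 0.6, "FCz": 0.3, "Cz": 0.0,
    "CPz": -0.3, "Pz": -0.6, "POz": -0.8, "Oz": -1.0,
}

# inner electrodes: (midline anchor, rim anchor, interpolation fraction)
_INNER = {
    "AF3": ("AFz", "AF7", 0.5), "AF4": ("AFz", "AF8", 0.5),
    "F3": ("Fz", "F7", 0.5), "F4": ("Fz", "F8", 0.5),
    "FC1": ("FCz", "FT7", 0.25), "FC2": ("FCz", "FT8", 0.25),
    "FC3": ("FCz", "FT7", 0.5), "FC4": ("FCz", "FT8", 0.5),
    "FC5": ("FCz", "FT7", 0.75), "FC6": ("FCz", "FT8", 0.75),
    "C1": ("Cz", "T7", 0.25), "C2": ("Cz", "T8", 0.25),
    "C3": ("Cz", "T7", 0.5), "C4": ("Cz", "T8", 0.5),
    "C5": ("Cz", "T7", 0.75), "C6": ("Cz", "T8", 0.75),
    "CP1": ("CPz", "TP7", 0.25), "CP2": ("CPz", "TP8", 0.25),
    "CP3": ("CPz", "TP7", 0.5), "CP4": ("CPz", "TP8", 0.5),
    "CP5": ("CPz", "TP7", 0.75), "CP6": ("CPz", "TP8", 0.75),
    "P1": ("Pz", "P7", 0.25), "P2": ("Pz", "P8", 0.25),
    "P3": ("Pz", "P7", 0.5), "P4": ("Pz", "P8", 0.5),
    "PO3": ("POz", "PO7", 0.5), "PO4": ("POz", "PO8", 0.5),
}

#: recording montage channel order (10-10 subset with linked-mastoid sites)
STANDARD_CHANNELS = (
    "FPz", "FP1", "FP2", "AFz", "AF7", "AF3", "AF4", "AF8",
    "Fz", "F7", "F3", "F4", "F8",
    "FCz", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "Cz", "C1", "C2", "C4", "C6", "T8",
    "TP7", "TP8",
    "CPz", "CP5", "CP3", "CP1", "CP2", "CP4", "CP6",
    "Pz", "P7", "P3", "P1", "P2", "P4", "P8",
    "POz", "PO9", "PO7", "PO3", "PO4", "PO8", "PO10",
    "Oz", "O1", "O2", "M1", "M2",
)


def _position(name: str) -> np.ndarray:
    if name in _MIDLINE:
        return np.array([0.0, _MIDLINE[name]])
    if name in _RIM:
        a = np.deg2rad(_RIM[name])
        return np.array([np.cos(a), np.sin(a)])
    if name in _BELOW_RIM:
        deg, r = _BELOW_RIM[name]
        a = np.deg2rad(deg)
        return r * np.array([np.cos(a), np.sin(a)])
    if name in _INNER:
        mid, rim, f = _INNER[name]
        return (1 - f) * _position(mid) + f * _position(rim)
    raise KeyError(f"no coordinate rule for channel {name!r}")


def standard_montage() -> Montage:
    """The full recording montage (59 scalp channels incl. mastoids)."""
    pos = np.array([_position(c) for c in STANDARD_CHANNELS])
    return Montage(STANDARD_CHANNELS, pos)


def analysis_montage() -> Montage:
    """Reduced montage: the Ne/Pe feature electrodes plus the mastoids.

    Every channel the feature extraction and ERP quantification touch is
    present; useful to keep large simulated cohorts cheap.
    """
    names = ("Fz", "FCz", "FC1", "FC2", "Cz", "CPz", "C1", "C2", "M1", "M2")
    return standard_montage().subset(names)
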