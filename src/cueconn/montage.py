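"""32-channel 10-20 montage: labels, 2-D positions, and region assignment.

The default region table groups the recording montage into six scalp
regions (frontal, central, left/right temporal, parietal, occipital) used
for region-level aggregation of supra-threshold connections.  The table can
be overridden by the user (e.g. from a YAML mapping) for other montages.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Montage", "CHANNELS_32", "DEFAULT_REGIONS", "REGION_ORDER"]

#: recording sites of the 32-channel cap, 10-20 convention
CHANNELS_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "TP9", "CP3", "CPz", "CP4", "TP8", "TP10",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
]

REGION_ORDER = [
    "frontal", "central", "left_temporal", "right_temporal", "parietal",
    "occipital",
]

DEFAULT_REGIONS: dict[str, str] = {}
for _ch in ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FT7", "FC3", "FCz",
            "FC4", "FT8"]:
    DEFAULT_REGIONS[_ch] = "frontal"
for _ch in ["C3", "Cz", "C4"]:
    DEFAULT_REGIONS[_ch] = "central"
for _ch in ["T7", "TP7", "TP9"]:
    DEFAULT_REGIONS[_ch] = "left_temporal"
for _ch in ["T8", "TP8", "TP10"]:
    DEFAULT_REGIONS[_ch] = "right_temporal"
for _ch in ["CP3", "CPz", "CP4", "P3", "Pz", "P4", "P7", "P8"]:
    DEFAULT_REGIONS[_ch] = "parietal"
for _ch in ["O1", "Oz", "O2"]:
    DEFAULT_REGIONS[_ch] = "occipital"


def _positions_from_mne(labels: list[str]) -> dict[str, tuple[float, float]]:
    """Top-down 2-D electrode positions from the standard 10-20 layout."""
    try:
        import warnings

        import mne

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            std = mne.channels.make_standard_montage("standard_1020")
        pos3 = std.get_positions()["ch_pos"]
        out = {}
        for lab in labels:
            if lab in pos3:
                x, y, _ = pos3[lab]
                out[lab] = (float(x), float(y))
        if len(out) == len(labels):
            return out
    except Exception:
        pass
    # fallback: evenly spaced ring (keeps plotting usable for any label set)
    n = len(labels)
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return {lab: (float(np.cos(a)), float(np.sin(a)))
            for lab, a in zip(labels, ang)}


@dataclass
class Montage:
    """Channel label -> (2-D position, scalp region) mapping."""

    labels: list[str] = field(default_factory=lambda: list(CHANNELS_32))
    regions: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_REGIONS))
    positions: dict[str, tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        if self.positions is None:
            self.positions = _positions_from_mne(self.labels)

    def region_of(self, channel: str) -> str:
        try:
            return self.regions[channel]
        except KeyError:
            raise KeyError(f"channel {channel!r} has no region assignment") from None

    def validate(self, channel_labels: list[str]) -> None:
        """Ensure every channel of an EpochSet maps to exactly one region."""
        missing = [c for c in channel_labels if c not in self.regions]
        if missing:
            raise KeyError(f"unmapped channel(s): {missing}")

    @property
    def region_names(self) -> list[str]:
        seen = [r for r in REGION_ORDER if r in set(self.regions.values())]
        extra = sorted(set(self.regions.values()) - set(seen))
        return seen + extra
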