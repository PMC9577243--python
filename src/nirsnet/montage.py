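"""Sensorimotor fNIRS montage: channels, hemispheres, homotopic pairing.

The default probe covers the hand-motor cortex around scalp sites C3 (left
hemisphere) and C4 (right hemisphere) with 10 sources and 8 detectors at a
3 cm inter-optode distance, giving 12 measurement channels per hemisphere.
Each left-hemisphere channel has a mirror-symmetric ("homotopic") partner on
the right; the 12 homotopic pairs are the basis of the laterality analysis,
while the 12 x 12 x 2 directed cross-hemisphere ("heterotopic") pairs are
the basis of the causal-network analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

__all__ = ["Channel", "Montage", "build_default_montage"]


class Channel(NamedTuple):
    """One source-detector pairing with its hemisphere assignment."""

    source: str
    detector: str
    hemisphere: str  # "left" | "right"

    @property
    def name(self) -> str:
        return f"{self.source}_{self.detector}"


# Right-hemisphere (around C4) channels; sources S1-S5, detectors D1-D4.
_RIGHT_CHANNELS = (
    ("S1", "D1"), ("S2", "D1"), ("S1", "D2"), ("S3", "D1"),
    ("S2", "D3"), ("S3", "D2"), ("S3", "D3"), ("S4", "D2"),
    ("S3", "D4"), ("S5", "D3"), ("S4", "D4"), ("S5", "D4"),
)

# Mirror maps completing the left-hemisphere layout by geometric symmetry.
_MIRROR_SOURCE = {"S1": "S7", "S2": "S6", "S3": "S8", "S4": "S10", "S5": "S9"}
_MIRROR_DETECTOR = {"D1": "D5", "D2": "D7", "D3": "D6", "D4": "D8"}


@dataclass(frozen=True)
class Montage:
    """Probe layout over both sensorimotor cortices.

    Parameters
    ----------
    sources, detectors
        Optode identifiers ("S1".."S10", "D1".."D8" by default).
    channels
        24 source-detector channels, 12 per hemisphere.
    homotopic_pairs
        12 ``(left_channel, right_channel)`` name pairs; every channel
        appears in exactly one pair.
    inter_optode_distance
        Source-detector separation in cm (3 cm by default).
    """

    sources: tuple[str, ...]
    detectors: tuple[str, ...]
    channels: tuple[Channel, ...]
    homotopic_pairs: tuple[tuple[str, str], ...]
    inter_optode_distance: float = 3.0

    def __post_init__(self) -> None:
        if len(self.channels) != 24:
            raise ValueError(f"expected 24 channels, got {len(self.channels)}")
        by_hemi = {"left": self.left_channels, "right": self.right_channels}
        for hemi, chans in by_hemi.items():
            if len(chans) != 12:
                raise ValueError(
                    f"expected 12 {hemi}-hemisphere channels, got {len(chans)}"
                )
        if self.inter_optode_distance <= 0:
            raise ValueError("inter_optode_distance must be positive (cm)")
        if len(self.homotopic_pairs) != 12:
            raise ValueError(
                f"expected 12 homotopic pairs, got {len(self.homotopic_pairs)}"
            )
        names = set(self.channel_names)
        used: set[str] = set()
        left = set(self.left_channels)
        right = set(self.right_channels)
        for lname, rname in self.homotopic_pairs:
            if lname not in left or rname not in right:
                raise ValueError(
                    f"homotopic pair ({lname}, {rname}) must pair a left "
                    "channel with a right channel"
                )
            if lname in used or rname in used:
                raise ValueError(f"channel reused in homotopic pairs: {lname}/{rname}")
            used.update((lname, rname))
        if used != names:
            raise ValueError("homotopic pairs must cover every channel exactly once")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels)

    @property
    def hemispheres(self) -> tuple[str, ...]:
        return tuple(ch.hemisphere for ch in self.channels)

    @property
    def left_channels(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels if ch.hemisphere == "left")

    @property
    def right_channels(self) -> tuple[str, ...]:
        return tuple(ch.name for ch in self.channels if ch.hemisphere == "right")

    def hemisphere_of(self, channel_name: str) -> str:
        for ch in self.channels:
            if ch.name == channel_name:
                return ch.hemisphere
        raise KeyError(f"unknown channel {channel_name!r}")

    def heterotopic_pairs(self) -> Iterator[tuple[str, str]]:
        """Yield all 288 ordered cross-hemisphere (src, dst) channel pairs."""
        left, right = self.left_channels, self.right_channels
        for a in left:
            for b in right:
                yield (a, b)
                yield (b, a)


def build_default_montage(inter_optode_distance: float = 3.0) -> Montage:
    """Build the default 24-channel bilateral sensorimotor montage.

    The right-hemisphere channel set and seven of the homotopic pairs follow
    the published probe layout; the remaining left-hemisphere channels and
    pairs are completed by mirror symmetry of the grid. Pass a custom
    ``Montage`` anywhere downstream to override the layout.
    """
    channels: list[Channel] = []
    pairs: list[tuple[str, str]] = []
    for src, det in _RIGHT_CHANNELS:
        right = Channel(src, det, "right")
        left = Channel(_MIRROR_SOURCE[src], _MIRROR_DETECTOR[det], "left")
        channels.append(left)
        channels.append(right)
        pairs.append((left.name, right.name))
    sources = tuple(f"S{i}" for i in range(1, 11))
    detectors = tuple(f"D{i}" for i in range(1, 9))
    return Montage(
        sources=sources,
        detectors=detectors,
        channels=tuple(channels),
        homotopic_pairs=tuple(pairs),
        inter_optode_distance=inter_optode_distance,
    )
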