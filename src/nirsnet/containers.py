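"""In-memory containers for fNIRS recordings, epochs and block averages."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["RawIntensity", "OpticalDensity", "HbTimeSeries", "EpochSet", "BlockAverage"]


@dataclass
class RawIntensity:
    """Dual-wavelength light-intensity recording.

    ``data`` has shape (n_channels, 2, n_samples); axis 1 indexes the two
    laser wavelengths. ``reference`` (n_channels, 2) is the per-trace
    reference intensity that defines optical density zero.
    """

    data: np.ndarray
    fs: float
    channels: tuple[str, ...]
    wavelengths: tuple[float, float]
    hemispheres: tuple[str, ...]
    reference: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("intensity data must have shape (n_channels, 2, n_samples)")
        if self.data.shape[0] != len(self.channels):
            raise ValueError("channel count mismatch")
        if np.any(self.data <= 0):
            ch, wl, t = np.argwhere(self.data <= 0)[0]
            raise ValueError(
                f"nonpositive intensity at channel {self.channels[ch]}, "
                f"wavelength {self.wavelengths[wl]} nm, sample {t}"
            )

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class OpticalDensity:
    """Per-channel, per-wavelength optical-density change series."""

    data: np.ndarray  # (n_channels, 2, n_samples)
    fs: float
    channels: tuple[str, ...]
    wavelengths: tuple[float, float]
    hemispheres: tuple[str, ...]


@dataclass
class HbTimeSeries:
    """Oxy-/deoxyhemoglobin concentration-change series, micromol/L.

    ``hbo`` and ``hbr`` are (n_channels, n_samples) arrays on the same time
    base at sampling rate ``fs`` (Hz).
    """

    hbo: np.ndarray
    hbr: np.ndarray
    fs: float
    channels: tuple[str, ...]
    hemispheres: tuple[str, ...]

    def __post_init__(self) -> None:
        self.hbo = np.asarray(self.hbo, dtype=float)
        self.hbr = np.asarray(self.hbr, dtype=float)
        if self.hbo.shape != self.hbr.shape:
            raise ValueError("HbO and HbR must share one time base")
        if self.hbo.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.hbo.shape[0]} traces for {len(self.channels)} channels"
            )
        if len(self.hemispheres) != len(self.channels):
            raise ValueError("hemisphere labels must match channels")

    @property
    def n_channels(self) -> int:
        return self.hbo.shape[0]

    @property
    def n_samples(self) -> int:
        return self.hbo.shape[1]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.fs

    def copy(self) -> "HbTimeSeries":
        return replace(self, hbo=self.hbo.copy(), hbr=self.hbr.copy())

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None


@dataclass
class EpochSet:
    """Task-locked, baseline-corrected epochs.

    ``data`` has shape (n_epochs, n_channels, n_samples) spanning
    ``[tmin, tmax]`` around each task onset; every epoch was baseline
    corrected by subtracting its per-channel mean over the baseline window
    (``[-5, 0)`` s by default).
    """

    data: np.ndarray
    conditions: tuple[str, ...]
    tmin: float
    tmax: float
    fs: float
    channels: tuple[str, ...]
    hemispheres: tuple[str, ...]
    baseline: tuple[float, float] = (-5.0, 0.0)
    n_dropped: int = 0

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[2]) / self.fs


@dataclass
class BlockAverage:
    """Per-condition mean epoch with pointwise dispersion.

    ``data`` and ``sd`` have shape (n_channels, n_samples); ``sd`` is the
    pointwise standard deviation over the ``n_blocks`` averaged epochs (or
    over subjects, for a grand average).
    """

    data: np.ndarray
    sd: np.ndarray
    n_blocks: int
    condition: str
    tmin: float
    fs: float
    channels: tuple[str, ...]
    hemispheres: tuple[str, ...]

    @property
    def times(self) -> np.ndarray:
        return self.tmin + np.arange(self.data.shape[1]) / self.fs

    @property
    def tmax(self) -> float:
        return float(self.times[-1])

    def channel_index(self, name: str) -> int:
        try:
            return self.channels.index(name)
        except ValueError:
            raise KeyError(f"unknown channel {name!r}") from None
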