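"""Multichannel fNIRS concentration-change recordings.

A :class:`Recording` holds oxygenated (HbO) and deoxygenated (HbR)
hemoglobin concentration changes for a fixed optode montage: 8
source-detector channels at 3.5 cm separation on the forehead, sampled at
25 Hz.  Values are concentration changes in arbitrary micromolar units;
fNIRS systems report changes relative to an unknown baseline, so only
relative amplitudes are meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Chromophore axis ordering used throughout the package.
CHROMOPHORES: tuple[str, str] = ("HbO", "HbR")

#: Default montage size (4 sources x 4 detectors, time-multiplexed pairs).
N_CHANNELS: int = 8

#: Default sampling rate of the acquisition system, Hz.
SAMPLING_RATE_HZ: float = 25.0

#: Source-detector separation of the montage, cm.
OPTODE_SEPARATION_CM: float = 3.5


@dataclass(frozen=True)
class ChannelInfo:
    """Geometry of one source-detector channel."""

    source: int
    detector: int
    separation_cm: float = OPTODE_SEPARATION_CM


def default_montage(n_channels: int = N_CHANNELS) -> list[ChannelInfo]:
    """Forehead montage: each detector reads two neighbouring sources."""
    return [ChannelInfo(source=i // 2 + 1, detector=(i + 1) // 2 + 1) for i in range(n_channels)]


@dataclass
class Recording:
    """Concentration-change time series, shape ``(channel, chromophore, sample)``.

    The chromophore axis is ordered ``(HbO, HbR)`` (see :data:`CHROMOPHORES`).
    """

    data: np.ndarray
    sampling_rate: float = SAMPLING_RATE_HZ
    channel_meta: list[ChannelInfo] = field(default_factory=default_montage)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[1] != len(CHROMOPHORES):
            raise ValueError(
                f"data must be (channel, chromophore, sample) with "
                f"{len(CHROMOPHORES)} chromophores, got shape {self.data.shape}"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite values")
        if len(self.channel_meta) != self.data.shape[0]:
            raise ValueError("channel_meta length does not match channel axis")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.sampling_rate

    def series(self, channel: int, chromophore: str) -> np.ndarray:
        """Return one channel/chromophore trace (a view)."""
        return self.data[channel, CHROMOPHORES.index(chromophore)]

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.sampling_rate, list(self.channel_meta))
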