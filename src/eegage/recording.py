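"""In-memory containers for multichannel EEG."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RawRecording", "EpochSet"]


@dataclass
class RawRecording:
    """A channels x samples EEG matrix in microvolts.

    Parameters
    ----------
    data
        2-D array, shape ``(n_channels, n_samples)``, in microvolts.
    fs
        Sampling rate in Hz.
    labels
        Ordered channel names, one per row of ``data``.
    """

    data: np.ndarray
    fs: float
    labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        self.labels = list(self.labels)
        if len(self.labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.labels)} labels for {self.data.shape[0]} channels"
            )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def copy(self) -> "RawRecording":
        return RawRecording(self.data.copy(), self.fs, list(self.labels))


@dataclass
class EpochSet:
    """Fixed-length, possibly overlapping segments of a recording.

    ``data`` has shape ``(n_channels, m, epoch_samples)`` where ``m`` is the
    epoch count per channel; every channel is segmented identically so the
    epoch axis is shared.
    """

    data: np.ndarray
    fs: float
    labels: list[str]
    epoch_len: float
    overlap: float
    starts: np.ndarray = field(default=None)  # start sample of each epoch

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (channels, epochs, samples)")
        if self.data.shape[1] < 1:
            raise ValueError("need at least one epoch")
        if self.starts is None:
            step = self.epoch_len * (1.0 - self.overlap) * self.fs
            self.starts = np.round(np.arange(self.data.shape[1]) * step).astype(int)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def m(self) -> int:
        """Epoch count per channel."""
        return self.data.shape[1]

    @property
    def epoch_samples(self) -> int:
        return self.data.shape[2]
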