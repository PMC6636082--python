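"""Shared in-memory containers for EEG and analysis results."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class EEGRecording:
    """Multichannel EEG: a channels × time sample matrix with metadata."""

    data: np.ndarray
    rate: float
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]
        if len(self.channel_names) != self.n_channels:
            raise ValueError("channel_names length must match data rows")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.rate
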