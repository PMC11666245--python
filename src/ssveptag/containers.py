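"""In-memory containers shared across pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Recording:
    """Continuous multi-channel EEG.

    data : (n_channels, n_samples) array, microvolts
    sampling_rate : Hz
    channel_labels : list of channel names, row order of ``data``
    events : list of (sample_index, condition_label) condition onsets
    meta : free-form metadata (participant_id, session_id, age_days, ...)
    """

    data: np.ndarray
    sampling_rate: float
    channel_labels: list
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.data.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"channel count mismatch: {self.data.shape[0]} rows vs "
                f"{len(self.channel_labels)} labels"
            )
        for s, _ in self.events:
            if not (0 <= s < self.data.shape[1]):
                raise ValueError(f"event sample index {s} out of range")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.sampling_rate, list(self.channel_labels),
            [tuple(e) for e in self.events], dict(self.meta),
        )


@dataclass
class EpochSet:
    """Segmented epochs with a per-epoch-per-channel validity mask.

    data : (n_epochs, n_channels, n_samples) array, microvolts
    condition : length-n_epochs sequence of category labels
    valid : (n_epochs, n_channels) boolean mask
    """

    data: np.ndarray
    condition: np.ndarray
    valid: np.ndarray
    sampling_rate: float
    epoch_duration: float
    channel_labels: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.condition = np.asarray(self.condition)
        self.valid = np.asarray(self.valid, dtype=bool)
        n_e, n_c, n_s = self.data.shape
        if len(self.condition) != n_e:
            raise ValueError("every epoch needs a condition label")
        if self.valid.shape != (n_e, n_c):
            raise ValueError("valid mask must be (n_epochs, n_channels)")
        if abs(self.epoch_duration * self.sampling_rate - n_s) > 1.0:
            raise ValueError("epoch_duration inconsistent with sample count")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), self.condition.copy(), self.valid.copy(),
            self.sampling_rate, self.epoch_duration,
            list(self.channel_labels), dict(self.meta),
        )
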