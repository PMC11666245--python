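"""Experiment design for the frequency-tagging paradigm.

Images from five categories are shown in a rapid stream at the image-update
rate (4.286 Hz, one image every ~233 ms).  Every fifth image belongs to the
target category, so target-category images recur at 0.857 Hz.  A recording
sequence lasts 70 s and contains one 14 s condition block per category, each
with a one-cycle stimulus fade-in and fade-out.

Rates are stored as exact rationals (30/7 Hz, 6/7 Hz) so that at the 420 Hz
analysis rate every period is an integer number of samples: one category
cycle (the analysis epoch) is 490 samples, one image period is 98 samples,
and a two-epoch segment of 980 samples yields a DFT bin spacing of
3/7 ≈ 0.4286 Hz.
"""

from __future__ import annotations

from dataclasses import dataclass


DEFAULT_CATEGORIES = ("faces", "limbs", "corridors", "characters", "cars")


@dataclass(frozen=True)
class ExperimentDesign:
    image_rate: float = 30.0 / 7.0          # Hz, image-update frequency
    category_rate: float = 6.0 / 7.0        # Hz, target-category frequency
    n_categories: int = 5
    category_names: tuple = DEFAULT_CATEGORIES
    epoch_duration: float = 7.0 / 6.0       # s, one category cycle (5 images)
    condition_duration: float = 14.0        # s per condition block
    fade_duration: float = 7.0 / 6.0        # s fade-in and fade-out
    sampling_rate_raw: float = 500.0        # Hz, acquisition rate
    sampling_rate_analysis: float = 420.0   # Hz, analysis rate

    def __post_init__(self):
        if abs(self.category_rate - self.image_rate / self.n_categories) > 1e-9:
            raise ValueError("category_rate must equal image_rate / n_categories")
        if abs(self.epoch_duration - self.n_categories / self.image_rate) > 1e-9:
            raise ValueError("epoch_duration must equal one category cycle")
        ratio = self.condition_duration / self.epoch_duration
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError("condition_duration must be an integer number of epochs")
        if len(self.category_names) != self.n_categories:
            raise ValueError("category_names length must equal n_categories")

    @property
    def epochs_per_condition(self) -> int:
        return round(self.condition_duration / self.epoch_duration)

    @property
    def sequence_duration(self) -> float:
        return self.condition_duration * self.n_categories

    @property
    def epoch_samples(self) -> int:
        return round(self.epoch_duration * self.sampling_rate_analysis)

    @property
    def image_period_samples(self) -> int:
        return round(self.sampling_rate_analysis / self.image_rate)

    @property
    def segment_duration(self) -> float:
        """Duration of a paired-epoch segment (two category cycles)."""
        return 2.0 * self.epoch_duration

    @property
    def segment_samples(self) -> int:
        return 2 * self.epoch_samples

    @property
    def bin_spacing(self) -> float:
        """DFT resolution of the paired-epoch segment, in Hz."""
        return 1.0 / self.segment_duration
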