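"""Two-step artifact pipeline: filter, resample, bad-channel interpolation,
common-average re-reference, epoching, channel-wise epoch rejection.

The fixed stage order is: bandpass filter -> resample -> channel repair ->
average reference -> epoch -> channel-wise rejection.  Channel repair uses
absolute-voltage thresholds and replaces a flagged channel with the unweighted
mean of its six nearest neighbors; epoch rejection marks (epoch, channel)
cells invalid when too large a fraction of samples exceeds threshold, leaving
the data untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal

from .containers import EpochSet, Recording
from .design import ExperimentDesign
from .montage import Montage


@dataclass(frozen=True)
class PreprocessProfile:
    bandpass_low: float = 0.03            # Hz
    bandpass_high: float = 50.0           # Hz
    resample_to: float = 420.0            # Hz
    channel_sample_threshold: float = 125.0   # uV (midpoint of 100-150)
    channel_bad_fraction: float = 0.20
    epoch_sample_threshold: float = 175.0     # uV (midpoint of 150-200)
    epoch_bad_fraction: float = 0.15
    n_neighbors: int = 6
    min_epochs_per_condition: int = 20
    exclude_fade_epochs: bool = True

    def __post_init__(self):
        if not (0 < self.bandpass_low < self.bandpass_high < self.resample_to / 2):
            raise ValueError("need 0 < low < high < resample_to/2")
        for f in (self.channel_bad_fraction, self.epoch_bad_fraction):
            if not (0 < f < 1):
                raise ValueError("bad fractions must be in (0, 1)")
        if self.channel_sample_threshold <= 0 or self.epoch_sample_threshold <= 0:
            raise ValueError("thresholds must be positive")


#: Infant thresholds (ranges 100-150 / 150-200 uV, midpoints used).
INFANT = PreprocessProfile()
#: Adult thresholds: 30 uV channel threshold at 15%, 30-80 uV epoch range at 10%.
ADULT = PreprocessProfile(
    channel_sample_threshold=30.0, channel_bad_fraction=0.15,
    epoch_sample_threshold=55.0, epoch_bad_fraction=0.10,
)


def get_profile(name: str) -> PreprocessProfile:
    try:
        return {"infant": INFANT, "adult": ADULT}[name]
    except KeyError:
        raise ValueError(f"unknown profile: {name!r} (expected infant|adult)") from None


def bandpass_filter(recording: Recording, profile: PreprocessProfile = INFANT) -> Recording:
    """Zero-phase bandpass, realized as a 2nd-order high-pass cascaded with an
    8th-order low-pass (Butterworth, forward-backward)."""
    fs = recording.sampling_rate
    if fs <= 2 * profile.bandpass_high:
        raise ValueError("sampling rate must exceed twice the bandpass_high corner")
    sos_hp = signal.butter(2, profile.bandpass_low, "highpass", fs=fs, output="sos")
    sos_lp = signal.butter(8, profile.bandpass_high, "lowpass", fs=fs, output="sos")
    sos = np.vstack([sos_hp, sos_lp])
    out = recording.copy()
    out.data = signal.sosfiltfilt(sos, out.data, axis=1)
    return out


def resample(recording: Recording, target_rate: float) -> Recording:
    """Anti-aliased polyphase resampling; event indices are rescaled."""
    fs = recording.sampling_rate
    if target_rate > fs:
        raise ValueError("target rate must not exceed the original rate")
    if target_rate == fs:
        return recording.copy()
    from fractions import Fraction

    frac = Fraction(target_rate / fs).limit_denominator(10000)
    out = recording.copy()
    out.data = signal.resample_poly(out.data, frac.numerator, frac.denominator, axis=1)
    out.sampling_rate = target_rate
    out.events = [
        (int(round(s * target_rate / fs)), lab) for s, lab in recording.events
    ]
    return out


def detect_and_interpolate_channels(
    recording: Recording, montage: Montage, profile: PreprocessProfile = INFANT,
) -> tuple[Recording, list]:
    """Replace channels whose supra-threshold sample fraction is strictly
    greater than ``channel_bad_fraction`` with the mean of their nearest
    neighbors' original traces."""
    frac = np.mean(np.abs(recording.data) > profile.channel_sample_threshold, axis=1)
    bad = np.flatnonzero(frac > profile.channel_bad_fraction)
    if len(bad) > recording.n_channels / 2:
        raise ValueError(
            f"{len(bad)} of {recording.n_channels} channels exceed the artifact "
            "criterion; recording unusable"
        )
    out = recording.copy()
    original = recording.data
    repaired = []
    for i in bad:
        label = recording.channel_labels[i]
        nbrs = montage.neighbors(label, profile.n_neighbors)
        idx = montage.indices(nbrs)
        out.data[i] = original[idx].mean(axis=0)
        repaired.append(label)
    return out, repaired


def rereference_average(recording: Recording) -> Recording:
    """Common-average reference: subtract the across-channel mean at every
    sample (idempotent)."""
    if recording.n_channels < 2:
        raise ValueError("need at least two channels to re-reference")
    out = recording.copy()
    out.data = out.data - out.data.mean(axis=0, keepdims=True)
    return out


def epoch(
    recording: Recording,
    design: ExperimentDesign,
    exclude_fade: bool = True,
) -> EpochSet:
    """Cut non-overlapping category-cycle epochs aligned to target-category
    stimulus onsets; fade-in and fade-out cycles are dropped."""
    if not recording.events:
        raise ValueError("recording has no condition-onset events")
    fs = recording.sampling_rate
    n_per_cond = design.epochs_per_condition
    n_fade = round(design.fade_duration / design.epoch_duration) if exclude_fade else 0
    n_samp = round(design.epoch_duration * fs)
    epochs, labels = [], []
    for onset, cond in recording.events:
        for k in range(n_fade, n_per_cond - n_fade):
            start = onset + round(k * design.epoch_duration * fs)
            stop = start + n_samp
            if stop > recording.n_samples:
                break
            epochs.append(recording.data[:, start:stop])
            labels.append(cond)
    if not epochs:
        raise ValueError("no complete epochs could be cut")
    data = np.stack(epochs)
    return EpochSet(
        data=data,
        condition=np.array(labels),
        valid=np.ones(data.shape[:2], dtype=bool),
        sampling_rate=fs,
        epoch_duration=design.epoch_duration,
        channel_labels=list(recording.channel_labels),
        meta=dict(recording.meta),
    )


def reject_epochs(epochs: EpochSet, profile: PreprocessProfile = INFANT) -> EpochSet:
    """Mark (epoch, channel) cells invalid where the fraction of samples with
    absolute value above threshold is strictly greater than
    ``epoch_bad_fraction``; the data itself is untouched."""
    frac = np.mean(np.abs(epochs.data) > profile.epoch_sample_threshold, axis=2)
    out = epochs.copy()
    out.valid = epochs.valid & ~(frac > profile.epoch_bad_fraction)
    for cond in np.unique(out.condition):
        rows = out.condition == cond
        dead = np.flatnonzero(~out.valid[rows].any(axis=0))
        for c in dead:
            label = out.channel_labels[c] if out.channel_labels else c
            warnings.warn(
                f"channel {label} has no valid epochs for condition {cond!r}; "
                "it will be excluded downstream for that condition",
                stacklevel=2,
            )
    return out


def preprocess_recording(
    recording: Recording,
    montage: Montage,
    design: ExperimentDesign,
    profile: PreprocessProfile = INFANT,
) -> tuple[EpochSet, dict]:
    """Run the full fixed-order pipeline; returns the epoch set and a report
    with repaired channels and rejection counts."""
    rec = bandpass_filter(recording, profile)
    rec = resample(rec, profile.resample_to)
    rec, repaired = detect_and_interpolate_channels(rec, montage, profile)
    rec = rereference_average(rec)
    eps = epoch(rec, design, exclude_fade=profile.exclude_fade_epochs)
    eps = reject_epochs(eps, profile)
    report = {
        "repaired_channels": repaired,
        "n_epochs": int(eps.n_epochs),
        "n_rejected_cells": int((~eps.valid).sum()),
        "rejected_fraction": float((~eps.valid).mean()),
    }
    return eps, report
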