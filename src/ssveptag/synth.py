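"""Synthetic infant EEG cohorts with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes, so every downstream stage can be exercised and validated without
real data:

* a general visual response entrained at the image-update rate (4.286 Hz
  and harmonics) with an occipital topography, whose cycle waveform has two
  deflections in the youngest infants and four later on, with peak latencies
  shrinking linearly in log10(age);
* a category-selective response at the target-category rate (0.857 Hz and
  harmonics) with a lateral occipitotemporal topography; faces have a
  positive deflection near 500 ms followed by a negative one near 900 ms,
  other categories a single negative deflection near 500 ms;
* 1/f background noise with random phases;
* transient high-amplitude artifacts on random channel subsets, scheduled
  as a Poisson process, to exercise the two-step artifact rejection;
* cross-sectional + longitudinal age structure over 3-15 months.

Waveform deflections are Gaussian-windowed lobes; each component waveform is
rescaled so that its one-sided Fourier amplitude at its fundamental equals
the specified amplitude in microvolts, which gives the amplitude-recovery
tests an exact target.  All randomness derives from ``GroundTruthSpec.rng_seed``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import Recording
from .design import ExperimentDesign
from .montage import Montage, gsn128

AGE_REF_DAYS = 90.0  # reference age for log-age amplitude/latency maps

# default topography foci: occipital ROI for the visual response, bilateral
# occipitotemporal ROIs for the category response (channel numbers of the
# 128-channel net)
OCC_FOCUS = tuple(f"E{c}" for c in (69, 70, 71, 74, 75, 76, 82, 83, 89))
LAT_FOCUS = tuple(
    f"E{c}" for c in (57, 58, 59, 63, 64, 65, 68, 90, 91, 94, 95, 96, 99, 100)
)


def make_topography(montage: Montage, focus_channels, spread: float) -> np.ndarray:
    """Non-negative channel weights with Gaussian falloff from the focus set.

    Falloff is with planar distance to the nearest focus electrode, so in the
    ``spread -> 0`` limit the weight concentrates on the focus channels in
    equal shares.  Weights are normalized to unit sum of squares.
    """
    if spread <= 0:
        raise ValueError("spread must be positive")
    focus_idx = montage.indices(focus_channels)  # raises on unknown label
    pos = montage.positions_2d
    d = np.min(
        np.linalg.norm(pos[:, None, :] - pos[focus_idx][None, :, :], axis=-1),
        axis=1,
    )
    w = np.exp(-(d ** 2) / (2.0 * spread ** 2))
    return w / np.linalg.norm(w)


@dataclass(frozen=True)
class CategoryTruth:
    """Ground truth for one category's selective response.

    amplitude : microvolts at the category fundamental (0.857 Hz) at the
        reference age; the realized amplitude is
        ``amplitude * max(0, 1 + amp_slope * log10(age/AGE_REF_DAYS))``.
    peaks_ms / polarities : deflection peak times and signs within one
        1.1667 s category cycle.
    """

    amplitude: float
    peaks_ms: tuple
    polarities: tuple
    amp_slope: float = 0.0

    def __post_init__(self):
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if len(self.peaks_ms) != len(self.polarities):
            raise ValueError("peaks_ms and polarities must align")

    def amplitude_at(self, age_days: float) -> float:
        factor = 1.0 + self.amp_slope * np.log10(age_days / AGE_REF_DAYS)
        return self.amplitude * max(0.0, factor)


@dataclass(frozen=True)
class VisualTruth:
    """Ground truth for the image-update response cycle.

    Below ``four_deflection_age`` days the 233 ms cycle has two deflections
    (a negativity then a positivity); at or above it, four.  The first two
    peak latencies are linear in log10(age in days):
    ``lat = intercept + slope * log10(age)``.
    """

    amplitude: float = 3.0          # uV at the image fundamental
    lat1_intercept: float = 95.0    # ms; ~76 ms at 84 d, ~69 ms at 445 d
    lat1_slope: float = -10.0
    lat2_intercept: float = 182.8   # ms; ~126 ms at 100 d, ~90 ms at 445 d
    lat2_slope: float = -35.0
    late_peaks_ms: tuple = (160.0, 205.0)   # extra deflections in older infants
    four_deflection_age: float = 120.0      # days
    rel_amps: tuple = (1.0, 0.8, 0.5, 0.4)  # per-deflection relative size

    def peaks_at(self, age_days: float):
        la = np.log10(age_days)
        lat1 = self.lat1_intercept + self.lat1_slope * la
        lat2 = self.lat2_intercept + self.lat2_slope * la
        if age_days < self.four_deflection_age:
            return (lat1, lat2), (-1.0, 1.0), self.rel_amps[:2]
        return (lat1, lat2, *self.late_peaks_ms), (-1.0, 1.0, -1.0, 1.0), self.rel_amps


@dataclass
class GroundTruthSpec:
    """Complete per-session generative specification."""

    age_days: float
    categories: dict                       # name -> CategoryTruth
    visual: VisualTruth
    visual_topography: np.ndarray          # unit sum-of-squares weights
    category_topography: np.ndarray
    noise_exponent: float = 1.0            # 1/f power-spectrum slope
    noise_scale: float = 5.0               # uV RMS of the background
    artifact_rate: float = 2.0             # transient events per minute
    artifact_amplitude: float = 300.0      # uV
    artifact_duration: float = 0.5         # s; long enough that a transient
                                           # can trip the epoch rejection rule
    rng_seed: int = 0

    def __post_init__(self):
        if self.age_days <= 0:
            raise ValueError("age_days must be positive")
        for w in (self.visual_topography, self.category_topography):
            if abs(np.sum(np.asarray(w) ** 2) - 1.0) > 1e-6:
                raise ValueError("topography weights must have unit sum of squares")
        if self.noise_scale < 0 or self.artifact_rate < 0:
            raise ValueError("noise_scale and artifact_rate must be >= 0")


def default_spec(
    montage: Montage,
    age_days: float,
    rng_seed: int = 0,
    **overrides,
) -> GroundTruthSpec:
    """Study-like defaults: face amplitude grows with log-age, occipital
    visual topography, lateral occipitotemporal category topography."""
    categories = {
        "faces": CategoryTruth(1.0, (500.0, 900.0), (1.0, -1.0), amp_slope=0.9),
        "limbs": CategoryTruth(0.8, (500.0,), (-1.0,)),
        "corridors": CategoryTruth(0.8, (520.0,), (-1.0,)),
        "characters": CategoryTruth(0.7, (480.0,), (-1.0,)),
        "cars": CategoryTruth(0.6, (1000.0,), (1.0,)),
    }
    # fall back to whole-head foci on montages without the net's labels
    occ = [c for c in OCC_FOCUS if c in montage.channel_labels] or montage.channel_labels
    lat = [c for c in LAT_FOCUS if c in montage.channel_labels] or montage.channel_labels
    spec = GroundTruthSpec(
        age_days=age_days,
        categories=categories,
        visual=VisualTruth(),
        visual_topography=make_topography(montage, occ, 0.35),
        category_topography=make_topography(montage, lat, 0.35),
        rng_seed=rng_seed,
    )
    for k, v in overrides.items():
        setattr(spec, k, v)
    spec.__post_init__()
    return spec


# ---------------------------------------------------------------------------
# waveform construction


def _lobe_train(t: np.ndarray, period: float, peaks_s, pols, sigmas_s, amps) -> np.ndarray:
    """Periodic sum of Gaussian lobes evaluated at arbitrary times."""
    phase = np.mod(t, period)
    out = np.zeros_like(phase, dtype=float)
    for p, sgn, sig, a in zip(peaks_s, pols, sigmas_s, amps):
        for shift in (-period, 0.0, period):  # wrap-around continuity
            out += sgn * a * np.exp(-((phase - p - shift) ** 2) / (2.0 * sig ** 2))
    return out


def _lobe_sigmas(peaks_s, default: float = 0.060) -> list:
    """Lobe width: 15% of the spacing to the nearest other peak."""
    if len(peaks_s) < 2:
        return [default] * len(peaks_s)
    peaks = np.asarray(peaks_s)
    sig = []
    for p in peaks:
        d = np.abs(peaks - p)
        sig.append(0.15 * np.min(d[d > 0]))
    return sig


def _fundamental_amplitude(template: np.ndarray) -> float:
    """One-sided DFT amplitude (2/N scaling) at bin 1 of a one-period template."""
    coef = np.fft.rfft(template) / len(template)
    return 2.0 * np.abs(coef[1])


def _category_shape(truth: CategoryTruth, design: ExperimentDesign) -> np.ndarray:
    n = design.epoch_samples
    t = np.arange(n) / design.sampling_rate_analysis
    peaks = [p / 1000.0 for p in truth.peaks_ms]
    sig = _lobe_sigmas(peaks)
    return _lobe_train(t, design.epoch_duration, peaks, truth.polarities, sig,
                       [1.0] * len(peaks))


def simulate_category_waveform(
    category: str, age_days: float, spec: GroundTruthSpec,
    design: ExperimentDesign | None = None,
) -> np.ndarray:
    """One category cycle (1.1667 s at the analysis rate), scaled so its
    Fourier amplitude at the category fundamental equals the ground truth."""
    design = design or ExperimentDesign()
    if category not in spec.categories:
        raise KeyError(f"unknown category: {category!r}")
    truth = spec.categories[category]
    target = truth.amplitude_at(age_days)
    if target == 0.0:
        return np.zeros(design.epoch_samples)
    shape = _category_shape(truth, design)
    base = _fundamental_amplitude(shape)
    if base < 1e-12:
        raise ValueError("waveform shape has no energy at the category fundamental")
    return shape * (target / base)


def _visual_shape(age_days: float, spec: GroundTruthSpec,
                  design: ExperimentDesign) -> np.ndarray:
    n = design.image_period_samples
    period = 1.0 / design.image_rate
    t = np.arange(n) / design.sampling_rate_analysis
    peaks_ms, pols, amps = spec.visual.peaks_at(age_days)
    peaks = [p / 1000.0 for p in peaks_ms]
    sig = _lobe_sigmas(peaks, default=0.015)
    return _lobe_train(t, period, peaks, pols, sig, amps)


def simulate_visual_cycle(
    age_days: float, spec: GroundTruthSpec,
    design: ExperimentDesign | None = None,
) -> np.ndarray:
    """One image period (233 ms at the analysis rate), scaled so the image
    fundamental has the specified amplitude."""
    design = design or ExperimentDesign()
    if age_days <= 0:
        raise ValueError("age_days must be positive")
    if spec.visual.amplitude == 0.0:
        return np.zeros(design.image_period_samples)
    shape = _visual_shape(age_days, spec, design)
    base = _fundamental_amplitude(shape)
    return shape * (spec.visual.amplitude / base)


def count_deflections(waveform: np.ndarray, rel_threshold: float = 0.2) -> int:
    """Number of local extrema whose magnitude exceeds ``rel_threshold`` of
    the waveform's maximum absolute value (lightly smoothed first)."""
    w = np.convolve(waveform, np.ones(5) / 5.0, mode="same")
    thr = rel_threshold * np.max(np.abs(w))
    n = 0
    for i in range(1, len(w) - 1):
        if abs(w[i]) < thr:
            continue
        if (w[i] - w[i - 1]) * (w[i + 1] - w[i]) < 0:
            n += 1
    return n


# ---------------------------------------------------------------------------
# recordings


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, scale: float) -> np.ndarray:
    """1/f^exponent power-spectrum noise with random phases, RMS = scale."""
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    sd = np.std(x)
    return x * (scale / sd) if sd > 0 else x


def _raised_cosine(n: int) -> np.ndarray:
    return 0.5 * (1.0 - np.cos(2.0 * np.pi * np.arange(n) / max(n - 1, 1)))


def simulate_recording(
    design: ExperimentDesign,
    montage: Montage,
    spec: GroundTruthSpec,
    n_sequences: int = 1,
    sampling_rate: float | None = None,
) -> Recording:
    """Continuous recording of ``n_sequences`` 70 s sequences.

    Each sequence holds the five 14 s condition blocks in randomized order.
    Within a block the channel signal is the visual response train (occipital
    topography) plus the target category's waveform train (lateral topography),
    both under a fade-in/out envelope, plus 1/f noise and Poisson-scheduled
    artifact transients.  Deterministic given ``spec.rng_seed``.
    """
    if n_sequences < 1:
        raise ValueError("n_sequences must be >= 1")
    if len(spec.visual_topography) != montage.n_channels:
        raise ValueError("topography length does not match montage size")
    fs = sampling_rate or design.sampling_rate_raw
    rng = np.random.default_rng(spec.rng_seed)

    block_n = round(design.condition_duration * fs)
    seq_n = block_n * design.n_categories
    total_n = seq_n * n_sequences
    n_ch = montage.n_channels

    t_block = np.arange(block_n) / fs
    env = np.minimum(1.0, np.minimum(
        t_block / design.fade_duration,
        (design.condition_duration - t_block) / design.fade_duration,
    ))
    env = np.clip(env, 0.0, 1.0)

    # visual train: identical in every block
    vshape = _visual_shape(spec.age_days, spec, design)
    vscale = spec.visual.amplitude / _fundamental_amplitude(vshape) \
        if spec.visual.amplitude else 0.0
    peaks_ms, pols, amps = spec.visual.peaks_at(spec.age_days)
    vper = 1.0 / design.image_rate
    vtrain = vscale * _lobe_train(
        t_block, vper, [p / 1000.0 for p in peaks_ms], pols,
        _lobe_sigmas([p / 1000.0 for p in peaks_ms], default=0.015), amps)

    # category trains, one per category
    ctrains = {}
    for name, truth in spec.categories.items():
        target = truth.amplitude_at(spec.age_days)
        if target == 0.0:
            ctrains[name] = np.zeros(block_n)
            continue
        shape = _category_shape(truth, design)
        scale = target / _fundamental_amplitude(shape)
        peaks = [p / 1000.0 for p in truth.peaks_ms]
        ctrains[name] = scale * _lobe_train(
            t_block, design.epoch_duration, peaks, truth.polarities,
            _lobe_sigmas(peaks), [1.0] * len(peaks))

    data = np.zeros((n_ch, total_n))
    events = []
    for s in range(n_sequences):
        order = rng.permutation(design.n_categories)
        for b, cat_idx in enumerate(order):
            name = design.category_names[cat_idx]
            start = s * seq_n + b * block_n
            block = (np.outer(spec.visual_topography, vtrain * env)
                     + np.outer(spec.category_topography, ctrains[name] * env))
            data[:, start:start + block_n] += block
            events.append((start, name))

    if spec.noise_scale > 0:
        for c in range(n_ch):
            data[c] += _pink_noise(rng, total_n, fs,
                                   spec.noise_exponent, spec.noise_scale)

    if spec.artifact_rate > 0 and spec.artifact_amplitude > 0:
        n_events = rng.poisson(spec.artifact_rate * total_n / fs / 60.0)
        burst_n = round(spec.artifact_duration * fs)
        burst = _raised_cosine(burst_n)
        for _ in range(n_events):
            onset = int(rng.integers(0, max(total_n - burst_n, 1)))
            k = int(rng.integers(1, max(2, n_ch // 8)))
            chans = rng.choice(n_ch, size=k, replace=False)
            sign = rng.choice([-1.0, 1.0])
            data[chans, onset:onset + burst_n] += sign * spec.artifact_amplitude * burst

    return Recording(
        data=data, sampling_rate=fs, channel_labels=list(montage.channel_labels),
        events=events,
        meta={"age_days": spec.age_days, "rng_seed": spec.rng_seed},
    )


# ---------------------------------------------------------------------------
# cohorts

AGE_GROUP_EDGES = ((0, 120, "3-4mo"), (120, 194, "4-6mo"),
                   (194, 365, "6-8mo"), (365, np.inf, "12-15mo"))


def age_group(age_days: float) -> str:
    for lo, hi, label in AGE_GROUP_EDGES:
        if lo <= age_days < hi:
            return label
    raise ValueError(f"age out of range: {age_days}")


@dataclass
class CohortSession:
    participant_id: str
    session_id: str
    age_days: float
    spec: GroundTruthSpec
    recording: Recording | None = None


def default_cohort_config(longitudinal: bool = False) -> list:
    """Cross-sectional cohort with the study's group sizes (17/14/15/15);
    optionally 12 participants gain a second session ~90 days later."""
    groups = [("3-4mo", 17, 84, 119), ("4-6mo", 14, 121, 193),
              ("6-8mo", 15, 195, 250), ("12-15mo", 15, 365, 445)]
    config, p = [], 0
    for label, n, lo, hi in groups:
        ages = np.linspace(lo, hi, n)
        for a in ages:
            p += 1
            config.append({
                "participant_id": f"p{p:03d}",
                "sessions": [{"session_id": "s1", "age_days": float(round(a))}],
            })
    if longitudinal:
        for entry in config[::5][:12]:
            a0 = entry["sessions"][0]["age_days"]
            entry["sessions"].append(
                {"session_id": "s2", "age_days": a0 + 90.0})
    return config


def generate_cohort(
    config: list,
    montage: Montage | None = None,
    design: ExperimentDesign | None = None,
    with_recordings: bool = False,
    n_sequences: int = 2,
    base_seed: int = 0,
    spec_overrides: dict | None = None,
) -> tuple:
    """Build per-session ground-truth specs (and optionally recordings).

    Returns ``(sessions, table)`` where ``table`` is the CohortTable skeleton
    (participant_id, session_id, age_days, group_label).
    """
    design = design or ExperimentDesign()
    montage = montage or gsn128()
    seen = set()
    sessions, rows = [], []
    ss = np.random.SeedSequence(base_seed)
    for entry in config:
        pid = entry["participant_id"]
        for sess in entry["sessions"]:
            key = (pid, sess["session_id"])
            if key in seen:
                raise ValueError(f"duplicate participant/session key: {key}")
            seen.add(key)
            seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2 ** 31))
            spec = default_spec(montage, sess["age_days"], rng_seed=seed,
                                **(entry.get("overrides") or {}),
                                **(spec_overrides or {}))
            rec = None
            if with_recordings:
                rec = simulate_recording(design, montage, spec, n_sequences)
                rec.meta.update(participant_id=pid, session_id=sess["session_id"])
            sessions.append(CohortSession(pid, sess["session_id"],
                                          sess["age_days"], spec, rec))
            rows.append({"participant_id": pid, "session_id": sess["session_id"],
                         "age_days": sess["age_days"],
                         "group_label": age_group(sess["age_days"])})
    return sessions, pd.DataFrame(rows)


def simulate_measurement_table(
    table: pd.DataFrame,
    response: str,
    intercept: float,
    slope_per_log10_age: float,
    participant_sd: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Attach a measurement that is linear in log10(age) with participant
    random intercepts — a well-specified truth for LMM recovery tests."""
    out = table.copy()
    pids = out["participant_id"].unique()
    u = dict(zip(pids, participant_sd * rng.standard_normal(len(pids))))
    out[response] = (
        intercept
        + slope_per_log10_age * np.log10(out["age_days"].to_numpy(dtype=float))
        + out["participant_id"].map(u).to_numpy()
        + noise_sd * rng.standard_normal(len(out))
    )
    return out
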