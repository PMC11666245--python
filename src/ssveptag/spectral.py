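"""Frequency-domain analysis on the 0.4286 Hz bin grid.

Valid epochs are concatenated in consecutive pairs into 2.3334 s segments and
averaged, the mean segment is Fourier-transformed at 0.4286 Hz resolution,
and bins are partitioned into image-frequency, category-frequency and noise
bins.  Complex coefficients are vector-averaged across channels and
participants; response significance uses Hotelling's T-squared on the
(real, imaginary) coefficient pairs; multiple comparisons use
Benjamini-Hochberg FDR.

Amplitude scaling is one-sided 2/N, so a real sinusoid of amplitude A at an
exact bin reads A microvolts at that bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

from .containers import EpochSet
from .design import ExperimentDesign


@dataclass(frozen=True)
class ROISet:
    """Named, disjoint electrode lists."""

    rois: dict

    def __post_init__(self):
        seen = set()
        for name, chans in self.rois.items():
            dup = seen.intersection(chans)
            if dup:
                raise ValueError(f"ROI {name!r} overlaps others on {sorted(dup)}")
            if len(set(chans)) != len(chans):
                raise ValueError(f"ROI {name!r} has duplicate channels")
            seen.update(chans)

    def __getitem__(self, name):
        return self.rois[name]

    @property
    def names(self):
        return list(self.rois)

    @property
    def all_channels(self):
        out = []
        for name in self.rois:
            out.extend(self.rois[name])
        return out


def default_roi_set() -> ROISet:
    """The study's a-priori ROIs on the 128-channel net: 7 left (LOT) and 7
    right (ROT) occipitotemporal electrodes and 9 occipital (OCC)."""
    return ROISet({
        "LOT": [f"E{c}" for c in (57, 58, 59, 63, 64, 65, 68)],
        "OCC": [f"E{c}" for c in (69, 70, 71, 74, 75, 76, 82, 83, 89)],
        "ROT": [f"E{c}" for c in (90, 91, 94, 95, 96, 99, 100)],
    })


@dataclass(frozen=True)
class HarmonicSet:
    """Partition of the DFT bin grid into image, category and noise bins."""

    bin_frequencies: np.ndarray
    image_idx: np.ndarray       # multiples of the image rate
    category_idx: np.ndarray    # multiples of the category rate, minus image bins
    noise_idx: np.ndarray       # everything else in (0, cap]
    cap: float

    def frequencies(self, which: str) -> np.ndarray:
        return self.bin_frequencies[getattr(self, f"{which}_idx")]


def classify_bins(design: ExperimentDesign, cap: float,
                  resolution: float | None = None) -> HarmonicSet:
    """Partition bins k * 0.4286 Hz for 0 < k*res <= cap.

    Category bins are multiples of 0.857 Hz that are not multiples of
    4.286 Hz (even bin indices); noise bins are the remaining (odd) indices.
    """
    res = resolution or design.bin_spacing
    if cap > design.sampling_rate_analysis / 2:
        raise ValueError("cap exceeds the Nyquist frequency")
    kmax = int(np.floor(cap / res + 1e-9))
    k = np.arange(1, kmax + 1)
    k_img = round(design.image_rate / res)        # 10 on the default grid
    k_cat = round(design.category_rate / res)     # 2
    is_img = k % k_img == 0
    is_cat = (k % k_cat == 0) & ~is_img
    is_noise = ~is_img & ~is_cat
    return HarmonicSet(
        bin_frequencies=k * res,
        image_idx=k[is_img] - 1,
        category_idx=k[is_cat] - 1,
        noise_idx=k[is_noise] - 1,
        cap=cap,
    )


@dataclass
class ComplexSpectrum:
    """One-sided complex Fourier coefficients on the bin grid (DC dropped).

    coefficients : (..., n_bins) complex array in microvolts; the modulus of
    a coefficient is the amplitude at that bin.
    """

    coefficients: np.ndarray
    resolution: float
    n_segments_averaged: int = 1

    def __post_init__(self):
        self.coefficients = np.asarray(self.coefficients, dtype=complex)

    @property
    def frequencies(self) -> np.ndarray:
        return (np.arange(self.coefficients.shape[-1]) + 1) * self.resolution

    def amplitude(self) -> np.ndarray:
        return np.abs(self.coefficients)

    def bin_index(self, freq: float) -> int:
        k = round(freq / self.resolution)
        if abs(k * self.resolution - freq) > 1e-6 or k < 1:
            raise ValueError(f"{freq} Hz is not on the bin grid")
        return k - 1


def pair_segments(epochs: EpochSet, condition: str) -> tuple[np.ndarray, np.ndarray]:
    """Average consecutive valid-epoch pairs into one mean 2.3334 s segment
    per channel.

    For each channel, the valid epochs of ``condition`` are taken in order,
    consecutive pairs concatenated into double-length segments (a trailing
    unpaired epoch is dropped), and the segments averaged.  Returns
    ``(mean_segments, n_pairs)`` of shapes (n_channels, 2*n_samples) and
    (n_channels,); channels with no valid pair are NaN with n_pairs 0.
    """
    rows = np.flatnonzero(epochs.condition == condition)
    if len(rows) == 0:
        raise ValueError(f"no epochs for condition {condition!r}")
    n_ch, n_s = epochs.n_channels, epochs.data.shape[2]
    out = np.full((n_ch, 2 * n_s), np.nan)
    n_pairs = np.zeros(n_ch, dtype=int)
    for c in range(n_ch):
        valid = rows[epochs.valid[rows, c]]
        m = len(valid) // 2
        if m == 0:
            continue
        pairs = epochs.data[valid[: 2 * m], c, :].reshape(m, 2 * n_s)
        out[c] = pairs.mean(axis=0)
        n_pairs[c] = m
    return out, n_pairs


def dft_spectrum(mean_segment: np.ndarray, sampling_rate: float,
                 n_segments_averaged: int = 1) -> ComplexSpectrum:
    """One-sided DFT with 2/N scaling (DC dropped) of 2.3334 s mean segments.

    ``mean_segment`` may be (..., n_samples); coefficients keep leading axes.
    """
    x = np.asarray(mean_segment, dtype=float)
    n = x.shape[-1]
    coef = np.fft.rfft(x, axis=-1) / n
    coef = 2.0 * coef[..., 1:]
    return ComplexSpectrum(coef, resolution=sampling_rate / n,
                           n_segments_averaged=n_segments_averaged)


def vector_average(spectra: list) -> ComplexSpectrum:
    """Coefficient-wise complex mean across spectra on identical grids."""
    if not spectra:
        raise ValueError("nothing to average")
    res = spectra[0].resolution
    shape = spectra[0].coefficients.shape
    for s in spectra:
        if abs(s.resolution - res) > 1e-9 or s.coefficients.shape != shape:
            raise ValueError("spectra are not on identical grids")
    mean = np.mean([s.coefficients for s in spectra], axis=0)
    return ComplexSpectrum(mean, resolution=res, n_segments_averaged=len(spectra))


@dataclass(frozen=True)
class TcircResult:
    statistic: float     # Hotelling's T-squared
    f_value: float
    dof: tuple
    p: float
    n: int
    ridge_used: bool = False


def tcirc_test(coefficients: np.ndarray, ridge_eps: float = 1e-10) -> TcircResult:
    """Hotelling's T-squared test of a complex mean against zero.

    The (real, imaginary) parts of the per-participant coefficients are a
    bivariate sample; T2 = n * m' S^-1 m with sample covariance S,
    F = T2 (n-2) / (2 (n-1)) on (2, n-2) dof.  A singular covariance falls
    back to a documented ridge (eps * trace(S)/2 on the diagonal).
    """
    z = np.asarray(coefficients, dtype=complex).ravel()
    n = len(z)
    if n < 3:
        raise ValueError("Hotelling's T-squared requires n >= 3")
    xy = np.column_stack([z.real, z.imag])
    m = xy.mean(axis=0)
    if np.allclose(xy, 0):
        return TcircResult(0.0, 0.0, (2, n - 2), 1.0, n)
    s = np.cov(xy, rowvar=False, ddof=1)
    ridge = False
    if np.linalg.cond(s) > 1e12 or np.linalg.det(s) <= 0:
        s = s + ridge_eps * max(np.trace(s) / 2.0, 1e-30) * np.eye(2)
        ridge = True
        if np.linalg.det(s) <= 0:
            s = s + 1e-30 * np.eye(2)
    t2 = float(n * m @ np.linalg.solve(s, m))
    f = t2 * (n - 2) / (2.0 * (n - 1))
    p = float(stats.f.sf(f, 2, n - 2))
    return TcircResult(t2, f, (2, n - 2), p, n, ridge_used=ridge)


def roi_participant_spectrum(spectrum: ComplexSpectrum, roi_channels,
                             channel_labels) -> ComplexSpectrum:
    """Coefficient-wise complex mean across the ROI's available channels.

    ``spectrum.coefficients`` must be (n_channels, n_bins); channels whose
    coefficients are NaN (marked missing upstream) are skipped.  If every ROI
    channel is missing a ValueError is raised so the caller can exclude the
    participant for that ROI/condition.
    """
    index = {c: i for i, c in enumerate(channel_labels)}
    try:
        idx = [index[c] for c in roi_channels]
    except KeyError as e:
        raise KeyError(f"ROI channel not in spectrum: {e.args[0]!r}") from None
    coefs = spectrum.coefficients[idx]
    present = ~np.isnan(coefs).any(axis=1)
    if not present.any():
        raise ValueError("all ROI channels missing for this participant/condition")
    return ComplexSpectrum(coefs[present].mean(axis=0), spectrum.resolution,
                           spectrum.n_segments_averaged)


def category_rms_amplitude(roi_spectrum: ComplexSpectrum,
                           design: ExperimentDesign | None = None) -> float:
    """RMS of the amplitudes at the category fundamental (0.857 Hz) and its
    first harmonic (1.714 Hz)."""
    design = design or ExperimentDesign()
    a1 = np.abs(roi_spectrum.coefficients[..., roi_spectrum.bin_index(design.category_rate)])
    a2 = np.abs(roi_spectrum.coefficients[..., roi_spectrum.bin_index(2 * design.category_rate)])
    return float(np.sqrt((a1 ** 2 + a2 ** 2) / 2.0))


def noise_amplitude(roi_spectrum: ComplexSpectrum, harmonic_set: HarmonicSet,
                    first_k: int = 5) -> float:
    """Mean modulus over the ``first_k`` lowest-frequency noise bins."""
    idx = harmonic_set.noise_idx[:first_k]
    if len(idx) < first_k:
        raise ValueError("fewer noise bins in band than requested")
    return float(np.mean(np.abs(roi_spectrum.coefficients[..., idx])))


def fdr_bh(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level ``q``."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def load_roi_set(name_or_path: str) -> ROISet:
    """Load the packaged default ROI set or a JSON file of name -> channels."""
    if name_or_path in ("paper_default", "default"):
        return default_roi_set()
    path = Path(name_or_path)
    if not path.exists():
        raise ValueError(f"unknown ROI set name or missing file: {name_or_path!r}")
    with open(path) as f:
        rois = json.load(f)
    return ROISet({k: [str(c) for c in v] for k, v in rois.items()})
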