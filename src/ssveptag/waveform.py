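"""Time-domain analysis: harmonic-band reconstruction, cycle averaging, peak
measures, and the cluster-based sign-flip permutation test.

Reconstruction zeroes all DFT bins outside a harmonic selection, inverts the
transform, splits the 2.3334 s segment into its two category cycles and
averages them; the result is the evoked waveform carried only by the selected
harmonics (category or image-update response).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .design import ExperimentDesign
from .spectral import HarmonicSet


def reconstruct_band(mean_segment: np.ndarray, bin_indices: np.ndarray,
                     sampling_rate: float) -> np.ndarray:
    """Inverse-DFT band reconstruction of a 2.3334 s mean segment.

    ``bin_indices`` index the DC-dropped bin grid (bin k-1 holds frequency
    k * resolution), as produced by :func:`ssveptag.spectral.classify_bins`.
    Output is one epoch (half the segment length): the two cycles of the
    band-limited segment averaged.  An empty selection yields zeros.
    """
    x = np.asarray(mean_segment, dtype=float)
    n = x.shape[-1]
    coef = np.fft.rfft(x, axis=-1)
    keep = np.zeros(coef.shape[-1], dtype=bool)
    idx = np.asarray(bin_indices, dtype=int)
    if idx.size:
        keep[idx + 1] = True  # +1: reconstruction grid includes DC at 0
    filt = np.where(keep, coef, 0.0)
    y = np.fft.irfft(filt, n=n, axis=-1)
    half = n // 2
    return 0.5 * (y[..., :half] + y[..., half:])


def category_reconstruction(mean_segment: np.ndarray, design: ExperimentDesign,
                            harmonic_set: HarmonicSet) -> np.ndarray:
    """Category-band waveform: 0.857 Hz harmonics up to the cap, excluding
    image-frequency harmonics."""
    return reconstruct_band(mean_segment, harmonic_set.category_idx,
                            design.sampling_rate_analysis)


def image_reconstruction(mean_segment: np.ndarray, design: ExperimentDesign,
                         harmonic_set: HarmonicSet) -> np.ndarray:
    """Image-update waveform: 4.286 Hz and its harmonics up to the cap."""
    return reconstruct_band(mean_segment, harmonic_set.image_idx,
                            design.sampling_rate_analysis)


def cycle_average_visual(image_waveform: np.ndarray,
                         design: ExperimentDesign | None = None) -> np.ndarray:
    """Average the epoch waveform over its five 233 ms image periods."""
    design = design or ExperimentDesign()
    w = np.asarray(image_waveform, dtype=float)
    per = design.image_period_samples
    n_cycles = w.shape[-1] // per
    return w[..., : n_cycles * per].reshape(*w.shape[:-1], n_cycles, per).mean(axis=-2)


@dataclass(frozen=True)
class PeakMeasure:
    latency_ms: float
    amplitude: float
    window_ms: tuple
    polarity: int


def peak_measure(waveform: np.ndarray, sampling_rate: float,
                 window_ms: tuple, polarity: int = 1) -> PeakMeasure:
    """Extremum of the stated polarity within a latency window.

    Latency is reported at the extremum sample (ties break to the earliest
    sample); amplitude is the signed value at that sample.
    """
    w = np.asarray(waveform, dtype=float)
    lo = int(np.ceil(window_ms[0] / 1000.0 * sampling_rate))
    hi = int(np.floor(window_ms[1] / 1000.0 * sampling_rate))
    if hi < lo or lo < 0 or hi >= len(w):
        raise ValueError("window is empty or outside the waveform span")
    seg = w[lo:hi + 1] * (1 if polarity >= 0 else -1)
    i = int(np.argmax(seg))
    return PeakMeasure(
        latency_ms=(lo + i) * 1000.0 / sampling_rate,
        amplitude=float(w[lo + i]),
        window_ms=tuple(window_ms),
        polarity=1 if polarity >= 0 else -1,
    )


def second_deflection_window(age_days: float) -> tuple:
    """Latency window for the second visual deflection: 90-160 ms before 120
    days of age, 90-110 ms after."""
    return (90.0, 160.0) if age_days < 120 else (90.0, 110.0)


FIRST_DEFLECTION_WINDOW = (60.0, 90.0)
CATEGORY_PEAK_WINDOW = (400.0, 700.0)


@dataclass(frozen=True)
class ClusterResult:
    clusters: list           # (start_ms, end_ms, mass)
    cluster_p: np.ndarray
    significant: np.ndarray  # per-cluster two-tailed decision at 5%
    n_permutations: int
    alpha_point: float


def _t_against_zero(x: np.ndarray) -> np.ndarray:
    n = x.shape[0]
    m = x.mean(axis=0)
    sd = x.std(axis=0, ddof=1)
    sd = np.where(sd == 0, np.inf, sd)
    return m / (sd / np.sqrt(n))


def _cluster_runs(mask: np.ndarray) -> list:
    """Maximal runs of True as (start, stop_exclusive)."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i))
            start = None
    if start is not None:
        runs.append((start, len(mask)))
    return runs


def _max_min_cluster_mass(t: np.ndarray, mask: np.ndarray) -> tuple:
    """Per-row extreme cluster masses of t over maximal significant runs.

    ``t`` and ``mask`` are (B, P); returns (max_mass, min_mass) arrays with 0
    where a row has no cluster.  Implemented as a running scan over time so
    permutations stay vectorized.
    """
    b, p = t.shape
    run = np.zeros(b)
    max_mass = np.zeros(b)
    min_mass = np.zeros(b)
    prev = np.zeros(b, dtype=bool)
    for j in range(p):
        m = mask[:, j]
        closing = prev & ~m
        if closing.any():
            max_mass[closing] = np.maximum(max_mass[closing], run[closing])
            min_mass[closing] = np.minimum(min_mass[closing], run[closing])
        run = np.where(m, np.where(prev, run, 0.0) + t[:, j], 0.0)
        prev = m
    open_ = prev
    if open_.any():
        max_mass[open_] = np.maximum(max_mass[open_], run[open_])
        min_mass[open_] = np.minimum(min_mass[open_], run[open_])
    return max_mass, min_mass


def cluster_permutation_test(
    waveforms: np.ndarray,
    alpha_point: float = 0.05,
    n_perm: int = 10000,
    rng: np.random.Generator | None = None,
    sampling_rate: float = 420.0,
) -> ClusterResult:
    """Cluster-based sign-flip permutation t-test against zero.

    Per-point two-tailed one-sample t-tests at ``alpha_point`` define
    clusters as maximal runs of consecutive significant points; the cluster
    mass is the sum of t-values in the run.  The null distribution of the
    per-permutation maximum (and minimum) cluster mass is built by assigning
    a random sign to each participant's whole waveform.  A cluster is
    significant (two-tailed, 5%) if its mass exceeds the 97.5th percentile of
    the maxima or falls below the 2.5th percentile of the minima; reported
    p-values use the (b+1)/(B+1) convention.
    """
    x = np.asarray(waveforms, dtype=float)
    n, p = x.shape
    if n < 5:
        raise ValueError("need at least 5 participants")
    rng = rng or np.random.default_rng()
    tcrit = stats.t.ppf(1.0 - alpha_point / 2.0, n - 1)

    t_obs = _t_against_zero(x)
    mask_obs = np.abs(t_obs) > tcrit
    runs = _cluster_runs(mask_obs)
    masses = np.array([t_obs[a:b].sum() for a, b in runs])

    # sign-flip null: second moments are flip-invariant, so t under flips
    # needs only the flipped mean
    sumsq = np.sum(x ** 2, axis=0)
    signs = rng.choice([-1.0, 1.0], size=(n_perm, n))
    mean_p = (signs @ x) / n
    var_p = (sumsq / n - mean_p ** 2) * (n / (n - 1))
    var_p = np.maximum(var_p, 1e-300)
    t_p = mean_p / np.sqrt(var_p / n)
    null_max, null_min = _max_min_cluster_mass(t_p, np.abs(t_p) > tcrit)

    hi = np.quantile(null_max, 0.975)
    lo = np.quantile(null_min, 0.025)
    cluster_p = np.empty(len(runs))
    significant = np.empty(len(runs), dtype=bool)
    clusters = []
    for i, ((a, b), m) in enumerate(zip(runs, masses)):
        if m >= 0:
            cluster_p[i] = (1 + np.sum(null_max >= m)) / (n_perm + 1)
            significant[i] = m > hi
        else:
            cluster_p[i] = (1 + np.sum(null_min <= m)) / (n_perm + 1)
            significant[i] = m < lo
        clusters.append((a * 1000.0 / sampling_rate,
                         (b - 1) * 1000.0 / sampling_rate, float(m)))
    return ClusterResult(clusters, cluster_p, significant, n_perm, alpha_point)
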