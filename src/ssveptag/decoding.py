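"""Multivariate analyses of spatiotemporal category patterns.

A spatiotemporal pattern is the concatenation of category waveforms — ROI
means (LOT, OCC, ROT; 3 x 490 values) at the group level, or the 23
occipital/occipitotemporal channels (23 x 490 values) within an individual.
Group-level decoding is leave-one-out winner-take-all by correlation;
individual-level analyses use odd/even split halves, the split-half RSM,
and the category distinctiveness statistic (within-category correlation
minus mean between-category correlation, bounded in [-2, 2]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .containers import EpochSet
from .design import ExperimentDesign
from .spectral import HarmonicSet, ROISet, pair_segments
from .waveform import reconstruct_band

ROI_ORDER = ("LOT", "OCC", "ROT")


def build_group_pattern(roi_waveforms: dict, roi_order=ROI_ORDER) -> np.ndarray:
    """Concatenate per-ROI mean waveforms in the fixed (LOT, OCC, ROT) order."""
    missing = [r for r in roi_order if r not in roi_waveforms]
    if missing:
        raise KeyError(f"missing ROI waveform(s): {missing}")
    return np.concatenate([np.asarray(roi_waveforms[r], dtype=float)
                           for r in roi_order])


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return np.nan
    return float(a @ b / (na * nb))


@dataclass
class DecodingResult:
    hits: pd.DataFrame        # participant, category, predicted, hit, tie
    accuracy: pd.Series       # per-participant accuracy
    group_accuracy: float
    per_category_rate: pd.Series  # fraction of participants decoded per category


def loocv_wta_decode(patterns: np.ndarray, categories=None,
                     participants=None) -> DecodingResult:
    """Leave-one-out winner-take-all correlation decoding.

    ``patterns`` is (n_participants, n_categories, length).  For each left-out
    participant the training pattern per category is the element-wise mean
    over the rest; each test vector is assigned to the training category of
    highest Pearson correlation (ties take the lowest category index and are
    flagged).  A zero-variance test vector has no defined correlation and
    counts as a miss for every category.
    """
    x = np.asarray(patterns, dtype=float)
    n_p, n_c, _ = x.shape
    if n_p < 3:
        raise ValueError("need at least 3 participants")
    categories = list(categories) if categories is not None else list(range(n_c))
    participants = list(participants) if participants is not None else list(range(n_p))
    rows = []
    total = x.sum(axis=0)
    for i in range(n_p):
        train = (total - x[i]) / (n_p - 1)      # (n_c, L)
        for c in range(n_c):
            test = x[i, c]
            r = np.array([_corr(test, train[k]) for k in range(n_c)])
            if np.all(np.isnan(r)):
                warnings.warn(
                    f"zero-variance test vector for participant {participants[i]}, "
                    f"category {categories[c]}; counted as a miss", stacklevel=2)
                rows.append({"participant": participants[i],
                             "category": categories[c], "predicted": None,
                             "hit": 0, "tie": False})
                continue
            best = np.nanmax(r)
            winners = np.flatnonzero(r == best)
            pred = int(winners[0])
            rows.append({"participant": participants[i],
                         "category": categories[c],
                         "predicted": categories[pred],
                         "hit": int(pred == c), "tie": len(winners) > 1})
    hits = pd.DataFrame(rows)
    accuracy = hits.groupby("participant", sort=False)["hit"].mean()
    per_cat = hits.groupby("category", sort=False)["hit"].mean()
    return DecodingResult(hits, accuracy, float(accuracy.mean()), per_cat)


def split_half_patterns(
    epochs: EpochSet,
    roi_set: ROISet,
    design: ExperimentDesign,
    harmonic_set: HarmonicSet,
    roi_order=ROI_ORDER,
) -> dict:
    """Odd/even spatiotemporal patterns per category for one participant.

    Epochs of each condition are split by within-condition ordinal position
    (1st, 3rd, ... = odd half); each half runs through paired-segment
    averaging and category-band reconstruction per channel, and the 23 ROI
    channels are concatenated in fixed ROI order.  Categories with fewer than
    two valid epochs in a half are omitted (marked missing).
    """
    chan_order = []
    for r in roi_order:
        chan_order.extend(roi_set[r])
    index = {c: i for i, c in enumerate(epochs.channel_labels)}
    idx = [index[c] for c in chan_order]
    out = {}
    for cond in np.unique(epochs.condition):
        rows = np.flatnonzero(epochs.condition == cond)
        halves = {}
        ok = True
        for half, sel in (("odd", rows[0::2]), ("even", rows[1::2])):
            sub = EpochSet(
                epochs.data[sel][:, idx, :], epochs.condition[sel],
                epochs.valid[sel][:, idx], epochs.sampling_rate,
                epochs.epoch_duration, chan_order)
            if not _enough_pairs(sub, cond):
                ok = False
                break
            seg, _ = pair_segments(sub, cond)
            if np.isnan(seg).any():
                ok = False
                break
            wave = reconstruct_band(seg, harmonic_set.category_idx,
                                    design.sampling_rate_analysis)
            halves[half] = wave.ravel()
        if ok:
            out[str(cond)] = halves
    return out


def _enough_pairs(epochs: EpochSet, cond) -> bool:
    rows = np.flatnonzero(epochs.condition == cond)
    return bool(np.all(epochs.valid[rows].sum(axis=0) >= 2))


def compute_rsm(odd_patterns: dict, even_patterns: dict, categories) -> pd.DataFrame:
    """Split-half RSM: rows are odd-half categories, columns even-half;
    entry (i, j) is the Pearson correlation of odd_i with even_j.  Missing
    categories give NaN rows/columns.  Not constrained symmetric."""
    n = len(categories)
    m = np.full((n, n), np.nan)
    for i, ci in enumerate(categories):
        for j, cj in enumerate(categories):
            if ci in odd_patterns and cj in even_patterns:
                m[i, j] = _corr(odd_patterns[ci], even_patterns[cj])
    return pd.DataFrame(m, index=list(categories), columns=list(categories))


@dataclass(frozen=True)
class DistinctivenessRecord:
    category: str
    within: float
    between_mean: float
    distinctiveness: float


def distinctiveness(rsm: pd.DataFrame, category,
                    between: str = "row_and_column") -> DistinctivenessRecord:
    """Within-category correlation minus mean between-category correlation.

    Because the split-half RSM is asymmetric, the between mean uses by
    default the off-diagonal entries of both the category's row and column
    (8 cells for 5 categories); ``between="row"`` restricts to the row.
    """
    i = list(rsm.index).index(category)
    m = rsm.to_numpy()
    within = m[i, i]
    others = [j for j in range(m.shape[0]) if j != i]
    if between == "row_and_column":
        vals = np.concatenate([m[i, others], m[others, i]])
    elif between == "row":
        vals = m[i, others]
    else:
        raise ValueError("between must be 'row_and_column' or 'row'")
    bm = float(np.nanmean(vals))
    return DistinctivenessRecord(str(category), float(within), bm,
                                 float(within - bm))


def accuracy_vs_chance(accuracies_by_group: dict, chance: float = 0.2,
                       correction: str = "fdr") -> pd.DataFrame:
    """One-tailed one-sample t-tests of decoding accuracy against chance,
    corrected across age groups (FDR by default, Bonferroni optional).

    Zero-variance groups are handled by the documented degenerate rule:
    all values equal to chance give p = 1; all equal and above chance give
    p = 0 (reported significant).
    """
    rows = []
    for group, acc in accuracies_by_group.items():
        a = np.asarray(acc, dtype=float)
        if len(a) < 3:
            raise ValueError(f"group {group!r} has fewer than 3 participants")
        if np.allclose(a.std(ddof=1), 0.0):
            p = 0.0 if a.mean() > chance else 1.0
            t = np.inf if a.mean() > chance else 0.0
        else:
            t, p_two = stats.ttest_1samp(a, chance)
            p = p_two / 2.0 if t > 0 else 1.0 - p_two / 2.0
        rows.append({"group": group, "n": len(a), "mean_accuracy": a.mean(),
                     "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if correction == "fdr":
        from statsmodels.stats.multitest import multipletests
        reject, p_adj, *_ = multipletests(out["p"], alpha=0.05, method="fdr_bh")
        out["p_corrected"] = p_adj
        out["significant"] = reject
    elif correction == "bonferroni":
        out["p_corrected"] = np.minimum(1.0, out["p"] * len(out))
        out["significant"] = out["p_corrected"] < 0.05
    else:
        raise ValueError("correction must be 'fdr' or 'bonferroni'")
    return out
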