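"""Spatiotemporal patterns, WTA decoding, split-half RSMs and category
distinctiveness."""

import warnings

import numpy as np
import pandas as pd
import pytest

from conftest import make_mini_spec
from ssveptag.containers import EpochSet
from ssveptag.decoding import (accuracy_vs_chance, build_group_pattern,
                               compute_rsm, distinctiveness, loocv_wta_decode,
                               split_half_patterns)
from ssveptag.spectral import ROISet, classify_bins
from ssveptag.synth import simulate_recording
from ssveptag.preprocess import epoch


class TestGroupPattern:
    def test_zero_waveforms_give_zero_vector_of_1470(self):
        v = build_group_pattern({r: np.zeros(490) for r in ("LOT", "OCC", "ROT")})
        assert v.shape == (1470,)
        assert np.all(v == 0)

    def test_canonical_roi_order_enforced(self):
        wf = {"LOT": np.full(3, 1.0), "OCC": np.full(3, 2.0),
              "ROT": np.full(3, 3.0)}
        v = build_group_pattern(wf)
        assert np.allclose(v, [1, 1, 1, 2, 2, 2, 3, 3, 3])

    def test_missing_roi_rejected(self):
        with pytest.raises(KeyError, match="OCC"):
            build_group_pattern({"LOT": np.zeros(3), "ROT": np.zeros(3)})


class TestLoocvWta:
    def test_perfect_signal_decodes_perfectly(self):
        base = np.eye(5).repeat(4, axis=1)  # orthogonal category patterns
        pats = np.tile(base, (6, 1, 1))
        res = loocv_wta_decode(pats)
        assert res.group_accuracy == 1.0
        assert np.all(res.per_category_rate.to_numpy() == 1.0)

    def test_hand_computed_assignment(self):
        # 3 participants, 2 categories, 3-point patterns; the expected winner
        # per test vector is recomputed with numpy's corrcoef as the oracle
        rng = np.random.default_rng(0)
        pats = rng.normal(size=(3, 2, 3))
        res = loocv_wta_decode(pats)
        for i in range(3):
            train = pats[[j for j in range(3) if j != i]].mean(axis=0)
            for c in range(2):
                r = [np.corrcoef(pats[i, c], train[k])[0, 1] for k in range(2)]
                expected = int(np.argmax(r))
                got = res.hits[(res.hits.participant == i)
                               & (res.hits.category == c)].predicted.iloc[0]
                assert got == expected

    def test_zero_variance_test_vector_is_a_miss(self):
        pats = np.random.default_rng(1).normal(size=(4, 2, 10))
        pats[0, 0] = 5.0  # constant vector: correlation undefined
        with warnings.catch_warnings(record=True) as rec:
            warnings.simplefilter("always")
            res = loocv_wta_decode(pats)
        assert any("zero-variance" in str(w.message) for w in rec)
        row = res.hits[(res.hits.participant == 0) & (res.hits.category == 0)]
        assert row.hit.iloc[0] == 0

    def test_affine_transform_invariance(self):
        rng = np.random.default_rng(2)
        pats = rng.normal(size=(6, 5, 50))
        a = loocv_wta_decode(pats).group_accuracy
        b = loocv_wta_decode(3.7 * pats + 11.0).group_accuracy
        assert a == b

    def test_needs_three_participants(self):
        with pytest.raises(ValueError):
            loocv_wta_decode(np.zeros((2, 5, 10)))


class TestSplitHalf:
    def _mini_roi_set(self):
        return ROISet({"LOT": ["m1", "m2"], "OCC": ["m4", "m5"],
                       "ROT": ["m7", "m8"]})

    def _epochs(self, mini_montage, design, seed=0, noise=0.0):
        spec = make_mini_spec(mini_montage, seed=seed, noise_scale=noise)
        rec = simulate_recording(design, mini_montage, spec, 2,
                                 sampling_rate=420.0)
        return epoch(rec, design)

    def test_twenty_epochs_split_ten_ten(self, mini_montage, design):
        eps = self._epochs(mini_montage, design)
        hset = classify_bins(design, 30.0)
        halves = split_half_patterns(eps, self._mini_roi_set(), design, hset)
        assert set(halves) == set(design.category_names)
        for h in halves.values():
            assert h["odd"].shape == (6 * 490,)
            assert h["even"].shape == (6 * 490,)

    def test_noiseless_halves_identical(self, mini_montage, design):
        eps = self._epochs(mini_montage, design)
        hset = classify_bins(design, 30.0)
        halves = split_half_patterns(eps, self._mini_roi_set(), design, hset)
        for h in halves.values():
            r = np.corrcoef(h["odd"], h["even"])[0, 1]
            assert r == pytest.approx(1.0, abs=1e-9)

    def test_insufficient_epochs_marks_category_missing(self, mini_montage,
                                                        design):
        eps = self._epochs(mini_montage, design)
        rows = np.flatnonzero(eps.condition == "faces")
        eps.valid[rows[::2]] = False  # starve the odd half
        hset = classify_bins(design, 30.0)
        halves = split_half_patterns(eps, self._mini_roi_set(), design, hset)
        assert "faces" not in halves
        assert "limbs" in halves

    def test_null_signal_within_correlation_near_zero(self, mini_montage,
                                                      design):
        from ssveptag.synth import CategoryTruth, VisualTruth
        rs = []
        hset = classify_bins(design, 30.0)
        for seed in range(12):
            spec = make_mini_spec(mini_montage, seed=seed, noise_scale=1.0,
                                  visual=VisualTruth(amplitude=0.0))
            for name, t in spec.categories.items():
                spec.categories[name] = CategoryTruth(0.0, t.peaks_ms,
                                                      t.polarities)
            rec = simulate_recording(design, mini_montage, spec, 2,
                                     sampling_rate=420.0)
            eps = epoch(rec, design)
            halves = split_half_patterns(eps, self._mini_roi_set(), design, hset)
            for h in halves.values():
                rs.append(np.corrcoef(h["odd"], h["even"])[0, 1])
        assert abs(np.mean(rs)) < 0.1


class TestRsmAndDistinctiveness:
    def test_identical_orthogonal_halves_give_identity_rsm(self):
        pats = {c: v for c, v in zip("abc", np.eye(3).repeat(4, axis=1))}
        rsm = compute_rsm(pats, pats, list("abc"))
        assert np.allclose(rsm.to_numpy(),
                           np.corrcoef(np.eye(3).repeat(4, axis=1)))
        assert np.allclose(np.diag(rsm.to_numpy()), 1.0)

    def test_identical_patterns_everywhere_give_all_ones(self):
        v = np.sin(np.arange(20))
        pats = {c: v for c in "abc"}
        rsm = compute_rsm(pats, pats, list("abc"))
        assert np.allclose(rsm.to_numpy(), 1.0)

    def test_entries_match_brute_force_correlations(self):
        rng = np.random.default_rng(3)
        odd = {c: rng.normal(size=7) for c in "abc"}
        even = {c: rng.normal(size=7) for c in "abc"}
        rsm = compute_rsm(odd, even, list("abc"))
        for i, ci in enumerate("abc"):
            for j, cj in enumerate("abc"):
                assert rsm.iloc[i, j] == pytest.approx(
                    np.corrcoef(odd[ci], even[cj])[0, 1])

    def test_missing_category_gives_nan_row(self):
        v = np.arange(5.0)
        rsm = compute_rsm({"a": v}, {"a": v, "b": v ** 2}, ["a", "b"])
        assert np.isnan(rsm.loc["b", "a"])

    def test_extreme_rsm_attains_plus_two(self):
        rsm = pd.DataFrame([[1.0, -1.0], [-1.0, 1.0]], index=["a", "b"],
                           columns=["a", "b"])
        assert distinctiveness(rsm, "a").distinctiveness == 2.0

    def test_mirror_case_attains_minus_two(self):
        rsm = pd.DataFrame([[-1.0, 1.0], [1.0, -1.0]], index=["a", "b"],
                           columns=["a", "b"])
        assert distinctiveness(rsm, "a").distinctiveness == -2.0

    def test_constant_rsm_gives_zero(self):
        rsm = pd.DataFrame(np.full((4, 4), 0.37), index=list("abcd"),
                           columns=list("abcd"))
        assert distinctiveness(rsm, "c").distinctiveness == pytest.approx(0.0)

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(4)
        m = rng.uniform(-1, 1, (5, 5))
        rsm = pd.DataFrame(m, index=list("abcde"), columns=list("abcde"))
        rec = distinctiveness(rsm, "b")
        i = 1
        others = [j for j in range(5) if j != i]
        expected = m[i, i] - np.mean(np.r_[m[i, others], m[others, i]])
        assert rec.distinctiveness == pytest.approx(expected)
        assert -2.0 <= rec.distinctiveness <= 2.0

    def test_row_only_variant(self):
        rng = np.random.default_rng(5)
        m = rng.uniform(-1, 1, (3, 3))
        rsm = pd.DataFrame(m, index=list("abc"), columns=list("abc"))
        rec = distinctiveness(rsm, "a", between="row")
        assert rec.distinctiveness == pytest.approx(m[0, 0] - m[0, 1:].mean())

    def test_bounds_hold_over_random_rsms(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            m = rng.uniform(-1, 1, (5, 5))
            rsm = pd.DataFrame(m, index=list("abcde"), columns=list("abcde"))
            for c in "abcde":
                assert -2.0 <= distinctiveness(rsm, c).distinctiveness <= 2.0


class TestAccuracyVsChance:
    def test_at_chance_not_significant(self):
        out = accuracy_vs_chance({"g1": [0.2] * 10, "g2": [0.2] * 10})
        assert np.allclose(out["t"], 0.0)
        assert not out["significant"].any()

    def test_perfect_zero_variance_group_significant(self):
        out = accuracy_vs_chance({"g1": [1.0] * 10, "g2": [0.2] * 10})
        row = out[out.group == "g1"].iloc[0]
        assert row["significant"] and row["p"] == 0.0

    def test_bonferroni_option(self):
        out = accuracy_vs_chance({"g1": [0.5, 0.6, 0.55, 0.5],
                                  "g2": [0.2, 0.21, 0.19, 0.2]},
                                 correction="bonferroni")
        assert np.allclose(out["p_corrected"],
                           np.minimum(1.0, out["p"] * 2))

    def test_null_rejection_rate_bounded(self):
        rng = np.random.default_rng(7)
        rejections = 0
        n_sims = 300
        for _ in range(n_sims):
            accs = np.clip(0.2 + rng.normal(0, 0.05, 12), 0, 1)
            out = accuracy_vs_chance({"g": list(accs), "h": [0.2] * 12})
            rejections += int(out[out.group == "g"].significant.iloc[0])
        assert rejections / n_sims <= 0.07  # one-tailed 5% plus slack

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            accuracy_vs_chance({"g1": [0.2, 0.3]})
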