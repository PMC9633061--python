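import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu

from callcat.cochleagram import Cochleagram
from callcat.mif import (
    MIF,
    CandidateFeature,
    MIFSet,
    auc_from_scores,
    best_threshold_mi,
    evaluate_auc,
    fd_response,
    fit_feature,
    greedy_select,
    load_mifsets,
    max_ncc,
    relative_detection_rate,
    sample_candidates,
    save_mifsets,
    simulate_response,
    train_instantiations,
    wta_decide,
)
from callcat.mif import _mi_bits


def _coch(values, frame_rate=1000.0):
    values = np.asarray(values, dtype=float)
    cfs = np.geomspace(200, 20000, values.shape[0])
    return Cochleagram(values=values, cfs=cfs, frame_rate=frame_rate, source_id="toy")


def _feature(patch, row0=0):
    patch = np.asarray(patch, dtype=float)
    return CandidateFeature(
        patch=patch, cf_span=(row0, row0 + patch.shape[0]), duration_ms=patch.shape[1]
    )


def _brute_force_max_ncc(patch, values, row0):
    """Exhaustive correlation over every valid time placement."""
    k, m = patch.shape
    C = values[row0 : row0 + k]
    best = -np.inf
    p = patch.flatten() - patch.mean()
    pn = np.linalg.norm(p)
    if pn < 1e-12:
        return 0.0
    for t in range(C.shape[1] - m + 1):
        w = C[:, t : t + m].flatten()
        w = w - w.mean()
        wn = np.linalg.norm(w)
        r = 0.0 if wn < 1e-12 else float(p @ w / (pn * wn))
        best = max(best, r)
    return best


class TestMaxNCC:
    def test_verbatim_patch_scores_one(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, (10, 40))
        patch = values[2:7, 10:25].copy()
        r = max_ncc(_feature(patch, row0=2), _coch(values))
        assert r == pytest.approx(1.0, abs=1e-9)

    def test_matches_brute_force_toy(self):
        rng = np.random.default_rng(1)
        values = rng.uniform(0, 1, (10, 20))
        patch = rng.uniform(0, 1, (4, 6))
        got = max_ncc(_feature(patch, row0=3), _coch(values))
        want = _brute_force_max_ncc(patch, values, 3)
        assert got == pytest.approx(want, abs=1e-10)

    def test_constant_patch_degenerate(self):
        values = np.random.default_rng(2).uniform(0, 1, (5, 12))
        assert max_ncc(_feature(np.ones((3, 4)), row0=1), _coch(values)) == 0.0

    def test_too_long_feature_rejected(self):
        values = np.zeros((5, 10))
        with pytest.raises(ValueError):
            max_ncc(_feature(np.ones((2, 12))), _coch(values))

    def test_bounded(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            values = rng.uniform(0, 1, (6, 15))
            patch = rng.uniform(0, 1, (3, 5))
            r = max_ncc(_feature(patch, row0=1), _coch(values))
            assert -1.0 <= r <= 1.0

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_brute_force_equivalence_property(self, seed):
        rng = np.random.default_rng(seed)
        rows = int(rng.integers(3, 8))
        frames = int(rng.integers(6, 16))
        k = int(rng.integers(2, rows + 1))
        m = int(rng.integers(2, frames + 1))
        row0 = int(rng.integers(0, rows - k + 1))
        values = rng.uniform(0, 1, (rows, frames))
        patch = rng.uniform(0, 1, (k, m))
        got = max_ncc(_feature(patch, row0=row0), _coch(values))
        want = _brute_force_max_ncc(patch, values, row0)
        assert got == pytest.approx(want, abs=1e-9)


def _brute_force_threshold_mi(scores, labels):
    """Enumerate every midpoint between consecutive sorted unique scores."""
    uniq = np.unique(scores)
    best = (uniq[0], 0.0)
    nt = labels.sum()
    no = len(labels) - nt
    for thr in (uniq[:-1] + uniq[1:]) / 2:
        det = scores > thr
        n11 = int((det & labels).sum())
        n10 = int((det & ~labels).sum())
        mi = _mi_bits(n11, n10, nt - n11, no - n10)
        if mi > best[1] + 1e-15:
            best = (thr, mi)
    return best


class TestFitFeature:
    def test_perfect_separation_one_bit(self):
        thr, merit, weight = fit_feature([0.9, 0.8], [0.2, 0.3])
        assert merit == pytest.approx(1.0)
        assert 0.3 < thr < 0.8
        assert weight > 0

    def test_identical_scores_zero_merit(self):
        _, merit, _ = fit_feature([0.5, 0.5], [0.5, 0.5])
        assert merit == 0.0

    def test_overlapping_sets_match_enumeration_oracle(self):
        scores = np.array([0.9, 0.6, 0.4, 0.5, 0.3])
        labels = np.array([True, True, True, False, False])
        want_thr, want_mi = _brute_force_threshold_mi(scores, labels)
        thr, merit = best_threshold_mi(scores, labels)
        assert merit == pytest.approx(want_mi, abs=1e-12)
        assert thr == pytest.approx(want_thr)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            fit_feature([], [0.1])

    def test_weight_add_one_smoothing(self):
        # perfect separation of 2 vs 2: ln((3/4) / (1/4)) = ln 3
        _, _, weight = fit_feature([0.9, 0.8], [0.2, 0.3])
        assert weight == pytest.approx(np.log(3.0))

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_threshold_sweep_matches_enumeration_property(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        scores = np.round(rng.uniform(0, 1, n), 2)
        labels = rng.uniform(size=n) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        _, want_mi = _brute_force_threshold_mi(scores, labels)
        _, got_mi = best_threshold_mi(scores, labels)
        assert got_mi == pytest.approx(want_mi, abs=1e-12)


def _mif(weight, detections, merit=0.5):
    feat = _feature(np.arange(6.0).reshape(2, 3))
    return MIF(feature=feat, threshold=0.5, weight=weight, merit=merit), np.asarray(detections, bool)


class TestGreedySelect:
    def _ensemble_mi(self, mifs, det, labels, idx):
        w = np.array([mifs[i].weight for i in idx])
        scores = (w @ det[idx]) / w.sum()
        return best_threshold_mi(scores, labels)[1]

    def test_identical_candidates_selected_once(self):
        labels = np.array([True, True, False, False])
        m1, d1 = _mif(1.0, [1, 1, 0, 0])
        m2, d2 = _mif(1.0, [1, 1, 0, 0])
        idx = greedy_select([m1, m2], np.vstack([d1, d2]), labels)
        assert len(idx) == 1

    def test_matches_exhaustive_subset_oracle(self):
        # six candidates with complementary detection patterns
        labels = np.array([True] * 4 + [False] * 4)
        patterns = [
            [1, 1, 0, 0, 0, 0, 0, 0],
            [0, 0, 1, 1, 0, 0, 0, 0],
            [1, 0, 1, 0, 1, 0, 0, 0],
            [1, 1, 1, 1, 1, 1, 0, 0],
            [0, 1, 0, 1, 0, 0, 1, 0],
            [1, 0, 0, 1, 0, 1, 0, 1],
        ]
        weights = [1.0, 1.0, 0.8, 0.9, 0.7, 0.6]
        mifs, det = [], []
        for w, p in zip(weights, patterns):
            m, d = _mif(w, p)
            mifs.append(m)
            det.append(d)
        det = np.vstack(det)
        got = greedy_select(mifs, det, labels, max_n=3)
        got_mi = self._ensemble_mi(mifs, det, labels, got)
        best_mi = max(
            self._ensemble_mi(mifs, det, labels, list(sub))
            for r in (1, 2, 3)
            for sub in itertools.combinations(range(6), r)
        )
        assert got_mi == pytest.approx(best_mi, abs=1e-12)

    def test_max_n_respected(self):
        labels = np.tile([True, False], 8)
        rng = np.random.default_rng(0)
        mifs, det = [], []
        for _ in range(30):
            m, d = _mif(rng.uniform(0.5, 1.5), rng.uniform(size=16) < 0.5)
            mifs.append(m)
            det.append(d)
        idx = greedy_select(mifs, np.vstack(det), labels, max_n=20)
        assert len(idx) <= 20

    def test_no_informative_candidate_rejected(self):
        labels = np.array([True, False])
        m, d = _mif(1.0, [1, 1], merit=0.0)
        with pytest.raises(ValueError):
            greedy_select([m], d[None, :], labels)

    def test_ensemble_mi_nondecreasing_over_steps(self):
        rng = np.random.default_rng(4)
        labels = rng.uniform(size=20) < 0.5
        labels[:2] = [True, False]
        mifs, det = [], []
        for _ in range(15):
            d = rng.uniform(size=20) < 0.4
            m, _ = _mif(rng.uniform(0.3, 2.0), d)
            m.merit = 0.1
            mifs.append(m)
            det.append(d)
        det = np.vstack(det)
        idx = greedy_select(mifs, det, labels, max_n=10, min_gain_bits=1e-6)
        mis = [self._ensemble_mi(mifs, det, labels, idx[: k + 1]) for k in range(len(idx))]
        assert all(b >= a - 1e-12 for a, b in zip(mis, mis[1:]))


class TestSampleCandidates:
    def test_count_and_bounds(self, mini_cochleagrams):
        cochs = list(mini_cochleagrams.values())[:4]
        cands = sample_candidates(cochs, n=200, seed=0)
        assert len(cands) == 200
        by_id = {c.source_id: c for c in cochs}
        for f in cands:
            assert f.duration_ms <= 200.0
            src = by_id[f.source_call]
            r0, c0 = f.source_offset
            assert f.patch.shape[0] + r0 <= src.n_channels
            assert f.patch.shape[1] + c0 <= src.n_frames

    def test_constrained_75ms_variant(self, mini_cochleagrams):
        cochs = list(mini_cochleagrams.values())[:4]
        cands = sample_candidates(cochs, n=100, max_dur_ms=75, seed=1)
        assert all(f.duration_ms <= 75.0 for f in cands)

    def test_patches_are_verbatim_submatrices(self, mini_cochleagrams):
        cochs = list(mini_cochleagrams.values())[:4]
        by_id = {c.source_id: c for c in cochs}
        for f in sample_candidates(cochs, n=50, seed=2):
            src = by_id[f.source_call]
            r0, c0 = f.source_offset
            k, m = f.patch.shape
            np.testing.assert_array_equal(f.patch, src.values[r0 : r0 + k, c0 : c0 + m])


class TestTrainInstantiations:
    def test_disjoint_sets_and_auc(self, mini_corpus, mini_cochleagrams):
        sets = train_instantiations(
            mini_corpus,
            "chut",
            n_instantiations=3,
            n_candidates=120,
            mode="one_vs_one",
            partner="purr",
            cochleagrams=mini_cochleagrams,
            seed=5,
        )
        assert len(sets) == 3
        seen = set()
        for s in sets:
            for m in s.mifs:
                key = (m.feature.source_call, m.feature.source_offset, m.feature.patch.shape)
                assert key not in seen
                seen.add(key)
            assert s.training_auc >= 0.97
            assert 1 <= len(s.mifs) <= 20

    def test_deterministic(self, mini_corpus, mini_cochleagrams):
        kwargs = dict(
            n_instantiations=2,
            n_candidates=60,
            mode="one_vs_one",
            partner="purr",
            cochleagrams=mini_cochleagrams,
            seed=9,
        )
        a = train_instantiations(mini_corpus, "chut", **kwargs)
        b = train_instantiations(mini_corpus, "chut", **kwargs)
        for sa, sb in zip(a, b):
            assert len(sa.mifs) == len(sb.mifs)
            for ma, mb in zip(sa.mifs, sb.mifs):
                assert ma.threshold == mb.threshold
                assert ma.weight == mb.weight
                np.testing.assert_array_equal(ma.feature.patch, mb.feature.patch)

    def test_one_vs_one_requires_partner(self, mini_corpus):
        with pytest.raises(ValueError):
            train_instantiations(mini_corpus, "chut", mode="one_vs_one")

    def test_selected_weights_positive(self, mini_models):
        for sets in mini_models.values():
            for s in sets:
                assert all(m.weight > 0 for m in s.mifs)
                assert all(m.merit >= 0 for m in s.mifs)


class TestFDResponse:
    def _set_with_thresholds(self, thresholds, weights):
        rng = np.random.default_rng(0)
        values = rng.uniform(0, 1, (6, 30))
        coch = _coch(values)
        mifs = []
        for thr, w in zip(thresholds, weights):
            patch = values[1:4, 5:12].copy()  # verbatim -> r_max == 1
            mifs.append(
                MIF(feature=_feature(patch, row0=1), threshold=thr, weight=w, merit=0.5)
            )
        return MIFSet(category="toy", mifs=mifs), coch

    def test_all_detected(self):
        s, coch = self._set_with_thresholds([0.5, 0.5, 0.5], [1.0, 2.0, 3.0])
        assert fd_response(s, coch) == pytest.approx(1.0)

    def test_none_detected(self):
        s, coch = self._set_with_thresholds([1.1, 1.1], [1.0, 2.0])
        assert fd_response(s, coch) == 0.0

    def test_two_of_three_weighted(self):
        # weights 1, 2, 3; first two detected -> (1+2)/6 = 0.5
        s, coch = self._set_with_thresholds([0.5, 0.5, 1.1], [1.0, 2.0, 3.0])
        assert fd_response(s, coch) == pytest.approx(0.5)

    def test_monotone_in_detected_set(self):
        # lowering a threshold (adding a detection) never lowers the response
        s_fewer, coch = self._set_with_thresholds([0.5, 1.1, 1.1], [1.0, 2.0, 3.0])
        s_more, _ = self._set_with_thresholds([0.5, 0.5, 1.1], [1.0, 2.0, 3.0])
        assert fd_response(s_more, coch) >= fd_response(s_fewer, coch)


class TestWTA:
    def test_target_wins(self):
        assert wta_decide(0.8, 0.3) == 0.9

    def test_distractor_wins(self):
        assert wta_decide(0.3, 0.8) == 0.1

    def test_tie(self):
        assert wta_decide(0.5, 0.5) == 0.5

    def test_custom_bounds(self):
        assert wta_decide(1.0, 0.0, p_min=0.2, p_max=0.8) == 0.8


class TestSimulateResponse:
    def test_never_go(self):
        rng = np.random.default_rng(0)
        assert all(simulate_response(0.0, rng)[0] == "nogo" for _ in range(100))

    def test_always_go(self):
        rng = np.random.default_rng(0)
        assert all(simulate_response(1.0, rng)[0] == "go" for _ in range(100))

    def test_monte_carlo_rate(self):
        rng = np.random.default_rng(123)
        n = 100_000
        goes = sum(simulate_response(0.9, rng)[0] == "go" for _ in range(n))
        assert goes / n == pytest.approx(0.9, abs=0.005)

    def test_draw_recorded_in_unit_interval(self):
        rng = np.random.default_rng(5)
        _, x = simulate_response(0.5, rng)
        assert 0.0 <= x <= 1.0


class TestAUC:
    def test_perfect(self):
        assert auc_from_scores([0.9, 0.8], [0.1, 0.2]) == pytest.approx(1.0)

    def test_all_equal(self):
        assert auc_from_scores([0.5, 0.5], [0.5, 0.5]) == pytest.approx(0.5)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_rank_statistic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.round(rng.uniform(0, 1, int(rng.integers(2, 10))), 1)
        neg = np.round(rng.uniform(0, 1, int(rng.integers(2, 10))), 1)
        u = mannwhitneyu(pos, neg, alternative="two-sided").statistic
        want = u / (len(pos) * len(neg))
        assert auc_from_scores(pos, neg) == pytest.approx(want, abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc_from_scores([], [0.1])


class TestRelativeDetectionRate:
    def _simple_set(self, thr):
        rng = np.random.default_rng(7)
        base = rng.uniform(0, 1, (6, 30))
        patch = base[1:4, 5:12].copy()
        s = MIFSet(
            category="toy",
            mifs=[MIF(feature=_feature(patch, row0=1), threshold=thr, weight=1.0, merit=0.5)],
        )
        return s, base

    def test_perfect_discrimination(self):
        s, base = self._simple_set(thr=0.98)
        within = [_coch(base)] * 3  # contains the patch verbatim -> r = 1
        outside = [_coch(np.random.default_rng(8).uniform(0, 1, (6, 30)))] * 3
        df = relative_detection_rate(s, within, outside)
        assert df.loc[0, "rate_diff"] == pytest.approx(1.0)

    def test_detected_everywhere_is_zero(self):
        s, base = self._simple_set(thr=-1.1)
        within = [_coch(base)] * 2
        outside = [_coch(np.random.default_rng(9).uniform(0, 1, (6, 30)))] * 2
        df = relative_detection_rate(s, within, outside)
        assert df.loc[0, "rate_diff"] == pytest.approx(0.0)

    def test_hand_computed_three_call_case(self):
        s, base = self._simple_set(thr=0.98)
        other = _coch(np.random.default_rng(10).uniform(0, 1, (6, 30)))
        df = relative_detection_rate(s, [_coch(base), other, other], [other])
        # detected in 1 of 3 within, 0 of 1 outside
        assert df.loc[0, "rate_within"] == pytest.approx(1 / 3)
        assert df.loc[0, "rate_diff"] == pytest.approx(1 / 3)

    def test_empty_lists_rejected(self):
        s, base = self._simple_set(0.5)
        with pytest.raises(ValueError):
            relative_detection_rate(s, [], [_coch(base)])


def test_mifset_size_invariant():
    m, _ = _mif(1.0, [1, 0])
    with pytest.raises(ValueError):
        MIFSet(category="x", mifs=[])
    with pytest.raises(ValueError):
        MIFSet(category="x", mifs=[m] * 21)


def test_save_load_roundtrip(tmp_path, mini_models):
    sets = mini_models["chut"]
    save_mifsets(tmp_path / "chut", sets)
    back = load_mifsets(tmp_path / "chut")
    assert len(back) == len(sets)
    for sa, sb in zip(sets, back):
        assert sb.category == sa.category
        assert sb.training_auc == pytest.approx(sa.training_auc)
        for ma, mb in zip(sa.mifs, sb.mifs):
            assert mb.threshold == ma.threshold
            assert mb.weight == ma.weight
            np.testing.assert_array_equal(mb.feature.patch, ma.feature.patch)


def test_evaluate_auc_on_trained_model(mini_corpus, mini_cochleagrams, mini_models):
    s = mini_models["chut"][0]
    pos = [mini_cochleagrams[c.exemplar_id] for c in mini_corpus.subset("train", "chut")]
    neg = [mini_cochleagrams[c.exemplar_id] for c in mini_corpus.subset("train", "purr")]
    assert evaluate_auc(s, pos, neg) == pytest.approx(s.training_auc, abs=1e-9)
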