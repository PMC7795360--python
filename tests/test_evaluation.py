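"""Sample metrics, boundary timing error, and the LOSO harness."""

import json

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import precision_recall_fscore_support

import shoulderseg as ss
import shoulderseg.evaluation as ev


class TestSampleMetrics:
    def test_hand_computed_confusion(self):
        m = ss.sample_metrics(list("AABB"), list("ABBB"))
        a, b = m["per_class"]["A"], m["per_class"]["B"]
        assert a.sensitivity == pytest.approx(0.5)
        assert a.precision == pytest.approx(1.0)
        assert a.f_score == pytest.approx(2 / 3)
        assert b.sensitivity == pytest.approx(1.0)
        assert b.precision == pytest.approx(2 / 3)
        assert b.f_score == pytest.approx(0.8)
        assert m["overall"]["f_score"] == pytest.approx((2 / 3 + 0.8) / 2)

    def test_perfect_prediction(self):
        gt = list("AABBCC")
        m = ss.sample_metrics(gt, gt)
        for c in "ABC":
            assert m["per_class"][c].f_score == 1.0
        assert m["overall"]["f_score"] == 1.0

    def test_constant_prediction_on_balanced_classes(self):
        gt = list("ABC") * 4
        m = ss.sample_metrics(gt, ["A"] * 12)
        assert m["per_class"]["A"].precision == pytest.approx(1 / 3)
        assert m["per_class"]["A"].sensitivity == 1.0

    def test_absent_class_excluded_from_macro_with_warning(self):
        with pytest.warns(RuntimeWarning, match="absent"):
            m = ss.sample_metrics(list("AABB"), list("AABB"), classes=["A", "B", "C"])
        assert m["overall"]["f_score"] == 1.0

    def test_matches_sklearn(self, rng):
        gt = rng.choice(list("ABC"), size=200)
        pred = rng.choice(list("ABC"), size=200)
        m = ss.sample_metrics(gt, pred)
        p, r, f, _ = precision_recall_fscore_support(
            gt, pred, labels=["A", "B", "C"], zero_division=0
        )
        for i, c in enumerate("ABC"):
            assert m["per_class"][c].precision == pytest.approx(p[i])
            assert m["per_class"][c].sensitivity == pytest.approx(r[i])
            assert m["per_class"][c].f_score == pytest.approx(f[i])

    def test_micro_average_available(self):
        m = ss.sample_metrics(list("AABBCC"), list("AABBCA"), average="micro")
        assert m["overall"]["f_score"] == pytest.approx(5 / 6)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ss.sample_metrics(list("AB"), list("ABC"))

    @given(
        st.lists(st.sampled_from("ABC"), min_size=4, max_size=60),
        st.integers(0, 2**31 - 1),
    )
    def test_f_between_min_and_max_of_rates(self, gt, seed):
        pred = np.random.default_rng(seed).choice(list("ABC"), size=len(gt))
        m = ss.sample_metrics(gt, pred)
        for cm in m["per_class"].values():
            lo = min(cm.sensitivity, cm.precision)
            hi = max(cm.sensitivity, cm.precision)
            assert lo - 1e-12 <= cm.f_score <= hi + 1e-12


class TestBoundaries:
    def test_run_scan(self):
        assert ss.extract_boundaries(list("AABBC")) == [("AB", 3), ("BC", 5)]

    def test_single_class_stream_has_no_boundaries(self):
        assert ss.extract_boundaries(["A"] * 5) == []

    def test_reverse_transitions_ignored(self):
        assert ss.extract_boundaries(list("ABAB")) == [("AB", 2), ("AB", 4)]


class TestMate:
    def test_identity_prediction_zero_error(self):
        b = [("AB", 100), ("BC", 300)]
        rep = ss.mate(b, b)
        assert rep.mate_ab == rep.mate_bc == rep.mate_overall == 0.0
        assert rep.n_matched == 2 and rep.n_unmatched == 0

    def test_64_sample_shift_is_500_ms(self):
        rep = ss.mate([("AB", 100), ("BC", 300)], [("AB", 164), ("BC", 300)])
        assert rep.mate_ab == pytest.approx(500.0)
        assert rep.mate_overall == pytest.approx(250.0)

    @pytest.mark.parametrize("shift", [-40, 40])
    def test_symmetric_and_linear_in_shift(self, shift):
        rep = ss.mate([("AB", 200)], [("AB", 200 + shift)])
        assert rep.mate_ab == pytest.approx(abs(shift) / 128 * 1000)

    def test_missing_subtask_counts_unmatched(self):
        rep = ss.mate([("AB", 100), ("BC", 300)], [("AB", 104)])
        assert rep.n_unmatched == 1
        assert np.isnan(rep.mate_bc)
        assert rep.mate_overall == rep.mate_ab

    def test_nearest_same_type_match(self):
        rep = ss.mate([("AB", 100)], [("AB", 90), ("AB", 160), ("BC", 101)])
        assert rep.mate_ab == pytest.approx(10 / 128 * 1000)

    def test_malformed_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            ss.mate([("XY", 5)], [("AB", 5)])


@pytest.fixture
def loso_kwargs():
    return dict(
        task_spec=ss.TaskClassifierSpec(model="knn", knn_k=3),
        window=ss.WindowConfig.from_seconds(0.3),
    )


class TestLoso:
    def test_fold_bookkeeping_two_subjects(self, loso_kwargs):
        ds = ss.generate_dataset(1, 1, ["T1", "T2"], seed=21)
        res = ss.loso_cv(ds, **loso_kwargs)
        assert [f.subject_id for f in res.folds] == ["H01", "P01"]
        assert all(f.n_sequences == 2 for f in res.folds)
        assert res.aggregate["n_folds"] == 2

    def test_order_invariance(self, small_dataset, loso_kwargs):
        res1 = ss.loso_cv(small_dataset, **loso_kwargs)
        shuffled = list(small_dataset)
        np.random.default_rng(0).shuffle(shuffled)
        res2 = ss.loso_cv(shuffled, **loso_kwargs)
        # string comparison so NaN boundary-error entries compare equal
        assert json.dumps(res1.to_dict()) == json.dumps(res2.to_dict())

    def test_no_test_fold_leakage(self, small_dataset, loso_kwargs, monkeypatch):
        """Every fitting call sees only training-subject feature rows."""
        seen: list[np.ndarray] = []
        real_fit_pca = ev.fit_pca

        def spy(F, *a, **k):
            seen.append(np.asarray(F))
            return real_fit_pca(F, *a, **k)

        monkeypatch.setattr(ev, "fit_pca", spy)
        import shoulderseg.segmentation as seg

        monkeypatch.setattr(seg, "fit_pca", spy)
        res = ss.loso_cv(small_dataset, **loso_kwargs)

        # recompute the held-out subjects' raw features and check absence
        subjects = sorted({s.subject_id for s in small_dataset})
        prep = ev._prepare(
            sorted(small_dataset, key=lambda s: (s.subject_id, s.task_id)),
            loso_kwargs["window"],
            ss.SwmaConfig(),
            0.1,
        )
        calls_per_fold = len(seen) // len(subjects)
        assert len(seen) == calls_per_fold * len(subjects)
        for i, subj in enumerate(subjects):
            fold_mats = seen[i * calls_per_fold : (i + 1) * calls_per_fold]
            held_rows = [p.seq_features for p in prep if p.seq.subject_id == subj]
            held_rows += [
                w for p in prep if p.seq.subject_id == subj for w in p.win_features
            ]
            for mat in fold_mats:
                for row in held_rows:
                    if mat.shape[1] == row.shape[0]:
                        assert not np.any(np.all(mat == row, axis=1))

    def test_oracle_pipeline_reaches_perfect_task_f(self, small_dataset):
        # with easy data and the default pipeline, the tiny 4-subject set
        # already yields valid reports with finite metrics
        res = ss.loso_cv(
            small_dataset,
            task_spec=ss.TaskClassifierSpec(model="knn", knn_k=3),
            window=ss.WindowConfig.from_seconds(0.3),
        )
        a = res.aggregate
        assert 0.0 <= a["subtask"]["f_score"] <= 1.0
        assert a["task"]["f_score"] > 0.2  # far above 5-class chance
        assert np.isfinite(a["mate"]["mate_overall_ms"])

    def test_single_subject_rejected(self):
        ds = ss.generate_dataset(1, 0, ["T1", "T2"], seed=2)
        with pytest.raises(ValueError):
            ss.loso_cv(ds)
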