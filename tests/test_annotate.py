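"""Leading-seizure selection, SOP/SPH labelling, chronological splits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ictalert.annotate import (
    EXCLUDED,
    INTERICTAL,
    PREICTAL,
    HorizonConfig,
    SeizureAnnotation,
    build_training_selection,
    chronological_split,
    label_windows,
    select_leading_seizures,
)

H = 3600.0


def ann(*onsets_h):
    return SeizureAnnotation(onsets=np.array(onsets_h) * H)


class TestLeadingSeizures:
    def test_all_kept_when_far_apart(self, horizon):
        out = select_leading_seizures(ann(0, 5, 10), horizon)
        np.testing.assert_array_equal(out.onsets / H, [0, 5, 10])

    def test_close_seizure_dropped(self, horizon):
        with pytest.warns(UserWarning, match="leading"):
            out = select_leading_seizures(ann(0, 2, 5), horizon)
        np.testing.assert_array_equal(out.onsets / H, [0, 5])

    @settings(max_examples=200, deadline=None)
    @given(
        st.lists(st.floats(0, 100), min_size=1, max_size=8, unique=True)
    )
    def test_matches_greedy_oracle(self, onsets_h):
        """Exhaustive check against an independently written greedy scan."""
        onsets = np.sort(np.array(onsets_h)) * H
        if np.any(np.diff(onsets) == 0):
            return
        cfg = HorizonConfig()
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            got = select_leading_seizures(SeizureAnnotation(onsets=onsets), cfg).onsets
        kept = [onsets[0]]
        for t in onsets[1:]:
            if t - kept[-1] >= 4.5 * H:
                kept.append(t)
        np.testing.assert_array_equal(got, np.array(kept))


class TestLabelWindows:
    def test_preictal_span(self, horizon, make_grid_windows):
        ws = make_grid_windows(1100)  # 11000 s of windows
        lw = label_windows(ws, SeizureAnnotation(onsets=np.array([10000.0])), horizon)
        starts = ws.start_times
        pre = starts[lw.labels == PREICTAL]
        assert pre.min() == 7600.0 and pre.max() == 9990.0
        assert len(pre) == 240  # 40 min of 10-s windows

    def test_post_ictal_exclusion(self, horizon, make_grid_windows):
        ws = make_grid_windows(1500)
        lw = label_windows(ws, SeizureAnnotation(onsets=np.array([10000.0])), horizon)
        # a window starting 29 min after onset overlaps the exclusion zone
        idx = int((10000 + 29 * 60) // 10)
        assert lw.labels[idx] == EXCLUDED
        idx_after = int((10000 + 31 * 60) // 10)
        assert lw.labels[idx_after] == INTERICTAL


class TestTrainingSelection:
    def test_full_data_counts(self, horizon, make_grid_windows):
        """3 h 20 min interictal (1200 windows) + 30 min preictal (180) per
        training seizure; the 20:3 class ratio follows."""
        ws = make_grid_windows(6000)
        a = SeizureAnnotation(onsets=np.array([15 * H]))
        lw = label_windows(ws, a, horizon)
        sel = build_training_selection(lw, a, horizon)
        assert int((sel.labels == INTERICTAL).sum()) == 1200
        assert int((sel.labels == PREICTAL).sum()) == 180
        assert 1200 / 180 == pytest.approx(20 / 3)
        starts = ws.start_times[sel.indices]
        onset = 15 * H
        assert starts.min() == onset - 4 * H
        assert starts.max() == onset - horizon.sph_s - 10  # SPH dropped

    def test_gap_covering_sop_warns(self, horizon, make_grid_windows):
        onset = 15 * H
        valid = np.ones(6000, dtype=bool)
        sop_span = (np.arange(6000) * 10 >= onset - horizon.preictal_s) & (
            np.arange(6000) * 10 < onset - horizon.sph_s
        )
        valid[sop_span] = False
        ws = make_grid_windows(6000, valid=valid)
        a = SeizureAnnotation(onsets=np.array([onset]))
        lw = label_windows(ws, a, horizon)
        with pytest.warns(UserWarning, match="no valid preictal"):
            sel = build_training_selection(lw, a, horizon)
        assert (sel.labels == PREICTAL).sum() == 0

    def test_interictal_subsample_is_seeded(self, horizon, make_grid_windows):
        ws = make_grid_windows(6000)
        a = SeizureAnnotation(onsets=np.array([15 * H]))
        lw = label_windows(ws, a, horizon)
        s1 = build_training_selection(lw, a, horizon, max_interictal_per_seizure=100, seed=5)
        s2 = build_training_selection(lw, a, horizon, max_interictal_per_seizure=100, seed=5)
        s3 = build_training_selection(lw, a, horizon, max_interictal_per_seizure=100, seed=6)
        np.testing.assert_array_equal(s1.indices, s2.indices)
        assert (s1.labels == INTERICTAL).sum() == 100
        assert not np.array_equal(s1.indices, s3.indices)


class TestChronologicalSplit:
    def _setup(self, n_seiz, horizon, make_grid_windows, spacing_h=5.0):
        onsets = (np.arange(n_seiz) + 1.3) * spacing_h * H
        n_win = int((onsets[-1] + H) // 10)
        ws = make_grid_windows(n_win)
        a = SeizureAnnotation(onsets=onsets)
        return a, label_windows(ws, a, horizon)

    @pytest.mark.parametrize("n,expected_train", [(5, 3), (3, 2), (10, 6)])
    def test_seizure_counts(self, n, expected_train, horizon, make_grid_windows):
        a, lw = self._setup(n, horizon, make_grid_windows)
        plan = chronological_split(a, lw, horizon)
        assert len(plan.train_seizures) == expected_train
        assert len(plan.test_seizures) == n - expected_train

    def test_too_few_seizures_rejected(self, horizon, make_grid_windows):
        a, lw = self._setup(2, horizon, make_grid_windows)
        with pytest.raises(ValueError, match="at least 3"):
            chronological_split(a, lw, horizon)

    def test_test_segments_start_after_exclusion(self, horizon, make_grid_windows):
        a, lw = self._setup(5, horizon, make_grid_windows)
        plan = chronological_split(a, lw, horizon)
        for k, i in enumerate(plan.test_seizures):
            lo, hi = plan.test_segments[k]
            assert lo == a.onsets[i - 1] + 30 * 60
            assert hi == a.onsets[i]

    def test_no_temporal_leakage(self, horizon, make_grid_windows):
        a, lw = self._setup(5, horizon, make_grid_windows)
        plan = chronological_split(a, lw, horizon)
        starts = lw.windows.start_times
        used = np.concatenate([plan.train_idx, plan.val_idx])
        assert starts[used].max() < a.onsets[plan.test_seizures].min()
        for lo, hi in plan.test_segments:
            assert not np.any((starts[used] >= lo) & (starts[used] < hi))

    def test_holdout_deterministic_and_stratified(self, horizon, make_grid_windows):
        a, lw = self._setup(5, horizon, make_grid_windows)
        p1 = chronological_split(a, lw, horizon, seed=3)
        p2 = chronological_split(a, lw, horizon, seed=3)
        np.testing.assert_array_equal(p1.train_idx, p2.train_idx)
        np.testing.assert_array_equal(p1.val_idx, p2.val_idx)
        # label proportions preserved within 2 percentage points
        frac_all = 180 / (180 + 1200)
        frac_val = (p1.val_labels == PREICTAL).mean()
        assert abs(frac_val - frac_all) < 0.02
        # 80/20 ratio
        n_tot = len(p1.train_idx) + len(p1.val_idx)
        assert len(p1.val_idx) / n_tot == pytest.approx(0.2, abs=0.01)

    def test_preictal_duration_never_exceeds_horizon(self, horizon, make_grid_windows):
        a, lw = self._setup(4, horizon, make_grid_windows)
        for onset in a.onsets:
            starts = lw.windows.start_times
            n_pre = np.sum(
                (lw.labels == PREICTAL)
                & (starts >= onset - horizon.preictal_s)
                & (starts < onset)
            )
            assert n_pre * 10 <= horizon.preictal_s
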