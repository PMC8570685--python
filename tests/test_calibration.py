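import numpy as np
import pytest

from swimscore import (
    LabeledSeconds,
    exclude_transitions,
    load_manual_labels,
    optimum_cutpoint,
    roc_curve,
    split_calibration,
)
from swimscore.calibration import (
    ROCCurve,
    LabelDuplicateError,
    LabelGapError,
    NonBinaryLabelError,
    SingleClassError,
)


def mann_whitney_oracle(imm, mob):
    """Pair-ordering probability: P(immobile value < mobile value), ties 1/2."""
    wins = 0.0
    for a in imm:
        for b in mob:
            if a < b:
                wins += 1.0
            elif a == b:
                wins += 0.5
    return wins / (len(imm) * len(mob))


def labeled(imm_values, mob_values):
    values = np.concatenate([imm_values, mob_values])
    labels = np.r_[np.ones(len(imm_values)), np.zeros(len(mob_values))]
    return LabeledSeconds(values, labels, np.ones(len(values), dtype=bool))


class TestExcludeTransitions:
    def test_window_rule(self):
        kept = exclude_transitions([0, 0, 0, 1, 1, 1, 0, 0], k=1)
        assert list(np.flatnonzero(kept)) == [0, 1, 4, 7]

    def test_k_zero_keeps_everything(self):
        assert exclude_transitions([0, 1, 0, 1, 1], k=0).all()

    def test_constant_labels_keep_everything(self):
        assert exclude_transitions([1] * 10, k=3).all()

    def test_exclusion_monotone_in_k(self, rng):
        labels = rng.integers(0, 2, size=120)
        removed = [
            (~exclude_transitions(labels, k)).sum() for k in range(5)
        ]
        assert removed == sorted(removed)


class TestRocCurve:
    def test_perfect_separation(self):
        roc = roc_curve(labeled([0.1, 0.2], [0.5, 0.9]))
        assert roc.auc == pytest.approx(1.0)
        assert np.max(roc.sensitivity * roc.specificity) == pytest.approx(1.0)

    def test_all_ties_gives_half(self):
        roc = roc_curve(labeled([2.0, 2.0], [2.0, 2.0, 2.0]))
        assert roc.auc == pytest.approx(0.5)

    def test_interleaved_example(self):
        roc = roc_curve(labeled([1.0, 3.0], [2.0, 4.0]))
        assert roc.auc == pytest.approx(0.75)  # 3 of 4 pairs ordered

    def test_endpoints_reach_corners(self):
        roc = roc_curve(labeled([1.0, 2.0], [1.5, 3.0]))
        assert (roc.sensitivity[0], roc.specificity[0]) == (0.0, 1.0)
        assert (roc.sensitivity[-1], roc.specificity[-1]) == (1.0, 0.0)
        assert np.all(np.diff(roc.sensitivity) >= 0)

    def test_single_class_rejected(self):
        data = LabeledSeconds([1.0, 2.0], [1, 1], [True, True])
        with pytest.raises(SingleClassError):
            roc_curve(data)

    def test_auc_equals_mann_whitney(self, rng):
        for _ in range(25):
            n1 = int(rng.integers(2, 25))
            n0 = int(rng.integers(2, 25))
            if rng.random() < 0.5:  # continuous values
                imm = rng.uniform(0, 5, n1)
                mob = rng.uniform(0, 5, n0)
            else:  # coarse grid forces ties
                imm = rng.integers(0, 6, n1).astype(float)
                mob = rng.integers(0, 6, n0).astype(float)
            roc = roc_curve(labeled(imm, mob))
            assert roc.auc == pytest.approx(
                mann_whitney_oracle(imm, mob), abs=1e-9
            )


class TestOptimumCutpoint:
    def test_argmax_of_product(self):
        roc = ROCCurve(
            thresholds=np.array([0.3, 0.5]),
            sensitivity=np.array([0.8, 0.9]),
            specificity=np.array([0.9, 0.85]),
            auc=0.9,
        )
        assert optimum_cutpoint(roc).optimum_threshold == pytest.approx(0.5)

    def test_tie_breaks_to_smaller_threshold(self):
        roc = ROCCurve(
            thresholds=np.array([0.2, 0.4, 0.8]),
            sensitivity=np.array([0.6, 0.3, 0.9]),
            specificity=np.array([0.5, 1.0, 1 / 3]),
            auc=0.5,
        )
        # products 0.30, 0.30, 0.30: all tied -> smallest c
        assert optimum_cutpoint(roc).optimum_threshold == pytest.approx(0.2)

    def test_matches_exhaustive_search(self, rng):
        for _ in range(25):
            imm = rng.uniform(0, 3, int(rng.integers(2, 20)))
            mob = rng.uniform(1, 5, int(rng.integers(2, 20)))
            roc = roc_curve(labeled(imm, mob))
            best = max(
                range(len(roc.thresholds)),
                key=lambda i: (
                    roc.sensitivity[i] * roc.specificity[i],
                    -roc.thresholds[i],
                ),
            )
            assert optimum_cutpoint(roc).optimum_threshold == pytest.approx(
                roc.thresholds[best]
            )

    def test_perfect_grid_attains_product_one(self):
        roc = roc_curve(labeled([0.1, 0.3], [1.0, 2.0]))
        res = optimum_cutpoint(roc)
        i = int(np.argmin(np.abs(roc.thresholds - res.optimum_threshold)))
        assert roc.sensitivity[i] * roc.specificity[i] == pytest.approx(1.0)


class TestSplitCalibration:
    def test_sixty_percent_of_twenty(self):
        cal, val = split_calibration(list(range(20)), fraction=0.60, seed=1)
        assert (len(cal), len(val)) == (12, 8)
        assert sorted(cal + val) == list(range(20))

    def test_half_of_ten(self):
        cal, val = split_calibration(list(range(10)), fraction=0.5, seed=0)
        assert (len(cal), len(val)) == (5, 5)

    def test_same_seed_reproduces_split(self):
        a = split_calibration(list(range(15)), seed=42)
        b = split_calibration(list(range(15)), seed=42)
        assert a == b

    def test_too_few_videos_rejected(self):
        with pytest.raises(ValueError):
            split_calibration([1], seed=0)


class TestLoadManualLabels:
    def _write(self, tmp_path, rows):
        path = tmp_path / "labels.csv"
        path.write_text("second_index,label\n" + "\n".join(rows) + "\n")
        return path

    def test_parses_labels(self, tmp_path):
        path = self._write(tmp_path, ["0,1", "1,1", "2,0"])
        np.testing.assert_array_equal(load_manual_labels(path), [1, 1, 0])

    def test_gap_raises(self, tmp_path):
        path = self._write(tmp_path, ["0,1", "2,0"])
        with pytest.raises(LabelGapError):
            load_manual_labels(path)

    def test_duplicate_raises(self, tmp_path):
        path = self._write(tmp_path, ["0,1", "1,0", "1,1"])
        with pytest.raises(LabelDuplicateError):
            load_manual_labels(path)

    def test_non_binary_raises(self, tmp_path):
        path = self._write(tmp_path, ["0,1", "1,2"])
        with pytest.raises(NonBinaryLabelError):
            load_manual_labels(path)
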