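import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cvmstage.evaluation import (
    ConfusionMatrix,
    cohen_kappa,
    confusion,
    f1_from_pr,
    icc,
    landmark_error_summary,
    landmark_errors,
    metric_report,
    overall_accuracy,
    per_class_metrics,
    round_half_up,
)
from cvmstage.landmark_io import ANATOMIC_NAMES, Landmark
from cvmstage.staging import CVMStage
from cvmstage.synthetic import sample_case

from conftest import make_record

S = list(CVMStage)


def cm_from(counts):
    return ConfusionMatrix(np.array(counts))


def random_cm(rng, n_max=30):
    return cm_from(rng.integers(0, n_max, size=(6, 6)))


class TestConfusion:
    def test_diagonal_tally(self):
        cm = confusion([CVMStage.CS1] * 5, [CVMStage.CS1] * 5)
        assert cm.counts[0, 0] == 5 and cm.total == 5

    def test_off_diagonal_tally(self):
        cm = confusion([CVMStage.CS1, CVMStage.CS2], [CVMStage.CS2, CVMStage.CS2])
        assert cm.counts[0, 1] == 1 and cm.counts[1, 1] == 1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            confusion([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion([CVMStage.CS1], [])


class TestPerClassMetrics:
    def test_counts_example(self):
        # CS1 one-vs-rest with TP=12, FP=6, FN=1, TN=81 on 100 records
        m = np.zeros((6, 6), dtype=int)
        m[0, 0] = 12
        m[0, 1] = 1          # FN
        m[1, 0] = 6          # FP
        m[1, 1] = 81         # rest correct
        met = per_class_metrics(cm_from(m), CVMStage.CS1)
        assert met.precision == pytest.approx(12 / 18, abs=5e-4)
        assert met.recall == pytest.approx(12 / 13, abs=5e-4)
        assert met.specificity == pytest.approx(81 / 87, abs=5e-4)
        assert met.f1 == pytest.approx(0.774, abs=5e-4)

    def test_perfect_classifier(self):
        cm = cm_from(np.diag([3, 4, 5, 6, 7, 8]))
        for s in S:
            met = per_class_metrics(cm, s)
            assert met.precision == met.recall == met.specificity == met.f1 == 1.0

    def test_absent_class_contract(self):
        cm = cm_from(np.diag([5, 5, 5, 5, 5, 0]))
        met = per_class_metrics(cm, CVMStage.CS6)
        assert met.recall is None
        assert met.specificity == 1.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_sklearn(self, seed):
        from sklearn.metrics import precision_score, recall_score

        rng = np.random.default_rng(seed)
        gold = rng.integers(0, 6, 60)
        pred = rng.integers(0, 6, 60)
        cm = confusion([S[g] for g in gold], [S[p] for p in pred])
        for c in range(6):
            met = per_class_metrics(cm, S[c])
            skl_p = precision_score(gold, pred, labels=[c], average="macro",
                                    zero_division=np.nan)
            skl_r = recall_score(gold, pred, labels=[c], average="macro",
                                 zero_division=np.nan)
            assert (met.precision is None) == bool(np.isnan(skl_p))
            if met.precision is not None:
                assert met.precision == pytest.approx(skl_p)
            if met.recall is not None:
                assert met.recall == pytest.approx(skl_r)


class TestF1:
    @pytest.mark.parametrize("p, r, rounded", [(1.00, 0.74, 0.85),
                                               (0.25, 0.40, 0.31)])
    def test_harmonic_mean_examples(self, p, r, rounded):
        assert round_half_up(f1_from_pr(p, r)) == rounded

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(x=st.floats(0.01, 1.0, allow_nan=False))
    def test_identity_on_equal_arguments(self, x):
        assert f1_from_pr(x, x) == pytest.approx(x)

    def test_both_zero_undefined(self):
        assert f1_from_pr(0.0, 0.0) is None


class TestOverallStatistics:
    def test_accuracy_of_diagonal_matrix(self):
        assert overall_accuracy(cm_from(np.diag([1, 2, 3, 4, 5, 6]))) == 1.0

    def test_accuracy_zero_trace(self):
        m = np.ones((6, 6), dtype=int) - np.eye(6, dtype=int)
        assert overall_accuracy(cm_from(m)) == 0.0

    def test_kappa_perfect_agreement(self):
        assert cohen_kappa(cm_from(np.diag([4] * 6))) == 1.0

    def test_kappa_hand_computed_two_by_two(self):
        # 2x2 table [[25, 5], [10, 60]] embedded in the 6x6 frame:
        # p_o = 0.85, p_e = 0.56 -> kappa = 0.29 / 0.44
        m = np.zeros((6, 6), dtype=int)
        m[0, 0], m[0, 1], m[1, 0], m[1, 1] = 25, 5, 10, 60
        assert cohen_kappa(cm_from(m)) == pytest.approx(0.29 / 0.44, abs=1e-9)

    def test_kappa_chance_level_for_independent_raters(self):
        row = np.array([1, 2, 3, 4, 5, 6])
        m = np.outer(row, row)  # rank-1: p_o == p_e
        assert cohen_kappa(cm_from(m)) == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_kappa_agrees_with_sklearn(self, seed):
        from sklearn.metrics import cohen_kappa_score

        rng = np.random.default_rng(seed)
        gold = rng.integers(0, 6, 80)
        pred = (gold + rng.integers(0, 3, 80)) % 6
        cm = confusion([S[g] for g in gold], [S[p] for p in pred])
        assert cohen_kappa(cm) == pytest.approx(cohen_kappa_score(gold, pred))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_accuracy_is_count_weighted_mean_recall(self, seed):
        rng = np.random.default_rng(seed)
        cm = random_cm(rng)
        if cm.total == 0:
            return
        acc = overall_accuracy(cm)
        weighted = sum(
            (per_class_metrics(cm, s).recall or 0.0) * cm.row_sum(s)
            for s in S
        ) / cm.total
        assert acc == pytest.approx(weighted)
        k = cohen_kappa(cm)
        if k is not None:
            assert k <= acc + 1e-12


class TestICC:
    def test_identical_columns_perfect(self):
        x = np.tile(np.arange(1, 7, dtype=float)[:, None], (1, 2))
        assert icc(x) == pytest.approx(1.0)

    def test_absolute_vs_consistency_ordering(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=30)
        x = np.stack([a, a + 5.0], axis=1)
        assert icc(x, "icc2") < icc(x, "icc3")
        assert icc(x, "icc3") == pytest.approx(1.0)

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(1)
        vals = [icc(rng.normal(size=(100, 2))) for _ in range(50)]
        assert abs(np.median(vals)) < 0.15

    def test_constant_ratings_undefined(self):
        assert icc(np.full((5, 2), 3.0)) is None

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_agrees_with_pingouin(self, seed):
        import pandas as pd
        import pingouin as pg

        rng = np.random.default_rng(seed)
        x = rng.normal(size=(15, 3)) + rng.normal(size=(15, 1))
        df = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 3),
                "rater": np.tile(np.arange(3), 15),
                "score": x.ravel(),
            }
        )
        res = pg.intraclass_corr(df, "subject", "rater", "score").set_index("Type")
        assert icc(x, "icc2") == pytest.approx(res.loc["ICC(A,1)", "ICC"], abs=1e-6)
        assert icc(x, "icc3") == pytest.approx(res.loc["ICC(C,1)", "ICC"], abs=1e-6)
        assert icc(x, "icc2k") == pytest.approx(res.loc["ICC(A,k)", "ICC"], abs=1e-6)


class TestLandmarkErrors:
    def _pair(self, offset_px=(0.0, 0.0), which="C3m"):
        rng = np.random.default_rng(11)
        truth = sample_case(CVMStage.CS3, rng, render=False, image_id="a").record
        coords = {n: (lm.x, lm.y) for n, lm in truth.landmarks.items()}
        coords[which] = (coords[which][0] + offset_px[0],
                         coords[which][1] + offset_px[1])
        pred = make_record(coords, image_id="a")
        return pred, truth

    def test_identical_records_zero_error(self):
        pred, truth = self._pair()
        rep = landmark_errors([pred], [truth])
        assert rep.total_mean == 0.0
        assert all(v == 0.0 for v in rep.per_landmark_mean.values())

    def test_single_offset_three_four_five(self):
        # (3,4) px at 0.25 mm/px -> 5 px -> 1.25 mm for that landmark
        pred, truth = self._pair((3.0, 4.0), "C4la")
        rep = landmark_errors([pred], [truth])
        assert rep.per_landmark_mean["C4la"] == pytest.approx(1.25)
        assert rep.per_landmark_mean["C3m"] == 0.0

    def test_unpaired_id_raises(self):
        pred, truth = self._pair()
        pred.image_id = "other"
        with pytest.raises(ValueError, match="paired"):
            landmark_errors([pred], [truth])

    def test_summary_is_mean_and_sample_sd_of_means(self):
        means = [0.1 * i for i in range(1, 14)]
        mean, sd = landmark_error_summary(means)
        assert mean == pytest.approx(np.mean(means))
        assert sd == pytest.approx(np.std(means, ddof=1))


def test_metric_report_end_to_end_perfect():
    gold = [s for s in S for _ in range(4)]
    rep = metric_report(gold, gold)
    assert rep.accuracy == 1.0 and rep.kappa == 1.0
    assert rep.icc == pytest.approx(1.0)


def test_permutation_equivariance():
    """Relabelling stages by a permutation permutes the per-class metrics."""
    rng = np.random.default_rng(9)
    gold = rng.integers(0, 6, 120)
    pred = (gold + rng.integers(0, 2, 120)) % 6
    perm = rng.permutation(6)
    cm1 = confusion([S[g] for g in gold], [S[p] for p in pred])
    cm2 = confusion([S[perm[g]] for g in gold], [S[perm[p]] for p in pred])
    for c in range(6):
        m1 = per_class_metrics(cm1, S[c])
        m2 = per_class_metrics(cm2, S[perm[c]])
        assert m1 == m2
    assert overall_accuracy(cm1) == overall_accuracy(cm2)
    assert cohen_kappa(cm1) == pytest.approx(cohen_kappa(cm2))
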