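import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from agingaccel.clock import (
    ClockError,
    ClockModel,
    acceleration_test,
    age_label,
    balanced_error,
    bh_fdr,
    kruskal_wallis,
    score_samples,
    screen_markers,
    train_clock,
)
from agingaccel.preprocess import preprocess_cohort


class TestAgeLabel:
    def test_rule(self):
        assert age_label(61) == 1
        assert age_label(60) == 0
        assert age_label(0) == 0

    def test_negative_rejected(self):
        with pytest.raises(ClockError):
            age_label(-1)


class TestKruskalWallis:
    def test_hand_example(self):
        # ranks 1..6; H = 12/(6*7) * (36/3 + 225/3) - 21 = 27/7
        h, p = kruskal_wallis([np.array([1.0, 2, 3]), np.array([4.0, 5, 6])])
        assert h == pytest.approx(27.0 / 7.0, abs=1e-9)
        assert h == pytest.approx(3.857, abs=1e-3)
        assert p == pytest.approx(0.0495, abs=1e-3)

    def test_exchangeable_groups(self):
        h, p = kruskal_wallis([np.array([1.0, 2]), np.array([1.0, 2])])
        assert h == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_degenerate_all_identical(self):
        h, p = kruskal_wallis([np.array([2.0, 2.0]), np.array([2.0, 2.0])])
        assert (h, p) == (0.0, 1.0)

    def test_reference_oracle_with_ties(self, rng):
        for _ in range(100):
            sizes = rng.integers(3, 12, size=int(rng.integers(2, 4)))
            groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
            pooled = np.concatenate(groups)
            if np.all(pooled == pooled[0]):
                continue
            h, p = kruskal_wallis(groups)
            h_ref, p_ref = stats.kruskal(*groups)
            assert h == pytest.approx(h_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_input_validation(self):
        with pytest.raises(ClockError):
            kruskal_wallis([np.array([1.0])])
        with pytest.raises(ClockError):
            kruskal_wallis([np.array([1.0]), np.array([])])


class TestBhFdr:
    def test_worked_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_constant_vector(self):
        assert np.allclose(bh_fdr([0.05] * 4), [0.05] * 4)

    def test_out_of_range_rejected(self):
        with pytest.raises(ClockError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ClockError):
            bh_fdr([1.5])

    def test_statsmodels_oracle(self, rng):
        for _ in range(100):
            p = rng.uniform(1e-6, 1.0, size=int(rng.integers(1, 40)))
            ref = multipletests(p, method="fdr_bh")[1]
            assert np.abs(bh_fdr(p) - ref).max() < 1e-12

    def test_fdr_at_least_p(self, rng):
        p = rng.uniform(1e-6, 1.0, size=30)
        assert (bh_fdr(p) >= p - 1e-15).all()


@pytest.fixture(scope="module")
def screened(planted_cohort):
    cfg, cohort, truth = planted_cohort
    processed = preprocess_cohort(cohort)
    ann = processed.annotations
    nids = processed.normal_ids()
    labels = np.array([age_label(a) for a in ann.loc[nids, "age"]])
    markers = screen_markers(processed.dnam.loc[nids], labels)
    return processed, nids, labels, markers, truth


class TestScreenMarkers:
    def test_sorted_by_p(self, screened):
        _, _, _, markers, _ = screened
        ps = [m.p_value for m in markers]
        assert ps == sorted(ps)

    def test_thresholds_hold(self, screened):
        _, _, _, markers, _ = screened
        assert all(m.p_value < 0.05 and m.fdr < 0.2 for m in markers)
        assert all(m.fdr >= m.p_value - 1e-15 for m in markers)

    def test_recovers_planted_cpgs(self, screened):
        _, _, _, markers, truth = screened
        recovered = {m.cpg_id for m in markers} & set(truth.aging_cpg_ids)
        assert len(recovered) >= 18

    def test_feature_order_invariance(self, screened, rng):
        processed, nids, labels, markers, _ = screened
        dnam = processed.dnam.loc[nids]
        perm = list(rng.permutation(dnam.columns))
        again = screen_markers(dnam[perm], labels)
        assert [m.cpg_id for m in again] == [m.cpg_id for m in markers]

    def test_single_class_rejected(self, screened):
        processed, nids, _, _, _ = screened
        with pytest.raises(ClockError):
            screen_markers(processed.dnam.loc[nids], np.ones(len(nids), dtype=int))


@pytest.fixture(scope="module")
def model(screened):
    processed, nids, labels, markers, _ = screened
    ann = processed.annotations
    return train_clock(
        processed.dnam.loc[nids],
        labels,
        ann.loc[nids, "tissue"].to_numpy(),
        [m.cpg_id for m in markers],
        k_grid=list(range(1, min(30, len(markers)) + 1)),
    )


class TestTrainClock:

    def test_learning_curve_contract(self, model, screened):
        _, _, _, markers, _ = screened
        grid = list(range(1, min(30, len(markers)) + 1))
        assert [k for k, _ in model.learning_curve] == grid
        errors = dict(model.learning_curve)
        best = min(errors.values())
        assert errors[len(model.marker_ids)] == best
        # smallest k on ties
        assert all(errors[k] > best for k in grid if k < len(model.marker_ids))

    def test_cv_error_low_on_planted_cohort(self, model):
        assert min(e for _, e in model.learning_curve) < 0.15

    def test_marker_precision_against_planted(self, model, screened):
        _, _, _, _, truth = screened
        chosen = set(model.marker_ids)
        precision = len(chosen & set(truth.aging_cpg_ids)) / len(chosen)
        assert precision >= 0.8

    def test_shuffled_labels_near_chance(self, screened):
        processed, nids, _, markers, _ = screened
        ann = processed.annotations
        tissues = ann.loc[nids, "tissue"].to_numpy()
        dnam = processed.dnam.loc[nids]
        ids = [m.cpg_id for m in markers]
        means = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            shuffled = np.empty(len(nids), dtype=int)
            base = np.array([age_label(a) for a in ann.loc[nids, "age"]])
            for t in np.unique(tissues):
                idx = np.flatnonzero(tissues == t)
                shuffled[idx] = base[rng.permutation(idx)]
            if len(set(shuffled)) < 2:
                continue
            model = train_clock(dnam, shuffled, tissues, ids, k_grid=[5, 10])
            means.append(float(np.mean([e for _, e in model.learning_curve])))
        assert 0.4 <= float(np.mean(means)) <= 0.6

    def test_requires_candidates_and_tissues(self, screened):
        processed, nids, labels, markers, _ = screened
        with pytest.raises(ClockError):
            train_clock(processed.dnam.loc[nids], labels, ["T01"] * len(nids), [])


@pytest.fixture
def toy_model():
    return ClockModel(marker_ids=["a", "b"], weights=np.array([1.0, -0.5]), offset=0.25)


class TestScoring:

    def test_identical_samples_identical_scores(self, toy_model):
        dnam = pd.DataFrame([[0.2, 0.4], [0.2, 0.4]], index=["s1", "s2"], columns=["a", "b"])
        scores = score_samples(toy_model, dnam)
        assert scores.scores.loc["s1", "score"] == scores.scores.loc["s2", "score"]

    def test_score_exactly_half_labels_young(self, toy_model):
        dnam = pd.DataFrame([[0.5, 0.5]], index=["s"], columns=["a", "b"])
        scores = score_samples(toy_model, dnam)
        assert scores.scores.loc["s", "score"] == pytest.approx(0.5)
        assert scores.scores.loc["s", "label"] == 0

    def test_acceleration_is_subtraction(self, toy_model):
        dnam = pd.DataFrame([[0.65, 0.0], [0.25, 0.0]], index=["p1_T", "p1_N"], columns=["a", "b"])
        ann = pd.DataFrame(
            {"pair_id": ["p1", "p1"], "tissue": ["X", "X"], "age": [50.0, 50.0],
             "status": ["tumor", "normal"]},
            index=["p1_T", "p1_N"],
        )
        scores = score_samples(toy_model, dnam, ann)
        assert scores.acceleration.loc["p1"] == pytest.approx(0.4)

    def test_missing_marker_named(self, toy_model):
        dnam = pd.DataFrame([[0.5]], index=["s"], columns=["a"])
        with pytest.raises(ClockError, match="'b'"):
            score_samples(toy_model, dnam)

    def test_invariant_to_extra_columns(self, toy_model, rng):
        dnam = pd.DataFrame(rng.uniform(size=(3, 2)), columns=["a", "b"])
        extra = dnam.copy()
        extra["zzz"] = rng.uniform(size=3)
        s1 = score_samples(toy_model, dnam).scores["score"]
        s2 = score_samples(toy_model, extra).scores["score"]
        assert np.allclose(s1.to_numpy(), s2.to_numpy())

    def test_model_json_roundtrip(self, toy_model):
        back = ClockModel.from_json(toy_model.to_json())
        assert back.marker_ids == toy_model.marker_ids
        assert np.allclose(back.weights, toy_model.weights)
        assert back.offset == toy_model.offset


class TestBalancedError:
    def test_perfect(self):
        assert balanced_error([0, 1, 0, 1], [0, 1, 0, 1]) == 0.0

    def test_definition_arithmetic(self):
        # truth: 2 positives, 10 negatives; FNR 0.5, FPR 0.1 -> 0.3
        truth = [1, 1] + [0] * 10
        pred = [1, 0] + [1] + [0] * 9
        assert balanced_error(pred, truth) == pytest.approx(0.3)

    def test_all_one_predictor_on_balanced_truth(self):
        assert balanced_error([1, 1, 1, 1], [1, 1, 0, 0]) == pytest.approx(0.5)

    def test_single_class_truth_rejected(self):
        with pytest.raises(ClockError):
            balanced_error([1, 0], [1, 1])


class TestAccelerationTest:
    def test_identical_vectors(self, rng):
        v = rng.uniform(size=20)
        h, p, med, mean = acceleration_test(v, v)
        assert med == 0.0 and mean == 0.0
        assert p > 0.9

    def test_unit_shift(self, rng):
        v = rng.uniform(size=15)
        _, _, med, mean = acceleration_test(v + 1.0, v)
        assert med == pytest.approx(1.0)
        assert mean == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ClockError):
            acceleration_test([], [1.0])

    def test_planted_cohort_shows_acceleration(self, model, screened):
        processed, nids, _, _, _ = screened
        scores = score_samples(model, processed.dnam, processed.annotations)
        tumor = scores.scores.loc[processed.tumor_ids(), "score"].to_numpy()
        normal = scores.scores.loc[nids, "score"].to_numpy()
        _, p, _, mean_diff = acceleration_test(tumor, normal)
        assert p < 0.01
        assert mean_diff > 0
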