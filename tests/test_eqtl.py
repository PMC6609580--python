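import math

import numpy as np
import pandas as pd
import pytest

from agingaccel.eqtl import (
    EqtlError,
    deg_candidates,
    find_modules,
    loocv_size,
    mrmr_rank,
    mutual_information,
    sign_test,
    ternary_discretize,
)
from conftest import paired_frames


def exact_sign_p(k, n):
    """Independent oracle: direct binomial enumeration."""
    lower = sum(math.comb(n, i) for i in range(0, k + 1)) / 2**n
    upper = sum(math.comb(n, i) for i in range(k, n + 1)) / 2**n
    return min(1.0, 2.0 * min(lower, upper))


class TestSignTest:
    def test_eight_of_eight(self):
        assert sign_test([1.0] * 8) == pytest.approx(2 * (0.5**8))
        assert sign_test([1.0] * 8) == pytest.approx(0.0078125)

    def test_seven_of_eight(self):
        assert sign_test([1.0] * 7 + [-1.0]) == pytest.approx(0.0703125)

    def test_balanced_is_one(self):
        assert sign_test([1.0, 1, 1, 1, -1, -1, -1, -1]) == 1.0

    def test_zeros_dropped(self):
        assert sign_test([0.0, 0.0, 1.0, 1.0, 1.0]) == pytest.approx(exact_sign_p(3, 3))

    def test_all_zero_is_one(self):
        assert sign_test([0.0, 0.0]) == 1.0

    def test_enumeration_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(1, 25))
            k = int(rng.integers(0, n + 1))
            diffs = [1.0] * k + [-1.0] * (n - k)
            assert sign_test(diffs) == pytest.approx(exact_sign_p(k, n), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(EqtlError):
            sign_test([])


class TestDegCandidates:
    def test_identical_matrices_empty(self, rng):
        expr = pd.DataFrame(rng.uniform(1, 10, size=(10, 5)), columns=list("abcde"))
        kept, _ = deg_candidates(expr, expr.copy())
        assert kept == []

    def test_fold_change_gate(self):
        # 1.5-fold with a tiny sign-test p is still excluded
        normal = pd.DataFrame({"g": np.full(20, 4.0)})
        tumor = normal * 1.5
        kept, records = deg_candidates(tumor, normal)
        assert kept == []
        rec = records[0]
        assert rec.p_value < 0.05 and rec.fold_change == pytest.approx(1.5)

    def test_downregulation_counts(self):
        normal = pd.DataFrame({"g": np.full(20, 8.0)})
        tumor = normal * 0.25
        kept, _ = deg_candidates(tumor, normal)
        assert kept == ["g"]

    def test_planted_module_genes_retained(self, planted_cohort):
        _, cohort, truth = planted_cohort
        tumor, normal, _ = paired_frames(cohort)
        kept, _ = deg_candidates(tumor, normal)
        planted = {g for gs in truth.module_map.values() for g in gs}
        assert len(planted & set(kept)) / len(planted) >= 0.9


class TestTernaryDiscretize:
    def test_worked_example(self):
        # mean 5, sd 5.7735 -> thresholds 5 +/- 2.8868
        out = ternary_discretize([0.0, 0.0, 10.0, 10.0])
        assert out.tolist() == [-1, -1, 1, 1]

    def test_constant_all_zero(self):
        assert ternary_discretize([3.0, 3.0, 3.0]).tolist() == [0, 0, 0]

    def test_boundary_in_middle_bin(self):
        # [-sqrt(5), -1, 1, sqrt(5)]: mean 0, sample sd 2, thresholds at +/-1;
        # the values sitting exactly on a threshold fall in the middle bin
        a = np.sqrt(5.0)
        out = ternary_discretize([-a, -1.0, 1.0, a])
        assert out.tolist() == [-1, 0, 0, 1]

    def test_too_short_rejected(self):
        with pytest.raises(EqtlError):
            ternary_discretize([1.0])


def mi_oracle(x, y):
    """Independent histogram-based mutual information (bits)."""
    x, y = np.asarray(x), np.asarray(y)
    total = 0.0
    for xv in set(x.tolist()):
        for yv in set(y.tolist()):
            pxy = np.mean((x == xv) & (y == yv))
            if pxy == 0:
                continue
            px, py = np.mean(x == xv), np.mean(y == yv)
            total += pxy * np.log2(pxy / (px * py))
    return total


class TestMutualInformation:
    def test_one_bit(self):
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(1.0)

    def test_empirical_independence(self):
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == pytest.approx(0.0)

    def test_symmetry(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 30))
            x = rng.integers(-1, 2, size=n)
            y = rng.integers(-1, 2, size=n)
            assert mutual_information(x, y) == pytest.approx(mutual_information(y, x), abs=1e-12)

    def test_histogram_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 40))
            x = rng.integers(0, 4, size=n)
            y = rng.integers(0, 3, size=n)
            assert mutual_information(x, y) == pytest.approx(mi_oracle(x, y), abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(EqtlError):
            mutual_information([0, 1], [0, 1, 1])


class TestMrmrRank:
    def test_perfect_gene_first(self, rng):
        label = np.array([0, 0, 0, 1, 1, 1] * 4)
        frame = pd.DataFrame(
            {
                "noise1": rng.integers(-1, 2, size=24),
                "perfect": np.where(label == 1, 1, -1),
                "noise2": rng.integers(-1, 2, size=24),
            }
        )
        assert mrmr_rank(frame, label)[0] == "perfect"

    def test_redundancy_penalty_demotes_duplicate(self):
        label = np.array([0, 0, 0, 0, 1, 1, 1, 1] * 3)
        top = np.where(label == 1, 1, -1)
        # informative (imperfect) second gene vs an exact duplicate of the top gene
        other = top.copy()
        other[[0, 4]] = 0
        frame = pd.DataFrame({"top": top, "dup": top.copy(), "other": other})
        order = mrmr_rank(frame, label)
        assert order[0] in ("dup", "top")  # tie on relevance, id order
        assert order[1] == "other"  # duplicate penalized by redundancy

    def test_first_element_matches_exhaustive_maximizer(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 20))
            label = rng.integers(0, 2, size=n)
            if len(set(label.tolist())) < 2:
                continue
            frame = pd.DataFrame(
                {f"g{i}": rng.integers(-1, 2, size=n) for i in range(int(rng.integers(2, 8)))}
            )
            order = mrmr_rank(frame, label, k=1)
            rel = {g: mutual_information(frame[g].to_numpy(), label) for g in frame.columns}
            best = max(rel.values())
            brute = sorted(g for g, r in rel.items() if r == pytest.approx(best, abs=1e-12))[0]
            assert order[0] == brute

    def test_permutation_prefix_property(self, rng):
        label = rng.integers(0, 2, size=20)
        label[:2] = [0, 1]
        frame = pd.DataFrame({f"g{i}": rng.integers(-1, 2, size=20) for i in range(6)})
        order = mrmr_rank(frame, label)
        assert len(order) == len(set(order)) == 6
        assert set(order) == set(frame.columns)

    def test_k_zero_empty(self, rng):
        frame = pd.DataFrame({"a": [0, 1, 0, 1]})
        assert mrmr_rank(frame, np.array([0, 1, 0, 1]), k=0) == []


class TestLoocvSize:
    def test_separable_single_gene(self, rng):
        label = np.array([0] * 10 + [1] * 10)
        expr = pd.DataFrame(
            {
                "sep": np.where(label == 1, 5.0, -5.0) + rng.normal(0, 0.1, 20),
                "noise": rng.normal(size=20),
            }
        )
        curve, size = loocv_size(expr, label)
        assert curve[0] == 0.0
        assert size == 1

    def test_curve_length_contract(self, rng):
        label = np.array([0, 1] * 8)
        expr = pd.DataFrame(rng.normal(size=(16, 5)))
        curve, _ = loocv_size(expr, label, max_size=4)
        assert len(curve) == 4

    def test_random_labels_stay_errorful(self):
        mins = []
        for seed in range(6):
            rng = np.random.default_rng(seed)
            label = np.array([0] * 10 + [1] * 10)
            rng.shuffle(label)
            expr = pd.DataFrame(rng.normal(size=(20, 6)))
            curve, _ = loocv_size(expr, label, max_size=4)
            mins.append(curve.min())
        assert float(np.median(mins)) >= 0.2

    def test_singleton_class_rejected(self, rng):
        label = np.array([0] * 5 + [1])
        expr = pd.DataFrame(rng.normal(size=(6, 3)))
        with pytest.raises(EqtlError):
            loocv_size(expr, label)


class TestFindModules:
    def test_determinism(self, planted_cohort):
        _, cohort, truth = planted_cohort
        tumor, normal, status = paired_frames(cohort)
        driver = truth.driver_mutation_ids[0]
        r1 = find_modules(tumor, normal, status, [driver])
        r2 = find_modules(tumor, normal, status, [driver])
        assert [m.module_gene_ids for m in r1] == [m.module_gene_ids for m in r2]

    def test_module_is_prefix_of_mrmr_order(self, planted_cohort):
        _, cohort, truth = planted_cohort
        tumor, normal, status = paired_frames(cohort)
        results = find_modules(tumor, normal, status, truth.driver_mutation_ids)
        for res in results:
            assert res.module_gene_ids == res.mrmr_order[: res.module_size]
            assert res.loocv_error_curve[res.module_size - 1] == res.loocv_error_curve.min()

    def test_too_few_mutated_skipped_with_warning(self, planted_cohort):
        _, cohort, truth = planted_cohort
        tumor, normal, status = paired_frames(cohort)
        rare = status.columns[status.sum() < 3]
        if rare.empty:
            pytest.skip("no rare mutation in fixture")
        with pytest.warns(UserWarning, match="skipped"):
            out = find_modules(tumor, normal, status, [rare[0]])
        assert out == []

    def test_unknown_mutation_rejected(self, planted_cohort):
        _, cohort, _ = planted_cohort
        tumor, normal, status = paired_frames(cohort)
        with pytest.raises(EqtlError, match="nope"):
            find_modules(tumor, normal, status, ["nope"])
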