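"""Ratio kernels against brute-force oracles, and the combination lattice."""

import math
import random

import numpy as np
import pytest

import plexquant as pq
from plexquant.quant import (
    apply_peptide_kernel,
    apply_protein_kernel,
    enumerate_combinations,
    fixed_design_combinations,
    median_ratio,
    peptide_weight,
    protein_equivalence_key,
    psm_ratio,
    regression_slope_ratio,
    sum_intensity_ratio,
    trimmed_mean_ratio,
    weighted_mean_ratio,
)


# ---------------------------------------------------------------------------
# Brute-force oracles: explicit loops and sorts, no numpy shortcuts
# ---------------------------------------------------------------------------

def oracle_regression(points):
    sxy = sxx = 0.0
    for x, y in points:
        sxy += x * y
        sxx += x * x
    return sxy / sxx if sxx > 0 else None


def oracle_sum(points):
    sden = sum(x for x, _ in points)
    snum = sum(y for _, y in points)
    return snum / sden if sden > 0 and snum > 0 else None


def oracle_median(values):
    if not values:
        return None
    s = sorted(values)
    n = len(s)
    return s[n // 2] if n % 2 else (s[n // 2 - 1] + s[n // 2]) / 2.0


def oracle_weighted_mean(values, weights):
    total = sum(weights)
    if total <= 0:
        return sum(values) / len(values)
    acc = 0.0
    for v, w in zip(values, weights):
        acc += v * w
    return acc / total


def oracle_trimmed_mean(values):
    n = len(values)
    k = int(math.floor(0.2 * n))
    s = sorted(values)[k : n - k]
    return sum(s) / len(s)


class TestKernelExamples:
    def test_psm_ratio_and_weight(self):
        profile = pq.ReporterProfile(
            "p", ("A", "B"), np.array([200.0, 100.0]), np.array([200.0, 100.0])
        )
        rv = psm_ratio(profile, pq.ChannelPair("A", "B"))
        assert rv.value == pytest.approx(2.0)
        assert rv.weight == pytest.approx(300.0)

    def test_psm_ratio_equal_is_one(self):
        profile = pq.ReporterProfile(
            "p", ("A", "B"), np.array([5.0, 5.0]), np.array([5.0, 5.0])
        )
        assert psm_ratio(profile, pq.ChannelPair("A", "B")).value == pytest.approx(1.0)

    def test_psm_ratio_zero_denominator_undefined(self):
        profile = pq.ReporterProfile(
            "p", ("A", "B"), np.array([200.0, 0.0]), np.array([200.0, 0.0])
        )
        assert psm_ratio(profile, pq.ChannelPair("A", "B")) is None

    def test_regression_examples(self):
        assert regression_slope_ratio([(1, 2), (2, 4), (3, 6)]) == pytest.approx(2.0)
        assert regression_slope_ratio([(100, 150)]) == pytest.approx(1.5)
        # sum(x*y) = 2 + 8 + 21 = 31, sum(x^2) = 14
        assert regression_slope_ratio([(1, 2), (2, 4), (3, 7)]) == pytest.approx(31 / 14)

    def test_sum_intensity_examples(self):
        assert sum_intensity_ratio([(50, 100), (150, 300)]) == pytest.approx(2.0)
        assert sum_intensity_ratio([(100, 150)]) == pytest.approx(1.5)
        assert sum_intensity_ratio([(100, 100), (100, 100)]) == pytest.approx(1.0)

    def test_median_examples(self):
        assert median_ratio([1, 2, 3]) == pytest.approx(2.0)
        assert median_ratio([1, 2, 3, 4]) == pytest.approx(2.5)
        assert median_ratio([5]) == pytest.approx(5.0)

    def test_weighted_mean_examples(self):
        assert weighted_mean_ratio([2.0, 1.0], [300, 100]) == pytest.approx(1.75)
        assert weighted_mean_ratio([2.0, 4.0], [7, 7]) == pytest.approx(3.0)
        assert weighted_mean_ratio([3.3], [10]) == pytest.approx(3.3)

    def test_weighted_mean_zero_weights_falls_back(self, caplog):
        with caplog.at_level("WARNING"):
            assert weighted_mean_ratio([2.0, 4.0], [0, 0]) == pytest.approx(3.0)

    def test_trimmed_mean_examples(self):
        assert trimmed_mean_ratio(list(range(1, 11))) == pytest.approx(5.5)
        assert trimmed_mean_ratio([1, 2, 3, 4]) == pytest.approx(2.5)  # k = 0
        assert trimmed_mean_ratio([7.0] * 9) == pytest.approx(7.0)

    def test_peptide_weight_examples(self):
        assert peptide_weight([100, 300, 500]) == pytest.approx(300)
        assert peptide_weight([100]) == pytest.approx(100)
        assert peptide_weight([100, 200]) == pytest.approx(150)


class TestProteinKernelDispatch:
    def test_singleton_all_kernels_coincide(self):
        groups = {"PEPK": [(100.0, 200.0)]}
        for protein_kernel in pq.model.PROTEIN_KERNELS:
            for peptide_kernel in pq.model.PEPTIDE_KERNELS:
                value, support = apply_protein_kernel(protein_kernel, peptide_kernel, groups)
                assert value == pytest.approx(2.0)
                assert support == 1

    def test_weighted_pep_ratio_example(self):
        # peptide 1: ratio 2.0 with PSM weights [100, 300, 500] -> weight 300
        # peptide 2: ratio 1.0 with weight 100 -> (2*300 + 1*100)/400 = 1.75
        groups = {
            "AK": [(100 / 3, 200 / 3), (100.0, 200.0), (500 / 3, 1000 / 3)],
            "BK": [(50.0, 50.0)],
        }
        value, support = apply_protein_kernel("WeightedPepRatio", "MedianPsmRatio", groups)
        assert value == pytest.approx(1.75)
        assert support == 2

    def test_outlier_handling_median_vs_weighted(self):
        # PSM ratios {1,2,3,4,100}; the outlier carries 10x the weight
        dens = [10.0, 10.0, 10.0, 10.0, 100.0]
        nums = [r * d for r, d in zip([1, 2, 3, 4, 100], dens)]
        groups = {"PEPK": list(zip(dens, nums))}
        med, _ = apply_protein_kernel("MedianPsmRatio", "LinearRegression", groups)
        assert med == pytest.approx(3.0)
        wgt, _ = apply_protein_kernel("WeightedPsmRatio", "LinearRegression", groups)
        assert wgt > 3.0


@pytest.fixture(scope="module")
def instances():
    rng = random.Random(20240917)
    out = []
    for _ in range(1000):
        n = rng.randint(1, 12)
        pairs = [(rng.uniform(1.0, 1e4), rng.uniform(1.0, 1e4)) for _ in range(n)]
        out.append(pairs)
    return out


class TestOracleEquivalence:
    """Every kernel matches the explicit brute-force arithmetic on random
    small instances, for both PSM-weight definitions."""

    def test_regression_matches_oracle(self, instances):
        for pairs in instances:
            assert regression_slope_ratio(pairs) == pytest.approx(
                oracle_regression(pairs), rel=1e-12
            )

    def test_sum_matches_oracle(self, instances):
        for pairs in instances:
            assert sum_intensity_ratio(pairs) == pytest.approx(
                oracle_sum(pairs), rel=1e-12
            )

    def test_median_matches_oracle(self, instances):
        for pairs in instances:
            ratios = [n / d for d, n in pairs]
            assert median_ratio(ratios) == pytest.approx(
                oracle_median(ratios), rel=1e-12
            )

    @pytest.mark.parametrize("weight_mode", ["pair", "all"])
    def test_weighted_mean_matches_oracle(self, instances, weight_mode):
        rng = random.Random(99)
        for pairs in instances:
            ratios = [n / d for d, n in pairs]
            if weight_mode == "pair":
                weights = [n + d for d, n in pairs]
            else:
                # all-channel sums: the pair channels plus extra channels
                weights = [n + d + rng.uniform(0, 1e4) for d, n in pairs]
            assert weighted_mean_ratio(ratios, weights) == pytest.approx(
                oracle_weighted_mean(ratios, weights), rel=1e-12
            )

    def test_trimmed_mean_matches_oracle(self, instances):
        for pairs in instances:
            ratios = [n / d for d, n in pairs]
            assert trimmed_mean_ratio(ratios) == pytest.approx(
                oracle_trimmed_mean(ratios), rel=1e-12
            )

    def test_peptide_weight_matches_oracle(self, instances):
        for pairs in instances:
            weights = [n + d for d, n in pairs]
            assert peptide_weight(weights) == pytest.approx(
                oracle_median(weights), rel=1e-12
            )


class TestKernelProperties:
    def _random_pairs(self, rng, n):
        return [(rng.uniform(1, 1e4), rng.uniform(1, 1e4)) for _ in range(n)]

    def test_permutation_invariance(self):
        rng = random.Random(1)
        for _ in range(50):
            pairs = self._random_pairs(rng, rng.randint(2, 10))
            shuffled = pairs[:]
            rng.shuffle(shuffled)
            for kernel in pq.model.PEPTIDE_KERNELS:
                a = apply_peptide_kernel(kernel, pairs)
                b = apply_peptide_kernel(kernel, shuffled)
                assert a[0] == pytest.approx(b[0], rel=1e-12)

    def test_reciprocal_symmetry(self):
        rng = random.Random(2)
        for _ in range(50):
            pairs = self._random_pairs(rng, rng.randint(1, 8))
            flipped = [(n, d) for d, n in pairs]
            # SumPsmIntensity: ratio(A/B) * ratio(B/A) = 1 exactly
            assert sum_intensity_ratio(pairs) * sum_intensity_ratio(
                flipped
            ) == pytest.approx(1.0, rel=1e-12)
            # median on exactly inverted PSM ratios
            ratios = [n / d for d, n in pairs]
            inverted = [1 / r for r in ratios]
            if len(ratios) % 2 == 1:
                assert median_ratio(ratios) * median_ratio(inverted) == pytest.approx(
                    1.0, rel=1e-12
                )

    def test_robust_kernels_ignore_largest_value(self):
        rng = random.Random(3)
        for _ in range(25):
            n = rng.randint(5, 15)
            ratios = sorted(rng.uniform(0.5, 2.0) for _ in range(n))
            for replacement in (ratios[-1] * 2, ratios[-1] * 1e6):
                bumped = ratios[:-1] + [replacement]
                assert median_ratio(bumped) == pytest.approx(
                    median_ratio(ratios), rel=1e-12
                )
                if math.floor(0.2 * n) >= 1:
                    assert trimmed_mean_ratio(bumped) == pytest.approx(
                        trimmed_mean_ratio(ratios), rel=1e-12
                    )

    def test_all_equal_ratios_give_common_value(self):
        pairs = [(d, 3.0 * d) for d in (10.0, 20.0, 400.0, 5.0)]
        for kernel in pq.model.PEPTIDE_KERNELS:
            value, _, _ = apply_peptide_kernel(kernel, pairs)
            assert value == pytest.approx(3.0, rel=1e-12)
        for kernel in pq.model.PROTEIN_KERNELS:
            value, _ = apply_protein_kernel(kernel, "MedianPsmRatio", {"PEPK": pairs})
            assert value == pytest.approx(3.0, rel=1e-12)


class TestCombinationLattice:
    def test_full_lattice_is_336(self):
        assert len(enumerate_combinations()) == 336

    def test_no_normalization_is_48(self):
        assert len(enumerate_combinations(["none"])) == 48

    def test_fixed_design_is_12(self):
        combos = fixed_design_combinations()
        assert len(combos) == 12
        assert all(c.normalization == "none" for c in combos)
        by_protein = {c.protein_kernel for c in combos}
        assert len(by_protein) == 6

    def test_enumeration_is_deterministic(self):
        a = enumerate_combinations()
        b = enumerate_combinations()
        assert [c.combo_id for c in a] == [c.combo_id for c in b]

    def test_protein_output_collapse_to_168(self, small_prepared):
        """Within each normalization x RCC cell, PSM-level protein kernels
        produce identical protein tables for all four peptide kernels:
        (4 + 2*4) = 12 distinct outputs per cell, 168 over the 14 cells."""
        pairs = [pq.ChannelPair("127", "126")]
        combos = enumerate_combinations()
        outputs = {}
        for combo in combos:
            result = pq.run_pipeline(small_prepared, combo, pairs)
            key = tuple(
                (acc, round(v["127/126"], 12))
                for acc, v in sorted(result.protein_values.items())
                if "127/126" in v
            )
            outputs[combo] = key
        # group per (normalization, rcc) cell
        distinct_total = 0
        for norm in pq.model.NORMALIZATION_STRATEGIES:
            for rcc in (False, True):
                cell = [
                    outputs[c] for c in combos
                    if c.normalization == norm and c.rcc is rcc
                ]
                assert len(cell) == 24
                distinct_total += len(set(cell))
        assert distinct_total == 168
        # and the analytic equivalence key predicts exactly that collapse
        by_key = {}
        for combo in combos:
            by_key.setdefault(protein_equivalence_key(combo), set()).add(outputs[combo])
        assert all(len(v) == 1 for v in by_key.values())
        assert len(by_key) == 168
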