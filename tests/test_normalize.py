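"""Reporter-level and ratio-level normalization post-conditions."""

import numpy as np
import pytest

import plexquant as pq
from plexquant.normalize import (
    channel_scaling_factors,
    normalize_ratio_set,
    normalize_reporter_medians,
)


def _channel_medians(X):
    return np.array(
        [np.median(col[col > 0]) for col in X.T]
    )


class TestReporterNormalization:
    def test_hand_example(self):
        X = np.array([[100.0, 50.0], [200.0, 100.0], [300.0, 150.0]])
        out = normalize_reporter_medians(X, ("A", "B"))
        # medians 200 and 100, target 150: A x0.75, B x1.5
        assert np.allclose(out[:, 0], [75.0, 150.0, 225.0])
        assert np.allclose(out[:, 1], [75.0, 150.0, 225.0])
        assert np.allclose(_channel_medians(out), 150.0)

    def test_equal_medians_unchanged(self):
        X = np.array([[100.0, 100.0], [200.0, 200.0], [300.0, 300.0]])
        assert np.allclose(normalize_reporter_medians(X, ("A", "B")), X)

    def test_single_profile_degenerate_medians(self):
        out = normalize_reporter_medians(np.array([[200.0, 100.0]]), ("A", "B"))
        assert np.allclose(out, [[150.0, 150.0]])

    def test_postcondition_all_medians_equal(self, small_prepared):
        out = normalize_reporter_medians(small_prepared.corrected, small_prepared.channels)
        medians = _channel_medians(out)
        assert np.all(np.abs(medians - medians[0]) < 1e-9 * medians[0])

    def test_idempotent(self, small_prepared):
        once = normalize_reporter_medians(small_prepared.corrected, small_prepared.channels)
        twice = normalize_reporter_medians(once, small_prepared.channels)
        assert np.allclose(once, twice, rtol=1e-12)

    def test_all_zero_channel_fatal_names_channel(self):
        X = np.array([[100.0, 0.0], [50.0, 0.0]])
        with pytest.raises(ValueError, match="B"):
            normalize_reporter_medians(X, ("A", "B"))

    def test_zeros_excluded_from_medians(self):
        X = np.array([[100.0, 100.0], [0.0, 100.0], [100.0, 100.0]])
        factors = channel_scaling_factors(X, ("A", "B"))
        assert np.allclose(factors, [1.0, 1.0])

    def test_target_choice_is_ratio_neutral(self, small_prepared):
        """Any common target rescales all channels by one global factor, so
        every downstream ratio is unchanged."""
        X = small_prepared.corrected
        channels = small_prepared.channels
        default = normalize_reporter_medians(X, channels)
        custom = normalize_reporter_medians(X, channels, target=1234.5)
        mask = (X[:, 0] > 0) & (X[:, 1] > 0)
        assert np.allclose(
            default[mask, 0] / default[mask, 1],
            custom[mask, 0] / custom[mask, 1],
            rtol=1e-12,
        )

    def test_commutes_with_channel_relabeling(self):
        rng = np.random.default_rng(5)
        X = rng.uniform(10, 1000, size=(20, 4))
        perm = [2, 0, 3, 1]
        a = normalize_reporter_medians(X, ("A", "B", "C", "D"))[:, perm]
        b = normalize_reporter_medians(X[:, perm], tuple("ABCD"[i] for i in perm))
        assert np.allclose(a, b, rtol=1e-12)


class TestRatioNormalization:
    def test_hand_example(self):
        assert np.allclose(normalize_ratio_set([1.0, 2.0, 3.0]), [0.5, 1.0, 1.5])

    def test_median_one_unchanged(self):
        values = [0.5, 1.0, 2.0]
        assert np.allclose(normalize_ratio_set(values), values)

    def test_singleton(self):
        assert np.allclose(normalize_ratio_set([4.0]), [1.0])

    def test_postcondition_median_is_one(self):
        rng = np.random.default_rng(11)
        values = rng.lognormal(0.3, 0.7, size=101)
        out = normalize_ratio_set(values)
        assert abs(np.median(out) - 1.0) < 1e-12

    def test_idempotent(self):
        rng = np.random.default_rng(12)
        values = rng.lognormal(0.0, 0.5, size=50)
        once = normalize_ratio_set(values)
        assert np.allclose(normalize_ratio_set(once), once, rtol=1e-12)

    def test_preserves_order_and_ratios_of_ratios(self):
        rng = np.random.default_rng(13)
        values = rng.lognormal(0.0, 0.5, size=30)
        out = normalize_ratio_set(values)
        assert np.array_equal(np.argsort(values), np.argsort(out))
        assert np.allclose(
            np.outer(values, 1 / values), np.outer(out, 1 / out), rtol=1e-12
        )

    def test_empty_is_noop_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            out = normalize_ratio_set([])
        assert out.size == 0
        assert any("empty" in r.message for r in caplog.records)


class TestStrategyComposition:
    def test_none_is_identity(self, small_prepared):
        pairs = [pq.ChannelPair("127", "126")]
        base = pq.AlgorithmCombination("MedianPsmRatio", "MedianPsmRatio", "none", False)
        result = pq.run_pipeline(small_prepared, base, pairs)
        # recompute by hand from the impurity-corrected stage
        X = small_prepared.corrected
        idx = {c: j for j, c in enumerate(small_prepared.channels)}
        acc = sorted(result.protein_values)[0]
        rows = [
            i for i, accs in enumerate(small_prepared.proteins_of) if acc in accs
        ]
        expected = np.median(
            [X[i, idx["127"]] / X[i, idx["126"]] for i in rows if X[i, idx["126"]] > 0]
        )
        assert result.protein_values[acc]["127/126"] == pytest.approx(expected)

    def test_seven_strategies_compose_as_named(self, small_prepared):
        """'protein' in the strategy forces protein-ratio median 1; 'reporter'
        changes the intensity stage; 'peptide' rescales peptide ratios."""
        pairs = [pq.ChannelPair("127", "126")]
        for strategy in pq.model.NORMALIZATION_STRATEGIES:
            combo = pq.AlgorithmCombination(
                "MedianPsmRatio", "MedianPepRatio", strategy, False
            )
            result = pq.run_pipeline(small_prepared, combo, pairs)
            values = [v["127/126"] for v in result.protein_values.values()]
            if "protein" in strategy.split("+"):
                assert np.median(values) == pytest.approx(1.0, abs=1e-12)
            peptide_values = [v["127/126"] for v in result.peptide_values.values()]
            if "peptide" in strategy.split("+"):
                assert np.median(peptide_values) == pytest.approx(1.0, abs=1e-12)
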