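"""Function metrics: rate distributions, overlap, decoding, effect sizes."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from agecircuit.metrics import (
    RateDistribution,
    baseline_rate_distribution,
    cohens_d,
    compare_conditions,
    decoding_accuracy,
    detection_error,
    recurrent_rate_distribution,
    spike_count_vectors,
)
from agecircuit.microcircuit import SpikeData


def make_spikes(times, ids, n_pyr=800, n_other=200, duration=15000.0, stim=()):
    """SpikeData with the first ``n_pyr`` neurons labeled Pyr."""
    pop = np.concatenate(
        [np.zeros(n_pyr, dtype=np.int32), np.full(n_other, 2, dtype=np.int32)]
    )
    return SpikeData(
        times_ms=np.asarray(times, dtype=float),
        neuron_ids=np.asarray(ids, dtype=int),
        pop_idx=pop,
        duration_ms=duration,
        stim_times_ms=np.asarray(stim, dtype=float),
    )


class TestBaselineRateDistribution:
    def test_no_spikes_window_count_forced_by_geometry(self):
        spikes = make_spikes([], [], stim=[4000.0])
        dist = baseline_rate_distribution(spikes)
        assert dist.rates.size == (3000 - 40) // 1 + 1
        assert np.all(dist.rates == 0.0)

    def test_hand_counted_regular_train(self):
        # one Pyr neuron firing every 10 ms through the baseline window:
        # every 40 ms window holds 4 spikes -> 4 / (800 x 0.04 s) Hz
        times = np.arange(1000.0, 4000.0, 10.0)
        spikes = make_spikes(times, np.zeros(times.size), stim=[4000.0])
        dist = baseline_rate_distribution(spikes)
        expected = 4 / (800 * 0.04)
        # windows fully inside the train see exactly 4 spikes
        assert np.median(dist.rates) == pytest.approx(expected)

    def test_deterministic(self):
        rng = np.random.default_rng(0)
        times = rng.uniform(1000, 4000, 500)
        ids = rng.integers(0, 800, 500)
        spikes = make_spikes(times, ids, stim=[4000.0])
        a = baseline_rate_distribution(spikes).rates
        b = baseline_rate_distribution(spikes).rates
        assert np.array_equal(a, b)

    def test_insufficient_span_rejected(self):
        spikes = make_spikes([], [], stim=[1000.0])
        with pytest.raises(ValueError):
            baseline_rate_distribution(spikes)


class TestRecurrentRateDistribution:
    def test_no_spikes_gives_zero_per_trial(self):
        stim = 4000.0 + 500.0 * np.arange(20)
        dist = recurrent_rate_distribution(make_spikes([], [], stim=stim))
        assert dist.rates.size == 20
        assert np.all(dist.rates == 0.0)

    def test_hand_counted_rate(self):
        # exactly 8 Pyr spikes in each 10-50 ms window -> 8/(800 x 0.04) Hz
        stim = 4000.0 + 500.0 * np.arange(5)
        times, ids = [], []
        for t in stim:
            times.extend(t + 20.0 + np.arange(8))
            ids.extend(range(8))
        dist = recurrent_rate_distribution(make_spikes(times, ids, stim=stim))
        assert np.allclose(dist.rates, 8 / (800 * 0.04))
        assert dist.rates.std() == 0.0

    def test_missing_markers_rejected(self):
        with pytest.raises(ValueError):
            recurrent_rate_distribution(make_spikes([], []))


class TestDetectionError:
    def test_identical_distributions_full_overlap(self):
        x = RateDistribution(np.tile([0.0, 1.0, 2.0, 3.0], 25), 40.0)
        res = detection_error(x, RateDistribution(x.rates.copy(), 40.0), n_boot=50)
        assert res.overlap_pct == pytest.approx(100.0)

    def test_disjoint_supports_zero_overlap(self):
        x = RateDistribution(np.random.default_rng(0).uniform(0, 1, 200), 40.0)
        y = RateDistribution(np.random.default_rng(1).uniform(5, 6, 200), 40.0)
        assert detection_error(x, y, n_boot=50).overlap_pct == pytest.approx(0.0)

    def test_hand_computed_partial_overlap(self):
        # histograms [0.8, 0.2, 0] vs [0, 0.2, 0.8] share only the middle
        # bin: overlap = 20%
        x = RateDistribution(np.array([0.0] * 8 + [1.0] * 2), 40.0)
        y = RateDistribution(np.array([1.0] * 2 + [2.0] * 8), 40.0)
        assert detection_error(x, y, n_boot=50).overlap_pct == pytest.approx(20.0)

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(5)
        x = RateDistribution(rng.normal(2, 1, 300).clip(0), 40.0)
        y = RateDistribution(rng.normal(3, 1, 300).clip(0), 40.0)
        assert detection_error(x, y, n_boot=10).overlap_pct == pytest.approx(
            detection_error(y, x, n_boot=10).overlap_pct
        )

    def test_bootstrap_interval_brackets_point(self):
        rng = np.random.default_rng(6)
        x = RateDistribution(rng.normal(2, 1, 300).clip(0), 40.0)
        y = RateDistribution(rng.normal(2.5, 1, 300).clip(0), 40.0)
        res = detection_error(x, y, n_boot=200, seed=1)
        assert res.ci_low <= res.boot_mean <= res.ci_high

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            detection_error(
                RateDistribution(np.array([]), 40.0),
                RateDistribution(np.array([1.0]), 40.0),
            )


class TestDecodingAccuracy:
    def test_separable_counts_reach_full_accuracy(self):
        rng = np.random.default_rng(0)
        X = np.vstack([np.zeros((20, 50)), rng.poisson(3.0, (20, 50)) + 1.0])
        y = np.repeat([0, 1], 20)
        accs = decoding_accuracy(X=X, y=y, n_perm=20, seed=1)
        assert accs.mean() == pytest.approx(100.0)

    def test_identical_conditions_decode_at_chance(self):
        # grand mean over label permutations concentrates at chance level
        rng = np.random.default_rng(1)
        y = np.repeat([0, 1], 40)
        means = []
        for _ in range(8):
            X = rng.poisson(1.0, (80, 60)).astype(float)
            yp = rng.permutation(y)
            means.append(decoding_accuracy(X=X, y=yp, n_perm=25, seed=2).mean())
        assert np.mean(means) == pytest.approx(50.0, abs=5.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(2)
        X = rng.poisson(1.0, (40, 30)).astype(float)
        y = np.repeat([0, 1], 20)
        a = decoding_accuracy(X=X, y=y, n_perm=10, seed=3)
        b = decoding_accuracy(X=X, y=y, n_perm=10, seed=3)
        assert np.array_equal(a, b)

    def test_ann_classifier_runs(self):
        rng = np.random.default_rng(3)
        X = np.vstack([np.zeros((10, 20)), rng.poisson(4.0, (10, 20)) + 1.0])
        y = np.repeat([0, 1], 10)
        accs = decoding_accuracy(X=X, y=y, classifier="ann", n_perm=3, seed=1)
        assert accs.mean() > 80.0

    def test_unknown_classifier_rejected(self):
        with pytest.raises(ValueError):
            decoding_accuracy(X=np.zeros((4, 2)), y=np.array([0, 0, 1, 1]), classifier="forest")

    def test_spike_count_vectors_shapes(self):
        stim = 4000.0 + 500.0 * np.arange(4)
        times, ids = [], []
        for t in stim:
            times.extend([t + 30.0, t + 40.0])
            ids.extend([0, 1])
        spikes = make_spikes(times, ids, n_pyr=10, n_other=2, stim=stim)
        X, y = spike_count_vectors(spikes)
        assert X.shape == (8, 10)
        assert y.sum() == 4
        # response windows hold the spikes, baseline windows are empty
        assert X[y == 1].sum() == 8
        assert X[y == 0].sum() == 0


class TestCohensD:
    def test_equal_samples_zero(self):
        x = np.array([1.0, 2.0, 3.0])
        assert cohens_d(x, x) == 0.0

    def test_textbook_value(self):
        assert cohens_d([1, 2, 3], [2, 3, 4]) == pytest.approx(1.0)

    def test_sign_convention_comparison_minus_reference(self):
        assert cohens_d([2, 3, 4], [1, 2, 3]) == pytest.approx(-1.0)

    def test_matches_pooled_formula_on_random_pairs(self):
        rng = np.random.default_rng(9)
        for _ in range(200):
            nx, ny = rng.integers(2, 40, 2)
            x = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nx)
            y = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), ny)
            pooled = np.sqrt(
                ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1))
                / (nx + ny - 2)
            )
            assert cohens_d(x, y) == pytest.approx(
                (np.mean(y) - np.mean(x)) / pooled, abs=1e-12
            )

    @given(st.floats(-5, 5), st.floats(0.1, 10), st.integers(0, 2**31 - 1))
    def test_invariant_to_common_affine_transform(self, shift, scale, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(0, 1, 20)
        y = rng.normal(1, 1, 25)
        d0 = cohens_d(x, y)
        d1 = cohens_d(scale * x + shift, scale * y + shift)
        assert d1 == pytest.approx(d0, rel=1e-9, abs=1e-9)

    def test_degenerate_cases(self):
        with pytest.raises(ValueError):
            cohens_d([1.0], [1.0, 2.0])
        with pytest.raises(ZeroDivisionError):
            cohens_d([1.0, 1.0], [2.0, 2.0])


class TestCompareConditions:
    def test_identical_groups(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        out = compare_conditions(x, x.copy())
        assert out["t"] == pytest.approx(0.0)
        assert out["d"] == 0.0
        assert not out["significant"]

    def test_separated_groups_significant(self):
        rng = np.random.default_rng(1)
        x = np.zeros(4) + rng.normal(0, 1e-3, 4)
        y = np.ones(4) + rng.normal(0, 1e-3, 4)
        out = compare_conditions(x, y)
        assert out["p"] < 0.05
        assert abs(out["d"]) > 0.5
        assert out["significant"]

    def test_null_type_one_error_rate(self):
        """Type-I rate of the equal-variance t test at α=0.05 under the
        null: 5% ± 2% over repeated standard-normal draws (n=20 vs 20)."""
        rng = np.random.default_rng(123)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            out = compare_conditions(rng.normal(size=20), rng.normal(size=20))
            hits += out["p"] < 0.05
        assert hits / n_rep == pytest.approx(0.05, abs=0.02)
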