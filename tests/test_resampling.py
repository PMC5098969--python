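import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from phenonet import (
    bootstrap_networks,
    cliff_delta,
    cliff_delta_ci,
    compare_groups,
    node_wise_stability,
    subject_wise_stability,
)
from phenonet.resampling import BootstrapDistributions
from _oracles import cliff_naive
from conftest import make_survey


class TestCliffDelta:
    @pytest.mark.parametrize(
        "x, y, expected",
        [
            ([1, 2, 3], [1, 2, 3], 0.0),
            ([4, 5], [1, 2], 1.0),
            ([1, 2], [4, 5], -1.0),
            ([1, 2, 3], [2, 2, 2], 0.0),  # 3 greater, 3 less, 3 tied
        ],
    )
    def test_examples(self, x, y, expected):
        assert cliff_delta(x, y) == pytest.approx(expected)

    def test_empty_sample_raises(self):
        with pytest.raises(ValueError):
            cliff_delta([], [1.0])

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=rng.integers(2, 15)).astype(float)
        y = rng.integers(0, 6, size=rng.integers(2, 15)).astype(float)
        assert cliff_delta(x, y) == pytest.approx(cliff_naive(x, y))

    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=1, max_size=20),
    )
    @settings(derandomize=True, max_examples=60)
    def test_bounds_and_antisymmetry(self, x, y):
        d = cliff_delta(x, y)
        assert -1.0 <= d <= 1.0
        assert cliff_delta(y, x) == pytest.approx(-d)

    def test_ci_contains_point_and_stays_in_range(self, rng):
        x = rng.normal(0.5, 1.0, size=60)
        y = rng.normal(0.0, 1.0, size=40)
        d, lo, hi = cliff_delta_ci(x, y)
        assert -1.0 <= lo <= d <= hi <= 1.0
        assert d == pytest.approx(cliff_naive(x, y))


def _fake_boot(values, labels=("a", "b", "c")):
    values = np.asarray(values, float)
    return BootstrapDistributions(
        labels=list(labels), betweenness=values, strength=values,
        edge_counts=np.ones(values.shape[0]), B=values.shape[0],
        failures=0, seed=0, gamma=0.5,
    )


class TestCompareGroups:
    def test_identical_distributions_give_zero(self, rng):
        v = rng.normal(size=(30, 3))
        table = compare_groups(_fake_boot(v), _fake_boot(v))
        assert table["delta"].abs().max() <= 1e-12
        assert table["negligible"].all()

    def test_swap_negates_delta(self, rng):
        va, vb = rng.normal(size=(25, 3)), rng.normal(1.0, 1.0, (20, 3))
        t1 = compare_groups(_fake_boot(va), _fake_boot(vb))
        t2 = compare_groups(_fake_boot(vb), _fake_boot(va))
        assert t1["delta"].to_numpy() == pytest.approx(
            -t2["delta"].to_numpy())

    def test_label_mismatch_rejected(self, rng):
        v = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="label"):
            compare_groups(_fake_boot(v), _fake_boot(v, labels=("x", "y",
                                                                "z")))

    def test_known_asymmetry_detected(self, rng):
        """A node with systematically doubled centrality in one group shows
        a positive, non-negligible dominance effect."""
        va = rng.normal(2.0, 0.3, size=(200, 3))
        vb = va.copy()
        vb[:, 1] = rng.normal(1.0, 0.3, size=200)
        table = compare_groups(_fake_boot(va), _fake_boot(vb))
        assert table.loc[1, "delta"] > 0.25
        assert not table.loc[1, "negligible"]
        assert table.loc[0, "negligible"]


class TestBootstrapNetworks:
    def test_determinism_and_shapes(self, small_survey):
        a = bootstrap_networks(small_survey, B=4, gamma=0.5, seed=3,
                               n_lambda=30)
        b = bootstrap_networks(small_survey, B=4, gamma=0.5, seed=3,
                               n_lambda=30)
        assert np.array_equal(a.betweenness, b.betweenness)
        assert np.array_equal(a.edge_counts, b.edge_counts)
        assert a.n_success + a.failures == 4

    def test_single_replicate_shape(self, small_survey):
        boot = bootstrap_networks(small_survey, B=1, gamma=0.5, seed=0,
                                  n_lambda=30)
        assert boot.betweenness.shape == (1, small_survey.n_descriptors)
        assert boot.strength.shape == (1, small_survey.n_descriptors)

    def test_degenerate_constant_columns_abort(self):
        resp = np.full((30, 4), 3)
        resp[0, :] = 4  # almost constant: every resample is degenerate
        data = make_survey(resp)
        with pytest.raises(RuntimeError, match="failed"):
            bootstrap_networks(data, B=10, gamma=0.5, seed=0, n_lambda=20)

    def test_too_few_subjects_rejected(self, small_survey):
        tiny = small_survey.select_subjects(range(10))
        with pytest.raises(ValueError, match="subjects"):
            bootstrap_networks(tiny, B=2)


class TestStability:
    def test_full_node_set_correlates_perfectly(self, small_survey):
        curves = node_wise_stability(small_survey, sizes=[6], B=3,
                                     gamma=0.5, seed=0, n_lambda=30)
        t = curves.table
        assert t[t["metric"] == "strength"]["pearson"].iloc[0] == \
            pytest.approx(1.0)

    def test_node_sizes_validated(self, small_survey):
        with pytest.raises(ValueError):
            node_wise_stability(small_survey, sizes=[2], B=1)

    def test_small_subsets_average_over_successes_only(self, small_survey):
        curves = node_wise_stability(small_survey, sizes=[3], B=5,
                                     gamma=0.5, seed=1, n_lambda=30)
        t = curves.table
        assert (t["n_success"] <= 5).all()
        finite = t["pearson"].dropna()
        assert ((finite >= -1) & (finite <= 1)).all()

    def test_full_retention_reproduces_original(self, small_survey):
        curves = subject_wise_stability(small_survey, fractions=[1.0], B=2,
                                        gamma=0.5, seed=0, n_lambda=30)
        t = curves.table
        for metric in ("betweenness", "strength"):
            r = t[t["metric"] == metric]["pearson"].iloc[0]
            assert r == pytest.approx(1.0)

    def test_default_grid_spans_quarter_to_ninety_five(self, small_survey):
        curves = subject_wise_stability(small_survey, B=1, gamma=0.5,
                                        seed=2, n_lambda=20)
        levels = sorted(curves.table["level"].unique())
        assert len(levels) == 10
        assert levels[0] == pytest.approx(0.25)
        assert levels[-1] == pytest.approx(0.95)

    def test_smallest_fraction_guard(self, small_survey):
        with pytest.raises(ValueError, match="fraction"):
            subject_wise_stability(small_survey, fractions=[0.05], B=1)

    def test_edge_count_spread_larger_for_smaller_sample(self):
        """Matched-truth groups of unequal size: the smaller sample shows a
        larger bootstrap spread of the edge count."""
        from phenonet.simulate import (
            GroupConfig, TrueNetworkSpec, generate_survey,
            generate_true_network, thresholds_from_probs,
        )

        spec = TrueNetworkSpec(p=6, density=0.3, weight_low=0.4,
                               weight_high=0.5, seed=5)
        W = generate_true_network(spec)
        thr = thresholds_from_probs(
            np.tile([0.1, 0.2, 0.3, 0.25, 0.15], (6, 1)))
        big = GroupConfig(name="big", n_subjects=120, n_raters=120,
                          thresholds=thr, rater_sd=0.0, missing_rate=0.0)
        small = GroupConfig(name="small", n_subjects=55, n_raters=55,
                            thresholds=thr, rater_sd=0.0, missing_rate=0.0)
        data = generate_survey(W, [big, small], seed=9)
        boot_big = bootstrap_networks(data.subset_group("big"), B=100,
                                      gamma=0.5, seed=1, n_lambda=30)
        boot_small = bootstrap_networks(data.subset_group("small"), B=100,
                                        gamma=0.5, seed=2, n_lambda=30)
        assert boot_small.edge_count_sd() > boot_big.edge_count_sd()
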