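"""Age bands, gate routing, post hoc FDR, effect sizes and their bootstraps."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfdbp.bands import (
    assign_bands,
    bootstrap_effect_ci,
    cliffs_delta,
    gate_and_omnibus,
    hedges_d,
    posthoc_pairwise,
)

finite_group = st.lists(
    st.floats(-1e3, 1e3, allow_nan=False, allow_infinity=False), min_size=2, max_size=25
)


class TestBands:
    def test_reference_cohort_band_sizes(self, analysis_subset):
        bands = assign_bands(analysis_subset, (5.0, 7.5))
        assert bands.sizes() == {"Early": 11, "Transitional": 13, "Late": 11}

    def test_partition_conserves_n(self, analysis_subset):
        bands = assign_bands(analysis_subset, (4.0, 9.0))
        assert sum(bands.sizes().values()) == len(analysis_subset)

    def test_half_open_boundary_membership(self, analysis_subset):
        bands = assign_bands(analysis_subset, (5.0, 7.5))
        early_ages = bands.members["Early"]["abx_years"]
        trans_ages = bands.members["Transitional"]["abx_years"]
        assert 5.0 not in early_ages.values
        assert 5.0 in trans_ages.values  # [5.0, 7.5) is closed on the left

    def test_degenerate_boundaries_warn_on_empty_bands(self, analysis_subset, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="mfdbp"):
            bands = assign_bands(analysis_subset, (0.5, 0.6))
        assert bands.sizes()["Early"] == 0
        assert "empty" in caplog.text


class TestGate:
    def test_normal_groups_take_parametric_route(self):
        rng = np.random.default_rng(2)
        groups = {k: rng.normal(0, 1, 30) for k in "abc"}
        route, gate, _, _ = gate_and_omnibus(groups)
        assert route == "parametric"

    def test_skewed_group_forces_rank_route(self):
        rng = np.random.default_rng(4)
        groups = {
            "a": rng.normal(0, 1, 30),
            "b": rng.normal(0, 1, 30),
            "c": np.exp(rng.normal(0, 1.5, 30)),  # heavy right skew
        }
        route, _, _, _ = gate_and_omnibus(groups)
        assert route == "rank"

    def test_zero_variance_group_forces_rank_route(self):
        rng = np.random.default_rng(5)
        groups = {"a": np.full(10, 3.0), "b": rng.normal(0, 1, 10)}
        route, _, _, _ = gate_and_omnibus(groups)
        assert route == "rank"

    def test_identical_groups_yield_high_omnibus_p(self):
        rng = np.random.default_rng(6)
        base = rng.normal(0, 1, 20)
        route, _, _, p = gate_and_omnibus({"a": base, "b": base.copy(), "c": base.copy()})
        assert p > 0.9


class TestPosthoc:
    def test_adjusted_p_never_below_raw(self):
        rng = np.random.default_rng(7)
        groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(1, 1, 15), "c": rng.normal(2, 1, 15)}
        for route in ("parametric", "rank"):
            table = posthoc_pairwise(groups, route)
            assert (table["p_fdr"] >= table["p_raw"] - 1e-12).all()

    def test_fdr_adjustment_monotone_in_raw_p(self):
        rng = np.random.default_rng(8)
        groups = {"a": rng.normal(0, 1, 12), "b": rng.normal(0.5, 1, 12), "c": rng.normal(3, 1, 12)}
        table = posthoc_pairwise(groups, "rank").sort_values("p_raw")
        assert table["p_fdr"].is_monotonic_increasing

    def test_identical_groups_nothing_significant(self):
        rng = np.random.default_rng(9)
        base = rng.normal(0, 1, 15)
        table = posthoc_pairwise({"a": base, "b": base.copy(), "c": base.copy()}, "rank")
        assert (table["p_fdr"] > 0.9).all()


class TestEffectSizes:
    def test_identical_groups_are_null(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        assert hedges_d(g, g) == 0.0
        assert cliffs_delta(g, g) == 0.0

    def test_fully_separated_groups_have_unit_delta(self):
        assert cliffs_delta([1.0, 2.0], [10.0, 11.0, 12.0]) == 1.0
        assert cliffs_delta([10.0, 11.0], [1.0, 2.0]) == -1.0

    def test_hedges_is_cohen_times_correction(self):
        rng = np.random.default_rng(10)
        a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 9)
        na, nb = len(a), len(b)
        pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
        cohen = (b.mean() - a.mean()) / pooled
        j = 1 - 3 / (4 * (na + nb) - 9)
        assert hedges_d(a, b) == pytest.approx(cohen * j, abs=1e-12)

    @given(a=finite_group, b=finite_group)
    @settings(max_examples=50, deadline=None)
    def test_delta_equals_bruteforce_double_loop(self, a, b):
        expected = (
            sum(1 for x in a for y in b if y > x) - sum(1 for x in a for y in b if y < x)
        ) / (len(a) * len(b))
        assert cliffs_delta(a, b) == pytest.approx(expected, abs=1e-12)

    # integer-valued inputs: the exp warp then provably preserves order in
    # floating point, so the invariance is exact rather than approximate
    int_group = st.lists(st.integers(-1000, 1000).map(float), min_size=2, max_size=25)

    @given(a=int_group, b=int_group)
    @settings(max_examples=30, deadline=None)
    def test_delta_invariant_under_monotone_transform(self, a, b):
        f = lambda v: np.exp(np.asarray(v) / 500.0)  # strictly increasing
        assert cliffs_delta(a, b) == pytest.approx(cliffs_delta(f(a), f(b)), abs=1e-12)

    def test_delta_bounded(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            a, b = rng.normal(0, 1, 8), rng.normal(0.5, 2, 13)
            assert -1.0 <= cliffs_delta(a, b) <= 1.0


class TestBootstrapCI:
    def test_identical_groups_interval_contains_zero(self):
        g = np.arange(12.0)
        lo, hi = bootstrap_effect_ci("cliffs_delta", g, g.copy(), reps=500, seed=1)
        assert lo <= 0.0 <= hi

    def test_bounds_ordered_and_in_statistic_range(self, analysis_subset):
        bands = assign_bands(analysis_subset, (5.0, 7.5))
        vals = bands.values("sd_mfs_um2")
        lo, hi = bootstrap_effect_ci("cliffs_delta", vals["Early"], vals["Late"], reps=1000, seed=2)
        assert -1.0 <= lo <= hi <= 1.0

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(12)
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        ci1 = bootstrap_effect_ci("hedges_d", a, b, reps=500, seed=9)
        ci2 = bootstrap_effect_ci("hedges_d", a, b, reps=500, seed=9)
        assert ci1 == ci2
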