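import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from landmarkerr import (
    DistanceRepeatability,
    MethodSpec,
    SimulationParams,
    between_method_repeatability,
    convert_units,
    distance_table,
    simulate_dataset,
    variance_components,
    within_method_repeatability,
)

from _oracles import anova_mean_squares


def _sim_table(params):
    ds, _ = simulate_dataset(params)
    for m in params.methods:
        if m.units == "voxel":
            ds = convert_units(ds, m.label, m.mm_per_unit)
    return distance_table(ds)


class TestVarianceComponents:
    def test_hand_computed_example(self):
        vc = variance_components([("A", 1), ("A", 3), ("B", 5), ("B", 7)])
        assert vc.ms_within == pytest.approx(2.0, abs=1e-12)
        assert vc.ms_among == pytest.approx(16.0, abs=1e-12)
        assert vc.s2_A == pytest.approx(7.0, abs=1e-12)
        assert vc.repeatability == pytest.approx(7.0 / 9.0, abs=1e-12)
        assert not vc.clipped

    def test_zero_within_variance(self):
        vc = variance_components([("A", 2), ("A", 2), ("B", 5), ("B", 5), ("C", 9), ("C", 9)])
        assert vc.s2 == 0.0
        assert vc.repeatability == 1.0

    def test_all_identical_defines_zero(self):
        vc = variance_components([("A", 4), ("A", 4), ("B", 4), ("B", 4)])
        assert vc.s2 == 0.0 and vc.s2_A == 0.0
        assert vc.repeatability == 0.0

    def test_negative_component_clipped(self):
        # within spread huge, group means identical -> raw s2_A < 0
        vc = variance_components([("A", 0), ("A", 10), ("B", 4), ("B", 6)])
        assert vc.clipped
        assert vc.s2_A == 0.0
        assert vc.s2_A_raw < 0
        assert vc.repeatability == 0.0

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError, match="single value"):
            variance_components([("A", 1), ("A", 2), ("B", 3)])

    def test_agrees_with_statsmodels_anova_on_random_tables(self, rng):
        for _ in range(20):
            a = int(rng.integers(2, 8))
            k = int(rng.integers(2, 5))
            groups = np.repeat([f"g{i}" for i in range(a)], k)
            values = rng.normal(size=a * k)
            vc = variance_components(groups, values)
            ms_a, ms_w = anova_mean_squares(groups, values)
            assert vc.ms_among == pytest.approx(ms_a, abs=1e-10)
            assert vc.ms_within == pytest.approx(ms_w, abs=1e-10)
            assert vc.s2_A_raw == pytest.approx((ms_a - ms_w) / k, abs=1e-10)

    def test_unbalanced_effective_group_size(self):
        with pytest.warns(UserWarning, match="unbalanced"):
            vc = variance_components(
                [("A", 1), ("A", 2), ("A", 3), ("B", 4), ("B", 5)]
            )
        n, a = 5, 2
        k0 = (n - (9 + 4) / n) / (a - 1)
        assert vc.k == pytest.approx(k0, abs=1e-12)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        shift=st.floats(-50, 50, allow_nan=False),
        scale=st.floats(0.01, 100, allow_nan=False),
    )
    def test_repeatability_invariant_to_affine_rescaling(self, shift, scale):
        data = [("A", 1.0), ("A", 3.0), ("B", 5.0), ("B", 7.0), ("C", 2.0), ("C", 2.5)]
        r0 = variance_components(data).repeatability
        moved = [(g, v * scale + shift) for g, v in data]
        r1 = variance_components(moved).repeatability
        assert r1 == pytest.approx(r0, abs=1e-9)


class TestWithinMethod:
    def test_error_free_data_has_unit_repeatability(self):
        params = SimulationParams(
            n_individuals=8,
            methods=[MethodSpec("X", err_sd=0.0)],
            individual_sd=0.2,
            seed=5,
        )
        table = _sim_table(params)
        rep = within_method_repeatability(table, "X")
        assert np.allclose(rep.per_distance["r"], 1.0)

    def test_replicate_label_permutation_leaves_r_unchanged(self):
        params = SimulationParams(n_individuals=6, methods=[MethodSpec("X", err_sd=0.1)], seed=7)
        table = _sim_table(params)
        rep1 = within_method_repeatability(table, "X")
        flipped = table.frame.copy()
        flipped["replicate"] = 3 - flipped["replicate"]  # swap 1 <-> 2
        from landmarkerr import DistanceTable

        rep2 = within_method_repeatability(DistanceTable(flipped, table.distance_scheme), "X")
        assert np.allclose(rep1.per_distance["r"], rep2.per_distance["r"])

    def test_recovers_known_variance_ratio(self):
        # distance-level individual:error variance 9:1 at every distance
        params = SimulationParams(
            n_individuals=200,
            methods=[MethodSpec("X", err_sd=0.05)],
            individual_sd=0.15,
            individual_scale_sd=0.0,
            rigid_nuisance=False,
            seed=11,
        )
        table = _sim_table(params)
        rep = within_method_repeatability(table, "X")
        assert rep.mean_r == pytest.approx(0.9, abs=0.03)


class TestBetweenMethod:
    def test_identical_methods_match_within(self):
        params = SimulationParams(n_individuals=6, methods=[MethodSpec("A", err_sd=0.1)], seed=3)
        table = _sim_table(params)
        dup = table.frame.copy()
        dup["method"] = "B"
        from landmarkerr import DistanceTable

        both = DistanceTable(pd.concat([table.frame, dup], ignore_index=True), table.distance_scheme)
        within = within_method_repeatability(both, "A")
        between = between_method_repeatability(both, "A", "B")
        assert between.dataset_label == "A + B"
        # B duplicates A's values, so the pooled k=4 ANOVA sees the same
        # information with different degrees of freedom; the estimates obey
        # r_pooled = (3A - w) / (3 (A + w)) exactly, with A and w the
        # within-analysis mean squares, and agree closely in value.
        ok = ~within.per_distance["clipped"] & ~between.per_distance["clipped"]
        assert ok.sum() >= 20
        a_ms = (within.per_distance["s2_A"] * 2 + within.per_distance["s2"])[ok]  # MS_among
        w_ms = within.per_distance["s2"][ok]
        expected = (3 * a_ms - w_ms) / (3 * (a_ms + w_ms))
        assert np.allclose(between.per_distance["r"][ok], expected, atol=1e-10)
        # equivalently r_pooled - r_within = (1 - r_within) / 3: no drop, a
        # slight df-driven rise that vanishes as r -> 1
        gap = between.per_distance["r"][ok] - within.per_distance["r"][ok]
        assert np.allclose(gap, (1 - within.per_distance["r"][ok]) / 3, atol=1e-10)

    def test_shared_individual_join_counts(self):
        params = SimulationParams(
            n_individuals=20,
            methods=[MethodSpec("A", err_sd=0.05), MethodSpec("B", err_sd=0.05)],
            seed=9,
        )
        table = _sim_table(params)
        # drop 4 individuals from method A only (lost skulls)
        keep = ~((table.frame.method == "A") & (table.frame.individual.isin(["ind01", "ind02", "ind03", "ind04"])))
        from landmarkerr import DistanceTable

        pruned = DistanceTable(table.frame[keep].reset_index(drop=True), table.distance_scheme)
        rep = between_method_repeatability(pruned, "A", "B")
        assert (rep.per_distance["n_groups"] == 16).all()
        assert (rep.per_distance["k"] == 4).all()

    def test_disjoint_individuals_error(self):
        params = SimulationParams(n_individuals=4, methods=[MethodSpec("A"), MethodSpec("B")], seed=1)
        table = _sim_table(params)
        df = table.frame.copy()
        df.loc[df.method == "B", "individual"] = df.loc[df.method == "B", "individual"] + "_x"
        from landmarkerr import DistanceTable

        with pytest.raises(ValueError, match="shared"):
            between_method_repeatability(DistanceTable(df, table.distance_scheme), "A", "B")

    def test_method_bias_depresses_between_repeatability(self):
        from landmarkerr import random_method_biases

        drops = []
        for seed in range(10):
            bias = random_method_biases(35, sd=0.15, seed=1000 + seed)
            params = SimulationParams(
                n_individuals=20,
                methods=[MethodSpec("A", err_sd=0.1), MethodSpec("B", err_sd=0.1, bias=bias)],
                rigid_nuisance=False,
                seed=seed,
            )
            table = _sim_table(params)
            wa = within_method_repeatability(table, "A").mean_r
            wb = within_method_repeatability(table, "B").mean_r
            ab = between_method_repeatability(table, "A", "B").mean_r
            drops.append(ab < min(wa, wb))
        assert sum(drops) >= 9
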