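import numpy as np
import pandas as pd
import pytest

from landmarkerr import (
    DistanceTable,
    between_method_differences,
    pearson_correlation,
    percentage_error,
    repeatability_length_correlation,
    within_method_differences,
    within_method_repeatability,
)

from _oracles import pearson_from_sums


def _table(rows):
    df = pd.DataFrame(
        rows, columns=["individual", "method", "replicate", "distance", "value_mm"]
    )
    df["single_side"] = False
    from landmarkerr.schemes import DistanceEntry, DistanceScheme

    ids = sorted(df["distance"].unique())
    scheme = DistanceScheme(tuple(DistanceEntry(i, 1, 2, f"d{i}") for i in ids))
    return DistanceTable(df, scheme)


class TestWithinDifferences:
    def test_hand_arithmetic(self):
        table = _table(
            [
                ("a", "DIG", 1, 1, 10.0),
                ("a", "DIG", 2, 1, 10.2),
                ("b", "DIG", 1, 1, 8.0),
                ("b", "DIG", 2, 1, 7.9),
            ]
        )
        res = within_method_differences(table, "DIG")
        row = res.per_distance.iloc[0]
        assert row["mean_raw"] == pytest.approx((-0.2 + 0.1) / 2, abs=1e-12)
        assert row["mean_abs"] == pytest.approx(0.15, abs=1e-12)

    def test_identical_replicates_all_zero(self):
        table = _table(
            [("a", "DIG", r, d, v) for r in (1, 2) for d, v in [(1, 5.0), (2, 3.0)]]
            + [("b", "DIG", r, d, v) for r in (1, 2) for d, v in [(1, 6.0), (2, 2.5)]]
        )
        res = within_method_differences(table, "DIG")
        assert (res.per_distance["mean_raw"] == 0).all()
        assert (res.per_distance["mean_abs"] == 0).all()

    def test_replicate_swap_antisymmetry(self):
        rows = [
            ("a", "DIG", 1, 1, 10.0),
            ("a", "DIG", 2, 1, 10.3),
            ("b", "DIG", 1, 1, 9.0),
            ("b", "DIG", 2, 1, 8.6),
        ]
        table = _table(rows)
        res1 = within_method_differences(table, "DIG")
        swapped = _table([(i, m, 3 - r, d, v) for i, m, r, d, v in rows])
        res2 = within_method_differences(swapped, "DIG")
        assert res2.per_distance["mean_raw"].iloc[0] == pytest.approx(
            -res1.per_distance["mean_raw"].iloc[0], abs=1e-12
        )
        assert res2.per_distance["mean_abs"].iloc[0] == pytest.approx(
            res1.per_distance["mean_abs"].iloc[0], abs=1e-12
        )

    def test_triangle_inequality_on_random_tables(self, rng):
        rows = []
        for ind in range(10):
            for d in range(1, 6):
                base = rng.uniform(2, 20)
                for rep in (1, 2):
                    rows.append((f"i{ind}", "X", rep, d, base + rng.normal(scale=0.3)))
        res = within_method_differences(_table(rows), "X")
        assert (res.per_distance["mean_abs"] >= res.per_distance["mean_raw"].abs() - 1e-12).all()


class TestBetweenDifferences:
    def _two_methods(self, shift=0.1):
        rows = []
        for ind in ("a", "b", "c"):
            for d, v in [(1, 10.0), (2, 4.0)]:
                for rep in (1, 2):
                    rows.append((ind, "A", rep, d, v))
                    rows.append((ind, "B", rep, d, v + shift))
        return _table(rows)

    def test_constant_shift_recovered(self):
        res = between_method_differences(self._two_methods(0.1), "A", "B")
        assert np.allclose(res.per_distance["mean_raw"], -0.1, atol=1e-12)
        assert np.allclose(res.per_distance["mean_abs"], 0.1, atol=1e-12)
        assert res.pairing_label == "A - B"
        assert res.n_pairs == 3

    def test_identical_methods_zero(self):
        res = between_method_differences(self._two_methods(0.0), "A", "B")
        assert (res.per_distance["mean_raw"] == 0).all()
        assert (res.per_distance["mean_abs"] == 0).all()

    def test_unbiased_noise_raw_near_zero_abs_positive(self, rng):
        rows = []
        for ind in range(50):
            for d in range(1, 6):
                base = rng.uniform(5, 15)
                for m in ("A", "B"):
                    for rep in (1, 2):
                        rows.append((f"i{ind}", m, rep, d, base + rng.normal(scale=0.2)))
        res = between_method_differences(_table(rows), "A", "B")
        assert np.abs(res.per_distance["mean_raw"]).max() < 0.15
        assert (res.per_distance["mean_abs"] > 0.05).all()

    def test_no_shared_individuals_errors(self):
        rows = [("a", "A", r, 1, 5.0) for r in (1, 2)] + [("b", "B", r, 1, 5.0) for r in (1, 2)]
        with pytest.raises(ValueError, match="shared"):
            between_method_differences(_table(rows), "A", "B")


class TestPercentageError:
    def test_hand_arithmetic(self):
        # abs difference 0.1 mm on a distance with mean 2.0 mm -> 5.0 %
        table = _table(
            [
                ("a", "X", 1, 1, 1.95),
                ("a", "X", 2, 1, 2.05),
            ]
        )
        res = percentage_error(within_method_differences(table, "X"), table, methods=["X"])
        assert res.per_distance["pct_of_mean"].iloc[0] == pytest.approx(5.0, abs=1e-12)

    def test_zero_abs_gives_zero_pct(self):
        table = _table([("a", "X", 1, 1, 4.0), ("a", "X", 2, 1, 4.0)])
        res = percentage_error(within_method_differences(table, "X"), table, methods=["X"])
        assert res.per_distance["pct_of_mean"].iloc[0] == 0.0

    def test_halving_distances_doubles_percentages(self):
        rows = [
            ("a", "X", 1, 1, 10.0),
            ("a", "X", 2, 1, 10.4),
            ("b", "X", 1, 1, 9.8),
            ("b", "X", 2, 1, 10.2),
        ]
        t1 = _table(rows)
        r1 = percentage_error(within_method_differences(t1, "X"), t1, methods=["X"])
        t2 = _table([(i, m, r, d, v / 2) for i, m, r, d, v in rows])
        r2 = percentage_error(within_method_differences(t2, "X"), t2, methods=["X"])
        assert r2.per_distance["pct_of_mean"].iloc[0] == pytest.approx(
            r1.per_distance["pct_of_mean"].iloc[0], abs=1e-12
        )  # halving values halves abs differences too: pct unchanged
        # scaling only the means (same abs diff) doubles pct instead
        t3 = _table([(i, m, r, d, v - 5.0) for i, m, r, d, v in rows])
        r3 = percentage_error(within_method_differences(t3, "X"), t3, methods=["X"])
        m1 = t1.method_means(methods=["X"]).iloc[0]
        m3 = t3.method_means(methods=["X"]).iloc[0]
        assert r3.per_distance["pct_of_mean"].iloc[0] == pytest.approx(
            r1.per_distance["pct_of_mean"].iloc[0] * m1 / m3, abs=1e-10
        )


class TestCorrelation:
    def test_perfect_linear_relationship(self):
        res = pearson_correlation([1, 2, 3, 4], [2, 4, 6, 8])
        assert res.r == pytest.approx(1.0)
        assert res.df == 2

    def test_t_and_p_match_bruteforce_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(5, 40))
            x = rng.normal(size=n)
            y = 0.5 * x + rng.normal(size=n)
            res = pearson_correlation(x, y)
            r0, t0, p0 = pearson_from_sums(x, y)
            assert res.r == pytest.approx(r0, abs=1e-10)
            assert res.t_statistic == pytest.approx(t0, abs=1e-10)
            assert res.p_value == pytest.approx(p0, abs=1e-10)
            assert res.t_statistic == pytest.approx(
                res.r * np.sqrt(res.df / (1 - res.r**2)), abs=1e-10
            )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_correlation([1, 1, 1], [2, 3, 4])

    def test_24_distances_give_df_22(self, rng):
        rows = []
        for ind in range(8):
            for d in range(1, 25):
                base = d + rng.uniform(0, 0.5)
                for rep in (1, 2):
                    rows.append((f"i{ind}", "X", rep, d, base + rng.normal(scale=0.05)))
        table = _table(rows)
        rep = within_method_repeatability(table, "X")
        corr = repeatability_length_correlation(rep, table, methods=["X"])
        assert corr.df == 22
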