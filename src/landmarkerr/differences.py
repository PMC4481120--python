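"""Raw, absolute and percentage differences of distances, within and
between methods, plus the repeatability-versus-length correlation.

Raw differences (first value minus second, kept signed) reveal a
consistent bias of one replicate or method over another; absolute
differences measure the magnitude of disagreement regardless of
direction; dividing the mean absolute difference by the distance's mean
and multiplying by 100 expresses the error as a percentage of the
measurement, which is what makes small distances look noisy even under
homogeneous landmark error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .distances import DistanceTable
from .reliability import RepeatabilityResults


@dataclass
class DifferenceResults:
    """Per-distance raw/absolute/percentage differences for one pairing
    (replicates of a method, or two methods).  The sign convention is
    first-listed minus second."""

    pairing_label: str  # e.g. "DIG (rep1 - rep2)" or "MED - DIG"
    per_distance: pd.DataFrame
    # columns: distance, mean_raw, sd_raw, mean_abs, sd_abs, n, pct_of_mean (NaN until filled)
    n_pairs: int

    @property
    def summary_raw(self) -> tuple[float, float]:
        return float(self.per_distance["mean_raw"].mean()), float(self.per_distance["mean_raw"].std(ddof=1))

    @property
    def summary_abs(self) -> tuple[float, float]:
        return float(self.per_distance["mean_abs"].mean()), float(self.per_distance["mean_abs"].std(ddof=1))

    @property
    def summary_pct(self) -> tuple[float, float]:
        pct = self.per_distance["pct_of_mean"].dropna()
        if pct.empty:
            return (float("nan"), float("nan"))
        return float(pct.mean()), float(pct.std(ddof=1))

    def to_frame(self) -> pd.DataFrame:
        return self.per_distance.copy()

    def summary(self) -> str:
        raw_m, raw_s = self.summary_raw
        abs_m, abs_s = self.summary_abs
        pct_m, pct_s = self.summary_pct
        lines = [
            f"Distance differences — {self.pairing_label} (n = {self.n_pairs} pairs/distance)",
            f"  raw:      {raw_m:+.3f} ± {raw_s:.3f} mm",
            f"  absolute: {abs_m:.3f} ± {abs_s:.3f} mm",
        ]
        if not np.isnan(pct_m):
            lines.append(f"  % of mean: {pct_m:.1f} ± {pct_s:.1f} %")
        lines += [
            "",
            self.per_distance.to_string(index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


def _summarize(diffs: pd.DataFrame) -> pd.DataFrame:
    """Per-distance mean/SD of signed and absolute differences."""
    rows = []
    for dist, g in diffs.groupby("distance", sort=True):
        d = g["diff"].to_numpy()
        d = d[~np.isnan(d)]
        rows.append(
            (
                int(dist),
                d.mean(),
                d.std(ddof=1) if len(d) > 1 else 0.0,
                np.abs(d).mean(),
                np.abs(d).std(ddof=1) if len(d) > 1 else 0.0,
                len(d),
                np.nan,
            )
        )
    return pd.DataFrame(
        rows, columns=["distance", "mean_raw", "sd_raw", "mean_abs", "sd_abs", "n", "pct_of_mean"]
    )


class DistanceDifferences:
    """Difference model for a distance table.

    One method label: replicate differences within that method (first
    replicate minus second, per individual).  Two labels: per-individual
    method difference (first-listed minus second), each individual's
    value being the mean over that method's replicates (or replicate 1
    only with ``use_first_replicate=True``), restricted to shared
    individuals.
    """

    def __init__(
        self,
        table: DistanceTable,
        methods: str | tuple[str, str] | list[str],
        use_first_replicate: bool = False,
    ):
        self.table = table
        if isinstance(methods, str):
            methods = (methods,)
        self.methods = tuple(methods)
        if not 1 <= len(self.methods) <= 2:
            raise ValueError("methods must name one or two method labels")
        present = set(table.frame["method"].unique())
        for m in self.methods:
            if m not in present:
                raise ValueError(f"method {m!r} not in table")
        self.use_first_replicate = use_first_replicate

    def fit(self) -> DifferenceResults:
        if len(self.methods) == 1:
            return self._within()
        return self._between()

    def _within(self) -> DifferenceResults:
        method = self.methods[0]
        df = self.table.frame
        df = df[df["method"] == method]
        rows = []
        for (ind, dist), g in df.groupby(["individual", "distance"], sort=True):
            g = g.sort_values("replicate")
            vals = g["value_mm"].to_numpy()
            if len(vals) < 2:
                warnings.warn(
                    f"individual {ind}, distance {dist}: single replicate, skipped",
                    stacklevel=2,
                )
                continue
            if len(vals) > 2:
                warnings.warn(
                    f"individual {ind}: {len(vals)} replicates, using consecutive pairs",
                    stacklevel=2,
                )
            for r1, r2 in zip(vals[:-1], vals[1:]):
                rows.append((dist, r1 - r2))
        diffs = pd.DataFrame(rows, columns=["distance", "diff"])
        per = _summarize(diffs)
        n_pairs = int(per["n"].max()) if not per.empty else 0
        return DifferenceResults(
            pairing_label=f"{method} (rep1 - rep2)", per_distance=per, n_pairs=n_pairs
        )

    def _between(self) -> DifferenceResults:
        a, b = self.methods
        df = self.table.frame
        df = df[df["method"].isin(self.methods)]
        if self.use_first_replicate:
            df = df[df["replicate"] == df.groupby("method")["replicate"].transform("min")]
        shared = set(df[df["method"] == a]["individual"]) & set(df[df["method"] == b]["individual"])
        if not shared:
            raise ValueError(f"no shared individuals between {a!r} and {b!r}")
        df = df[df["individual"].isin(shared)]
        per_ind = (
            df.groupby(["individual", "method", "distance"])["value_mm"].mean().unstack("method")
        )
        diffs = (per_ind[a] - per_ind[b]).rename("diff").reset_index()
        per = _summarize(diffs)
        n_pairs = len(shared)
        return DifferenceResults(pairing_label=f"{a} - {b}", per_distance=per, n_pairs=n_pairs)


def within_method_differences(table: DistanceTable, method: str) -> DifferenceResults:
    """Replicate differences (rep1 - rep2) within one method."""
    return DistanceDifferences(table, method).fit()


def between_method_differences(
    table: DistanceTable, method_a: str, method_b: str, use_first_replicate: bool = False
) -> DifferenceResults:
    """Per-individual differences between two methods (A - B)."""
    return DistanceDifferences(table, (method_a, method_b), use_first_replicate).fit()


def percentage_error(report: DifferenceResults, table: DistanceTable, methods: list[str] | None = None) -> DifferenceResults:
    """Fill ``pct_of_mean``: 100 x mean absolute difference / distance mean.

    Distance means are taken over the methods involved in the pairing
    (parsed from the pairing label unless given explicitly).  A zero
    mean masks the percentage.  The summary percentage is the mean ± SD
    of per-distance percentages, not the ratio of summary means.
    """
    if methods is None:
        label = report.pairing_label.split(" (")[0]
        methods = [m.strip() for m in label.split("-")] if " - " in label else [label]
    means = table.method_means(methods=methods)
    per = report.per_distance.copy()
    pct = []
    for r in per.itertuples():
        m = means.get(r.distance, np.nan)
        if not np.isfinite(m) or m == 0:
            pct.append(np.nan)
        else:
            pct.append(100.0 * r.mean_abs / m)
    per["pct_of_mean"] = pct
    return DifferenceResults(
        pairing_label=report.pairing_label, per_distance=per, n_pairs=report.n_pairs
    )


@dataclass
class CorrelationResult:
    """Pearson correlation with its two-sided t test."""

    r: float
    df: int
    t_statistic: float
    p_value: float
    alpha: float = 0.05

    @property
    def significant(self) -> bool:
        return self.p_value < self.alpha

    def summary(self) -> str:
        verdict = "significant" if self.significant else "not significant"
        return (
            f"Pearson r = {self.r:.3f}, d.f. = {self.df}, t = {self.t_statistic:.3f}, "
            f"P = {self.p_value:.4f} ({verdict} at alpha = {self.alpha})"
        )


def pearson_correlation(x, y, alpha: float = 0.05) -> CorrelationResult:
    """Pearson product-moment correlation with the two-sided t test on
    n - 2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    df = len(x) - 2
    if abs(r) < 1:
        t = r * np.sqrt(df / (1 - r**2))
    else:
        t = np.inf * np.sign(r)
    return CorrelationResult(r=r, df=df, t_statistic=float(t), p_value=float(res.pvalue), alpha=alpha)


def repeatability_length_correlation(
    rep: RepeatabilityResults,
    table: DistanceTable,
    methods: list[str] | None = None,
    alpha: float = 0.05,
) -> CorrelationResult:
    """Correlate per-distance repeatability against mean distance length.

    A positive association means the proportional impact of a fixed
    mm-scale measurement error is larger for shorter distances.
    """
    if methods is None:
        methods = [m.strip() for m in rep.dataset_label.split("+")]
    means = table.method_means(methods=methods)
    rs = rep.r_series()
    common = [d for d in rs.index if d in means.index]
    if len(common) < 3:
        raise ValueError("need at least 3 distances")
    return pearson_correlation(rs.loc[common].to_numpy(), means.loc[common].to_numpy(), alpha=alpha)
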