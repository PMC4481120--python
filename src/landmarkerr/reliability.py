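"""Distance repeatability from one-way ANOVA variance components.

Repeatability (the intraclass correlation of a measurement protocol) is

    r = s2_A / (s2 + s2_A)

with s2_A the among-individual variance component and s2 the residual
(within-individual, replicate-to-replicate) variance, both estimated
from the one-way ANOVA sums of squares with individuals as groups:

    s2   = MS_within
    s2_A = (MS_among - MS_within) / k0

k0 is the replicate count per individual for balanced designs and the
standard effective group size (N - sum(n_i^2)/N) / (a - 1) otherwise.
Within-method repeatability uses the replicates of one method (k = 2 in
the reference design); between-method repeatability pools the
replicates of two methods per individual (k = 4), so any systematic
disagreement between the methods inflates the residual and depresses r.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .distances import DistanceTable


@dataclass
class VarianceComponents:
    s2_A: float  # among-individual variance (mm^2), clipped at 0
    s2: float  # residual variance (mm^2)
    ms_among: float
    ms_within: float
    n_groups: int
    k: float  # replicates per group (k0 for unbalanced designs)
    clipped: bool  # raw s2_A was negative and set to 0
    s2_A_raw: float  # un-clipped estimate, retained for inspection

    @property
    def repeatability(self) -> float:
        total = self.s2 + self.s2_A
        if total == 0:
            return 0.0  # no variance anywhere: r defined as 0
        return self.s2_A / total


def variance_components(groups, values=None) -> VarianceComponents:
    """One-way ANOVA variance components from (group, value) data.

    Accepts either an iterable of ``(group_id, value)`` pairs or two
    parallel sequences.  Every group must contribute at least 2 values
    (a group with a single value has no within-group information).
    """
    if values is None:
        pairs = list(groups)
        labels = np.array([p[0] for p in pairs])
        vals = np.array([float(p[1]) for p in pairs])
    else:
        labels = np.asarray(groups)
        vals = np.asarray(values, dtype=float)
    if len(vals) != len(labels):
        raise ValueError("groups/values length mismatch")
    uniq, inverse = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need at least 2 groups")
    n_i = np.bincount(inverse)
    if (n_i < 2).any():
        bad = uniq[n_i < 2]
        raise ValueError(f"groups with a single value: {list(bad)}")
    n = len(vals)
    grand = vals.mean()
    group_means = np.bincount(inverse, weights=vals) / n_i
    ss_among = float(np.sum(n_i * (group_means - grand) ** 2))
    ss_within = float(np.sum((vals - group_means[inverse]) ** 2))
    ms_among = ss_among / (a - 1)
    ms_within = ss_within / (n - a)
    if np.all(n_i == n_i[0]):
        k0 = float(n_i[0])
        balanced = True
    else:
        k0 = (n - np.sum(n_i**2) / n) / (a - 1)
        balanced = False
    s2_a_raw = (ms_among - ms_within) / k0
    clipped = s2_a_raw < 0
    vc = VarianceComponents(
        s2_A=max(s2_a_raw, 0.0),
        s2=ms_within,
        ms_among=ms_among,
        ms_within=ms_within,
        n_groups=a,
        k=k0,
        clipped=bool(clipped),
        s2_A_raw=s2_a_raw,
    )
    if not balanced:
        warnings.warn("unbalanced design: using effective group size k0", stacklevel=2)
    return vc


@dataclass
class RepeatabilityResults:
    """Per-distance repeatability for one data subset (a single method,
    or two methods joined)."""

    dataset_label: str  # e.g. "DIG" or "MED + DIG"
    per_distance: pd.DataFrame  # distance, r, s2_A, s2, n_groups, k, clipped

    @property
    def mean_r(self) -> float:
        return float(self.per_distance["r"].mean())

    @property
    def sd_r(self) -> float:
        return float(self.per_distance["r"].std(ddof=1))

    def r_series(self) -> pd.Series:
        return self.per_distance.set_index("distance")["r"]

    def to_frame(self) -> pd.DataFrame:
        return self.per_distance.copy()

    def summary(self) -> str:
        lines = [
            f"Distance repeatability — {self.dataset_label}",
            f"  distances: {len(self.per_distance)}   "
            f"individuals: {int(self.per_distance['n_groups'].iloc[0])}   "
            f"replicates/individual: {self.per_distance['k'].iloc[0]:g}",
            f"  mean r = {self.mean_r:.3f} ± {self.sd_r:.3f}",
            "",
            self.per_distance[["distance", "r", "s2_A", "s2"]].to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
        ]
        return "\n".join(lines)


class DistanceRepeatability:
    """Repeatability model for a distance table.

    ``methods`` is one label (within-method analysis: groups are
    individuals, values the method's replicates) or two labels
    (between-method analysis: the two methods' replicates are pooled per
    individual, restricted to individuals measured by both).
    """

    def __init__(self, table: DistanceTable, methods: str | tuple[str, str] | list[str]):
        self.table = table
        if isinstance(methods, str):
            methods = (methods,)
        self.methods = tuple(methods)
        if not 1 <= len(self.methods) <= 2:
            raise ValueError("methods must name one or two method labels")
        present = set(table.frame["method"].unique())
        for m in self.methods:
            if m not in present:
                raise ValueError(f"method {m!r} not in table (have {sorted(present)})")

    def fit(self) -> RepeatabilityResults:
        df = self.table.frame
        df = df[df["method"].isin(self.methods)]
        if len(self.methods) == 2:
            by_method = [set(df[df["method"] == m]["individual"]) for m in self.methods]
            shared = by_method[0] & by_method[1]
            if not shared:
                raise ValueError(f"no shared individuals between {self.methods}")
            df = df[df["individual"].isin(shared)]
            label = " + ".join(self.methods)
        else:
            label = self.methods[0]
        rows = []
        for dist, g in df.groupby("distance", sort=True):
            g = g.dropna(subset=["value_mm"])
            vc = variance_components(g["individual"].to_numpy(), g["value_mm"].to_numpy())
            rows.append(
                (int(dist), vc.repeatability, vc.s2_A, vc.s2, vc.n_groups, vc.k, vc.clipped)
            )
        per = pd.DataFrame(rows, columns=["distance", "r", "s2_A", "s2", "n_groups", "k", "clipped"])
        return RepeatabilityResults(dataset_label=label, per_distance=per)


def within_method_repeatability(table: DistanceTable, method: str) -> RepeatabilityResults:
    """Per-distance repeatability from one method's replicates."""
    return DistanceRepeatability(table, method).fit()


def between_method_repeatability(table: DistanceTable, method_a: str, method_b: str) -> RepeatabilityResults:
    """Per-distance repeatability with both methods' replicates pooled
    per individual (individuals restricted to those measured by both)."""
    return DistanceRepeatability(table, (method_a, method_b)).fit()
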