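"""Inter-landmark distance extraction, bilateral averaging and
gross-error quality control.

Each scheme distance is the Euclidean distance between two landmarks.
Distances with at least one bilateral endpoint exist on both sides of
the skull; the left and right values are averaged into a single value
per digitization (single-side fallback, flagged, when one side is
masked).  Replicate pairs whose distance values differ by more than a
threshold — 0.5 mm in general, 0.3 mm for distances whose method-wise
mean is below 3.0 mm — are flagged as gross (human) measurement error
for manual re-measurement; nothing is auto-corrected.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LandmarkConfiguration, LandmarkDataset
from .schemes import DistanceScheme, LandmarkScheme


def compute_distances(
    config: LandmarkConfiguration,
    scheme: LandmarkScheme,
    distance_scheme: DistanceScheme,
) -> pd.DataFrame:
    """Per-distance values for one configuration, before bilateral
    averaging.

    Returns a frame with columns ``distance_id, side, value``; bilateral
    entries yield one L and one R row (a side landmark paired with a
    midline landmark uses that side's instance plus the shared midline
    point).  A masked endpoint masks the affected side's value (NaN),
    never zero.
    """
    if config.units != "mm":
        raise ValueError("configuration must be converted to mm before measuring distances")
    rows = []
    for e in distance_scheme.entries:
        a_mid = scheme.is_midline(e.landmark_a)
        b_mid = scheme.is_midline(e.landmark_b)
        if a_mid and b_mid:
            sides = ["M"]
        else:
            sides = ["L", "R"]
        for side in sides:
            ia = scheme.index_of(e.landmark_a, "M" if a_mid else side)
            ib = scheme.index_of(e.landmark_b, "M" if b_mid else side)
            if config.missing[ia] or config.missing[ib]:
                value = np.nan
            else:
                value = float(np.linalg.norm(config.coords[ia] - config.coords[ib]))
                if value == 0.0:
                    warnings.warn(
                        f"distance {e.distance_id} ({side}): coincident landmarks in "
                        f"{config.key()}",
                        stacklevel=2,
                    )
            rows.append((e.distance_id, side, value))
    return pd.DataFrame(rows, columns=["distance_id", "side", "value"])


def average_bilateral(raw: pd.DataFrame, distance_scheme: DistanceScheme) -> pd.DataFrame:
    """Collapse L/R rows of each bilateral distance to their mean.

    Midline-only distances pass through unchanged.  If one side is
    masked the present side is used and the row is flagged
    ``single_side``; both masked leaves the value masked.
    """
    out = []
    for did, g in raw.groupby("distance_id", sort=True):
        vals = g["value"].to_numpy()
        if len(g) == 1:
            out.append((did, float(vals[0]), False))
        else:
            ok = ~np.isnan(vals)
            if ok.sum() == 2:
                out.append((did, float(vals.mean()), False))
            elif ok.sum() == 1:
                out.append((did, float(vals[ok][0]), True))
            else:
                out.append((did, np.nan, False))
    return pd.DataFrame(out, columns=["distance_id", "value", "single_side"])


@dataclass
class DistanceTable:
    """Long table of bilaterally averaged distances: one row per
    (individual, method, replicate, distance), values in mm."""

    frame: pd.DataFrame  # individual, method, replicate, distance, value_mm, single_side
    distance_scheme: DistanceScheme

    COLUMNS = ["individual", "method", "replicate", "distance", "value_mm", "single_side"]

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"distance table missing columns {missing}")
        key = ["individual", "method", "replicate", "distance"]
        if self.frame.duplicated(subset=key).any():
            raise ValueError("duplicate (individual, method, replicate, distance) rows")
        self.frame = self.frame.sort_values(key, kind="mergesort").reset_index(drop=True)

    @property
    def methods(self) -> list[str]:
        return sorted(self.frame["method"].unique())

    def method_means(self, methods: list[str] | None = None, individuals: list[str] | None = None) -> pd.Series:
        """Mean value per distance over the given methods (all by default)."""
        df = self.frame
        if methods is not None:
            df = df[df["method"].isin(methods)]
        if individuals is not None:
            df = df[df["individual"].isin(individuals)]
        return df.groupby("distance")["value_mm"].mean()

    def to_csv(self, path: str) -> None:
        self.frame[["individual", "method", "replicate", "distance", "value_mm"]].to_csv(
            path, index=False
        )


def distance_table(dataset: LandmarkDataset, distance_scheme: DistanceScheme | None = None) -> DistanceTable:
    """Measure every configuration of a dataset: extract all scheme
    distances and average bilateral pairs."""
    ds = distance_scheme or dataset.distance_scheme
    if ds is None:
        raise ValueError("no distance scheme available")
    rows = []
    for c in dataset.configurations:
        raw = compute_distances(c, dataset.scheme, ds)
        avg = average_bilateral(raw, ds)
        for r in avg.itertuples():
            rows.append(
                (c.individual_id, c.method, c.replicate, int(r.distance_id), r.value, bool(r.single_side))
            )
    return DistanceTable(pd.DataFrame(rows, columns=DistanceTable.COLUMNS), ds)


@dataclass
class QCConfig:
    """Gross-error thresholds.

    ``default_threshold`` applies to most distances; distances whose
    method-wise mean falls below ``small_mean_cutoff`` (or whose id is
    in the explicit ``small_distance_ids`` override) use the stricter
    ``small_threshold`` instead, since a 0.5 mm discrepancy on a 2 mm
    distance would be enormous relative to the measurement.
    """

    default_threshold: float = 0.5  # mm
    small_threshold: float = 0.3  # mm
    small_mean_cutoff: float = 3.0  # mm
    small_distance_ids: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.default_threshold <= 0 or self.small_threshold <= 0:
            raise ValueError("thresholds must be > 0")
        if self.small_threshold > self.default_threshold:
            raise ValueError("small_threshold must not exceed default_threshold")


@dataclass
class QCReport:
    flags: pd.DataFrame  # individual, method, distance, replicate_pair, abs_difference, threshold_used

    COLUMNS = ["individual", "method", "distance", "replicate_pair", "abs_difference", "threshold_used"]

    @property
    def n_flags(self) -> int:
        return len(self.flags)

    def to_csv(self, path: str) -> None:
        self.flags.to_csv(path, index=False)

    def __str__(self) -> str:
        if self.flags.empty:
            return "QC: no replicate pair exceeds its gross-error threshold."
        lines = ["QC: gross-error flags (re-measure these landmarks):"]
        for r in self.flags.itertuples():
            lines.append(
                f"  individual {r.individual}, method {r.method}, distance {r.distance}, "
                f"replicates {r.replicate_pair}: |diff| = {r.abs_difference:.3f} mm "
                f"> {r.threshold_used} mm"
            )
        return "\n".join(lines)


def flag_gross_errors(table: DistanceTable, qc: QCConfig | None = None) -> QCReport:
    """Compare every within-method replicate pair of each distance
    against its gross-error threshold; list all violations.

    Report-only: flagged values are never altered or dropped here (the
    remedy is re-placing the offending landmarks in both replicates).
    """
    qc = qc or QCConfig()
    df = table.frame
    rows = []
    for method, g in df.groupby("method", sort=True):
        means = g.groupby("distance")["value_mm"].mean()
        n_reps = g.groupby(["individual", "distance"])["replicate"].nunique()
        if (n_reps < 2).all():
            warnings.warn(f"method {method}: single replicate, QC skipped", stacklevel=2)
            continue
        for (ind, dist), gg in g.groupby(["individual", "distance"], sort=True):
            if qc.small_distance_ids is not None:
                small = dist in qc.small_distance_ids
            else:
                small = means[dist] < qc.small_mean_cutoff
            threshold = qc.small_threshold if small else qc.default_threshold
            reps = gg.sort_values("replicate")
            for (r1, r2) in itertools.combinations(reps.itertuples(), 2):
                if np.isnan(r1.value_mm) or np.isnan(r2.value_mm):
                    continue
                diff = abs(r1.value_mm - r2.value_mm)
                if diff > threshold:
                    rows.append(
                        (ind, method, dist, f"{r1.replicate}-{r2.replicate}", diff, threshold)
                    )
    return QCReport(pd.DataFrame(rows, columns=QCReport.COLUMNS))
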