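"""Leave-one-landmark-out landmark precision.

A plain GPA confounds variation across landmarks: a single highly
variable landmark drags the superimposition and spreads its variance
over the other points.  The leave-one-out estimator avoids this by
excluding the landmark of interest from the superimposition: GPA is run
on the remaining K-1 landmarks, each configuration's fitted similarity
transform (centering by the reduced centroid, scaling by the reduced
centroid size, then its rotation matrix) is applied to the held-out
landmark, and the landmark's deviation is its Euclidean distance from
the mean of the transformed held-out points.  Repeating for every
landmark yields a per-landmark precision profile.

Deviations live in shape space (dimensionless); multiplying by the
sample's mean centroid size in mm restores an interpretable mm scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LandmarkDataset
from .procrustes import centroid_size, gpa


def loo_landmark_deviation(
    configs: list[np.ndarray],
    landmark_k: int,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """Per-configuration shape-space deviation of one held-out landmark.

    Runs GPA on the configurations with landmark ``landmark_k`` deleted,
    maps the held-out landmark of each configuration into shape space
    with that configuration's fitted similarity transform, and returns
    each configuration's distance from its transformed held-out landmark
    to the mean of the transformed held-out landmarks.
    """
    k = configs[0].shape[0]
    if k < 4:
        raise ValueError("need K >= 4 so the reduced configuration supports a rotation")
    if not 0 <= landmark_k < k:
        raise ValueError(f"landmark index {landmark_k} out of range for K={k}")
    reduced = [np.delete(np.asarray(c, dtype=float), landmark_k, axis=0) for c in configs]
    res = gpa(reduced, tol=tol, max_iter=max_iter)
    held = np.array(
        [t.apply(np.asarray(c, dtype=float)[landmark_k]) for c, t in zip(configs, res.transforms)]
    )
    mean_lm = held.mean(axis=0)
    return np.linalg.norm(held - mean_lm, axis=1)


def naive_landmark_deviation(
    configs: list[np.ndarray],
    landmark_k: int,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> np.ndarray:
    """The same deviation statistic from a single all-landmark GPA (no
    exclusion); the contrast against the leave-one-out estimator shows
    how much variance a plain superimposition spreads across landmarks."""
    res = gpa([np.asarray(c, dtype=float) for c in configs], tol=tol, max_iter=max_iter)
    pts = np.array([a[landmark_k] for a in res.aligned])
    return np.linalg.norm(pts - pts.mean(axis=0), axis=1)


@dataclass
class PrecisionResults:
    """Per-landmark precision of one method: mean and SD of individual
    deviations from the mean landmark, in shape space and in mm."""

    method: str
    per_landmark: pd.DataFrame
    # columns: landmark, side, mean_dev_shape, sd_dev_shape, mean_dev_mm, sd_dev_mm, n_configs
    mean_centroid_size_mm: float
    use_sides: str

    def to_frame(self) -> pd.DataFrame:
        return self.per_landmark.copy()

    def deviations_mm(self) -> pd.Series:
        idx = pd.MultiIndex.from_frame(self.per_landmark[["landmark", "side"]])
        return pd.Series(self.per_landmark["mean_dev_mm"].to_numpy(), index=idx)

    def summary(self) -> str:
        dev = self.per_landmark["mean_dev_mm"]
        lines = [
            f"Leave-one-landmark-out precision — method {self.method}",
            f"  configurations: {int(self.per_landmark['n_configs'].iloc[0])}   "
            f"landmarks: {len(self.per_landmark)} ({self.use_sides})",
            f"  mean centroid size: {self.mean_centroid_size_mm:.3f} mm",
            f"  deviation range: {dev.min():.3f} to {dev.max():.3f} mm",
            "",
            self.per_landmark[["landmark", "side", "mean_dev_mm", "sd_dev_mm"]].to_string(
                index=False, float_format=lambda v: f"{v:.4f}"
            ),
        ]
        return "\n".join(lines)


class LandmarkPrecision:
    """Leave-one-landmark-out precision model for one method of a
    replicated landmark dataset.

    ``use_sides='midline_and_left'`` (default) analyses one instance of
    every landmark — the midline points plus the left side — so a
    20-landmark bilateral protocol yields 20 report rows; ``'all'``
    analyses every side-expanded point.
    """

    def __init__(
        self,
        dataset: LandmarkDataset,
        method: str,
        use_sides: str = "midline_and_left",
        tol: float = 1e-10,
        max_iter: int = 100,
    ):
        self.dataset = dataset
        self.method = method
        self.use_sides = use_sides
        self.tol = tol
        self.max_iter = max_iter

        configs = dataset.select(method=method)
        if not configs:
            raise ValueError(f"method {method!r} not in dataset")
        if any(c.units != "mm" for c in configs):
            raise ValueError(
                f"method {method!r} has voxel-unit configurations; run convert_units first"
            )
        self._subset = dataset.scheme.subset_indices(use_sides)
        complete = [c for c in configs if not c.missing[self._subset].any()]
        if len(complete) < 2:
            raise ValueError("need at least 2 configurations with the selected landmarks unmasked")
        self._configs = complete

    def fit(self) -> PrecisionResults:
        exp = self.dataset.scheme.expanded()
        labels = [exp[i] for i in self._subset]
        blocks = [c.coords[self._subset] for c in self._configs]
        mcs = float(np.mean([centroid_size(b) for b in blocks]))
        rows = []
        for local_k, (lid, side) in enumerate(labels):
            dev = loo_landmark_deviation(blocks, local_k, tol=self.tol, max_iter=self.max_iter)
            m, s = float(dev.mean()), float(dev.std(ddof=1))
            rows.append((lid, side, m, s, m * mcs, s * mcs, len(blocks)))
        per = pd.DataFrame(
            rows,
            columns=[
                "landmark",
                "side",
                "mean_dev_shape",
                "sd_dev_shape",
                "mean_dev_mm",
                "sd_dev_mm",
                "n_configs",
            ],
        )
        return PrecisionResults(
            method=self.method,
            per_landmark=per,
            mean_centroid_size_mm=mcs,
            use_sides=self.use_sides,
        )


def landmark_precision_report(
    dataset: LandmarkDataset,
    method: str,
    use_sides: str = "midline_and_left",
    tol: float = 1e-10,
    max_iter: int = 100,
) -> PrecisionResults:
    """Functional spelling of :class:`LandmarkPrecision` + ``fit``."""
    return LandmarkPrecision(dataset, method, use_sides=use_sides, tol=tol, max_iter=max_iter).fit()
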