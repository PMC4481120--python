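"""Ordinary and generalized Procrustes superimposition for 3D landmarks.

Landmark configurations digitized on different specimens (or with
different instruments) live in arbitrary coordinate frames.  Procrustes
superimposition removes location, size and orientation: each
configuration is centred on its centroid, scaled to unit centroid size,
and rotated by the least-squares proper rotation onto a reference.
Generalized Procrustes Analysis (GPA) iterates rotation against an
evolving mean shape until the mean stabilises, producing the shared
shape space in which landmark deviations are measured.

Reflections are always excluded: an anatomical configuration must not
be mirrored to fit its mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def centroid_size(config: np.ndarray) -> float:
    """Centroid size: sqrt of summed squared landmark distances from the
    centroid — the standard size measure of geometric morphometrics.

    Zero iff all landmarks coincide; scales linearly under uniform
    scaling; invariant to rotation and translation.
    """
    config = np.asarray(config, dtype=float)
    if config.ndim != 2 or len(config) < 2:
        raise ValueError("centroid size needs at least 2 landmarks")
    centered = config - config.mean(axis=0)
    return float(np.sqrt(np.sum(centered**2)))


def optimal_rotation(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Least-squares proper rotation R (applied as ``source @ R``)
    minimizing ``||source @ R - target||_F``.

    Kabsch solution via SVD of the cross-covariance; a reflection in the
    raw solution is repaired by flipping the axis of the smallest
    singular value, so det(R) = +1 always.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if source.shape != target.shape:
        raise ValueError("source/target shape mismatch")
    h = source.T @ target  # 3x3 cross-covariance
    u, s, vt = np.linalg.svd(h)
    if s[1] <= 1e-12 * max(s[0], 1.0):
        raise ValueError("degenerate cross-covariance: rotation not identifiable")
    d = np.sign(np.linalg.det(u @ vt))
    if d == 0:
        d = 1.0
    flip = np.ones(3)
    flip[-1] = d
    return u @ np.diag(flip) @ vt


@dataclass
class SimilarityTransform:
    """The similarity transform GPA fitted to one configuration:
    ``aligned = ((X - translation) / scale) @ rotation``."""

    rotation: np.ndarray  # 3x3 proper orthogonal
    scale: float  # centroid size divided out (> 0)
    translation: np.ndarray  # 3-vector: the configuration centroid

    def apply(self, points: np.ndarray) -> np.ndarray:
        """Apply to a point or configuration, in the same translate /
        rescale / rotate order GPA applied to the fitted landmarks."""
        pts = np.asarray(points, dtype=float)
        return ((pts - self.translation) / self.scale) @ self.rotation


# Backwards-friendly functional spelling.
def apply_transform(points: np.ndarray, transform: SimilarityTransform) -> np.ndarray:
    return transform.apply(points)


@dataclass
class GPAResult:
    mean_shape: np.ndarray  # (K, 3), centroid at origin, unit centroid size
    aligned: list[np.ndarray]  # per configuration, shape-space coordinates
    transforms: list[SimilarityTransform]
    mean_centroid_size: float  # mean of the input centroid sizes (data units)
    iterations: int
    converged: bool

    @property
    def n_configs(self) -> int:
        return len(self.aligned)

    def procrustes_distances(self) -> np.ndarray:
        """Per-configuration root summed squared deviation from the mean."""
        return np.array([np.sqrt(np.sum((a - self.mean_shape) ** 2)) for a in self.aligned])

    def total_ss(self) -> float:
        """Summed squared deviation of all aligned configurations from
        the mean shape (the GPA objective)."""
        return float(sum(np.sum((a - self.mean_shape) ** 2) for a in self.aligned))


def gpa(
    configs: list[np.ndarray],
    tol: float = 1e-10,
    max_iter: int = 100,
) -> GPAResult:
    """Generalized Procrustes Analysis with all configurations fixed at
    unit centroid size.

    Algorithm: centre each configuration and scale it to unit centroid
    size; seed the mean with the first configuration's orientation; then
    iterate (rotate every configuration onto the current mean; replace
    the mean by the average of the rotated configurations, renormalized
    to unit centroid size) until the root-mean-square change of the mean
    shape drops below ``tol`` or ``max_iter`` is reached.

    The result is invariant, up to a global rotation of shape space,
    under any rigid motion and positive rescaling applied independently
    to each input.
    """
    if len(configs) < 2:
        raise ValueError("GPA needs at least 2 configurations")
    k = configs[0].shape[0]
    arrs = []
    sizes = []
    for c in configs:
        c = np.asarray(c, dtype=float)
        if c.shape != (k, 3):
            raise ValueError("configurations must share the same K x 3 shape")
        cs = centroid_size(c)
        if cs == 0:
            raise ValueError("degenerate configuration: zero centroid size")
        sizes.append(cs)
        arrs.append((c - c.mean(axis=0)) / cs)

    mean = arrs[0].copy()
    mean = mean / np.sqrt(np.sum(mean**2))
    rotations = [np.eye(3) for _ in arrs]
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        rotated = []
        for i, a in enumerate(arrs):
            r = optimal_rotation(a, mean)
            rotations[i] = r
            rotated.append(a @ r)
        new_mean = np.mean(rotated, axis=0)
        norm = np.sqrt(np.sum((new_mean - new_mean.mean(axis=0)) ** 2))
        if norm == 0:
            raise ValueError("degenerate mean shape (configurations cancel)")
        new_mean = (new_mean - new_mean.mean(axis=0)) / norm
        change = np.sqrt(np.mean((new_mean - mean) ** 2))
        mean = new_mean
        if change < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"GPA did not converge in {max_iter} iterations (last change {change:.2e})",
            stacklevel=2,
        )

    aligned = [a @ r for a, r in zip(arrs, rotations)]
    transforms = [
        SimilarityTransform(rotation=r, scale=s, translation=np.asarray(c, dtype=float).mean(axis=0))
        for r, s, c in zip(rotations, sizes, configs)
    ]
    return GPAResult(
        mean_shape=mean,
        aligned=aligned,
        transforms=transforms,
        mean_centroid_size=float(np.mean(sizes)),
        iterations=iterations,
        converged=converged,
    )
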