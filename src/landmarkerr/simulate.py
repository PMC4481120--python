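"""Synthetic replicated landmark datasets with known ground truth.

The generator emulates a replicated multi-method measurement study: a
fixed template shape (a bilaterally symmetric, roughly 20 mm toad-skull
configuration by default), individual shapes drawn around the template
(per-coordinate Gaussian shape jitter plus a per-individual size
factor), and one digitization per (individual, method, replicate)
obtained by adding the method's fixed per-landmark bias and independent
per-landmark Gaussian digitizing error.  Each digitization can live in
its own arbitrary rigid frame (random rotation and translation), as it
would coming off a digitizer arm; an optional nuisance *scale* per
frame is available to exercise the full similarity invariance of the
superimposition machinery, but is off by default because a calibrated
instrument does not distort real distances.  Voxel-unit methods are
emitted in voxel coordinates awaiting unit conversion.

Because individual size varies while digitizing error is an additive
mm-scale noise, short distances carry proportionally more error than
long ones — the mechanism that links distance repeatability to distance
length.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import LandmarkConfiguration, LandmarkDataset
from .schemes import DistanceScheme, LandmarkScheme, default_schemes

# Template coordinates (mm): x runs anterior -> posterior, y is the
# left(+)/right(-) axis, z is dorsal height.  Spans ~19 mm total length.
_TOAD_MIDLINE = {
    1: (0.5, 0.0, 3.0),
    2: (8.0, 0.0, 4.0),
    3: (17.0, 0.0, 4.2),
    13: (10.0, 0.0, 0.5),
    14: (19.0, 0.0, 0.3),
}
_TOAD_LEFT = {
    4: (3.0, 5.0, 2.5),
    5: (8.5, 2.8, 3.8),
    6: (14.5, 5.5, 3.5),
    7: (17.5, 4.5, 3.0),
    8: (18.5, 6.0, 2.0),
    9: (17.8, 1.5, 3.8),
    10: (1.0, 2.5, 2.0),
    11: (3.0, 3.5, 1.8),
    12: (16.0, 7.5, 1.0),
    15: (0.8, 1.5, 0.5),
    16: (2.0, 3.0, 0.6),
    17: (12.5, 6.5, 0.4),
    18: (8.0, 2.5, 0.5),
    19: (17.0, 5.0, 0.2),
    20: (17.5, 2.0, 0.4),
}


def make_template(style: str = "toad_like", k: int | None = None, seed: int | None = None) -> np.ndarray:
    """A K x 3 mean shape in mm.

    ``toad_like`` returns the fixed 35-point bilaterally symmetric
    configuration matching the bundled 20-landmark scheme (left and
    right point sets are exact mirror images about the y = 0 midline
    plane).  ``random`` draws a well-conditioned K-point configuration.
    """
    if style == "toad_like":
        scheme, _ = default_schemes()
        if k is not None and k != scheme.k_total:
            raise ValueError(f"toad_like template has K={scheme.k_total}, requested {k}")
        rows = []
        for lid, side in scheme.expanded():
            if side == "M":
                rows.append(_TOAD_MIDLINE[lid])
            elif side == "L":
                rows.append(_TOAD_LEFT[lid])
            else:
                x, y, z = _TOAD_LEFT[lid]
                rows.append((x, -y, z))
        return np.array(rows, dtype=float)
    if style == "random":
        if k is None or k < 4:
            raise ValueError("random template needs K >= 4")
        rng = np.random.default_rng(seed)
        for _ in range(100):
            pts = rng.normal(scale=5.0, size=(k, 3))
            centered = pts - pts.mean(axis=0)
            if np.linalg.svd(centered, compute_uv=False)[2] > 1e-3:
                return pts
        raise RuntimeError("failed to draw a well-conditioned template")
    raise ValueError(f"unknown template style {style!r}")


@dataclass
class MethodSpec:
    """One measurement method: its per-landmark digitizing error SD
    (mm), an optional fixed per-landmark bias (mm, K x 3), and the unit
    system its coordinates are reported in."""

    label: str
    err_sd: float | np.ndarray = 0.1  # mm; scalar or per-landmark (K,)
    bias: np.ndarray | None = None  # (K, 3) mm, fixed across individuals/replicates
    units: str = "mm"  # mm | voxel
    mm_per_unit: float = 1.0

    def err_sd_vector(self, k: int) -> np.ndarray:
        v = np.broadcast_to(np.asarray(self.err_sd, dtype=float), (k,)).copy()
        if (v < 0).any():
            raise ValueError("error SDs must be >= 0")
        return v

    def bias_matrix(self, k: int) -> np.ndarray:
        if self.bias is None:
            return np.zeros((k, 3))
        b = np.asarray(self.bias, dtype=float)
        if b.shape != (k, 3):
            raise ValueError(f"bias must be (K, 3) = ({k}, 3), got {b.shape}")
        return b


@dataclass
class SimulationParams:
    """Design and error model of a simulated study.

    Defaults mirror the reference design: 20 individuals, 2 replicates
    per individual per method, three methods — a digitizer arm (DIG, mm
    units) and two CT resolutions (MED, HIGH) in voxel units with their
    mm-per-voxel factors — with per-landmark digitizing error SDs on
    the order of 0.1-0.2 mm, individual shape jitter of 0.15 mm per
    coordinate and an 8 % individual size CV.
    """

    n_individuals: int = 20
    n_replicates: int = 2
    methods: list[MethodSpec] = field(default_factory=lambda: [
        MethodSpec("DIG", err_sd=0.20, units="mm"),
        MethodSpec("MED", err_sd=0.11, units="voxel", mm_per_unit=0.01742),
        MethodSpec("HIGH", err_sd=0.10, units="voxel", mm_per_unit=0.00871),
    ])
    individual_sd: float = 0.15  # mm per coordinate, shape variation
    individual_scale_sd: float = 0.08  # CV of individual size
    template: np.ndarray | None = None  # K x 3 mm; toad_like when None
    rigid_nuisance: bool = True  # every digitization in its own rigid frame
    scale_nuisance: bool = False  # also distort each frame's scale (uniform [0.9, 1.1])
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.n_replicates < 1:
            raise ValueError("need >= 1 individual and replicate")
        if not self.methods:
            raise ValueError("need >= 1 method")
        if self.individual_sd < 0 or self.individual_scale_sd < 0:
            raise ValueError("SDs must be >= 0")

    def resolved_template(self) -> np.ndarray:
        return make_template("toad_like") if self.template is None else np.asarray(self.template, dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth behind a simulated dataset."""

    template: np.ndarray  # (K, 3) mm
    individual_shapes: np.ndarray  # (n, K, 3) mm, size factor applied
    size_factors: np.ndarray  # (n,)
    err_sd: dict[str, np.ndarray]  # method -> (K,) mm
    bias: dict[str, np.ndarray]  # method -> (K, 3) mm
    seed: int


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q = q * np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def random_method_biases(k: int, sd: float, seed: int | np.random.Generator) -> np.ndarray:
    """Draw a fixed per-landmark bias field: K independent 3-vectors
    with per-coordinate SD ``sd`` mm."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return rng.normal(scale=sd, size=(k, 3))


def simulate_dataset(params: SimulationParams) -> tuple[LandmarkDataset, SyntheticTruth]:
    """Generate a replicated multi-method dataset and its ground truth.

    Byte-identically reproducible from (params, params.seed).
    """
    template = params.resolved_template()
    k = len(template)
    if params.template is None:
        scheme, dist_scheme = default_schemes()
    else:
        from .schemes import LandmarkScheme, SchemeEntry

        scheme = LandmarkScheme(
            tuple(SchemeEntry(i + 1, f"landmark {i + 1}", "midline", "I") for i in range(k))
        )
        dist_scheme = None
    rng = np.random.default_rng(params.seed)

    centroid = template.mean(axis=0)
    size_factors = 1.0 + rng.normal(scale=params.individual_scale_sd, size=params.n_individuals)
    shapes = np.empty((params.n_individuals, k, 3))
    for i in range(params.n_individuals):
        jitter = rng.normal(scale=params.individual_sd, size=(k, 3)) if params.individual_sd > 0 else 0.0
        shapes[i] = centroid + (template - centroid + jitter) * size_factors[i]

    err_sd = {m.label: m.err_sd_vector(k) for m in params.methods}
    bias = {m.label: m.bias_matrix(k) for m in params.methods}

    width = len(str(params.n_individuals))
    configs = []
    for i in range(params.n_individuals):
        ind = f"ind{i + 1:0{width}d}"
        for m in params.methods:
            for rep in range(1, params.n_replicates + 1):
                noise = rng.normal(size=(k, 3)) * err_sd[m.label][:, None]
                coords = shapes[i] + bias[m.label] + noise
                if params.rigid_nuisance:
                    rot = _random_rotation(rng)
                    trans = rng.uniform(-10.0, 10.0, size=3)
                    scale = rng.uniform(0.9, 1.1) if params.scale_nuisance else 1.0
                    coords = scale * (coords @ rot.T) + trans
                if m.units == "voxel":
                    coords = coords / m.mm_per_unit
                configs.append(
                    LandmarkConfiguration(ind, m.label, rep, coords, units=m.units)
                )
    dataset = LandmarkDataset(configs, scheme, dist_scheme)
    truth = SyntheticTruth(
        template=template,
        individual_shapes=shapes,
        size_factors=size_factors,
        err_sd=err_sd,
        bias=bias,
        seed=params.seed,
    )
    return dataset, truth


def _distance_gradients(
    template: np.ndarray, scheme: LandmarkScheme, entry
) -> tuple[dict[int, np.ndarray], float]:
    """Gradient of the (bilaterally averaged) distance with respect to
    every expanded landmark, at the template; plus the template value."""
    a_mid = scheme.is_midline(entry.landmark_a)
    b_mid = scheme.is_midline(entry.landmark_b)
    sides = ["M"] if (a_mid and b_mid) else ["L", "R"]
    w = 1.0 / len(sides)
    grads: dict[int, np.ndarray] = {}
    value = 0.0
    for side in sides:
        ia = scheme.index_of(entry.landmark_a, "M" if a_mid else side)
        ib = scheme.index_of(entry.landmark_b, "M" if b_mid else side)
        diff = template[ia] - template[ib]
        d = np.linalg.norm(diff)
        if d == 0:
            raise ValueError(f"degenerate template distance {entry.distance_id}")
        u = diff / d
        value += w * d
        grads[ia] = grads.get(ia, np.zeros(3)) + w * u
        grads[ib] = grads.get(ib, np.zeros(3)) - w * u
    return grads, float(value)


def expected_repeatability(
    params: SimulationParams,
    method: str | None = None,
    scheme: LandmarkScheme | None = None,
    distance_scheme: DistanceScheme | None = None,
) -> dict[int, float]:
    """Delta-method prediction of per-distance within-method
    repeatability under the generator's model.

    Valid only for bias-free methods (a fixed bias breaks the one-way
    variance decomposition the prediction rests on): returns
    sigma2_ind,d / (sigma2_ind,d + sigma2_err,d) with the distance-level
    variances propagated from the coordinate-level SDs along the
    inter-landmark directions (bilateral averaging and midline-shared
    endpoints accounted for via the gradient).
    """
    if scheme is None or distance_scheme is None:
        s, d = default_schemes()
        scheme = scheme or s
        distance_scheme = distance_scheme or d
    spec = params.methods[0] if method is None else next(m for m in params.methods if m.label == method)
    template = params.resolved_template()
    k = len(template)
    if spec.bias is not None and np.any(spec.bias_matrix(k) != 0):
        raise ValueError("expected_repeatability is invalid for biased methods")
    sd_err = spec.err_sd_vector(k)
    out: dict[int, float] = {}
    for e in distance_scheme.entries:
        grads, value = _distance_gradients(template, scheme, e)
        v_err = sum(sd_err[i] ** 2 * float(g @ g) for i, g in grads.items())
        v_shape = params.individual_sd**2 * sum(float(g @ g) for g in grads.values())
        v_size = (params.individual_scale_sd * value) ** 2
        v_ind = v_shape + v_size
        total = v_ind + v_err
        out[e.distance_id] = v_ind / total if total > 0 else 0.0
    return out
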