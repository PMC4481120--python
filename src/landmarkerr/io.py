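"""Reading, writing and unit handling for replicated landmark data.

The reference on-disk dialect is a long-format CSV with header
``individual,method,replicate,landmark,side,x,y,z`` (side in M/L/R, one
row per digitized point).  Two import conveniences are supported: a
whitespace ``x y z`` TXT block (one file per digitization, metadata
parsed from a ``<individual>_<method>_<replicate>.txt`` filename) and
TPS files with LM3 records.

Coordinates may arrive in voxel units (points clicked on CT
cross-sections); :func:`convert_units` rescales a method's
configurations to mm with the scan resolution's mm-per-voxel factor.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schemes import DistanceScheme, LandmarkScheme, default_schemes, scheme_from_observed

LONG_CSV_COLUMNS = ["individual", "method", "replicate", "landmark", "side", "x", "y", "z"]


@dataclass
class LandmarkConfiguration:
    """One digitization event: a K x 3 coordinate block for one
    individual / method / replicate, plus a per-landmark missing mask."""

    individual_id: str
    method: str
    replicate: int
    coords: np.ndarray  # (K, 3) float64
    units: str = "mm"  # mm | voxel
    missing: np.ndarray | None = None  # (K,) bool, True = not digitized

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"coords must be (K, 3), got {self.coords.shape}")
        if self.units not in ("mm", "voxel"):
            raise ValueError(f"units must be mm or voxel, got {self.units!r}")
        if self.missing is None:
            self.missing = np.zeros(len(self.coords), dtype=bool)
        else:
            self.missing = np.asarray(self.missing, dtype=bool)
            if self.missing.shape != (len(self.coords),):
                raise ValueError("missing mask shape mismatch")
        present = self.coords[~self.missing]
        if not np.all(np.isfinite(present)):
            raise ValueError(
                f"non-finite coordinates in unmasked landmarks of "
                f"({self.individual_id}, {self.method}, {self.replicate})"
            )

    @property
    def k_total(self) -> int:
        return len(self.coords)

    @property
    def complete(self) -> bool:
        return not bool(self.missing.any())

    def key(self) -> tuple[str, str, int]:
        return (self.individual_id, self.method, self.replicate)


@dataclass
class LandmarkDataset:
    """The full replicated study table plus its protocol metadata."""

    configurations: list[LandmarkConfiguration]
    scheme: LandmarkScheme
    distance_scheme: DistanceScheme | None = None
    unit_factors: dict[str, float] = field(default_factory=dict)  # method -> mm per unit

    def __post_init__(self) -> None:
        k = self.scheme.k_total
        for c in self.configurations:
            if c.k_total != k:
                raise ValueError(
                    f"configuration {c.key()} has {c.k_total} landmarks, scheme expects {k}"
                )
        seen = set()
        for c in self.configurations:
            if c.key() in seen:
                raise ValueError(f"duplicate configuration {c.key()}")
            seen.add(c.key())
        self.configurations.sort(key=lambda c: c.key())

    @property
    def k_total(self) -> int:
        return self.scheme.k_total

    @property
    def methods(self) -> list[str]:
        return sorted({c.method for c in self.configurations})

    @property
    def individuals(self) -> list[str]:
        return sorted({c.individual_id for c in self.configurations})

    def select(self, method: str | None = None, individual: str | None = None) -> list[LandmarkConfiguration]:
        out = self.configurations
        if method is not None:
            out = [c for c in out if c.method == method]
        if individual is not None:
            out = [c for c in out if c.individual_id == individual]
        return out

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per digitized point, canonical order."""
        exp = self.scheme.expanded()
        rows = []
        for c in self.configurations:
            for idx, (lid, side) in enumerate(exp):
                x, y, z = c.coords[idx]
                if c.missing[idx]:
                    x = y = z = np.nan
                rows.append((c.individual_id, c.method, c.replicate, lid, side, x, y, z))
        return pd.DataFrame(rows, columns=LONG_CSV_COLUMNS)

    def equals(self, other: "LandmarkDataset") -> bool:
        if len(self.configurations) != len(other.configurations):
            return False
        for a, b in zip(self.configurations, other.configurations):
            if a.key() != b.key() or a.units != b.units:
                return False
            if not np.array_equal(a.missing, b.missing):
                return False
            if not np.array_equal(a.coords[~a.missing], b.coords[~b.missing]):
                return False
        return self.scheme.expanded() == other.scheme.expanded()


# -- reading ---------------------------------------------------------------


def _configs_from_long(df: pd.DataFrame, scheme: LandmarkScheme | None) -> tuple[list[LandmarkConfiguration], LandmarkScheme]:
    missing_cols = [c for c in LONG_CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"long_csv missing columns {missing_cols}")
    dup = df.duplicated(subset=["individual", "method", "replicate", "landmark", "side"])
    if dup.any():
        bad = df.loc[dup.idxmax(), ["individual", "method", "replicate", "landmark", "side"]]
        raise ValueError(f"duplicate row for {tuple(bad)}")
    if scheme is None:
        pairs = list({(int(r.landmark), str(r.side)) for r in df.itertuples()})
        scheme = scheme_from_observed(pairs)
    exp = scheme.expanded()
    index = {pair: i for i, pair in enumerate(exp)}
    configs = []
    grouped = df.groupby(["individual", "method", "replicate"], sort=True)
    expected_n: int | None = None
    for (ind, method, rep), g in grouped:
        if expected_n is None:
            expected_n = len(g)
        elif len(g) != expected_n:
            raise ValueError(
                f"ragged landmark count: configuration ({ind}, {method}, {rep}) "
                f"has {len(g)} rows, expected {expected_n}"
            )
        coords = np.zeros((len(exp), 3))
        mask = np.ones(len(exp), dtype=bool)
        for r in g.itertuples():
            key = (int(r.landmark), str(r.side))
            if key not in index:
                raise ValueError(f"row references ({key}) absent from scheme")
            i = index[key]
            xyz = np.array([r.x, r.y, r.z], dtype=float)
            if np.isnan(xyz).all():
                continue  # serialized NA -> masked
            coords[i] = xyz
            mask[i] = False
        configs.append(
            LandmarkConfiguration(str(ind), str(method), int(rep), coords, "mm", mask)
        )
    return configs, scheme


_TXT_NAME = re.compile(r"^(?P<ind>.+)_(?P<method>[^_]+)_(?P<rep>\d+)\.txt$")


def _read_txt_block(path: str) -> LandmarkConfiguration:
    name = os.path.basename(path)
    m = _TXT_NAME.match(name)
    if m is None:
        raise ValueError(
            f"txt_block filename {name!r} does not match '<individual>_<method>_<replicate>.txt'"
        )
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 3:
                raise ValueError(f"{name}: expected 'x y z' per line, got {line!r}")
            rows.append([float("nan") if p.upper() == "NA" else float(p) for p in parts])
    coords = np.array(rows, dtype=float)
    mask = np.isnan(coords).any(axis=1)
    coords[mask] = 0.0
    return LandmarkConfiguration(
        m.group("ind"), m.group("method"), int(m.group("rep")), coords, "mm", mask
    )


def _read_tps(path: str, method: str, replicate: int) -> list[LandmarkConfiguration]:
    configs: list[LandmarkConfiguration] = []
    coords: list[list[float]] = []
    ident: str | None = None
    expecting = 0

    def flush() -> None:
        nonlocal coords, ident
        if expecting and coords:
            arr = np.array(coords, dtype=float)
            mask = np.isnan(arr).any(axis=1)
            arr[mask] = 0.0
            configs.append(
                LandmarkConfiguration(ident or f"specimen{len(configs) + 1}", method, replicate, arr, "mm", mask)
            )
        coords, ident = [], None

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            upper = line.upper()
            if upper.startswith("LM3="):
                flush()
                expecting = int(line.split("=", 1)[1])
            elif upper.startswith("ID="):
                ident = line.split("=", 1)[1].strip()
            elif "=" in line and not line[0].isdigit() and not line[0] in "-+.":
                continue  # IMAGE=, SCALE= ... ignored
            else:
                coords.append([float(p) for p in line.split()])
    flush()
    return configs


def read_landmark_table(
    path: str,
    dialect: str = "long_csv",
    scheme: LandmarkScheme | None = None,
    distance_scheme: DistanceScheme | None = None,
    method: str | None = None,
    replicate: int = 1,
    units: str = "mm",
) -> LandmarkDataset:
    """Read replicated landmark data into a :class:`LandmarkDataset`.

    ``dialect`` is one of ``long_csv`` (the reference format),
    ``txt_block`` (a file, or a directory of files, of whitespace
    ``x y z`` lines) or ``tps`` (LM3 records; ``method``/``replicate``
    must be supplied since TPS carries neither).

    Row order in the input never affects the result: configurations and
    landmark slots are put in canonical order (individual/method/
    replicate keys sorted; landmarks ordered midline-then-left-then-
    right by ascending id).
    """
    if dialect == "long_csv":
        df = pd.read_csv(path, float_precision="round_trip")
        configs, scheme = _configs_from_long(df, scheme)
    elif dialect == "txt_block":
        if os.path.isdir(path):
            files = sorted(f for f in os.listdir(path) if f.endswith(".txt"))
            configs = [_read_txt_block(os.path.join(path, f)) for f in files]
        else:
            configs = [_read_txt_block(path)]
        if scheme is None:
            if configs and configs[0].k_total == 35:
                scheme, default_dist = default_schemes()
                distance_scheme = distance_scheme or default_dist
            else:
                raise ValueError(
                    "txt_block carries no landmark metadata; pass scheme= "
                    "(the bundled 35-point scheme is assumed only for K=35 files)"
                )
    elif dialect == "tps":
        if method is None:
            raise ValueError("tps dialect requires method=")
        configs = _read_tps(path, method, replicate)
        if scheme is None:
            raise ValueError("tps dialect requires scheme=")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    if units == "voxel":
        for c in configs:
            c.units = "voxel"
    if distance_scheme is None:
        default_scheme, default_dist = default_schemes()
        if scheme.expanded() == default_scheme.expanded():
            distance_scheme = default_dist  # bundled 24-distance protocol
    return LandmarkDataset(configs, scheme, distance_scheme)


def write_landmark_table(dataset: LandmarkDataset, path: str, dialect: str = "long_csv") -> None:
    """Serialize a dataset; ``read_landmark_table`` round-trips it exactly.

    Masked landmarks are written as NA and recovered as masked.
    """
    if dialect == "long_csv":
        df = dataset.to_frame()
        # %.17g guarantees bit-exact float round-trips
        df.to_csv(path, index=False, na_rep="NA", float_format="%.17g")
    elif dialect == "txt_block":
        os.makedirs(path, exist_ok=True)
        for c in dataset.configurations:
            fn = os.path.join(path, f"{c.individual_id}_{c.method}_{c.replicate}.txt")
            with open(fn, "w") as fh:
                for i, row in enumerate(c.coords):
                    if c.missing[i]:
                        fh.write("NA NA NA\n")
                    else:
                        fh.write(f"{row[0]:.17g} {row[1]:.17g} {row[2]:.17g}\n")
    else:
        raise ValueError(f"unsupported write dialect {dialect!r}")


def convert_units(dataset: LandmarkDataset, method: str, factor: float) -> LandmarkDataset:
    """Rescale one method's voxel coordinates to mm.

    ``factor`` is the mm-per-voxel size of the scan resolution (0.01742
    for the medium-resolution scans, 0.00871 for high resolution).
    Converting a method already in mm is refused, so the operation
    cannot be applied twice.
    """
    if factor <= 0:
        raise ValueError("factor must be > 0")
    targets = dataset.select(method=method)
    if not targets:
        raise ValueError(f"no configurations for method {method!r}")
    if any(c.units == "mm" for c in targets):
        raise ValueError(f"method {method!r} is already in mm; refusing to convert twice")
    new_configs = []
    for c in dataset.configurations:
        if c.method == method:
            new_configs.append(
                LandmarkConfiguration(
                    c.individual_id, c.method, c.replicate, c.coords * factor, "mm", c.missing.copy()
                )
            )
        else:
            new_configs.append(
                LandmarkConfiguration(
                    c.individual_id, c.method, c.replicate, c.coords.copy(), c.units, c.missing.copy()
                )
            )
    factors = dict(dataset.unit_factors)
    factors[method] = factor
    return LandmarkDataset(new_configs, dataset.scheme, dataset.distance_scheme, factors)
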