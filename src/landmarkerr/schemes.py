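"""Landmark and distance schemes.

A landmark scheme describes the measurement protocol: which anatomical
points are digitized, whether each lies on the midline or is present on
both sides of the skull, and whether it is a type I landmark (an
intersection of bone sutures) or a type II landmark (the tip of a bone
or point of maximal curvature).  Bilateral landmarks share one id and
appear twice in a scheme, once per side.

The distance scheme lists the inter-landmark distances extracted from a
configuration, each defined by a pair of landmark ids and labelled with
the bone (or structure) it measures.
"""

from __future__ import annotations

from dataclasses import dataclass, field

MIDLINE = "midline"
LEFT = "left"
RIGHT = "right"

_SIDE_CODE = {MIDLINE: "M", LEFT: "L", RIGHT: "R"}
_CODE_SIDE = {v: k for k, v in _SIDE_CODE.items()}


@dataclass(frozen=True)
class SchemeEntry:
    landmark_id: int
    name: str
    position: str  # midline | left | right
    landmark_type: str  # I | II

    def __post_init__(self) -> None:
        if self.position not in (MIDLINE, LEFT, RIGHT):
            raise ValueError(f"invalid position {self.position!r}")
        if self.landmark_type not in ("I", "II"):
            raise ValueError(f"invalid landmark type {self.landmark_type!r}")


@dataclass(frozen=True)
class LandmarkScheme:
    """The landmark protocol: ids, names, sides and types.

    Invariants: landmark ids are unique per side and contiguous from 1;
    every left entry has a right partner with the same id; midline
    entries have no side partner.
    """

    entries: tuple[SchemeEntry, ...]

    def __post_init__(self) -> None:
        ids = sorted({e.landmark_id for e in self.entries})
        if not ids:
            raise ValueError("empty landmark scheme")
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError(f"landmark ids not contiguous from 1: {ids}")
        by_id: dict[int, set[str]] = {}
        for e in self.entries:
            sides = by_id.setdefault(e.landmark_id, set())
            if e.position in sides:
                raise ValueError(f"duplicate entry for landmark {e.landmark_id} ({e.position})")
            sides.add(e.position)
        for lid, sides in by_id.items():
            if sides == {MIDLINE}:
                continue
            if sides != {LEFT, RIGHT}:
                raise ValueError(
                    f"landmark {lid}: sides must be midline alone or a left/right pair, got {sorted(sides)}"
                )

    # -- derived structure ------------------------------------------------

    @property
    def midline_ids(self) -> tuple[int, ...]:
        return tuple(sorted({e.landmark_id for e in self.entries if e.position == MIDLINE}))

    @property
    def bilateral_ids(self) -> tuple[int, ...]:
        return tuple(sorted({e.landmark_id for e in self.entries if e.position != MIDLINE}))

    @property
    def n_landmarks(self) -> int:
        """Number of distinct landmark ids (bilateral pairs counted once)."""
        return len({e.landmark_id for e in self.entries})

    @property
    def k_total(self) -> int:
        """Side-expanded landmark count (bilateral landmarks counted twice)."""
        return len(self.midline_ids) + 2 * len(self.bilateral_ids)

    def expanded(self) -> tuple[tuple[int, str], ...]:
        """Canonical side-expanded ordering: (id, side-code) pairs.

        Midline ids first in ascending id order, then left ids, then
        right ids.  This ordering defines row indices of every
        coordinate matrix in the package and is a pure function of the
        scheme, never of file row order.
        """
        out = [(i, "M") for i in self.midline_ids]
        out += [(i, "L") for i in self.bilateral_ids]
        out += [(i, "R") for i in self.bilateral_ids]
        return tuple(out)

    def index_of(self, landmark_id: int, side: str) -> int:
        try:
            return self.expanded().index((landmark_id, side))
        except ValueError:
            raise KeyError(f"landmark ({landmark_id}, {side}) not in scheme") from None

    def is_midline(self, landmark_id: int) -> bool:
        return landmark_id in self.midline_ids

    def type_of(self, landmark_id: int) -> str:
        for e in self.entries:
            if e.landmark_id == landmark_id:
                return e.landmark_type
        raise KeyError(landmark_id)

    def subset_indices(self, use_sides: str = "midline_and_left") -> list[int]:
        """Row indices of the landmark subset used for precision analyses.

        ``midline_and_left`` keeps one instance of every landmark
        (midline plus left side), avoiding the double-counting of the
        bilaterally mirrored points; ``all`` keeps everything.
        """
        exp = self.expanded()
        if use_sides == "all":
            return list(range(len(exp)))
        if use_sides == "midline_and_left":
            return [i for i, (_, s) in enumerate(exp) if s in ("M", "L")]
        raise ValueError(f"unknown use_sides {use_sides!r}")


@dataclass(frozen=True)
class DistanceEntry:
    distance_id: int
    landmark_a: int
    landmark_b: int
    label: str


@dataclass(frozen=True)
class DistanceScheme:
    entries: tuple[DistanceEntry, ...]

    def __post_init__(self) -> None:
        ids = [e.distance_id for e in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate distance ids")
        for e in self.entries:
            if e.landmark_a == e.landmark_b:
                raise ValueError(f"distance {e.distance_id}: identical endpoints")

    def validate_against(self, scheme: LandmarkScheme) -> None:
        known = set(scheme.midline_ids) | set(scheme.bilateral_ids)
        for e in self.entries:
            for lid in (e.landmark_a, e.landmark_b):
                if lid not in known:
                    raise ValueError(
                        f"distance {e.distance_id} references unknown landmark {lid}"
                    )

    @property
    def distance_ids(self) -> tuple[int, ...]:
        return tuple(e.distance_id for e in self.entries)

    def entry(self, distance_id: int) -> DistanceEntry:
        for e in self.entries:
            if e.distance_id == distance_id:
                return e
        raise KeyError(distance_id)


# -- bundled toad-skull schemes -------------------------------------------

_TOAD_LANDMARKS: list[tuple[int, str, str, str]] = [
    # (id, name, position, type)
    (1, "anterior tip of nasal bone", MIDLINE, "II"),
    (2, "nasal and frontoparietal suture", MIDLINE, "I"),
    (3, "posterior tip of frontoparietal suture", MIDLINE, "I"),
    (4, "nasal and maxillary suture", "bilateral", "I"),
    (5, "nasal and frontoparietal lateral suture", "bilateral", "I"),
    (6, "frontoparietal and squamosal suture", "bilateral", "I"),
    (7, "frontoparietal, squamosal and occipital suture", "bilateral", "I"),
    (8, "squamosal and occipital suture", "bilateral", "I"),
    (9, "frontoparietal and occipital suture", "bilateral", "I"),
    (10, "prenasal and maxillary lateral suture", "bilateral", "I"),
    (11, "nasal and maxillary lateral suture", "bilateral", "I"),
    (12, "squamosal and maxillary suture", "bilateral", "I"),
    (13, "sphenethmoid and parasphenoid suture", MIDLINE, "I"),
    (14, "posterior tip of parasphenoid corpus", MIDLINE, "II"),
    (15, "anterior tip of premaxillary bone", "bilateral", "II"),
    (16, "premaxillary and maxillary suture", "bilateral", "I"),
    (17, "pterygoid and maxillary suture", "bilateral", "I"),
    (18, "neopalatine and sphenethmoid suture", "bilateral", "I"),
    (19, "tip of pterygoid process", "bilateral", "II"),
    (20, "pterygoid and parasphenoid suture", "bilateral", "I"),
]

_TOAD_DISTANCES: list[tuple[int, int, int, str]] = [
    (1, 1, 2, "nasal"),
    (2, 2, 3, "frontoparietal"),
    (3, 1, 4, "nasal"),
    (4, 1, 5, "nasal"),
    (5, 2, 5, "frontoparietal"),
    (6, 5, 6, "frontoparietal"),
    (7, 4, 6, "orbit"),
    (8, 6, 8, "squamosal"),
    (9, 7, 9, "occipital"),
    (10, 3, 9, "frontoparietal"),
    (11, 1, 10, "prenasal"),
    (12, 1, 11, "nasal"),
    (13, 10, 11, "nasal"),
    (14, 5, 11, "nasal"),
    (15, 10, 12, "maxilla"),
    (16, 8, 12, "squamosal"),
    (17, 13, 14, "parasphenoid"),
    (18, 13, 20, "parasphenoid"),
    (19, 15, 16, "premaxilla"),
    (20, 16, 17, "nasal"),
    (21, 17, 18, "neopalatine"),
    (22, 17, 19, "pterygoid"),
    (23, 19, 20, "pterygoid"),
    (24, 14, 20, "parasphenoid"),
]


def default_schemes() -> tuple[LandmarkScheme, DistanceScheme]:
    """The bundled toad-skull protocol: 20 landmarks (5 midline, 15
    bilateral; 35 points counting both sides) and 24 linear distances."""
    entries: list[SchemeEntry] = []
    for lid, name, pos, typ in _TOAD_LANDMARKS:
        if pos == MIDLINE:
            entries.append(SchemeEntry(lid, name, MIDLINE, typ))
        else:
            entries.append(SchemeEntry(lid, name, LEFT, typ))
            entries.append(SchemeEntry(lid, name, RIGHT, typ))
    scheme = LandmarkScheme(tuple(entries))
    dist = DistanceScheme(
        tuple(DistanceEntry(d, a, b, label) for d, a, b, label in _TOAD_DISTANCES)
    )
    dist.validate_against(scheme)
    return scheme, dist


def scheme_from_observed(pairs: list[tuple[int, str]]) -> LandmarkScheme:
    """Build a minimal scheme from observed (landmark_id, side-code) pairs.

    Used when reading files that carry no protocol metadata: ids seen
    with side ``M`` become midline landmarks, ids seen with ``L``/``R``
    become bilateral pairs.  Landmark type defaults to I.
    """
    sides: dict[int, set[str]] = {}
    for lid, code in pairs:
        sides.setdefault(int(lid), set()).add(code)
    entries: list[SchemeEntry] = []
    for lid in sorted(sides):
        s = sides[lid]
        if s == {"M"}:
            entries.append(SchemeEntry(lid, f"landmark {lid}", MIDLINE, "I"))
        elif s <= {"L", "R"}:
            entries.append(SchemeEntry(lid, f"landmark {lid}", LEFT, "I"))
            entries.append(SchemeEntry(lid, f"landmark {lid}", RIGHT, "I"))
        else:
            raise ValueError(f"landmark {lid} seen with inconsistent sides {sorted(s)}")
    return LandmarkScheme(tuple(entries))
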