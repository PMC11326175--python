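"""Visual-field geometry for a swimming larva.

A focal fish perceives neighbors and projected dots through two lateral
eyes whose combined horizontal field spans +/-165 deg around the heading,
leaving a 30 deg blind zone behind the animal.  Each object is summarized
by its horizontal bearing and the vertical angular extent ("vertical
retinal occupancy") it subtends, ``2 * arctan(H / d)`` for an object of
half-extent ``H`` at center distance ``d``.  Occupancy profiles feed the
turning policy (:mod:`zfschool.policy`), and frame-to-frame increases in
occupancy define the looming signal integrated by the internal state
(:mod:`zfschool.state`).

Conventions
-----------
* Positions in cm, angles in degrees.
* Headings are counter-clockwise positive with 0 along the arena +x axis
  and are wrapped to (-180, 180].
* Positive bearings lie to the *left* of the heading; an object at
  exactly 0 deg is assigned to the right eye (deterministic tie-break).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

FIELD_LIMIT_DEG = 165.0
RASTER_DEG = 1.0

__all__ = [
    "BodyPose",
    "VisualObject",
    "OccupancyProfile",
    "LoomingSignal",
    "wrap_angle",
    "relative_bearing",
    "vertical_occupancy",
    "occupancy_profile",
    "looming_input",
]


def wrap_angle(angle_deg):
    """Wrap angles (degrees) to the half-open interval (-180, 180]."""
    return 180.0 - np.mod(180.0 - np.asarray(angle_deg, dtype=float), 360.0)


@dataclass(frozen=True)
class BodyPose:
    """Planar pose of a fish: position (cm) and heading (deg, CCW, 0 = +x)."""

    x: float
    y: float
    heading_deg: float

    def __post_init__(self):
        object.__setattr__(self, "heading_deg", float(wrap_angle(self.heading_deg)))

    @property
    def xy(self) -> np.ndarray:
        return np.array([self.x, self.y], dtype=float)


@dataclass(frozen=True)
class VisualObject:
    """A visible scene element: a neighboring fish or a projected dot.

    ``half_extent`` is radius-like (cm): dot radius, or the fish-height
    parameter for conspecifics; the vertical occupancy of the object at
    distance ``d`` is ``2*arctan(half_extent/d)``.
    """

    x: float
    y: float
    half_extent: float
    kind: Literal["agent", "dot"] = "dot"
    obj_id: int = 0

    def __post_init__(self):
        if not self.half_extent > 0:
            raise ValueError("half_extent must be > 0")


@dataclass
class OccupancyProfile:
    """Per-eye samples of (bearing, vertical occupancy, source object).

    In ``per_object`` mode there is one sample per visible object at its
    center bearing.  In ``rasterized`` mode bearings form a fixed 1 deg
    grid over the eye's field and each covered cell carries the vertical
    occupancy of the *nearest* object covering it (occlusion-corrected).
    """

    eye: Literal["left", "right"]
    bearings_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    occupancy_deg: np.ndarray = field(default_factory=lambda: np.empty(0))
    object_ids: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    mode: Literal["per_object", "rasterized"] = "per_object"

    def __post_init__(self):
        self.bearings_deg = np.atleast_1d(np.asarray(self.bearings_deg, dtype=float))
        self.occupancy_deg = np.atleast_1d(np.asarray(self.occupancy_deg, dtype=float))
        self.object_ids = np.atleast_1d(np.asarray(self.object_ids, dtype=int))

    def __len__(self) -> int:
        return self.bearings_deg.size

    @property
    def is_empty(self) -> bool:
        return len(self) == 0

    def total_vertical(self) -> float:
        """Sum of vertical occupancies over samples (deg)."""
        return float(self.occupancy_deg.sum())

    def total_horizontal(self) -> float:
        """Horizontal field coverage (deg); raster cells count 1 deg each."""
        if self.mode == "rasterized":
            return float(len(self) * RASTER_DEG)
        return float(len(self))  # per-object: one nominal sample per object

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "eye": self.eye,
                "bearing_deg": self.bearings_deg,
                "occupancy_deg": self.occupancy_deg,
                "object_id": self.object_ids,
            }
        )


@dataclass(frozen=True)
class LoomingSignal:
    """Maximal single-object increase in vertical occupancy per step (deg >= 0)."""

    value: float
    object_id: int = -1


def relative_bearing(focal: BodyPose, target_xy: Sequence[float]) -> float:
    """Signed bearing (deg) of ``target_xy`` in the focal fish frame.

    0 is dead ahead; positive bearings are to the left of the heading.
    Raises ``ValueError`` for a target coincident with the focal position
    (the bearing is undefined there).
    """
    dx = float(target_xy[0]) - focal.x
    dy = float(target_xy[1]) - focal.y
    if dx * dx + dy * dy < 1e-18:
        raise ValueError("bearing undefined: target coincides with focal position")
    return float(wrap_angle(np.degrees(np.arctan2(dy, dx)) - focal.heading_deg))


def vertical_occupancy(half_extent_cm, distance_cm):
    """Vertical angular extent ``2*arctan(H/d)`` in degrees.

    Strictly decreasing in distance; ``half_extent_cm`` may be 0 (empty
    object).  Raises for non-positive distances.
    """
    h = np.asarray(half_extent_cm, dtype=float)
    d = np.asarray(distance_cm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("distance must be > 0")
    out = 2.0 * np.degrees(np.arctan2(h, d))
    return float(out) if out.ndim == 0 else out


def _as_objects(objects: Iterable[VisualObject]) -> list[VisualObject]:
    # ids default to position in the sequence when left at 0
    return list(objects)


def _object_geometry(focal: BodyPose, obj: VisualObject) -> tuple[float, float, float]:
    """(bearing deg, distance cm, vertical occupancy deg) of ``obj``."""
    d = float(np.hypot(obj.x - focal.x, obj.y - focal.y))
    if d <= 0:
        raise ValueError("object at zero distance from focal fish")
    theta = relative_bearing(focal, (obj.x, obj.y))
    return theta, d, vertical_occupancy(obj.half_extent, d)


def occupancy_profile(
    focal: BodyPose,
    objects: Iterable[VisualObject],
    mode: Literal["per_object", "rasterized"] = "per_object",
    field_limit_deg: float = FIELD_LIMIT_DEG,
) -> tuple[OccupancyProfile, OccupancyProfile]:
    """Project a scene onto the two eyes.

    Returns ``(left, right)`` profiles.  Objects inside the rear blind
    zone (|bearing| > ``field_limit_deg``) are excluded.  ``per_object``
    mode records one sample per object at its center bearing and ignores
    occlusion (the model used for simulated agents); ``rasterized`` mode
    paints a 1 deg bearing grid where each covered cell takes the
    occupancy of the nearest covering object, correcting for neighbors
    occluding one another.  An empty scene yields empty profiles.
    """
    objs = _as_objects(objects)
    geo = []
    for idx, o in enumerate(objs):
        theta, d, v = _object_geometry(focal, o)
        if abs(theta) > field_limit_deg:
            continue
        oid = o.obj_id if o.obj_id != 0 else idx
        geo.append((theta, d, v, oid, o))

    if mode == "per_object":
        def build(eye: str, sel) -> OccupancyProfile:
            if not sel:
                return OccupancyProfile(eye=eye, bearings_deg=np.empty(0),
                                        occupancy_deg=np.empty(0),
                                        object_ids=np.empty(0, dtype=int), mode=mode)
            th, _, v, oid = zip(*[(g[0], g[1], g[2], g[3]) for g in sel])
            return OccupancyProfile(eye=eye, bearings_deg=np.array(th),
                                    occupancy_deg=np.array(v),
                                    object_ids=np.array(oid, dtype=int), mode=mode)

        left = build("left", [g for g in geo if g[0] > 0.0])
        right = build("right", [g for g in geo if g[0] <= 0.0])
        return left, right

    if mode != "rasterized":
        raise ValueError(f"unknown mode {mode!r}")

    # 1 deg grid of cell centers over the full field; cells at positive
    # bearings belong to the left eye, others (including 0-) to the right.
    centers = np.arange(-field_limit_deg + RASTER_DEG / 2, field_limit_deg, RASTER_DEG)
    cell_v = np.zeros_like(centers)
    cell_d = np.full_like(centers, np.inf)
    cell_id = np.full(centers.shape, -1, dtype=int)
    for theta, d, v, oid, o in geo:
        # horizontal half-width of a disc of radius half_extent at distance d
        half_w = 90.0 if o.half_extent >= d else np.degrees(np.arcsin(o.half_extent / d))
        covered = np.abs(wrap_angle(centers - theta)) <= half_w
        closer = covered & (d < cell_d)
        cell_v[closer] = v
        cell_d[closer] = d
        cell_id[closer] = oid

    def build_raster(eye: str, sel: np.ndarray) -> OccupancyProfile:
        sel = sel & (cell_id >= 0)
        return OccupancyProfile(eye=eye, bearings_deg=centers[sel],
                                occupancy_deg=cell_v[sel],
                                object_ids=cell_id[sel], mode="rasterized")

    left = build_raster("left", centers > 0)
    right = build_raster("right", centers < 0)
    return left, right


def looming_input(
    focal_now: BodyPose,
    objects_now: Iterable[VisualObject],
    objects_prev: Iterable[VisualObject],
    focal_prev: BodyPose | None = None,
    mode: Literal["neighbor_induced", "raw"] = "neighbor_induced",
    field_limit_deg: float = FIELD_LIMIT_DEG,
) -> LoomingSignal:
    """Maximal per-object increase in vertical occupancy over one step.

    Objects are matched between the two instants by ``obj_id`` (or by
    sequence position when ids are left at 0).  In ``neighbor_induced``
    mode the previous occupancy of every object is re-projected from the
    *current* focal pose, so occupancy changes caused purely by the focal
    fish's own motion contribute nothing.  In ``raw`` mode the previous
    occupancy is the one actually experienced from ``focal_prev`` (which
    must then be given).  An object visible now but absent previously
    counts its full occupancy as loom.  Objects currently inside the
    blind zone are ignored.  The result is floored at 0.
    """
    if mode == "raw" and focal_prev is None:
        raise ValueError("raw mode requires focal_prev")

    prev: dict[int, VisualObject] = {}
    for idx, o in enumerate(_as_objects(objects_prev)):
        prev[o.obj_id if o.obj_id != 0 else idx] = o

    best = 0.0
    best_id = -1
    for idx, o in enumerate(_as_objects(objects_now)):
        oid = o.obj_id if o.obj_id != 0 else idx
        theta, d, v = _object_geometry(focal_now, o)
        if abs(theta) > field_limit_deg:
            continue
        v_prev = 0.0
        po = prev.get(oid)
        if po is not None:
            if mode == "neighbor_induced":
                dp = float(np.hypot(po.x - focal_now.x, po.y - focal_now.y))
                v_prev = 180.0 if dp <= 0 else vertical_occupancy(po.half_extent, dp)
            else:
                thp, dp, vp = _object_geometry(focal_prev, po)
                v_prev = vp if abs(thp) <= field_limit_deg else 0.0
        inc = v - v_prev
        if inc > best:
            best = inc
            best_id = oid
    return LoomingSignal(value=best, object_id=best_id)
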