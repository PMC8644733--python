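"""Hook geometry: hook angle, angle bisector, and the concave→convex tissue chord.

The hook angle is the angle between the hypocotyl axis and the imaginary
line joining the cotyledons.  Convention: 180° = fully closed hook
(cotyledon line antiparallel to the hypocotyl), 0° = fully open.  The
staining gradient is read along the bisector of the hook angle, from the
concave (inner) tissue edge to the convex (outer) edge.

Coordinates are (row, col), 0-based, with pixel centers at integer
positions.  Rows increase downward, columns to the right.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Union

import numpy as np
from scipy.ndimage import map_coordinates

from .errors import (
    DegenerateGeometryError,
    NoTissueError,
    OutOfBoundsError,
    ValidationError,
)

Point = tuple[float, float]

__all__ = [
    "SeedlingLandmarks",
    "BisectorChord",
    "Ray",
    "hook_angle",
    "bisect_directions",
    "bisector_ray",
    "tissue_chord",
    "read_landmarks_json",
    "write_landmarks_json",
]


def _as_point(p) -> np.ndarray:
    a = np.asarray(p, dtype=float)
    if a.shape != (2,) or not np.all(np.isfinite(a)):
        raise ValidationError(f"point must be a finite (row, col) pair, got {p!r}")
    return a


@dataclass(frozen=True)
class SeedlingLandmarks:
    """Annotated geometry of one seedling.

    Parameters
    ----------
    hypocotyl_axis : pair of points
        (proximal, distal) along the hypocotyl; distal is the end toward
        the hook.
    cotyledon_line : pair of points
        (hook side, tip side) along the line between the cotyledons.
    hook_vertex : point
        Interior corner of the hook on the concave side; the bisector ray
        originates here.
    """

    hypocotyl_axis: tuple[Point, Point]
    cotyledon_line: tuple[Point, Point]
    hook_vertex: Point

    def __post_init__(self):
        hyp = tuple(_as_point(p) for p in self.hypocotyl_axis)
        cot = tuple(_as_point(p) for p in self.cotyledon_line)
        vtx = _as_point(self.hook_vertex)
        for name, (a, b) in (("hypocotyl_axis", hyp), ("cotyledon_line", cot)):
            if np.linalg.norm(b - a) < 1.0:
                raise ValidationError(
                    f"{name}: the two points must be at least 1 px apart"
                )
        object.__setattr__(self, "hypocotyl_axis", hyp)
        object.__setattr__(self, "cotyledon_line", cot)
        object.__setattr__(self, "hook_vertex", vtx)

    def to_dict(self) -> dict:
        return {
            "hypocotyl_axis": [list(map(float, p)) for p in self.hypocotyl_axis],
            "cotyledon_line": [list(map(float, p)) for p in self.cotyledon_line],
            "hook_vertex": list(map(float, self.hook_vertex)),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SeedlingLandmarks":
        try:
            return cls(
                hypocotyl_axis=tuple(tuple(p) for p in d["hypocotyl_axis"]),
                cotyledon_line=tuple(tuple(p) for p in d["cotyledon_line"]),
                hook_vertex=tuple(d["hook_vertex"]),
            )
        except KeyError as e:  # pragma: no cover - message path
            raise ValidationError(f"landmark JSON missing key {e}") from e


@dataclass(frozen=True)
class BisectorChord:
    """Segment from the concave tissue edge to the convex tissue edge."""

    concave_point: Point
    convex_point: Point

    def __post_init__(self):
        a = _as_point(self.concave_point)
        b = _as_point(self.convex_point)
        if np.allclose(a, b):
            raise ValidationError("chord endpoints must be distinct")
        object.__setattr__(self, "concave_point", a)
        object.__setattr__(self, "convex_point", b)

    @property
    def length(self) -> float:
        return float(
            np.linalg.norm(
                np.asarray(self.convex_point) - np.asarray(self.concave_point)
            )
        )


@dataclass(frozen=True)
class Ray:
    """Half-line with unit direction, in (row, col) coordinates."""

    origin: Point
    direction: Point

    def __post_init__(self):
        o = _as_point(self.origin)
        d = np.asarray(self.direction, dtype=float)
        n = np.linalg.norm(d)
        if n == 0 or not np.all(np.isfinite(d)):
            raise ValidationError("ray direction must be a nonzero finite vector")
        object.__setattr__(self, "origin", o)
        object.__setattr__(self, "direction", d / n)


def _unit(v: np.ndarray, name: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0:
        raise ValidationError(f"{name}: zero-length direction")
    return v / n


def hook_angle(landmarks: SeedlingLandmarks) -> float:
    """Hook angle in degrees, in [0, 180].

    Angle between the oriented hypocotyl direction (proximal → distal) and
    the oriented cotyledon direction (hook side → tip side).  180° means
    the cotyledon line runs antiparallel to the hypocotyl (closed hook);
    0° means parallel (fully open).  Invariant under translation, rotation
    and uniform scaling of all landmarks.
    """
    (hp, hd) = landmarks.hypocotyl_axis
    (cb, ct) = landmarks.cotyledon_line
    d1 = _unit(np.asarray(hd) - np.asarray(hp), "hypocotyl_axis")
    d2 = _unit(np.asarray(ct) - np.asarray(cb), "cotyledon_line")
    cosang = float(np.clip(np.dot(d1, d2), -1.0, 1.0))
    return float(np.degrees(np.arccos(cosang)))


def bisect_directions(d1, d2) -> np.ndarray:
    """Unit bisector of two directions: the normalized sum (polar mean).

    Raises
    ------
    DegenerateGeometryError
        If the directions are antiparallel (bisector undefined).
    """
    u1 = _unit(np.asarray(d1, dtype=float), "d1")
    u2 = _unit(np.asarray(d2, dtype=float), "d2")
    s = u1 + u2
    n = np.linalg.norm(s)
    if n < 1e-12:
        raise DegenerateGeometryError("directions are antiparallel; bisector undefined")
    return s / n


def bisector_ray(landmarks: SeedlingLandmarks) -> Ray:
    """Ray from the hook vertex along the hook-angle bisector, pointing
    from the concave interior outward through the tissue.

    The bisector line of the corner formed at the vertex by the hypocotyl
    and the cotyledon is oriented outward by bisecting the distally
    oriented hypocotyl direction with the *reversed* cotyledon direction;
    for a hook bending along a circular arc this is exactly the outward
    radial at mid-arc.  Undefined for a fully open hook (angle 0°).
    """
    (hp, hd) = landmarks.hypocotyl_axis
    (cb, ct) = landmarks.cotyledon_line
    d1 = np.asarray(hd) - np.asarray(hp)  # through the hook, distally
    d2 = np.asarray(cb) - np.asarray(ct)  # cotyledon tip -> hook side
    try:
        direction = bisect_directions(d1, d2)
    except DegenerateGeometryError:
        raise DegenerateGeometryError(
            "hook angle is 0 (open hook); bisector undefined"
        ) from None
    return Ray(origin=tuple(landmarks.hook_vertex), direction=tuple(direction))


def _ray_travel_to_border(origin: np.ndarray, direction: np.ndarray, shape) -> float:
    """Maximum arc length along the ray that stays inside the image."""
    tmax = np.inf
    for ax, size in zip((0, 1), shape):
        d = direction[ax]
        if abs(d) < 1e-15:
            continue
        bound = (size - 1.0) if d > 0 else 0.0
        tmax = min(tmax, (bound - origin[ax]) / d)
    return max(tmax, 0.0)


def tissue_chord(
    image: np.ndarray,
    ray: Ray,
    background_threshold: Union[float, str] = "auto",
    step: float = 0.5,
) -> BisectorChord:
    """Walk the bisector ray and return the concave→convex tissue chord.

    Samples the signal image by bilinear interpolation every ``step``
    pixels from the ray origin to the image border.  The concave point is
    the first sample at or above the threshold; the convex point is the
    last sample of the same contiguous tissue run; both ends are then
    refined to the subpixel threshold crossing between the bracketing
    samples.

    ``background_threshold="auto"`` uses the midpoint between the minimum
    and maximum sampled value along the ray.

    Raises
    ------
    NoTissueError
        If no sample reaches the threshold (or the ray shows no contrast
        under the auto threshold).
    OutOfBoundsError
        If the ray origin lies outside the image, or the tissue run is
        truncated by the image border (the chord would exit the image).
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValidationError("tissue_chord expects a 2-D signal image")
    if step <= 0:
        raise ValidationError("step must be > 0")
    o = np.asarray(ray.origin, dtype=float)
    d = np.asarray(ray.direction, dtype=float)
    H, W = img.shape
    if not (0 <= o[0] <= H - 1 and 0 <= o[1] <= W - 1):
        raise OutOfBoundsError("ray origin lies outside the image")

    tmax = _ray_travel_to_border(o, d, img.shape)
    ts = np.arange(0.0, tmax + step * 1e-9, step)
    pts = o[None, :] + ts[:, None] * d[None, :]
    vals = map_coordinates(img, pts.T, order=1, mode="nearest")

    if background_threshold == "auto":
        vmin, vmax = float(vals.min()), float(vals.max())
        if vmax - vmin <= 1e-9:
            raise NoTissueError("no contrast along ray; cannot auto-threshold")
        thr = 0.5 * (vmin + vmax)
    else:
        thr = float(background_threshold)

    above = vals >= thr
    if not above.any():
        raise NoTissueError("no tissue found along the bisector ray")
    i0 = int(np.argmax(above))
    below_after = np.nonzero(~above[i0:])[0]
    if below_after.size == 0:
        raise OutOfBoundsError("tissue run reaches the image border; chord exits image")
    i1 = i0 + int(below_after[0]) - 1
    if i1 <= i0:
        raise NoTissueError("tissue run thinner than one sampling step")

    # refine both run ends to the subpixel threshold crossing so the chord
    # is not quantized to the sampling step
    def crossing(t_lo, v_lo, t_hi, v_hi):
        if v_hi == v_lo:
            return t_hi
        frac = (thr - v_lo) / (v_hi - v_lo)
        return t_lo + np.clip(frac, 0.0, 1.0) * (t_hi - t_lo)

    t_concave = ts[i0] if i0 == 0 else crossing(ts[i0 - 1], vals[i0 - 1],
                                                ts[i0], vals[i0])
    t_convex = crossing(ts[i1 + 1], vals[i1 + 1], ts[i1], vals[i1])
    return BisectorChord(
        concave_point=tuple(o + t_concave * d),
        convex_point=tuple(o + t_convex * d),
    )


def read_landmarks_json(path) -> dict[str, SeedlingLandmarks]:
    """Read a JSON mapping ``seedling_id -> landmark dict``."""
    with open(path) as f:
        raw = json.load(f)
    return {sid: SeedlingLandmarks.from_dict(d) for sid, d in raw.items()}


def write_landmarks_json(path, landmarks: dict[str, SeedlingLandmarks]) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        json.dump(
            {sid: lm.to_dict() for sid, lm in sorted(landmarks.items())},
            f,
            indent=1,
            sort_keys=True,
        )
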