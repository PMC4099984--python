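"""Geometric primitives for synthetic phantom construction.

Organs are represented by closed analytic solids (ellipsoid, capsule, box,
spherical shell).  Each primitive answers a vectorized point-membership query,
which is all the voxelizer needs: a voxel belongs to a solid iff the voxel
*center* lies inside it.  Points exactly on a surface are classified inside
(closed solids), so classification is deterministic.

All lengths are millimetres; volumes are mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

Vec3 = Tuple[float, float, float]


class Primitive:
    """Base class for closed analytic solids."""

    def contains(self, pts: np.ndarray) -> np.ndarray:
        """Vectorized membership test.

        Parameters
        ----------
        pts : (N, 3) array of point coordinates in mm.

        Returns
        -------
        (N,) boolean array, True where the point is inside or on the surface.
        """
        raise NotImplementedError

    def bounding_box(self) -> Tuple[np.ndarray, np.ndarray]:
        """Axis-aligned bounding box as (lower, upper) corners in mm."""
        raise NotImplementedError

    def volume(self) -> float:
        """Analytic volume in mm^3."""
        raise NotImplementedError

    def to_dict(self) -> dict:
        raise NotImplementedError


@dataclass(frozen=True)
class Ellipsoid(Primitive):
    center: Vec3
    semi_axes: Vec3  # (a, b, c) along x, y, z

    def __post_init__(self):
        if min(self.semi_axes) <= 0:
            raise ValueError(f"degenerate ellipsoid semi-axes {self.semi_axes}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = (pts - np.asarray(self.center)) / np.asarray(self.semi_axes)
        return np.einsum("ij,ij->i", d, d) <= 1.0

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        s = np.asarray(self.semi_axes, dtype=float)
        return c - s, c + s

    def volume(self) -> float:
        a, b, c = self.semi_axes
        return 4.0 / 3.0 * np.pi * a * b * c

    def to_dict(self):
        return {"shape": "ellipsoid", "center": list(self.center),
                "semi_axes": list(self.semi_axes)}


@dataclass(frozen=True)
class Capsule(Primitive):
    """Cylinder of radius r with hemispherical caps, along a coordinate axis.

    ``p0`` and ``p1`` are the centers of the two cap hemispheres (the axis
    segment); the capsule is the set of points within ``radius`` of the
    segment.  Arbitrary (non-axis-aligned) segments are supported.
    """

    p0: Vec3
    p1: Vec3
    radius: float

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError(f"degenerate capsule radius {self.radius}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        a = np.asarray(self.p0, dtype=float)
        b = np.asarray(self.p1, dtype=float)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0.0:
            d2 = np.einsum("ij,ij->i", pts - a, pts - a)
            return d2 <= self.radius**2
        t = np.clip((pts - a) @ ab / denom, 0.0, 1.0)
        proj = a + t[:, None] * ab
        d = pts - proj
        return np.einsum("ij,ij->i", d, d) <= self.radius**2

    def bounding_box(self):
        a = np.asarray(self.p0, dtype=float)
        b = np.asarray(self.p1, dtype=float)
        lo = np.minimum(a, b) - self.radius
        hi = np.maximum(a, b) + self.radius
        return lo, hi

    def volume(self) -> float:
        L = float(np.linalg.norm(np.asarray(self.p1) - np.asarray(self.p0)))
        r = self.radius
        return np.pi * r * r * L + 4.0 / 3.0 * np.pi * r**3

    def to_dict(self):
        return {"shape": "capsule", "p0": list(self.p0), "p1": list(self.p1),
                "radius": self.radius}


@dataclass(frozen=True)
class Box(Primitive):
    """Axis-aligned box given by center and full edge lengths."""

    center: Vec3
    size: Vec3

    def __post_init__(self):
        if min(self.size) <= 0:
            raise ValueError(f"degenerate box size {self.size}")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        c = np.asarray(self.center, dtype=float)
        h = np.asarray(self.size, dtype=float) / 2.0
        return np.all(np.abs(pts - c) <= h, axis=1)

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        h = np.asarray(self.size, dtype=float) / 2.0
        return c - h, c + h

    def volume(self) -> float:
        return float(np.prod(self.size))

    def to_dict(self):
        return {"shape": "box", "center": list(self.center),
                "size": list(self.size)}


@dataclass(frozen=True)
class SphericalShell(Primitive):
    """Closed shell between two concentric spheres (r_inner may be 0)."""

    center: Vec3
    r_inner: float
    r_outer: float

    def __post_init__(self):
        if not (0 <= self.r_inner < self.r_outer):
            raise ValueError(
                f"degenerate shell radii ({self.r_inner}, {self.r_outer})")

    def contains(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        d = pts - np.asarray(self.center, dtype=float)
        d2 = np.einsum("ij,ij->i", d, d)
        return (d2 >= self.r_inner**2) & (d2 <= self.r_outer**2)

    def bounding_box(self):
        c = np.asarray(self.center, dtype=float)
        return c - self.r_outer, c + self.r_outer

    def volume(self) -> float:
        return 4.0 / 3.0 * np.pi * (self.r_outer**3 - self.r_inner**3)

    def to_dict(self):
        return {"shape": "spherical-shell", "center": list(self.center),
                "r_inner": self.r_inner, "r_outer": self.r_outer}


def primitive_from_dict(d: dict) -> Primitive:
    """Inverse of ``Primitive.to_dict``; raises on unknown shape keywords."""
    kind = d["shape"]
    if kind == "ellipsoid":
        return Ellipsoid(tuple(d["center"]), tuple(d["semi_axes"]))
    if kind == "capsule":
        return Capsule(tuple(d["p0"]), tuple(d["p1"]), float(d["radius"]))
    if kind == "box":
        return Box(tuple(d["center"]), tuple(d["size"]))
    if kind == "spherical-shell":
        return SphericalShell(tuple(d["center"]), float(d["r_inner"]),
                              float(d["r_outer"]))
    raise ValueError(f"unknown primitive shape {kind!r}")


def scale_to_volume(prim: Primitive, volume_mm3: float) -> Primitive:
    """Return a copy of ``prim`` isotropically rescaled about its center to the
    requested volume.  Used to size organ primitives from target mass/density
    while keeping the aspect ratio given in the layout file."""
    if volume_mm3 <= 0:
        raise ValueError("target volume must be positive")
    f = (volume_mm3 / prim.volume()) ** (1.0 / 3.0)
    if isinstance(prim, Ellipsoid):
        return Ellipsoid(prim.center, tuple(np.asarray(prim.semi_axes) * f))
    if isinstance(prim, Box):
        return Box(prim.center, tuple(np.asarray(prim.size) * f))
    if isinstance(prim, Capsule):
        c = (np.asarray(prim.p0) + np.asarray(prim.p1)) / 2.0
        p0 = c + (np.asarray(prim.p0) - c) * f
        p1 = c + (np.asarray(prim.p1) - c) * f
        return Capsule(tuple(p0), tuple(p1), prim.radius * f)
    if isinstance(prim, SphericalShell):
        return SphericalShell(prim.center, prim.r_inner * f, prim.r_outer * f)
    raise TypeError(type(prim))
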