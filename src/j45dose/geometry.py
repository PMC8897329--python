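"""Quadric-surface constructive solid geometry for stylized phantoms.

Bodies are defined by general second-order surfaces
``f(p) = p'Ap + b.p + c`` combined through Boolean half-space operations,
the classical construction used for mathematically-defined ("stylized")
anthropomorphic phantoms.  Point membership is deterministic and
boundary-consistent: a half-space claims ``f(p) <= 0`` (closed below, open
above), complements claim the strict opposite, so a point is never in both
a region and its complement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Quadric",
    "Region",
    "HalfSpace",
    "Intersection",
    "Union",
    "Difference",
    "Solid",
    "ellipsoid",
    "zcylinder",
    "zfrustum",
    "ellipsoid_shell",
    "zcylinder_shell",
    "zfrustum_shell",
]

_INF = 1e9


@dataclass(frozen=True)
class Quadric:
    """General quadric surface f(p) = p'Ap + b.p + c.

    ``A`` is the symmetric 3x3 coefficient matrix, ``b`` the linear part.
    """

    A: np.ndarray
    b: np.ndarray
    c: float

    def evaluate(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(pts)
        return (np.einsum("ni,ij,nj->n", pts, self.A, pts)
                + pts @ self.b + self.c)


class Region:
    def contains(self, pts: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        raise NotImplementedError

    def __and__(self, other: "Region") -> "Region":
        return Intersection([self, other])

    def __or__(self, other: "Region") -> "Region":
        return Union([self, other])

    def __sub__(self, other: "Region") -> "Region":
        return Difference(self, other)


@dataclass(frozen=True)
class HalfSpace(Region):
    """The closed region f(p) <= 0 of a quadric (open if negated)."""

    quadric: Quadric
    negate: bool = False
    _bbox: tuple | None = field(default=None, compare=False)

    def contains(self, pts: np.ndarray) -> np.ndarray:
        f = self.quadric.evaluate(pts)
        return f > 0.0 if self.negate else f <= 0.0

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        if self._bbox is not None:
            return self._bbox
        return (np.full(3, -_INF), np.full(3, _INF))


@dataclass(frozen=True)
class Intersection(Region):
    parts: list

    def contains(self, pts: np.ndarray) -> np.ndarray:
        out = self.parts[0].contains(pts)
        for p in self.parts[1:]:
            if not out.any():
                break
            out = out & p.contains(pts)
        return out

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(p.bbox() for p in self.parts))
        return np.max(los, axis=0), np.min(his, axis=0)


@dataclass(frozen=True)
class Union(Region):
    parts: list

    def contains(self, pts: np.ndarray) -> np.ndarray:
        out = self.parts[0].contains(pts)
        for p in self.parts[1:]:
            out = out | p.contains(pts)
        return out

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        los, his = zip(*(p.bbox() for p in self.parts))
        return np.min(los, axis=0), np.max(his, axis=0)


@dataclass(frozen=True)
class Difference(Region):
    keep: Region
    cut: Region

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.keep.contains(pts) & ~self.cut.contains(pts)

    def bbox(self) -> tuple[np.ndarray, np.ndarray]:
        return self.keep.bbox()


@dataclass
class Solid:
    """A named, homogeneous body: a CSG region plus its medium."""

    name: str
    region: Region
    medium: str

    def contains(self, pts: np.ndarray) -> np.ndarray:
        return self.region.contains(pts)


def _boxed(hs: HalfSpace, lo, hi) -> HalfSpace:
    return HalfSpace(hs.quadric, hs.negate,
                     (np.asarray(lo, float), np.asarray(hi, float)))


def ellipsoid(center, semiaxes) -> Region:
    """Axis-aligned ellipsoid (x-cx)^2/a^2 + ... <= 1."""
    c = np.asarray(center, float)
    s = np.asarray(semiaxes, float)
    if np.any(s <= 0):
        raise ValueError("semiaxes must be positive")
    A = np.diag(1.0 / s**2)
    b = -2.0 * c / s**2
    const = float(np.sum(c**2 / s**2) - 1.0)
    return _boxed(HalfSpace(Quadric(A, b, const)), c - s, c + s)


def _zslab(z0: float, z1: float, lo, hi) -> Region:
    """z0 <= z <= z1 as two planar half-spaces."""
    zero = np.zeros((3, 3))
    below = HalfSpace(Quadric(zero, np.array([0, 0, 1.0]), -z1))   # z <= z1
    above = HalfSpace(Quadric(zero, np.array([0, 0, -1.0]), z0))   # z >= z0
    return Intersection([_boxed(below, lo, hi), _boxed(above, lo, hi)])


def zcylinder(center_xy, a: float, b: float, z0: float, z1: float) -> Region:
    """Elliptic cylinder along z with semi-axes (a, b), capped at z0..z1."""
    cx, cy = center_xy
    if a <= 0 or b <= 0 or z1 <= z0:
        raise ValueError("cylinder needs positive semi-axes and z1 > z0")
    A = np.diag([1.0 / a**2, 1.0 / b**2, 0.0])
    lin = np.array([-2 * cx / a**2, -2 * cy / b**2, 0.0])
    const = cx**2 / a**2 + cy**2 / b**2 - 1.0
    lo = np.array([cx - a, cy - b, z0])
    hi = np.array([cx + a, cy + b, z1])
    side = _boxed(HalfSpace(Quadric(A, lin, const)), lo, hi)
    return Intersection([side, _zslab(z0, z1, lo, hi)])


def zfrustum(center_xy, r0: float, z0: float, r1: float, z1: float) -> Region:
    """Circular cone frustum along z: radius r0 at z0 linearly to r1 at z1."""
    cx, cy = center_xy
    if r0 <= 0 or r1 <= 0 or z1 <= z0:
        raise ValueError("frustum needs positive radii and z1 > z0")
    # radius(z) = r0 + k (z - z0); surface x^2 + y^2 - radius(z)^2 = 0
    k = (r1 - r0) / (z1 - z0)
    # expand: x^2 + y^2 - k^2 z^2 + ... with m = r0 - k z0
    m = r0 - k * z0
    A = np.diag([1.0, 1.0, -k * k])
    lin = np.array([-2 * cx, -2 * cy, -2 * k * m])
    const = cx**2 + cy**2 - m * m
    rmax = max(r0, r1)
    lo = np.array([cx - rmax, cy - rmax, z0])
    hi = np.array([cx + rmax, cy + rmax, z1])
    side = _boxed(HalfSpace(Quadric(A, lin, const)), lo, hi)
    return Intersection([side, _zslab(z0, z1, lo, hi)])


def ellipsoid_shell(center, semiaxes, thickness: float) -> Region:
    s = np.asarray(semiaxes, float)
    if thickness <= 0 or np.any(s - thickness <= 0):
        raise ValueError("shell thickness must be positive and < semiaxes")
    return Difference(ellipsoid(center, s), ellipsoid(center, s - thickness))


def zcylinder_shell(center_xy, a, b, z0, z1, thickness: float) -> Region:
    """Lateral shell of an elliptic cylinder (no end caps)."""
    return Difference(zcylinder(center_xy, a, b, z0, z1),
                      zcylinder(center_xy, a - thickness, b - thickness, z0, z1))


def zfrustum_shell(center_xy, r0, z0, r1, z1, thickness: float) -> Region:
    return Difference(zfrustum(center_xy, r0, z0, r1, z1),
                      zfrustum(center_xy, r0 - thickness, z0,
                               r1 - thickness, z1))
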