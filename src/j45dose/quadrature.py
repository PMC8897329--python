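"""Discrete-ordinates angular quadrature for binned survivor fluences.

The DS02-style fluence datasets index direction by a customized S-8
level-symmetric quadrature for two-dimensional R-Z geometry: 48 angles over a
2*pi solid angle (one zero-weight "starting direction" per polar level, a
standard device for stabilizing discrete-ordinates sweeps in curvilinear
geometry), refined by splitting every direction into five polar sub-directions.
That yields 240 directions for mirror-symmetric (in-open) shielding, of which
200 carry weight, and 480 directions (400 weighted) once the set is unfolded
across the beta = 0 mirror plane for asymmetric shielding.

Each direction is described by ``mu`` and ``eta``, the direction cosines with
respect to the horizontal hypocenter axis (R) and the vertical (Z); the third
cosine ``beta`` is determined up to sign.  Weights are fractions of total solid
angle and sum to 1 over the contributing bins.

The base ordinates and weights live in an editable data file
(``data/s8_base_quadrature.csv``) so an alternative set can be dropped in.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "DirectionBin",
    "AngularQuadrature",
    "build_base_quadrature",
    "refine_polar",
    "mirror_asymmetric",
    "direction_vector",
    "ds02_quadrature",
]

_TOL = 1e-9


@dataclass(frozen=True)
class DirectionBin:
    """One discrete ordinate: direction cosines, weight, polar level.

    ``mu`` is the cosine w.r.t. the horizontal hypocenter->survivor axis (x),
    ``eta`` the cosine w.r.t. vertical z.  ``beta_sign`` in {+1, -1, 0} fixes
    the sign of the third cosine ``beta = sqrt(1 - mu^2 - eta^2)``; starting
    directions sit in the beta = 0 plane.  ``weight`` is the bin's fraction of
    total solid angle (zero iff the bin is a starting direction).
    """

    mu: float
    eta: float
    beta_sign: int
    weight: float
    level: int
    is_starting: bool = False

    def __post_init__(self) -> None:
        if self.mu * self.mu + self.eta * self.eta > 1.0 + _TOL:
            raise ValueError(
                f"invalid direction bin: mu^2 + eta^2 = "
                f"{self.mu**2 + self.eta**2:.6f} > 1"
            )
        if self.weight < 0.0:
            raise ValueError("direction bin weight must be >= 0")
        if (self.weight == 0.0) != self.is_starting:
            raise ValueError("weight == 0 exactly for starting directions")
        if self.beta_sign not in (-1, 0, 1):
            raise ValueError("beta_sign must be one of {-1, 0, +1}")

    @property
    def beta(self) -> float:
        return self.beta_sign * math.sqrt(
            max(0.0, 1.0 - self.mu * self.mu - self.eta * self.eta)
        )


def direction_vector(b: DirectionBin) -> np.ndarray:
    """Unit direction (mu, beta, eta) in the fixed frame.

    x is the horizontal hypocenter->survivor axis, z is up, y completes the
    right-handed frame.  For bins of a folded symmetric set (beta_sign=+1) the
    representative +beta direction is returned.
    """
    r2 = 1.0 - b.mu * b.mu - b.eta * b.eta
    if r2 < -_TOL:
        raise ValueError("mu^2 + eta^2 > 1: no real beta exists")
    beta = b.beta_sign * math.sqrt(max(0.0, r2))
    if b.beta_sign == 0 and r2 > _TOL:
        raise ValueError(
            "beta_sign 0 but mu^2 + eta^2 < 1: direction is not unit length"
        )
    return np.array([b.mu, beta, b.eta])


@dataclass
class AngularQuadrature:
    """An ordered set of direction bins with a symmetry tag.

    ``symmetry`` is 'symmetric' (bins folded across beta = 0, used for the
    in-open scenario) or 'asymmetric' (both beta half-spaces explicit).
    ``refinement`` records the polar split factor applied to the base set.
    """

    bins: list[DirectionBin]
    symmetry: str = "symmetric"
    refinement: int = 1

    def __post_init__(self) -> None:
        if self.symmetry not in ("symmetric", "asymmetric"):
            raise ValueError(f"unknown symmetry {self.symmetry!r}")

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def n_contributing(self) -> int:
        return sum(1 for b in self.bins if b.weight > 0.0)

    @property
    def weights(self) -> np.ndarray:
        return np.array([b.weight for b in self.bins])

    @property
    def directions(self) -> np.ndarray:
        """(n_bins, 3) array of unit vectors (mu, beta, eta)."""
        return np.array([direction_vector(b) for b in self.bins])

    def integrate(self, f: Callable[[np.ndarray], np.ndarray]) -> float:
        """Quadrature sum of f over the unit sphere (f maps (n,3) -> (n,))."""
        return float(self.weights @ np.asarray(f(self.directions), dtype=float))

    # -- columnar text serialization ------------------------------------
    def to_text(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(
                ["bin_index", "level", "mu", "eta", "beta_sign", "weight",
                 "is_starting"]
            )
            for i, b in enumerate(self.bins):
                w.writerow(
                    [i, b.level, f"{b.mu:.17g}", f"{b.eta:.17g}", b.beta_sign,
                     f"{b.weight:.17g}", int(b.is_starting)]
                )

    @classmethod
    def from_text(
        cls, path: str | Path, symmetry: str = "symmetric", refinement: int = 1
    ) -> "AngularQuadrature":
        bins = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                bins.append(
                    DirectionBin(
                        mu=float(row["mu"]),
                        eta=float(row["eta"]),
                        beta_sign=int(row["beta_sign"]),
                        weight=float(row["weight"]),
                        level=int(row["level"]),
                        is_starting=bool(int(row["is_starting"])),
                    )
                )
        return cls(bins=bins, symmetry=symmetry, refinement=refinement)


def _base_table_path() -> Path:
    return Path(resources.files("j45dose.data") / "s8_base_quadrature.csv")


def build_base_quadrature() -> AngularQuadrature:
    """The unrefined symmetric set: 48 directions on 8 polar levels.

    Eight bins (one per level, at mu = -sqrt(1 - eta^2), beta = 0) are
    zero-weight starting directions; the remaining 40 carry level-symmetric
    S-8 weights renormalized to sum to exactly 1.
    """
    q = AngularQuadrature.from_text(_base_table_path(), symmetry="symmetric")
    total = sum(b.weight for b in q.bins)
    q.bins = [
        replace(b, weight=b.weight / total) if b.weight > 0 else b
        for b in q.bins
    ]
    return q


def _level_spans(bins: Sequence[DirectionBin]) -> dict[float, tuple[float, float]]:
    """Polar-angle span attributed to each distinct eta level.

    Edges are placed midway between adjacent level polar angles, with the
    outermost edges at 0 and pi.
    """
    thetas = sorted({math.acos(max(-1.0, min(1.0, b.eta))) for b in bins})
    edges = [0.0]
    for lo, hi in zip(thetas[:-1], thetas[1:]):
        edges.append(0.5 * (lo + hi))
    edges.append(math.pi)
    return {
        math.cos(t): (edges[i], edges[i + 1]) for i, t in enumerate(thetas)
    }


def refine_polar(q: AngularQuadrature, factor: int) -> AngularQuadrature:
    """Split every bin into ``factor`` polar sub-directions.

    Children are spaced span/factor apart in polar angle, centred on the
    parent direction, and preserve the parent's azimuth; each child of a
    contributing bin carries weight parent/factor, children of starting
    directions stay zero-weight.  factor=1 returns an identical quadrature.
    """
    if not isinstance(factor, (int, np.integer)) or factor < 1:
        raise ValueError(f"refinement factor must be a positive integer, got {factor!r}")
    if factor == 1:
        return AngularQuadrature(list(q.bins), q.symmetry, q.refinement)
    spans = _level_spans(q.bins)
    out: list[DirectionBin] = []
    for b in q.bins:
        theta_p = math.acos(max(-1.0, min(1.0, b.eta)))
        lo, hi = spans[min(spans, key=lambda e: abs(e - b.eta))]
        step = (hi - lo) / factor
        sin_p = math.sin(theta_p)
        for j in range(factor):
            theta_c = theta_p + (j - (factor - 1) / 2.0) * step
            eta_c = math.cos(theta_c)
            # preserve azimuth: mu scales with sin(theta)
            mu_c = b.mu * (math.sin(theta_c) / sin_p) if sin_p > 0 else 0.0
            out.append(
                DirectionBin(
                    mu=mu_c,
                    eta=eta_c,
                    beta_sign=b.beta_sign,
                    weight=b.weight / factor,
                    level=b.level,
                    is_starting=b.is_starting,
                )
            )
    return AngularQuadrature(out, q.symmetry, q.refinement * factor)


def mirror_asymmetric(q: AngularQuadrature) -> AngularQuadrature:
    """Unfold a symmetric set across beta = 0 into an asymmetric set.

    Every bin is duplicated with the beta sign negated; each mirrored pair
    splits the original weight evenly, so the total stays 1.
    """
    if q.symmetry != "symmetric":
        raise ValueError("quadrature is already asymmetric; cannot mirror again")
    out: list[DirectionBin] = []
    for b in q.bins:
        out.append(replace(b, beta_sign=b.beta_sign, weight=b.weight / 2.0))
        out.append(replace(b, beta_sign=-b.beta_sign, weight=b.weight / 2.0))
    return AngularQuadrature(out, "asymmetric", q.refinement)


def ds02_quadrature(symmetry: str = "symmetric") -> AngularQuadrature:
    """The refinement-5 production set: 240 bins symmetric, 480 asymmetric."""
    q = refine_polar(build_base_quadrature(), 5)
    if symmetry == "symmetric":
        return q
    if symmetry == "asymmetric":
        return mirror_asymmetric(q)
    raise ValueError(f"unknown symmetry {symmetry!r}")
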