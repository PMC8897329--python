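"""Sampling binned fluences into Monte Carlo phase-space source files.

The point fluence (defined 1 m above ground at the survivor's location) is
expanded to a sphere surrounding the phantom — radius 40 cm for ages 0-1 y,
70 cm for 5-10 y, 100 cm for 15 y and adults — realized as a composite of
discs, one per contributing angle bin.  For each sampled particle:

* the angle bin is chosen with probability (bin fluence x bin weight) /
  total weighted fluence, so zero-weight starting directions never fire;
* the energy group is chosen by the bin's relative group fluences; within
  the group, gammas are uniform in energy, neutrons below the thermal
  cutoff follow a truncated Maxwell-Boltzmann energy distribution (default
  300 K), and neutrons above it follow a 1/E (log-uniform) density;
* the position is uniform on a disc initially in the x-y plane, rotated so
  its normal equals the bin direction (rotation about x by the angle from
  eta, then about z by the angle from mu), then translated one radius
  opposite to the flight direction.  Every particle therefore satisfies
  position . direction = -radius and flies toward the phantom.

Particles are logged line-by-line to an ASCII dialect (`#` header lines,
then ``ptype energy x y z u v w weight``) and can be converted to the MCPL
binary dialect (:mod:`j45dose.mcpl_io`).  All sampled particles carry
statistical weight 1; absolute normalization happens at dose conversion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import special

from j45dose.fluence import (
    COMPONENT_PARTICLE,
    FluenceComponent,
    ScenarioFluence,
)
from j45dose.quadrature import AngularQuadrature, DirectionBin, direction_vector

__all__ = [
    "SamplerConfig",
    "ParticleBatch",
    "PhaseSpaceFile",
    "DegenerateSourceError",
    "EXPANSION_RADIUS_BY_AGE_CM",
    "sample_angle_bin",
    "sample_angle_bins",
    "sample_energy",
    "sample_energies",
    "place_on_disc",
    "generate_phase_space",
]

#: fluence expansion radius by phantom age class (cm)
EXPANSION_RADIUS_BY_AGE_CM = {
    "newborn": 40.0, "1": 40.0,
    "5": 70.0, "10": 70.0,
    "15": 100.0, "adult": 100.0,
}

_BOLTZMANN_MEV_PER_K = 8.617333262e-11


class DegenerateSourceError(ValueError):
    """Raised when a fluence component carries no sampleable intensity."""


@dataclass
class SamplerConfig:
    expansion_radius: float = 100.0      # cm
    n_particles: int = 10_000
    thermal_cutoff: float = 1e-6         # MeV; Maxwellian below, 1/E above
    maxwellian_temperature: float = 300.0  # K
    seed: int = 0

    def __post_init__(self) -> None:
        if self.expansion_radius <= 0:
            raise ValueError("expansion_radius must be positive")
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")

    @property
    def kT_MeV(self) -> float:
        return _BOLTZMANN_MEV_PER_K * self.maxwellian_temperature


@dataclass
class ParticleBatch:
    """Columnar particle records: the in-memory phase-space representation."""

    ptype: str                    # gamma | neutron | electron
    energy: np.ndarray            # MeV, (n,)
    position: np.ndarray          # cm, (n, 3)
    direction: np.ndarray         # unit vectors, (n, 3)
    weight: np.ndarray            # statistical weight, (n,)

    def __post_init__(self) -> None:
        n = len(self.energy)
        if self.position.shape != (n, 3) or self.direction.shape != (n, 3):
            raise ValueError("inconsistent particle array shapes")
        if np.any(self.energy <= 0):
            raise ValueError("particle energies must be positive")
        if np.any(self.weight <= 0):
            raise ValueError("statistical weights must be positive")
        norms = np.linalg.norm(self.direction, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-9):
            raise ValueError("directions must be unit vectors to 1e-9")

    def __len__(self) -> int:
        return len(self.energy)


def _weighted_bin_fluence(c: FluenceComponent, q: AngularQuadrature) -> np.ndarray:
    if c.values.shape[0] != q.n_bins:
        raise ValueError("component/quadrature angle-bin mismatch")
    return q.weights * c.values.sum(axis=1)


def sample_angle_bins(
    c: FluenceComponent, q: AngularQuadrature, rng: np.random.Generator,
    n: int = 1,
) -> np.ndarray:
    """Indices of contributing bins, p proportional to fluence x weight."""
    wf = _weighted_bin_fluence(c, q)
    total = wf.sum()
    if total <= 0.0:
        raise DegenerateSourceError(
            f"component {c.name}: total weighted fluence is zero")
    return rng.choice(len(wf), size=n, p=wf / total)


def sample_angle_bin(
    c: FluenceComponent, q: AngularQuadrature, rng: np.random.Generator
) -> int:
    return int(sample_angle_bins(c, q, rng, 1)[0])


def _sample_in_group(
    particle: str, lo: np.ndarray, hi: np.ndarray, cfg: SamplerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Vectorized within-group energy draw for groups [lo, hi)."""
    n = len(lo)
    u = rng.random(n)
    if particle == "gamma":
        return lo + u * (hi - lo)
    out = np.empty(n)
    thermal = hi <= cfg.thermal_cutoff
    # thermal: Maxwell-Boltzmann energy pdf ~ sqrt(E) exp(-E/kT), i.e.
    # Gamma(3/2, kT), truncated to the group via the inverse regularized
    # incomplete gamma function
    if np.any(thermal):
        kT = cfg.kT_MeV
        a, b = lo[thermal] / kT, hi[thermal] / kT
        ca, cb = special.gammainc(1.5, a), special.gammainc(1.5, b)
        out[thermal] = kT * special.gammaincinv(
            1.5, ca + u[thermal] * (cb - ca))
    # epithermal/fast: 1/E density -> log-uniform on the group
    if np.any(~thermal):
        l, h = lo[~thermal], hi[~thermal]
        out[~thermal] = l * (h / l) ** u[~thermal]
    return out


def sample_energies(
    c: FluenceComponent, bins: np.ndarray, cfg: SamplerConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """Energies (MeV) for particles already assigned to angle bins."""
    bins = np.atleast_1d(np.asarray(bins, dtype=int))
    spectra = c.values[bins]                       # (n, n_groups)
    totals = spectra.sum(axis=1)
    if np.any(totals <= 0.0):
        bad = bins[totals <= 0.0][0]
        raise DegenerateSourceError(
            f"component {c.name}: empty spectrum in angle bin {bad}")
    cdf = np.cumsum(spectra, axis=1) / totals[:, None]
    groups = (rng.random(len(bins))[:, None] > cdf).sum(axis=1)
    lo = c.groups.lower[groups]
    hi = c.groups.upper[groups]
    return _sample_in_group(c.particle, lo, hi, cfg, rng)


def sample_energy(
    c: FluenceComponent, bin: int, cfg: SamplerConfig,
    rng: np.random.Generator,
) -> float:
    return float(sample_energies(c, np.array([bin]), cfg, rng)[0])


def _disc_rotation(b: DirectionBin) -> np.ndarray:
    """Rotation taking z-hat to the bin direction: Rz(psi) @ Rx(theta).

    theta = arccos(eta) is the polar rotation about x; psi, derived from mu,
    is the subsequent rotation about z.  The composite maps the disc normal
    (0, 0, 1) exactly onto direction_vector(bin).
    """
    d = direction_vector(b)
    eta = d[2]
    st = math.sqrt(max(0.0, 1.0 - eta * eta))
    if st < 1e-14:
        return np.diag([1.0, 1.0, math.copysign(1.0, eta)])
    ct = eta
    psi = math.atan2(d[0], -d[1])   # sin(psi) ~ mu, cos(psi) ~ -beta
    cp, sp = math.cos(psi), math.sin(psi)
    rx = np.array([[1, 0, 0], [0, ct, -st], [0, st, ct]], dtype=float)
    rz = np.array([[cp, -sp, 0], [sp, cp, 0], [0, 0, 1]], dtype=float)
    return rz @ rx


def place_on_disc(
    b: DirectionBin, radius: float, rng: np.random.Generator, n: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Positions and directions for particles started on the bin's disc.

    Positions are uniform on a disc of the given radius, oriented normal to
    the bin direction and translated one radius upstream, so
    position . direction = -radius for every particle.
    """
    if b.weight == 0.0:
        raise ValueError("cannot start particles from a zero-weight bin")
    if radius <= 0:
        raise ValueError("disc radius must be positive")
    d = direction_vector(b)
    rot = _disc_rotation(b)
    r = radius * np.sqrt(rng.random(n))
    phi = 2.0 * math.pi * rng.random(n)
    flat = np.column_stack([r * np.cos(phi), r * np.sin(phi), np.zeros(n)])
    pos = flat @ rot.T - radius * d
    dirs = np.broadcast_to(d, (n, 3)).copy()
    return pos, dirs


def generate_phase_space(
    s: ScenarioFluence, component: str, cfg: SamplerConfig,
    path: str | Path,
) -> "PhaseSpaceFile":
    """Sample one component into an ASCII phase-space file.

    Reproducible from ``cfg.seed``: the same configuration writes a
    byte-identical file.
    """
    if component not in s.components:
        raise KeyError(f"scenario has no component {component!r}")
    c = s.components[component]
    q = s.quadrature
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_particles

    bins = sample_angle_bins(c, q, rng, n)
    energies = sample_energies(c, bins, cfg, rng)
    pos = np.empty((n, 3))
    dirs = np.empty((n, 3))
    # particles sharing an angle bin share a disc; draw positions bin-wise
    for bi in np.unique(bins):
        m = bins == bi
        pos[m], dirs[m] = place_on_disc(q.bins[bi], cfg.expansion_radius,
                                        rng, int(m.sum()))
    batch = ParticleBatch(
        ptype=c.particle, energy=energies, position=pos, direction=dirs,
        weight=np.ones(n))
    meta = {
        "scenario": s.descriptor.key,
        "component": component,
        "particle": c.particle,
        "n_particles": str(n),
        "expansion_radius_cm": f"{cfg.expansion_radius:g}",
        "total_fluence": f"{s.total_fluence(component):.17g}",
        "seed": str(cfg.seed),
    }
    return PhaseSpaceFile.write_ascii(path, batch, meta)


class PhaseSpaceFile:
    """Handle to an on-disk ASCII phase-space particle list."""

    COLUMNS = "ptype energy_MeV x_cm y_cm z_cm u v w weight"

    def __init__(self, path: str | Path, metadata: dict[str, str]):
        self.path = Path(path)
        self.metadata = metadata

    @property
    def n_particles(self) -> int:
        return int(self.metadata.get("n_particles", 0))

    @property
    def total_fluence(self) -> float:
        return float(self.metadata.get("total_fluence", 0.0))

    @classmethod
    def write_ascii(
        cls, path: str | Path, batch: ParticleBatch, metadata: dict[str, str],
    ) -> "PhaseSpaceFile":
        path = Path(path)
        with open(path, "w") as f:
            f.write("# j45dose phase-space v1\n")
            for k, v in metadata.items():
                f.write(f"# {k}: {v}\n")
            f.write(f"# columns: {cls.COLUMNS}\n")
            for i in range(len(batch)):
                p, d = batch.position[i], batch.direction[i]
                f.write(
                    f"{batch.ptype} {batch.energy[i]:.17g} "
                    f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g} "
                    f"{d[0]:.17g} {d[1]:.17g} {d[2]:.17g} "
                    f"{batch.weight[i]:.9e}\n")
        meta = dict(metadata)
        meta["n_particles"] = str(len(batch))
        return cls(path, meta)

    @classmethod
    def open(cls, path: str | Path) -> "PhaseSpaceFile":
        path = Path(path)
        meta: dict[str, str] = {}
        with open(path) as f:
            for line in f:
                if not line.startswith("#"):
                    break
                body = line[1:].strip()
                if ":" in body:
                    k, v = body.split(":", 1)
                    meta[k.strip()] = v.strip()
        return cls(path, meta)

    def read(self) -> ParticleBatch:
        ptypes: list[str] = []
        rows: list[list[float]] = []
        with open(self.path) as f:
            for lineno, line in enumerate(f, start=1):
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                parts = line.split()
                if len(parts) != 9:
                    raise ValueError(
                        f"{self.path}:{lineno}: expected 9 fields, "
                        f"got {len(parts)}")
                ptypes.append(parts[0])
                try:
                    rows.append([float(x) for x in parts[1:]])
                except ValueError as exc:
                    raise ValueError(f"{self.path}:{lineno}: {exc}")
        if not rows:
            raise ValueError(f"{self.path}: no particle records")
        if len(set(ptypes)) != 1:
            raise ValueError(f"{self.path}: mixed particle types")
        arr = np.array(rows)
        return ParticleBatch(
            ptype=ptypes[0], energy=arr[:, 0], position=arr[:, 1:4],
            direction=arr[:, 4:7], weight=arr[:, 7])
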