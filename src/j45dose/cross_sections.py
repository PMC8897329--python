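"""Interaction-coefficient tables for the three phantom media.

Small editable CSV tables of photon mass attenuation / mass energy-absorption
coefficients and neutron total interaction coefficients / fluence-to-KERMA
factors, interpolated log-log.  The shipped tables are approximate,
testing-grade compilations (see the data-file headers); evaluated nuclear
data fidelity is out of scope for this engine.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["CrossSectionTable", "load_cross_sections", "EnergyRangeError"]


class EnergyRangeError(ValueError):
    """Particle energy outside the tabulated grid."""


def _loglog_interp(e: np.ndarray, grid_e: np.ndarray, grid_v: np.ndarray) -> np.ndarray:
    return np.exp(np.interp(np.log(e), np.log(grid_e), np.log(grid_v)))


@dataclass
class CrossSectionTable:
    """Per-medium photon and neutron coefficients on a coarse energy grid."""

    photon: pd.DataFrame    # medium, energy_MeV, mu_rho, muen_rho
    neutron: pd.DataFrame   # medium, energy_MeV, sigma_rho, kerma

    def __post_init__(self) -> None:
        ph, nt = self.photon, self.neutron
        if np.any(ph[["mu_rho_cm2_g", "muen_rho_cm2_g"]].values <= 0):
            raise ValueError("photon coefficients must be positive")
        if np.any(ph.muen_rho_cm2_g.values > ph.mu_rho_cm2_g.values * (1 + 1e-12)):
            raise ValueError("energy absorption cannot exceed attenuation")
        if np.any(nt[["sigma_rho_cm2_g", "kerma_Gy_cm2"]].values <= 0):
            raise ValueError("neutron coefficients must be positive")
        self._ph = {m: g.sort_values("energy_MeV")
                    for m, g in ph.groupby("medium")}
        self._nt = {m: g.sort_values("energy_MeV")
                    for m, g in nt.groupby("medium")}

    @property
    def media(self) -> tuple[str, ...]:
        return tuple(sorted(set(self._ph) & set(self._nt)))

    def _grid(self, ptype: str, medium: str) -> pd.DataFrame:
        table = self._ph if ptype == "gamma" else self._nt
        if medium not in table:
            raise KeyError(f"no {ptype} coefficients for medium {medium!r}")
        return table[medium]

    def check_range(self, ptype: str, medium: str, energy) -> None:
        g = self._grid(ptype, medium).energy_MeV.values
        e = np.atleast_1d(energy)
        bad = (e < g[0]) | (e > g[-1])
        if bad.any():
            i = int(np.flatnonzero(bad)[0])
            raise EnergyRangeError(
                f"{ptype} energy {e[bad][0]:.4g} MeV outside table range "
                f"[{g[0]:.3g}, {g[-1]:.3g}] for medium {medium} "
                f"(particle index {i})")

    def mu_rho(self, medium: str, energy) -> np.ndarray:
        g = self._grid("gamma", medium)
        return _loglog_interp(np.atleast_1d(energy), g.energy_MeV.values,
                              g.mu_rho_cm2_g.values)

    def muen_rho(self, medium: str, energy) -> np.ndarray:
        g = self._grid("gamma", medium)
        return _loglog_interp(np.atleast_1d(energy), g.energy_MeV.values,
                              g.muen_rho_cm2_g.values)

    def sigma_rho(self, medium: str, energy) -> np.ndarray:
        g = self._grid("neutron", medium)
        return _loglog_interp(np.atleast_1d(energy), g.energy_MeV.values,
                              g.sigma_rho_cm2_g.values)

    def kerma_factor(self, medium: str, energy) -> np.ndarray:
        """Fluence-to-KERMA factor, Gy cm^2."""
        g = self._grid("neutron", medium)
        return _loglog_interp(np.atleast_1d(energy), g.energy_MeV.values,
                              g.kerma_Gy_cm2.values)


def load_cross_sections(
    photon_path: str | Path | None = None,
    neutron_path: str | Path | None = None,
) -> CrossSectionTable:
    data = resources.files("j45dose.data")
    ph = pd.read_csv(photon_path or (data / "xs_photon.csv"), comment="#")
    nt = pd.read_csv(neutron_path or (data / "xs_neutron.csv"), comment="#")
    return CrossSectionTable(ph, nt)
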