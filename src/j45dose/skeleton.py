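"""Bone-site registry: 25 skeletal sites with marrow/endosteum fractions.

Skeletal dosimetry works through site fluences rather than direct energy
deposition: neutron and gamma fluences are tallied at 25 bone sites,
converted to site doses with fluence-to-dose response functions, and
combined into total active-marrow and bone-endosteum doses with
age-dependent site distribution fractions.

Two selectable fraction tables are shipped, a legacy DS86-style table and a
modern reference-style distribution (the two differ mainly in how much
active marrow is attributed to the long bones); both are synthetic
reconstructions, normalized so fractions sum to 1 per tissue and age.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = ["BONE_SITES", "AGE_GROUPS", "BoneSiteRegistry", "load_registry"]

BONE_SITES = (
    "cranium", "facial_bones", "teeth", "mandible", "hyoid",
    "cervical_spine", "thoracic_spine", "lumbar_spine", "sacrum", "coccyx",
    "sternum", "ribs_upper", "ribs_lower", "clavicles", "scapulae",
    "pelvis", "patellae",
    "arm_bone_upper", "arm_bone_middle", "arm_bone_lower",
    "leg_bone_upper", "leg_bone_middle", "leg_bone_lower",
    "hands", "feet",
)

AGE_GROUPS = ("infant", "child", "adult")

_STYLES = ("ds86", "modern")


@dataclass
class BoneSiteRegistry:
    """Site fraction tables for one style (legacy DS86 or modern)."""

    style: str
    marrow_fraction: pd.DataFrame      # index site, columns age
    endosteum_fraction: pd.DataFrame

    def __post_init__(self) -> None:
        for df in (self.marrow_fraction, self.endosteum_fraction):
            if tuple(df.index) != BONE_SITES:
                raise ValueError("fraction table must cover the 25 sites in order")
            sums = df.sum(axis=0)
            if np.any(np.abs(sums - 1.0) > 1e-9):
                raise ValueError(
                    f"fractions must sum to 1 per age, got {dict(sums)}")

    @property
    def sites(self) -> tuple[str, ...]:
        return BONE_SITES

    def fractions(self, tissue: str, age: str) -> pd.Series:
        if age not in AGE_GROUPS:
            raise KeyError(f"unknown age group {age!r}; use one of {AGE_GROUPS}")
        if tissue == "active_marrow":
            return self.marrow_fraction[age]
        if tissue == "endosteum":
            return self.endosteum_fraction[age]
        raise KeyError(f"unknown skeletal tissue {tissue!r}")


def load_registry(style: str = "modern") -> BoneSiteRegistry:
    if style not in _STYLES:
        raise ValueError(f"unknown fraction table style {style!r}; "
                         f"choose from {_STYLES}")
    path = resources.files("j45dose.data") / f"marrow_fractions_{style}.csv"
    df = pd.read_csv(path, comment="#")
    marrow = (df[df.tissue == "active_marrow"]
              .set_index("site")[list(AGE_GROUPS)])
    endo = (df[df.tissue == "endosteum"]
            .set_index("site")[list(AGE_GROUPS)])
    return BoneSiteRegistry(style, marrow.loc[list(BONE_SITES)],
                            endo.loc[list(BONE_SITES)])
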