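"""Recreated DS86/02-style stylized adult phantom.

Builds the adult stylized phantom from the quadric-surface parameter file
(``data/phantom_adult.yaml``): a reconstruction based on the public ORNL
adult stylized phantom with the documented modification list applied — the
1945 Japanese adult standing height, a cylindrical neck containing thyroid
and cervical spine, arms as conical frustums separated from the trunk,
arm/leg bones split into upper/middle/lower thirds, adjusted lung/pancreas/
thyroid/testes volumes, and exactly three media (soft tissue, skeleton,
lung).  The numeric coefficients are reconstructions, not the original
report's values, and are all editable in the config.

Overlaps are resolved by a fixed priority: skeleton > internal organs >
skin > residual soft tissue (registered as the ``muscle`` organ).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from j45dose.geometry import (
    Region,
    Solid,
    Union,
    ellipsoid,
    ellipsoid_shell,
    zcylinder,
    zcylinder_shell,
    zfrustum,
    zfrustum_shell,
)

__all__ = ["ORGANS_28", "MEDIA", "StylizedPhantom", "build_ds8602_adult"]

#: the 28-organ dose-tally registry
ORGANS_28 = (
    "adrenal_glands", "brain", "breasts", "colon", "esophagus",
    "extrathoracic", "eye_lens", "gall_bladder_wall", "heart_wall",
    "kidneys", "liver", "lungs", "lymph_nodes", "muscle", "oral_mucosa",
    "ovaries", "pancreas", "prostate", "salivary_glands",
    "small_intestine_wall", "skin", "spleen", "stomach_wall", "testes",
    "thymus", "thyroid", "urinary_bladder_wall", "uterus",
)

MEDIA = ("soft_tissue", "skeleton", "lung")


class PhantomConfigError(ValueError):
    """Malformed phantom parameter file."""


def _halfplane_cut(region: Region, xmax: float) -> Region:
    from j45dose.geometry import HalfSpace, Intersection, Quadric
    cut = HalfSpace(Quadric(np.zeros((3, 3)), np.array([1.0, 0, 0]), -xmax))
    return Intersection([region, cut])


def _build_region(spec: dict, context: str) -> Region:
    try:
        t = spec["type"]
        if t == "ellipsoid":
            r = ellipsoid(spec["center"], spec["semiaxes"])
        elif t == "ellipsoid_shell":
            r = ellipsoid_shell(spec["center"], spec["semiaxes"],
                                spec["thickness"])
        elif t == "zcylinder":
            r = zcylinder(spec["center"], spec["a"], spec["b"], *spec["z"])
        elif t == "zcylinder_shell":
            r = zcylinder_shell(spec["center"], spec["a"], spec["b"],
                                *spec["z"], spec["thickness"])
        elif t == "zfrustum":
            r = zfrustum(spec["center"], spec["r"][0], spec["z"][0],
                         spec["r"][1], spec["z"][1])
        elif t == "zfrustum_shell":
            r = zfrustum_shell(spec["center"], spec["r"][0], spec["z"][0],
                               spec["r"][1], spec["z"][1], spec["thickness"])
        else:
            raise PhantomConfigError(f"{context}: unknown solid type {t!r}")
    except (KeyError, TypeError, ValueError) as exc:
        if isinstance(exc, PhantomConfigError):
            raise
        raise PhantomConfigError(f"{context}: bad solid spec: {exc}") from exc
    for key, lim in (("zmin", True), ("zmax", False)):
        if key in spec:
            from j45dose.geometry import HalfSpace, Intersection, Quadric
            sign = -1.0 if lim else 1.0
            hs = HalfSpace(Quadric(np.zeros((3, 3)),
                                   np.array([0, 0, sign]),
                                   -sign * spec[key]))
            r = Intersection([r, hs])
    if "xmax" in spec:
        r = _halfplane_cut(r, spec["xmax"])
    return r


def _ellipsoid_volume(spec: dict) -> float:
    a, b, c = spec["semiaxes"]
    return 4.0 / 3.0 * np.pi * a * b * c


def _apply_volume_target(solids: list[dict], target: float, organ: str) -> None:
    """Uniformly rescale ellipsoid semi-axes so total volume hits target."""
    if not all(s["type"] == "ellipsoid" for s in solids):
        raise PhantomConfigError(
            f"volume target for {organ} requires ellipsoid solids")
    current = sum(_ellipsoid_volume(s) for s in solids)
    f = (target / current) ** (1.0 / 3.0)
    for s in solids:
        s["semiaxes"] = [x * f for x in s["semiaxes"]]


@dataclass
class StylizedPhantom:
    """The CSG phantom: named solids in claim-priority order plus media."""

    name: str
    height: float
    solids: list[Solid]                      # priority order, skeleton first
    envelope: Region                          # body outline (union of parts)
    media: dict[str, str]                     # organ -> medium
    densities: dict[str, float]               # medium -> g/cm3
    bone_sites: tuple[str, ...]
    organ_names: tuple[str, ...] = field(default=())

    def organ_solids(self, organ: str) -> list[Solid]:
        out = [s for s in self.solids if s.name == organ]
        if not out:
            raise KeyError(f"phantom has no organ {organ!r}")
        return out

    @property
    def n_media(self) -> int:
        return len(set(self.media.values()))


def _default_config_path() -> Path:
    return Path(resources.files("j45dose.data") / "phantom_adult.yaml")


def build_ds8602_adult(params: str | Path | dict | None = None) -> StylizedPhantom:
    """Build the recreated stylized adult from a parameter file.

    ``params`` may be a path to a YAML config, an already-parsed dict, or
    None for the shipped defaults.
    """
    if params is None or isinstance(params, (str, Path)):
        path = _default_config_path() if params is None else Path(params)
        try:
            cfg = yaml.safe_load(path.read_text())
        except yaml.YAMLError as exc:
            raise PhantomConfigError(f"{path}: {exc}") from exc
    else:
        cfg = params
    for key in ("body", "skeleton", "organs", "densities"):
        if key not in cfg:
            raise PhantomConfigError(f"phantom config missing section {key!r}")
    densities = dict(cfg["densities"])
    if set(densities) != set(MEDIA):
        raise PhantomConfigError(
            f"densities must cover exactly the media {MEDIA}")

    targets = cfg.get("volume_targets_cm3", {})
    for organ, target in targets.items():
        if organ in cfg["organs"]:
            _apply_volume_target(cfg["organs"][organ], target, organ)

    solids: list[Solid] = []
    media: dict[str, str] = {}
    for site, specs in cfg["skeleton"].items():
        media[site] = "skeleton"
        for spec in specs:
            solids.append(Solid(site, _build_region(spec, f"skeleton/{site}"),
                                "skeleton"))
    for organ, specs in cfg["organs"].items():
        for spec in specs:
            medium = spec.get("medium", "soft_tissue")
            media[organ] = medium
            solids.append(Solid(organ, _build_region(spec, f"organs/{organ}"),
                                medium))

    body_parts = {}
    skin_parts = []
    for part, spec in cfg["body"].items():
        body_parts[part] = _build_region(spec, f"body/{part}")
        if spec.get("skin"):
            skin_parts.append(_skin_shell(spec, cfg["skin_thickness_cm"]))
    envelope = Union(list(body_parts.values()))
    solids.append(Solid("skin", Union(skin_parts), "soft_tissue"))
    media["skin"] = "soft_tissue"
    media["muscle"] = "soft_tissue"   # residual soft tissue at voxelization

    bone_sites = tuple(cfg["skeleton"].keys())
    organ_names = tuple(cfg["organs"].keys()) + ("skin", "muscle")
    return StylizedPhantom(
        name=cfg.get("name", "stylized_adult"),
        height=float(cfg.get("height_cm", 160.0)),
        solids=solids,
        envelope=envelope,
        media=media,
        densities=densities,
        bone_sites=bone_sites,
        organ_names=organ_names,
    )


def _skin_shell(spec: dict, thickness: float) -> Region:
    t = spec["type"]
    if t == "zcylinder":
        return zcylinder_shell(spec["center"], spec["a"], spec["b"],
                               *spec["z"], thickness)
    if t == "zfrustum":
        return zfrustum_shell(spec["center"], spec["r"][0], spec["z"][0],
                              spec["r"][1], spec["z"][1], thickness)
    if t == "ellipsoid":
        r: Region = ellipsoid_shell(spec["center"], spec["semiaxes"], thickness)
        if "zmin" in spec:
            from j45dose.geometry import HalfSpace, Intersection, Quadric
            hs = HalfSpace(Quadric(np.zeros((3, 3)),
                                   np.array([0, 0, -1.0]), spec["zmin"]))
            r = Intersection([r, hs])
        return r
    raise PhantomConfigError(f"no skin-shell construction for type {t!r}")
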