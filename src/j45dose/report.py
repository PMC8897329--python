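"""Comparison arithmetic and reporting for survivor organ doses.

Implements the bookkeeping used when comparing a new dose calculation
against the reference dosimetry-system values: percent differences with
the reference-minus-new-over-new convention, RBE weighting of the neutron
absorbed dose (factors of 10, or up to 80 for the colon, are used in
survivor risk analyses), surrogate-organ evaluation for organs absent from
the legacy phantom (including the shielded-air-KERMA skin surrogate), and
long-format scenario sweep tables with chart-ready nine-component
decompositions.

Percent differences are ``(dose_ref - dose_new) / dose_new * 100``,
reported to one decimal with round-half-even — e.g. reference 3465.3 mGy
vs new 3545.2 mGy gives -2.3%.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from j45dose.transport import (
    DoseResult,
    GAMMA_COMPONENTS,
    NEUTRON_COMPONENTS,
    NINE_COMPONENTS,
)

__all__ = [
    "DoseComparison",
    "SurrogateMap",
    "DEFAULT_SURROGATES",
    "percent_difference",
    "rbe_weighted_total",
    "surrogate_report",
    "scenario_sweep",
    "compare_doses",
]

CATEGORIES = ("total", "neutron", "gamma")


def percent_difference(dose_new: float, dose_ref: float) -> float:
    """(reference - new) / new x 100, rounded to one decimal (half-even)."""
    if dose_new == 0:
        raise ZeroDivisionError(
            "percent difference undefined for a zero new-method dose")
    return float(np.round((dose_ref - dose_new) / dose_new * 100.0, 1))


@dataclass(frozen=True)
class DoseComparison:
    organ: str
    category: str
    dose_new: float      # mGy
    dose_ref: float      # mGy

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown dose category {self.category!r}")

    @property
    def percent_diff(self) -> float:
        return percent_difference(self.dose_new, self.dose_ref)


def rbe_weighted_total(
    components: dict[str, float] | pd.Series,
    rbe: float,
    weight_ng: bool = False,
) -> float:
    """RBE-weighted total dose: gammas + rbe x neutron absorbed dose (mGy).

    Only the prompt/delayed neutron absorbed-dose components are weighted by
    default; neutron-induced gammas and air electrons are gamma-type dose
    and stay unweighted unless ``weight_ng`` is set.
    """
    if rbe < 0:
        raise ValueError("RBE must be non-negative")
    comp = pd.Series(components)
    missing = set(NINE_COMPONENTS) - set(comp.index)
    if missing:
        raise KeyError(f"missing dose components: {sorted(missing)}")
    weighted = set(NEUTRON_COMPONENTS)
    if weight_ng:
        weighted |= {"body_prompt_NG", "body_delayed_NG",
                     "sec_shielded_prompt_NG", "sec_shielded_delayed_NG"}
    total = 0.0
    for name in NINE_COMPONENTS:
        total += comp[name] * (rbe if name in weighted else 1.0)
    return float(total)


@dataclass(frozen=True)
class SurrogateMap:
    """Organ -> surrogate pairs used in legacy risk analyses.

    The special surrogate ``shielded_air_kerma`` marks organs whose legacy
    dose came from the free-in-air KERMA scalar rather than a phantom organ
    (the maximum-skin-dose convention).
    """

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        for organ, surrogate in self.pairs.items():
            seen = {organ}
            cur = surrogate
            while cur in self.pairs:
                if cur in seen:
                    raise ValueError(f"cyclic surrogate chain at {cur!r}")
                seen.add(cur)
                cur = self.pairs[cur]


DEFAULT_SURROGATES = SurrogateMap({
    "extrathoracic": "skin",
    "prostate": "urinary_bladder_wall",
    "gall_bladder_wall": "pancreas",
    "esophagus": "stomach_wall",
    "skin": "shielded_air_kerma",
})


def surrogate_report(
    results: DoseResult,
    surrogates: SurrogateMap = DEFAULT_SURROGATES,
    shielded_air_kerma: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Percent difference of the surrogate dose vs the true organ dose.

    One row per (organ, category): dose_new is the organ's own dose,
    dose_ref the surrogate's.  The skin surrogate uses the scenario's
    shielded air KERMA scalar (gamma + neutron parts), which is constant
    across phantom ages by construction.
    """
    rows = []
    for organ, surrogate in surrogates.pairs.items():
        if organ not in results.organs:
            raise KeyError(f"results carry no organ {organ!r}")
        for category in CATEGORIES:
            new = results.category(organ, category)
            if surrogate == "shielded_air_kerma":
                if shielded_air_kerma is None:
                    raise ValueError(
                        "skin surrogate needs the shielded_air_kerma scalars")
                if category == "total":
                    ref = sum(shielded_air_kerma.values())
                else:
                    ref = shielded_air_kerma[category]
            else:
                if surrogate not in results.organs:
                    raise KeyError(f"results carry no organ {surrogate!r}")
                ref = results.category(surrogate, category)
            rows.append({
                "organ": organ,
                "surrogate": surrogate,
                "category": category,
                "dose_new_mGy": new,
                "dose_surrogate_mGy": ref,
                "percent_diff": percent_difference(new, ref),
            })
    return pd.DataFrame(rows)


def compare_doses(
    new: DoseResult, ref: DoseResult, organs=None,
) -> pd.DataFrame:
    """Organ x category percent-difference table between two dose results."""
    organs = organs or [o for o in new.organs if o in ref.organs]
    rows = []
    for organ in organs:
        for category in CATEGORIES:
            dn = new.category(organ, category)
            rows.append({
                "organ": organ, "category": category,
                "dose_new_mGy": dn,
                "dose_ref_mGy": ref.category(organ, category),
                "percent_diff": percent_difference(
                    dn, ref.category(organ, category)),
            })
    return pd.DataFrame(rows)


def scenario_sweep(
    results_by_scenario: dict[str, DoseResult],
    organs: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Long-format sweep table plus stacked-component chart data.

    Returns ``(table, chart)``: the table has one row per scenario x organ
    x category with the dose and its quadrature-propagated error; the chart
    frame has one row per scenario x organ with the nine components in
    their canonical stacking order plus the total.
    """
    if not results_by_scenario:
        raise ValueError("need at least one scenario result")
    table_rows, chart_rows = [], []
    for scenario, res in results_by_scenario.items():
        names = organs or res.organs
        for organ in names:
            for category in CATEGORIES:
                table_rows.append({
                    "scenario": scenario, "organ": organ,
                    "category": category,
                    "dose_mGy": res.category(organ, category),
                    "error_mGy": res.category_error(organ, category),
                })
            row = {"scenario": scenario, "organ": organ}
            for comp in NINE_COMPONENTS:
                row[comp] = float(res.dose.loc[organ, comp])
            row["total"] = res.total(organ)
            chart_rows.append(row)
    return pd.DataFrame(table_rows), pd.DataFrame(chart_rows)
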