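"""Dietary exposure indices and hazard characterization.

Implements the standard food-chain risk-assessment quantities for a
contamination cocktail of 6 organochlorine-pesticide groups (DDT, HCB,
HCH, aldrin, endosulfan, heptachlor) and 8 heavy metals (Cu, Zn, Ni,
Co, As, Pb, Cd, Cr) measured in 7 food items:

EDI     estimated daily intake, C·Cons/Bw (mg/kg-bw/day), summed over
        foods for a contaminant-group total; a lifetime-averaged
        variant C·IR·(EF/365)·ED/(Bw·AT) is provided for carcinogenic
        averaging times.
ESTI    estimated short-term intake from one full portion at the
        highest residue level, Σ F·HR:P / mean body weight.
HQ/HI   hazard quotient and hazard index, EDI/ADI; a food or group is
        flagged hazardous when the ratio exceeds 1.0.  Percentage
        variants: cHQ = HI_pct = 100·EDI/ADI (chronic) and
        aHQ = 100·ESTI/ARfD (acute).
MPC     fold-excess of a measured concentration over the maximum
        permissible concentration, C/MPC.

Reference doses (ADI, ARfD) are chronic and acute toxicological
limits in mg/kg-bw/day; groups without a published limit (HCB, HCH)
yield explicitly not-computable indices, never silent zeros.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FOOD_ITEMS",
    "PESTICIDE_GROUPS",
    "HEAVY_METALS",
    "CONTAMINANT_GROUPS",
    "ContaminationTable",
    "ReferenceDoses",
    "HazardIndices",
    "compute_edi",
    "compute_edi_lifetime",
    "compute_esti",
    "hazard_indices",
    "mpc_excess",
    "individual_group_edi",
    "cohort_exposure",
    "cohort_norm_exposure",
]

FOOD_ITEMS: tuple[str, ...] = (
    "meat",
    "cucumbers",
    "tomatoes",
    "peppers",
    "apples",
    "pears",
    "milk",
)
PESTICIDE_GROUPS: tuple[str, ...] = (
    "DDT",
    "HCB",
    "HCH",
    "aldrin",
    "endosulfan",
    "heptachlor",
)
HEAVY_METALS: tuple[str, ...] = ("Cu", "Zn", "Ni", "Co", "As", "Pb", "Cd", "Cr")
CONTAMINANT_GROUPS: tuple[str, ...] = PESTICIDE_GROUPS + HEAVY_METALS

#: days per year; EF enters lifetime averaging as the fraction EF/365
DAYS_PER_YEAR = 365.0
#: default carcinogenic averaging time: 70 years in days
DEFAULT_AT_DAYS = 25_550.0


def contaminant_kind(group: str) -> Literal["pesticide", "heavy_metal"]:
    if group in PESTICIDE_GROUPS:
        return "pesticide"
    if group in HEAVY_METALS:
        return "heavy_metal"
    raise KeyError(f"unknown contaminant group {group!r}")


class ContaminationTable:
    """Mean contaminant concentration per (food item, contaminant group).

    Wraps a foods x groups DataFrame of concentrations in mg/kg.
    Missing cells are NaN and stay explicit; an optional parallel table
    of highest residue levels (HR:P) supports acute intake estimates.
    """

    def __init__(self, mean: pd.DataFrame, highest_residue: pd.DataFrame | None = None):
        mean = mean.reindex(index=list(FOOD_ITEMS), columns=list(CONTAMINANT_GROUPS))
        if (mean.to_numpy() < 0).any():
            raise ValueError("concentrations must be non-negative")
        self.mean = mean.astype(float)
        if highest_residue is not None:
            highest_residue = highest_residue.reindex(
                index=list(FOOD_ITEMS), columns=list(CONTAMINANT_GROUPS)
            ).astype(float)
        self.highest_residue = highest_residue

    def concentration(self, food: str, group: str) -> float:
        value = self.mean.at[food, group]
        if pd.isna(value):
            raise KeyError(f"concentration missing for ({food}, {group})")
        return float(value)

    def scaled(self, factor: float) -> "ContaminationTable":
        hr = None if self.highest_residue is None else self.highest_residue * factor
        return ContaminationTable(self.mean * factor, hr)

    # --- long-format CSV round trip: food,group,value with NA tokens ----
    def to_csv(self, path) -> None:
        long = (
            self.mean.rename_axis("food")
            .reset_index()
            .melt(id_vars="food", var_name="group", value_name="value")
        )
        long.to_csv(path, index=False, na_rep="NA")

    @classmethod
    def from_csv(cls, path) -> "ContaminationTable":
        long = pd.read_csv(path, na_values=["NA"])
        required = {"food", "group", "value"}
        if not required.issubset(long.columns):
            raise ValueError(f"contamination file must have columns {sorted(required)}")
        wide = long.pivot(index="food", columns="group", values="value").rename_axis(
            index=None, columns=None
        )
        return cls(wide)


@dataclass
class ReferenceDoses:
    """Toxicological reference values and exposure constants.

    adi / arfd: mg/kg-bw/day per contaminant group, absent where no
    limit is published.  mpc: mg/kg per (food, group).  portion: full
    single-sitting portion mass per food (kg).  EF in days/year, ED
    and AT in days.
    """

    adi: dict[str, float] = field(default_factory=dict)
    arfd: dict[str, float] = field(default_factory=dict)
    mpc: pd.DataFrame | None = None
    portion: dict[str, float] = field(default_factory=dict)
    ef_days_per_year: float = DAYS_PER_YEAR
    ed_days: float = DEFAULT_AT_DAYS
    at_days: float = DEFAULT_AT_DAYS

    def __post_init__(self) -> None:
        for name, table in (("ADI", self.adi), ("ARfD", self.arfd)):
            for group, value in table.items():
                if value is not None and value <= 0:
                    raise ValueError(f"{name}[{group}] must be > 0, got {value}")
        if self.at_days < self.ed_days:
            raise ValueError("averaging time AT must be >= exposure duration ED")

    def mpc_for(self, food: str, group: str) -> float | None:
        if self.mpc is None:
            return None
        try:
            value = self.mpc.at[food, group]
        except KeyError:
            return None
        return None if pd.isna(value) else float(value)


@dataclass(frozen=True)
class HazardIndices:
    """Hazard characterization of one contaminant group.

    Fields are None when the required reference dose is absent
    (explicitly not computable).  ``hi_pct`` and ``chq_pct`` coincide
    by construction — both are 100·EDI/ADI; the hazard flag applies
    the 1.0 threshold to the ratio form.
    """

    group: str
    edi: float
    esti: float | None = None
    hq: float | None = None
    hi_ratio: float | None = None
    hi_pct: float | None = None
    chq_pct: float | None = None
    ahq_pct: float | None = None

    @property
    def hazardous(self) -> bool | None:
        if self.hi_ratio is None:
            return None
        return self.hi_ratio > 1.0


def compute_edi(concentration: float, consumption: float, body_weight: float) -> float:
    """Estimated daily intake C·Cons/Bw in mg/kg-bw/day."""
    if body_weight <= 0:
        raise ValueError(f"body weight must be > 0, got {body_weight}")
    if concentration < 0 or consumption < 0:
        raise ValueError("concentration and consumption must be non-negative")
    return concentration * consumption / body_weight


def compute_edi_lifetime(
    concentration: float,
    ingestion_rate: float,
    ef_days_per_year: float,
    ed_days: float,
    body_weight: float,
    at_days: float = DEFAULT_AT_DAYS,
) -> float:
    """Lifetime-averaged daily intake C·IR·(EF/365)·ED/(Bw·AT).

    The exposure frequency enters as the dimensionless fraction EF/365
    so the result keeps units mg/kg-bw/day and is directly comparable
    with an ADI; with EF=365 and ED=AT it reduces to C·IR/Bw.
    """
    if body_weight <= 0:
        raise ValueError(f"body weight must be > 0, got {body_weight}")
    if at_days <= 0:
        raise ValueError(f"averaging time must be > 0, got {at_days}")
    ef_fraction = ef_days_per_year / DAYS_PER_YEAR
    return concentration * ingestion_rate * ef_fraction * ed_days / (body_weight * at_days)


def compute_esti(
    portions: Mapping[str, float],
    highest_residue: Mapping[str, float],
    mean_body_weight: float,
) -> float:
    """Estimated short-term intake Σ F·HR:P / mean body weight."""
    if mean_body_weight <= 0:
        raise ValueError(f"mean body weight must be > 0, got {mean_body_weight}")
    total = 0.0
    for food, portion in portions.items():
        if food not in highest_residue or pd.isna(highest_residue[food]):
            raise KeyError(f"highest residue level missing for {food!r}")
        total += portion * highest_residue[food]
    return total / mean_body_weight


def hazard_indices(
    edi: float,
    esti: float | None,
    doses: ReferenceDoses,
    group: str,
) -> HazardIndices:
    """All hazard indices of one group; absent doses give None fields."""
    adi = doses.adi.get(group)
    arfd = doses.arfd.get(group)
    hq = hi_ratio = hi_pct = chq_pct = ahq_pct = None
    if adi is not None:
        hq = edi / adi
        hi_ratio = edi / adi
        hi_pct = chq_pct = 100.0 * edi / adi
    if arfd is not None and esti is not None:
        ahq_pct = 100.0 * esti / arfd
    return HazardIndices(
        group=group,
        edi=edi,
        esti=esti,
        hq=hq,
        hi_ratio=hi_ratio,
        hi_pct=hi_pct,
        chq_pct=chq_pct,
        ahq_pct=ahq_pct,
    )


def mpc_excess(concentration: float, mpc: float | None) -> tuple[float | None, bool | None]:
    """(C/MPC fold-excess, exceeds-limit flag); (None, None) if no MPC."""
    if mpc is None or (isinstance(mpc, float) and math.isnan(mpc)):
        return None, None
    if mpc <= 0:
        raise ValueError(f"MPC must be > 0, got {mpc}")
    ratio = concentration / mpc
    return ratio, ratio > 1.0


def individual_group_edi(
    consumption: Mapping[str, float],
    body_weight: float,
    contamination: ContaminationTable,
    groups: Iterable[str] = CONTAMINANT_GROUPS,
) -> dict[str, float]:
    """Group-wise EDI for one diet, summing C·cons/Bw over the 7 foods.

    Milk volumes (L/day) are treated as mass (kg/day) at density 1.
    Missing concentration cells contribute nothing only if the whole
    (food, group) column is absent from the table; a present-but-NaN
    cell raises.
    """
    out: dict[str, float] = {}
    for group in groups:
        total = 0.0
        for food in FOOD_ITEMS:
            cons = consumption.get(food, 0.0)
            if cons == 0.0:
                continue
            total += compute_edi(contamination.concentration(food, group), cons, body_weight)
        out[group] = total
    return out


def _consumption_of(row: pd.Series) -> dict[str, float]:
    return {food: float(row[f"cons_{food}"]) for food in FOOD_ITEMS}


def cohort_exposure(
    individuals: pd.DataFrame,
    contamination: ContaminationTable | Mapping[str, ContaminationTable],
    groups: Iterable[str] = PESTICIDE_GROUPS,
) -> pd.DataFrame:
    """Per-village mean ± sd of individual group-wise EDIs.

    ``contamination`` is either one table for every village or a
    mapping village -> table.  Rows need ``village``, ``weight`` and
    ``cons_<food>`` columns.  Returns a village x group table with
    MultiIndex columns (group, {mean,sd}); sd is the ddof=1 sample
    standard deviation (0 for a single-person village).
    """
    groups = list(groups)
    if len(individuals) == 0:
        raise ValueError("cohort is empty: no individuals to aggregate")
    records = []
    for village, block in individuals.groupby("village", sort=False):
        if len(block) == 0:
            raise ValueError(f"village {village!r} has no individuals")
        table = (
            contamination[village]
            if isinstance(contamination, Mapping)
            else contamination
        )
        per_person = pd.DataFrame(
            [
                individual_group_edi(
                    _consumption_of(row), float(row["weight"]), table, groups
                )
                for _, row in block.iterrows()
            ]
        )
        record: dict[str, object] = {"village": village, "n": len(block)}
        for group in groups:
            record[(group, "mean")] = per_person[group].mean()
            record[(group, "sd")] = (
                per_person[group].std(ddof=1) if len(block) > 1 else 0.0
            )
        records.append(record)
    frame = pd.DataFrame(records).set_index("village")
    frame.columns = pd.MultiIndex.from_tuples(
        [c if isinstance(c, tuple) else (c, "") for c in frame.columns]
    )
    return frame


def cohort_norm_exposure(
    norm_consumption: Mapping[str, float],
    mean_body_weight: float,
    contamination: ContaminationTable,
    groups: Iterable[str] = PESTICIDE_GROUPS,
) -> pd.Series:
    """Cohort-level group EDIs from standard food-intake norms.

    The cohort-norm analogue of the individual calculation: one
    average diet and one mean body weight for the whole cohort.
    """
    edis = individual_group_edi(norm_consumption, mean_body_weight, contamination, groups)
    return pd.Series(edis, name="EDI")
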