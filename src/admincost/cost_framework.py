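"""Cost-centre framework for annual drug-administration costs.

Administration costs are split into two cost centres:

* **proximal costs (Pc)** — resources consumed before or after the drug is
  physically introduced into the patient (pharmacy preparation, monitoring,
  pre-medication, disposal, ...);
* **physical administration costs (PAc)** — the cost of physically
  introducing the drug via an intravenous (IV), subcutaneous (SC) or
  intramuscular (IM) route.

All costs are annual, GBP, for a single patient completing a single
continuous treatment course over 12 months. Dosing frequency (DOSFREQ) is
the number of distinct unit administrations per year, derived from the
licensed dosing interval.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

__all__ = [
    "Route",
    "Indication",
    "CostCentre",
    "DosingRegimen",
    "Product",
    "ResourceItem",
    "CostBreakdown",
    "compute_dosfreq",
    "aggregate_cost_centres",
    "annual_admin_cost",
    "read_products_csv",
    "read_cost_items_csv",
]


class Route(str, Enum):
    """Administration route. IV is the conventional reference formulation."""

    IV = "IV"
    SC = "SC"
    IM = "IM"


class Indication(str, Enum):
    ACUTE = "acute"
    CHRONIC = "chronic"


class CostCentre(str, Enum):
    PROXIMAL = "proximal"
    PHYSICAL = "physical"


#: administrations per year implied by a unit interval of 1
_INTERVALS_PER_YEAR = {"day": 365.0, "week": 52.0, "month": 12.0, "year": 1.0}


@dataclass(frozen=True)
class DosingRegimen:
    """A licensed dosing schedule: one administration every ``interval_value``
    ``interval_unit``s, optionally capped at ``max_doses_per_year`` and with
    ``loading_doses`` extra administrations in the first year."""

    interval_value: float
    interval_unit: str
    max_doses_per_year: Optional[int] = None
    loading_doses: int = 0

    def __post_init__(self) -> None:
        if not self.interval_value > 0:
            raise ValueError(
                f"interval_value must be positive, got {self.interval_value!r}"
            )
        if self.interval_unit not in _INTERVALS_PER_YEAR:
            raise ValueError(
                f"interval_unit must be one of {sorted(_INTERVALS_PER_YEAR)}, "
                f"got {self.interval_unit!r}"
            )
        if self.max_doses_per_year is not None and self.max_doses_per_year <= 0:
            raise ValueError("max_doses_per_year must be a positive integer")
        if self.loading_doses < 0:
            raise ValueError("loading_doses must be non-negative")


def compute_dosfreq(regimen: DosingRegimen) -> float:
    """Annual number of unit administrations implied by a dosing regimen.

    Continuous dosing over 12 months is assumed: ``52/interval`` for weekly
    intervals, ``365/interval`` for daily, ``12/interval`` for monthly.
    Loading doses add to the first-year count; an explicit
    ``max_doses_per_year`` caps the result. Rounded to 2 decimal places
    (three-weekly dosing gives 17.33).
    """
    freq = _INTERVALS_PER_YEAR[regimen.interval_unit] / regimen.interval_value
    freq += regimen.loading_doses
    if regimen.max_doses_per_year is not None:
        freq = min(freq, float(regimen.max_doses_per_year))
    return round(freq, 2)


@dataclass
class Product:
    """A biologic drug product and the regressor-determining attributes.

    ``bundled`` marks products sold together with some of the equipment and
    consumables used in their administration (e.g. prefilled pens).
    ``dosfreq`` may be given directly or derived from ``regimen``.
    """

    name: str
    route: Route
    indication: Indication
    bundled: bool
    dosfreq: Optional[float] = None
    regimen: Optional[DosingRegimen] = None

    def __post_init__(self) -> None:
        self.route = Route(self.route)
        self.indication = Indication(self.indication)
        if self.dosfreq is None and self.regimen is not None:
            self.dosfreq = compute_dosfreq(self.regimen)
        if self.dosfreq is not None and not self.dosfreq > 0:
            raise ValueError(f"dosfreq must be positive, got {self.dosfreq!r}")


@dataclass(frozen=True)
class ResourceItem:
    """One cost line item attributed to a single cost centre.

    Exactly one of ``quantity_per_administration`` / ``quantity_per_year``
    may be nonzero: per-administration quantities scale with DOSFREQ, annual
    quantities do not. Mixed records are rejected to keep provenance
    unambiguous.
    """

    label: str
    cost_centre: CostCentre
    unit_cost: float
    quantity_per_administration: float = 0.0
    quantity_per_year: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "cost_centre", CostCentre(self.cost_centre))
        if self.unit_cost < 0:
            raise ValueError(f"unit_cost must be non-negative, got {self.unit_cost}")
        if self.quantity_per_administration < 0 or self.quantity_per_year < 0:
            raise ValueError("quantities must be non-negative")
        if self.quantity_per_administration > 0 and self.quantity_per_year > 0:
            raise ValueError(
                f"item {self.label!r}: only one of quantity_per_administration "
                "and quantity_per_year may be nonzero"
            )


@dataclass(frozen=True)
class CostBreakdown:
    """Deterministic annual proximal (pc) and physical (pac) costs, GBP."""

    pc: float
    pac: float

    def __post_init__(self) -> None:
        if self.pc < 0 or self.pac < 0:
            raise ValueError("cost-centre totals must be non-negative")

    @property
    def total(self) -> float:
        return self.pc + self.pac


def aggregate_cost_centres(
    items: Iterable[ResourceItem], dosfreq: float
) -> CostBreakdown:
    """Roll line items up into annual per-centre totals.

    Per-administration quantities are multiplied by ``dosfreq``; per-year
    quantities enter once.
    """
    if not dosfreq > 0:
        raise ValueError(f"dosfreq must be positive, got {dosfreq!r}")
    totals = {CostCentre.PROXIMAL: 0.0, CostCentre.PHYSICAL: 0.0}
    for item in items:
        annual = item.unit_cost * (
            item.quantity_per_administration * dosfreq + item.quantity_per_year
        )
        totals[item.cost_centre] += annual
    return CostBreakdown(pc=totals[CostCentre.PROXIMAL], pac=totals[CostCentre.PHYSICAL])


def annual_admin_cost(breakdown: CostBreakdown) -> float:
    """Total annual administration cost: Pc + PAc."""
    return breakdown.total


# ---------------------------------------------------------------------------
# CSV round-tripping


def read_products_csv(path: Union[str, Path]) -> list[Product]:
    """Read a product table.

    Columns: ``name,route,indication,bundled`` plus either ``dosfreq`` or
    ``interval_value,interval_unit[,max_doses_per_year]``.
    """
    df = pd.read_csv(path)
    required = {"name", "route", "indication", "bundled"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"products CSV missing columns: {sorted(missing)}")
    products = []
    for idx, row in df.iterrows():
        try:
            regimen = None
            dosfreq = None
            if "dosfreq" in df.columns and not pd.isna(row["dosfreq"]):
                dosfreq = float(row["dosfreq"])
            elif "interval_value" in df.columns and not pd.isna(row["interval_value"]):
                cap = None
                if "max_doses_per_year" in df.columns and not pd.isna(
                    row.get("max_doses_per_year")
                ):
                    cap = int(row["max_doses_per_year"])
                regimen = DosingRegimen(
                    interval_value=float(row["interval_value"]),
                    interval_unit=str(row["interval_unit"]),
                    max_doses_per_year=cap,
                )
            products.append(
                Product(
                    name=str(row["name"]),
                    route=Route(str(row["route"])),
                    indication=Indication(str(row["indication"])),
                    bundled=bool(int(row["bundled"])),
                    dosfreq=dosfreq,
                    regimen=regimen,
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(f"products CSV row {idx} ({row.get('name')}): {exc}") from exc
    return products


def read_cost_items_csv(path: Union[str, Path]) -> dict[str, list[ResourceItem]]:
    """Read per-product cost line items, keyed by product name.

    Columns: ``product,cost_centre,label,unit_cost,quantity_per_administration,
    quantity_per_year``.
    """
    df = pd.read_csv(path)
    required = {
        "product",
        "cost_centre",
        "label",
        "unit_cost",
        "quantity_per_administration",
        "quantity_per_year",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cost-items CSV missing columns: {sorted(missing)}")
    out: dict[str, list[ResourceItem]] = {}
    for idx, row in df.iterrows():
        try:
            item = ResourceItem(
                label=str(row["label"]),
                cost_centre=CostCentre(str(row["cost_centre"])),
                unit_cost=float(row["unit_cost"]),
                quantity_per_administration=float(row["quantity_per_administration"]),
                quantity_per_year=float(row["quantity_per_year"]),
            )
        except ValueError as exc:
            raise ValueError(f"cost-items CSV row {idx}: {exc}") from exc
        out.setdefault(str(row["product"]), []).append(item)
    return out
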