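"""Synthetic product samples, model-based data generation, and fixtures.

The real cost inputs behind the 18-product study sample (per-product dosing
regimens and line-item unit costs) are not publicly deposited, so this
module generates product samples with the same *structure*: 18 biologics
(8 IV, 8 SC, 2 IM), two acute indications (one IV, one IM — no SC product
is acute), every SC/IM product sold bundled, route-typical annual dosing
frequencies, and skewed positive cost magnitudes in which intravenous
products carry a larger physical-administration (PAc) share than
subcutaneous or intramuscular ones.

``reference_fixtures`` loads the printed constants (product roster, fitted
coefficient tables, smearing factors, and the trastuzumab reformulation
worked example) shipped as JSON/CSV package data, for desk-scale checks and
prediction-only use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cost_framework import (
    CostBreakdown,
    CostCentre,
    Indication,
    Product,
    ResourceItem,
    Route,
    aggregate_cost_centres,
)
from .prediction import CoefficientSet, Scenario, predict_ln_cost
from .retransformation import SmearingFactors

__all__ = [
    "GeneratorConfig",
    "FixtureBundle",
    "generate_product_sample",
    "generate_input_tables",
    "generate_from_model",
    "reference_fixtures",
]

#: route-typical annual dosing-frequency ranges (administrations/year)
DOSFREQ_RANGES = {"IV": (4.0, 26.0), "SC": (12.0, 156.0), "IM": (6.0, 365.0)}

#: route-typical per-administration cost magnitudes (GBP, log-normal medians).
#: IV administration consumes infusion-suite time so its physical (PAc)
#: component dominates; SC/IM products are largely self- or nurse-injected
#: so the proximal (Pc) component dominates.
_COST_MEDIANS = {
    "IV": {"pc_per_admin": 150.0, "pac_per_admin": 250.0},
    "SC": {"pc_per_admin": 25.0, "pac_per_admin": 8.0},
    "IM": {"pc_per_admin": 20.0, "pac_per_admin": 10.0},
}
_COST_LOG_SD = 0.5  # spread of per-administration costs across products


@dataclass
class GeneratorConfig:
    """Study-sample structure for the synthetic generator."""

    n_products: int = 18
    route_mix: dict = field(default_factory=lambda: {"IV": 8, "SC": 8, "IM": 2})
    n_acute: int = 2
    seed: int = 0
    cost_scale_range: tuple = (35.0, 19000.0)
    true_coefficients: Optional[CoefficientSet] = None

    def __post_init__(self) -> None:
        if sum(self.route_mix.values()) != self.n_products:
            raise ValueError(
                f"route_mix {self.route_mix} does not sum to n_products "
                f"{self.n_products}"
            )
        if self.n_acute > self.route_mix.get("IV", 0) + self.route_mix.get("IM", 0):
            raise ValueError("acute products are placed in IV/IM groups only")


def _make_products(config: GeneratorConfig, rng: np.random.Generator) -> list[Product]:
    products = []
    # acute slots: first IV product, then first IM product, then further IV
    acute_slots = []
    if config.route_mix.get("IV", 0) > 0 and config.n_acute >= 1:
        acute_slots.append(("IV", 0))
    if config.route_mix.get("IM", 0) > 0 and config.n_acute >= 2:
        acute_slots.append(("IM", 0))
    for extra in range(config.n_acute - len(acute_slots)):
        acute_slots.append(("IV", 1 + extra))
    acute_slots = set(acute_slots)

    for route in ("IV", "SC", "IM"):
        count = config.route_mix.get(route, 0)
        lo, hi = DOSFREQ_RANGES[route]
        # all SC/IM products are bundled; a fixed quarter of IV ones are,
        # which keeps bundling linearly independent of the route dummies
        n_iv_bundled = max(1, count // 4) if route == "IV" and count > 1 else 0
        iv_bundled = set(rng.permutation(count)[:n_iv_bundled]) if count else set()
        for i in range(count):
            dosfreq = round(float(rng.uniform(lo, hi)), 2)
            indication = (
                Indication.ACUTE if (route, i) in acute_slots else Indication.CHRONIC
            )
            bundled = True if route in ("SC", "IM") else i in iv_bundled
            products.append(
                Product(
                    name=f"{route}-{i + 1:02d}",
                    route=Route(route),
                    indication=indication,
                    bundled=bundled,
                    dosfreq=dosfreq,
                )
            )
    return products


def _make_items(
    product: Product, rng: np.random.Generator, config: GeneratorConfig
) -> list[ResourceItem]:
    med = _COST_MEDIANS[product.route.value]
    pc_admin = float(np.exp(np.log(med["pc_per_admin"]) + _COST_LOG_SD * rng.standard_normal()))
    pac_admin = float(np.exp(np.log(med["pac_per_admin"]) + _COST_LOG_SD * rng.standard_normal()))
    items = [
        ResourceItem(
            label="preparation and monitoring",
            cost_centre=CostCentre.PROXIMAL,
            unit_cost=pc_admin,
            quantity_per_administration=1.0,
        ),
        ResourceItem(
            label="physical administration",
            cost_centre=CostCentre.PHYSICAL,
            unit_cost=pac_admin,
            quantity_per_administration=1.0,
        ),
    ]
    if product.indication == Indication.CHRONIC:
        items.append(
            ResourceItem(
                label="annual clinical review",
                cost_centre=CostCentre.PROXIMAL,
                unit_cost=float(rng.uniform(50.0, 150.0)),
                quantity_per_year=2.0,
            )
        )
    return items


def generate_product_sample(
    config: Optional[GeneratorConfig] = None,
) -> list[tuple[Product, CostBreakdown]]:
    """Products with deterministic annual Pc/PAc cost breakdowns.

    Deterministic under ``config.seed``. Cost totals are clipped into
    ``cost_scale_range`` to keep magnitudes in a realistic GBP band.
    """
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    out = []
    lo, hi = config.cost_scale_range
    for product in _make_products(config, rng):
        items = _make_items(product, rng, config)
        bd = aggregate_cost_centres(items, product.dosfreq)
        total = bd.total
        if total > 0 and not (lo <= total <= hi):
            scale = float(np.clip(total, lo, hi)) / total
            bd = CostBreakdown(pc=bd.pc * scale, pac=bd.pac * scale)
        out.append((product, bd))
    return out


def generate_input_tables(
    config: Optional[GeneratorConfig] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(products, cost-items) DataFrames in the CSV interchange layout."""
    config = config or GeneratorConfig()
    rng = np.random.default_rng(config.seed)
    prod_rows, item_rows = [], []
    for product in _make_products(config, rng):
        prod_rows.append(
            {
                "name": product.name,
                "route": product.route.value,
                "indication": product.indication.value,
                "bundled": int(product.bundled),
                "dosfreq": product.dosfreq,
            }
        )
        for item in _make_items(product, rng, config):
            item_rows.append(
                {
                    "product": product.name,
                    "cost_centre": item.cost_centre.value,
                    "label": item.label,
                    "unit_cost": round(item.unit_cost, 2),
                    "quantity_per_administration": item.quantity_per_administration,
                    "quantity_per_year": item.quantity_per_year,
                }
            )
    return pd.DataFrame(prod_rows), pd.DataFrame(item_rows)


def generate_from_model(
    config: GeneratorConfig, log_error_sd: float = 0.84
) -> tuple[list[Product], np.ndarray]:
    """Products plus raw-scale responses drawn from the cost model itself.

    ln(cost) = linear index of ``config.true_coefficients`` + N(0, sd) noise.
    Used for parameter-recovery and retransformation-bias experiments; the
    default noise scale matches the log-scale prediction SE of the full
    model fit.
    """
    if config.true_coefficients is None:
        raise ValueError("config.true_coefficients is required for model-based generation")
    if log_error_sd < 0:
        raise ValueError("log_error_sd must be non-negative")
    rng = np.random.default_rng(config.seed)
    products = _make_products(config, rng)
    index = np.array(
        [
            predict_ln_cost(
                config.true_coefficients,
                Scenario(
                    route=p.route,
                    indication=p.indication,
                    bundled=p.bundled,
                    dosfreq=p.dosfreq,
                ),
            )
            for p in products
        ]
    )
    ln_y = index + log_error_sd * rng.standard_normal(len(products))
    return products, np.exp(ln_y)


# ---------------------------------------------------------------------------
# fixtures: printed constants for desk-scale checks and prediction-only use


@dataclass
class FixtureBundle:
    """The printed study constants, loaded from packaged data files."""

    products: list
    coefficients_table2: dict  # model id -> CoefficientSet (stats attached)
    coefficients_table3: dict  # estimator name -> CoefficientSet
    table2_stats: dict
    table3_stats: dict
    smearing: dict
    worked_example: dict

    def worked_example_coefficients(self) -> CoefficientSet:
        return CoefficientSet.from_dict(self.worked_example["coefficient_set"])

    def worked_example_scenarios(self) -> tuple[Scenario, Scenario]:
        def _mk(d):
            return Scenario(
                route=Route(d["route"]),
                indication=Indication(d["indication"]),
                bundled=bool(d["bundled"]),
                dosfreq=float(d["dosfreq"]),
            )

        return _mk(self.worked_example["scenario_iv"]), _mk(
            self.worked_example["scenario_sc"]
        )


def _fixture_text(name: str) -> str:
    return resources.files("admincost.fixtures").joinpath(name).read_text()


def reference_fixtures() -> FixtureBundle:
    """Load the product roster, coefficient tables, smearing factors and the
    trastuzumab worked example from packaged fixture files."""
    import io

    products_df = pd.read_csv(io.StringIO(_fixture_text("products_table1.csv")))
    products = [
        Product(
            name=str(r["name"]),
            route=Route(str(r["route"])),
            indication=Indication(str(r["indication"])),
            bundled=bool(int(r["bundled"])),
        )
        for _, r in products_df.iterrows()
    ]
    t2 = json.loads(_fixture_text("coefficients_table2.json"))
    t3 = json.loads(_fixture_text("coefficients_table3.json"))
    table2, t2_stats = {}, {}
    for model_id, block in t2["models"].items():
        table2[model_id] = CoefficientSet(
            coefficients=block["coefficients"],
            se=block["se"],
            estimator="log_ols",
            model_id=model_id,
            se_source=t2["se_source"],
        )
        t2_stats[model_id] = block["stats"]
    table3, t3_stats = {}, {}
    for est, block in t3["estimators"].items():
        table3[est] = CoefficientSet(
            coefficients=block["coefficients"],
            se=block["se"],
            estimator=est,
            model_id="C",
            se_source=t3["se_source"],
        )
        t3_stats[est] = block["stats"]
    return FixtureBundle(
        products=products,
        coefficients_table2=table2,
        coefficients_table3=table3,
        table2_stats=t2_stats,
        table3_stats=t3_stats,
        smearing=json.loads(_fixture_text("smearing_validation.json")),
        worked_example=json.loads(_fixture_text("worked_example.json")),
    )
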