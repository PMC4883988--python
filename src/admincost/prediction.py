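"""The administration-cost algorithm: raw-scale prediction for a
formulation scenario, incremental and marginal effects, turning points,
and route-switch savings.

A fitted coefficient set on the full (model C) regressor list predicts
ln(annual administration cost) as a linear index; the raw-scale cost is
exp(index) times a smearing factor. Coefficients are stored signed; the
Kennedy-corrected incremental effect for a dummy regressor is
100*[exp(b - SE(b)^2/2) - 1] and the dosing-frequency marginal effect is
the derivative 100*(b_DOSFREQ + 2*b_DOSFREQ2*f + b_DOSFREQxIND*INDICATN).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

from .cost_framework import Indication, Route
from .retransformation import SmearingFactors

__all__ = [
    "Scenario",
    "CoefficientSet",
    "PredictionResult",
    "MODEL_C_TERMS",
    "predict_ln_cost",
    "predict_cost",
    "incremental_effect",
    "marginal_effect_dosfreq",
    "turning_point",
    "switch_savings",
]

#: full-model coefficient names, intercept first
MODEL_C_TERMS = [
    "intercept",
    "subcutaneous",
    "intramuscular",
    "dosfreq",
    "productbund",
    "indicatn",
    "dosfreq_sq",
    "dosfreq_x_indicatn",
]


@dataclass(frozen=True)
class Scenario:
    """A formulation scenario: route, indication, bundling, annual dosing."""

    route: Route
    indication: Indication
    bundled: bool
    dosfreq: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "route", Route(self.route))
        object.__setattr__(self, "indication", Indication(self.indication))
        if not self.dosfreq > 0:
            raise ValueError(f"dosfreq must be positive, got {self.dosfreq}")


@dataclass
class CoefficientSet:
    """Full-model coefficients (log-GBP scale), their SEs and smearing.

    ``se_source`` records whether the stored SEs are classical ("default")
    or heteroskedasticity-robust ("robust").
    """

    coefficients: dict
    se: dict = field(default_factory=dict)
    smearing: Optional[SmearingFactors] = None
    estimator: str = ""
    model_id: str = "C"
    se_source: str = "robust"

    def require(self, term: str) -> float:
        if term not in self.coefficients:
            raise ValueError(f"coefficient set is missing {term!r}")
        return float(self.coefficients[term])

    # -- JSON round-trip -----------------------------------------------------

    def to_dict(self) -> dict:
        d = {
            "model_id": self.model_id,
            "estimator": self.estimator,
            "se_source": self.se_source,
            "coefficients": dict(self.coefficients),
            "se": dict(self.se),
        }
        if self.smearing is not None:
            d["smearing"] = {
                "normal_theory": self.smearing.normal_theory,
                "duan": self.smearing.duan_overall,
                "subgroup": dict(self.smearing.subgroup),
                "wooldridge": self.smearing.wooldridge,
                "selected": self.smearing.selected or "subgroup",
            }
        return d

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, d: dict) -> "CoefficientSet":
        smearing = None
        if "smearing" in d:
            s = d["smearing"]
            smearing = SmearingFactors(
                normal_theory=s.get("normal_theory", float("nan")),
                duan_overall=s.get("duan", float("nan")),
                subgroup=dict(s.get("subgroup", {})),
                wooldridge=s.get("wooldridge", float("nan")),
                selected=s.get("selected"),
            )
        return cls(
            coefficients=dict(d["coefficients"]),
            se=dict(d.get("se", {})),
            smearing=smearing,
            estimator=d.get("estimator", ""),
            model_id=d.get("model_id", "C"),
            se_source=d.get("se_source", "robust"),
        )

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "CoefficientSet":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass(frozen=True)
class PredictionResult:
    """One raw-scale cost prediction: cost = exp(ln_cost) * factor_used."""

    ln_cost: float
    cost: float
    factor_used: float
    factor_method: str


def predict_ln_cost(coefs: CoefficientSet, scenario: Scenario) -> float:
    """Linear index: a + b0*SC + b1*IM + b2*f + b3*BUND + b4*IND
    + b5*f^2 + b6*f*IND."""
    f = scenario.dosfreq
    ind = 1.0 if scenario.indication == Indication.CHRONIC else 0.0
    return (
        coefs.require("intercept")
        + coefs.require("subcutaneous") * (1.0 if scenario.route == Route.SC else 0.0)
        + coefs.require("intramuscular") * (1.0 if scenario.route == Route.IM else 0.0)
        + coefs.require("dosfreq") * f
        + coefs.require("productbund") * (1.0 if scenario.bundled else 0.0)
        + coefs.require("indicatn") * ind
        + coefs.require("dosfreq_sq") * f**2
        + coefs.require("dosfreq_x_indicatn") * f * ind
    )


def predict_cost(
    coefs: CoefficientSet,
    scenario: Scenario,
    factor_method: str = "subgroup",
) -> PredictionResult:
    """Raw-scale annual cost: exp(linear index) times the smearing factor
    for the scenario's route (overall Duan factor as fallback)."""
    if coefs.smearing is None:
        raise ValueError("coefficient set carries no smearing factors")
    ln_cost = predict_ln_cost(coefs, scenario)
    factor = coefs.smearing.factor_for_route(scenario.route.value, factor_method)
    return PredictionResult(
        ln_cost=ln_cost,
        cost=math.exp(ln_cost) * factor,
        factor_used=factor,
        factor_method=factor_method,
    )


def incremental_effect(beta: float, se: float = 0.0, method: str = "kennedy") -> float:
    """Percent change in predicted cost when a dummy regressor flips 0 -> 1.

    ``kennedy`` subtracts half the squared SE inside the exponent,
    correcting small-sample bias: 100*[exp(b - SE^2/2) - 1]. ``simple`` is
    100*[exp(b) - 1].
    """
    if method == "kennedy":
        if se < 0:
            raise ValueError("se must be non-negative")
        return 100.0 * (math.exp(beta - 0.5 * se**2) - 1.0)
    if method == "simple":
        return 100.0 * (math.exp(beta) - 1.0)
    raise ValueError(f"unknown method {method!r}")


def marginal_effect_dosfreq(
    coefs: CoefficientSet, dosfreq: float, indication: Union[Indication, str]
) -> float:
    """Percent change in cost per additional unit administration.

    The curvilinear derivative of the log-cost index:
    100*(b_DOSFREQ + 2*b_DOSFREQ2*f + b_DOSFREQxIND*INDICATN) with signed
    coefficients.
    """
    if dosfreq < 0:
        raise ValueError("dosfreq must be non-negative")
    ind = 1.0 if Indication(indication) == Indication.CHRONIC else 0.0
    return 100.0 * (
        coefs.require("dosfreq")
        + 2.0 * coefs.require("dosfreq_sq") * dosfreq
        + coefs.require("dosfreq_x_indicatn") * ind
    )


def turning_point(
    coefs: CoefficientSet, indication: Union[Indication, str]
) -> Optional[float]:
    """Dosing frequency beyond which predicted cost declines.

    DOSFREQ* = (b_DOSFREQ + b_DOSFREQxIND*INDICATN) / (-2*b_DOSFREQ2);
    None when the quadratic coefficient is non-negative (monotone
    relationship, no interior maximum).
    """
    b5 = coefs.require("dosfreq_sq")
    if b5 >= 0:
        return None
    ind = 1.0 if Indication(indication) == Indication.CHRONIC else 0.0
    return (coefs.require("dosfreq") + coefs.require("dosfreq_x_indicatn") * ind) / (
        -2.0 * b5
    )


def switch_savings(
    coefs: CoefficientSet,
    scenario_from: Scenario,
    scenario_to: Scenario,
    cohort_size: int = 1,
    factor_method: str = "subgroup",
) -> tuple[float, float]:
    """(per-patient, cohort) annual saving from switching formulation.

    Negative values are reported as-is: they are cost increases.
    """
    cost_from = predict_cost(coefs, scenario_from, factor_method).cost
    cost_to = predict_cost(coefs, scenario_to, factor_method).cost
    per_patient = cost_from - cost_to
    return per_patient, per_patient * cohort_size
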