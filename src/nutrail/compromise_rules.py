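"""Rules of compromise: predicted intake on a single imbalanced food rail.

When an animal is confined to one food whose protein:lipid ratio differs from
its intake target IT = (P_T, L_T), it cannot reach the target: every feasible
intake lies on the food rail.  A "rule of compromise" picks the point on the
rail at which feeding stops.  Five rules are implemented in closed form, with
``a`` the total amount of food eaten (mg/bee), ``p``/``l`` the diet's protein
and lipid mass fractions:

``protein_priority``
    Eat until protein intake meets the target regardless of lipid:
    ``a = P_T / p``.
``lipid_priority``
    Eat until lipid intake meets the target: ``a = L_T / l``.
``closest_distance``
    Stop at the point on the rail nearest the target (orthogonal projection):
    ``a = (P_T p + L_T l) / (p^2 + l^2)``.
``equal_distance``
    Overeat one nutrient by exactly the amount the other is undereaten:
    ``a = (P_T + L_T) / (p + l)``.
``strict_restraint``
    Stop as soon as *either* nutrient reaches its target, so neither is ever
    overconsumed: ``a = min(P_T / p, L_T / l)``.  This is the regulation
    signature observed in nurse honeybees.

If the rail passes through the target all five rules coincide at the target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .diet_geometry import Diet, NutrientPoint, pl_ratio, rail_point
from .errors import DegenerateRailError, DomainError, InsufficientDataError

#: Fixed rule order; also the deterministic tie-break order in classify_rule.
RULES: tuple[str, ...] = ("strict_restraint", "closest_distance",
                          "equal_distance", "protein_priority", "lipid_priority")


@dataclass(frozen=True)
class IntakeTarget:
    """The protein-lipid intake target IT, mg per bee over the experiment horizon."""

    point: NutrientPoint
    source: str = ""

    def __post_init__(self) -> None:
        if self.point.protein_mg <= 0 or self.point.lipid_mg <= 0:
            raise DomainError(
                f"intake target coordinates must be positive, got {self.point}")

    @property
    def ratio(self) -> float:
        return self.point.protein_mg / self.point.lipid_mg


@dataclass(frozen=True)
class RulePrediction:
    """Predicted stopping point on one diet's rail under one rule."""

    rule: str
    diet: Diet
    amount: float  # mg food per bee
    point: NutrientPoint


@dataclass(frozen=True)
class Deviation:
    """Observed minus target intake; positive means overconsumption."""

    delta_protein: float
    delta_lipid: float


@dataclass(frozen=True)
class RuleFit:
    """Model-selection result: summed squared residual per rule, best rule first."""

    best_rule: str
    residuals: dict[str, float]
    n_diets: int


def _rule_amount(rule: str, diet: Diet, target: IntakeTarget) -> float:
    p, l = diet.protein_frac, diet.lipid_frac
    pt, lt = target.point.protein_mg, target.point.lipid_mg
    if rule == "protein_priority":
        return pt / p
    if rule == "lipid_priority":
        return lt / l
    if rule == "closest_distance":
        return (pt * p + lt * l) / (p * p + l * l)
    if rule == "equal_distance":
        return (pt + lt) / (p + l)
    if rule == "strict_restraint":
        return min(pt / p, lt / l)
    raise ValueError(f"unknown rule {rule!r}; expected one of {RULES}")


def predict_intake(rule: str, diet: Diet, target: IntakeTarget) -> RulePrediction:
    """Closed-form predicted intake point for one rule on one food rail."""
    if diet.protein_frac == 0 or diet.lipid_frac == 0:
        raise DegenerateRailError(f"{diet.name}: rail must have p > 0 and l > 0")
    amount = _rule_amount(rule, diet, target)
    return RulePrediction(rule=rule, diet=diet, amount=amount,
                          point=rail_point(diet, amount))


def infer_intake_target(no_choice_summary: dict[Diet, float]) -> IntakeTarget:
    """Infer the intake target from no-choice mean total per-capita consumption.

    The target is the intake point reached on the most-consumed diet's rail:
    the diet whose rail the animals can fully exploit reveals both the
    preferred ratio and the preferred amount.  Exact ties in consumption are
    broken toward the diet whose P:L ratio is nearest 1 on a log scale, and
    the tie is recorded in the returned target's ``source``.
    """
    if not no_choice_summary:
        raise DomainError("no-choice summary is empty")
    positive = {d: c for d, c in no_choice_summary.items() if c > 0}
    if len(positive) < 2:
        raise DomainError("need >= 2 diets with positive consumption")
    best = max(positive.values())
    winners = [d for d, c in positive.items() if c == best]
    tie = len(winners) > 1
    diet = min(winners, key=lambda d: abs(math.log(pl_ratio(d))))
    source = f"argmax no-choice consumption ({diet.name})"
    if tie:
        source += f"; tie among {sorted(d.name for d in winners)} broken by log-ratio"
    return IntakeTarget(point=rail_point(diet, positive[diet]), source=source)


def deviation_from_target(point: NutrientPoint, target: IntakeTarget) -> Deviation:
    """Per-nutrient deviation (observed - target); positive = overconsumption."""
    return Deviation(delta_protein=point.protein_mg - target.point.protein_mg,
                     delta_lipid=point.lipid_mg - target.point.lipid_mg)


def classify_rule(observed: dict[Diet, NutrientPoint],
                  target: IntakeTarget) -> RuleFit:
    """Select the rule of compromise best explaining observed intake points.

    Residual per rule is the summed squared Euclidean distance (mg^2) between
    each diet's observed intake point and that rule's prediction.  Diets whose
    rails pass through the target are uninformative (all rules predict the
    target there) and at least two informative diets are required.  Ties are
    broken by the fixed order in :data:`RULES`.
    """
    informative = 0
    for diet in observed:
        preds = {r: _rule_amount(r, diet, target) for r in RULES}
        if max(preds.values()) - min(preds.values()) > 1e-9:
            informative += 1
    if informative < 2:
        raise InsufficientDataError(
            f"need >= 2 diets whose rails miss the target; got {informative}")
    residuals: dict[str, float] = {}
    for rule in RULES:
        ss = 0.0
        for diet, pt in observed.items():
            pred = predict_intake(rule, diet, target).point
            ss += pt.distance_to(pred) ** 2
        residuals[rule] = ss
    best_rule = min(RULES, key=lambda r: residuals[r])
    return RuleFit(best_rule=best_rule, residuals=residuals,
                   n_diets=len(observed))
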