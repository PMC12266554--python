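"""Artificial diets as recipes and as rays ("food rails") in protein-lipid space.

The experimental diets are solid pollen-substitute foods whose protein (P) plus
lipid (L) content is always 50% of wet mass; the other half is a fixed
carbohydrate-vitamin-filler blend (39.5% sucrose solution, 0.5% vitamin mix,
10% cellulose).  Because a single food has a fixed P:L composition, everything a
cage eats from it lies on a ray through the origin of the (protein, lipid)
intake plane — the food rail.  This module owns the recipe arithmetic, the rail
geometry, and the canonical "P30:L20"-style naming.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import pandas as pd

from .errors import (
    DomainError,
    InvalidCompositionError,
    LookupError_,
    UndefinedRatioError,
)

#: Fixed non-macronutrient recipe fractions (of wet mass) shared by all diets.
SUCROSE_SOLUTION_FRAC = 0.395
VITAMIN_FRAC = 0.005
CELLULOSE_FRAC = 0.10
#: Protein + lipid is half the wet mass for every valid diet.
MACRO_FRAC = 0.50

_FRACTION_TOL = 1e-9

_NAME_RE = re.compile(r"^\s*P\s*(\d+(?:\.\d+)?)\s*:\s*L\s*(\d+(?:\.\d+)?)\s*$", re.I)


@dataclass(frozen=True)
class NutrientPoint:
    """A point in protein-lipid intake space, in mg per bee."""

    protein_mg: float
    lipid_mg: float

    def __add__(self, other: "NutrientPoint") -> "NutrientPoint":
        return NutrientPoint(self.protein_mg + other.protein_mg,
                             self.lipid_mg + other.lipid_mg)

    def distance_to(self, other: "NutrientPoint") -> float:
        return math.hypot(self.protein_mg - other.protein_mg,
                          self.lipid_mg - other.lipid_mg)


@dataclass(frozen=True)
class Diet:
    """A fixed-composition artificial diet, fractions of wet mass.

    Invariants: all fractions in [0, 1] and summing to 1; protein + lipid
    equal to 0.50 (the recipe's design constraint); both macronutrients
    strictly positive so the food rail is a proper ray.
    """

    name: str
    protein_frac: float
    lipid_frac: float
    sucrose_solution_frac: float = SUCROSE_SOLUTION_FRAC
    vitamin_frac: float = VITAMIN_FRAC
    cellulose_frac: float = CELLULOSE_FRAC

    def __post_init__(self) -> None:
        fracs = (self.protein_frac, self.lipid_frac, self.sucrose_solution_frac,
                 self.vitamin_frac, self.cellulose_frac)
        if any(f < -_FRACTION_TOL or f > 1 + _FRACTION_TOL for f in fracs):
            raise InvalidCompositionError(
                f"{self.name}: fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > _FRACTION_TOL:
            raise InvalidCompositionError(
                f"{self.name}: fractions sum to {sum(fracs)!r}, expected 1")
        if abs(self.protein_frac + self.lipid_frac - MACRO_FRAC) > _FRACTION_TOL:
            raise InvalidCompositionError(
                f"{self.name}: protein + lipid fraction must equal {MACRO_FRAC}, "
                f"got {self.protein_frac + self.lipid_frac}")
        if self.protein_frac <= 0 or self.lipid_frac <= 0:
            raise InvalidCompositionError(
                f"{self.name}: protein and lipid fractions must be positive")


@dataclass(frozen=True)
class RecipeBatch:
    """Masses (g) of each recipe component for one mixed batch of a diet."""

    diet: Diet
    batch_mass: float
    component_masses: dict[str, float] = field(compare=False)

    def __post_init__(self) -> None:
        total = sum(self.component_masses.values())
        if abs(total - self.batch_mass) > 1e-6:
            raise InvalidCompositionError(
                f"component masses sum to {total} g, batch is {self.batch_mass} g")


def make_diet(protein_pct: float, lipid_pct: float) -> Diet:
    """Build a Diet from protein/lipid percentages of wet mass (must sum to 50)."""
    name = f"P{protein_pct:g}:L{lipid_pct:g}"
    return Diet(name=name, protein_frac=protein_pct / 100.0,
                lipid_frac=lipid_pct / 100.0)


def parse_diet_name(name: str) -> Diet:
    """Parse a canonical "P{pp}:L{ll}" label (case- and whitespace-tolerant)."""
    m = _NAME_RE.match(name)
    if m is None:
        raise LookupError_(f"cannot parse diet name {name!r}")
    return make_diet(float(m.group(1)), float(m.group(2)))


#: The five diets used in the experiments, most protein-rich first.
PAPER_DIETS: dict[str, Diet] = {
    d.name: d
    for d in (make_diet(35, 15), make_diet(30, 20), make_diet(25, 25),
              make_diet(20, 30), make_diet(15, 35))
}

#: The three complementary food-pairing treatments of the choice experiment.
FOOD_PAIRINGS: dict[str, tuple[str, str]] = {
    "FPT1": ("P20:L30", "P30:L20"),
    "FPT2": ("P20:L30", "P35:L15"),
    "FPT3": ("P25:L25", "P35:L15"),
}


def formulate_diet(protein_pct: float, lipid_pct: float,
                   batch_mass: float) -> RecipeBatch:
    """Scale the printed recipe to a batch: component masses in grams.

    The recipe rule: protein and lipid at their stated percentages, 39.5%
    sucrose solution (50% w/v), 0.5% vitamin mix, 10% cellulose.
    """
    if abs(protein_pct + lipid_pct - 50.0) > _FRACTION_TOL:
        raise InvalidCompositionError(
            f"protein + lipid must be 50% of wet mass, got {protein_pct + lipid_pct}%")
    if not batch_mass > 0:
        raise DomainError(f"batch_mass must be positive, got {batch_mass}")
    diet = make_diet(protein_pct, lipid_pct)
    masses = {
        "protein": diet.protein_frac * batch_mass,
        "lipid": diet.lipid_frac * batch_mass,
        "sucrose_solution": diet.sucrose_solution_frac * batch_mass,
        "vitamin_mix": diet.vitamin_frac * batch_mass,
        "cellulose": diet.cellulose_frac * batch_mass,
    }
    return RecipeBatch(diet=diet, batch_mass=batch_mass, component_masses=masses)


def pl_ratio(diet: Diet) -> float:
    """Protein:lipid ratio of a diet (dimensionless protein/lipid)."""
    if diet.lipid_frac == 0:
        raise UndefinedRatioError(f"{diet.name}: lipid fraction is zero")
    return diet.protein_frac / diet.lipid_frac


def ratio_display(ratio: float) -> str:
    """Canonical one-decimal display, larger side scaled to 1: "2.3:1" or "1:2.3"."""
    if ratio <= 0 or not math.isfinite(ratio):
        raise UndefinedRatioError(f"cannot display ratio {ratio}")
    if ratio >= 1:
        left = f"{ratio:.1f}".rstrip("0").rstrip(".")
        return f"{left}:1"
    right = f"{1.0 / ratio:.1f}".rstrip("0").rstrip(".")
    return f"1:{right}"


def pl_ratio_display(diet: Diet) -> str:
    """One-decimal display string of a diet's P:L ratio."""
    return ratio_display(pl_ratio(diet))


def rail_point(diet: Diet, amount_eaten: float) -> NutrientPoint:
    """Map an amount of food eaten (mg/bee) to its point on the diet's rail."""
    if amount_eaten < 0:
        raise DomainError(f"amount_eaten must be >= 0, got {amount_eaten}")
    return NutrientPoint(protein_mg=amount_eaten * diet.protein_frac,
                         lipid_mg=amount_eaten * diet.lipid_frac)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

_DIET_COLUMNS = ["name", "protein_frac", "lipid_frac", "sucrose_solution_frac",
                 "vitamin_frac", "cellulose_frac"]


def diets_to_frame(diets: dict[str, Diet]) -> pd.DataFrame:
    """Serialize diets as one CSV-ready row per diet."""
    rows = [{c: getattr(d, c) if c != "name" else d.name for c in _DIET_COLUMNS}
            for d in diets.values()]
    return pd.DataFrame(rows, columns=_DIET_COLUMNS)


def diets_from_frame(frame: pd.DataFrame) -> dict[str, Diet]:
    """Load diets from a DataFrame with the columns written by diets_to_frame."""
    out: dict[str, Diet] = {}
    for _, row in frame.iterrows():
        d = Diet(name=str(row["name"]),
                 protein_frac=float(row["protein_frac"]),
                 lipid_frac=float(row["lipid_frac"]),
                 sucrose_solution_frac=float(row["sucrose_solution_frac"]),
                 vitamin_frac=float(row["vitamin_frac"]),
                 cellulose_frac=float(row["cellulose_frac"]))
        out[d.name] = d
    return out
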