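"""Raw dish masses and cage censuses to per-capita intake and P:L ratios.

Per-capita daily intake is the day's dish mass loss divided by the number of
bees alive in the cage that day (dead bees are removed daily, so they never
inflate the denominator).  Because each diet's protein and lipid fractions
are known, per-dish food totals map onto the protein-lipid plane by the rail
geometry, and a cage's self-selected P:L ratio is its total protein divided
by its total lipid over the whole experiment — never a mean of daily ratios.

Measurement noise can make a dish appear to gain a little mass; small gains
(within a tolerance, default 1 mg) are retained as negative intake and
flagged, while larger gains are suspect records that are excluded from
totals and reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import pandas as pd

from .diet_geometry import Diet, NutrientPoint
from .errors import EmptyCageError, LookupError_, SuspectRecordError, UndefinedRatioError
from .synthetic_cages import CageRecord, DishDayRecord

#: Mass gains up to this many mg are treated as measurement noise.
DEFAULT_NEGATIVE_TOLERANCE_MG = 1.0


class PerCapita(NamedTuple):
    """A per-capita daily intake value with its measurement-noise flag."""

    mg_per_bee: float
    flagged_negative: bool


@dataclass(frozen=True)
class CageIntake:
    """Cage-level intake summary over the whole experiment, per bee."""

    cage_id: str
    total_food_mg: float
    total_point: NutrientPoint
    per_dish_totals: dict[str, float]
    n_flagged_negative: int = 0
    excluded_records: tuple[DishDayRecord, ...] = field(default=(), compare=False)

    @property
    def ratio(self) -> float:
        return self_selected_ratio(self)


def daily_per_capita(initial_mass: float, final_mass: float, alive_count: int,
                     tolerance: float = DEFAULT_NEGATIVE_TOLERANCE_MG) -> PerCapita:
    """Per-capita intake (mg/bee) for one dish-day.

    Small apparent mass gains (<= tolerance) are kept as negative intake and
    flagged rather than clamped; gains beyond the tolerance raise
    :class:`SuspectRecordError`; an empty cage raises :class:`EmptyCageError`.
    """
    if alive_count <= 0:
        raise EmptyCageError("no live bees in cage on this day")
    gain = final_mass - initial_mass
    if gain > tolerance:
        raise SuspectRecordError(
            f"dish gained {gain:.2f} mg, beyond tolerance {tolerance} mg")
    value = (initial_mass - final_mass) / alive_count
    return PerCapita(mg_per_bee=value, flagged_negative=value < 0)


def cage_totals(cage: CageRecord, diets: dict[str, Diet],
                tolerance: float = DEFAULT_NEGATIVE_TOLERANCE_MG) -> CageIntake:
    """Aggregate a cage's dish-day records into per-bee totals and a P:L point.

    Per-dish totals sum the daily per-capita values (census denominator =
    bees alive that day); the total intake point sums each dish's rail point.
    Suspect records (mass gain beyond tolerance) are excluded from totals and
    returned in ``excluded_records``.
    """
    per_dish: dict[str, float] = {}
    n_flagged = 0
    excluded: list[DishDayRecord] = []
    for rec in cage.dish_day_records:
        if rec.diet not in diets:
            raise LookupError_(f"unknown diet {rec.diet!r} in cage {cage.cage_id}")
        alive = cage.alive_by_day[rec.day - 1]
        try:
            pc = daily_per_capita(rec.initial_mass_mg, rec.final_mass_mg,
                                  alive, tolerance)
        except SuspectRecordError:
            excluded.append(rec)
            continue
        n_flagged += pc.flagged_negative
        per_dish[rec.diet] = per_dish.get(rec.diet, 0.0) + pc.mg_per_bee
    protein = sum(diets[n].protein_frac * a for n, a in per_dish.items())
    lipid = sum(diets[n].lipid_frac * a for n, a in per_dish.items())
    return CageIntake(cage_id=cage.cage_id,
                      total_food_mg=sum(per_dish.values()),
                      total_point=NutrientPoint(protein, lipid),
                      per_dish_totals=per_dish,
                      n_flagged_negative=n_flagged,
                      excluded_records=tuple(excluded))


def self_selected_ratio(intake: CageIntake) -> float:
    """Whole-experiment protein/lipid intake ratio for one cage."""
    if intake.total_point.lipid_mg <= 0:
        raise UndefinedRatioError(
            f"{intake.cage_id}: lipid total {intake.total_point.lipid_mg} <= 0")
    return intake.total_point.protein_mg / intake.total_point.lipid_mg


def experiment_intake_table(cages: list[CageRecord] | tuple[CageRecord, ...],
                            diets: dict[str, Diet],
                            tolerance: float = DEFAULT_NEGATIVE_TOLERANCE_MG,
                            ) -> pd.DataFrame:
    """Per-cage intake summary table for a whole experiment.

    Columns: cage_id, treatment, arm, total_food_mg_per_bee,
    protein_mg_per_bee, lipid_mg_per_bee, pl_ratio (NaN for cages with no
    lipid intake, e.g. no-food controls), one column per dish diet with that
    dish's per-bee total, and bookkeeping counts of flagged/excluded records.
    """
    rows = []
    for cage in cages:
        ci = cage_totals(cage, diets, tolerance)
        row = {
            "cage_id": cage.cage_id,
            "treatment": cage.treatment,
            "arm": cage.arm,
            "total_food_mg_per_bee": ci.total_food_mg,
            "protein_mg_per_bee": ci.total_point.protein_mg,
            "lipid_mg_per_bee": ci.total_point.lipid_mg,
            "pl_ratio": (ci.total_point.protein_mg / ci.total_point.lipid_mg
                         if ci.total_point.lipid_mg > 0 else float("nan")),
            "n_flagged_negative": ci.n_flagged_negative,
            "n_excluded": len(ci.excluded_records),
        }
        for diet_name, total in ci.per_dish_totals.items():
            row[f"dish_{diet_name}_mg_per_bee"] = total
        rows.append(row)
    return pd.DataFrame(rows)
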