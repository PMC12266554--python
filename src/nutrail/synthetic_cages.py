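"""Seeded stochastic simulator of cage feeding experiments.

The study's raw data are cage-level: groups of nurse bees in plastic cages,
fed from one (no-choice) or two (choice) dishes of artificial diet for six
days, with dish masses weighed daily after humidity equilibration and deaths
recorded daily.  This module generates synthetic datasets with the same
statistical structure — agents follow a configurable rule of compromise
toward an intake target, cage-level feeding noise is lognormal, dish weighing
noise is additive Gaussian, and mortality is a constant per-bee daily hazard —
so that every downstream analysis stage can be tested end to end.

Defaults reproduce the study conditions: 5 diets + a no-food control x 12
cages x 30 bees x 6 days (no-choice); 3 complementary food pairings x 12
cages x 25 bees x 6 days (choice); per-bee daily mortality hazard 0.0267,
giving ~15% six-day mortality; intake target (30, 20) mg/bee on the P30:L20
rail.  Everything is reproducible from a single master seed, with per-cage
child seeds derived by a stable hash of (master seed, cage id).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .compromise_rules import IntakeTarget, RULES, _rule_amount, predict_intake
from .diet_geometry import (
    Diet,
    FOOD_PAIRINGS,
    NutrientPoint,
    PAPER_DIETS,
)
from .errors import ConfigError, DishExhaustedError, DomainError

#: Per-bee daily mortality hazard giving 1-(1-h)^6 ~ 15% six-day mortality.
DEFAULT_DAILY_HAZARD = 0.0267
#: Coefficient of variation of the lognormal daily cage-intake noise.
DEFAULT_FEEDING_NOISE_CV = 0.15
#: Additive Gaussian sd (mg) on each recorded equilibrated dish mass.
DEFAULT_WEIGHING_NOISE_SD = 0.5
#: Fresh dish mass offered each day (mg); ad libitum for all configurations.
DEFAULT_INITIAL_DISH_MASS = 4000.0
#: Default per-bee intake target over the six-day horizon (mg protein, mg lipid).
DEFAULT_TARGET = IntakeTarget(point=NutrientPoint(30.0, 20.0),
                              source="study default (P30:L20 rail, 100 mg/bee)")

#: Simulator rules: the five compromise rules plus a no-regulation null in
#: which each dish is eaten at its single-rail rate split across dishes.
SIM_RULES: tuple[str, ...] = RULES + ("no_regulation",)


@dataclass(frozen=True)
class CageConfig:
    """Everything needed to simulate one cage reproducibly."""

    cage_id: str
    dishes: tuple[Diet, ...]  # 0 (no-food control), 1 (no-choice) or 2 (choice)
    target: IntakeTarget = DEFAULT_TARGET
    n_bees: int = 30
    n_days: int = 6
    rule: str = "strict_restraint"
    daily_mortality_hazard: float = DEFAULT_DAILY_HAZARD
    feeding_noise_cv: float = DEFAULT_FEEDING_NOISE_CV
    weighing_noise_sd: float = DEFAULT_WEIGHING_NOISE_SD
    initial_dish_mass_mg: float = DEFAULT_INITIAL_DISH_MASS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bees <= 0:
            raise ConfigError(f"n_bees must be positive, got {self.n_bees}")
        if not 0 <= self.daily_mortality_hazard < 1:
            raise ConfigError("daily_mortality_hazard must be in [0, 1)")
        if self.feeding_noise_cv < 0 or self.weighing_noise_sd < 0:
            raise ConfigError("noise parameters must be >= 0")
        if len(self.dishes) > 2:
            raise ConfigError("at most two dishes per cage")
        if self.rule not in SIM_RULES:
            raise ConfigError(f"unknown rule {self.rule!r}")


@dataclass(frozen=True)
class DishDayRecord:
    """One dish on one day: equilibrated masses before and after the 24 h window."""

    cage_id: str
    day: int  # 1-based
    diet: str
    initial_mass_mg: float
    final_mass_mg: float


@dataclass(frozen=True)
class CageRecord:
    """Simulated (or reconstructed) raw data for one cage."""

    cage_id: str
    treatment: str
    arm: str  # "no_choice" | "choice"
    n_bees0: int
    n_days: int
    dish_day_records: tuple[DishDayRecord, ...]
    deaths_by_day: tuple[int, ...]
    alive_by_day: tuple[int, ...]  # end-of-day live counts
    allocation_flagged: bool = False
    #: Simulation ground truth (noise-free per-capita totals per dish); absent
    #: when the record was reconstructed from CSVs rather than simulated.
    true_per_capita_totals: dict[str, float] | None = field(
        default=None, compare=False)

    def __post_init__(self) -> None:
        alive = self.n_bees0
        for d, (deaths, end) in enumerate(zip(self.deaths_by_day,
                                              self.alive_by_day), start=1):
            alive -= deaths
            if alive != end:
                raise ConfigError(
                    f"{self.cage_id}: census inconsistent on day {d}")


@dataclass(frozen=True)
class BeeOutcomeParams:
    """Endpoint model: HPG acinus size responds to protein, body lipid does not.

    Mean acinus diameter is linear in total per-capita protein intake
    (baseline + slope x protein + bee-level noise), mirroring the strong
    protein/HPG coupling seen in nurse bees; body lipid is drawn from a
    diet-independent distribution because adult bees barely assimilate
    dietary lipid (slope with respect to lipid intake is 0 by default).
    """

    hpg_baseline_um: float = 60.0
    hpg_slope_um_per_mg_protein: float = 0.5
    hpg_bee_sd_um: float = 3.0
    acinus_sd_um: float = 5.0
    acini_per_bee: int = 10
    body_lipid_mean_mg: float = 4.0
    body_lipid_sd_mg: float = 0.8
    body_lipid_slope_per_mg_lipid: float = 0.0


@dataclass(frozen=True)
class BeeOutcome:
    """Endpoint measurements for one sampled bee."""

    cage_id: str
    hpg_acinus_diameters_um: tuple[float, ...]
    body_lipid_mg: float

    def __post_init__(self) -> None:
        if any(d <= 0 for d in self.hpg_acinus_diameters_um):
            raise DomainError(f"{self.cage_id}: acinus diameters must be positive")


@dataclass(frozen=True)
class ExperimentDesign:
    """The full two-arm design; defaults are the study's."""

    no_choice_diets: tuple[str, ...] = tuple(PAPER_DIETS)
    include_control: bool = True
    pairings: dict[str, tuple[str, str]] = field(
        default_factory=lambda: dict(FOOD_PAIRINGS))
    replicates: int = 12
    bees_no_choice: int = 30
    bees_choice: int = 25
    n_days: int = 6
    rule: str = "strict_restraint"
    target: IntakeTarget = DEFAULT_TARGET
    daily_mortality_hazard: float = DEFAULT_DAILY_HAZARD
    feeding_noise_cv: float = DEFAULT_FEEDING_NOISE_CV
    weighing_noise_sd: float = DEFAULT_WEIGHING_NOISE_SD
    outcome_params: BeeOutcomeParams = BeeOutcomeParams()

    def __post_init__(self) -> None:
        if self.replicates <= 0:
            raise ConfigError("replicates must be positive")
        for pairing, (a, b) in self.pairings.items():
            if a == b:
                raise ConfigError(f"{pairing}: pairing must use two distinct diets")


@dataclass(frozen=True)
class ExperimentData:
    """Simulated dataset: raw cage records plus per-cage endpoint bees."""

    design: ExperimentDesign
    cages: tuple[CageRecord, ...]
    bee_outcomes: tuple[BeeOutcome, ...]
    seed: int


# ---------------------------------------------------------------------------
# Seeding
# ---------------------------------------------------------------------------

def child_seed(master_seed: int, cage_id: str, stream: int = 0) -> int:
    """Stable per-cage child seed from (master seed, cage id) via CRC-32."""
    ss = np.random.SeedSequence((int(master_seed) & 0x7FFFFFFF,
                                 zlib.crc32(cage_id.encode("utf-8")), stream))
    return int(ss.generate_state(1, dtype=np.uint32)[0])


# ---------------------------------------------------------------------------
# Dish allocation
# ---------------------------------------------------------------------------

def dish_allocation(dishes: tuple[Diet, ...], rule: str,
                    target: IntakeTarget) -> tuple[tuple[float, ...], bool]:
    """Per-bee full-horizon amount (mg) demanded from each dish, plus a flag.

    One dish: the rule's single-rail stopping amount (``no_regulation``
    degenerates to strict restraint on a single rail).  Two dishes: if the
    target lies inside the cone spanned by the two rails, the unique
    nonnegative mixture reaching the target exactly is used for every
    regulating rule; when the target is outside the cone the admissible rail
    closest to the target carries the single-rail rule and the allocation is
    flagged.  Under ``no_regulation`` each dish is eaten at its own
    single-rail strict-restraint rate split evenly across dishes.
    """
    if not dishes:
        return (), False
    if rule == "no_regulation":
        amounts = tuple(_rule_amount("strict_restraint", d, target) / len(dishes)
                        for d in dishes)
        return amounts, False
    if len(dishes) == 1:
        return (_rule_amount(rule, dishes[0], target),), False
    d1, d2 = dishes
    a = np.array([[d1.protein_frac, d2.protein_frac],
                  [d1.lipid_frac, d2.lipid_frac]])
    b = np.array([target.point.protein_mg, target.point.lipid_mg])
    det = np.linalg.det(a)
    if abs(det) > 1e-12:
        x = np.linalg.solve(a, b)
        if (x >= -1e-9).all():
            return (max(x[0], 0.0), max(x[1], 0.0)), False
    # Target outside the cone (or parallel rails): feed on the admissible rail
    # whose closest-distance point is nearest the target, flagged.
    best = min(dishes, key=lambda d: predict_intake(
        "closest_distance", d, target).point.distance_to(target.point))
    amounts = tuple(_rule_amount(rule, d, target) if d is best else 0.0
                    for d in dishes)
    return amounts, True


# ---------------------------------------------------------------------------
# Cage simulation
# ---------------------------------------------------------------------------

def _lognormal_factor(rng: np.random.Generator, cv: float) -> float:
    """Unit-mean lognormal multiplier with coefficient of variation ``cv``."""
    if cv == 0:
        return 1.0
    sigma2 = np.log1p(cv * cv)
    return float(rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2)))


def simulate_cage(config: CageConfig, treatment: str = "",
                  arm: str = "no_choice") -> CageRecord:
    """Simulate one cage for ``n_days`` days; fully reproducible from its seed.

    Each day: deaths are drawn per live bee at the daily hazard and the dead
    removed; the surviving bees then demand ``allocation / n_days`` from each
    dish; the cage's realized dish intake is the demand times a unit-mean
    lognormal factor; the recorded final dish mass is initial - intake plus
    additive weighing noise.  The census denominator downstream (bees alive
    on that day) therefore matches the bees that actually fed.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    allocation, flagged = dish_allocation(config.dishes, config.rule,
                                          config.target)
    daily_demand = tuple(a / config.n_days for a in allocation)

    records: list[DishDayRecord] = []
    deaths_by_day: list[int] = []
    alive_by_day: list[int] = []
    true_totals = {d.name: 0.0 for d in config.dishes}
    alive = config.n_bees
    for day in range(1, config.n_days + 1):
        deaths = int(rng.binomial(alive, config.daily_mortality_hazard)) \
            if alive > 0 else 0
        alive -= deaths
        deaths_by_day.append(deaths)
        alive_by_day.append(alive)
        for diet, demand in zip(config.dishes, daily_demand):
            intake = alive * demand * _lognormal_factor(
                rng, config.feeding_noise_cv)
            if intake > config.initial_dish_mass_mg:
                raise DishExhaustedError(
                    f"{config.cage_id} day {day}: demand {intake:.0f} mg exceeds "
                    f"dish mass {config.initial_dish_mass_mg:.0f} mg")
            noise = (rng.normal(0.0, config.weighing_noise_sd)
                     if config.weighing_noise_sd > 0 else 0.0)
            records.append(DishDayRecord(
                cage_id=config.cage_id, day=day, diet=diet.name,
                initial_mass_mg=config.initial_dish_mass_mg,
                final_mass_mg=config.initial_dish_mass_mg - intake + noise))
            if alive > 0:
                true_totals[diet.name] += intake / alive
    return CageRecord(
        cage_id=config.cage_id, treatment=treatment or config.cage_id, arm=arm,
        n_bees0=config.n_bees, n_days=config.n_days,
        dish_day_records=tuple(records), deaths_by_day=tuple(deaths_by_day),
        alive_by_day=tuple(alive_by_day), allocation_flagged=flagged,
        true_per_capita_totals=true_totals)


def simulate_bee_outcomes(per_capita_protein: float, per_capita_lipid: float,
                          params: BeeOutcomeParams,
                          rng: np.random.Generator,
                          cage_id: str = "") -> BeeOutcome:
    """Sample one bee's HPG acinus diameters and body lipid given its intake."""
    if per_capita_protein < 0 or per_capita_lipid < 0:
        raise DomainError("per-capita intakes must be >= 0")
    mean_diam = (params.hpg_baseline_um
                 + params.hpg_slope_um_per_mg_protein * per_capita_protein
                 + (rng.normal(0.0, params.hpg_bee_sd_um)
                    if params.hpg_bee_sd_um > 0 else 0.0))
    if params.acinus_sd_um > 0:
        diams = rng.normal(mean_diam, params.acinus_sd_um, params.acini_per_bee)
    else:
        diams = np.full(params.acini_per_bee, mean_diam)
    lipid = (params.body_lipid_mean_mg
             + params.body_lipid_slope_per_mg_lipid * per_capita_lipid
             + (rng.normal(0.0, params.body_lipid_sd_mg)
                if params.body_lipid_sd_mg > 0 else 0.0))
    return BeeOutcome(cage_id=cage_id,
                      hpg_acinus_diameters_um=tuple(float(d) for d in diams),
                      body_lipid_mg=float(lipid))


def simulate_experiment(design: ExperimentDesign | None = None,
                        seed: int = 0) -> ExperimentData:
    """Simulate the full two-arm design from a single master seed.

    The default design yields 72 no-choice cages (5 diets + control, 12
    replicates, 30 bees each) and 36 choice cages (3 pairings, 12 replicates,
    25 bees each); one bee per cage is sampled for the HPG / body-lipid
    endpoints, using the cage's realized noise-free per-capita intake (intake
    0 for the no-food control).
    """
    if design is None:
        design = ExperimentDesign()
    diets = dict(PAPER_DIETS)
    cages: list[CageRecord] = []
    outcomes: list[BeeOutcome] = []

    def run_cage(cage_id: str, treatment: str, arm: str,
                 dishes: tuple[Diet, ...], n_bees: int) -> None:
        cfg = CageConfig(
            cage_id=cage_id, dishes=dishes, target=design.target,
            n_bees=n_bees, n_days=design.n_days, rule=design.rule,
            daily_mortality_hazard=design.daily_mortality_hazard,
            feeding_noise_cv=design.feeding_noise_cv,
            weighing_noise_sd=design.weighing_noise_sd,
            seed=child_seed(seed, cage_id))
        cage = simulate_cage(cfg, treatment=treatment, arm=arm)
        cages.append(cage)
        totals = cage.true_per_capita_totals or {}
        protein = sum(diets[n].protein_frac * a if n in diets else 0.0
                      for n, a in totals.items())
        lipid = sum(diets[n].lipid_frac * a if n in diets else 0.0
                    for n, a in totals.items())
        rng = np.random.default_rng(
            np.random.SeedSequence(child_seed(seed, cage_id, stream=1)))
        outcomes.append(simulate_bee_outcomes(
            protein, lipid, design.outcome_params, rng, cage_id=cage_id))

    for diet_name in design.no_choice_diets:
        if diet_name not in diets:
            raise ConfigError(f"unknown diet {diet_name!r} in design")
        for rep in range(1, design.replicates + 1):
            run_cage(f"NC-{diet_name}-{rep:02d}", diet_name, "no_choice",
                     (diets[diet_name],), design.bees_no_choice)
    if design.include_control:
        for rep in range(1, design.replicates + 1):
            run_cage(f"NC-control-{rep:02d}", "control", "no_choice",
                     (), design.bees_no_choice)
    for pairing, (a, b) in design.pairings.items():
        if a not in diets or b not in diets:
            raise ConfigError(f"{pairing}: unknown diet in pairing ({a}, {b})")
        for rep in range(1, design.replicates + 1):
            run_cage(f"CH-{pairing}-{rep:02d}", pairing, "choice",
                     (diets[a], diets[b]), design.bees_choice)
    return ExperimentData(design=design, cages=tuple(cages),
                          bee_outcomes=tuple(outcomes), seed=seed)


# ---------------------------------------------------------------------------
# Tabular I/O (CSV-ready frames and their inverse)
# ---------------------------------------------------------------------------

def dishes_frame(cages: tuple[CageRecord, ...] | list[CageRecord]) -> pd.DataFrame:
    rows = [{"cage_id": r.cage_id, "day": r.day, "diet": r.diet,
             "initial_mass_mg": r.initial_mass_mg,
             "final_mass_mg": r.final_mass_mg}
            for cage in cages for r in cage.dish_day_records]
    return pd.DataFrame(rows, columns=["cage_id", "day", "diet",
                                       "initial_mass_mg", "final_mass_mg"])


def cages_frame(cages: tuple[CageRecord, ...] | list[CageRecord]) -> pd.DataFrame:
    rows = []
    for c in cages:
        row = {"cage_id": c.cage_id, "treatment": c.treatment, "arm": c.arm,
               "n_bees0": c.n_bees0}
        for d in range(1, c.n_days + 1):
            row[f"deaths_day{d}"] = c.deaths_by_day[d - 1]
        rows.append(row)
    return pd.DataFrame(rows)


def bees_frame(outcomes: tuple[BeeOutcome, ...] | list[BeeOutcome]) -> pd.DataFrame:
    rows = [{"cage_id": o.cage_id,
             "acinus_diameters_um": ";".join(f"{d:.3f}"
                                             for d in o.hpg_acinus_diameters_um),
             "body_lipid_mg": o.body_lipid_mg}
            for o in outcomes]
    return pd.DataFrame(rows, columns=["cage_id", "acinus_diameters_um",
                                       "body_lipid_mg"])


def cages_from_frames(cage_table: pd.DataFrame,
                      dish_table: pd.DataFrame) -> list[CageRecord]:
    """Reconstruct CageRecords from the cages.csv / dishes.csv pair."""
    death_cols = sorted((c for c in cage_table.columns
                         if c.startswith("deaths_day")),
                        key=lambda c: int(c.removeprefix("deaths_day")))
    out: list[CageRecord] = []
    grouped = dish_table.groupby("cage_id")
    for _, row in cage_table.iterrows():
        cage_id = str(row["cage_id"])
        deaths = tuple(int(row[c]) for c in death_cols)
        alive, census = int(row["n_bees0"]), []
        for d in deaths:
            alive -= d
            census.append(alive)
        if cage_id in grouped.groups:
            sub = grouped.get_group(cage_id).sort_values(["day", "diet"])
            records = tuple(DishDayRecord(
                cage_id=cage_id, day=int(r["day"]), diet=str(r["diet"]),
                initial_mass_mg=float(r["initial_mass_mg"]),
                final_mass_mg=float(r["final_mass_mg"]))
                for _, r in sub.iterrows())
        else:
            records = ()
        out.append(CageRecord(
            cage_id=cage_id, treatment=str(row["treatment"]),
            arm=str(row["arm"]), n_bees0=int(row["n_bees0"]),
            n_days=len(deaths), dish_day_records=records,
            deaths_by_day=deaths, alive_by_day=tuple(census)))
    return out


def bees_from_frame(bee_table: pd.DataFrame) -> list[BeeOutcome]:
    return [BeeOutcome(
        cage_id=str(r["cage_id"]),
        hpg_acinus_diameters_um=tuple(
            float(x) for x in str(r["acinus_diameters_um"]).split(";")),
        body_lipid_mg=float(r["body_lipid_mg"]))
        for _, r in bee_table.iterrows()]
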