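"""Inferential layer: the no-regulation null, preference tests, and the
designed-experiment statistics for the cage feeding study.

The scientific question is whether bees offered two complementary foods
actively regulate toward an intake target, or simply eat each food at the
rate they would eat it alone.  The null ("theoretical") choice dataset is
built by halving each diet's no-choice per-capita consumption — with two
dishes in the arena, an unregulating cage would split its attention between
them.  Observed ("experimental") choice consumption is then compared to that
null per diet and pairing with Welch t-tests under a Bonferroni family, dish
preference within a pairing is tested against zero, and the self-selected
and theoretical P:L ratios are each compared to the target ratio.  The
surrounding standard statistics — one-way ANOVA with Tukey HSD and compact
letter display, mixed ANOVA, MANOVA, Cox survival comparison, and the
HPG-on-intake regressions — round out the study's analysis suite.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .compromise_rules import IntakeTarget
from .diet_geometry import Diet, NutrientPoint, rail_point
from .errors import (
    ConfigError,
    DegenerateModelError,
    InsufficientDataError,
    LookupError_,
)
from .intake_accounting import experiment_intake_table
from .synthetic_cages import CageRecord

DEFAULT_FAMILY_ALPHA = 0.05
#: Bonferroni family sizes used in the study's choice analysis.
PREFERENCE_FAMILY_M = 3       # one dish-preference test per food pairing
THEORETICAL_FAMILY_M = 6      # two diets x three pairings


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    """One hypothesis test inside a Bonferroni family."""

    label: str
    statistic: float
    df: float | tuple[float, float]
    raw_p: float
    m: int
    family_alpha: float = DEFAULT_FAMILY_ALPHA

    @property
    def adjusted_p(self) -> float:
        return min(1.0, self.raw_p * self.m)

    @property
    def adjusted_alpha(self) -> float:
        return self.family_alpha / self.m

    @property
    def significant(self) -> bool:
        return self.raw_p < self.adjusted_alpha

    def to_dict(self) -> dict:
        return {"label": self.label, "statistic": self.statistic,
                "df": self.df, "raw_p": self.raw_p,
                "adjusted_p": self.adjusted_p,
                "adjusted_alpha": self.adjusted_alpha, "m": self.m,
                "significant": self.significant}


@dataclass(frozen=True)
class AnovaResult:
    """One-way ANOVA with Tukey HSD pairwise structure."""

    f_statistic: float
    df: tuple[int, int]
    p_value: float
    group_means: dict[str, float]
    tukey: pd.DataFrame = field(compare=False)
    letters: dict[str, str] = field(compare=False, default_factory=dict)


@dataclass(frozen=True)
class TheoreticalChoiceTable:
    """No-regulation expectation per pairing: per-dish mg and the P:L point."""

    per_dish: dict[str, dict[str, float]]          # pairing -> diet -> mg/bee
    points: dict[str, NutrientPoint]               # pairing -> theoretical point
    ratios: dict[str, float | None]                # pairing -> ratio (None if 0/0)
    n_dishes: int = 2


# ---------------------------------------------------------------------------
# The no-regulation theoretical dataset
# ---------------------------------------------------------------------------

def theoretical_choice_dataset(no_choice_means: Mapping[str, float],
                               pairings: Mapping[str, tuple[str, str]],
                               diets: Mapping[str, Diet],
                               n_dishes: int = 2) -> TheoreticalChoiceTable:
    """Expected choice consumption in the absence of P:L regulation.

    Each diet's theoretical per-dish consumption is its no-choice mean
    divided by the number of dishes offered; the pairing's theoretical
    intake point is the sum of the two halved rail points.
    """
    per_dish: dict[str, dict[str, float]] = {}
    points: dict[str, NutrientPoint] = {}
    ratios: dict[str, float | None] = {}
    for pairing, pair in pairings.items():
        amounts = {}
        point = NutrientPoint(0.0, 0.0)
        for name in pair:
            if name not in no_choice_means:
                raise LookupError_(f"{pairing}: no no-choice mean for {name!r}")
            if name not in diets:
                raise LookupError_(f"{pairing}: unknown diet {name!r}")
            amounts[name] = no_choice_means[name] / n_dishes
            point = point + rail_point(diets[name], amounts[name])
        per_dish[pairing] = amounts
        points[pairing] = point
        ratios[pairing] = (point.protein_mg / point.lipid_mg
                           if point.lipid_mg > 0 else None)
    return TheoreticalChoiceTable(per_dish=per_dish, points=points,
                                  ratios=ratios, n_dishes=n_dishes)


# ---------------------------------------------------------------------------
# t-test families
# ---------------------------------------------------------------------------

def _one_sample_t(sample: np.ndarray, null_value: float) -> tuple[float, float, float]:
    n = len(sample)
    df = n - 1
    sd = float(np.std(sample, ddof=1))
    if sd == 0.0:
        # Degenerate but defined: no variance. Identical to the null -> t=0,p=1.
        if math.isclose(float(np.mean(sample)), null_value,
                        rel_tol=0.0, abs_tol=1e-12):
            return 0.0, df, 1.0
        return math.inf, df, 0.0
    t = float((np.mean(sample) - null_value) / (sd / math.sqrt(n)))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return t, df, p


def bonferroni_t_tests(samples: Sequence[Sequence[float]], null_value: float,
                       family_alpha: float = DEFAULT_FAMILY_ALPHA,
                       m: int | None = None,
                       labels: Sequence[str] | None = None) -> list[TestResult]:
    """Two-sided one-sample t-tests under a Bonferroni family of size ``m``."""
    if m is None:
        m = len(samples)
    if m < len(samples):
        raise InsufficientDataError(
            f"family size m={m} smaller than number of tests {len(samples)}")
    if labels is None:
        labels = [f"test_{i + 1}" for i in range(len(samples))]
    out = []
    for label, sample in zip(labels, samples):
        arr = np.asarray(sample, dtype=float)
        if len(arr) < 2:
            raise InsufficientDataError(f"{label}: need n >= 2, got {len(arr)}")
        t, df, p = _one_sample_t(arr, null_value)
        out.append(TestResult(label=label, statistic=t, df=df, raw_p=p,
                              m=m, family_alpha=family_alpha))
    return out


def bonferroni_welch_tests(pairs: Sequence[tuple[Sequence[float], Sequence[float]]],
                           family_alpha: float = DEFAULT_FAMILY_ALPHA,
                           m: int | None = None,
                           labels: Sequence[str] | None = None) -> list[TestResult]:
    """Two-sided Welch two-sample t-tests under a Bonferroni family."""
    if m is None:
        m = len(pairs)
    if m < len(pairs):
        raise InsufficientDataError(
            f"family size m={m} smaller than number of tests {len(pairs)}")
    if labels is None:
        labels = [f"test_{i + 1}" for i in range(len(pairs))]
    out = []
    for label, (a, b) in zip(labels, pairs):
        x = np.asarray(a, dtype=float)
        y = np.asarray(b, dtype=float)
        if len(x) < 2 or len(y) < 2:
            raise InsufficientDataError(f"{label}: both samples need n >= 2")
        if np.std(x, ddof=1) == 0 and np.std(y, ddof=1) == 0:
            same = math.isclose(float(np.mean(x)), float(np.mean(y)),
                                rel_tol=0.0, abs_tol=1e-12)
            t, df, p = (0.0, len(x) + len(y) - 2, 1.0) if same \
                else (math.inf, len(x) + len(y) - 2, 0.0)
        else:
            res = stats.ttest_ind(x, y, equal_var=False)
            t, p = float(res.statistic), float(res.pvalue)
            df = float(res.df)
        out.append(TestResult(label=label, statistic=t, df=df, raw_p=p,
                              m=m, family_alpha=family_alpha))
    return out


# ---------------------------------------------------------------------------
# ANOVA / Tukey with compact letter display
# ---------------------------------------------------------------------------

def _compact_letters(groups: Sequence[str],
                     distinct: set[tuple[str, str]]) -> dict[str, str]:
    """Greedy compact letter display: groups sharing a letter do not differ."""
    letter_sets: list[set[str]] = []
    for g in groups:
        placed = False
        for s in letter_sets:
            if all((g, o) not in distinct and (o, g) not in distinct for o in s):
                s.add(g)
                placed = True
        if not placed:
            letter_sets.append({g})
    # Ensure every significantly-different pair is actually separated.
    for a, b in distinct:
        if any(a in s and b in s for s in letter_sets):  # pragma: no cover
            raise AssertionError("letter display failed to separate groups")
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    return {g: "".join(alphabet[i] for i, s in enumerate(letter_sets) if g in s)
            for g in groups}


def anova_tukey(values_by_group: Mapping[str, Sequence[float]],
                alpha: float = 0.05) -> AnovaResult:
    """One-way ANOVA followed by Tukey HSD and a compact letter display.

    Degenerate case: if both the between- and within-group variances are
    zero the F statistic is defined as 0 with p = 1.
    """
    if len(values_by_group) < 2:
        raise InsufficientDataError("need >= 2 groups")
    for g, v in values_by_group.items():
        if len(v) < 2:
            raise InsufficientDataError(f"group {g!r} has n < 2")
    groups = list(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    k = len(arrays)
    n_total = sum(len(a) for a in arrays)
    grand = float(np.concatenate(arrays).mean())
    ss_between = sum(len(a) * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    df_between, df_within = k - 1, n_total - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    if ms_within == 0.0:
        f = 0.0 if ms_between == 0.0 else math.inf
        p = 1.0 if ms_between == 0.0 else 0.0
    else:
        f = float(ms_between / ms_within)
        p = float(stats.f.sf(f, df_between, df_within))
    means = {g: float(a.mean()) for g, a in zip(groups, arrays)}

    if ms_within > 0.0:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        endog = np.concatenate(arrays)
        labels = np.concatenate([[g] * len(a) for g, a in zip(groups, arrays)])
        hsd = pairwise_tukeyhsd(endog, labels, alpha=alpha)
        tukey = pd.DataFrame(hsd.summary().data[1:],
                             columns=hsd.summary().data[0])
        distinct = {(str(r["group1"]), str(r["group2"]))
                    for _, r in tukey.iterrows() if bool(r["reject"])}
    else:
        pairs = list(itertools.combinations(groups, 2))
        tukey = pd.DataFrame({"group1": [a for a, _ in pairs],
                              "group2": [b for _, b in pairs],
                              "meandiff": [means[b] - means[a] for a, b in pairs],
                              "p-adj": [1.0] * len(pairs),
                              "reject": [False] * len(pairs)})
        distinct = set()
    letters = _compact_letters(groups, distinct)
    return AnovaResult(f_statistic=f, df=(df_between, df_within), p_value=p,
                       group_means=means, tukey=tukey, letters=letters)


# ---------------------------------------------------------------------------
# Survival
# ---------------------------------------------------------------------------

def survival_long_table(cages: Sequence[CageRecord]) -> pd.DataFrame:
    """Per-bee (duration, event) table from daily cage death counts.

    Bees dying on day d get duration d with event 1; survivors are censored
    at the end of the experiment.
    """
    rows = []
    for cage in cages:
        for day, deaths in enumerate(cage.deaths_by_day, start=1):
            for _ in range(deaths):
                rows.append({"duration": day, "event": 1,
                             "treatment": cage.treatment, "cage": cage.cage_id})
        for _ in range(cage.alive_by_day[-1]):
            rows.append({"duration": cage.n_days, "event": 0,
                         "treatment": cage.treatment, "cage": cage.cage_id})
    return pd.DataFrame(rows)


def cox_survival_compare(event_table: pd.DataFrame) -> TestResult:
    """Cox proportional-hazards comparison of survival across treatments.

    Treatment enters as fixed effects (dummy-coded); the cage grouping is
    handled with cluster-robust variance.  The reported statistic is the
    likelihood-ratio chi-square of the treatment model against the null
    (no-covariate) model.
    """
    required = {"duration", "event", "treatment", "cage"}
    if not required.issubset(event_table.columns):
        raise ConfigError(f"event table must have columns {sorted(required)}")
    if event_table["treatment"].nunique() < 2:
        raise InsufficientDataError("need >= 2 treatments")
    if int(event_table["event"].sum()) == 0:
        raise DegenerateModelError("no death events; survival model undefined")
    from lifelines import CoxPHFitter
    x = pd.get_dummies(event_table[["duration", "event", "cage", "treatment"]],
                       columns=["treatment"], drop_first=True, dtype=float)
    cph = CoxPHFitter()
    cph.fit(x, duration_col="duration", event_col="event", cluster_col="cage")
    lrt = cph.log_likelihood_ratio_test()
    df = int(lrt.degrees_freedom)
    return TestResult(label="treatment vs null (Cox LRT)",
                      statistic=float(lrt.test_statistic), df=df,
                      raw_p=float(lrt.p_value), m=1)


# ---------------------------------------------------------------------------
# HPG regressions
# ---------------------------------------------------------------------------

def hpg_intake_regression(treatment_means: Mapping[str, tuple[float, float]],
                          ) -> dict[str, float]:
    """OLS of treatment-mean HPG acinus size on treatment-mean intake.

    ``treatment_means`` maps a treatment to (mean intake mg/bee, mean HPG
    acinus diameter um).  Returns slope, intercept, r_squared and the
    two-sided p-value of the slope.
    """
    if len(treatment_means) < 3:
        raise InsufficientDataError("need >= 3 treatment means for a regression")
    x = np.array([v[0] for v in treatment_means.values()], dtype=float)
    y = np.array([v[1] for v in treatment_means.values()], dtype=float)
    if np.ptp(y) == 0.0:
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0,
                "p_value": 1.0}
    res = stats.linregress(x, y)
    return {"slope": float(res.slope), "intercept": float(res.intercept),
            "r_squared": float(res.rvalue ** 2), "p_value": float(res.pvalue)}


# ---------------------------------------------------------------------------
# End-to-end choice regulation analysis
# ---------------------------------------------------------------------------

def _protein_rich_first(pair: tuple[str, str],
                        diets: Mapping[str, Diet]) -> tuple[str, str]:
    a, b = pair
    return (a, b) if diets[a].protein_frac >= diets[b].protein_frac else (b, a)


def run_choice_regulation_analysis(no_choice_cages: Sequence[CageRecord],
                                   choice_cages: Sequence[CageRecord],
                                   diets: Mapping[str, Diet],
                                   pairings: Mapping[str, tuple[str, str]],
                                   target: IntakeTarget,
                                   family_alpha: float = DEFAULT_FAMILY_ALPHA,
                                   ) -> dict:
    """Full regulation report for a choice experiment with its no-choice arm.

    Produces, as a JSON-ready dict: the theoretical (no-regulation) choice
    table; dish-preference one-sample t-tests (family m=3); per diet-within-
    pairing theoretical-vs-experimental Welch tests (family m=6); theoretical
    and experimental P:L ratios each tested against the target ratio; the
    mixed ANOVA of per-dish consumption (between = pairing, within = dish
    role, subject = cage); the MANOVA of (protein, lipid) totals across
    pairings; and the one-way ANOVA of self-selected ratios.
    """
    diets = dict(diets)
    nc_table = experiment_intake_table(
        [c for c in no_choice_cages if c.dish_day_records], diets)
    ch_table = experiment_intake_table(list(choice_cages), diets)
    needed = {d for pair in pairings.values() for d in pair}
    have = set(nc_table["treatment"])
    if not needed.issubset(have):
        raise ConfigError(
            f"no-choice arm lacks diets {sorted(needed - have)} used in pairings")

    # No-choice per-diet replicate totals (per cage) and their means.
    nc_totals = {d: nc_table.loc[nc_table["treatment"] == d,
                                 "total_food_mg_per_bee"].to_numpy()
                 for d in needed}
    nc_means = {d: float(v.mean()) for d, v in nc_totals.items()}
    theoretical = theoretical_choice_dataset(nc_means, pairings, diets)

    # Dish-preference tests: protein-rich minus lipid-rich dish total, vs 0.
    pref_samples, pref_labels = [], []
    per_dish_samples: dict[str, dict[str, np.ndarray]] = {}
    for pairing, pair in pairings.items():
        rich, poor = _protein_rich_first(pair, diets)
        sub = ch_table[ch_table["treatment"] == pairing]
        rich_col, poor_col = (f"dish_{rich}_mg_per_bee", f"dish_{poor}_mg_per_bee")
        if rich_col not in sub.columns or poor_col not in sub.columns:
            raise ConfigError(f"{pairing}: choice cages lack dishes {pair}")
        per_dish_samples[pairing] = {rich: sub[rich_col].to_numpy(),
                                     poor: sub[poor_col].to_numpy()}
        pref_samples.append(sub[rich_col].to_numpy() - sub[poor_col].to_numpy())
        pref_labels.append(f"{pairing}: {rich} - {poor}")
    preference_tests = bonferroni_t_tests(
        pref_samples, 0.0, family_alpha=family_alpha,
        m=max(PREFERENCE_FAMILY_M, len(pref_samples)), labels=pref_labels)

    # Theoretical vs experimental per-dish consumption (Welch, family m=6).
    welch_pairs, welch_labels = [], []
    for pairing, pair in pairings.items():
        for diet_name in _protein_rich_first(pair, diets):
            theo = nc_totals[diet_name] / theoretical.n_dishes
            expe = per_dish_samples[pairing][diet_name]
            welch_pairs.append((theo, expe))
            welch_labels.append(f"{pairing}: {diet_name} theoretical vs experimental")
    theoretical_vs_experimental = bonferroni_welch_tests(
        welch_pairs, family_alpha=family_alpha,
        m=max(THEORETICAL_FAMILY_M, len(welch_pairs)), labels=welch_labels)

    # Ratio tests against the target ratio (per-pairing, both datasets).
    ratio_samples, ratio_labels = [], []
    experimental_ratios: dict[str, float] = {}
    theoretical_ratio_means: dict[str, float] = {}
    for pairing, pair in pairings.items():
        d1, d2 = pair
        theo_p = (nc_totals[d1] / 2 * diets[d1].protein_frac
                  + nc_totals[d2] / 2 * diets[d2].protein_frac)
        theo_l = (nc_totals[d1] / 2 * diets[d1].lipid_frac
                  + nc_totals[d2] / 2 * diets[d2].lipid_frac)
        theo_ratios = theo_p / theo_l
        theoretical_ratio_means[pairing] = float(theo_ratios.mean())
        sub = ch_table[ch_table["treatment"] == pairing]
        exp_ratios = sub["pl_ratio"].to_numpy()
        experimental_ratios[pairing] = float(np.mean(exp_ratios))
        ratio_samples.extend([theo_ratios, exp_ratios])
        ratio_labels.extend([f"{pairing}: theoretical ratio vs target",
                             f"{pairing}: experimental ratio vs target"])
    ratio_tests = bonferroni_t_tests(
        ratio_samples, target.ratio, family_alpha=family_alpha,
        m=max(THEORETICAL_FAMILY_M, len(ratio_samples)), labels=ratio_labels)

    # Mixed ANOVA: dv = per-dish total, within = dish role, between = pairing.
    long_rows = []
    for pairing, pair in pairings.items():
        rich, poor = _protein_rich_first(pair, diets)
        sub = ch_table[ch_table["treatment"] == pairing]
        for _, row in sub.iterrows():
            for role, diet_name in (("protein_rich", rich), ("lipid_rich", poor)):
                long_rows.append({
                    "pairing": pairing, "cage": row["cage_id"], "role": role,
                    "consumption": row[f"dish_{diet_name}_mg_per_bee"]})
    long_df = pd.DataFrame(long_rows)
    import pingouin as pg
    mixed = pg.mixed_anova(data=long_df, dv="consumption", within="role",
                           subject="cage", between="pairing")
    mixed_summary = [
        {"effect": str(r["Source"]), "F": float(r["F"]),
         "df": (float(r["DF1"]), float(r["DF2"])), "p": float(r["p_unc"])}
        for _, r in mixed.iterrows() if np.isfinite(r["F"])]

    # MANOVA of (protein, lipid) cage totals across pairings (Pillai's trace).
    from statsmodels.multivariate.manova import MANOVA
    man_df = ch_table.rename(columns={"protein_mg_per_bee": "protein",
                                      "lipid_mg_per_bee": "lipid",
                                      "treatment": "pairing"})
    mv = MANOVA.from_formula("protein + lipid ~ pairing", data=man_df)
    pillai = mv.mv_test().results["pairing"]["stat"].loc["Pillai's trace"]
    manova_summary = {"statistic": float(pillai["Value"]),
                      "F": float(pillai["F Value"]),
                      "df": (float(pillai["Num DF"]), float(pillai["Den DF"])),
                      "p": float(pillai["Pr > F"])}

    # Self-selected ratio ANOVA across pairings.
    ratio_by_pairing = {p: ch_table.loc[ch_table["treatment"] == p,
                                        "pl_ratio"].tolist()
                        for p in pairings}
    ratio_anova = anova_tukey(ratio_by_pairing)

    return {
        "target": {"protein_mg": target.point.protein_mg,
                   "lipid_mg": target.point.lipid_mg,
                   "ratio": target.ratio, "source": target.source},
        "no_choice_means_mg_per_bee": nc_means,
        "theoretical": {
            "per_dish_mg_per_bee": theoretical.per_dish,
            "points": {p: [pt.protein_mg, pt.lipid_mg]
                       for p, pt in theoretical.points.items()},
            "ratios": theoretical.ratios,
        },
        "experimental_mean_ratios": experimental_ratios,
        "theoretical_mean_ratios": theoretical_ratio_means,
        "preference_tests": [t.to_dict() for t in preference_tests],
        "theoretical_vs_experimental": [t.to_dict()
                                        for t in theoretical_vs_experimental],
        "ratio_vs_target_tests": [t.to_dict() for t in ratio_tests],
        "mixed_anova": mixed_summary,
        "manova": manova_summary,
        "ratio_anova": {"F": ratio_anova.f_statistic, "df": ratio_anova.df,
                        "p": ratio_anova.p_value,
                        "group_means": ratio_anova.group_means,
                        "letters": ratio_anova.letters},
    }
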