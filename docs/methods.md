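# Methods

## The geometric model

A food with protein and lipid mass fractions `(p, l)` confines intake to the
ray `{a·(p, l) : a ≥ 0}` in the (protein, lipid) plane — the food rail. All
experimental diets satisfy `p + l = 0.5` of wet mass (the other half is a
fixed sucrose/vitamin/cellulose blend), so rails differ only in slope. The
intake target `IT = (P_T, L_T)` is the per-bee amount and balance of the two
nutrients the animals regulate toward over the six-day horizon.

### Rules of compromise

On a rail that misses the target, feeding must stop somewhere; the five
implemented rules are all closed-form in the amount eaten `a`:
protein priority `P_T/p`; lipid priority `L_T/l`; closest distance
`(P_T·p + L_T·l)/(p² + l²)` (the orthogonal projection of IT onto the rail);
equal distance `(P_T + L_T)/(p + l)`; strict restraint `min(P_T/p, L_T/l)`.
When the rail passes through IT all five coincide at IT. Two structural
facts worth noting: the equal-distance closed form makes the signed errors
sum to zero, so over- and under-consumption are *always* complementary on a
proper rail (`p, l > 0`) and no fallback geometry is needed; and strict
restraint is the only rule that never overshoots either nutrient, its
prediction always pinning at least one coordinate exactly to the target.

### Intake-target inference

No closed procedure for the target exists in the field; this package defines
it as the intake point on the rail of the most-consumed no-choice diet
(`rail_point(argmax diet, its mean per-capita total)`). Rationale: on the
rail the animals exploit most fully, consumption reveals both the preferred
balance and the preferred amount. Exact consumption ties are broken toward
the diet whose P:L ratio is nearest 1 on a log scale — deterministic and
symmetric in the two nutrients — and recorded in the result's `source`.

### Rule classification

`classify_rule` scores each rule by the summed squared Euclidean distance
(mg²) between observed and predicted intake points across diets, unweighted
because both axes are in mg. At least two diets whose rails miss the target
are required (rules are indistinguishable otherwise); ties are broken by a
fixed rule order with strict restraint first.

## The synthetic cage experiment

The simulator emulates the study design: no-choice arm of 5 diets plus a
no-food control × 12 cages × 30 bees × 6 days; choice arm of 3 complementary
food pairings (P20:L30+P30:L20, P20:L30+P35:L15, P25:L25+P35:L15) × 12 cages
× 25 bees × 6 days. Defaults, with units and reasons:

- **Intake target (30, 20) mg/bee over 6 days.** Places the target on the
  P30:L20 rail at 100 mg total food per bee, the consumption scale of caged
  nurse bees on their preferred diet.
- **Daily per-bee mortality hazard 0.0267** (probability/day), diet
  independent: `1 − (1 − 0.0267)⁶ ≈ 15.0%` six-day mortality, matching the
  observed cage attrition; survival showed no diet effect, so the hazard has
  no treatment term by default.
- **Feeding noise: lognormal, CV 0.15** multiplying each dish-day's cage
  intake (unit mean). Cage-level behavioral variation of this order is
  typical of group-feeding assays.
- **Weighing noise: additive Gaussian, sd 0.5 mg** on the recorded final
  dish mass — instrument precision (0.1 mg) plus humidity-equilibration
  drift.
- **Endpoints:** mean HPG acinus diameter = 60 µm + 0.5 µm/mg × per-capita
  protein intake + bee-level noise (sd 3 µm), with 10 acini per bee at
  within-bee sd 5 µm; body lipid ~ Normal(4.0, 0.8) mg independent of lipid
  intake (slope 0 by default), encoding the finding that adult bees barely
  assimilate dietary lipid. The acini-per-bee count is a parameter because
  source protocols report both 10 and 12 acini per bee.

Each day, deaths are drawn Binomial(alive, hazard) and removed; the
survivors then demand `allocation/n_days` from each dish, so the daily
census used as the per-capita denominator is exactly the set of bees that
fed. Choice cages allocate between the two dishes by solving the 2×2 rail
mixture that reaches the target; when the target lies outside the cone
spanned by the rails, the single-rail rule is applied on the rail whose
closest point is nearest the target and the allocation is flagged. A
`no_regulation` mode (each dish eaten at its own single-rail rate divided by
the number of dishes) generates data under the null of no compensatory
feeding, used for type-I-error checks of the theoretical-vs-experimental
comparison.

Reproducibility: one master seed; per-cage child seeds derived from
`(master, CRC-32(cage_id))` via numpy `SeedSequence`, with a separate stream
for the endpoint bees. Identical seed and config give identical records.

### What the generator does not emulate

Individual feeding bouts, dish crowding/queueing, diet-switching behavior,
evaporation blanks, palatability-driven intake suppression on extreme diets,
and between-cage heterogeneity in the target itself. Passing tests therefore
demonstrate that the *pipeline* is correct and well calibrated under the
stated noise model — not that real bees obey it.

## Intake accounting

Per-capita daily intake = (initial − final dish mass)/bees alive that day
(dead bees are removed daily and never inflate the denominator). Apparent
dish-mass gains up to 1.0 mg are retained as negative intake and flagged as
measurement noise — clamping would bias totals upward; gains beyond the
tolerance are suspect records, excluded from totals and reported. The
self-selected P:L ratio is total protein over total lipid for the whole
experiment, never a mean of daily ratios.

## Statistics

- **Theoretical choice dataset:** each diet's no-choice mean per-capita
  total divided by the number of dishes (2). Theoretical replicates
  propagate the 12 cage-level no-choice totals rather than expanding to
  per-bee observations; this gives Welch comparisons with ~12+12 cages
  rather than the very large one-sample dfs a per-bee expansion would imply.
- **Bonferroni families are explicit arguments** with study defaults: m=3
  for the dish-preference tests, m=6 for theoretical-vs-experimental and for
  the ratio-vs-target family (family α = 0.05, adjusted α = 0.0083).
- **Welch t** for theoretical-vs-experimental (no pooled-variance
  assumption between arms); one-sample t for preferences and ratios. The
  degenerate zero-variance-at-null case is defined as t = 0, p = 1.
- **One-way ANOVA** by explicit sums of squares (defined F = 0, p = 1 when
  both variance components vanish), Tukey HSD via statsmodels, and a greedy
  compact letter display.
- **Mixed ANOVA** (pingouin): between = food pairing, within = dish role
  (protein-rich vs lipid-rich dish), subject = cage. **MANOVA**
  (statsmodels, Pillai's trace) on cage (protein, lipid) totals.
- **Survival:** Cox proportional hazards (lifelines) with treatment fixed
  effects and the likelihood-ratio χ² against the null model. The cage
  grouping enters through cluster-robust (sandwich) variance rather than a
  frailty/random-effect term, since no installed Python survival library
  fits Cox frailty models; for the LRT reported here the two formulations
  test the same fixed-effect null.
- **HPG regressions** on treatment means (OLS), protein and lipid
  separately; HPG values are log-transformed upstream only for ANOVA-style
  comparisons, while the treatment-mean regressions use raw means.

## Numerical choices

Recipe and rail tolerances 1e-9 on fractions; collinearity asserted to
1e-12; ratio display rounded to one decimal only at presentation. The
acceptance script uses 12 choice cages (the study's replicate count) and
1000 mortality cages; the test suite's stochastic checks use 100 seeds for
rule recovery, 500 seeds for the type-I family rate, and 1000 random
(diet, target) pairs against bisection/minimization oracles — sizes chosen
to keep Monte-Carlo error well inside the asserted bands.

## Known limitations

The inferential layer reproduces the *procedures* of the study, not its
printed F/t/p values, which depend on unpublished raw data. The
no-regulation null assumes an even attention split across dishes; real
unregulated feeding could be biased by dish position or texture. The Cox
comparison omits a true frailty term (above). Diets with `p = 0` or `l = 0`
are excluded by construction, so protein- or lipid-free foods are out of
scope.
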