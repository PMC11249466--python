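# Methods

This note documents the models, parameters and design choices behind
`gripcalc`, and what its synthetic-data tests do and do not establish.

## Biomechanical scores

**CRIP.** The required resistance of a repair is
`CRIP = (0.5 · A + 15) · d`, where `A` is the hernia defect area (cm²) and
`d` the maximal abdominal-wall distension under a Valsalva maneuver (cm).
"Hernia size" is implemented as the **elliptical** defect area
`A = π/4 · w · ℓ`: clinical CRIP values of the order of 200–300 for large
hernias are unreachable if size were a single diameter (with a 30 cm wide
defect, `(0.5·30+15)·d` would need distensions near 8 cm), but arise
naturally from areas. The convention is isolated in
`biomech_scores.defect_size` so it can be swapped wholesale. CRIP and GRIP
are treated as dimensionless resistance scores; no physical unit is asserted.

**MDAR and GRIP.** MDAR is mesh area over defect area; because mesh and
defect share the shape model the elliptical constants cancel and the ratio
is convention-independent. GRIP applies the multiplicative chain —
adhesiveness class × mesh-position class × fixation coefficient — to the
MDAR, then adds the peritoneal and fascial closure factors. Reading the
closure terms as *additive last* follows the formula's word order; no other
ordering information exists. The fixation coefficient is looked up by
`(type, point-count band)` with configurable bands, because only "number and
type of fixation" is specified, not a functional form; zero fixation points
always map to a neutral multiplier of 1. Coefficient tables are immutable,
strictly positive, and missing lookups raise — silent defaults would be a
clinical hazard. The bundled identity table is an explicit placeholder
(GRIP = MDAR) and clinical CLI commands refuse it without
`--allow-placeholder`; the `synthetic_cohort.example_coefficients` table is
labelled synthetic and exists only so simulations reach realistic GRIP
magnitudes.

**Thresholds.** Stability: distension ≤ 1.5 cm (boundary stable).
Interobserver reliability: pooled coefficient of variation (sample SD over
mean of all readings, ≥ 3 observers × ≥ 4 readings) strictly below 5%.
Unstable wall area: shift strictly above 15 mm; strain strictly above 20%.
The 15 mm shift and the 1.5 cm distension limit are the same quantity in
different units, so a field whose peak magnitude is ≤ 15 mm is always
classified stable. Whether the shift and strain criteria combine by OR is
not operationally defined anywhere; both are computed and reported
separately.

## Repair planner

The escalation loop is realized as a deterministic monotone walk over a
discrete plan grid, in the order: overlap up (mesh = defect + 2·overlap,
isotropic, 0.5 cm overlap steps so mesh dimensions move on a 1 cm grid, caps
49 × 49 cm), then fixation points up (10-point steps to 300), then fixation
type up an ordered escalation list (tack → nonresorbable suture → pull-out
suture → bone anchor), then peritoneal and fascial closure on.
`plan_repair` returns the *first* durable state of the walk — the minimal
plan under the escalation order — and `escalation_trace` the audited walk,
in which consecutive states differ by exactly one escalation move. The
order itself (larger meshes before more fixation before closure) mirrors
the clinical narrative for increasingly complex hernias and is a documented
heuristic, configurable through `PlannerConstraints`. GRIP is non-decreasing
along the walk when the coefficient table is escalation-monotone; the
packaged tables are. When the caps leave less than the minimal overlap of
room, the planner degrades to the largest overlap the caps allow rather than
failing; when no grid state is durable it raises an infeasibility error
carrying the best achievable plan and margin. Multi-mesh (sandwich)
composite GRIP is out of scope: combined coefficients for those procedures
are not established.

## Instability maps

Fields are 2-D displacement grids (mm, isotropic spacing) with an optional
wall mask; registration from CT is out of scope. The magnitude map is the
per-pixel Euclidean norm; the unstable region is the strict superlevel set
above 15 mm, its area the pixel count times spacing², reported in cm².
`synth_field` produces three seeded phantoms: a stable low-amplitude wall, a
focal laxity (isotropic Gaussian bump, whose superlevel area has the closed
form `2π σ² ln(A/T)`, enabling an analytic accuracy check — discretization
error on the default 128² grid at 2 mm spacing is a few percent), and a
diffuse laxity plateau. The bump is offset half a pixel from the grid centre
to avoid symmetric threshold ties.

## Complexity score

One point per triggered category: defect width > 10 cm, lateral site,
recurrent hernia, age > 80, BMI > 30, the comorbidity cluster, concomitant
stoma/bowel repair, intensified surgery. All thresholds are strict. The
five comorbidity flags (metabolic, elevated intra-abdominal pressure,
bleeding risk, reduced wound healing, abnormal gait) jointly contribute at
most one point, since their shared biomechanical effect is increased tissue
laxity. Treating age and BMI as standalone categories rather than members
of the collapsible cluster is a modelling choice — they are listed as
distinct risk items and are not laxity-mediated in the same way — and gives
a maximum score of 8; observed cohorts span 0–5.

## Synthetic cohort generator

The generator's defaults are the study conditions: six strata of sizes
18/44/45/31/34/18 (190 patients). Per stratum:

- **Hernia width and length** are drawn from Beta distributions rescaled to
  the published [min, max] with total concentration 6 and the shape solved
  (Brent root-finding on the Beta quantile function) so the *population
  median equals the published median* exactly. Bounded support honours the
  printed extremes; the low median relative to the mean produces the
  documented right skew. Width and length are sampled independently; their
  within-stratum correlation is unpublished.
- **Age and BMI** are truncated Normals at the published mean/SD within the
  published min/max. **Preoperative pain** and all follow-up **NAS pain**
  values use a rounded-Normal sampler whose population median equals the
  published median (unit SD; location −0.8 for a target median of 0, so
  ~90% of late follow-up draws are pain-free — reproducing the
  zero-median late-pain pattern).
- **Distension** is a truncated Normal on [0.2, 12] cm with location
  `1.0 + 0.03 · score` and SD 0.35 — increasing with complexity and
  calibrated so mean stratum CRIPs land near the published stratum CRIP
  means under the area convention (under that convention the published CRIP
  and defect-size cells imply mean distensions of ~1.0–1.15 cm in every
  stratum). This is a calibration choice, not a published distribution.
- **Risk flags** are sampled consistently with the stratum label: flags
  derived from sampled values (width > 10, age > 80, BMI > 30, evaluated on
  the rounded values that enter the record) are counted first, then enough
  standalone categories are switched on uniformly at random that the
  recomputed complexity score equals the label; draws whose derived flags
  alone exceed the label are rejected and redrawn.
- **Mesh plans** come from the repair planner under the synthetic example
  coefficient table; planner-infeasible draws (anatomically extreme
  geometry/distension combinations, as occur clinically) are re-sampled up
  to three times and finally recorded with an `planner_infeasible` extra.
- **Outcomes** are Bernoulli at the published stratum rates
  (events/stratum-size); length of stay uses the bounded-median family on
  the published [min, median, max].

Per-stratum RNG substreams derive deterministically from the global seed, so
resizing one stratum leaves the others' draws unchanged.

**What passing tests show — and don't.** The generator matches published
*marginal, stratum-level* cells (medians, bounds, rates, median pain
trajectories). It does not model between-variable correlation beyond the
flag/score coupling and the planner's mesh–geometry link, site effects,
temporal trends, or measurement error; calibration results on it therefore
validate the pipeline's arithmetic and statistical behaviour, not clinical
effect sizes. The planner-retry policy slightly thins the upper geometry
tail in the highest stratum (its sample medians sit marginally below the
published ones, well inside order-statistic tolerance at the study's n).

## Statistics

Group homogeneity across strata uses the tie-corrected Kruskal–Wallis test;
pairwise two-sided Mann–Whitney U follow-ups (exact for small tie-free
samples, normal-approximated otherwise) run only when the omnibus p < 0.05,
matching the "then u-tests if necessary" policy; gating and Holm adjustment
are configurable, with no correction by default. Degenerate all-equal data
return H = 0, p = 1 rather than an error. Rate tables round half away from
zero to integer percentages — the rounding under which every verifiable
published contingency cell is reproduced; the score-4 postoperative cell is
the known exception (8/34 → 24 against a printed 26 = 8/31, a denominator
slip) and is excluded from the reproduction checks. Descriptive medians use
the mean-of-middle-two convention.

## Problem sizes and numerical choices

Calibration checks run at the sizes the quantities demand: sample-median
checks at the study's own stratum sizes against binomial order-statistic
bands (99% central coverage of the generating quantile function);
complication rates on 10,000 pooled highest-stratum draws against a 3-SE
band; Kruskal–Wallis type-I error on 2,000 null replicates of 6 × 30
observations against a 2-SE band; the trend test on a ×10-scaled cohort
(1,900 records), where the width trend is expected below p = 0.001. All
stochastic tests fix their seeds. Planner search is exact over its grid (no
floating tolerance beyond strict `>` comparisons); Beta shape solving uses
Brent's method to machine precision with the target median clamped to
(0.001, 0.999) of the support for degenerate inputs.

## Known limitations

- GRIP coefficient values are configuration, not code; all shipped tables
  are placeholders or labelled synthetic.
- The isotropic-overlap mesh grid cannot exploit asymmetric cap room (a
  long narrow defect may be declared infeasible although an anisotropic
  mesh would fit).
- The instability stage is planar and threshold-based; no registration,
  3-D volumes, or anisotropic strain tensors.
- Only one recurrence exists in the emulated study, so recurrence is a
  representable flag, not a modelled outcome.
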