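# Methods

## The care-pathway model

`gestasynth` models the Colombian gestation care process as a state
machine advanced in whole gestational weeks. A synthetic woman enters the
pathway at week 0 (pathway entry is dated by drawing a start week
uniformly over the year following 2023-01-02, so cohort dates spread over
a calendar year), and progresses along a common backbone:

- **Prenatal schedule** — 10 prenatal control encounters at weeks 4, 8,
  12, 16, 20, 24, 28, 31, 34 and 36; obstetric ultrasound visits at weeks
  12 and 22; tetanus, influenza and pertussis vaccination procedures at
  weeks 16, 20 and 28, following the Colombian antenatal-care guideline's
  shape. The week placements within guideline-typical windows are a
  package choice; the tracked outcome frequencies do not depend on them.
- **Complication gates** — scheduled Bernoulli decision points:
  ectopic pregnancy (week 8), first-trimester abortion (week 11),
  second-trimester abortion (week 16) — each of these three *terminates*
  the pregnancy pathway through a shared loss-management encounter and a
  type-appropriate surgical procedure — then pregnancy-induced
  hypertension and chronic hypertensive disorders (week 20), hypertensive
  complication (week 22), preeclampsia (week 24), eclampsia and
  gestational diabetes (week 26), fetal growth restriction (week 28),
  hemorrhagic complications (week 30, routed through an emergency visit),
  placenta previa (week 30), placental abruption (week 32) and premature
  rupture of membranes (week 34).
- **Delivery** — at week 34 a gestational-length gate draws preterm
  (calibrated conditional; delivery uniform on weeks 35–36, with a
  premature-newborn condition event at delivery) versus term (delivery
  uniform on weeks 37–41). Delivery is an admission encounter plus an
  attended-delivery procedure; postpartum hemorrhage is drawn immediately
  after delivery; a maternal-death outcome state follows with transition
  probability 0 by default (present in the model, never entered); a
  postpartum control closes the record two weeks after delivery.

Every tracked gate sits on the common backbone, so the probability of a
woman reaching gate *g* is exactly the survivor mass 1 − Σ marginals of
earlier terminating gates. This is what makes the calibration below
exact in expectation.

## Marginal-to-conditional calibration

Gates are specified by cohort *marginals* (fraction of all women with
the outcome) but drawn *conditionally* among women still on the pathway.
`conditional_from_marginals` walks the ordered gate list keeping the
survivor mass *s* (initially 1): each gate receives conditional
*p = m / s*, and terminating gates then reduce *s* by *m*. The defaults
are calibrated to a 10,637-woman reference table of 14 outcome counts
(e.g. ectopic 218, first-trimester abortion 1,714, postpartum hemorrhage
1,443), giving e.g. an abortion conditional of 1714/10419 after the
ectopic gate and preterm/postpartum-hemorrhage conditionals of 603/8069
and 1443/8069 among the 8,069 expected to reach delivery. Simulated
counts are binomial around the targets; the suite checks each percentage
within 4 binomial standard errors at the full cohort size.

Assumptions worth noting:

- Non-terminating complications are **independent Bernoulli draws** given
  survival to their week. In particular eclampsia is drawn independently
  of preeclampsia at its own marginal — no dependency structure between
  complications is modeled, which is the minimal assumption when only
  marginal frequencies are targeted. Real comorbidity correlations
  (e.g. preeclampsia → eclampsia progression) are therefore absent.
- Whether the hypertensive-disorder subcategories should be mutually
  exclusive is an open modelling question; they are independent here.
- Placenta previa and placental abruption have no entry in the reference
  outcome table; their defaults (marginal 0.005 each) are configurable
  placeholders needed to complete the 16-condition inventory.
- Premature rupture of membranes has default marginal 0, so no cohort
  contains a PROM event unless the marginal is overridden.

## Demographics

Sex is always female (the pathway is entered only by pregnant women;
the OMOP integrity audit enforces it). Age at pathway entry is uniform
on 15–49 whole years (plus a uniform day-of-year offset), configurable;
no empirical maternal-age distribution is claimed. Municipality of
residence is drawn proportional to a population-weight table keyed by
DIVIPOLA codes; the bundled 30-municipality table
(`data/synthetic_municipality_weights.csv`) is a synthetic stand-in with
plausible relative sizes of large Colombian municipalities — real census
data can be supplied as a CSV with the same columns. Department filtering
restricts and renormalizes the table; an "all"-departments run allocates
the cohort across departments by a multinomial draw under the master
seed.

## Randomness and reproducibility

Person *i* of a run with master seed *k* uses the numpy stream seeded
with the sequence `(k, i)` for both her demographics and her walk, so any
subset of a cohort can be regenerated independently and generation order
does not matter. Re-running with the same configuration is byte-identical
across all outputs (CSV row order is person id, then event order; the
manifest contains no timestamps).

## OMOP export

One `person` row per woman; one `visit_occurrence` per encounter event;
one `condition_occurrence` per condition-onset event; one
`procedure_occurrence` per procedure event; `observation_period` spans
each woman's first to last event; `death` is populated only from death
events (empty under the default module). Conditions and procedures link
to the latest visit on or before their date, which attaches same-week
onsets to the visit they triggered. Locations carry the Colombian
political division (municipality in `city`, department in `state`, `zip`
empty, country `CO`). Concept ids come from a
`vocabulary,source_code,concept_id` map; the bundled
`data/synthetic_concept_map.csv` is a synthetic stand-in for the licensed
vocabularies (its ids, apart from the standard female gender concept
8532, are arbitrary) — unmapped codes export concept id 0 with the source
code preserved in `*_source_value`. The simulated state name is kept in a
secondary source column (`admitted_from_source_value` for visits,
`condition_status_source_value` for conditions, `modifier_source_value`
for procedures) so encounter-class detail survives the ETL. Observation
events (e.g. pregnancy confirmation) are not exported — the bundle has no
`observation` table; they are available in the `events-json` output.

## Numerical choices

- Distributed transition mass must equal 1 within 1e-9; the final branch
  absorbs any floating-point shortfall at draw time, so a walk cannot
  fall off the end of a branch list.
- Conditional transitions must end in a predicate-free catch-all —
  validated, not assumed — so no walk can dead-end.
- Walks are capped at 10,000 state visits (the shipped pathway uses
  ~100), turning an authoring cycle into an explicit error.
- Report percentages are rounded to one decimal, half-up, matching how
  such tables are printed; raw fractions are kept alongside. Literature
  comparisons are computed with decimal arithmetic so one-decimal inputs
  give exact cell values; the sign convention is observed minus
  reference, against both bounds of a range, with a point reference
  producing a single direct difference.

## What the generator does and does not emulate

The generator reproduces marginal outcome frequencies, trimester
placement, and the encounter/procedure scaffolding of the care pathway.
It does **not** emulate: inter-complication correlation; week-to-week
variation in visit attendance (every surviving woman follows the same
schedule, so the data is more deterministic than real care records);
fetal/newborn records beyond the premature-newborn condition code;
tobacco/alcohol exposure; providers, costs or insurance. Passing
frequency tests therefore says the calibration layer is correct, not
that downstream models trained on this data transfer to real cohorts.

## Problem sizes used by the suite

The frequency-recovery checks simulate the full 10,637-woman reference
cohort (about a second); structural, ETL and property checks use a
1,200-woman cohort and small purpose-built modules; the branch-frequency
check uses 100,000 walks of a two-branch module; the municipality
goodness-of-fit uses 50,000 draws.
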