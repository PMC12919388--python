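# gestasynth

Synthetic maternal-health cohorts for the Colombian pregnancy care
pathway, exported to the OMOP Common Data Model v5.4.

Real obstetric EHR data is scarce, access-restricted and rarely coded
uniformly — particularly in Colombia, which lacks a national clinical
information system. `gestasynth` generates fully synthetic longitudinal
records for pregnant women instead: each woman is walked through a
week-granularity clinical state machine of gestation (prenatal controls,
trimester-anchored complications, vaccinations, delivery, postpartum
care), her demographics drawn from DIVIPOLA-coded municipality population
weights, and the resulting event logs are converted to standard CDM v5.4
CSV tables (`person`, `location`, `observation_period`,
`visit_occurrence`, `condition_occurrence`, `procedure_occurrence`,
`death`) ready for OHDSI-style analyses and AI model development.

It is aimed at health-informatics and epidemiology groups who need
shareable, privacy-free obstetric datasets whose outcome frequencies are
controlled and clinically coherent.

## The model

The pathway is a directed graph of typed states (`Encounter`,
`ConditionOnset`, `Procedure`, `Delay`, …) with `Direct`, `Distributed`
(probabilistic) and `Conditional` (attribute-tested) transitions.
Complications enter through scheduled Bernoulli **gates**. A gate *g* has
a target *marginal* incidence *m<sub>g</sub>* — the fraction of the whole
cohort with the outcome — but is drawn only among women still pregnant at
its gestational week, so the engine needs the *conditional* probability

&nbsp;&nbsp;&nbsp;&nbsp;*p<sub>g</sub>* = *m<sub>g</sub>* / (1 − Σ<sub>t&lt;g, t terminating</sub> *m<sub>t</sub>*),

where the sum runs over earlier pregnancy-terminating gates (ectopic
pregnancy, first- and second-trimester abortion). Forward-multiplying the
conditionals by the survivor mass returns the marginals exactly, so a
simulated cohort reproduces the target frequencies in expectation. The
default gates are calibrated to a reference table of 14 outcome counts
over a 10,637-woman cohort; the maternal-death outcome state is present
but has transition probability 0 by default, so no synthetic woman dies.

## Worked example

```bash
gestasynth --n 10637 --seed 7 --outdir out --format omop-csv --format report
```

writes the seven CDM tables, `report.csv`/`report.txt`, the module
definition used, and a run manifest. The log reports per-stage counts:

```
[gestasynth] generating cohort: n=10637 seed=7 department=all
[gestasynth] simulated 10637 persons, 177196 events
[gestasynth] OMOP CDM v5.4 tables: person=10637, location=30, observation_period=10637,
             visit_occurrence=122028, condition_occurrence=7642, procedure_occurrence=36889, death=0
[gestasynth] frequency report written (14 conditions)
```

`report.txt` begins:

```
            code  condition                                             n (%)  literature (%)    difference (%)
        34801009  Embarazo ectópico                                 234 (2.2)               2               0.2
        19169002  Aborto en el primer trimestre                   1712 (16.1)           10-20       6.1 to -3.9
        85116003  Aborto en el segundo trimestre                    636 (6.0)               5                 1
```

Reading row one: 234 of 10,637 women (2.2 %) had an ectopic-pregnancy
condition event, against a literature estimate of 2 %, i.e. 0.2
percentage points above it. The counts are binomially distributed around
the calibrated targets (here 218/10,637 = 2.05 %), so a different seed
gives slightly different counts; differences are observed minus
reference, reported against both bounds when the literature gives a
range.

The same pipeline is available as a library:

```python
import gestasynth as gs
from gestasynth.cli import generate_cohort

module = gs.default_pregnancy_module()
cohort = generate_cohort(2000, 7, gs.default_weights(), module)
print(gs.tabulate(cohort)[["code", "count", "percent"]])
```

## Layout

- `src/gestasynth/engine.py` — generic state-machine loader/validator/executor
- `src/gestasynth/pregnancy.py` — the Colombian gestation module and gate calibration
- `src/gestasynth/demographics.py` — person sampling from DIVIPOLA municipality weights
- `src/gestasynth/omop.py` — CDM v5.4 ETL, concept mapping, integrity checks
- `src/gestasynth/report.py` — frequency tabulation and literature comparison
- `src/gestasynth/cli.py` — the `gestasynth` command
- `src/gestasynth/data/` — module JSON schema and synthetic stand-in fixtures
  (municipality weights, concept map)
- `docs/methods.md` — modelling assumptions, parameters and limitations
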