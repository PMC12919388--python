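"""Colombian gestation care-pathway module.

Builds the pregnancy state machine: a week-granularity backbone from
conception to the postpartum control, carrying the prenatal encounter
schedule of the Colombian clinical practice guideline (10 prenatal
controls, 2 obstetric ultrasounds, tetanus/influenza/pertussis
vaccination), with complication *gates* anchored to their gestational
trimester:

- first trimester: ectopic pregnancy, first-trimester abortion (both end
  the pregnancy pathway);
- second trimester: second-trimester abortion (terminating), the
  hypertensive-disorder group (pregnancy-induced hypertension, chronic
  hypertensive disorders, hypertensive complication, preeclampsia,
  eclampsia) and gestational diabetes;
- third trimester: fetal growth restriction, hemorrhagic complications,
  placenta previa, placental abruption, premature rupture of membranes,
  and the preterm/term gestational-length decision;
- immediately postpartum: postpartum hemorrhage, and a maternal-death
  outcome state whose default transition probability is zero.

Each gate is a Bernoulli decision at its scheduled week.  Gate
probabilities are *conditional* (among women still on the pathway at that
week) but are specified as cohort *marginals*; :func:`conditional_from_marginals`
converts one to the other so that cohort-level condition frequencies
reproduce the target marginals in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Any, Optional, Sequence

from .engine import (
    CodedConcept,
    ModuleDefinition,
    ModuleValidationError,
    validate_module,
)

__all__ = [
    "Gate",
    "ReferenceRange",
    "InfeasibleCalibrationError",
    "DEFAULT_COHORT_SIZE",
    "OBSERVED_COUNTS",
    "CONDITIONS",
    "default_gates",
    "conditional_from_marginals",
    "build_pregnancy_module",
    "default_pregnancy_module",
    "default_reference_ranges",
]

#: Size of the reference synthetic cohort the default gates are calibrated to.
DEFAULT_COHORT_SIZE = 10_637

# SNOMED-CT condition concepts of the pathway's clinical outcomes.
ECTOPIC = CodedConcept(system="SNOMED-CT", code="34801009", display="Embarazo ectópico")
ABORTION_T1 = CodedConcept(
    system="SNOMED-CT", code="19169002", display="Aborto en el primer trimestre"
)
ABORTION_T2 = CodedConcept(
    system="SNOMED-CT", code="85116003", display="Aborto en el segundo trimestre"
)
PIH = CodedConcept(
    system="SNOMED-CT", code="48194001", display="Hipertensión inducida por el embarazo"
)
HTN_DISORDERS = CodedConcept(
    system="SNOMED-CT", code="38341003", display="Hipertensión arterial, trastornos"
)
HTN_COMPLICATION = CodedConcept(
    system="SNOMED-CT",
    code="37618003",
    display="Complicación de hipertensión arterial en el embarazo",
)
PREECLAMPSIA = CodedConcept(system="SNOMED-CT", code="398254007", display="Preeclampsia")
ECLAMPSIA = CodedConcept(system="SNOMED-CT", code="198992004", display="Eclampsia")
GDM = CodedConcept(
    system="SNOMED-CT", code="40801000119106", display="Diabetes mellitus gestacional"
)
FGR = CodedConcept(
    system="SNOMED-CT", code="22033007", display="Restricción del crecimiento fetal"
)
PRETERM = CodedConcept(
    system="SNOMED-CT", code="367494004", display="Recién nacido prematuro"
)
PROM = CodedConcept(
    system="SNOMED-CT", code="44223004", display="Ruptura prematura de membranas"
)
HEMORRHAGE = CodedConcept(
    system="SNOMED-CT", code="106004004", display="Complicaciones hemorrágicas del embarazo"
)
PPH = CodedConcept(system="SNOMED-CT", code="47821001", display="Hemorragia posparto")
PLACENTA_PREVIA = CodedConcept(
    system="SNOMED-CT", code="36813001", display="Placenta previa"
)
ABRUPTIO = CodedConcept(
    system="SNOMED-CT", code="415105001", display="Abruptio de placenta"
)

#: The 14 tracked outcome concepts, in pathway order.
CONDITIONS: tuple[CodedConcept, ...] = (
    ECTOPIC,
    ABORTION_T1,
    ABORTION_T2,
    PIH,
    HTN_DISORDERS,
    HTN_COMPLICATION,
    PREECLAMPSIA,
    ECLAMPSIA,
    GDM,
    FGR,
    PRETERM,
    PROM,
    HEMORRHAGE,
    PPH,
)

#: Reference-cohort case counts the default gates are calibrated to
#: (denominator :data:`DEFAULT_COHORT_SIZE`).
OBSERVED_COUNTS: dict[str, int] = {
    ECTOPIC.code: 218,
    ABORTION_T1.code: 1714,
    ABORTION_T2.code: 636,
    PIH.code: 107,
    HTN_DISORDERS.code: 604,
    HTN_COMPLICATION.code: 92,
    PREECLAMPSIA.code: 802,
    ECLAMPSIA.code: 445,
    GDM.code: 696,
    FGR.code: 30,
    PRETERM.code: 603,
    PROM.code: 0,
    HEMORRHAGE.code: 172,
    PPH.code: 1443,
}


class InfeasibleCalibrationError(ValueError):
    """Survivor mass hit zero (or a conditional left [0, 1]) during
    marginal-to-conditional conversion."""


@dataclass(frozen=True)
class Gate:
    """One scheduled Bernoulli complication gate.

    ``marginal`` is the target fraction of the *full* cohort with the
    outcome; ``conditional`` (filled by :func:`conditional_from_marginals`)
    is the draw probability among women still on the pathway at
    ``week``.  ``terminates`` marks gates that end the pregnancy pathway
    (ectopic, both abortions)."""

    condition: CodedConcept
    marginal: float
    week: int
    terminates: bool = False
    conditional: Optional[float] = None


@dataclass(frozen=True)
class ReferenceRange:
    """Literature prevalence for one outcome, in percent of pregnancies.

    Point estimates are encoded as ``lower == upper``."""

    condition: CodedConcept
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.lower <= self.upper <= 100.0):
            raise ValueError(
                f"invalid reference range [{self.lower}, {self.upper}] for "
                f"{self.condition.code}"
            )

    @property
    def is_point(self) -> bool:
        return self.lower == self.upper


def default_gates(
    cohort_size: int = DEFAULT_COHORT_SIZE,
    *,
    overrides: Optional[dict[str, float]] = None,
    placenta_previa_marginal: float = 0.005,
    abruptio_marginal: float = 0.005,
) -> list[Gate]:
    """Default gate sequence, marginals calibrated to the reference cohort.

    ``overrides`` maps a condition code to a replacement marginal
    (fraction of cohort).  Placenta previa and placental abruption are not
    part of the tracked outcome table; their defaults are small
    placeholders and configurable here.
    """
    n = float(cohort_size)
    m = {code: count / n for code, count in OBSERVED_COUNTS.items()}
    if overrides:
        m.update(overrides)
    gates = [
        Gate(ECTOPIC, m[ECTOPIC.code], week=8, terminates=True),
        Gate(ABORTION_T1, m[ABORTION_T1.code], week=11, terminates=True),
        Gate(ABORTION_T2, m[ABORTION_T2.code], week=16, terminates=True),
        Gate(PIH, m[PIH.code], week=20),
        Gate(HTN_DISORDERS, m[HTN_DISORDERS.code], week=20),
        Gate(HTN_COMPLICATION, m[HTN_COMPLICATION.code], week=22),
        Gate(PREECLAMPSIA, m[PREECLAMPSIA.code], week=24),
        Gate(ECLAMPSIA, m[ECLAMPSIA.code], week=26),
        Gate(GDM, m[GDM.code], week=26),
        Gate(FGR, m[FGR.code], week=28),
        Gate(HEMORRHAGE, m[HEMORRHAGE.code], week=30),
        Gate(PLACENTA_PREVIA, placenta_previa_marginal, week=30),
        Gate(ABRUPTIO, abruptio_marginal, week=32),
        Gate(PROM, m[PROM.code], week=34),
        Gate(PRETERM, m[PRETERM.code], week=34),
        Gate(PPH, m[PPH.code], week=40),
    ]
    return conditional_from_marginals(gates)


def conditional_from_marginals(gates: Sequence[Gate]) -> list[Gate]:
    """Fill each gate's conditional probability from its cohort marginal.

    Walking the gates in order, the *survivor mass* before gate ``g`` is
    ``1 − Σ marginals of earlier terminating gates``; the conditional draw
    probability is ``marginal / survivor mass``.  Forward-multiplying the
    conditionals by the survivor mass recovers the input marginals
    exactly, so a cohort simulated with the conditionals reproduces the
    marginals in expectation.

    Raises :class:`InfeasibleCalibrationError` if the survivor mass is
    exhausted or any conditional leaves [0, 1].
    """
    out: list[Gate] = []
    survivors = 1.0
    for gate in gates:
        if not (0.0 <= gate.marginal <= 1.0):
            raise InfeasibleCalibrationError(
                f"marginal {gate.marginal} for {gate.condition.code} outside [0, 1]"
            )
        if survivors <= 0.0:
            raise InfeasibleCalibrationError(
                f"no survivor mass left at gate {gate.condition.code}"
            )
        conditional = gate.marginal / survivors
        if conditional > 1.0:
            raise InfeasibleCalibrationError(
                f"marginal {gate.marginal} for {gate.condition.code} exceeds "
                f"survivor mass {survivors}"
            )
        out.append(replace(gate, conditional=conditional))
        if gate.terminates:
            survivors -= gate.marginal
    return out


# ---------------------------------------------------------------------------
# Module assembly

# Encounter concepts (SNOMED-CT) — 16 encounter states:
# 10 prenatal controls, 2 ultrasound visits, 1 pregnancy-loss management
# visit, 1 emergency visit, 1 delivery admission, 1 postpartum control.
_PRENATAL_INITIAL = CodedConcept(
    system="SNOMED-CT", code="424441002", display="Control prenatal inicial"
)
_PRENATAL = CodedConcept(
    system="SNOMED-CT", code="424619006", display="Control prenatal de seguimiento"
)
_ULTRASOUND = CodedConcept(
    system="SNOMED-CT", code="268445003", display="Ecografía obstétrica"
)
_LOSS_VISIT = CodedConcept(
    system="SNOMED-CT", code="183452005", display="Admisión urgente por pérdida gestacional"
)
_EMERGENCY = CodedConcept(
    system="SNOMED-CT", code="50849002", display="Admisión a urgencias"
)
_DELIVERY_ADMISSION = CodedConcept(
    system="SNOMED-CT", code="305408004", display="Admisión para atención del parto"
)
_POSTPARTUM_VISIT = CodedConcept(
    system="SNOMED-CT", code="133906008", display="Control posparto"
)

# Procedure concepts (CUPS, Colombia's unified procedure classification).
_ECTOPIC_SURGERY = CodedConcept(
    system="CUPS", code="683500", display="Salpingectomía por embarazo ectópico"
)
_EVACUATION = CodedConcept(
    system="CUPS", code="695100", display="Evacuación uterina obstétrica"
)
_DELIVERY_CARE = CodedConcept(system="CUPS", code="735000", display="Atención del parto")
_PPH_CARE = CodedConcept(
    system="CUPS", code="689200", display="Manejo de hemorragia posparto"
)
_TETANUS_VACC = CodedConcept(
    system="CUPS", code="993102", display="Vacunación antitetánica"
)
_INFLUENZA_VACC = CodedConcept(
    system="CUPS", code="993504", display="Vacunación contra influenza"
)
_PERTUSSIS_VACC = CodedConcept(
    system="CUPS", code="993130", display="Vacunación contra tos ferina (Tdap)"
)

_PREGNANT_OBS = CodedConcept(
    system="SNOMED-CT", code="77386006", display="Paciente actualmente embarazada"
)
_MATERNAL_DEATH = CodedConcept(
    system="CIE-10", code="O95", display="Muerte obstétrica de causa no especificada"
)


def _concept(c: CodedConcept) -> dict[str, str]:
    return {"system": c.system, "code": c.code, "display": c.display}


def _direct(target: str) -> dict[str, Any]:
    return {"mode": "Direct", "branches": [{"target": target}]}


def _distributed(*branches: tuple[str, float]) -> dict[str, Any]:
    return {
        "mode": "Distributed",
        "branches": [{"target": t, "probability": p} for t, p in branches],
    }


def build_pregnancy_module(
    gates: Optional[Sequence[Gate]] = None,
    *,
    death_probability: float = 0.0,
    name: str = "gestacion_colombia",
) -> ModuleDefinition:
    """Assemble the gestation module from a calibrated gate sequence.

    The backbone advances week by week from pathway entry (week 0) to a
    term delivery drawn uniformly on weeks 37–41 (or a preterm delivery on
    weeks 35–36 at the calibrated preterm conditional), then a postpartum
    control two weeks after delivery.  Every gate of the default sequence
    sits on the common backbone, so the probability of reaching a gate is
    exactly the survivor mass used by the calibration.

    ``death_probability`` is the transition probability into the
    maternal-death outcome state after delivery; the default 0 keeps the
    state present but never entered, so no synthetic woman dies.
    """
    if gates is None:
        gates = default_gates()
    gate_by_code = {g.condition.code: g for g in gates}
    required = CONDITIONS + (PLACENTA_PREVIA, ABRUPTIO)
    missing = [c.code for c in required if c.code not in gate_by_code]
    if missing:
        raise ValueError(f"gate sequence lacks required conditions: {missing}")
    if any(g.conditional is None for g in gates):
        gates = conditional_from_marginals(gates)
        gate_by_code = {g.condition.code: g for g in gates}

    def p_of(code: str) -> float:
        return float(gate_by_code[code].conditional)

    states: dict[str, dict[str, Any]] = {}

    def add(name_: str, **kwargs: Any) -> None:
        states[name_] = kwargs

    def add_gate(
        gate_name: str, code: str, onset_name: str, next_name: str
    ) -> None:
        # Non-terminating gate: Bernoulli draw, onset rejoins the backbone.
        p = p_of(code)
        concept = gate_by_code[code].condition
        add(gate_name, kind="Simple", transition=_distributed((onset_name, p), (next_name, 1.0 - p)))
        add(
            onset_name,
            kind="ConditionOnset",
            codes=[_concept(concept)],
            transition=_direct(next_name),
        )

    def add_loss_gate(
        gate_name: str, code: str, mark: str, onset_name: str, next_name: str, loss_type: str
    ) -> None:
        # Terminating gate: mark the loss type, record the onset, route to
        # the shared loss-management visit.
        p = p_of(code)
        concept = gate_by_code[code].condition
        add(gate_name, kind="Simple", transition=_distributed((mark, p), (next_name, 1.0 - p)))
        add(
            mark,
            kind="SetAttribute",
            attribute="loss_type",
            value=loss_type,
            transition=_direct(onset_name),
        )
        add(
            onset_name,
            kind="ConditionOnset",
            codes=[_concept(concept)],
            transition=_direct("Loss_Management_Visit"),
        )

    def add_delay(name_: str, weeks: int, next_name: str) -> None:
        add(name_, kind="Delay", weeks=weeks, transition=_direct(next_name))

    def add_encounter(name_: str, concept: CodedConcept, next_name: str) -> None:
        add(name_, kind="Encounter", codes=[_concept(concept)], transition=_direct(next_name))

    def add_procedure(name_: str, concept: CodedConcept, next_name: str) -> None:
        add(name_, kind="Procedure", codes=[_concept(concept)], transition=_direct(next_name))

    # --- backbone, week 0 → delivery ------------------------------------
    add("Start", kind="Initial", transition=_direct("Set_Pregnant"))
    add(
        "Set_Pregnant",
        kind="SetAttribute",
        attribute="pregnant",
        value=True,
        transition=_direct("Delay_To_Week_4"),
    )
    add_delay("Delay_To_Week_4", 4, "Prenatal_Control_1")
    add_encounter("Prenatal_Control_1", _PRENATAL_INITIAL, "Pregnancy_Confirmation")
    add(
        "Pregnancy_Confirmation",
        kind="Observation",
        codes=[_concept(_PREGNANT_OBS)],
        transition=_direct("Delay_To_Week_8"),
    )
    add_delay("Delay_To_Week_8", 4, "Prenatal_Control_2")
    add_encounter("Prenatal_Control_2", _PRENATAL, "Ectopic_Gate")
    add_loss_gate(
        "Ectopic_Gate", ECTOPIC.code, "Mark_Ectopic", "Ectopic_Onset", "Delay_To_Week_11", "ectopic"
    )
    add_delay("Delay_To_Week_11", 3, "Abortion_T1_Gate")
    add_loss_gate(
        "Abortion_T1_Gate",
        ABORTION_T1.code,
        "Mark_Abortion_T1",
        "Abortion_T1_Onset",
        "Delay_To_Week_12",
        "abortion",
    )
    add_delay("Delay_To_Week_12", 1, "Prenatal_Control_3")
    add_encounter("Prenatal_Control_3", _PRENATAL, "Ultrasound_1")
    add_encounter("Ultrasound_1", _ULTRASOUND, "Delay_To_Week_16")
    add_delay("Delay_To_Week_16", 4, "Prenatal_Control_4")
    add_encounter("Prenatal_Control_4", _PRENATAL, "Tetanus_Vaccination")
    add_procedure("Tetanus_Vaccination", _TETANUS_VACC, "Abortion_T2_Gate")
    add_loss_gate(
        "Abortion_T2_Gate",
        ABORTION_T2.code,
        "Mark_Abortion_T2",
        "Abortion_T2_Onset",
        "Delay_To_Week_20",
        "abortion",
    )
    add_delay("Delay_To_Week_20", 4, "Prenatal_Control_5")
    add_encounter("Prenatal_Control_5", _PRENATAL, "Influenza_Vaccination")
    add_procedure("Influenza_Vaccination", _INFLUENZA_VACC, "PIH_Gate")
    add_gate("PIH_Gate", PIH.code, "PIH_Onset", "Hypertension_Gate")
    add_gate("Hypertension_Gate", HTN_DISORDERS.code, "Hypertension_Onset", "Delay_To_Week_22")
    add_delay("Delay_To_Week_22", 2, "Ultrasound_2")
    add_encounter("Ultrasound_2", _ULTRASOUND, "Hypertension_Complication_Gate")
    add_gate(
        "Hypertension_Complication_Gate",
        HTN_COMPLICATION.code,
        "Hypertension_Complication_Onset",
        "Delay_To_Week_24",
    )
    add_delay("Delay_To_Week_24", 2, "Prenatal_Control_6")
    add_encounter("Prenatal_Control_6", _PRENATAL, "Preeclampsia_Gate")
    add_gate("Preeclampsia_Gate", PREECLAMPSIA.code, "Preeclampsia_Onset", "Delay_To_Week_26")
    add_delay("Delay_To_Week_26", 2, "Eclampsia_Gate")
    add_gate("Eclampsia_Gate", ECLAMPSIA.code, "Eclampsia_Onset", "GDM_Gate")
    add_gate("GDM_Gate", GDM.code, "GDM_Onset", "Delay_To_Week_28")
    add_delay("Delay_To_Week_28", 2, "Prenatal_Control_7")
    add_encounter("Prenatal_Control_7", _PRENATAL, "Pertussis_Vaccination")
    add_procedure("Pertussis_Vaccination", _PERTUSSIS_VACC, "FGR_Gate")
    add_gate("FGR_Gate", FGR.code, "FGR_Onset", "Delay_To_Week_30")
    add_delay("Delay_To_Week_30", 2, "Hemorrhage_Gate")
    # hemorrhagic complication routes through the emergency visit
    p_hem = p_of(HEMORRHAGE.code)
    add(
        "Hemorrhage_Gate",
        kind="Simple",
        transition=_distributed(("Hemorrhage_Onset", p_hem), ("Placenta_Previa_Gate", 1.0 - p_hem)),
    )
    add(
        "Hemorrhage_Onset",
        kind="ConditionOnset",
        codes=[_concept(HEMORRHAGE)],
        transition=_direct("Emergency_Visit"),
    )
    add_encounter("Emergency_Visit", _EMERGENCY, "Placenta_Previa_Gate")
    add_gate("Placenta_Previa_Gate", PLACENTA_PREVIA.code, "Placenta_Previa_Onset", "Delay_To_Week_31")
    add_delay("Delay_To_Week_31", 1, "Prenatal_Control_8")
    add_encounter("Prenatal_Control_8", _PRENATAL, "Delay_To_Week_32")
    add_delay("Delay_To_Week_32", 1, "Abruptio_Gate")
    add_gate("Abruptio_Gate", ABRUPTIO.code, "Abruptio_Onset", "Delay_To_Week_34")
    add_delay("Delay_To_Week_34", 2, "Prenatal_Control_9")
    add_encounter("Prenatal_Control_9", _PRENATAL, "PROM_Gate")
    add_gate("PROM_Gate", PROM.code, "PROM_Onset", "Gestational_Length_Gate")

    # --- gestational length and delivery --------------------------------
    p_preterm = p_of(PRETERM.code)
    add(
        "Gestational_Length_Gate",
        kind="Simple",
        transition=_distributed(
            ("Preterm_Week_Choice", p_preterm), ("Delay_To_Week_36", 1.0 - p_preterm)
        ),
    )
    add(
        "Preterm_Week_Choice",
        kind="Simple",
        transition=_distributed(("Preterm_Delay_35", 0.5), ("Preterm_Delay_36", 0.5)),
    )
    add_delay("Preterm_Delay_35", 1, "Preterm_Onset")
    add_delay("Preterm_Delay_36", 2, "Preterm_Onset")
    add(
        "Preterm_Onset",
        kind="ConditionOnset",
        codes=[_concept(PRETERM)],
        transition=_direct("Delivery_Admission"),
    )
    add_delay("Delay_To_Week_36", 2, "Prenatal_Control_10")
    add_encounter("Prenatal_Control_10", _PRENATAL, "Term_Week_Choice")
    add(
        "Term_Week_Choice",
        kind="Simple",
        transition=_distributed(*[(f"Term_Delay_{w}", 0.2) for w in range(37, 42)]),
    )
    for week in range(37, 42):
        add_delay(f"Term_Delay_{week}", week - 36, "Delivery_Admission")
    add_encounter("Delivery_Admission", _DELIVERY_ADMISSION, "Delivery_Care")
    add_procedure("Delivery_Care", _DELIVERY_CARE, "End_Pregnancy_Delivered")
    add(
        "End_Pregnancy_Delivered",
        kind="SetAttribute",
        attribute="pregnant",
        value=False,
        transition=_direct("Postpartum_Hemorrhage_Gate"),
    )
    p_pph = p_of(PPH.code)
    add(
        "Postpartum_Hemorrhage_Gate",
        kind="Simple",
        transition=_distributed(
            ("Postpartum_Hemorrhage_Onset", p_pph), ("Maternal_Death_Gate", 1.0 - p_pph)
        ),
    )
    add(
        "Postpartum_Hemorrhage_Onset",
        kind="ConditionOnset",
        codes=[_concept(PPH)],
        transition=_direct("Postpartum_Hemorrhage_Care"),
    )
    add_procedure("Postpartum_Hemorrhage_Care", _PPH_CARE, "Maternal_Death_Gate")
    add(
        "Maternal_Death_Gate",
        kind="Simple",
        transition=_distributed(
            ("Maternal_Death", death_probability), ("Postpartum_Delay", 1.0 - death_probability)
        ),
    )
    add(
        "Maternal_Death",
        kind="Death",
        codes=[_concept(_MATERNAL_DEATH)],
        transition=_direct("End"),
    )
    add_delay("Postpartum_Delay", 2, "Postpartum_Control")
    add_encounter("Postpartum_Control", _POSTPARTUM_VISIT, "End")

    # --- pregnancy-loss branch ------------------------------------------
    add(
        "Loss_Management_Visit",
        kind="Encounter",
        codes=[_concept(_LOSS_VISIT)],
        transition={
            "mode": "Conditional",
            "branches": [
                {
                    "target": "Ectopic_Surgery",
                    "predicate": {"attribute": "loss_type", "operator": "==", "value": "ectopic"},
                },
                {"target": "Uterine_Evacuation"},
            ],
        },
    )
    add_procedure("Ectopic_Surgery", _ECTOPIC_SURGERY, "End_Pregnancy_Loss")
    add_procedure("Uterine_Evacuation", _EVACUATION, "End_Pregnancy_Loss")
    add(
        "End_Pregnancy_Loss",
        kind="SetAttribute",
        attribute="pregnant",
        value=False,
        transition=_direct("End"),
    )
    add("End", kind="Terminal")

    module = ModuleDefinition.model_validate(
        {"name": name, "schema_version": "1.0", "initial": "Start", "states": states}
    )
    issues = validate_module(module)
    if issues:  # defensive: the builder should always emit a valid module
        raise ModuleValidationError(issues)
    return module


def default_pregnancy_module() -> ModuleDefinition:
    """The shipped gestation module with default calibrated gates."""
    return build_pregnancy_module()


def default_reference_ranges() -> list[ReferenceRange]:
    """Literature prevalence ranges (percent) for the 14 tracked outcomes;
    point values are encoded with ``lower == upper``."""
    return [
        ReferenceRange(ECTOPIC, 2.0, 2.0),
        ReferenceRange(ABORTION_T1, 10.0, 20.0),
        ReferenceRange(ABORTION_T2, 5.0, 5.0),
        ReferenceRange(PIH, 2.0, 8.0),
        ReferenceRange(HTN_DISORDERS, 2.0, 8.0),
        ReferenceRange(HTN_COMPLICATION, 2.0, 8.0),
        ReferenceRange(PREECLAMPSIA, 2.0, 8.0),
        ReferenceRange(ECLAMPSIA, 2.0, 8.0),
        ReferenceRange(GDM, 2.0, 5.0),
        ReferenceRange(FGR, 8.0, 10.0),
        ReferenceRange(PRETERM, 7.2, 7.2),
        ReferenceRange(PROM, 8.0, 10.0),
        ReferenceRange(HEMORRHAGE, 4.0, 4.0),
        ReferenceRange(PPH, 4.0, 6.0),
    ]
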