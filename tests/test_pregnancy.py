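import pytest
from hypothesis import given, strategies as st

import gestasynth as gs
from gestasynth.engine import StateKind
from gestasynth.pregnancy import (
    ABORTION_T1,
    ABORTION_T2,
    ECTOPIC,
    HEMORRHAGE,
    PPH,
    PRETERM,
    PROM,
    Gate,
    InfeasibleCalibrationError,
)

from conftest import enumerate_marginals

N = gs.DEFAULT_COHORT_SIZE  # 10,637


def gate_map(gates):
    return {g.condition.code: g for g in gates}


class TestConditionalFromMarginals:
    @pytest.mark.parametrize(
        "code,expected",
        [
            # first gate: no prior losses, conditional equals marginal
            (ECTOPIC.code, 218 / 10637),
            # after the ectopic gate 10,419 of 10,637 remain
            (ABORTION_T1.code, 1714 / 10419),
            # after both first-trimester losses 8,705 remain
            (ABORTION_T2.code, 636 / 8705),
            # 8,069 reach the delivery decision
            (PRETERM.code, 603 / 8069),
            (PPH.code, 1443 / 8069),
        ],
    )
    def test_default_conditionals(self, code, expected):
        gates = gate_map(gs.default_gates())
        assert gates[code].conditional == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_exhaustive_enumeration(self):
        gates = gs.default_gates()
        realized = enumerate_marginals(gates)
        for gate in gates:
            assert realized[gate.condition.code] == pytest.approx(
                gate.marginal, abs=1e-12
            )

    def test_forward_product_recovers_marginals(self):
        gates = gs.default_gates()
        survivors = 1.0
        for gate in gates:
            assert gate.conditional * survivors == pytest.approx(gate.marginal, abs=1e-12)
            if gate.terminates:
                survivors -= gate.marginal

    def test_exhausted_survivor_mass_is_infeasible(self):
        gates = [
            Gate(ECTOPIC, 0.6, week=8, terminates=True),
            Gate(ABORTION_T1, 0.5, week=11, terminates=True),
        ]
        with pytest.raises(InfeasibleCalibrationError):
            gs.conditional_from_marginals(gates)

    def test_marginal_outside_unit_interval_rejected(self):
        with pytest.raises(InfeasibleCalibrationError):
            gs.conditional_from_marginals([Gate(ECTOPIC, 1.2, week=8)])

    @given(
        st.lists(
            st.tuples(st.floats(0.0, 0.12), st.booleans()),
            min_size=1,
            max_size=8,
        )
    )
    def test_random_gate_specs_roundtrip(self, spec):
        gates = [
            Gate(ECTOPIC, marginal, week=8 + i, terminates=term)
            for i, (marginal, term) in enumerate(spec)
        ]
        filled = gs.conditional_from_marginals(gates)
        survivors = 1.0
        for gate in filled:
            assert 0.0 <= gate.conditional <= 1.0
            assert gate.conditional * survivors == pytest.approx(gate.marginal, abs=1e-12)
            if gate.terminates:
                survivors -= gate.marginal


class TestBuildPregnancyModule:
    def test_inventory_counts(self, default_module):
        counts = gs.count_elements(default_module)
        assert counts["conditions"] == 16
        assert counts["encounters"] == 16
        assert counts["death"] == 1

    def test_module_is_valid(self, default_module):
        assert gs.validate_module(default_module) == []

    def test_ectopic_code_on_its_onset_state(self, default_module):
        onset = default_module.states["Ectopic_Onset"]
        assert onset.kind is StateKind.CONDITION_ONSET
        assert onset.codes[0].system == "SNOMED-CT"
        assert onset.codes[0].code == "34801009"

    def test_death_state_default_probability_zero(self, default_module):
        gate = default_module.states["Maternal_Death_Gate"]
        branch = {b.target: b.probability for b in gate.transition.branches}
        assert branch["Maternal_Death"] == 0.0

    def test_missing_required_gate_rejected(self):
        gates = [g for g in gs.default_gates() if g.condition.code != PPH.code]
        with pytest.raises(ValueError, match="47821001"):
            gs.build_pregnancy_module(gates)

    def test_marginal_override_changes_gate_probability(self):
        gates = gate_map(gs.default_gates(overrides={PROM.code: 0.05}))
        assert gates[PROM.code].conditional == pytest.approx(
            0.05 / (8069 / 10637), abs=1e-12
        )


class TestDefaultReferenceRanges:
    def test_fourteen_entries(self):
        assert len(gs.default_reference_ranges()) == 14

    @pytest.mark.parametrize(
        "code,lower,upper",
        [
            ("47821001", 4.0, 6.0),   # postpartum hemorrhage
            ("367494004", 7.2, 7.2),  # preterm newborn (point value)
            ("44223004", 8.0, 10.0),  # premature rupture of membranes
        ],
    )
    def test_known_ranges(self, code, lower, upper):
        ranges = {r.condition.code: r for r in gs.default_reference_ranges()}
        assert (ranges[code].lower, ranges[code].upper) == (lower, upper)

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError):
            gs.ReferenceRange(ECTOPIC, 5.0, 2.0)


class TestCohortProperties:
    def test_no_male_pregnancies(self, small_cohort):
        assert all(p.sex == "F" for p in small_cohort)

    def test_prom_marginal_zero_means_zero_events(self, small_cohort):
        assert all(
            PROM.code not in {c.code for e in p.events for c in e.codes}
            for p in small_cohort
        )

    def test_gestational_weeks_monotone_while_pregnant(self, small_cohort):
        for person in small_cohort:
            weeks = [
                e.gestational_week for e in person.events if e.gestational_week is not None
            ]
            assert weeks == sorted(weeks)
            dates = [e.date for e in person.events]
            assert dates == sorted(dates)

    def test_trimester_placement(self, small_cohort):
        first_tri = {ECTOPIC.code, ABORTION_T1.code}
        third_tri = {HEMORRHAGE.code, "36813001", "415105001"}
        for person in small_cohort:
            for event in person.events:
                if event.kind is not StateKind.CONDITION_ONSET:
                    continue
                code = event.codes[0].code
                if code in first_tri:
                    assert event.gestational_week <= 13
                elif code == ABORTION_T2.code:
                    assert 14 <= event.gestational_week <= 26
                elif code in third_tri:
                    assert event.gestational_week >= 27

    def test_pph_only_after_delivery(self, small_cohort):
        for person in small_cohort:
            states = [e.state for e in person.events]
            if "Postpartum_Hemorrhage_Onset" in states:
                pph_at = states.index("Postpartum_Hemorrhage_Onset")
                delivery_at = states.index("Delivery_Admission")
                assert delivery_at < pph_at
                assert person.events[pph_at].date >= person.events[delivery_at].date

    def test_losses_skip_delivery(self, small_cohort):
        for person in small_cohort:
            states = {e.state for e in person.events}
            if "Loss_Management_Visit" in states:
                assert "Delivery_Admission" not in states
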