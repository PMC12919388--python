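import datetime
import json
import math

import numpy as np
import pytest

from gestasynth import (
    ModuleDefinition,
    ModuleLoadError,
    ModuleValidationError,
    NonTerminationError,
    StateKind,
    count_elements,
    load_module,
    simulate_person,
    validate_module,
)
from gestasynth.demographics import PersonRecord


def make_person(pid=1):
    return PersonRecord(
        person_id=pid,
        sex="F",
        birthdate=datetime.date(1995, 3, 1),
        municipality="05001",
        department="05",
    )


def toy_module_dict():
    return {
        "name": "toy",
        "initial": "Start",
        "states": {
            "Start": {
                "kind": "Initial",
                "transition": {"mode": "Direct", "branches": [{"target": "Onset"}]},
            },
            "Onset": {
                "kind": "ConditionOnset",
                "codes": [{"system": "SNOMED-CT", "code": "111", "display": "toy condition"}],
                "transition": {"mode": "Direct", "branches": [{"target": "End"}]},
            },
            "End": {"kind": "Terminal"},
        },
    }


def write_module(tmp_path, payload):
    path = tmp_path / "module.json"
    path.write_text(json.dumps(payload))
    return path


class TestLoadModule:
    def test_minimal_module_loads(self, tmp_path):
        module = load_module(write_module(tmp_path, toy_module_dict()))
        assert isinstance(module, ModuleDefinition)
        assert len(module.states) == 3

    def test_malformed_json_is_a_parse_error(self, tmp_path):
        path = tmp_path / "module.json"
        path.write_text("{not json")
        with pytest.raises(ModuleLoadError, match="parse"):
            load_module(path)

    def test_excess_probability_mass_names_the_state(self, tmp_path):
        payload = toy_module_dict()
        payload["states"]["Start"]["transition"] = {
            "mode": "Distributed",
            "branches": [
                {"target": "Onset", "probability": 0.6},
                {"target": "End", "probability": 0.5},
            ],
        }
        with pytest.raises(ModuleValidationError) as err:
            load_module(write_module(tmp_path, payload))
        assert any(i.kind == "probability_mass" and i.state == "Start" for i in err.value.issues)

    def test_dangling_transition_target(self, tmp_path):
        payload = toy_module_dict()
        payload["states"]["Onset"]["transition"]["branches"][0]["target"] = "Nowhere"
        with pytest.raises(ModuleValidationError) as err:
            load_module(write_module(tmp_path, payload))
        assert any(i.kind == "unknown_target" for i in err.value.issues)


class TestValidateModule:
    def test_valid_module_has_no_issues(self):
        module = ModuleDefinition.model_validate(toy_module_dict())
        assert validate_module(module) == []

    def test_unreachable_state_is_reported(self):
        payload = toy_module_dict()
        payload["states"]["X"] = {
            "kind": "Simple",
            "transition": {"mode": "Direct", "branches": [{"target": "End"}]},
        }
        module = ModuleDefinition.model_validate(payload)
        issues = validate_module(module)
        assert [(i.kind, i.state) for i in issues] == [("unreachable", "X")]

    def test_exact_half_half_mass_is_fine(self):
        payload = toy_module_dict()
        payload["states"]["Start"]["transition"] = {
            "mode": "Distributed",
            "branches": [
                {"target": "Onset", "probability": 0.5},
                {"target": "End", "probability": 0.5},
            ],
        }
        module = ModuleDefinition.model_validate(payload)
        assert validate_module(module) == []

    @pytest.mark.parametrize(
        "mutate,kind",
        [
            (lambda p: p["states"]["Onset"].update(codes=[]), "missing_codes"),
            (lambda p: p["states"]["End"].update(
                transition={"mode": "Direct", "branches": [{"target": "Start"}]}
            ), "terminal_transition"),
            (lambda p: p["states"]["Onset"].pop("transition"), "missing_transition"),
            (lambda p: p.update(initial="Onset"), "bad_initial_kind"),
        ],
    )
    def test_structural_violations_become_issues(self, mutate, kind):
        payload = toy_module_dict()
        mutate(payload)
        module = ModuleDefinition.model_validate(payload)
        assert kind in {i.kind for i in validate_module(module)}

    def test_conditional_requires_catch_all(self):
        payload = toy_module_dict()
        payload["states"]["Start"]["transition"] = {
            "mode": "Conditional",
            "branches": [
                {"target": "Onset", "predicate": {"attribute": "x", "value": 1}},
            ],
        }
        module = ModuleDefinition.model_validate(payload)
        assert "missing_catch_all" in {i.kind for i in validate_module(module)}


class TestCountElements:
    def test_toy_module_total(self):
        module = ModuleDefinition.model_validate(toy_module_dict())
        counts = count_elements(module)
        assert counts["states"] == 3
        assert counts["conditions"] == 1
        assert counts["encounters"] == 0


class TestSimulatePerson:
    def test_single_condition_event(self):
        module = ModuleDefinition.model_validate(toy_module_dict())
        events = simulate_person(module, make_person(), np.random.default_rng(0))
        assert len(events) == 1
        assert events[0].kind is StateKind.CONDITION_ONSET
        assert events[0].codes[0].code == "111"

    def test_degenerate_distribution_always_taken(self):
        payload = toy_module_dict()
        payload["states"]["Start"]["transition"] = {
            "mode": "Distributed",
            "branches": [
                {"target": "Onset", "probability": 1.0},
                {"target": "End", "probability": 0.0},
            ],
        }
        module = ModuleDefinition.model_validate(payload)
        for seed in range(20):
            events = simulate_person(module, make_person(), np.random.default_rng(seed))
            assert [e.state for e in events] == ["Onset"]

    def test_same_seed_gives_identical_logs(self, default_module):
        person = make_person()
        first = simulate_person(default_module, person, np.random.default_rng([3, 14]))
        second = simulate_person(default_module, person, np.random.default_rng([3, 14]))
        assert first == second

    def test_cycle_exhausts_step_budget(self):
        payload = {
            "name": "loop",
            "initial": "Start",
            "states": {
                "Start": {"kind": "Initial",
                          "transition": {"mode": "Direct", "branches": [{"target": "A"}]}},
                "A": {"kind": "Simple",
                      "transition": {"mode": "Direct", "branches": [{"target": "B"}]}},
                "B": {"kind": "Simple",
                      "transition": {"mode": "Direct", "branches": [{"target": "A"}]}},
                "End": {"kind": "Terminal"},
            },
        }
        module = ModuleDefinition.model_validate(payload)
        with pytest.raises(NonTerminationError):
            simulate_person(module, make_person(), np.random.default_rng(0), max_steps=500)

    def test_branch_frequencies_converge(self):
        """Empirical branch frequency of a (p, 1-p) split stays within
        4 standard errors of p over 100,000 walks."""
        p = 0.3
        payload = {
            "name": "split",
            "initial": "Start",
            "states": {
                "Start": {"kind": "Initial",
                          "transition": {"mode": "Distributed", "branches": [
                              {"target": "A", "probability": p},
                              {"target": "B", "probability": 1 - p},
                          ]}},
                "A": {"kind": "ConditionOnset",
                      "codes": [{"system": "SNOMED-CT", "code": "A1"}],
                      "transition": {"mode": "Direct", "branches": [{"target": "End"}]}},
                "B": {"kind": "ConditionOnset",
                      "codes": [{"system": "SNOMED-CT", "code": "B1"}],
                      "transition": {"mode": "Direct", "branches": [{"target": "End"}]}},
                "End": {"kind": "Terminal"},
            },
        }
        module = ModuleDefinition.model_validate(payload)
        n = 100_000
        rng = np.random.default_rng(2024)
        person = make_person()
        hits = sum(
            simulate_person(module, person, rng, start_date=datetime.date(2023, 1, 2))[0].codes[0].code == "A1"
            for _ in range(n)
        )
        se = math.sqrt(p * (1 - p) / n)
        assert abs(hits / n - p) < 4 * se
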