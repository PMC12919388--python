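"""Generic clinical state-machine engine.

A *module* is a named directed graph of typed clinical states with
probabilistic transitions.  Each synthetic person is walked from the
``Initial`` state to a ``Terminal`` state under an explicit seeded random
stream; clinical states (encounters, condition onsets/ends, procedures,
observations, death) each append one event to the person's event log,
``Delay`` states advance a week-granularity clock.

The engine is deliberately domain-agnostic: everything obstetric lives in
:mod:`gestasynth.pregnancy`, which builds a module definition and hands it
to this engine.
"""

from __future__ import annotations

import bisect
import datetime
import itertools
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Literal, Optional, Sequence, Union

import numpy as np
from pydantic import BaseModel, ConfigDict, Field, PrivateAttr, ValidationError

__all__ = [
    "StateKind",
    "CodedConcept",
    "Predicate",
    "Branch",
    "Transition",
    "State",
    "ModuleDefinition",
    "Issue",
    "Event",
    "ModuleLoadError",
    "ModuleValidationError",
    "NonTerminationError",
    "load_module",
    "validate_module",
    "count_elements",
    "simulate_person",
    "module_json_schema",
    "events_to_dicts",
]

#: Probability mass of a Distributed transition must sum to 1 within this.
MASS_TOLERANCE = 1e-9

#: Default cap on state visits per walk; guards against authoring cycles.
DEFAULT_STEP_BUDGET = 10_000

#: Calendar anchor for simulated pregnancies (a Monday).
REFERENCE_DATE = datetime.date(2023, 1, 2)


class StateKind(str, Enum):
    INITIAL = "Initial"
    SIMPLE = "Simple"
    DELAY = "Delay"
    ENCOUNTER = "Encounter"
    CONDITION_ONSET = "ConditionOnset"
    CONDITION_END = "ConditionEnd"
    PROCEDURE = "Procedure"
    OBSERVATION = "Observation"
    SET_ATTRIBUTE = "SetAttribute"
    DEATH = "Death"
    TERMINAL = "Terminal"


#: Kinds that must carry at least one coded concept and emit one event each.
CODED_KINDS = frozenset(
    {
        StateKind.ENCOUNTER,
        StateKind.CONDITION_ONSET,
        StateKind.CONDITION_END,
        StateKind.PROCEDURE,
        StateKind.OBSERVATION,
    }
)

#: Kinds that append an event to the log (coded kinds plus Death).
EVENT_KINDS = CODED_KINDS | {StateKind.DEATH}


class CodedConcept(BaseModel):
    """A clinical code from one of the three vocabularies the pathway uses:
    SNOMED-CT for conditions/findings, CUPS (Colombia's unified procedure
    classification) for procedures, CIE-10 (Spanish ICD-10) for diagnoses."""

    model_config = ConfigDict(frozen=True)

    system: Literal["SNOMED-CT", "CIE-10", "CUPS"]
    code: str = Field(min_length=1)
    display: str = ""


class Predicate(BaseModel):
    """Attribute test attached to a Conditional branch."""

    model_config = ConfigDict(frozen=True)

    attribute: str = Field(min_length=1)
    operator: Literal["==", "!="] = "=="
    value: Optional[Union[bool, int, float, str]] = None

    def holds(self, attributes: dict[str, Any]) -> bool:
        current = attributes.get(self.attribute)
        if self.operator == "==":
            return current == self.value
        return current != self.value


class Branch(BaseModel):
    model_config = ConfigDict(frozen=True)

    target: str = Field(min_length=1)
    probability: Optional[float] = Field(default=None, ge=0.0, le=1.0)
    predicate: Optional[Predicate] = None


class Transition(BaseModel):
    """Outgoing edge set of a state.

    - ``Direct``: exactly one branch, taken unconditionally.
    - ``Distributed``: branch drawn at random; probabilities must sum to 1.
    - ``Conditional``: branches evaluated in declared order against the
      person's attributes; the last branch must be a catch-all (no
      predicate) so a walk can never dead-end.
    """

    model_config = ConfigDict(frozen=True)

    mode: Literal["Direct", "Distributed", "Conditional"]
    branches: tuple[Branch, ...] = Field(min_length=1)


class State(BaseModel):
    model_config = ConfigDict(frozen=True)

    kind: StateKind
    codes: tuple[CodedConcept, ...] = ()
    weeks: Optional[int] = Field(default=None, ge=0)
    attribute: Optional[str] = None
    value: Optional[Union[bool, int, float, str]] = None
    transition: Optional[Transition] = None


class ModuleDefinition(BaseModel):
    """Named directed graph of typed clinical states.

    Structural shape is enforced here (pydantic); graph-level invariants —
    exactly one Initial, no dangling targets, probability mass, catch-alls,
    reachability — are audited by :func:`validate_module` so that a
    malformed in-memory module can still be inspected and reported on.
    """

    name: str = Field(min_length=1)
    schema_version: str = "1.0"
    initial: str = Field(min_length=1)
    states: dict[str, State]

    _compiled: Any = PrivateAttr(default=None)


@dataclass(frozen=True)
class Issue:
    """One validation finding; issues are data, not exceptions."""

    kind: str
    state: Optional[str]
    detail: str

    def to_dict(self) -> dict[str, Any]:
        return {"kind": self.kind, "state": self.state, "detail": self.detail}

    def __str__(self) -> str:  # plain-text emission
        where = f" [{self.state}]" if self.state else ""
        return f"{self.kind}{where}: {self.detail}"


@dataclass(frozen=True, slots=True)
class Event:
    """One entry of a person's clinical trajectory."""

    date: datetime.date
    gestational_week: Optional[int]
    state: str
    kind: StateKind
    codes: tuple[CodedConcept, ...]


class ModuleLoadError(ValueError):
    """Raised when a module file cannot be parsed or fails shape checks."""


class ModuleValidationError(ValueError):
    """Raised by :func:`load_module` when graph invariants are violated.

    Carries every violation found, not just the first."""

    def __init__(self, issues: Sequence[Issue]):
        self.issues = list(issues)
        super().__init__(
            "module validation failed:\n" + "\n".join(str(i) for i in self.issues)
        )


class NonTerminationError(RuntimeError):
    """A walk exceeded its step budget without reaching a Terminal state."""


# ---------------------------------------------------------------------------
# Loading and validation


def load_module(path: Union[str, Path]) -> ModuleDefinition:
    """Load a module definition from a JSON file and fully validate it.

    Raises :class:`ModuleLoadError` on malformed JSON or shape violations
    and :class:`ModuleValidationError` (listing every violation) on graph
    invariant failures.
    """
    path = Path(path)
    try:
        raw = json.loads(path.read_text(encoding="utf-8"))
    except (OSError, json.JSONDecodeError) as exc:
        raise ModuleLoadError(f"cannot parse module file {path}: {exc}") from exc
    try:
        module = ModuleDefinition.model_validate(raw)
    except ValidationError as exc:
        raise ModuleLoadError(f"module file {path} has invalid shape:\n{exc}") from exc
    issues = validate_module(module)
    if issues:
        raise ModuleValidationError(issues)
    return module


def validate_module(module: ModuleDefinition) -> list[Issue]:
    """Audit graph-level invariants; returns an empty list iff all hold.

    Checks: exactly one Initial state and it is ``module.initial``; every
    transition target exists; Direct transitions have exactly one certain
    branch; Distributed probability mass sums to 1 within ``MASS_TOLERANCE``;
    Conditional transitions end in a catch-all; coded kinds carry codes;
    Delay states carry a non-negative week count; Terminal states carry no
    transition and every other state carries one; all states are reachable
    from the initial state and at least one Terminal state is reachable.
    """
    issues: list[Issue] = []
    states = module.states

    initials = [n for n, s in states.items() if s.kind is StateKind.INITIAL]
    if module.initial not in states:
        issues.append(
            Issue("missing_initial", None, f"initial state {module.initial!r} not defined")
        )
    elif states[module.initial].kind is not StateKind.INITIAL:
        issues.append(
            Issue("bad_initial_kind", module.initial, "initial state must have kind Initial")
        )
    if len(initials) != 1:
        issues.append(
            Issue(
                "initial_count",
                None,
                f"exactly one Initial state required, found {len(initials)}: {initials}",
            )
        )

    for name, state in states.items():
        if state.kind in CODED_KINDS and not state.codes:
            issues.append(
                Issue("missing_codes", name, f"{state.kind.value} state carries no codes")
            )
        if state.kind is StateKind.DELAY and state.weeks is None:
            issues.append(Issue("missing_delay", name, "Delay state has no week count"))
        if state.kind is StateKind.SET_ATTRIBUTE and not state.attribute:
            issues.append(
                Issue("missing_attribute", name, "SetAttribute state names no attribute")
            )
        if state.kind is StateKind.TERMINAL:
            if state.transition is not None:
                issues.append(
                    Issue("terminal_transition", name, "Terminal state carries a transition")
                )
            continue
        if state.transition is None:
            issues.append(Issue("missing_transition", name, "non-terminal state has no transition"))
            continue
        issues.extend(_check_transition(name, state.transition, states))

    reachable = _reachable_states(module)
    for name in states:
        if name not in reachable:
            issues.append(Issue("unreachable", name, "state unreachable from initial"))
    if not any(states[n].kind is StateKind.TERMINAL for n in reachable):
        issues.append(
            Issue("no_terminal", None, "no Terminal state reachable from initial")
        )
    return issues


def _check_transition(
    name: str, transition: Transition, states: dict[str, State]
) -> Iterable[Issue]:
    issues: list[Issue] = []
    for branch in transition.branches:
        if branch.target not in states:
            issues.append(
                Issue("unknown_target", name, f"transition targets unknown state {branch.target!r}")
            )
    if transition.mode == "Direct":
        if len(transition.branches) != 1:
            issues.append(
                Issue("direct_branches", name, "Direct transition must have exactly one branch")
            )
        else:
            p = transition.branches[0].probability
            if p is not None and p != 1.0:
                issues.append(
                    Issue("direct_probability", name, f"Direct branch probability must be 1, got {p}")
                )
    elif transition.mode == "Distributed":
        probs = [b.probability for b in transition.branches]
        if any(p is None for p in probs):
            issues.append(
                Issue("missing_probability", name, "Distributed branch lacks a probability")
            )
        else:
            mass = float(sum(probs))  # type: ignore[arg-type]
            if abs(mass - 1.0) > MASS_TOLERANCE:
                issues.append(
                    Issue(
                        "probability_mass",
                        name,
                        f"Distributed probabilities sum to {mass!r}, expected 1",
                    )
                )
    else:  # Conditional
        if transition.branches[-1].predicate is not None:
            issues.append(
                Issue(
                    "missing_catch_all",
                    name,
                    "Conditional transition must end in a catch-all branch",
                )
            )
        for branch in transition.branches[:-1]:
            if branch.predicate is None:
                issues.append(
                    Issue(
                        "unordered_catch_all",
                        name,
                        "only the last Conditional branch may omit a predicate",
                    )
                )
    return issues


def _reachable_states(module: ModuleDefinition) -> set[str]:
    seen: set[str] = set()
    stack = [module.initial]
    while stack:
        name = stack.pop()
        if name in seen or name not in module.states:
            continue
        seen.add(name)
        transition = module.states[name].transition
        if transition is not None:
            stack.extend(b.target for b in transition.branches)
    return seen


def count_elements(module: ModuleDefinition) -> dict[str, int]:
    """Inventory of the module: total states and per-kind counts.

    ``conditions`` counts *distinct* codes across ConditionOnset states, the
    convention used when comparing care-pathway models; the other entries
    count states.
    """
    condition_codes = {
        c.code
        for s in module.states.values()
        if s.kind is StateKind.CONDITION_ONSET
        for c in s.codes
    }
    by_kind = {
        "states": len(module.states),
        "encounters": sum(
            1 for s in module.states.values() if s.kind is StateKind.ENCOUNTER
        ),
        "procedures": sum(
            1 for s in module.states.values() if s.kind is StateKind.PROCEDURE
        ),
        "conditions": len(condition_codes),
        "death": sum(1 for s in module.states.values() if s.kind is StateKind.DEATH),
    }
    return by_kind


# ---------------------------------------------------------------------------
# Simulation


@dataclass(slots=True)
class _Node:
    # Flattened state for the inner loop; pydantic attribute access is too
    # slow for ~10^6 visits per cohort.
    kind: StateKind
    codes: tuple[CodedConcept, ...]
    weeks: int
    attribute: Optional[str]
    value: Any
    mode: Optional[str]
    targets: tuple[str, ...]
    cumprobs: tuple[float, ...]
    predicates: tuple[Optional[Predicate], ...]


def _compile(module: ModuleDefinition) -> dict[str, _Node]:
    compiled = module._compiled
    if compiled is not None:
        return compiled
    nodes: dict[str, _Node] = {}
    for name, state in module.states.items():
        transition = state.transition
        if transition is None:
            mode, targets, cumprobs, predicates = None, (), (), ()
        else:
            mode = transition.mode
            targets = tuple(b.target for b in transition.branches)
            predicates = tuple(b.predicate for b in transition.branches)
            if mode == "Distributed":
                cumprobs = tuple(
                    itertools.accumulate(b.probability for b in transition.branches)
                )
            else:
                cumprobs = ()
        nodes[name] = _Node(
            kind=state.kind,
            codes=state.codes,
            weeks=state.weeks or 0,
            attribute=state.attribute,
            value=state.value,
            mode=mode,
            targets=targets,
            cumprobs=cumprobs,
            predicates=predicates,
        )
    module._compiled = nodes
    return nodes


def simulate_person(
    module: ModuleDefinition,
    person: Any,
    rng: np.random.Generator,
    *,
    start_date: Optional[datetime.date] = None,
    max_steps: int = DEFAULT_STEP_BUDGET,
) -> list[Event]:
    """Walk one person through the module; returns the ordered event log.

    The walk is a pure function of ``(module, person, seed)``: all
    randomness comes from ``rng``.  If ``start_date`` is None the pathway
    entry date is drawn uniformly over the 52 weeks following
    ``REFERENCE_DATE`` so event dates vary across a cohort.  Gestational
    weeks are recorded on events while the walk's ``pregnant`` attribute is
    truthy.  Raises :class:`NonTerminationError` after ``max_steps`` state
    visits.
    """
    nodes = _compile(module)
    if start_date is None:
        start_date = REFERENCE_DATE + datetime.timedelta(weeks=int(rng.integers(0, 52)))

    attributes: dict[str, Any] = {}
    events: list[Event] = []
    week = 0
    current = module.initial
    for _ in range(max_steps):
        node = nodes[current]
        kind = node.kind
        if kind is StateKind.DELAY:
            week += node.weeks
        elif kind is StateKind.SET_ATTRIBUTE:
            attributes[node.attribute] = node.value
        elif kind in EVENT_KINDS:
            events.append(
                Event(
                    date=start_date + datetime.timedelta(weeks=week),
                    gestational_week=week if attributes.get("pregnant") else None,
                    state=current,
                    kind=kind,
                    codes=node.codes,
                )
            )
        elif kind is StateKind.TERMINAL:
            return events

        mode = node.mode
        if mode == "Direct":
            current = node.targets[0]
        elif mode == "Distributed":
            # last branch absorbs any floating-point shortfall in the mass
            idx = bisect.bisect_right(node.cumprobs, rng.random())
            current = node.targets[min(idx, len(node.targets) - 1)]
        else:  # Conditional
            for target, predicate in zip(node.targets, node.predicates):
                if predicate is None or predicate.holds(attributes):
                    current = target
                    break
    raise NonTerminationError(
        f"walk through module {module.name!r} exceeded {max_steps} steps at state {current!r}"
    )


# ---------------------------------------------------------------------------
# Serialization helpers


def module_json_schema() -> dict[str, Any]:
    """JSON Schema (2020-12) for module definition files."""
    return ModuleDefinition.model_json_schema()


def module_to_json(module: ModuleDefinition, path: Union[str, Path]) -> None:
    """Write a module definition as a UTF-8 JSON file round-trippable by
    :func:`load_module`."""
    Path(path).write_text(
        module.model_dump_json(indent=2, exclude_none=True), encoding="utf-8"
    )


def events_to_dicts(events: Sequence[Event]) -> list[dict[str, Any]]:
    """JSON-friendly rendering of an event log."""
    return [
        {
            "date": e.date.isoformat(),
            "gestational_week": e.gestational_week,
            "state": e.state,
            "kind": e.kind.value,
            "codes": [
                {"system": c.system, "code": c.code, "display": c.display}
                for c in e.codes
            ],
        }
        for e in events
    ]


def issues_to_json(issues: Sequence[Issue]) -> str:
    return json.dumps([i.to_dict() for i in issues], indent=2)
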