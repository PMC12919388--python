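import pytest
from hypothesis import settings

import gestasynth as gs
from gestasynth.cli import generate_cohort

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

#: Seed of the reference runs used across the suite (the CLI default).
COHORT_SEED = 7


@pytest.fixture(scope="session")
def default_module():
    return gs.default_pregnancy_module()


@pytest.fixture(scope="session")
def weights():
    return gs.default_weights()


@pytest.fixture(scope="session")
def concept_map():
    return gs.default_concept_map()


@pytest.fixture(scope="session")
def small_cohort(default_module, weights):
    """1,200-woman cohort for structural and ETL checks."""
    return generate_cohort(1200, 11, weights, default_module)


@pytest.fixture(scope="session")
def full_cohort(default_module, weights):
    """Reference-size cohort (10,637 women) for frequency recovery."""
    return generate_cohort(gs.DEFAULT_COHORT_SIZE, COHORT_SEED, weights, default_module)


@pytest.fixture(scope="session")
def small_bundle(small_cohort, concept_map):
    return gs.export_cdm(small_cohort, concept_map)


def enumerate_marginals(gates):
    """Independent oracle: exhaustive enumeration of gate-outcome sequences.

    Walks every hit/miss combination of the gate sequence, tracking the
    probability mass of each path and whether the pathway is still alive
    (terminating gates end it), and accumulates each gate's realized
    marginal.  Exponential in the number of gates — only for small specs.
    """
    totals = {id(g): 0.0 for g in gates}

    def recurse(i, prob, alive):
        if i == len(gates) or prob == 0.0:
            return
        gate = gates[i]
        if not alive:
            recurse(i + 1, prob, False)
            return
        hit = prob * gate.conditional
        totals[id(gate)] += hit
        recurse(i + 1, hit, not gate.terminates)
        recurse(i + 1, prob - hit, True)

    recurse(0, 1.0, True)
    return {g.condition.code: totals[id(g)] for g in gates}
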