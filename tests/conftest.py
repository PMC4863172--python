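import numpy as np
import pytest

import poreflux as pf

# Published (k0 ns^-1, d) per transition for the two reference pores.
TABLE1 = {
    "ANT-5": {
        ("S2", "S2+1"): (8.5, -0.079),
        ("S2+1", "S3"): (2230.6, 0.009),
        ("S3", "S1+2"): (49.1, 0.074),
        ("S1+2", "S2"): (93.0, 0.073),
    },
    "ANT-6": {
        ("S3", "S3+1"): (73.9, 0.014),
        ("S3+1", "S2+2"): (6.1, 0.100),
        ("S2+2", "S1+3"): (234.3, 0.023),
        ("S1+3", "S3"): (7151.1, -0.025),
    },
}

MASTER_SEED = 1


def make_cycle(labels, rates, ds=None, name="test", perm=None, backward=None):
    """Unidirectional cycle over ``labels`` with given forward rates."""
    ds = ds if ds is not None else [0.0] * len(labels)
    n = len(labels)
    transitions = tuple(
        pf.Transition(
            from_state=labels[i],
            to_state=labels[(i + 1) % n],
            rate=pf.VoltageRate(k0=rates[i], d=ds[i]),
        )
        for i in range(n)
    )
    return pf.PermeationCycle(
        name=name,
        states=tuple(pf.kinetic_model.state_from_label(s) for s in labels),
        transitions=transitions,
        permeation_transition=perm or (labels[-1], labels[0]),
        backward_transitions=tuple(backward or ()),
    )


def random_unidirectional_cycle(rng):
    n = int(rng.integers(3, 7))
    labels = [f"A{i}" for i in range(n)]
    rates = 10.0 ** rng.uniform(-2, 3, size=n)
    ds = rng.uniform(-0.1, 0.1, size=n)
    return make_cycle(labels, rates, ds)


@pytest.fixture(scope="session")
def ant5():
    return pf.builtin_cycle("ANT-5")


@pytest.fixture(scope="session")
def ant6():
    return pf.builtin_cycle("ANT-6")


@pytest.fixture(scope="session")
def pipelines(ant5, ant6):
    """Full-design pipeline runs (100 x 10 ns at 5 voltages) for both pores."""
    return {
        "ANT-5": pf.run_pipeline(ant5, seed=MASTER_SEED),
        "ANT-6": pf.run_pipeline(ant6, seed=MASTER_SEED),
    }
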