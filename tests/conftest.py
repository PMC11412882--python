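"""Shared fixtures and a random-network generator for property tests."""

from __future__ import annotations

import numpy as np
import pytest

from nnsim.model import ElementDecl, InOutEvent, Model, Reaction, SimulationConfig

_FAMILIES = ("standard", "mono", "decay_zero", "linear_dec", "linear_inc")


def random_model(rng: np.random.Generator, *, end_time: int = 40) -> Model:
    """A small random, valid reaction network for property tests."""
    n_el = int(rng.integers(2, 7))
    names = [f"E{i}" for i in range(n_el)]
    if rng.random() < 0.3:  # exercise exotic chemical labels
        names[0] = "H(O2)*+-_0"
    elements = [
        ElementDecl(
            name,
            int(rng.integers(0, 60)),
            color="tab:blue" if rng.random() < 0.2 else None,
        )
        for name in names
    ]
    N = float(rng.choice([10.0, 100.0, 1000.0]))
    reactions = []
    for j in range(int(rng.integers(1, 6))):
        family = str(rng.choice(_FAMILIES))

        def pairs(lo: int, hi: int) -> list[tuple[int, str]]:
            k = min(int(rng.integers(lo, hi + 1)), n_el)
            chosen = rng.choice(names, size=k, replace=False)
            return [(int(rng.integers(1, 4)), str(name)) for name in chosen]

        if family == "standard":
            reactants, products = pairs(2, 3), pairs(0, 2)
        elif family == "mono":
            reactants, products = pairs(1, 1), pairs(1, 2)
        elif family in ("decay_zero", "linear_dec"):
            reactants, products = pairs(1, 1), []
        else:  # linear_inc
            reactants, products = [], pairs(1, 1)
        rate = float(rng.choice([0.0, 0.01, 0.1, 1.0, 5.0, 50.0]))
        reactions.append(Reaction(f"r{j}", family, reactants, products, rate, N))

    inout = []
    if rng.random() < 0.4:
        inout.append(
            InOutEvent(
                int(rng.integers(0, end_time + 1)),
                str(rng.choice(names)),
                int(rng.integers(-30, 31)),
            )
        )
    plots = [("line", [names[0]])] if rng.random() < 0.5 else []
    return Model(
        elements=elements,
        reactions=reactions,
        config=SimulationConfig(0, end_time, 1000, 1000, int(rng.choice([1, 5]))),
        inout=inout,
        plots=plots,
    )


def reconstruct_step_deltas(model: Model, trajectory) -> None:
    """Independent bookkeeping check for a csv_interval=1 trajectory.

    Asserts that between consecutive recorded steps every element changed by
    exactly the stoichiometric multiples of the logged draws plus scheduled
    in/out flows (with outflow floored at zero, checked conservatively).
    """
    assert model.config.csv_interval == 1 and trajectory.events is not None
    by_step: dict[int, list] = {}
    for ev in trajectory.events:
        by_step.setdefault(ev.step, []).append(ev)
    rxn_by_label = {r.label: r for r in model.reactions}
    inout_by_step: dict[int, list] = {}
    for ev in model.inout:
        inout_by_step.setdefault(ev.time, []).append(ev)

    for i, t in enumerate(trajectory.times[:-1]):
        state = {name: trajectory.counts[name][i] for name in trajectory.order}
        for ev in inout_by_step.get(t, []):
            state[ev.element] = max(state[ev.element] + ev.delta, 0)
        for ev in by_step.get(t, []):
            rxn = rxn_by_label[ev.label]
            assert 0 <= ev.successes <= ev.trials
            for q, name in rxn.reactants:
                state[name] -= q * ev.successes
            for r, name in rxn.products:
                state[name] += r * ev.successes
        for name in trajectory.order:
            assert state[name] == trajectory.counts[name][i + 1], (
                f"bookkeeping mismatch for {name} at step {t}"
            )


@pytest.fixture
def michaelis_menten_model():
    from nnsim.examples import build_michaelis_menten

    return build_michaelis_menten()
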