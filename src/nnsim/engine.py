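"""The natural-number update algorithm.

Each simulation step, every reaction performs one binomial draw
``B ~ Binomial(n, p)`` where the trial count ``n`` is set by the limiting
reactant and the success probability ``p`` by the rate constant and the
non-limiting reactant counts.  Counts then change by exact stoichiometric
multiples of ``B``, so every count stays a non-negative integer at every
step — no clamping is ever needed.

Per family:

* ``standard`` (>= 2 reactants): ``n = floor(min_i X_i/q_i)``; the reactant
  attaining the minimum ratio is *limiting* (first in declaration order on
  ties) and ``p`` is the product over the remaining reactants of
  ``(k*X_i/(q_i*N)) / (1 + k*X_i/(q_i*N))``.
* ``mono`` / ``decay_zero``: ``n = floor(X/a)``, ``p = k/(1+k)``.
* ``linear_dec`` / ``linear_inc``: at most one trial per step with
  ``p = k/(1+k)``; ``linear_dec`` only fires while ``X >= a``.

Reactions are applied sequentially in declaration order within a step, each
seeing the state already updated by earlier reactions; scheduled in/out
events apply at the start of their step, before any reaction.  A single
seeded generator is consumed in this deterministic order, so an identical
seed and model reproduce a bit-identical trajectory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable

import numpy as np

from .model import InOutEvent, Model, ModelError, Reaction, initial_state, validate_model

__all__ = [
    "EXACT_TRIALS_MAX",
    "ReactionEvent",
    "Trajectory",
    "compute_trials",
    "compute_prob",
    "sample_binomial",
    "apply_reaction",
    "apply_inout",
    "run",
]

#: Largest trial count handed to the exact platform binomial sampler (the
#: int64 range of numpy's generator).  Beyond this the draw falls back to a
#: moment-matched normal approximation, rounded and clamped to ``[0, n]``.
EXACT_TRIALS_MAX = 2**63 - 1

# Evaluate the standard-family probability product in log space once the
# number of non-limiting factors grows beyond this, to avoid underflow.
_LOG_SPACE_FACTORS = 10


@dataclass(slots=True)
class ReactionEvent:
    """Record of one reaction's binomial draw in one step."""

    step: int
    label: str
    trials: int
    prob: float
    successes: int


@dataclass
class Trajectory:
    """Time-indexed element counts plus an optional per-reaction event log."""

    times: list[int]
    counts: dict[str, list[int]]
    order: list[str]
    time_unit: str = "Steps"
    events: list[ReactionEvent] | None = None

    def final_counts(self) -> dict[str, int]:
        return {name: series[-1] for name, series in self.counts.items()}

    def series(self, name: str) -> list[int]:
        return self.counts[name]

    def to_dataframe(self):
        """Counts as a pandas DataFrame indexed by time (column ``time``)."""
        import pandas as pd

        data = {"time": self.times}
        data.update({name: self.counts[name] for name in self.order})
        return pd.DataFrame(data)


def _trials_and_limiting(reaction: Reaction, state: dict[str, int]) -> tuple[int, int]:
    """Trial count and index of the limiting reactant (exact rational argmin)."""
    best_i = 0
    best_x, best_q = None, None
    for i, (q, name) in enumerate(reaction.reactants):
        if name not in state:  # model-integrity error
            raise KeyError(f"element {name!r} missing from state")
        x = state[name]
        # compare x/q < best_x/best_q exactly with integer cross products
        if best_x is None or x * best_q < best_x * q:
            best_i, best_x, best_q = i, x, q
    return best_x // best_q, best_i


def compute_trials(reaction: Reaction, state: dict[str, int]) -> int:
    """Binomial trial count ``n`` for one reaction against the current state.

    For the linear families the returned value is already capped at one trial
    per step (``linear_dec`` yields 0 when its reactant has fewer than ``a``
    copies, so counts can never go negative).
    """
    fam = reaction.family
    if fam == "linear_inc":
        raise ValueError("linear_inc has no reactants; trials are fixed at 1")
    if fam == "standard":
        return _trials_and_limiting(reaction, state)[0]
    a, name = reaction.reactants[0]
    x = state[name]
    if fam in ("mono", "decay_zero"):
        return x // a
    if fam == "linear_dec":
        return 1 if x >= a else 0
    raise ValueError(f"unknown family {fam!r}")


def compute_prob(reaction: Reaction, state: dict[str, int], limiting_index: int = 0) -> float:
    """Per-trial success probability ``p``.

    ``limiting_index`` (standard family only) is the reactant excluded from
    the probability product; single-reactant and linear families use
    ``k/(1+k)`` regardless.
    """
    k = reaction.rate_constant
    N = reaction.normalization
    if not N > 0:
        raise ValueError("normalization parameter must be > 0")
    if reaction.family != "standard":
        return k / (1.0 + k)
    factors = []
    for i, (q, name) in enumerate(reaction.reactants):
        if i == limiting_index:
            continue
        u = k * state[name] / (q * N)
        if u == 0.0:
            return 0.0
        factors.append(u)
    if len(factors) <= _LOG_SPACE_FACTORS:
        p = 1.0
        for u in factors:
            p *= u / (1.0 + u)
        return p
    log_p = sum(math.log(u) - math.log1p(u) for u in factors)
    return math.exp(log_p)


def sample_binomial(trials: int, prob: float, rng: np.random.Generator) -> int:
    """One binomial draw with arbitrary-precision trial counts.

    Exact (platform sampler) for ``trials <= EXACT_TRIALS_MAX``; above that,
    a moment-matched normal draw ``round(n*p + z*sqrt(n*p*(1-p)))`` clamped
    to ``[0, trials]``.
    """
    if not 0.0 <= prob <= 1.0:
        raise ValueError(f"probability {prob} outside [0, 1]")
    if trials < 0:
        raise ValueError("trials must be >= 0")
    if trials == 0 or prob == 0.0:
        return 0
    if prob == 1.0:
        return trials
    if trials <= EXACT_TRIALS_MAX:
        return int(rng.binomial(trials, prob))
    mean = trials * prob
    sd = math.sqrt(trials * prob * (1.0 - prob))
    draw = round(mean + rng.standard_normal() * sd)
    return min(max(draw, 0), trials)


def apply_reaction(
    reaction: Reaction, state: dict[str, int], step: int, rng: np.random.Generator
) -> ReactionEvent:
    """Draw one reaction and mutate ``state`` by exact stoichiometric multiples."""
    fam = reaction.family
    if fam == "linear_inc":
        n, limiting = 1, 0
    elif fam == "standard":
        n, limiting = _trials_and_limiting(reaction, state)
    else:
        n, limiting = compute_trials(reaction, state), 0
    if n == 0:
        return ReactionEvent(step, reaction.label, 0, 0.0, 0)
    p = compute_prob(reaction, state, limiting)
    b = sample_binomial(n, p, rng) if p > 0.0 else 0
    if b:
        for q, name in reaction.reactants:
            state[name] -= q * b
        for r, name in reaction.products:
            state[name] += r * b
    return ReactionEvent(step, reaction.label, n, p, b)


def apply_inout(
    events: Iterable[InOutEvent], step: int, state: dict[str, int]
) -> dict[str, int]:
    """Apply every in/out event scheduled at ``step``; outflow floors at zero."""
    for ev in events:
        if ev.time == step:
            state[ev.element] = max(state[ev.element] + ev.delta, 0)
    return state


def run(
    model: Model,
    *,
    seed: int | None = None,
    capture_events: bool | None = None,
    progress: Callable[[int, dict[str, int]], None] | None = None,
) -> Trajectory:
    """Simulate the model over its configured time window.

    ``seed`` and ``capture_events`` override the corresponding config fields
    when given.  ``progress``, if provided, is called with ``(step, state)``
    every ``console_interval`` steps.  Counts are recorded at ``start_time``
    and thereafter at every ``csv_interval`` boundary.
    """
    diags = validate_model(model)
    if diags:
        raise ModelError(diags)
    cfg = model.config
    if seed is None:
        seed = cfg.seed
    if capture_events is None:
        capture_events = cfg.capture_events
    rng = np.random.default_rng(seed)
    state = initial_state(model)
    order = model.element_names()

    inout_by_time: dict[int, list[InOutEvent]] = {}
    for ev in model.inout:
        inout_by_time.setdefault(ev.time, []).append(ev)

    times = [cfg.start_time]
    counts: dict[str, list[int]] = {name: [state[name]] for name in order}
    events: list[ReactionEvent] | None = [] if capture_events else None

    start, end = cfg.start_time, cfg.end_time
    for t in range(start, end):
        todo = inout_by_time.get(t)
        if todo:
            apply_inout(todo, t, state)
        for rxn in model.reactions:
            ev = apply_reaction(rxn, state, t, rng)
            if events is not None:
                events.append(ev)
        if (t + 1 - start) % cfg.csv_interval == 0:
            times.append(t + 1)
            for name in order:
                counts[name].append(state[name])
        if progress is not None and (t + 1 - start) % cfg.console_interval == 0:
            progress(t + 1, state)

    return Trajectory(times, counts, order, cfg.time_unit, events)
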