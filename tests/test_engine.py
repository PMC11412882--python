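"""The per-step binomial update: trials, probabilities, draws, trajectories."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nnsim.engine import (
    apply_inout,
    apply_reaction,
    compute_prob,
    compute_trials,
    run,
    sample_binomial,
    _trials_and_limiting,
)
from nnsim.model import (
    ElementDecl,
    InOutEvent,
    Model,
    ModelError,
    Reaction,
    SimulationConfig,
)
from conftest import random_model, reconstruct_step_deltas


def _rxn(family, reactants, products, k=1.0, N=100.0, label="r"):
    return Reaction(label, family, reactants, products, k, N)


class TestTrials:
    @pytest.mark.parametrize(
        "reactants, state, expected",
        [
            ([(1, "A"), (1, "B")], {"A": 10, "B": 4}, 4),
            ([(2, "A"), (1, "B")], {"A": 10, "B": 4}, 4),
            ([(2, "A"), (1, "B")], {"A": 7, "B": 4}, 3),
        ],
    )
    def test_standard_minimum_ratio(self, reactants, state, expected):
        assert compute_trials(_rxn("standard", reactants, []), state) == expected

    def test_mono_floor(self):
        assert compute_trials(_rxn("mono", [(3, "X")], [(1, "Y")]), {"X": 10}) == 3

    @pytest.mark.parametrize("x, expected", [(0, 0), (1, 0), (2, 1), (9, 1)])
    def test_linear_dec_caps_at_one_trial(self, x, expected):
        assert compute_trials(_rxn("linear_dec", [(2, "X")], []), {"X": x}) == expected

    def test_limiting_reactant_uses_exact_ratio_not_floor(self):
        # A/2 = 4.5 < B/1 = 5 even though both floor to 4
        rxn = _rxn("standard", [(2, "A"), (1, "B")], [])
        assert _trials_and_limiting(rxn, {"A": 9, "B": 5}) == (4, 0)

    def test_limiting_tie_break_takes_first_declared(self):
        rxn = _rxn("standard", [(1, "A"), (2, "B")], [])
        assert _trials_and_limiting(rxn, {"A": 4, "B": 8}) == (4, 0)

    def test_missing_element_is_integrity_error(self):
        with pytest.raises(KeyError):
            compute_trials(_rxn("standard", [(1, "A"), (1, "Z")], []), {"A": 1})


class TestProb:
    def test_mono_zero_rate_gives_zero(self):
        assert compute_prob(_rxn("mono", [(1, "X")], [(1, "Y")], k=0.0), {"X": 5}) == 0.0

    def test_single_reactant_families_use_k_over_1_plus_k(self):
        rxn = _rxn("decay_zero", [(1, "X")], [], k=3.0)
        assert compute_prob(rxn, {"X": 5}) == pytest.approx(0.75)

    def test_standard_single_factor(self):
        # A limiting; k=1, B = N, q_B = 1  ->  p = 1/(1+1)
        rxn = _rxn("standard", [(1, "A"), (1, "B")], [(1, "C")], k=1.0, N=100.0)
        assert compute_prob(rxn, {"A": 2, "B": 100}, 0) == pytest.approx(0.5)

    def test_standard_three_reactant_product(self):
        # A limiting; k=2, B = C = N  ->  (2/3) * (2/3) = 4/9
        rxn = _rxn(
            "standard", [(1, "A"), (1, "B"), (1, "C")], [(1, "D")], k=2.0, N=50.0
        )
        assert compute_prob(rxn, {"A": 1, "B": 50, "C": 50}, 0) == pytest.approx(4 / 9)

    def test_many_reactant_log_space_path_matches_direct_product(self):
        names = [f"X{i}" for i in range(14)]
        rxn = _rxn("standard", [(1, n) for n in names], [], k=1.0, N=10.0)
        state = {n: 5 for n in names}
        expected = (0.5 / 1.5) ** 13
        assert compute_prob(rxn, state, 0) == pytest.approx(expected, rel=1e-12)

    def test_nonpositive_normalization_rejected(self):
        rxn = _rxn("standard", [(1, "A"), (1, "B")], [], N=0.0)
        with pytest.raises(ValueError):
            compute_prob(rxn, {"A": 1, "B": 1}, 0)


class TestSampleBinomial:
    def test_degenerate_probabilities(self):
        rng = np.random.default_rng(0)
        assert sample_binomial(10**30, 0.0, rng) == 0
        assert sample_binomial(7, 1.0, rng) == 7
        assert sample_binomial(0, 0.3, rng) == 0

    def test_out_of_range_probability_rejected(self):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError):
            sample_binomial(5, 1.5, rng)

    def test_exact_sampler_moments(self):
        # mean of 1e6 draws of Binomial(100, 0.3) within 3 standard errors
        rng = np.random.default_rng(1234)
        m = 10**6
        sample = [sample_binomial(100, 0.3, rng) for _ in range(m)]
        assert abs(np.mean(sample) - 30.0) < 3 * math.sqrt(21 / m)

    def test_normal_approximation_branch_moments_and_bounds(self):
        rng = np.random.default_rng(7)
        n = 2**63 + 10**10  # beyond the exact sampler's integer range
        p = 1e-15
        draws = [sample_binomial(n, p, rng) for _ in range(4000)]
        assert all(0 <= d <= n for d in draws)
        mean = n * p
        se = math.sqrt(n * p * (1 - p) / len(draws))
        assert abs(np.mean(draws) - mean) < 4 * se

    @given(st.integers(0, 10**6), st.floats(0, 1, allow_nan=False))
    @settings(derandomize=True, max_examples=60, deadline=None)
    def test_draw_always_within_bounds(self, n, p):
        b = sample_binomial(n, p, np.random.default_rng(0))
        assert 0 <= b <= n


class TestApplyReaction:
    def test_exhausted_reactant_is_a_no_op(self):
        state = {"A": 0, "B": 9, "C": 1}
        rxn = _rxn("standard", [(1, "A"), (1, "B")], [(1, "C")])
        ev = apply_reaction(rxn, state, 3, np.random.default_rng(0))
        assert ev.trials == 0 and ev.successes == 0
        assert state == {"A": 0, "B": 9, "C": 1}

    def test_certain_success_converts_everything(self):
        # k so large that p rounds to 1: all 5 copies fire
        state = {"X": 5, "Y": 0, "Z": 0}
        rxn = _rxn("mono", [(1, "X")], [(1, "Y"), (1, "Z")], k=1e18)
        ev = apply_reaction(rxn, state, 0, np.random.default_rng(0))
        assert ev.successes == 5
        assert state == {"X": 0, "Y": 5, "Z": 5}

    def test_stoichiometric_multiples_are_exact(self):
        state = {"A": 100, "B": 100, "C": 0}
        rxn = _rxn("standard", [(2, "A"), (1, "B")], [(3, "C")], k=5.0, N=10.0)
        ev = apply_reaction(rxn, state, 0, np.random.default_rng(42))
        assert state["A"] == 100 - 2 * ev.successes
        assert state["B"] == 100 - ev.successes
        assert state["C"] == 3 * ev.successes

    @pytest.mark.parametrize("x", [0, 1, 2, 3])
    def test_linear_dec_never_goes_negative(self, x):
        rxn = _rxn("linear_dec", [(2, "X")], [], k=1e18)  # p ~ 1
        for seed in range(5):
            state = {"X": x}
            apply_reaction(rxn, state, 0, np.random.default_rng(seed))
            assert state["X"] == (x - 2 if x >= 2 else x)

    def test_linear_inc_adds_fixed_quantum(self):
        state = {"Y": 0}
        rxn = _rxn("linear_inc", [], [(3, "Y")], k=1e18)
        ev = apply_reaction(rxn, state, 0, np.random.default_rng(0))
        assert ev.trials == 1 and state["Y"] == 3


class TestInOut:
    def test_scheduled_inflow_is_exact(self):
        state = {"Sx": 2}
        apply_inout([InOutEvent(10_000, "Sx", 1000)], 10_000, state)
        assert state["Sx"] == 1002

    def test_outflow_floors_at_zero(self):
        state = {"A": 3}
        apply_inout([InOutEvent(5, "A", -10)], 5, state)
        assert state["A"] == 0

    def test_event_at_other_step_is_no_op(self):
        state = {"A": 3}
        apply_inout([InOutEvent(5, "A", -10)], 4, state)
        assert state["A"] == 3


class TestRun:
    def _ab_model(self, **cfg):
        return Model(
            elements=[ElementDecl("A", 1000), ElementDecl("B", 1000),
                      ElementDecl("C", 0)],
            reactions=[_rxn("standard", [(1, "A"), (1, "B")], [(1, "C")], k=1e18,
                            N=1000.0, label="bind")],
            config=SimulationConfig(0, 50, csv_interval=1, **cfg),
        )

    def test_no_reactions_means_constant_counts(self):
        model = Model(
            elements=[ElementDecl("A", 7)],
            reactions=[],
            config=SimulationConfig(0, 20, csv_interval=1),
        )
        traj = run(model, seed=0)
        assert traj.counts["A"] == [7] * 21

    def test_stoichiometric_conservation(self):
        traj = run(self._ab_model(), seed=1)
        for a, c in zip(traj.counts["A"], traj.counts["C"]):
            assert a + c == 1000

    def test_invalid_model_refuses_to_run(self):
        model = self._ab_model()
        model.reactions[0].reactants.append((1, "Q"))
        with pytest.raises(ModelError):
            run(model)

    def test_identical_seed_gives_identical_trajectory(self):
        model = random_model(np.random.default_rng(5))
        assert run(model, seed=99) == run(model, seed=99)

    def test_different_seeds_differ(self):
        model = self._ab_model()
        model.reactions[0].rate_constant = 1.0  # stochastic regime, p < 1
        assert run(model, seed=1) != run(model, seed=2)

    def test_config_seed_is_used_when_no_override_given(self):
        model = self._ab_model(seed=123)
        assert run(model) == run(model, seed=123)

    def test_recording_respects_csv_interval(self):
        model = self._ab_model()
        model.config.csv_interval = 7
        traj = run(model, seed=0)
        assert traj.times == [0, 7, 14, 21, 28, 35, 42, 49]

    def test_inout_applies_before_reactions_in_its_step(self):
        # A is empty until an inflow at t=10; with p ~ 1 the whole inflow
        # reacts within the same step.
        model = self._ab_model()
        model.elements[0].initial_count = 0
        model.inout.append(InOutEvent(10, "A", 500))
        traj = run(model, seed=3)
        assert traj.counts["C"][10] == 0 and traj.counts["C"][11] == 500

    def test_progress_callback_fires_at_console_interval(self):
        model = self._ab_model()
        model.config.console_interval = 10
        seen = []
        run(model, seed=0, progress=lambda t, state: seen.append(t))
        assert seen == [10, 20, 30, 40, 50]

    @given(st.integers(0, 10_000))
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_random_networks_stay_natural_and_balanced(self, seed):
        rng = np.random.default_rng(seed)
        model = random_model(rng)
        model.config.csv_interval = 1
        traj = run(model, seed=seed, capture_events=True)
        for series in traj.counts.values():
            assert all(isinstance(v, int) and v >= 0 for v in series)
        reconstruct_step_deltas(model, traj)
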