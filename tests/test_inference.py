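"""ABC distance, chain transitions, posterior bookkeeping."""

import math

import numpy as np
import pandas as pd
import pytest

from ratchetabc.inference import (
    ABCConfig,
    ChainState,
    ObservedDataset,
    PosteriorTrace,
    PriorSpec,
    _propose_parameter,
    _restricted_network,
    abc_step,
    combine_traces,
    credible_set,
    distance,
    posterior_model_probabilities,
    posterior_predictive,
    run_chains,
)
from ratchetabc.kinetics import MODEL_SPACE, PARAMETER_NAMES, Condition, ParameterSet


def make_dataset(velocities, forces=None):
    v = np.asarray(velocities, dtype=float)
    forces = forces if forces is not None else np.zeros(v.size)
    conds = tuple(Condition.make(f, 100.0) for f in forces)
    return ObservedDataset(conds, v)


def make_trace(models, seed=0, n=400):
    rng = np.random.default_rng(seed)
    rows = {
        "chain": np.zeros(n, dtype=int),
        "iteration": np.arange(n),
        "model": rng.choice(models, size=n),
    }
    for name in PARAMETER_NAMES:
        rows[name] = rng.normal(10, 1, size=n)
    rows["delta1"] = rng.uniform(0.1, 3.3, size=n)
    rows["X2"] = rng.uniform(0, 1, size=n)
    return PosteriorTrace(pd.DataFrame(rows), 0, 1, seed)


class TestPriors:
    def test_table_defaults(self):
        pr = PriorSpec.for_enzyme("rnap")
        assert pr.parameters["k_cat"] == ("lognormal", 3.454, 0.587)
        assert pr.parameters["dG_t1"] == ("normal", 0.0, 1.55)
        t7 = PriorSpec.for_enzyme("t7")
        assert t7.parameters["k_cat"] == ("lognormal", 4.585, 0.457)
        assert t7.parameters["dG_tdag"] == ("normal", 2.5, 1.36)
        assert t7.parameters["K_D"] == pr.parameters["K_D"]

    def test_unknown_enzyme(self):
        with pytest.raises(ValueError):
            PriorSpec.for_enzyme("pol-III")

    def test_support(self):
        pr = PriorSpec.for_enzyme("rnap")
        assert not pr.in_support("delta1", -0.1)
        assert not pr.in_support("k_cat", -5.0)
        assert pr.in_support("dG_t1", -100.0)

    def test_sampling_matches_density_location(self, rng):
        pr = PriorSpec.for_enzyme("rnap")
        x = np.array([pr.sample("k_cat", rng) for _ in range(4000)])
        assert np.median(x) == pytest.approx(math.exp(3.454), rel=0.1)


class TestDistance:
    def test_identical_is_zero(self):
        ds = make_dataset([10.0, 20.0])
        assert distance([10.0, 20.0], ds) == 0.0

    def test_single_row_value(self):
        ds = make_dataset([10.0])
        assert distance([12.0], ds) == pytest.approx(0.4)

    def test_matched_row_leaves_distance_unchanged(self):
        d1 = distance([12.0], make_dataset([10.0]))
        d2 = distance([12.0, 7.0], make_dataset([10.0, 7.0]))
        assert d1 == d2

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            distance([1.0], make_dataset([1.0, 2.0]))

    def test_dataset_validation(self):
        with pytest.raises(ValueError):
            make_dataset([10.0, -1.0])
        with pytest.raises(ValueError):
            make_dataset([])


class TestAbcStep:
    def setup_method(self):
        self.prior = PriorSpec.for_enzyme("rnap")
        self.network = _restricted_network(None)
        self.config = ABCConfig(epsilon=0.4)
        self.dataset = make_dataset([10.0])

    def start_state(self, model=12):
        rng = np.random.default_rng(0)
        return ChainState(model, self.prior.sample_parameter_set(rng), 0.0)

    def test_boundary_distance_is_accepted(self):
        # simulated velocity 12 vs observed 10 gives X^2 = 0.4 = epsilon
        # exactly; the inclusive rule must admit such proposals
        simulate = lambda model, params, seed: np.array([12.0])
        state = self.start_state()
        accepted = 0
        for seed in range(60):
            rng = np.random.default_rng(seed)
            new = abc_step(state, self.prior, self.network, self.dataset,
                           simulate, self.config, rng)
            accepted += new.distance == 0.4 and new is not state
        assert accepted > 0

    def test_epsilon_monotonicity_pointwise(self):
        # with an identical proposal stream, any proposal accepted at a
        # smaller threshold is accepted at a larger one
        simulate = lambda model, params, seed: np.array(
            [10.0 + np.random.default_rng(seed).uniform(0, 5)]
        )
        state = self.start_state()
        for seed in range(40):
            results = {}
            for eps in (0.3, 1.5):
                rng = np.random.default_rng(seed)
                cfg = ABCConfig(epsilon=eps)
                new = abc_step(state, self.prior, self.network, self.dataset,
                               simulate, cfg, rng)
                results[eps] = new.iteration == state.iteration + 1 and (
                    new.distance != state.distance or new.params != state.params
                )
            assert not (results[0.3] and not results[1.5])

    def test_simulator_failure_counts_as_rejection(self):
        def simulate(model, params, seed):
            raise RuntimeError("stalled")

        state = self.start_state()
        new = abc_step(state, self.prior, self.network, self.dataset,
                       simulate, self.config, np.random.default_rng(3))
        assert new.model_index == state.model_index
        assert new.params == state.params
        assert new.iteration == state.iteration + 1

    def test_delta1_reflection_stays_in_support(self):
        pr = self.prior
        params = ParameterSet(k_cat=30, K_D=20, delta1=0.05)
        rng = np.random.default_rng(8)
        cfg = ABCConfig()
        for _ in range(300):
            params = _propose_parameter(params, "delta1", pr, rng, cfg)
            assert 0.0 <= params.delta1 <= 3.4

    def test_model_moves_follow_network_edges(self):
        state = self.start_state(model=1)
        cfg = ABCConfig(model_move_probability=1.0)
        seen = set()
        for seed in range(200):
            rng = np.random.default_rng(seed)
            new = abc_step(state, self.prior, self.network, None, None, cfg, rng)
            if new.model_index != 1:
                seen.add(new.model_index)
        assert seen <= set(self.network[1])
        assert len(seen) >= 2


class TestRunChains:
    def test_determinism(self):
        pr = PriorSpec.for_enzyme("rnap")
        cfg = ABCConfig(chain_length=500, n_chains=2, seed=9)
        a = run_chains(pr, None, None, cfg)
        b = run_chains(pr, None, None, cfg)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.samples, tb.samples)

    def test_burn_in_and_thinning(self):
        pr = PriorSpec.for_enzyme("rnap")
        cfg = ABCConfig(chain_length=1000, n_chains=1, seed=2,
                        burn_in_fraction=0.2, target_retained=100)
        (trace,) = run_chains(pr, None, None, cfg)
        assert trace.burn_in == 200
        assert trace.samples["iteration"].min() >= 200
        assert len(trace) <= 110

    def test_restricted_model_space(self):
        pr = PriorSpec.for_enzyme("rnap")
        cfg = ABCConfig(chain_length=800, n_chains=1, seed=3,
                        allowed_models=(4, 11))
        (trace,) = run_chains(pr, None, None, cfg)
        assert set(trace.samples["model"].unique()) <= {4, 11}

    def test_prior_model_frequencies_with_infinite_epsilon(self):
        # acceptance governed by the prior alone: translocation-equilibrium
        # models appear about twice as often as the others
        pr = PriorSpec.for_enzyme("rnap")
        cfg = ABCConfig(chain_length=12_000, n_chains=2, seed=7)
        traces = run_chains(pr, None, None, cfg)
        probs = posterior_model_probabilities(traces)
        p_eq = np.mean([probs[m] for m in (1, 2, 4, 5)])
        p_kin = np.mean([probs[m] for m in (3, 6, 7, 8, 9, 10, 11, 12)])
        assert p_eq / p_kin == pytest.approx(2.0, rel=0.25)


class TestPosteriorSummaries:
    def test_single_model_trace(self):
        trace = make_trace([5])
        probs = posterior_model_probabilities([trace])
        assert probs == {5: 1.0}
        assert credible_set([trace]) == [5]

    def test_two_model_credible_set(self):
        rng = np.random.default_rng(0)
        models = rng.choice([11, 12], p=[0.81, 0.19], size=2000)
        trace = make_trace([1], n=2000)
        trace.samples["model"] = models
        cset = credible_set([trace])
        assert set(cset) == {11, 12}

    def test_probabilities_sum_to_one(self):
        trace = make_trace([1, 4, 11], seed=3)
        probs = posterior_model_probabilities([trace])
        assert sum(probs.values()) == pytest.approx(1.0)

    def test_empty_trace_rejected(self):
        empty = PosteriorTrace(pd.DataFrame(columns=["model"]), 0, 1, 0)
        with pytest.raises(ValueError):
            posterior_model_probabilities([empty])

    def test_chain_order_invariance(self):
        t1 = make_trace([4, 11], seed=1)
        t2 = make_trace([11, 12], seed=2)
        assert posterior_model_probabilities([t1, t2]) == pytest.approx(
            posterior_model_probabilities([t2, t1])
        )


class TestPosteriorPredictive:
    def test_degenerate_trace_gives_identical_parameters(self):
        trace = make_trace([7], n=50)
        for name in PARAMETER_NAMES:
            trace.samples[name] = 5.0
        trace.samples["delta1"] = 1.7
        captured = []

        def simulate(model, params, seed):
            captured.append(params)
            return np.array([1.0, 2.0])

        conds = (Condition.make(0, 10.0), Condition.make(5, 10.0))
        df = posterior_predictive([trace], conds, simulate, n_draws=8,
                                  rng=np.random.default_rng(0))
        assert len(df) == 16
        assert len(set(captured)) == 1
        assert df["model"].unique().tolist() == [7]

    def test_draw_count_protocol(self):
        trace = make_trace([11], n=100)
        simulate = lambda model, params, seed: np.array([1.0])
        df = posterior_predictive([trace], (Condition.make(0, 1.0),),
                                  simulate, n_draws=30,
                                  rng=np.random.default_rng(1))
        assert df["draw"].nunique() == 30
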