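"""MCMC-ABC joint sampling of the model indicator and kinetic parameters.

The likelihood is replaced by simulation: a proposed state (M, Theta) is
accepted only if the Pearson-type distance between simulated and observed
mean velocities satisfies X^2 <= epsilon (inclusive) *and* a
Metropolis-Hastings draw on the prior and proposal densities accepts
(Marjoram-style ABC-MCMC; the distance is recomputed from fresh simulations
at every proposal, and rejected proposals repeat the current state).

All six parameters are always carried in the chain state; a model move along
an edge of the single-parameter-difference network draws any newly activated
parameter from its prior, so no further dimension matching is needed (the
prior proposal density cancels the prior ratio of the activated entries).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .constants import DELTA_ANGSTROM
from .energetics import EnergyLandscape, TemplateSequence
from .kinetics import (
    MODEL_PRIOR,
    MODEL_SPACE,
    PARAMETER_NAMES,
    Condition,
    ModelSpec,
    ParameterSet,
    model_network,
)
from .simulator import SimulationConfig, build_site_rates, estimate_mean_velocity

LOG_SPACE_PARAMETERS = ("k_cat", "K_D", "k_bind")


# ---------------------------------------------------------------------------
# priors


@dataclass(frozen=True)
class PriorSpec:
    """Per-parameter prior descriptors and model-indicator masses.

    Descriptors are ("lognormal", mu, sigma), ("normal", mu, sigma) or
    ("uniform", lo, hi); lognormal priors are parameterised in log space.
    """

    parameters: Mapping[str, tuple[str, float, float]]
    model_masses: Mapping[int, float] = field(
        default_factory=lambda: dict(MODEL_PRIOR)
    )

    @classmethod
    def for_enzyme(cls, enzyme: str) -> "PriorSpec":
        """Default priors per enzyme profile: 'rnap' / 'polii' (shared) or 't7'."""
        enzyme = enzyme.lower()
        if enzyme in ("rnap", "polii", "pol2", "pol_ii"):
            k_cat = ("lognormal", 3.454, 0.587)
            dG_t1 = ("normal", 0.0, 1.55)
            dG_tdag = ("normal", 5.5, 0.97)
        elif enzyme in ("t7", "t7pol", "t7_pol"):
            k_cat = ("lognormal", 4.585, 0.457)
            dG_t1 = ("normal", -3.3, 1.55)
            dG_tdag = ("normal", 2.5, 1.36)
        else:
            raise ValueError(f"unknown enzyme profile {enzyme!r}")
        return cls(
            {
                "k_cat": k_cat,
                "K_D": ("lognormal", 1.844, 1.762),
                "k_bind": ("lognormal", -1.498, 1.585),
                "dG_t1": dG_t1,
                "delta1": ("uniform", 0.0, DELTA_ANGSTROM),
                "dG_tdag": dG_tdag,
            }
        )

    def sample(self, name: str, rng: np.random.Generator) -> float:
        kind, a, b = self.parameters[name]
        if kind == "lognormal":
            return float(np.exp(rng.normal(a, b)))
        if kind == "normal":
            return float(rng.normal(a, b))
        if kind == "uniform":
            return float(rng.uniform(a, b))
        raise ValueError(f"unknown prior kind {kind!r}")

    def log_density_sampling_space(self, name: str, value: float) -> float:
        """Log prior density in the space the random walk moves in (log space
        for lognormal parameters, natural space otherwise); -inf outside
        support."""
        kind, a, b = self.parameters[name]
        if kind == "lognormal":
            if value <= 0:
                return -math.inf
            z = (math.log(value) - a) / b
            return -0.5 * z * z - math.log(b)
        if kind == "normal":
            z = (value - a) / b
            return -0.5 * z * z - math.log(b)
        if kind == "uniform":
            return 0.0 if a <= value <= b else -math.inf
        raise ValueError(kind)

    def in_support(self, name: str, value: float) -> bool:
        return self.log_density_sampling_space(name, value) > -math.inf

    def sample_parameter_set(self, rng: np.random.Generator) -> ParameterSet:
        return ParameterSet(
            **{n: self.sample(n, rng) for n in PARAMETER_NAMES}
        )

    def interval(self, name: str, mass: float = 0.95) -> tuple[float, float]:
        """Central prior interval (analytic)."""
        from scipy import stats

        kind, a, b = self.parameters[name]
        z = stats.norm.ppf(0.5 + mass / 2)
        if kind == "lognormal":
            return math.exp(a - z * b), math.exp(a + z * b)
        if kind == "normal":
            return a - z * b, a + z * b
        lo, hi = a, b
        half = mass / 2 * (hi - lo)
        mid = (lo + hi) / 2
        return mid - half, mid + half


# ---------------------------------------------------------------------------
# observed data


@dataclass(frozen=True)
class ObservedDataset:
    """Rows of (condition, observed mean pause-free velocity in bp/s)."""

    conditions: tuple[Condition, ...]
    velocities: np.ndarray
    enzyme: str = "rnap"

    def __post_init__(self) -> None:
        v = np.asarray(self.velocities, dtype=float)
        object.__setattr__(self, "velocities", v)
        if len(self.conditions) != v.size or v.size == 0:
            raise ValueError("need one velocity per condition, at least one row")
        if np.any(v <= 0):
            raise ValueError("observed velocities must be positive")

    def __len__(self) -> int:
        return len(self.conditions)


def distance(simulated: Sequence[float], observed: ObservedDataset) -> float:
    """Pearson-type distance X^2 = sum_i (v_sim,i - v_obs,i)^2 / v_obs,i."""
    sim = np.asarray(simulated, dtype=float)
    if sim.shape != observed.velocities.shape:
        raise ValueError(
            f"{sim.size} simulated velocities for {len(observed)} observed rows"
        )
    return float(np.sum((sim - observed.velocities) ** 2 / observed.velocities))


class DatasetSimulator:
    """Simulates the observed dataset's conditions for a candidate state.

    Wraps the template, landscape and replicate count; per-condition mean
    velocities use the replicate-level average, matching the observable.
    """

    def __init__(
        self,
        sequence: TemplateSequence,
        landscape: EnergyLandscape,
        conditions: Sequence[Condition],
        replicates: int = 2,
        max_events: Optional[int] = None,
    ) -> None:
        self.sequence = sequence
        self.landscape = landscape
        self.conditions = list(conditions)
        self.replicates = replicates
        # cap on futile-cycle events per replicate: parameter draws that
        # cannot finish within it are treated as rejected proposals
        self.max_events = (
            max_events if max_events is not None
            else 200 * landscape.n_sites + 10_000
        )

    def __call__(
        self, model: ModelSpec, params: ParameterSet, seed: int
    ) -> np.ndarray:
        seeds = np.random.SeedSequence(seed).generate_state(
            len(self.conditions), np.uint32
        )
        out = np.empty(len(self.conditions))
        for j, cond in enumerate(self.conditions):
            rates = build_site_rates(
                self.sequence, model, params, cond, self.landscape
            )
            out[j] = estimate_mean_velocity(
                self.sequence, model, params, cond, self.landscape,
                SimulationConfig(self.replicates, int(seeds[j]), self.max_events),
                _rates=rates,
            )
        return out


# ---------------------------------------------------------------------------
# chain machinery


@dataclass
class ChainState:
    model_index: int
    params: ParameterSet
    distance: float
    iteration: int = 0


@dataclass(frozen=True)
class ABCConfig:
    epsilon: float = math.inf
    chain_length: int = 10_000
    n_chains: int = 2
    replicates: int = 2
    burn_in_fraction: float = 0.1
    target_retained: int = 1000
    model_move_probability: float = 0.25
    #: random-walk step sd as a fraction of each prior's own scale
    step_fraction: float = 0.5
    seed: int = 0
    allowed_models: Optional[tuple[int, ...]] = None
    init_attempts: int = 2000


@dataclass(frozen=True)
class PosteriorTrace:
    """Post burn-in, thinned chain states as a tidy DataFrame."""

    samples: pd.DataFrame
    burn_in: int
    thin: int
    seed: int

    def __len__(self) -> int:
        return len(self.samples)


def _restricted_network(allowed: Optional[Sequence[int]]) -> dict[int, tuple[int, ...]]:
    net = model_network()
    if allowed is None:
        return net
    allowed_set = set(allowed)
    sub = {
        i: tuple(j for j in net[i] if j in allowed_set)
        for i in net
        if i in allowed_set
    }
    return sub


def _log_prior_state(
    prior: PriorSpec, model: ModelSpec, params: ParameterSet
) -> float:
    total = math.log(prior.model_masses[model.index])
    for name in model.active_parameters:
        total += prior.log_density_sampling_space(name, getattr(params, name))
    return total


def _propose_parameter(
    params: ParameterSet,
    name: str,
    prior: PriorSpec,
    rng: np.random.Generator,
    config: ABCConfig,
) -> ParameterSet:
    """Symmetric Gaussian random walk in the parameter's sampling space, with
    the step sd scaled to the prior's own spread (uniform priors use the
    uniform sd and reflect at the bounds)."""
    kind, a, b = prior.parameters[name]
    value = getattr(params, name)
    if kind == "lognormal":
        new = value * math.exp(rng.normal(0.0, config.step_fraction * b))
    elif kind == "uniform":
        sd = config.step_fraction * (b - a) / math.sqrt(12.0)
        new = value + rng.normal(0.0, sd)
        period = 2 * (b - a)
        new = a + (new - a) % period
        if new > b:
            new = 2 * b - new
    else:
        new = value + rng.normal(0.0, config.step_fraction * b)
    return replace(params, **{name: new})


def abc_step(
    current: ChainState,
    prior: PriorSpec,
    network: Mapping[int, tuple[int, ...]],
    dataset: Optional[ObservedDataset],
    simulate: Optional[Callable[[ModelSpec, ParameterSet, int], np.ndarray]],
    config: ABCConfig,
    rng: np.random.Generator,
) -> ChainState:
    """One ABC-MCMC transition; returns the new state (possibly a repeat of
    the current one).

    The MH uniform draw is evaluated before simulating, so prior/proposal
    rejections never pay the simulation cost; with ``dataset`` (or
    ``simulate``) absent the acceptance is governed by the prior alone.
    """
    model = MODEL_SPACE[current.model_index]
    log_ratio = 0.0
    if rng.random() < config.model_move_probability and network[model.index]:
        new_index = int(rng.choice(network[model.index]))
        new_model = MODEL_SPACE[new_index]
        new_params = current.params
        for name in set(new_model.active_parameters) - set(model.active_parameters):
            new_params = replace(new_params, **{name: prior.sample(name, rng)})
        # prior densities of activated/deactivated entries cancel against the
        # prior-draw proposal; only model masses and neighbour counts remain
        log_ratio = (
            math.log(prior.model_masses[new_index])
            - math.log(prior.model_masses[model.index])
            + math.log(len(network[model.index]))
            - math.log(len(network[new_index]))
        )
    else:
        new_model = model
        name = model.active_parameters[
            int(rng.integers(len(model.active_parameters)))
        ]
        new_params = _propose_parameter(current.params, name, prior, rng, config)
        log_ratio = prior.log_density_sampling_space(
            name, getattr(new_params, name)
        ) - prior.log_density_sampling_space(name, getattr(current.params, name))

    repeat = replace(current, iteration=current.iteration + 1)
    if not all(
        prior.in_support(n, getattr(new_params, n))
        for n in new_model.active_parameters
    ):
        return repeat
    if log_ratio < 0 and math.log(rng.random()) > log_ratio:
        return repeat

    if simulate is None or dataset is None:
        x2 = 0.0
    else:
        try:
            sim = simulate(new_model, new_params, int(rng.integers(2**31 - 1)))
        except RuntimeError:
            return repeat
        x2 = distance(sim, dataset)
        if x2 > config.epsilon:  # acceptance region is inclusive: X^2 <= eps
            return repeat
    return ChainState(new_model.index, new_params, x2, current.iteration + 1)


def _initial_state(
    prior: PriorSpec,
    models: Sequence[int],
    dataset: Optional[ObservedDataset],
    simulate,
    config: ABCConfig,
    rng: np.random.Generator,
) -> ChainState:
    """Draw (M, Theta) from the prior until the distance ball is hit (or the
    attempt budget is spent, in which case the best draw found is used)."""
    masses = np.array([prior.model_masses[m] for m in models], dtype=float)
    masses /= masses.sum()
    best: Optional[ChainState] = None
    attempts = config.init_attempts if simulate is not None and dataset is not None else 1
    for _ in range(attempts):
        m = int(rng.choice(models, p=masses))
        params = prior.sample_parameter_set(rng)
        if simulate is None or dataset is None:
            return ChainState(m, params, 0.0)
        try:
            sim = simulate(MODEL_SPACE[m], params, int(rng.integers(2**31 - 1)))
        except RuntimeError:
            continue
        x2 = distance(sim, dataset)
        if best is None or x2 < best.distance:
            best = ChainState(m, params, x2)
        if x2 <= config.epsilon:
            return ChainState(m, params, x2)
    if best is None:
        raise RuntimeError("no viable initial state found from the prior")
    return best


def run_chains(
    prior: PriorSpec,
    dataset: Optional[ObservedDataset],
    simulate: Optional[Callable[[ModelSpec, ParameterSet, int], np.ndarray]],
    config: ABCConfig,
) -> list[PosteriorTrace]:
    """Run ``n_chains`` independent chains and return burn-in-stripped,
    thinned traces (combinable by concatenation; the combined posterior does
    not depend on chain order)."""
    network = _restricted_network(config.allowed_models)
    models = sorted(network)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    traces = []
    for c, ss in enumerate(seeds):
        rng = np.random.default_rng(ss)
        state = _initial_state(prior, models, dataset, simulate, config, rng)
        rows = np.empty((config.chain_length, 8))
        for it in range(config.chain_length):
            state = abc_step(state, prior, network, dataset, simulate, config, rng)
            rows[it, 0] = state.model_index
            rows[it, 1:7] = state.params.as_vector()
            rows[it, 7] = state.distance
        burn = int(config.burn_in_fraction * config.chain_length)
        thin = max(1, (config.chain_length - burn) // config.target_retained)
        kept = rows[burn::thin]
        df = pd.DataFrame(kept, columns=["model", *PARAMETER_NAMES, "X2"])
        df.insert(0, "iteration", np.arange(burn, config.chain_length, thin))
        df.insert(0, "chain", c)
        df["model"] = df["model"].astype(int)
        traces.append(PosteriorTrace(df, burn, thin, config.seed))
    return traces


def combine_traces(traces: Sequence[PosteriorTrace]) -> pd.DataFrame:
    if not traces:
        raise ValueError("no traces")
    return pd.concat([t.samples for t in traces], ignore_index=True)


def posterior_model_probabilities(
    traces: Sequence[PosteriorTrace],
) -> dict[int, float]:
    df = combine_traces(traces)
    if df.empty:
        raise ValueError("empty trace")
    freq = df["model"].value_counts(normalize=True)
    return {int(k): float(v) for k, v in freq.items()}


def credible_set(traces: Sequence[PosteriorTrace], mass: float = 0.95) -> list[int]:
    """Smallest set of models whose cumulative posterior probability reaches
    ``mass``, filled in order of descending probability."""
    probs = posterior_model_probabilities(traces)
    out, cum = [], 0.0
    for m, p in sorted(probs.items(), key=lambda kv: (-kv[1], kv[0])):
        out.append(m)
        cum += p
        if cum >= mass:
            break
    return out


def posterior_predictive(
    traces: Sequence[PosteriorTrace],
    conditions: Sequence[Condition],
    simulate: Callable[[ModelSpec, ParameterSet, int], np.ndarray],
    n_draws: int = 30,
    rng: Optional[np.random.Generator] = None,
) -> pd.DataFrame:
    """Simulate all conditions for states drawn uniformly from the combined
    trace; one row per (draw, condition)."""
    rng = rng if rng is not None else np.random.default_rng()
    df = combine_traces(traces)
    if df.empty:
        raise ValueError("empty trace")
    rows = []
    for d in range(n_draws):
        idx = int(rng.integers(len(df)))
        rec = df.iloc[idx]
        model = MODEL_SPACE[int(rec["model"])]
        params = ParameterSet.from_vector([rec[n] for n in PARAMETER_NAMES])
        vels = simulate(model, params, int(rng.integers(2**31 - 1)))
        for j, (cond, v) in enumerate(zip(conditions, vels)):
            rows.append(
                {
                    "draw": d,
                    "condition": j,
                    "force_pN": cond.force,
                    "velocity_bp_s": float(v),
                    "model": model.index,
                }
            )
    return pd.DataFrame(rows)
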