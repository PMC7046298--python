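"""Gillespie simulation of full-template transcription, and an exact
mean-first-passage oracle for short templates.

Every model variant reduces, per template site, to a continuous-time Markov
chain on at most three states: 0 = pretranslocated, 1 = posttranslocated
(or the coalesced translocation-equilibrium state, or the single fully
coalesced state), 2 = NTP-bound.  Catalysis advances the enzyme to state 0
(or the coalesced start state) of the next site.  The per-site rates depend
only on (l, register), so they are precomputed once per (model, parameters,
condition) and shared across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from numba import njit

from .constants import DELTA_ANGSTROM, force_term_kBT
from .energetics import EnergyLandscape, TemplateSequence
from .kinetics import Condition, ModelSpec, ParameterSet


class StalledSimulationError(RuntimeError):
    """All propensities vanished before the template was copied."""


class MaxEventsExceededError(RuntimeError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    replicates: int = 1
    seed: int = 0
    max_events: Optional[int] = None

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class SimulationResult:
    nucleotides_added: int
    elapsed_time: float
    mean_velocity: float
    seed: int
    n_events: int
    trajectory: Optional[np.ndarray] = None  # columns (time, l, state)


@dataclass(frozen=True)
class SiteRates:
    """Per-site rate arrays of the universal 3-state scheme.

    Index i corresponds to site l = l0 + i.  r01: pre->post; r10: post->pre;
    r12: post->bound; r21: bound->post; r2a: bound->advance (catalysis);
    r1a: post->advance (coalesced catalysis under binding equilibrium).
    """

    r01: np.ndarray
    r10: np.ndarray
    r12: np.ndarray
    r21: np.ndarray
    r1a: np.ndarray
    r2a: np.ndarray
    start_state: int
    l0: int

    @property
    def n_sites(self) -> int:
        return int(self.r01.size)


def build_site_rates(
    sequence: TemplateSequence,
    model: ModelSpec,
    params: ParameterSet,
    cond: Condition,
    landscape: EnergyLandscape,
) -> SiteRates:
    """Vectorized per-site rates for all four equilibrium variants."""
    params = params.with_inactive_neutral(model)
    n = landscape.n_sites
    zeros = np.zeros(n)
    mrna = sequence.mrna
    # NTP complementary to template position l+1 == mRNA base l+1 (1-based)
    next_bases = np.frombuffer(
        mrna[landscape.l0 : landscape.l0 + n].encode(), dtype="S1"
    ).astype("U1")
    conc = np.array([cond.ntp[b] for b in next_bases])

    r01 = zeros.copy()
    r10 = zeros.copy()
    r12 = zeros.copy()
    r21 = zeros.copy()
    r1a = zeros.copy()
    r2a = zeros.copy()

    if model.translocation_equilibrium:
        keff = np.exp(
            -(landscape.dG_pre - landscape.dG_post - params.dG_t1)
            - force_term_kBT(cond.force, DELTA_ANGSTROM)
        )
        occ_post = 1.0 / (1.0 + keff)
        start = 1
        if model.binding_equilibrium:
            with np.errstate(divide="ignore"):
                r1a = params.k_cat / (
                    1.0 + (params.K_D / conc) * (1.0 + keff)
                )
            r1a[conc == 0] = 0.0
        else:
            r12 = params.k_bind * conc * occ_post
            r21 = np.full(n, params.k_rel)
            r2a = np.full(n, params.k_cat)
    else:
        barrier = params.dG_tdag + landscape.dG_ts
        f_fwd = force_term_kBT(cond.force, params.delta1)
        f_bck = force_term_kBT(cond.force, DELTA_ANGSTROM - params.delta1)
        r01 = cond.prefactor * np.exp(-(barrier - landscape.dG_pre - f_fwd))
        k_bck = cond.prefactor * np.exp(
            -(barrier - (landscape.dG_post + params.dG_t1) + f_bck)
        )
        start = 0
        if model.binding_equilibrium:
            f = conc / (conc + params.K_D)
            r10 = k_bck * (1.0 - f)
            r1a = params.k_cat * f
        else:
            r10 = k_bck
            r12 = params.k_bind * conc
            r21 = np.full(n, params.k_rel)
            r2a = np.full(n, params.k_cat)

    return SiteRates(r01, r10, r12, r21, r1a, r2a, start, landscape.l0)


@njit(cache=True)
def _gillespie_kernel(
    r01, r10, r12, r21, r1a, r2a, start_state, seed, max_events,
    record, traj_time, traj_l, traj_state,
):  # pragma: no cover - exercised via wrappers
    np.random.seed(seed)
    n = r01.shape[0]
    t_now = 0.0
    events = 0
    for i in range(n):
        s = start_state
        while True:
            if s == 0:
                total = r01[i]
            elif s == 1:
                total = r10[i] + r12[i] + r1a[i]
            else:
                total = r21[i] + r2a[i]
            if total <= 0.0:
                return -1, t_now, events
            u = np.random.random()
            t_now += -np.log(1.0 - u) / total
            if events >= max_events:
                return -2, t_now, events
            advance = False
            u2 = np.random.random() * total
            if s == 0:
                s = 1
            elif s == 1:
                if u2 < r10[i]:
                    s = 0
                elif u2 < r10[i] + r12[i]:
                    s = 2
                else:
                    advance = True
            else:
                if u2 < r21[i]:
                    s = 1
                else:
                    advance = True
            if record:
                traj_time[events] = t_now
                if advance:
                    traj_l[events] = i + 1
                    traj_state[events] = start_state
                else:
                    traj_l[events] = i
                    traj_state[events] = s
            events += 1
            if advance:
                break
    return 0, t_now, events


def _derive_seeds(root_seed: int, n: int) -> np.ndarray:
    """Deterministic per-replicate streams independent of scheduling."""
    return np.random.SeedSequence(root_seed).generate_state(n, np.uint32)


def simulate_once(
    sequence: TemplateSequence,
    model: ModelSpec,
    params: ParameterSet,
    cond: Condition,
    landscape: EnergyLandscape,
    seed: int = 0,
    max_events: Optional[int] = None,
    record_trajectory: bool = False,
    _rates: Optional[SiteRates] = None,
) -> SimulationResult:
    """One Gillespie trajectory from S(l0, 0) to S(L, 0).

    Deterministic given ``seed``.  A template with L == l0 adds zero
    nucleotides in zero time and reports NaN velocity.
    """
    rates = _rates if _rates is not None else build_site_rates(
        sequence, model, params, cond, landscape
    )
    n = rates.n_sites
    if n == 0:
        return SimulationResult(0, 0.0, float("nan"), seed, 0)
    if max_events is None:
        max_events = 2000 * n + 10_000
    if record_trajectory:
        tt = np.empty(max_events)
        tl = np.empty(max_events, dtype=np.int64)
        ts = np.empty(max_events, dtype=np.int64)
    else:
        tt = np.empty(1)
        tl = np.empty(1, dtype=np.int64)
        ts = np.empty(1, dtype=np.int64)
    status, elapsed, events = _gillespie_kernel(
        rates.r01, rates.r10, rates.r12, rates.r21, rates.r1a, rates.r2a,
        rates.start_state, int(seed) & 0xFFFFFFFF, max_events,
        record_trajectory, tt, tl, ts,
    )
    if status == -1:
        raise StalledSimulationError(
            "all propensities vanished before the template was copied "
            "(is an NTP concentration zero?)"
        )
    if status == -2:
        raise MaxEventsExceededError(f"exceeded max_events={max_events}")
    traj = None
    if record_trajectory:
        traj = np.column_stack(
            [tt[:events], (tl[:events] + rates.l0).astype(float), ts[:events].astype(float)]
        )
    return SimulationResult(n, elapsed, n / elapsed, seed, events, traj)


def estimate_mean_velocity(
    sequence: TemplateSequence,
    model: ModelSpec,
    params: ParameterSet,
    cond: Condition,
    landscape: EnergyLandscape,
    config: SimulationConfig = SimulationConfig(),
    _rates: Optional[SiteRates] = None,
) -> float:
    """Mean of the per-replicate mean velocities across c replicates (the
    replicate-level average, not total distance over total time)."""
    rates = _rates if _rates is not None else build_site_rates(
        sequence, model, params, cond, landscape
    )
    seeds = _derive_seeds(config.seed, config.replicates)
    velocities = [
        simulate_once(
            sequence, model, params, cond, landscape,
            seed=int(s), max_events=config.max_events, _rates=rates,
        ).mean_velocity
        for s in seeds
    ]
    return float(np.mean(velocities))


def site_mean_first_passage_times(rates: SiteRates) -> np.ndarray:
    """Closed-form mean first-passage time, per site, from the site's start
    state to catalysis (the next site's start state)."""
    r01, r10, r12 = rates.r01, rates.r10, rates.r12
    r21, r1a, r2a = rates.r21, rates.r1a, rates.r2a
    D2 = r21 + r2a
    with np.errstate(divide="ignore", invalid="ignore"):
        via_bound = np.where(r12 > 0, r12 * r2a / D2, 0.0)
        leak = r1a + via_bound  # total productive outflow from state 1
        if np.any(leak <= 0):
            raise StalledSimulationError("a site has no productive pathway")
        bound_visits = np.where(r12 > 0, r12 / D2, 0.0)
        if rates.start_state == 0:
            if np.any(r01 <= 0):
                raise StalledSimulationError("zero forward translocation rate")
            T1 = (1.0 + r10 / r01 + bound_visits) / leak
            return 1.0 / r01 + T1
        return (1.0 + bound_visits) / leak


def master_equation_velocity(
    sequence: TemplateSequence,
    model: ModelSpec,
    params: ParameterSet,
    cond: Condition,
    landscape: EnergyLandscape,
) -> float:
    """Exact expected velocity: the template completion time is the sum over
    sites of the mean first-passage time from the site's start state to the
    next site, available in closed form for the 3-state site scheme."""
    rates = build_site_rates(sequence, model, params, cond, landscape)
    total = float(np.sum(site_mean_first_passage_times(rates)))
    return rates.n_sites / total
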