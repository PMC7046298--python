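"""The 12-model space of Brownian-ratchet elongation kinetics.

A single nucleotide-addition cycle is (1) forward translocation (pre -> post),
(2) NTP binding in the open active site, (3) catalysis, which extends the
mRNA and returns the enzyme to the pretranslocated register of the next site.
Backward translocation and NTP release oppose steps (1) and (2);
pyrophosphorolysis is neglected.

Translocation rates follow transition-state theory over the sequence-dependent
basepairing landscape:

    k_fwd(l) = A * exp(-(dG_ts# - dG_pre(l)      - F*delta1/kBT))
    k_bck(l) = A * exp(-(dG_ts# - dG_post'(l)    + F*(delta-delta1)/kBT))

with dG_ts# = dG_tdag + dG_ts(l) (barrier baseline plus sequence term),
dG_post' = dG_post(l) + dG_t1 (posttranslocated bias), assisting force F > 0,
and prefactor A fixed at 1e6 /s.  Either step (translocation, binding) may
instead be treated as a partial equilibrium, coalescing states and replacing
the pair of rate constants by an equilibrium constant; the four resulting
variants, crossed with whether dG_t1 and delta1 are estimated or held at
their neutral values (0 and delta/2), give the 12 models.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .constants import DELTA_ANGSTROM, PREFACTOR_PER_S, force_term_kBT
from .energetics import EnergyLandscape

PARAMETER_NAMES = ("k_cat", "K_D", "k_bind", "dG_t1", "delta1", "dG_tdag")

#: parameters every model estimates
_CORE = ("k_cat", "K_D")


@dataclass(frozen=True)
class ParameterSet:
    """The six kinetic/thermodynamic parameters.

    k_cat (s^-1), K_D = k_rel/k_bind (uM), k_bind (uM^-1 s^-1),
    dG_t1 (k_B*T, posttranslocated-state offset), delta1 (Angstrom,
    displacement to the translocation transition state), dG_tdag (k_B*T,
    sequence-independent barrier baseline).  k_rel is implied as K_D*k_bind
    and never stored.
    """

    k_cat: float
    K_D: float
    k_bind: float = 1.0
    dG_t1: float = 0.0
    delta1: float = DELTA_ANGSTROM / 2
    dG_tdag: float = 0.0

    def __post_init__(self) -> None:
        if self.k_cat <= 0 or self.K_D <= 0 or self.k_bind <= 0:
            raise ValueError("k_cat, K_D and k_bind must be positive")
        if not 0 < self.delta1 < DELTA_ANGSTROM:
            raise ValueError(f"delta1 must lie in (0, {DELTA_ANGSTROM})")

    @property
    def k_rel(self) -> float:
        return self.K_D * self.k_bind

    def as_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAMETER_NAMES])

    @classmethod
    def from_vector(cls, vec) -> "ParameterSet":
        return cls(**dict(zip(PARAMETER_NAMES, map(float, vec))))

    def with_inactive_neutral(self, model: "ModelSpec") -> "ParameterSet":
        """Return a copy with every parameter the model does not estimate
        reset to its neutral value (dG_t1=0, delta1=delta/2); k_bind is left
        untouched because it is irrelevant under binding equilibrium."""
        out = self
        if "dG_t1" not in model.active_parameters:
            out = replace(out, dG_t1=0.0)
        if "delta1" not in model.active_parameters:
            out = replace(out, delta1=DELTA_ANGSTROM / 2)
        return out


@dataclass(frozen=True)
class ModelSpec:
    """One of the 12 elongation models."""

    index: int
    translocation_equilibrium: bool
    binding_equilibrium: bool
    uses_dG_t1: bool
    uses_delta1: bool

    def __post_init__(self) -> None:
        if self.translocation_equilibrium and self.uses_delta1:
            raise ValueError("translocation-equilibrium models never use delta1")

    @property
    def active_parameters(self) -> tuple[str, ...]:
        out = list(_CORE)
        if not self.binding_equilibrium:
            out.append("k_bind")
        if self.uses_dG_t1:
            out.append("dG_t1")
        if self.uses_delta1:
            out.append("delta1")
        if not self.translocation_equilibrium:
            out.append("dG_tdag")
        return tuple(out)

    @property
    def n_parameters(self) -> int:
        return len(self.active_parameters)


def _build_model_space() -> dict[int, ModelSpec]:
    # Indices 1,2,4,5,11,12 are pinned by the text; 3 is the three-parameter
    # kinetic-translocation base and 8 its +dG_t1 variant; the assignment of
    # 6,7,9,10 is the canonical one (6={delta1}, 7={k_bind}, 9={k_bind,dG_t1},
    # 10={k_bind,delta1} added to model 3).
    mk = ModelSpec
    space = {
        1: mk(1, True, True, False, False),
        2: mk(2, True, False, False, False),
        4: mk(4, True, True, True, False),
        5: mk(5, True, False, True, False),
        3: mk(3, False, True, False, False),
        6: mk(6, False, True, False, True),
        7: mk(7, False, False, False, False),
        8: mk(8, False, True, True, False),
        9: mk(9, False, False, True, False),
        10: mk(10, False, False, False, True),
        11: mk(11, False, True, True, True),
        12: mk(12, False, False, True, True),
    }
    return space


MODEL_SPACE: Mapping[int, ModelSpec] = _build_model_space()

#: prior mass on the model indicator: translocation-equilibrium models do not
#: use delta1 and get double mass (2/16 vs 1/16)
MODEL_PRIOR = {
    i: (2 / 16 if MODEL_SPACE[i].translocation_equilibrium else 1 / 16)
    for i in MODEL_SPACE
}


def model_network(space: Mapping[int, ModelSpec] = MODEL_SPACE) -> dict[int, tuple[int, ...]]:
    """Undirected adjacency over models: an edge joins two models whose
    active-parameter sets differ by exactly one parameter."""
    items = sorted(space)
    adj: dict[int, list[int]] = {i: [] for i in items}
    for a in items:
        for b in items:
            if b <= a:
                continue
            diff = set(space[a].active_parameters) ^ set(space[b].active_parameters)
            if len(diff) == 1:
                adj[a].append(b)
                adj[b].append(a)
    out = {i: tuple(sorted(v)) for i, v in adj.items()}
    for i, nbrs in out.items():
        if not nbrs:
            raise ValueError(f"model {i} is isolated in the network")
    return out


@dataclass(frozen=True)
class Condition:
    """An experimental condition: applied force (pN, assisting positive) and
    per-NTP concentrations (uM)."""

    force: float = 0.0
    ntp: Mapping[str, float] = field(default_factory=dict)
    prefactor: float = PREFACTOR_PER_S

    @classmethod
    def make(cls, force: float = 0.0, ntp=1000.0, prefactor: float = PREFACTOR_PER_S):
        """Scalar NTP concentrations are broadcast to all four NTPs."""
        if isinstance(ntp, (int, float)):
            ntp = {b: float(ntp) for b in "ACGU"}
        else:
            ntp = {b: float(ntp[b]) for b in "ACGU"}
        if any(v < 0 for v in ntp.values()):
            raise ValueError("NTP concentrations must be non-negative")
        return cls(float(force), ntp, prefactor)

    def concentration(self, base: str) -> float:
        """Concentration of the NTP complementary to the next template
        position, i.e. keyed by the next mRNA base."""
        return self.ntp[base]


# ---------------------------------------------------------------------------
# rates and equilibrium constants


def translocation_rates(
    l: int, params: ParameterSet, cond: Condition, landscape: EnergyLandscape
) -> tuple[float, float]:
    """(k_fwd(l), k_bck(l)) in s^-1 from transition-state theory."""
    i = l - landscape.l0
    if not 0 <= i < landscape.n_sites:
        raise ValueError(f"site l={l} outside landscape [{landscape.l0}, "
                         f"{landscape.l0 + landscape.n_sites - 1}]")
    dg_pre = landscape.dG_pre[i]
    dg_post = landscape.dG_post[i]
    dg_ts = landscape.dG_ts[i]
    if not np.isfinite(dg_pre) or not np.isfinite(dg_post) or not np.isfinite(dg_ts):
        raise ValueError(f"non-finite landscape energy at site {l}")
    barrier = params.dG_tdag + dg_ts
    f_fwd = force_term_kBT(cond.force, params.delta1)
    f_bck = force_term_kBT(cond.force, DELTA_ANGSTROM - params.delta1)
    k_fwd = cond.prefactor * np.exp(-(barrier - dg_pre - f_fwd))
    k_bck = cond.prefactor * np.exp(-(barrier - (dg_post + params.dG_t1) + f_bck))
    return float(k_fwd), float(k_bck)


def translocation_equilibrium(
    l: int, params: ParameterSet, cond: Condition, landscape: EnergyLandscape
) -> float:
    """K_tau(l) = p(pre)/p(post) at zero force; under an applied force the
    posttranslocated weight gains the factor exp(+F*delta/kBT), i.e. the
    effective pre/post ratio is K_tau*exp(-F*delta/kBT)."""
    i = l - landscape.l0
    dg_pre = landscape.dG_pre[i]
    dg_post = landscape.dG_post[i]
    return float(np.exp(-(dg_pre - dg_post - params.dG_t1)))


def analytic_velocity(
    params: ParameterSet, K_tau: float, force: float, ntp: float
) -> float:
    """Mean elongation velocity (bp/s) of the sequence-homogeneous
    both-equilibria model:

        v = k_cat / (1 + (K_D/[NTP]) * (1 + K_tau * exp(-F*delta/kBT)))
    """
    if ntp == 0:
        return 0.0
    fterm = np.exp(-force_term_kBT(force, DELTA_ANGSTROM))
    return params.k_cat / (1.0 + (params.K_D / ntp) * (1.0 + K_tau * fterm))


def sequence_averaged_Ktau(
    params: ParameterSet, landscape: EnergyLandscape
) -> float:
    """Geometric mean of k_bck(l)/k_fwd(l) over sites at zero force: the exp
    of the arithmetic mean of ln K_tau(l) over l in [l0, L-1]."""
    ln_ratio = -(landscape.dG_pre - landscape.dG_post - params.dG_t1)
    return float(np.exp(np.mean(ln_ratio)))


# ---------------------------------------------------------------------------
# per-site propensities


@dataclass(frozen=True)
class Reaction:
    label: str
    rate: float
    successor: tuple[int, int, bool]  # (l, t, bound)


def _site_rates(
    l: int,
    next_base: str,
    model: ModelSpec,
    params: ParameterSet,
    cond: Condition,
    landscape: EnergyLandscape,
) -> dict[str, float]:
    """Raw per-site rate constants used by both the propensity table and the
    simulator's vectorized rate builder."""
    N = cond.concentration(next_base)
    out = {"N": N}
    if model.translocation_equilibrium:
        K = translocation_equilibrium(l, params, cond, landscape)
        keff = K * np.exp(-force_term_kBT(cond.force, DELTA_ANGSTROM))
        out["occ_post"] = 1.0 / (1.0 + keff)
    else:
        out["k_fwd"], out["k_bck"] = translocation_rates(l, params, cond, landscape)
    if model.binding_equilibrium:
        out["f_bound"] = N / (N + params.K_D)
    return out


def propensity_table(
    state: tuple[int, int, bool],
    model: ModelSpec,
    params: ParameterSet,
    cond: Condition,
    landscape: EnergyLandscape,
    next_base: str,
) -> list[Reaction]:
    """All outbound reactions of a (possibly coalesced) TEC state.

    ``state`` is (l, t, bound).  Under a partial equilibrium approximation the
    equilibrated states are coalesced and the outbound rates are weighted by
    the equilibrium occupancy of the state they leave from.
    """
    l, t, bound = state
    params = params.with_inactive_neutral(model)
    r = _site_rates(l, next_base, model, params, cond, landscape)
    N = r["N"]
    k_rel = params.k_rel
    te, be = model.translocation_equilibrium, model.binding_equilibrium
    out: list[Reaction] = []
    if te and be:
        # single coalesced state per site; catalysis at the occupancy-weighted rate
        occ_bound = (N / params.K_D) * r["occ_post"] / (
            1.0 + (N / params.K_D) * r["occ_post"]
        ) if N > 0 else 0.0
        # equivalently k_cat / (1 + (K_D/N)(1 + K_tau e^{-F delta/kBT}))
        out.append(Reaction("catalysis", params.k_cat * occ_bound, (l + 1, 0, False)))
    elif te and not be:
        if bound:
            out.append(Reaction("release", k_rel, (l, 1, False)))
            out.append(Reaction("catalysis", params.k_cat, (l + 1, 0, False)))
        else:
            out.append(
                Reaction("binding", params.k_bind * N * r["occ_post"], (l, 1, True))
            )
    elif be and not te:
        if t == 0:
            out.append(Reaction("forward", r["k_fwd"], (l, 1, False)))
        else:
            f = r["f_bound"]
            out.append(Reaction("backward", r["k_bck"] * (1.0 - f), (l, 0, False)))
            out.append(Reaction("catalysis", params.k_cat * f, (l + 1, 0, False)))
    else:  # fully kinetic
        if t == 0:
            out.append(Reaction("forward", r["k_fwd"], (l, 1, False)))
        elif not bound:
            out.append(Reaction("backward", r["k_bck"], (l, 0, False)))
            out.append(Reaction("binding", params.k_bind * N, (l, 1, True)))
        else:
            out.append(Reaction("release", k_rel, (l, 1, False)))
            out.append(Reaction("catalysis", params.k_cat, (l + 1, 0, False)))
    return out
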