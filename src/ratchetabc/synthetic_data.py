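"""Synthetic templates and force-velocity-[NTP] datasets with known truth.

The three built-in designs emulate the layouts of the single-molecule
optical-trapping experiments the elongation models are usually fitted to:
a force sweep at saturating and limiting NTP (bacterial RNAP style), an NTP
titration at fixed assisting/hindering loads (pol II style), and a force
sweep at several NTP levels (T7 style).  Velocities are generated by the
package's own Gillespie simulator and perturbed with multiplicative Gaussian
noise, so every pipeline stage can be tested end to end with a known
generating model, parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .energetics import EnergyModel, TemplateSequence
from .inference import ObservedDataset
from .kinetics import MODEL_SPACE, Condition, ParameterSet
from .simulator import SimulationConfig, estimate_mean_velocity

#: the limiting-NTP mix used in bacterial RNAP force-velocity experiments (uM)
NTP_EQ = {"A": 5.0, "C": 2.5, "G": 10.0, "U": 10.0}


@dataclass(frozen=True)
class ExperimentalDesign:
    """A list of (force, NTP condition) cells plus the replicate noise model
    (Gaussian with sd = cv * velocity, or an absolute sd)."""

    name: str
    cells: tuple[Condition, ...]
    noise_cv: float = 0.05
    noise_sd: Optional[float] = None
    enzyme: str = "rnap"

    def __post_init__(self) -> None:
        if len(self.cells) < 3:
            raise ValueError("a design needs at least 3 cells")
        if self.noise_cv < 0 or (self.noise_sd is not None and self.noise_sd < 0):
            raise ValueError("noise must be non-negative")

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "noise_cv": self.noise_cv,
            "noise_sd": self.noise_sd,
            "enzyme": self.enzyme,
            "cells": [
                {"force_pN": c.force, "ntp_uM": dict(c.ntp)} for c in self.cells
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentalDesign":
        cells = tuple(
            Condition.make(c["force_pN"], c["ntp_uM"]) for c in d["cells"]
        )
        return cls(d["name"], cells, d["noise_cv"], d.get("noise_sd"), d["enzyme"])


@dataclass(frozen=True)
class GroundTruth:
    """Everything needed to regenerate a synthetic dataset."""

    model_index: int
    params: ParameterSet
    template_length: int = 500
    gc_fraction: float = 0.5
    template_seed: int = 0
    seed: int = 0
    replicates: int = 8

    def to_dict(self) -> dict:
        return {
            "model_index": self.model_index,
            "params": dict(
                zip(
                    ("k_cat", "K_D", "k_bind", "dG_t1", "delta1", "dG_tdag"),
                    map(float, self.params.as_vector()),
                )
            ),
            "template_length": self.template_length,
            "gc_fraction": self.gc_fraction,
            "template_seed": self.template_seed,
            "seed": self.seed,
            "replicates": self.replicates,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        d = dict(d)
        d["params"] = ParameterSet(**d["params"])
        return cls(**d)


def random_template(
    L: int, gc_fraction: float = 0.5, seed: int = 0, identifier: str = "synthetic"
) -> TemplateSequence:
    """IID random coding strand with P(G) = P(C) = gc/2."""
    if not 0 <= gc_fraction <= 1:
        raise ValueError("gc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    bases = rng.choice(list("ACGT"), size=L, p=p)
    return TemplateSequence(identifier, "".join(bases))


def generate_dataset(
    truth: GroundTruth,
    design: ExperimentalDesign,
    energy_model: Optional[EnergyModel] = None,
    template: Optional[TemplateSequence] = None,
) -> ObservedDataset:
    """Simulate every design cell under the ground truth and add noise;
    deterministic given the truth's seeds."""
    em = energy_model if energy_model is not None else EnergyModel()
    seq = template if template is not None else random_template(
        truth.template_length, truth.gc_fraction, truth.template_seed
    )
    landscape = em.landscape(seq)
    model = MODEL_SPACE[truth.model_index]
    rng = np.random.default_rng(truth.seed)
    cell_seeds = np.random.SeedSequence(truth.seed).generate_state(
        len(design.cells), np.uint32
    )
    velocities = []
    for cond, s in zip(design.cells, cell_seeds):
        v = estimate_mean_velocity(
            seq, model, truth.params, cond, landscape,
            SimulationConfig(truth.replicates, int(s)),
        )
        if design.noise_sd is not None:
            v += rng.normal(0.0, design.noise_sd)
        elif design.noise_cv > 0:
            v *= 1.0 + rng.normal(0.0, design.noise_cv)
        velocities.append(v)
    return ObservedDataset(design.cells, np.array(velocities), design.enzyme)


def builtin_designs(noise_cv: float = 0.05) -> dict[str, ExperimentalDesign]:
    """The three literature-style designs, keyed by name."""
    forces = [-10.0, -5.0, 0.0, 5.0, 10.0, 15.0, 20.0, 30.0]
    abbondanzieri = ExperimentalDesign(
        "abbondanzieri-like",
        tuple(
            [Condition.make(f, 1000.0) for f in forces]
            + [Condition.make(f, NTP_EQ) for f in forces]
        ),
        noise_cv=noise_cv,
        enzyme="rnap",
    )
    ntps = [10.0, 35.0, 100.0, 350.0, 1000.0, 2000.0]
    schweikhard = ExperimentalDesign(
        "schweikhard-like",
        tuple(
            [Condition.make(6.5, n) for n in ntps]
            + [Condition.make(-6.5, n) for n in ntps]
        ),
        noise_cv=noise_cv,
        enzyme="polii",
    )
    thomen = ExperimentalDesign(
        "thomen-like",
        tuple(
            [Condition.make(f, n) for n in (100.0, 1000.0)
             for f in (-20.0, -15.0, -10.0, -5.0, 0.0, 5.0, 10.0)]
        ),
        noise_cv=noise_cv,
        enzyme="t7",
    )
    return {d.name: d for d in (abbondanzieri, schweikhard, thomen)}


def recovery_design(noise_cv: float = 0.05) -> ExperimentalDesign:
    """Twelve-cell design used by the scaled-down parameter-recovery study:
    six forces crossed with saturating (1 mM) and limiting NTP."""
    forces = [-10.0, -5.0, 0.0, 10.0, 20.0, 30.0]
    return ExperimentalDesign(
        "recovery-12cell",
        tuple(
            [Condition.make(f, 1000.0) for f in forces]
            + [Condition.make(f, 50.0) for f in forces]
        ),
        noise_cv=noise_cv,
        enzyme="rnap",
    )
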