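"""Sequence-dependent basepairing energetics of transcription elongation complexes.

A transcription elongation complex (TEC) state ``S(l, t)`` is described by the
nascent mRNA length ``l`` (nt, 1-based along the coding strand) and the
translocation register ``t`` (0 = pretranslocated, active site occluded by the
mRNA 3' end; 1 = posttranslocated, active site open).  The standard Gibbs
energy of a state that can be evaluated from the sequence alone is the sum of

* nearest-neighbour doublet energies of the closed double-stranded DNA
  flanking the transcription bubble (SantaLucia DNA/DNA parameters),
* nearest-neighbour doublet energies of the DNA/mRNA hybrid (Sugimoto
  DNA/RNA parameters, keyed by the RNA strand), and
* dangling-end terms at the exposed hybrid termini.

Energies are carried in multiples of k_B*T at 310 K.  Only energy
*differences* between states sharing the same mRNA length are ever consumed
by the kinetics, so each site uses a fixed local window of gene doublets;
window constants cancel in every downstream quantity.

The translocation transition state ``T(l, t)`` between ``S(l, t)`` and
``S(l, t+1)`` contains exactly the basepairs present in both flanking states
(set intersection), so climbing the barrier from either side requires melting
the basepairs unique to that side.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import numpy as np

from .constants import kcal_per_mol_to_kBT

_VALID_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class UnsupportedStateError(ValueError):
    """Raised for translocation registers outside {0, 1} (backtracking and
    hypertranslocation are outside the model)."""


class ConfigurationError(KeyError):
    """Raised when an energy table lacks a required doublet."""


@dataclass(frozen=True)
class TemplateSequence:
    """A transcribed gene, stored as the coding (non-template) strand 5'->3'.

    The mRNA is an exact copy of the coding strand with U for T; the template
    strand is its complement.  Storing the coding strand keeps a single
    source of truth for both derived views.
    """

    identifier: str
    bases: str

    def __post_init__(self) -> None:
        bases = self.bases.upper()
        bad = set(bases) - _VALID_BASES
        if bad:
            pos = next(i for i, b in enumerate(bases) if b in bad)
            raise ValueError(
                f"sequence {self.identifier!r}: invalid base {bases[pos]!r} "
                f"at position {pos + 1} (alphabet is A/C/G/T)"
            )
        object.__setattr__(self, "bases", bases)

    @property
    def length(self) -> int:
        return len(self.bases)

    @property
    def mrna(self) -> str:
        """The full-length mRNA sequence (coding strand with U for T)."""
        return self.bases.replace("T", "U")

    def base(self, position: int) -> str:
        """1-based coding-strand base."""
        return self.bases[position - 1]

    def coding_doublet(self, i: int) -> str:
        """Coding-strand doublet covering 1-based positions (i, i+1)."""
        return self.bases[i - 1 : i + 1]

    def mrna_doublet(self, i: int) -> str:
        return self.coding_doublet(i).replace("T", "U")


@dataclass(frozen=True)
class TECGeometry:
    """Fixed geometry of the elongation complex.

    h: basepairs in the DNA/mRNA hybrid; beta1/beta2: unpaired template bases
    upstream/downstream of the hybrid within the transcription bubble;
    delta: inter-basepair rise (Angstrom).
    """

    h: int = 9
    beta1: int = 2
    beta2: int = 1
    delta: float = 3.4

    @property
    def bubble_size(self) -> int:
        return self.beta1 + self.h + self.beta2

    @property
    def l0(self) -> int:
        """Initial mRNA length: transcription starts at S(l0, 0)."""
        return self.beta1 + self.h + 2


@dataclass(frozen=True)
class NearestNeighborTable:
    """Doublet and dangling-end standard Gibbs energies (kcal/mol at 37 C)."""

    doublet_energies: Mapping[str, float]
    dangling_end_energies: Mapping[tuple[str, str], float] = field(default_factory=dict)
    provenance: str = ""

    def doublet(self, key: str) -> float:
        try:
            return self.doublet_energies[key]
        except KeyError as exc:
            raise ConfigurationError(
                f"doublet {key!r} missing from table {self.provenance!r}"
            ) from exc

    def dangling(self, doublet: str, end: str) -> float:
        try:
            return self.dangling_end_energies[(doublet, end)]
        except KeyError as exc:
            raise ConfigurationError(
                f"dangling end ({doublet!r}, {end!r}) missing from table "
                f"{self.provenance!r}"
            ) from exc


def _read_tsv(name: str) -> list[list[str]]:
    text = (
        importlib.resources.files("ratchetabc.data").joinpath(name).read_text()
    )
    rows = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        rows.append(line.split("\t"))
    return rows[1:]  # drop header


@lru_cache(maxsize=None)
def load_dna_dna_table() -> NearestNeighborTable:
    """SantaLucia 1998 unified DNA/DNA doublet energies plus Bommarito 2000
    DNA dangling-end energies."""
    doublets = {d: float(v) for d, v in _read_tsv("nn_dna_dna_santalucia1998.tsv")}
    dangling = {
        (d, e): float(v)
        for d, e, v in _read_tsv("dangling_ends_dna_bommarito2000.tsv")
    }
    return NearestNeighborTable(doublets, dangling, "DNA/DNA SantaLucia")


@lru_cache(maxsize=None)
def load_dna_rna_table() -> NearestNeighborTable:
    """Sugimoto 1995 DNA/RNA hybrid doublet energies (keyed by RNA strand)."""
    doublets = {d: float(v) for d, v in _read_tsv("nn_dna_rna_sugimoto1995.tsv")}
    return NearestNeighborTable(doublets, {}, "DNA/RNA Sugimoto")


def uniform_tables(value_kcal: float = -1.0) -> tuple[NearestNeighborTable, NearestNeighborTable]:
    """Sequence-independence control: every doublet gets the same energy and
    dangling ends are zero."""
    dna = {a + b: value_kcal for a in "ACGT" for b in "ACGT"}
    rna = {a + b: value_kcal for a in "ACGU" for b in "ACGU"}
    return (
        NearestNeighborTable(dna, {}, "uniform DNA/DNA"),
        NearestNeighborTable(rna, {}, "uniform DNA/RNA"),
    )


@dataclass(frozen=True)
class BasepairLayout:
    """The set of paired template positions of a TEC state (or transition
    state) within its local window, plus dangling-end descriptors.

    gene_basepairs / hybrid_basepairs are 1-based coding-strand positions.
    dangling_ends are ``(position, end)`` descriptors where ``position`` is the
    first position of the coding-strand doublet and ``end`` is ``"5p"`` or
    ``"3p"`` relative to the mRNA strand.
    """

    gene_basepairs: frozenset[int]
    hybrid_basepairs: frozenset[int]
    dangling_ends: tuple[tuple[int, str], ...] = ()

    def intersection(self, other: "BasepairLayout") -> "BasepairLayout":
        """Basepairs present in both layouts; dangling ends recomputed by the
        caller (they are not basepairs)."""
        return BasepairLayout(
            self.gene_basepairs & other.gene_basepairs,
            self.hybrid_basepairs & other.hybrid_basepairs,
            (),
        )

    def union(self, other: "BasepairLayout") -> "BasepairLayout":
        return BasepairLayout(
            self.gene_basepairs | other.gene_basepairs,
            self.hybrid_basepairs | other.hybrid_basepairs,
            self.dangling_ends + other.dangling_ends,
        )


def _bubble(l: int, t: int, g: TECGeometry) -> tuple[int, int]:
    """Inclusive template-position span of the transcription bubble of S(l,t)."""
    start = l - g.h - g.beta1 + 1 + t
    end = l + g.beta2 + t
    return start, end


def _hybrid_span(l: int, t: int, g: TECGeometry) -> tuple[int, int]:
    """Inclusive span of paired hybrid positions: h bp when pretranslocated,
    h-1 when posttranslocated (the upstream hybrid basepair is lost)."""
    return l - g.h + 1 + t, l


def _check_state(sequence: TemplateSequence, l: int, t: int, g: TECGeometry) -> None:
    if t not in (0, 1):
        raise UnsupportedStateError(
            f"translocation register t={t} outside the main pathway "
            "(backtracked and hypertranslocated states are not modelled)"
        )
    if not g.l0 <= l <= sequence.length:
        raise ValueError(
            f"mRNA length l={l} outside [{g.l0}, {sequence.length}] for "
            f"sequence {sequence.identifier!r}"
        )


def _gene_window(l: int, g: TECGeometry, L: int, margin: int = 2) -> tuple[int, int]:
    # Shared between t=0 and t=1 so that state differences at a site are
    # exactly the melted/formed basepairs; constants cancel across registers.
    lo, _ = _bubble(l, 0, g)
    _, hi = _bubble(l, 1, g)
    return max(1, lo - margin), min(L, hi + margin)


def _dangling_descriptors(
    hybrid: Iterable[int], shortened_register: bool, L: int
) -> tuple[tuple[int, str], ...]:
    """The dangling end of the DNA/mRNA hybrid.

    Melting the upstream hybrid basepair (forward translocation) frees the
    mRNA base at the hybrid's 5' terminus, which remains stacked on the
    shortened hybrid as a 5' dangling end.  The term is therefore present in
    the posttranslocated and transition-state registers only; its mean
    magnitude over the dangling-end table is about -1 k_B*T, stabilising the
    shortened hybrid.
    """
    hybrid = sorted(hybrid)
    if not hybrid or not shortened_register:
        return ()
    p = hybrid[0]
    if p - 1 >= 1:
        return ((p - 1, "5p"),)
    return ()


def basepair_layout(
    sequence: TemplateSequence, l: int, t: int, geometry: TECGeometry = TECGeometry()
) -> BasepairLayout:
    """Full basepair layout of state S(l, t).

    Positions that would extend beyond the sequence ends are dropped.
    """
    _check_state(sequence, l, t, geometry)
    L = sequence.length
    b_lo, b_hi = _bubble(l, t, geometry)
    w_lo, w_hi = _gene_window(l, geometry, L)
    gene = frozenset(
        i for i in range(w_lo, w_hi + 1) if not b_lo <= i <= b_hi
    )
    h_lo, h_hi = _hybrid_span(l, t, geometry)
    hybrid = frozenset(i for i in range(max(1, h_lo), min(L, h_hi) + 1))
    dang = _dangling_descriptors(hybrid, shortened_register=(t == 1), L=L)
    return BasepairLayout(gene, hybrid, dang)


def transition_state_layout(
    sequence: TemplateSequence, l: int, t: int = 0, geometry: TECGeometry = TECGeometry()
) -> BasepairLayout:
    """Layout of the translocation transition state T(l, t): the intersection
    of the basepair sets of S(l, t) and S(l, t+1), with dangling ends placed
    as in an open-active-site configuration."""
    a = basepair_layout(sequence, l, t, geometry)
    b = basepair_layout(sequence, l, t + 1, geometry)
    inter = a.intersection(b)
    dang = _dangling_descriptors(inter.hybrid_basepairs, True, sequence.length)
    return BasepairLayout(inter.gene_basepairs, inter.hybrid_basepairs, dang)


def _run_doublet_sum(positions: frozenset[int], doublet_at) -> float:
    """Sum nearest-neighbour doublet energies over maximal runs of consecutive
    paired positions."""
    total = 0.0
    for i in positions:
        if i + 1 in positions:
            total += doublet_at(i)
    return total


def gibbs_basepairing(
    layout: BasepairLayout,
    sequence: TemplateSequence,
    dna_table: NearestNeighborTable,
    hybrid_table: NearestNeighborTable,
    dangling_ends: bool = True,
) -> float:
    """Standard Gibbs basepairing energy of a layout, in k_B*T.

    Purely additive: gene doublets from the DNA/DNA table, hybrid doublets
    from the DNA/RNA table (keyed by the mRNA strand), plus one dangling-end
    term per descriptor from the DNA table's dangling-end set.
    """
    for pos in layout.gene_basepairs | layout.hybrid_basepairs:
        if not 1 <= pos <= sequence.length:
            raise ValueError(f"layout position {pos} outside sequence")
    kcal = _run_doublet_sum(
        layout.gene_basepairs, lambda i: dna_table.doublet(sequence.coding_doublet(i))
    )
    kcal += _run_doublet_sum(
        layout.hybrid_basepairs,
        lambda i: hybrid_table.doublet(sequence.mrna_doublet(i)),
    )
    if dangling_ends:
        for i, end in layout.dangling_ends:
            kcal += dna_table.dangling(sequence.coding_doublet(i), end)
    return kcal_per_mol_to_kBT(kcal)


@dataclass(frozen=True)
class EnergyModel:
    """Bundle of energy tables, TEC geometry and dangling-end policy."""

    dna_table: NearestNeighborTable = None  # type: ignore[assignment]
    hybrid_table: NearestNeighborTable = None  # type: ignore[assignment]
    geometry: TECGeometry = TECGeometry()
    dangling_ends: bool = True

    def __post_init__(self) -> None:
        if self.dna_table is None:
            object.__setattr__(self, "dna_table", load_dna_dna_table())
        if self.hybrid_table is None:
            object.__setattr__(self, "hybrid_table", load_dna_rna_table())

    def state_energy(self, sequence: TemplateSequence, l: int, t: int) -> float:
        layout = basepair_layout(sequence, l, t, self.geometry)
        return gibbs_basepairing(
            layout, sequence, self.dna_table, self.hybrid_table, self.dangling_ends
        )

    def transition_state_energy(
        self, sequence: TemplateSequence, l: int, t: int = 0
    ) -> float:
        layout = transition_state_layout(sequence, l, t, self.geometry)
        return gibbs_basepairing(
            layout, sequence, self.dna_table, self.hybrid_table, self.dangling_ends
        )

    def landscape(self, sequence: TemplateSequence) -> "EnergyLandscape":
        return EnergyLandscape.from_sequence(sequence, self)


@dataclass(frozen=True)
class EnergyLandscape:
    """Per-site basepairing energies along a template.

    Arrays are indexed by site ``l`` in ``[l0, L-1]`` (``sites[i] = l0 + i``):
    ``dG_pre``/``dG_post`` are the basepairing energies of S(l,0)/S(l,1) and
    ``dG_ts`` that of the translocation transition state T(l,0), all in k_B*T
    within the site's shared local window.
    """

    sites: np.ndarray
    dG_pre: np.ndarray
    dG_post: np.ndarray
    dG_ts: np.ndarray
    l0: int
    length: int

    @classmethod
    def from_sequence(
        cls, sequence: TemplateSequence, model: EnergyModel
    ) -> "EnergyLandscape":
        g = model.geometry
        if sequence.length < g.l0 + 1:
            raise ValueError(
                f"template of length {sequence.length} shorter than l0+1={g.l0 + 1}"
            )
        sites = np.arange(g.l0, sequence.length)
        pre = np.empty(sites.size)
        post = np.empty(sites.size)
        ts = np.empty(sites.size)
        for i, l in enumerate(sites):
            pre[i] = model.state_energy(sequence, int(l), 0)
            post[i] = model.state_energy(sequence, int(l), 1)
            ts[i] = model.transition_state_energy(sequence, int(l), 0)
        return cls(sites, pre, post, ts, g.l0, sequence.length)

    @property
    def n_sites(self) -> int:
        return int(self.sites.size)
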