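"""File formats: FASTA templates, TSV datasets and traces, YAML run config.

Units are fixed by convention (pN, uM, bp/s, k_B*T, Angstrom); there is no
unit autodetection.  NTP concentrations in dataset files are either a scalar
(broadcast to all four NTPs) or a per-base spec like ``A=5;C=2.5;G=10;U=10``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from Bio import SeqIO

from .energetics import TemplateSequence
from .inference import ObservedDataset, PosteriorTrace
from .kinetics import PARAMETER_NAMES, Condition


class FormatError(ValueError):
    pass


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path, record_id: Optional[str] = None) -> TemplateSequence:
    """First (or named) record as a coding-strand template; lowercase input
    is uppercased and U is mapped back to T with a warning."""
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records")
    if record_id is not None:
        matches = [r for r in records if r.id == record_id]
        if not matches:
            raise FormatError(f"{path}: no record with id {record_id!r}")
        rec = matches[0]
    else:
        rec = records[0]
    seq = str(rec.seq).upper()
    if "U" in seq:
        warnings.warn(f"{path}: U bases mapped to T in record {rec.id!r}")
        seq = seq.replace("U", "T")
    try:
        return TemplateSequence(rec.id, seq)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_fasta(sequence: TemplateSequence, path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{sequence.identifier}\n")
        for i in range(0, sequence.length, 70):
            fh.write(sequence.bases[i : i + 70] + "\n")


# ---------------------------------------------------------------------------
# NTP specs and datasets


def parse_ntp_spec(spec: str) -> dict[str, float]:
    spec = spec.strip()
    if "=" not in spec:
        return {b: float(spec) for b in "ACGU"}
    out: dict[str, float] = {}
    for part in spec.split(";"):
        key, _, val = part.partition("=")
        key = key.strip().upper()
        if key not in "ACGU" or not key:
            raise FormatError(f"bad NTP spec component {part!r}")
        out[key] = float(val)
    missing = set("ACGU") - set(out)
    if missing:
        raise FormatError(f"NTP spec {spec!r} missing {sorted(missing)}")
    return out


def format_ntp_spec(ntp) -> str:
    vals = {b: float(ntp[b]) for b in "ACGU"}
    if len(set(vals.values())) == 1:
        return f"{next(iter(vals.values())):g}"
    return ";".join(f"{b}={vals[b]:g}" for b in "ACGU")


DATASET_COLUMNS = ("force_pN", "ntp_spec", "velocity_bp_s")


def read_dataset(path, enzyme: str = "rnap") -> ObservedDataset:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    conditions, velocities = [], []
    for i, row in df.iterrows():
        line = i + 2  # header is line 1
        try:
            force = float(row["force_pN"])
            ntp = parse_ntp_spec(str(row["ntp_spec"]))
            vel = float(row["velocity_bp_s"])
        except (ValueError, FormatError) as exc:
            raise FormatError(f"{path}, line {line}: {exc}") from exc
        conditions.append(Condition.make(force, ntp))
        velocities.append(vel)
    try:
        return ObservedDataset(tuple(conditions), np.array(velocities), enzyme)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_dataset(dataset: ObservedDataset, path) -> None:
    rows = [
        {
            "force_pN": f"{c.force:g}",
            "ntp_spec": format_ntp_spec(c.ntp),
            "velocity_bp_s": f"{v:.6g}",
        }
        for c, v in zip(dataset.conditions, dataset.velocities)
    ]
    pd.DataFrame(rows, columns=DATASET_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# traces

TRACE_COLUMNS = ("chain", "iteration", "model", *PARAMETER_NAMES, "X2")


def write_trace(traces: Sequence[PosteriorTrace] | pd.DataFrame, path) -> None:
    if isinstance(traces, pd.DataFrame):
        df = traces
    else:
        df = pd.concat([t.samples for t in traces], ignore_index=True)
    df.loc[:, TRACE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_trace(path) -> list[PosteriorTrace]:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = set(TRACE_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for _, sub in df.groupby("chain", sort=True):
        out.append(PosteriorTrace(sub.reset_index(drop=True), 0, 1, 0))
    return out


def write_propensities(reactions, path) -> None:
    """Debugging dump of a state's outbound reactions as TSV."""
    rows = [
        {
            "reaction": r.label,
            "rate_per_s": r.rate,
            "successor_l": r.successor[0],
            "successor_t": r.successor[1],
            "successor_bound": r.successor[2],
        }
        for r in reactions
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated inference run configuration; unknown keys are rejected."""

    enzyme: str = "rnap"
    epsilon: float = 2.39
    chains: int = 2
    length: int = 10_000
    replicates: int = 2
    seed: int = 0
    allowed_models: Optional[tuple[int, ...]] = None
    model_move_probability: float = 0.25
    burn_in_fraction: float = 0.1
    target_retained: int = 1000

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise FormatError(f"{path}: unknown config keys {sorted(unknown)}")
        if "allowed_models" in raw and raw["allowed_models"] is not None:
            raw["allowed_models"] = tuple(int(m) for m in raw["allowed_models"])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            d = asdict(self)
            if d["allowed_models"] is not None:
                d["allowed_models"] = list(d["allowed_models"])
            yaml.safe_dump(d, fh, sort_keys=False)


#: ABC thresholds used in the original analyses; tied to that analysis'
#: distance definition and chain scale, so treat as order-of-magnitude
#: defaults rather than transferable constants.
DEFAULT_EPSILON = {"rnap": 2.39, "polii": 0.705, "t7": 4.63}


def write_run_log(path, **fields) -> None:
    """Reproducibility sidecar: versions, seeds and timings as JSON."""
    import numba
    import scipy

    info = {
        "numpy": np.__version__,
        "scipy": scipy.__version__,
        "pandas": pd.__version__,
        "numba": numba.__version__,
    }
    info.update({k: v for k, v in fields.items()})
    with open(path, "w") as fh:
        json.dump(info, fh, indent=2, default=str)
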