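"""Abraham solvation model (pp-LFER) evaluation.

A phase system is one calibrated LFER equation

    log10 K = c + e*E + s*S + a*A + b*B + v*V (+ l*L)

pairing phase-specific system coefficients (lower case) with solute
descriptors (upper case).  Phase-water K values carry L/kg; phase-air
values are dimensionless.  Phases calibrated only against air (e.g.
polyurethane ester) reach the water side through a thermodynamic cycle
with an air-water equation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, replace
from io import StringIO
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_data import AbrahamDescriptors, ChemicalSet
from .errors import (
    DescriptorMissingError,
    PartitionError,
    RegistryError,
    SchemaError,
)

_COEFF_NAMES = ("c", "e", "s", "a", "b", "v", "l")
_REGISTRY_COLUMNS = ("phase", "counter_medium") + _COEFF_NAMES + ("provenance",)


@dataclass(frozen=True)
class PhaseSystem:
    """One calibrated LFER equation for a (phase, counter medium) pair.

    ``counter_medium`` is ``"water"`` (K = C_phase/C_water, L/kg) or
    ``"air"`` (K = C_phase/C_air).  ``v`` or ``l`` may be absent when the
    calibration never uses the paired descriptor, but not both.
    """

    phase: str
    counter_medium: str
    c: float
    e: float
    s: float
    a: float
    b: float
    v: float | None = None
    l: float | None = None
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.counter_medium not in ("water", "air"):
            raise RegistryError(
                f"counter_medium must be 'water' or 'air', got {self.counter_medium!r}"
            )
        if self.v is None and self.l is None:
            raise RegistryError(
                f"system {self.phase}-{self.counter_medium}: at least one of v, l required"
            )
        for name in _COEFF_NAMES:
            value = getattr(self, name)
            if value is not None and not math.isfinite(value):
                raise RegistryError(
                    f"system {self.phase}-{self.counter_medium}: coefficient {name} not finite"
                )

    @property
    def key(self) -> tuple[str, str]:
        return (self.phase, self.counter_medium)


def evaluate_lfer(d: AbrahamDescriptors, system: PhaseSystem) -> float:
    """log10 K of one solute in one phase system; pure function of its inputs."""
    value = (
        system.c
        + system.e * d.E
        + system.s * d.S
        + system.a * d.A
        + system.b * d.B
    )
    if system.v is not None:
        value += system.v * d.V
    if system.l is not None:
        if d.L is None:
            raise DescriptorMissingError(
                f"system {system.phase}-{system.counter_medium} needs descriptor L"
            )
        value += system.l * d.L
    return value


def compose_cycle(logk_phase_air: float, logk_air_water: float) -> float:
    """Thermodynamic cycle: log K_phase-water = log K_phase-air + log K_air-water.

    ``logk_air_water`` is oriented as C_air/C_water.
    """
    if not (math.isfinite(logk_phase_air) and math.isfinite(logk_air_water)):
        raise ValueError("cycle inputs must be finite")
    return logk_phase_air + logk_air_water


@dataclass(frozen=True)
class PartitionTable:
    """Chemicals (rows) x phases (columns) matrix of log10 K values.

    ``cycle_derived`` names the columns obtained through a thermodynamic
    cycle rather than a direct phase-water calibration.
    """

    frame: pd.DataFrame
    cycle_derived: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.frame.isna().any().any():
            raise PartitionError(
                [
                    (str(idx), str(col), "missing value")
                    for idx, col in zip(*np.where(self.frame.isna().to_numpy()))
                ]
            )
        if self.frame.index.has_duplicates or self.frame.columns.has_duplicates:
            raise RegistryError("partition table labels must be unique")
        object.__setattr__(self, "cycle_derived", tuple(self.cycle_derived))

    @property
    def phases(self) -> tuple[str, ...]:
        return tuple(self.frame.columns)

    def column(self, phase: str) -> np.ndarray:
        return self.frame[phase].to_numpy(dtype=float)

    def to_csv(self, path: str | Path, sidecar: str | Path | None = None) -> None:
        """Write the matrix as CSV plus a JSON sidecar flagging cycle columns."""
        path = Path(path)
        self.frame.to_csv(path, index_label="id")
        sidecar = Path(sidecar) if sidecar else path.with_suffix(".meta.json")
        sidecar.write_text(
            json.dumps({"cycle_derived": list(self.cycle_derived)}, indent=2) + "\n"
        )


def build_partition_table(
    cset: ChemicalSet,
    systems: Sequence[PhaseSystem],
    cycles: Mapping[str, tuple[PhaseSystem, PhaseSystem]] | None = None,
) -> PartitionTable:
    """Evaluate every requested (chemical, phase) cell.

    ``systems`` are evaluated directly; ``cycles`` maps a phase name to a
    (phase-air system, air-water system) pair composed via
    :func:`compose_cycle`.  Any failing cell aborts with a
    :class:`PartitionError` reporting all failing pairs.
    """
    cycles = dict(cycles or {})
    failures: list[tuple[str, str, str]] = []
    columns: dict[str, list[float]] = {}

    for system in systems:
        col: list[float] = []
        for rec in cset:
            try:
                col.append(evaluate_lfer(rec.descriptors, system))
            except DescriptorMissingError as exc:
                failures.append((rec.id, system.phase, str(exc)))
                col.append(math.nan)
        columns[system.phase] = col

    for phase, (phase_air, air_water) in cycles.items():
        if phase_air.counter_medium != "air":
            raise RegistryError(
                f"cycle for {phase!r}: first system must be phase-air"
            )
        if not (air_water.phase == "air" and air_water.counter_medium == "water"):
            raise RegistryError(
                f"cycle for {phase!r}: second system must be air-water"
            )
        col = []
        for rec in cset:
            try:
                col.append(
                    compose_cycle(
                        evaluate_lfer(rec.descriptors, phase_air),
                        evaluate_lfer(rec.descriptors, air_water),
                    )
                )
            except DescriptorMissingError as exc:
                failures.append((rec.id, phase, str(exc)))
                col.append(math.nan)
        columns[phase] = col

    if failures:
        raise PartitionError(failures)

    frame = pd.DataFrame(columns, index=pd.Index(cset.ids, name="id"))
    return PartitionTable(frame=frame, cycle_derived=tuple(cycles))


def _coeff_or_none(raw: object) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, str):
        raw = raw.strip()
        if raw == "":
            return None
        return float(raw)
    if isinstance(raw, float) and math.isnan(raw):
        return None
    return float(raw)


def _normalize(system: PhaseSystem) -> PhaseSystem:
    # A water-air row is the inverse orientation of air-water; flip signs so
    # downstream code sees only the C_air/C_water convention.
    if system.phase == "water" and system.counter_medium == "air":
        flipped = {
            name: (-getattr(system, name) if getattr(system, name) is not None else None)
            for name in _COEFF_NAMES
        }
        note = (system.provenance + " " if system.provenance else "") + "(inverted from water-air)"
        return PhaseSystem(
            phase="air", counter_medium="water", provenance=note, **flipped
        )
    return system


def load_system_registry(source: str | Path | IO[str]) -> list[PhaseSystem]:
    """Load a phase-system registry from TSV or JSON.

    JSON is a list of objects; TSV has the columns ``phase``,
    ``counter_medium``, ``c e s a b v l`` (blank allowed for v/l) and
    ``provenance``.  Water-air rows are normalized to air-water by sign
    flip, recorded in the provenance.  Duplicate (phase, counter_medium)
    pairs are rejected.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = Path(source).read_text()
    stripped = text.lstrip()
    if stripped.startswith("[") or stripped.startswith("{"):
        raw_rows = json.loads(text)
        if isinstance(raw_rows, dict):
            raw_rows = [raw_rows]
    else:
        frame = pd.read_csv(
            StringIO(text), sep="\t", dtype=str, keep_default_na=False, comment="#"
        )
        missing = [c for c in ("phase", "counter_medium", "c", "e", "s", "a", "b") if c not in frame.columns]
        if missing:
            raise SchemaError(f"registry missing column(s): {', '.join(missing)}")
        raw_rows = frame.to_dict(orient="records")

    systems: list[PhaseSystem] = []
    seen: set[tuple[str, str]] = set()
    for row in raw_rows:
        coeffs = {}
        for name in _COEFF_NAMES:
            if name not in row and name not in ("v", "l"):
                raise SchemaError(f"registry row for {row.get('phase')!r} missing coefficient {name!r}")
            try:
                coeffs[name] = _coeff_or_none(row.get(name))
            except ValueError as exc:
                raise RegistryError(
                    f"registry row for {row.get('phase')!r}: bad {name} value {row.get(name)!r}"
                ) from exc
        for name in ("c", "e", "s", "a", "b"):
            if coeffs[name] is None:
                raise SchemaError(
                    f"registry row for {row.get('phase')!r} missing coefficient {name!r}"
                )
        system = _normalize(
            PhaseSystem(
                phase=str(row["phase"]).strip(),
                counter_medium=str(row["counter_medium"]).strip(),
                provenance=str(row.get("provenance", "") or "").strip(),
                **coeffs,
            )
        )
        if system.key in seen:
            raise RegistryError(
                f"duplicate system ({system.phase}, {system.counter_medium}) in registry"
            )
        seen.add(system.key)
        systems.append(system)
    return systems


def write_system_registry(
    systems: Iterable[PhaseSystem], sink: str | Path | IO[str], fmt: str = "tsv"
) -> None:
    """Write systems as TSV (default) or JSON; round-trips with the loader."""
    rows = []
    for system in systems:
        row = {"phase": system.phase, "counter_medium": system.counter_medium}
        for name in _COEFF_NAMES:
            value = getattr(system, name)
            row[name] = "" if value is None else repr(float(value))
        row["provenance"] = system.provenance
        rows.append(row)
    if fmt == "json":
        payload = json.dumps(
            [
                {k: (float(v) if k in _COEFF_NAMES and v != "" else v) for k, v in row.items()}
                for row in rows
            ],
            indent=2,
        ) + "\n"
        if hasattr(sink, "write"):
            sink.write(payload)
        else:
            Path(sink).write_text(payload)
        return
    frame = pd.DataFrame(rows, columns=list(_REGISTRY_COLUMNS))
    frame.to_csv(sink, sep="\t", index=False)


def index_systems(systems: Sequence[PhaseSystem]) -> dict[tuple[str, str], PhaseSystem]:
    """(phase, counter_medium) -> system lookup with duplicate detection."""
    out: dict[tuple[str, str], PhaseSystem] = {}
    for system in systems:
        if system.key in out:
            raise RegistryError(f"duplicate system {system.key}")
        out[system.key] = system
    return out


def resolve_phase(
    systems: Sequence[PhaseSystem], phase: str
) -> tuple[PhaseSystem | None, tuple[PhaseSystem, PhaseSystem] | None]:
    """Find how ``phase`` reaches the water side in a registry.

    Returns ``(direct_system, None)`` when a phase-water calibration
    exists, otherwise ``(None, (phase_air, air_water))`` when the
    thermodynamic cycle is available.
    """
    index = index_systems(systems)
    direct = index.get((phase, "water"))
    if direct is not None:
        return direct, None
    phase_air = index.get((phase, "air"))
    air_water = index.get(("air", "water"))
    if phase_air is not None and air_water is not None:
        return None, (phase_air, air_water)
    raise RegistryError(
        f"phase {phase!r}: no phase-water system and no (phase-air, air-water) cycle in registry"
    )
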