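"""Domain types and validated I/O for chemical sets.

A chemical set is a table of solutes, each carrying experimental Abraham
solute descriptors (E, S, A, B, V and optionally L), an optional acute
fish toxicity value (log10 LC50 in mol/L) and a mode-of-action group.
Concentration conventions are fixed package-wide: LC50 in mol/L,
phase-bound concentrations in mol/kg, every "log" is log10.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping

import pandas as pd

from .errors import SchemaError, TableParseError, TableValidationError

#: Recognized mode-of-action groups. ``less_inert`` covers polar narcotics;
#: ``reactive`` chemicals act covalently and defeat pure partitioning models.
MOA_GROUPS = ("baseline", "less_inert", "reactive", "unknown")

#: Canonical column names of the chemical-table CSV schema.
CANONICAL_COLUMNS = (
    "id",
    "name",
    "E",
    "S",
    "A",
    "B",
    "V",
    "L",
    "log_lc50_mol_L",
    "moa",
)

_REQUIRED_COLUMNS = ("id", "E", "S", "A", "B", "V")
_NUMERIC_COLUMNS = ("E", "S", "A", "B", "V", "L", "log_lc50_mol_L")


def _require_finite(name: str, value: float) -> None:
    if not math.isfinite(value):
        raise TableValidationError(f"descriptor {name} must be finite, got {value!r}")


@dataclass(frozen=True)
class AbrahamDescriptors:
    """Abraham solute descriptors of one chemical.

    E: excess molar refraction; S: dipolarity/polarizability; A: H-bond
    acidity; B: H-bond basicity; V: McGowan volume (cm3/mol / 100);
    L: log hexadecane-air partition coefficient, needed only for
    phase-air systems and therefore optional.
    """

    E: float
    S: float
    A: float
    B: float
    V: float
    L: float | None = None

    def __post_init__(self) -> None:
        for name in ("E", "S", "A", "B", "V"):
            _require_finite(name, getattr(self, name))
        if self.V <= 0:
            raise TableValidationError(f"V must be positive, got {self.V!r}")
        if self.A < 0:
            raise TableValidationError(f"A must be nonnegative, got {self.A!r}")
        if self.B < 0:
            raise TableValidationError(f"B must be nonnegative, got {self.B!r}")
        if self.L is not None:
            _require_finite("L", self.L)


@dataclass(frozen=True)
class ChemicalRecord:
    """One chemical: identifiers, descriptors, optional toxicity, MOA group."""

    id: str
    descriptors: AbrahamDescriptors
    name: str = ""
    log_lc50: float | None = None
    moa: str = "unknown"

    def __post_init__(self) -> None:
        if not self.id:
            raise TableValidationError("chemical id must be a non-empty string")
        if self.moa not in MOA_GROUPS:
            raise TableValidationError(
                f"moa {self.moa!r} not one of {MOA_GROUPS} (chemical {self.id})"
            )
        if self.log_lc50 is not None and not math.isfinite(self.log_lc50):
            raise TableValidationError(
                f"log_lc50 must be finite when present (chemical {self.id})"
            )


@dataclass(frozen=True)
class ChemicalSet:
    """An ordered, non-empty collection of chemicals with unique ids."""

    label: str
    records: tuple[ChemicalRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        if not self.records:
            raise TableValidationError(f"chemical set {self.label!r} is empty")
        seen: dict[str, int] = {}
        dups = []
        for rec in self.records:
            seen[rec.id] = seen.get(rec.id, 0) + 1
        dups = sorted(cid for cid, k in seen.items() if k > 1)
        if dups:
            raise TableValidationError(
                f"duplicate chemical id(s) in set {self.label!r}: {', '.join(dups)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[ChemicalRecord]:
        return iter(self.records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(rec.id for rec in self.records)

    def log_lc50_values(self) -> list[float | None]:
        return [rec.log_lc50 for rec in self.records]

    def subset(self, moa: str, label: str | None = None) -> "ChemicalSet":
        """Records belonging to one mode-of-action group, order preserved."""
        recs = tuple(r for r in self.records if r.moa == moa)
        return ChemicalSet(label or f"{self.label}:{moa}", recs)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            d = rec.descriptors
            rows.append(
                {
                    "id": rec.id,
                    "name": rec.name,
                    "E": d.E,
                    "S": d.S,
                    "A": d.A,
                    "B": d.B,
                    "V": d.V,
                    "L": d.L,
                    "log_lc50_mol_L": rec.log_lc50,
                    "moa": rec.moa,
                }
            )
        return pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))


def _parse_cell(raw: str, row: int, column: str) -> float | None:
    raw = raw.strip()
    if raw == "":
        return None
    try:
        value = float(raw)
    except ValueError as exc:
        raise TableParseError(
            f"row {row}, column {column!r}: cannot parse {raw!r} as a number"
        ) from exc
    return value


def load_chemical_table(
    source: str | IO[str],
    column_map: Mapping[str, str] | None = None,
    delimiter: str = ",",
    label: str = "chemicals",
) -> ChemicalSet:
    """Read a delimited chemical table into a validated :class:`ChemicalSet`.

    ``column_map`` maps canonical names (see :data:`CANONICAL_COLUMNS`) to
    the actual header names in ``source``; identity by default.  Row order
    is preserved; malformed numeric cells are reported with 1-based data
    row numbers.
    """
    frame = pd.read_csv(source, sep=delimiter, dtype=str, keep_default_na=False)
    column_map = dict(column_map or {})
    resolve = {canon: column_map.get(canon, canon) for canon in CANONICAL_COLUMNS}

    missing = [resolve[c] for c in _REQUIRED_COLUMNS if resolve[c] not in frame.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    records = []
    for pos, (_, row) in enumerate(frame.iterrows(), start=1):
        values: dict[str, float | None] = {}
        for canon in _NUMERIC_COLUMNS:
            col = resolve[canon]
            values[canon] = _parse_cell(row[col], pos, col) if col in frame.columns else None
        for canon in ("E", "S", "A", "B", "V"):
            if values[canon] is None:
                raise TableParseError(
                    f"row {pos}, column {resolve[canon]!r}: required value is empty"
                )
        cid = row[resolve["id"]].strip()
        name = row[resolve["name"]].strip() if resolve["name"] in frame.columns else ""
        moa_col = resolve["moa"]
        moa = row[moa_col].strip() if moa_col in frame.columns and row[moa_col].strip() else "unknown"
        try:
            descriptors = AbrahamDescriptors(
                E=values["E"], S=values["S"], A=values["A"], B=values["B"],
                V=values["V"], L=values["L"],
            )
            record = ChemicalRecord(
                id=cid,
                name=name,
                descriptors=descriptors,
                log_lc50=values["log_lc50_mol_L"],
                moa=moa,
            )
        except TableValidationError as exc:
            raise TableValidationError(f"row {pos}: {exc}") from exc
        records.append(record)

    return ChemicalSet(label, tuple(records))


def _fmt(value: float | None) -> str:
    return "" if value is None else repr(float(value))


def write_chemical_table(
    cset: ChemicalSet, sink: str | IO[str], delimiter: str = ","
) -> int:
    """Write ``cset`` in the canonical schema; returns the data row count.

    Floats are written with ``repr`` so a load/write/load round-trip is
    the identity bit-for-bit.
    """
    rows = []
    for rec in cset.records:
        d = rec.descriptors
        rows.append(
            {
                "id": rec.id,
                "name": rec.name,
                "E": _fmt(d.E),
                "S": _fmt(d.S),
                "A": _fmt(d.A),
                "B": _fmt(d.B),
                "V": _fmt(d.V),
                "L": _fmt(d.L),
                "log_lc50_mol_L": _fmt(rec.log_lc50),
                "moa": rec.moa,
            }
        )
    frame = pd.DataFrame(rows, columns=list(CANONICAL_COLUMNS))
    frame.to_csv(sink, sep=delimiter, index=False)
    return len(rows)
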