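"""Toxic units and risk quotients from plastic-bound concentrations.

A toxic unit (TU) is exposure over effect concentration: C_w/LC50 on the
water side, or equivalently C_plastic/C_crit on the plastic side at
partition equilibrium.  TUs of same-mode components are additive; the
mixture sum converts to a screening risk quotient through a regulatory
assessment factor (REACH: 1000 freshwater, 10000 marine).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, MixedModeWarning, SchemaError

#: Named assessment-factor presets (REACH acute-to-PNEC factors).
ASSESSMENT_FACTORS: Mapping[str, float] = {"freshwater": 1000.0, "marine": 10000.0}

#: Orientation of the RQ equation.  PNEC = acute / AF, so RQ = C/PNEC
#: amounts to AF x TU; flip only if a registry-specific convention demands it.
RQ_IS_AF_TIMES_TU = True

_MIXTURE_COLUMNS = ("chemical_id", "phase")


def toxic_unit_water(c_w: float, lc50: float) -> float:
    """TU from a freely dissolved concentration and LC50 (both mol/L)."""
    if lc50 <= 0:
        raise DataError(f"lc50 must be positive, got {lc50!r}")
    if c_w < 0:
        raise DataError(f"c_w must be nonnegative, got {c_w!r}")
    return c_w / lc50


def toxic_unit_plastic(c_plastic: float, c_crit: float) -> float:
    """TU from a plastic-bound concentration and critical burden (both mol/kg).

    At partition equilibrium (C_plastic = K * C_w, C_crit = K * LC50)
    this equals :func:`toxic_unit_water` exactly.
    """
    if c_crit <= 0:
        raise DataError(f"c_crit must be positive, got {c_crit!r}")
    if c_plastic < 0:
        raise DataError(f"c_plastic must be nonnegative, got {c_plastic!r}")
    return c_plastic / c_crit


def sum_toxic_units(
    tus: Sequence[float], moa_groups: Sequence[str] | None = None
) -> float:
    """Arithmetic TU sum; warns (never blocks) on mixed-mode mixtures.

    TU additivity is established for baseline (same-mode) toxicants; a
    mixture spanning modes still sums but with a :class:`MixedModeWarning`.
    """
    arr = np.asarray(list(tus), dtype=float)
    if arr.size and (arr < 0).any():
        raise DataError("toxic units must be nonnegative")
    if moa_groups is not None:
        groups = {g for g in moa_groups if g != "unknown"}
        if len(groups) > 1:
            warnings.warn(
                f"summing toxic units across modes of action: {sorted(groups)}; "
                "TU additivity is established for same-mode (baseline) mixtures",
                MixedModeWarning,
                stacklevel=2,
            )
    return float(arr.sum())


def resolve_assessment_factor(af: float | str) -> float:
    """Accept a number or a preset name ('freshwater', 'marine')."""
    if isinstance(af, str):
        try:
            af = ASSESSMENT_FACTORS[af]
        except KeyError as exc:
            raise DataError(
                f"unknown assessment-factor preset {af!r}; "
                f"known: {sorted(ASSESSMENT_FACTORS)}"
            ) from exc
    af = float(af)
    if af <= 0:
        raise DataError(f"assessment factor must be positive, got {af!r}")
    return af


def risk_quotient(sum_tu: float, af: float | str = "freshwater") -> float:
    """RQ = AF x sum(TU) (the acute-to-PNEC convention)."""
    af = resolve_assessment_factor(af)
    if sum_tu < 0:
        raise DataError(f"sum_tu must be nonnegative, got {sum_tu!r}")
    return af * sum_tu if RQ_IS_AF_TIMES_TU else sum_tu / af


@dataclass(frozen=True)
class MixtureAssessment:
    """Per-component TUs plus the mixture-level summary for one sample."""

    chemical_ids: tuple[str, ...]
    toxic_units: np.ndarray
    sum_tu: float
    assessment_factor: float
    risk_quotient: float
    phase: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"chemical_id": self.chemical_ids, "toxic_unit": self.toxic_units}
        )

    def summary(self) -> dict:
        return {
            "phase": self.phase,
            "n_components": len(self.chemical_ids),
            "sum_tu": self.sum_tu,
            "assessment_factor": self.assessment_factor,
            "risk_quotient": self.risk_quotient,
        }

    def to_json(self, path: str | Path) -> None:
        payload = dict(self.summary())
        payload["toxic_units"] = {
            cid: float(tu) for cid, tu in zip(self.chemical_ids, self.toxic_units)
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def assess_mixture(
    concentrations: Mapping[str, float],
    critical_burden: float | Mapping[str, float],
    af: float | str = "freshwater",
    moa: Mapping[str, str] | None = None,
    phase: str = "",
) -> MixtureAssessment:
    """Toxic units, their sum, and the risk quotient for one plastic sample.

    ``concentrations`` maps chemical id to plastic-bound concentration in
    mol/kg; ``critical_burden`` is one group-level C_crit (mol/kg) or a
    per-chemical mapping.
    """
    ids = tuple(concentrations)
    if not ids:
        return MixtureAssessment(
            chemical_ids=(), toxic_units=np.array([]), sum_tu=0.0,
            assessment_factor=resolve_assessment_factor(af),
            risk_quotient=0.0, phase=phase,
        )
    if isinstance(critical_burden, Mapping):
        missing = [cid for cid in ids if cid not in critical_burden]
        if missing:
            raise DataError(f"no critical burden for: {', '.join(missing)}")
        crits = [critical_burden[cid] for cid in ids]
    else:
        crits = [float(critical_burden)] * len(ids)
    tus = np.array(
        [toxic_unit_plastic(concentrations[cid], c) for cid, c in zip(ids, crits)]
    )
    groups = [moa.get(cid, "unknown") for cid in ids] if moa else None
    total = sum_toxic_units(tus, moa_groups=groups)
    af_value = resolve_assessment_factor(af)
    return MixtureAssessment(
        chemical_ids=ids, toxic_units=tus, sum_tu=total,
        assessment_factor=af_value, risk_quotient=risk_quotient(total, af_value),
        phase=phase,
    )


def load_mixture_table(source: str | Path | IO[str]) -> pd.DataFrame:
    """Read a mixture CSV: chemical_id, phase, c_plastic_mol_per_kg
    (or c_w_mol_per_L for water-side input)."""
    frame = pd.read_csv(source)
    missing = [c for c in _MIXTURE_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"mixture table missing column(s): {', '.join(missing)}")
    if "c_plastic_mol_per_kg" not in frame.columns and "c_w_mol_per_L" not in frame.columns:
        raise SchemaError(
            "mixture table needs c_plastic_mol_per_kg or c_w_mol_per_L"
        )
    return frame
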