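"""Synthetic chemical sets, phase registries, and mixtures.

The generator emulates the statistical structure the target-phase model
assumes: three mode-of-action groups (baseline n=115, less-inert n=73,
reactive n=75), toxicity linear in hydrophobicity with a fixed critical
burden, Gaussian residual scatter of 0.32 log units, hydrophobicity
spanning six orders of magnitude, and a positive excess-toxicity offset
for reactive chemicals that partitioning-only models cannot capture.

Descriptors are sampled and log K is then computed through the real LFER
engine, so the full pipeline path is exercised; log K is steered into the
requested range by solving the LFER equation for the McGowan volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .chem_data import AbrahamDescriptors, ChemicalRecord, ChemicalSet
from .errors import DataError
from .lfer_engine import PhaseSystem, evaluate_lfer

_GROUPS = ("baseline", "less_inert", "reactive")

#: Sampling ranges for random phase-water system coefficients.  Shaped
#: like hydrophobic organic phases: large positive cavity term v, strongly
#: negative H-bond terms a and b.
SYSTEM_COEFF_RANGES: Mapping[str, tuple[float, float]] = {
    "c": (-0.5, 0.5),
    "e": (0.0, 1.2),
    "s": (-1.5, 0.5),
    "a": (-3.5, -0.5),
    "b": (-4.5, -1.0),
    "v": (2.0, 4.5),
}


def _default_counts() -> dict[str, int]:
    return {"baseline": 115, "less_inert": 73, "reactive": 75}


def _default_burdens() -> dict[str, float]:
    # -log10 C_crit (mol/kg) per group: ~108.5 mmol/kg for baseline
    # narcotics, ~46.3 mmol/kg for polar narcotics; reactive chemicals
    # start from the baseline burden and add the excess-toxicity offset.
    return {"baseline": 0.96, "less_inert": 1.33, "reactive": 0.96}


def _default_slopes() -> dict[str, float]:
    return {"baseline": 1.0, "less_inert": 1.0, "reactive": 1.0}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic data draw.

    residual_sd is the Gaussian scatter of log LC50 around the linear
    burden model, in log10 units; logk_range is the hydrophobicity span
    (log K against the reference phase); reactive_excess_toxicity is the
    (mean, sd) of the nonnegative extra -log LC50 offset applied to
    reactive chemicals.
    """

    n_per_group: Mapping[str, int] = field(default_factory=_default_counts)
    true_neg_log_burden: Mapping[str, float] = field(default_factory=_default_burdens)
    slope: Mapping[str, float] = field(default_factory=_default_slopes)
    residual_sd: float = 0.32
    logk_range: tuple[float, float] = (1.0, 7.0)
    reactive_excess_toxicity: tuple[float, float] = (2.0, 0.7)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_group.values()):
            raise DataError("group counts must be nonnegative")
        if self.residual_sd < 0:
            raise DataError("residual_sd must be nonnegative")
        lo, hi = self.logk_range
        if not lo < hi:
            raise DataError("logk_range must be a nonempty interval")


def generate_system(
    seed: int, phase: str = "synthetic_polymer", counter_medium: str = "water"
) -> PhaseSystem:
    """One random, reproducible phase system within documented ranges."""
    rng = np.random.default_rng(seed)
    coeffs = {
        name: float(rng.uniform(lo, hi)) for name, (lo, hi) in SYSTEM_COEFF_RANGES.items()
    }
    return PhaseSystem(
        phase=phase, counter_medium=counter_medium,
        provenance=f"synthetic (seed={seed})", **coeffs,
    )


def generate_registry(
    seed: int, phases: Sequence[str] | int = 6
) -> list[PhaseSystem]:
    """A registry of random phase-water systems with distinct names."""
    if isinstance(phases, int):
        phases = [f"polymer_{i + 1}" for i in range(phases)]
    children = np.random.SeedSequence(seed).spawn(len(phases))
    return [
        generate_system(int(child.generate_state(1)[0] % 2**31), phase=name)
        for name, child in zip(phases, children)
    ]


def _sample_descriptors(
    rng: np.random.Generator, system: PhaseSystem, target_logk: float
) -> AbrahamDescriptors:
    # Sample the polar descriptors, then solve the LFER equation for V so
    # the record lands on the requested hydrophobicity.  Resample when the
    # implied volume is unphysical (V <= 0.05).
    if system.v is None or system.v == 0:
        raise DataError("generator needs a system with a nonzero v coefficient")
    for _ in range(100):
        e_d = float(rng.uniform(0.0, 1.5))
        s_d = float(rng.uniform(0.0, 1.7))
        a_d = float(rng.uniform(0.0, 1.0))
        b_d = float(rng.uniform(0.0, 1.2))
        l_d = float(rng.uniform(1.0, 9.0))
        numer = (
            target_logk
            - system.c
            - system.e * e_d
            - system.s * s_d
            - system.a * a_d
            - system.b * b_d
        )
        if system.l is not None:
            numer -= system.l * l_d
        volume = numer / system.v
        if volume > 0.05:
            return AbrahamDescriptors(E=e_d, S=s_d, A=a_d, B=b_d, V=volume, L=l_d)
    raise DataError(
        f"could not place a record at logK={target_logk:.2f} on system {system.phase}"
    )


def default_system_for(cfg: SyntheticConfig) -> PhaseSystem:
    """The phase system :func:`generate_set` uses when none is supplied."""
    sys_seed = np.random.SeedSequence(cfg.seed).spawn(1 + len(_GROUPS))[0]
    return generate_system(int(sys_seed.generate_state(1)[0] % 2**31))


def generate_set(
    cfg: SyntheticConfig,
    system: PhaseSystem | None = None,
    label: str = "synthetic",
) -> tuple[ChemicalSet, dict]:
    """A chemical set drawn under ``cfg`` plus its generating truth record.

    log LC50 = -(true_neg_log_burden + slope * logK) + N(0, residual_sd),
    with reactive records additionally shifted down by a nonnegative
    excess-toxicity draw.  Fully reproducible from ``cfg.seed``.
    """
    root = np.random.SeedSequence(cfg.seed)
    _, *group_seeds = root.spawn(1 + len(_GROUPS))
    if system is None:
        system = default_system_for(cfg)

    prefixes = {"baseline": "bl", "less_inert": "li", "reactive": "rx"}
    records: list[ChemicalRecord] = []
    truth: dict = {
        "config": dataclasses.asdict(cfg),
        "system_phase": system.phase,
        "per_group": {},
    }
    for group, gseed in zip(_GROUPS, group_seeds):
        n = int(cfg.n_per_group.get(group, 0))
        if n == 0:
            continue
        rng = np.random.default_rng(gseed)
        beta0 = float(cfg.true_neg_log_burden[group])
        slope = float(cfg.slope.get(group, 1.0))
        targets = rng.uniform(*cfg.logk_range, size=n)
        noise = rng.normal(0.0, cfg.residual_sd, size=n) if cfg.residual_sd > 0 else np.zeros(n)
        if group == "reactive":
            mu, sd = cfg.reactive_excess_toxicity
            excess = np.maximum(rng.normal(mu, sd, size=n), 0.0)
        else:
            excess = np.zeros(n)
        logks, ids = [], []
        for i in range(n):
            descriptors = _sample_descriptors(rng, system, float(targets[i]))
            logk = evaluate_lfer(descriptors, system)  # through the real engine
            log_lc50 = -(beta0 + slope * logk) + float(noise[i]) - float(excess[i])
            cid = f"{prefixes[group]}-{i + 1:03d}"
            records.append(
                ChemicalRecord(
                    id=cid, name=f"{group} surrogate {i + 1}",
                    descriptors=descriptors, log_lc50=log_lc50, moa=group,
                )
            )
            logks.append(logk)
            ids.append(cid)
        truth["per_group"][group] = {
            "ids": ids,
            "logk": [float(v) for v in logks],
            "excess": [float(v) for v in excess],
            "true_neg_log_burden": beta0,
            "slope": slope,
        }
    return ChemicalSet(label, tuple(records)), truth


def generate_mixture(
    cset: ChemicalSet,
    logk: Sequence[float],
    seed: int,
    phase: str = "synthetic_polymer",
    fraction_range: tuple[float, float] = (0.05, 0.5),
    n_components: int | None = None,
) -> tuple[pd.DataFrame, dict]:
    """A plastic sample: per-chemical bound concentrations plus truth.

    Concentrations are sampled as fractions of each chemical's own
    critical burden, so the mixture's true TU sum equals the sum of the
    sampled fractions by construction.
    """
    logk = np.asarray(logk, dtype=float)
    if logk.shape != (len(cset),):
        raise DataError("logK column must align with the chemical set")
    if any(rec.log_lc50 is None for rec in cset):
        raise DataError("mixture generation needs log_lc50 for every record")
    rng = np.random.default_rng(seed)
    n = len(cset) if n_components is None else min(n_components, len(cset))
    picks = np.sort(rng.choice(len(cset), size=n, replace=False))
    rows, fractions = [], {}
    for idx in picks:
        rec = cset.records[idx]
        frac = float(rng.uniform(*fraction_range))
        c_crit = 10.0 ** (logk[idx] + rec.log_lc50)  # mol/kg
        rows.append(
            {
                "chemical_id": rec.id,
                "phase": phase,
                "c_plastic_mol_per_kg": frac * c_crit,
            }
        )
        fractions[rec.id] = frac
    frame = pd.DataFrame(rows, columns=["chemical_id", "phase", "c_plastic_mol_per_kg"])
    truth = {
        "fractions": fractions,
        "sum_tu": float(sum(fractions.values())),
        "critical_burdens_mol_per_kg": {
            cset.records[idx].id: float(10.0 ** (logk[idx] + cset.records[idx].log_lc50))
            for idx in picks
        },
    }
    return frame, truth
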