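"""Target Plastic / Target Lipid Model core.

The model relates acute fish toxicity to equilibrium partitioning into a
reference phase (a membrane lipid or a polymer):

    -log LC50 = -log C_crit + m * log K_phase-water

where C_crit (mol/kg) is the critical phase burden reached when the
freely dissolved concentration equals LC50.  This module computes
per-chemical burdens, calibrates group-level burdens by three methods
(fixed 100 mmol/kg, distribution median, regression intercept), predicts
LC50 from a calibrated burden, and scores predictions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .chem_data import ChemicalSet
from .errors import CalibrationError, DataError
from .lfer_engine import PartitionTable

#: Calibration methods for the group-level critical burden.
METHODS = ("fixed_100mmol", "median", "intercept")

#: 100 mmol/kg = 0.1 mol/kg, i.e. -log10 C_crit = 1.
FIXED_NEG_LOG_BURDEN = 1.0


def neg_log_to_mmol_per_kg(neg_log_burden: float) -> float:
    """Convert -log10 C_crit (mol/kg) to mmol/kg."""
    return 10.0 ** (-neg_log_burden) * 1000.0


@dataclass(frozen=True)
class BurdenEstimate:
    """A calibrated critical burden for one (phase, group, method).

    ``neg_log_burden`` is -log10 C_crit with C_crit in mol/kg.  The slope
    ``slope_m`` is 1 by definition for the fixed and median methods;
    standard errors and fit statistics are populated by the intercept
    (OLS) method only.
    """

    phase: str
    group: str
    method: str
    neg_log_burden: float
    n: int
    slope_m: float = 1.0
    se_intercept: float | None = None
    se_slope: float | None = None
    rmse_fit: float | None = None
    r2_fit: float | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise CalibrationError(f"unknown method {self.method!r}")
        if self.n < 1:
            raise CalibrationError("n must be >= 1")
        if self.method == "fixed_100mmol" and self.neg_log_burden != FIXED_NEG_LOG_BURDEN:
            raise CalibrationError(
                "fixed_100mmol estimates must carry neg_log_burden == 1.0"
            )
        for se in (self.se_intercept, self.se_slope):
            if se is not None and se < 0:
                raise CalibrationError("standard errors must be nonnegative")

    @property
    def critical_burden_mol_per_kg(self) -> float:
        return 10.0 ** (-self.neg_log_burden)

    @property
    def critical_burden_mmol_per_kg(self) -> float:
        return neg_log_to_mmol_per_kg(self.neg_log_burden)


def chemical_critical_burden(logk: float, log_lc50: float) -> float:
    """Per-chemical log10 C_crit (mol/kg) from log K and log LC50.

    Accepts scalars or numpy arrays.
    """
    out = np.asarray(logk, dtype=float) + np.asarray(log_lc50, dtype=float)
    return float(out) if out.ndim == 0 else out


def _aligned_arrays(
    cset: ChemicalSet, logk: Sequence[float], need_lc50: bool, drop_nonfinite: bool
) -> tuple[np.ndarray, np.ndarray, int]:
    logk = np.asarray(logk, dtype=float)
    if logk.shape != (len(cset),):
        raise DataError(
            f"logK column length {logk.shape} does not match set size {len(cset)}"
        )
    lc50_list = cset.log_lc50_values()
    if need_lc50 and any(v is None for v in lc50_list):
        missing = [rec.id for rec in cset if rec.log_lc50 is None]
        raise DataError(f"missing log_lc50 for: {', '.join(missing)}")
    lc50 = np.asarray(
        [math.nan if v is None else v for v in lc50_list], dtype=float
    )
    mask = np.isfinite(logk)
    if need_lc50:
        mask &= np.isfinite(lc50)
    dropped = int((~mask).sum())
    if dropped and not drop_nonfinite:
        bad = [cset.ids[i] for i in np.flatnonzero(~mask)]
        raise DataError(
            f"non-finite logK/LC50 for: {', '.join(bad)} "
            "(pass drop_nonfinite=True to drop with a report)"
        )
    return logk[mask], lc50[mask], dropped


def estimate_burden(
    cset: ChemicalSet,
    logk: Sequence[float],
    method: str,
    phase: str = "",
    group: str | None = None,
    drop_nonfinite: bool = False,
) -> BurdenEstimate:
    """Calibrate the group-level critical burden for one phase.

    fixed_100mmol assumes -log C_crit = 1 (the literature lipid value);
    median takes -median_i(logK_i + logLC50_i); intercept runs OLS of
    y = -log LC50 on x = log K and reads the burden off the intercept.
    """
    if method not in METHODS:
        raise CalibrationError(f"unknown method {method!r}; expected one of {METHODS}")
    group = group if group is not None else _infer_group(cset)

    if method == "fixed_100mmol":
        x, _, _ = _aligned_arrays(cset, logk, need_lc50=False, drop_nonfinite=drop_nonfinite)
        return BurdenEstimate(
            phase=phase, group=group, method=method,
            neg_log_burden=FIXED_NEG_LOG_BURDEN, n=len(x),
        )

    x, lc50, _ = _aligned_arrays(cset, logk, need_lc50=True, drop_nonfinite=drop_nonfinite)

    if method == "median":
        burdens = x + lc50
        return BurdenEstimate(
            phase=phase, group=group, method=method,
            neg_log_burden=float(-np.median(burdens)), n=len(x),
        )

    # intercept method: OLS of -log LC50 on log K
    if len(x) < 3:
        raise CalibrationError(f"intercept method needs n >= 3, got {len(x)}")
    y = -lc50
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    se_int, se_slope = fit.bse
    rmse = float(np.sqrt(fit.ssr / len(x)))
    return BurdenEstimate(
        phase=phase, group=group, method="intercept",
        neg_log_burden=float(intercept), slope_m=float(slope),
        se_intercept=float(se_int), se_slope=float(se_slope),
        rmse_fit=rmse, r2_fit=float(fit.rsquared), n=len(x),
    )


def _infer_group(cset: ChemicalSet) -> str:
    groups = {rec.moa for rec in cset}
    return groups.pop() if len(groups) == 1 else "mixed"


def fit_table1(
    sets: Mapping[str, ChemicalSet],
    table: PartitionTable,
    phases: Sequence[str] | None = None,
    drop_nonfinite: bool = False,
) -> list[BurdenEstimate]:
    """Intercept-method calibration for every (phase, group) combination.

    Mirrors the narcosis-regression table layout: one estimate per cell
    with intercept +- SE, slope +- SE, RMSE, R2 and n.
    """
    phases = list(phases) if phases is not None else list(table.phases)
    estimates = []
    for group, cset in sets.items():
        sub = table.frame.reindex(list(cset.ids))
        if sub.isna().any(axis=None):
            missing = sorted(set(cset.ids) - set(table.frame.index))
            raise DataError(
                f"group {group!r}: chemicals missing from partition table: {', '.join(missing)}"
            )
        for phase in phases:
            estimates.append(
                estimate_burden(
                    cset, sub[phase].to_numpy(dtype=float), "intercept",
                    phase=phase, group=group, drop_nonfinite=drop_nonfinite,
                )
            )
    return estimates


def estimates_to_frame(estimates: Sequence[BurdenEstimate]) -> pd.DataFrame:
    """Tabulate estimates with the narcosis-regression table's columns."""
    rows = [
        {
            "group": b.group,
            "phase": b.phase,
            "method": b.method,
            "neg_log_c_crit": b.neg_log_burden,
            "se_intercept": b.se_intercept,
            "slope_m": b.slope_m,
            "se_slope": b.se_slope,
            "rmse": b.rmse_fit,
            "r2": b.r2_fit,
            "n": b.n,
        }
        for b in estimates
    ]
    return pd.DataFrame(rows)


def predict_lc50(
    estimate: BurdenEstimate,
    logk: float | Sequence[float],
    slope_mode: str | None = None,
):
    """Predicted log10 LC50 (mol/L) from a calibrated burden and log K.

    ``slope_mode="unity"`` applies the model as derived
    (log LC50 = -neg_log_burden - logK); ``"fitted"`` uses the regression
    slope and is only defined for intercept estimates.  The default is
    unity for fixed/median estimates and fitted for intercept estimates.
    """
    if slope_mode is None:
        slope_mode = "fitted" if estimate.method == "intercept" else "unity"
    if slope_mode not in ("unity", "fitted"):
        raise CalibrationError(f"unknown slope_mode {slope_mode!r}")
    if slope_mode == "fitted" and estimate.method != "intercept":
        raise CalibrationError(
            "slope_mode='fitted' requires an intercept-method estimate"
        )
    logk_arr = np.asarray(logk, dtype=float)
    slope = estimate.slope_m if slope_mode == "fitted" else 1.0
    out = -(estimate.neg_log_burden + slope * logk_arr)
    return float(out) if np.isscalar(logk) else out


@dataclass(frozen=True)
class PredictionReport:
    """Per-chemical predictions plus summary accuracy statistics.

    ``residual`` is experimental - predicted in log10 units; ``rmse`` and
    ``bias`` are in log10 units; ``within_factor[N]`` is the fraction of
    chemicals with |residual| <= log10 N (inclusive).
    """

    ids: tuple[str, ...]
    predicted: np.ndarray
    experimental: np.ndarray
    residual: np.ndarray
    rmse: float
    bias: float
    r2: float
    within_factor: Mapping[int, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "predicted_log_lc50": self.predicted,
                "experimental_log_lc50": self.experimental,
                "residual": self.residual,
            }
        )

    def summary(self) -> dict:
        return {
            "n": len(self.ids),
            "rmse": self.rmse,
            "bias": self.bias,
            "r2": self.r2,
            "within_factor": {str(k): v for k, v in sorted(self.within_factor.items())},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.summary(), indent=2, sort_keys=True) + "\n")


def evaluate_predictions(
    predicted: Sequence[float],
    experimental: Sequence[float],
    ids: Sequence[str] | None = None,
    factors: Sequence[int] = (2, 3, 5),
) -> PredictionReport:
    """Score predicted against experimental log LC50 values."""
    pred = np.asarray(predicted, dtype=float)
    exp = np.asarray(experimental, dtype=float)
    if pred.shape != exp.shape or pred.ndim != 1 or pred.size == 0:
        raise DataError("predicted and experimental must be aligned non-empty vectors")
    if ids is None:
        ids = tuple(f"chem{i + 1}" for i in range(pred.size))
    ids = tuple(ids)
    if len(ids) != pred.size:
        raise DataError("ids length mismatch")
    residual = exp - pred
    rmse = float(np.sqrt(np.mean(residual**2)))
    bias = float(np.mean(residual))
    sstot = float(np.sum((exp - exp.mean()) ** 2))
    r2 = float(1.0 - np.sum(residual**2) / sstot) if sstot > 0 else math.nan
    within = {
        int(n): float(np.mean(np.abs(residual) <= math.log10(n))) for n in factors
    }
    return PredictionReport(
        ids=ids, predicted=pred, experimental=exp, residual=residual,
        rmse=rmse, bias=bias, r2=r2, within_factor=within,
    )


def burden_distribution(
    cset: ChemicalSet, logk: Sequence[float], drop_nonfinite: bool = False
) -> dict[str, float]:
    """Summary of the per-chemical log10 C_crit distribution (the PSD).

    The distribution of critical burdens over chemicals for one polymer
    plays the role a species sensitivity distribution plays across
    species — hence "plastic sensitivity distribution".
    """
    x, lc50, _ = _aligned_arrays(cset, logk, need_lc50=True, drop_nonfinite=drop_nonfinite)
    burdens = x + lc50
    return {
        "n": int(burdens.size),
        "min": float(burdens.min()),
        "q25": float(np.percentile(burdens, 25)),
        "median": float(np.median(burdens)),
        "mean": float(burdens.mean()),
        "q75": float(np.percentile(burdens, 75)),
        "max": float(burdens.max()),
    }
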