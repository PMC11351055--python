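"""Published reference values shipped with the package.

The narcosis-regression table (intercept-method fits of
-log LC50 = -log C_crit + m log K for eleven phases and three
mode-of-action groups) ships as package data; the critical-burden
intercepts support derived arithmetic such as the storage-lipid vs
phospholipid burden-overestimation factor.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .burden_model import BurdenEstimate
from .errors import DataError

_TABLE_FILE = "narcosis_regressions.csv"


def load_reported_regressions() -> pd.DataFrame:
    """The shipped table of published intercept-method regressions.

    Columns: group, phase, neg_log_c_crit, se_intercept, slope_m,
    se_slope, rmse, r2, n.
    """
    with resources.files("tpmtox.data").joinpath(_TABLE_FILE).open() as handle:
        return pd.read_csv(handle)


def reported_estimate(group: str, phase: str) -> BurdenEstimate:
    """One published regression row as a :class:`BurdenEstimate`."""
    table = load_reported_regressions()
    row = table[(table["group"] == group) & (table["phase"] == phase)]
    if row.empty:
        raise DataError(f"no reported regression for ({group!r}, {phase!r})")
    r = row.iloc[0]
    return BurdenEstimate(
        phase=phase, group=group, method="intercept",
        neg_log_burden=float(r["neg_log_c_crit"]),
        slope_m=float(r["slope_m"]),
        se_intercept=float(r["se_intercept"]),
        se_slope=float(r["se_slope"]),
        rmse_fit=float(r["rmse"]),
        r2_fit=float(r["r2"]),
        n=int(r["n"]),
    )


def burden_overestimation_factor(
    group: str, phase: str, reference_phase: str = "phospholipid"
) -> float:
    """Factor by which a surrogate phase's fitted critical burden
    understates/overstates the reference phase's, from published intercepts.

    Computed as 10**(intercept_surrogate - intercept_reference); e.g. the
    storage lipid overestimates the baseline critical lipid burden by a
    factor of ~3.6 relative to the phospholipid.
    """
    surrogate = reported_estimate(group, phase)
    reference = reported_estimate(group, reference_phase)
    return 10.0 ** (surrogate.neg_log_burden - reference.neg_log_burden)
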