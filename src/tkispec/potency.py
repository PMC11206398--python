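"""Potency transforms and structure-property correlation analysis.

Potency is handled throughout as the natural logarithm of IC50 expressed in
nM (smaller = more potent, so a more negative ln IC50 means a stronger
inhibitor). Descriptors — dipole moment of the global-minimum conformer,
crystal-pose spectral shift Δλmax — are related to ln IC50 with rank
statistics: with a five-compound halogen series, ranks are the statement the
data supports; no p-values are reported and no trend line is fit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "ln_ic50",
    "CorrelationReport",
    "correlate",
    "ShiftPotencySummary",
    "shift_potency_report",
]


def ln_ic50(ic50_nM: float) -> float:
    """Natural log of an IC50 given in nM; rejects non-positive input."""
    if ic50_nM <= 0:
        raise ValidationError(f"IC50 must be positive (nM), got {ic50_nM}")
    return math.log(ic50_nM)


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson/Spearman association between a descriptor and ln IC50.

    ``monotone_consistent`` is True iff the descriptor ranks are exactly the
    ln IC50 ranks or exactly their reversal — the strict "same order" claim.
    ``degenerate`` marks zero-variance input, for which the coefficients are
    undefined (None) rather than silently NaN.
    """

    pearson_r: Optional[float]
    spearman_rho: Optional[float]
    n: int
    monotone_consistent: bool
    degenerate: bool = False


def correlate(
    descriptor_values: Sequence[float], ln_ic50_values: Sequence[float]
) -> CorrelationReport:
    """Correlate a per-compound descriptor with ln IC50.

    Requires equal-length, complete vectors with n >= 3. Ties are handled by
    the usual midrank convention in Spearman's rho.
    """
    x = np.asarray(descriptor_values, dtype=float)
    y = np.asarray(ln_ic50_values, dtype=float)
    if x.shape != y.shape:
        raise ValidationError(f"length mismatch: {x.shape} vs {y.shape}")
    if x.ndim != 1 or len(x) < 3:
        raise ValidationError("correlation needs >= 3 paired values")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValidationError("correlation input contains missing/non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationReport(
            pearson_r=None,
            spearman_rho=None,
            n=len(x),
            monotone_consistent=False,
            degenerate=True,
        )
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    # identical order, or exactly reversed order (rank i <-> n+1-i)
    monotone = bool(np.array_equal(rx, ry) or np.array_equal(rx, (len(ry) + 1) - ry))
    return CorrelationReport(
        pearson_r=float(stats.pearsonr(x, y).statistic),
        spearman_rho=float(stats.spearmanr(x, y).statistic),
        n=len(x),
        monotone_consistent=monotone,
    )


@dataclass(frozen=True)
class ShiftPotencySummary:
    """Per-compound shift classes and the blue-shift/potency separation test.

    ``blue_more_potent`` answers: do *all* blue-shifted compounds have
    ln IC50 below *all* red-shifted compounds? It is None (with
    ``defined=False``) when either class is needed but the comparison is
    degenerate (fewer than two compounds); vacuously True when one class is
    empty.
    """

    classes: dict
    blue_more_potent: Optional[bool]
    defined: bool
    max_blue_ln_ic50: Optional[float] = None
    min_red_ln_ic50: Optional[float] = None


def shift_potency_report(table: pd.DataFrame) -> ShiftPotencySummary:
    """Classify each compound's spectral shift and test the potency separation.

    ``table`` needs columns ``substituent``, ``delta_lambda_nm`` and
    ``ln_ic50`` (a ``shift_class`` column is recomputed from the sign of
    Δλmax regardless). Blue = Δλmax < 0, red = Δλmax > 0.
    """
    required = {"substituent", "delta_lambda_nm", "ln_ic50"}
    missing = required - set(table.columns)
    if missing:
        raise ValidationError(f"shift_potency_report: missing columns {sorted(missing)}")
    if table[["delta_lambda_nm", "ln_ic50"]].isna().any().any():
        raise ValidationError("shift_potency_report: missing values in required columns")

    classes = {}
    for _, row in table.iterrows():
        d = row["delta_lambda_nm"]
        classes[row["substituent"]] = "blue" if d < 0 else ("red" if d > 0 else "none")

    if len(table) < 2:
        return ShiftPotencySummary(classes=classes, blue_more_potent=None, defined=False)

    blue_ln = table.loc[table["delta_lambda_nm"] < 0, "ln_ic50"]
    red_ln = table.loc[table["delta_lambda_nm"] > 0, "ln_ic50"]
    if blue_ln.empty or red_ln.empty:
        return ShiftPotencySummary(classes=classes, blue_more_potent=True, defined=True)
    return ShiftPotencySummary(
        classes=classes,
        blue_more_potent=bool(blue_ln.max() < red_ln.min()),
        defined=True,
        max_blue_ln_ic50=float(blue_ln.max()),
        min_red_ln_ic50=float(red_ln.min()),
    )
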