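"""Shake-flask LogD computation layer.

The shake-flask assay equilibrates a compound between n-octanol and
Danieau's solution (the embryo medium), quantifies both phases by
chromatography against an external calibration line, and reports

    LogD = log10( C_octanol / C_Danieau )

Only the calculation layer lives here: fitting the calibration line on
level means, the replicate-precision (%RSD) and linearity (R²) quality
gates, inverse prediction of concentrations, and the partition
coefficient itself.  The instrument side (columns, gradients, detector)
is out of scope.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "CalibrationCurve",
    "DEFAULT_LEVELS_UM",
    "R2_QC_THRESHOLD",
    "RSD_QC_THRESHOLD_PCT",
    "fit_calibration",
    "rsd_check",
    "quantify",
    "compute_logd",
]

#: standard calibration levels, µM (highest to lowest)
DEFAULT_LEVELS_UM = (10.0, 5.0, 2.5, 1.25, 0.63)

#: QC gates: calibration linearity and replicate precision
R2_QC_THRESHOLD = 0.998
RSD_QC_THRESHOLD_PCT = 10.0


@dataclass(frozen=True)
class CalibrationCurve:
    compound: str
    levels: tuple[float, ...]              # µM
    mean_responses: tuple[float, ...]      # detector signal per level
    replicate_rsd: tuple[float, ...]       # %RSD per level (NaN for single injections)
    slope: float
    intercept: float
    r2: float
    qc_flags: tuple[str, ...] = ()

    @property
    def passes_qc(self) -> bool:
        return not self.qc_flags


def rsd_check(replicates: Sequence[float]) -> float:
    """Relative standard deviation of replicate injections, in percent.

    100 × sample sd / mean; values at or above 10% indicate inadequate
    injection precision.
    """
    r = np.asarray(replicates, dtype=float)
    if r.size < 2:
        raise ValueError("need at least 2 replicates for %RSD")
    mean = r.mean()
    if mean == 0:
        raise ZeroDivisionError("%RSD undefined for zero-mean replicates")
    return float(100.0 * r.std(ddof=1) / mean)


def fit_calibration(
    levels: Sequence[float],
    responses: "Sequence[Sequence[float]] | Sequence[float]",
    compound: str = "",
) -> CalibrationCurve:
    """Fit the calibration line response ~ concentration on level means.

    ``responses`` holds the replicate signals per level (a flat sequence
    is treated as one injection per level).  Replicates collapse to their
    mean for the unweighted OLS line; per-level %RSD is kept as QC
    metadata.  QC flags are raised when R² < 0.998 or any level's
    %RSD >= 10%.
    """
    lv = np.asarray(levels, dtype=float)
    if lv.size < 4:
        raise ValueError("need at least 4 calibration levels")
    if np.any(lv <= 0):
        raise ValueError("calibration levels must be strictly positive")
    if np.unique(lv).size != lv.size:
        raise ValueError("calibration levels must be distinct")
    if len(responses) != lv.size:
        raise ValueError("one response group per level required")

    means = np.empty(lv.size)
    rsds = np.empty(lv.size)
    flags: list[str] = []
    for i, grp in enumerate(responses):
        arr = np.atleast_1d(np.asarray(grp, dtype=float))
        means[i] = arr.mean()
        rsds[i] = rsd_check(arr) if arr.size >= 2 else math.nan
        if arr.size >= 2 and rsds[i] >= RSD_QC_THRESHOLD_PCT:
            flags.append(f"rsd_level_{lv[i]:g}")

    slope, intercept = np.polyfit(lv, means, 1)
    fitted = slope * lv + intercept
    sst = float(((means - means.mean()) ** 2).sum())
    sse = float(((means - fitted) ** 2).sum())
    r2 = 1.0 if sst == 0 else 1.0 - sse / sst
    if r2 < R2_QC_THRESHOLD:
        flags.append("r2")
    return CalibrationCurve(
        compound=compound, levels=tuple(lv), mean_responses=tuple(means),
        replicate_rsd=tuple(rsds), slope=float(slope), intercept=float(intercept),
        r2=float(r2), qc_flags=tuple(flags),
    )


def quantify(curve: CalibrationCurve, response: float) -> float:
    """Inverse-predict a concentration (µM) from a detector response.

    Warns when the result falls outside the calibrated level range
    (extrapolation).
    """
    if curve.slope == 0:
        raise ZeroDivisionError("calibration slope is zero; cannot invert")
    conc = (response - curve.intercept) / curve.slope
    lo, hi = min(curve.levels), max(curve.levels)
    if not (lo <= conc <= hi):
        warnings.warn(
            f"quantified {conc:.4g} µM outside calibrated range [{lo:g}, {hi:g}]",
            UserWarning, stacklevel=2,
        )
    return float(conc)


def compute_logd(conc_octanol: float, conc_danieau: float) -> float:
    """LogD(octanol/Danieau) = log10 of the phase concentration ratio.

    The logarithm is part of the definition: distribution coefficients
    below the aqueous phase's give negative LogD, which a plain ratio
    could never produce.
    """
    if conc_octanol <= 0 or conc_danieau <= 0:
        raise ValueError("phase concentrations must be strictly positive")
    # difference of logs keeps the swap antisymmetry exact in floating point
    return math.log10(conc_octanol) - math.log10(conc_danieau)
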