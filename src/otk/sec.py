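"""Size-exclusion-chromatography calibration.

Fits a straight line of log10(hydrodynamic radius) against elution
(retention time or relative elution volume — proportional at constant
flow rate, the caller declares which is supplied) from a set of protein
standards, then interpolates an unknown's radius from its elution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import linregress

__all__ = ["SecStandard", "SecCalibration", "fit_calibration", "estimate_rh",
           "read_standards"]


@dataclass(frozen=True)
class SecStandard:
    name: str
    rh: float       # nm
    elution: float  # min, or relative elution volume

    def __post_init__(self) -> None:
        if self.rh <= 0:
            raise ValueError("rh must be positive")
        if self.elution <= 0:
            raise ValueError("elution must be positive")


@dataclass(frozen=True)
class SecCalibration:
    """OLS line log10(rh) = intercept + slope * elution."""

    slope: float
    intercept: float
    r_squared: float
    n_standards: int
    elution_range: tuple[float, float]


def fit_calibration(standards: list[SecStandard]) -> SecCalibration:
    """Least-squares calibration line from >= 3 standards.

    Warns when the slope is non-negative (larger molecules should elute
    earlier on a valid SEC column).
    """
    if len(standards) < 3:
        raise ValueError("at least 3 standards are required")
    elution = np.array([s.elution for s in standards], dtype=float)
    logrh = np.log10([s.rh for s in standards])
    if np.ptp(elution) == 0:
        raise ValueError("standards have degenerate (identical) elution values")
    res = linregress(elution, logrh)
    if res.slope >= 0:
        warnings.warn(
            f"calibration slope {res.slope:.3g} >= 0; larger molecules should "
            "elute earlier — check the standards"
        )
    return SecCalibration(slope=float(res.slope), intercept=float(res.intercept),
                          r_squared=float(res.rvalue**2), n_standards=len(standards),
                          elution_range=(float(elution.min()), float(elution.max())))


def estimate_rh(cal: SecCalibration, elution: float) -> tuple[float, bool]:
    """Hydrodynamic radius (nm) at the given elution, with an
    extrapolation flag set when the elution lies outside the standards'
    range."""
    rh = 10.0 ** (cal.intercept + cal.slope * float(elution))
    lo, hi = cal.elution_range
    return rh, not (lo <= elution <= hi)


def read_standards(path: str | Path) -> list[SecStandard]:
    """Read standards from a delimited file with header ``name,rh,elution``."""
    df = pd.read_csv(path, comment="#")
    missing = {"name", "rh", "elution"} - set(df.columns)
    if missing:
        raise ValueError(f"standards file missing columns: {sorted(missing)}")
    return [SecStandard(name=str(r.name_), rh=float(r.rh), elution=float(r.elution))
            for r in df.rename(columns={"name": "name_"}).itertuples(index=False)]
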