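"""Intensity-to-density calibration for dense protein surfaces.

Single spots can only be counted reliably up to ~1 spot/μm²; beyond that
the diffraction limit merges neighbours.  Total field fluorescence, in
contrast, keeps growing linearly with density (fluorescent proteins such as
mEGFP show no self-quenching at these densities).  The calibration
therefore fits a line, intensity = b + a·(spot density), in the resolvable
low-density regime and extrapolates it to convert dense-field intensities
into molecular densities.

Calibrations are dataset-scoped: build one per imaging session/dataset,
never share globally.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

__all__ = [
    "DensityCalibration",
    "build_calibration",
    "intensity_to_density",
    "check_linearity",
    "LinearityReport",
]

#: densities above this (spots/μm²) are excluded from calibration fits —
#: the single-spot counting ceiling
DEFAULT_DENSITY_CUT = 1.0


@dataclass
class DensityCalibration:
    """Linear map between total intensity and spot density.

    slope : counts per (spot/μm²)
    intercept : counts (background / offset absorbed here)
    calibration_range : (min, max) spot density used for the fit
    """

    slope: float
    intercept: float
    calibration_range: Tuple[float, float]
    r_squared: float
    residual_sd: float
    n_levels: int
    weighted: bool
    provenance: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "slope": self.slope,
            "intercept": self.intercept,
            "calibration_range": list(self.calibration_range),
            "r_squared": self.r_squared,
            "residual_sd": self.residual_sd,
            "n_levels": self.n_levels,
            "weighted": self.weighted,
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path) -> "DensityCalibration":
        payload = json.loads(Path(path).read_text())
        payload["calibration_range"] = tuple(payload["calibration_range"])
        return cls(**payload)


def _level_table(density, intensity, level) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "density": np.asarray(density, float),
            "intensity": np.asarray(intensity, float),
            "level": np.asarray(level) if level is not None else np.asarray(density, float),
        }
    )
    g = df.groupby("level")
    return pd.DataFrame(
        {
            "density": g["density"].mean().to_numpy(),
            "mean": g["intensity"].mean().to_numpy(),
            "var": g["intensity"].var(ddof=1).to_numpy(),
            "n": g["intensity"].count().to_numpy(),
        }
    )


def build_calibration(
    density,
    intensity,
    level=None,
    max_density: float = DEFAULT_DENSITY_CUT,
) -> DensityCalibration:
    """Fit intensity = b + a·density from replicated low-density measurements.

    Parameters
    ----------
    density, intensity : array-like, replicate-level pairs
        (spot density in spots/μm², total field intensity in counts).
    level : optional array-like of labels grouping replicates of the same
        preparation; defaults to grouping by exact density value.
    max_density : calibration cut; levels above it are ignored.

    Weighted least squares with weights = inverse replicate variance of the
    level means; falls back to ordinary least squares when any level lacks
    replicates.  Requires >= 3 distinct density levels; a non-positive
    fitted slope is rejected as non-physical.
    """
    levels = _level_table(density, intensity, level)
    levels = levels[levels["density"] <= max_density]
    if levels["density"].nunique() < 3:
        raise ValueError(
            f"calibration needs >=3 distinct density levels <= {max_density}, "
            f"got {levels['density'].nunique()}"
        )
    if np.ptp(levels["density"].to_numpy()) == 0:
        raise ValueError("all densities identical: rank-deficient calibration")
    x = levels["density"].to_numpy()
    y = levels["mean"].to_numpy()
    use_weights = bool(np.all(levels["n"] >= 2) and np.all(levels["var"] > 0))
    X = sm.add_constant(x)
    if use_weights:
        w = levels["n"].to_numpy() / levels["var"].to_numpy()  # 1/var of the mean
        fit = sm.WLS(y, X, weights=w).fit()
    else:
        fit = sm.OLS(y, X).fit()
    intercept, slope = fit.params
    if not slope > 0:
        raise ValueError(f"non-physical calibration: fitted slope {slope:.4g} <= 0")
    resid_sd = float(np.sqrt(np.mean(fit.resid**2)))
    table = pd.DataFrame({"density": np.asarray(density, float),
                          "intensity": np.asarray(intensity, float)})
    digest = hashlib.sha256(table.to_csv(index=False).encode()).hexdigest()
    return DensityCalibration(
        slope=float(slope),
        intercept=float(intercept),
        calibration_range=(float(x.min()), float(x.max())),
        r_squared=float(fit.rsquared),
        residual_sd=resid_sd,
        n_levels=int(levels["density"].nunique()),
        weighted=use_weights,
        provenance={"input_sha256": digest, "max_density": max_density},
    )


def intensity_to_density(cal: DensityCalibration, total_intensity: float):
    """Convert a total field intensity to molecules/μm², ρ̂ = (I − b)/a.

    Intensities below the fitted intercept return 0 with a warning.
    Extrapolation beyond the calibration range is permitted (that is the
    point of the scheme) and reported via the ``extrapolated`` flag.

    Returns
    -------
    (density, extrapolated) : float and bool
    """
    if total_intensity < cal.intercept:
        warnings.warn(
            "total intensity below calibration intercept (below background); returning 0",
            stacklevel=2,
        )
        return 0.0, False
    rho = (total_intensity - cal.intercept) / cal.slope
    extrapolated = not (cal.calibration_range[0] <= rho <= cal.calibration_range[1])
    return float(rho), extrapolated


@dataclass(frozen=True)
class LinearityReport:
    """Quadratic self-quenching diagnostic for a density-intensity series."""

    curvature: float  # quadratic coefficient c in I = b + a·ρ + c·ρ²
    curvature_se: float
    relative_loss_at_max: float  # fractional intensity deficit at ρ_max vs linear
    nonlinear: bool


def check_linearity(density, intensity) -> LinearityReport:
    """Test for self-quenching: fit I = b + a·ρ + c·ρ² across the full range.

    Flags ``nonlinear`` when the curvature is significant (|c| > 2 SE) *and*
    depresses the intensity at the highest density by more than 10% relative
    to the linear part — i.e., only physiologically meaningful quenching
    raises the flag, not statistical noise.
    """
    x = np.asarray(density, float)
    y = np.asarray(intensity, float)
    if len(np.unique(x)) < 5:
        raise ValueError("check_linearity needs >=5 distinct density levels")
    X = np.column_stack([np.ones_like(x), x, x**2])
    fit = sm.OLS(y, X).fit()
    b, a, c = fit.params
    c_se = fit.bse[2]
    rho_max = x.max()
    linear_part = b + a * rho_max
    loss = -c * rho_max**2 / linear_part if linear_part > 0 else 0.0
    nonlinear = bool(abs(c) > 2 * c_se and loss > 0.10)
    return LinearityReport(
        curvature=float(c),
        curvature_se=float(c_se),
        relative_loss_at_max=float(loss),
        nonlinear=nonlinear,
    )
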