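"""Equilibrium and kinetic models of vesicle adsorption onto surface proteins.

The central quantity throughout is the bound-vesicle surface density
``N_b`` (vesicles/μm²) as a function of the target-protein surface density
``ρ`` (molecules/μm²) and the free vesicle concentration ``V`` (pM).

Two equilibrium pictures are implemented:

* **Simple Langmuir adsorption** — every protein molecule is an independent
  binding site with a single equilibrium constant ``K_d``::

      N_b = α · ρ · V / (V + K_d)

* **Density-dependent cooperation** — proteins scattered at random (a
  homogeneous spatial Poisson process) are split into two site classes by a
  geometric *reach* ``d``: molecules whose nearest neighbour lies farther
  than ``d`` act as single-protein sites with constant ``K_d,1``, while
  molecules with a neighbour within reach pair up into composite sites with
  a (typically much smaller) constant ``K_d,2``.  For a Poisson field the
  probability that a molecule has no neighbour within ``d`` is
  ``exp(−ρπd²)``, giving site densities

      s₁ = ρ·exp(−λ),   s₂ = ρ·(1 − exp(−λ))/2,   λ = ρπd²

  and

      N_b = α·[ s₁·V/(V+K_d,1) + s₂·V/(V+K_d,2) ]

  The bookkeeping identity ``s₁ + 2·s₂ = ρ`` holds exactly: every protein
  belongs to exactly one site.  Because s₂ grows quadratically at low ρ,
  a small K_d,2 produces the super-linear density dependence characteristic
  of cooperative vesicle capture.

Vesicle-concentration dependence (Hill), sigmoidal dose-response inhibition
(IC50), and a single-exponential approach to equilibrium are also provided,
along with unit conversion between particle counts and molar concentration.

Units: densities in molecules (or vesicles)/μm², ``V`` in pM, dissociation
constants in nM as conventionally printed, reach ``d`` in μm, doses in μM.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.constants import N_A

__all__ = [
    "LangmuirParams",
    "CooperativeParams",
    "HillParams",
    "InhibitionParams",
    "KineticParams",
    "BindingCurve",
    "langmuir_Nb",
    "site_densities",
    "cooperative_Nb",
    "hill_N",
    "inhibition_N",
    "kinetic_N",
    "particles_per_ml_to_pM",
]

#: conversion factor nM -> pM, used to put K_d and V on a common scale
NM_TO_PM = 1.0e3


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise ValueError(f"{name} must be > 0, got {value!r}")


def _require_nonnegative(name: str, value) -> None:
    if np.any(np.asarray(value) < 0):
        raise ValueError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LangmuirParams:
    """Simple adsorption: independent single-protein sites.

    Parameters
    ----------
    K_d : float
        Equilibrium constant in nM (formulated with vesicle concentration
        and surface-protein density; not a bimolecular protein constant).
    alpha : float
        Capture-efficiency scale in (0, 1]; fraction of occupied sites that
        register as a bound vesicle.
    """

    K_d: float
    alpha: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("K_d", self.K_d)
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha!r}")


@dataclass(frozen=True)
class CooperativeParams:
    """Density-dependent cooperation: isolated and paired protein sites.

    K_d1 applies to isolated molecules, K_d2 (usually ≪ K_d1) to pairs of
    molecules within the cooperation reach ``d`` (μm).
    """

    K_d1: float
    K_d2: float
    d: float = 0.1
    alpha: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("K_d1", self.K_d1)
        _require_positive("K_d2", self.K_d2)
        _require_positive("d", self.d)
        if not (0 < self.alpha <= 1):
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha!r}")


@dataclass(frozen=True)
class HillParams:
    """Cooperative vesicle-concentration dependence, N = N_max·Vⁿ/(Vⁿ+Kⁿ).

    K_half is expressed in the same unit as the concentration axis
    (particles/ml in the assays this package emulates).
    """

    N_max: float
    K_half: float
    n: float

    def __post_init__(self) -> None:
        _require_positive("N_max", self.N_max)
        _require_positive("K_half", self.K_half)
        _require_positive("n", self.n)


@dataclass(frozen=True)
class InhibitionParams:
    """Sigmoidal dose-response: binding falls from N_0 to N_bg with IC50 in μM."""

    N_0: float
    N_bg: float
    IC50: float
    h: float = 1.0

    def __post_init__(self) -> None:
        _require_positive("IC50", self.IC50)
        _require_positive("h", self.h)
        if not self.N_0 > self.N_bg >= 0:
            raise ValueError(
                f"require N_0 > N_bg >= 0, got N_0={self.N_0!r}, N_bg={self.N_bg!r}"
            )


@dataclass(frozen=True)
class KineticParams:
    """Single-exponential binding kinetics, k_obs = k_on·V + k_off."""

    k_on: float  # 1/(pM·s)
    k_off: float  # 1/s
    N_eq: float  # vesicles/μm²

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("k_on and k_off must be non-negative")
        _require_nonnegative("N_eq", self.N_eq)

    def k_obs(self, V_pM: float) -> float:
        return self.k_on * V_pM + self.k_off


@dataclass
class BindingCurve:
    """Replicated binding measurements along one experimental axis.

    ``x_kind`` declares what the abscissa means: ``"density"`` (protein
    molecules/μm²), ``"concentration"`` (vesicle particles/ml),
    ``"dose"`` (inhibitor μM) or ``"time"`` (seconds).  Fitting routines
    check this tag against the model being fitted.
    """

    x: np.ndarray
    y_mean: np.ndarray
    x_kind: str
    y_sd: Optional[np.ndarray] = None
    n_rep: int = 1
    replicates: Optional[np.ndarray] = None  # shape (n_levels, n_rep)
    vesicle_conc_pM: Optional[float] = None
    meta: dict = field(default_factory=dict)

    _KINDS = ("density", "concentration", "dose", "time")

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y_mean = np.asarray(self.y_mean, dtype=float)
        if self.x_kind not in self._KINDS:
            raise ValueError(f"x_kind must be one of {self._KINDS}, got {self.x_kind!r}")
        if self.x.shape != self.y_mean.shape:
            raise ValueError("x and y_mean must have the same shape")
        _require_nonnegative("x", self.x)
        if self.y_sd is not None:
            self.y_sd = np.asarray(self.y_sd, dtype=float)
            _require_nonnegative("y_sd", self.y_sd)

    @classmethod
    def from_replicates(
        cls,
        x,
        replicates,
        x_kind: str,
        vesicle_conc_pM: Optional[float] = None,
        **meta,
    ) -> "BindingCurve":
        reps = np.asarray(replicates, dtype=float)
        if reps.ndim != 2:
            raise ValueError("replicates must be 2-D (n_levels, n_rep)")
        return cls(
            x=np.asarray(x, dtype=float),
            y_mean=reps.mean(axis=1),
            y_sd=reps.std(axis=1, ddof=1) if reps.shape[1] > 1 else None,
            n_rep=reps.shape[1],
            replicates=reps,
            x_kind=x_kind,
            vesicle_conc_pM=vesicle_conc_pM,
            meta=dict(meta),
        )

    def sem(self) -> Optional[np.ndarray]:
        """Standard error of the replicate mean, or None when unavailable."""
        if self.y_sd is None or self.n_rep < 2:
            return None
        return self.y_sd / np.sqrt(self.n_rep)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "x": self.x,
                "x_kind": self.x_kind,
                "y_mean": self.y_mean,
                "y_sd": self.y_sd if self.y_sd is not None else np.nan,
                "n_rep": self.n_rep,
            }
        )
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BindingCurve":
        df = pd.read_csv(Path(path))
        y_sd = df["y_sd"].to_numpy() if df["y_sd"].notna().all() else None
        return cls(
            x=df["x"].to_numpy(),
            y_mean=df["y_mean"].to_numpy(),
            y_sd=y_sd,
            n_rep=int(df["n_rep"].iloc[0]),
            x_kind=str(df["x_kind"].iloc[0]),
        )


# ---------------------------------------------------------------------------
# model evaluations
# ---------------------------------------------------------------------------

def langmuir_Nb(rho, V_pM, p: LangmuirParams):
    """Bound-vesicle density under simple Langmuir adsorption.

    N_b = α·ρ·V/(V + K_d), with V in pM and K_d converted from nM.
    Linear in ρ by construction.
    """
    rho = np.asarray(rho, dtype=float)
    _require_nonnegative("rho", rho)
    _require_nonnegative("V_pM", V_pM)
    occ = np.asarray(V_pM, dtype=float) / (np.asarray(V_pM, dtype=float) + p.K_d * NM_TO_PM)
    return p.alpha * rho * occ


def site_densities(rho, d):
    """Densities of isolated (s1) and paired (s2) sites on a Poisson field.

    λ = ρπd² is the expected number of neighbours within the reach; a
    molecule is isolated with probability exp(−λ).  Non-isolated molecules
    are booked pairwise, so s1 + 2·s2 = ρ exactly.

    Returns
    -------
    (s1, s2) : tuple of arrays, sites/μm²
    """
    rho = np.asarray(rho, dtype=float)
    _require_nonnegative("rho", rho)
    _require_positive("d", d)
    lam = rho * np.pi * d**2
    p_iso = np.exp(-lam)
    s1 = rho * p_iso
    s2 = rho * (1.0 - p_iso) / 2.0
    return s1, s2


def cooperative_Nb(rho, V_pM, p: CooperativeParams):
    """Bound-vesicle density under the density-dependent cooperation model.

    N_b = α·[s1·V/(V+K_d1) + s2·V/(V+K_d2)] with site densities from
    :func:`site_densities`.  Reduces to the Langmuir form with K_d1 as
    d → 0 (all sites isolated).
    """
    _require_nonnegative("V_pM", V_pM)
    s1, s2 = site_densities(rho, p.d)
    V = np.asarray(V_pM, dtype=float)
    occ1 = V / (V + p.K_d1 * NM_TO_PM)
    occ2 = V / (V + p.K_d2 * NM_TO_PM)
    return p.alpha * (s1 * occ1 + s2 * occ2)


def hill_N(V, p: HillParams):
    """Hill-type vesicle-concentration dependence, N = N_max·Vⁿ/(Vⁿ + K_halfⁿ)."""
    V = np.asarray(V, dtype=float)
    _require_nonnegative("V", V)
    with np.errstate(divide="ignore"):
        ratio = np.power(V / p.K_half, p.n)
    return p.N_max * ratio / (1.0 + ratio)


def inhibition_N(dose, p: InhibitionParams):
    """Sigmoidal inhibition, N = N_bg + (N_0 − N_bg)/(1 + (dose/IC50)^h)."""
    dose = np.asarray(dose, dtype=float)
    _require_nonnegative("dose", dose)
    return p.N_bg + (p.N_0 - p.N_bg) / (1.0 + np.power(dose / p.IC50, p.h))


def kinetic_N(t, p: KineticParams, V_pM: float):
    """Approach to equilibrium, N(t) = N_eq·(1 − exp(−(k_on·V + k_off)·t))."""
    t = np.asarray(t, dtype=float)
    _require_nonnegative("t", t)
    _require_nonnegative("V_pM", V_pM)
    return p.N_eq * (1.0 - np.exp(-p.k_obs(V_pM) * t))


def particles_per_ml_to_pM(c):
    """Convert a particle number concentration (particles/ml) to pM.

    c particles/ml = c·10³ particles/L = c·10³/N_A mol/L = c·10¹⁵/N_A pM.
    2×10⁹ particles/ml ≈ 3.3 pM.
    """
    c = np.asarray(c, dtype=float)
    _require_nonnegative("c", c)
    return c * 1.0e15 / N_A
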