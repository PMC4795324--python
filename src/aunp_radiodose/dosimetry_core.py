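"""Closed-form beta dosimetry chain for a surface-loaded spherical tumor.

Four small pieces of arithmetic connect nanoparticle loading to absorbed
dose:

* an empirical range-energy relation for beta particles
  (R = 0.542 E - 0.133 g/cm^2 for E >= 0.8 MeV, with the Katz-Penfold
  form 0.412 E^(1.265 - 0.0954 ln E) below 0.8 MeV),
* the average number of gold atoms per nanoparticle,
  N = (pi/6) (rho/M) N_A D^3  (= 30.896 D^3 for gold with D in nm),
* the activity deposited on the tumor surface,
  A [mCi] = lambda_phys[s^-1] n_a n_bv f_uptake / 3.7e7, and
* the tally-to-dose conversion D = X T p A / lambda_eff with X = 21.34
  converting mCi MeV/g per disintegration to Gy/h.

Note the decay constant is converted to s^-1 inside the activity formula:
1 mCi is 3.7e7 disintegrations per *second*, and the source literature
mixes per-hour decay constants with that per-second unit.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .nuclear_optical_data import NuclideData
from .plasmonics import NanoParticle

__all__ = [
    "RangeResult",
    "SourceLoading",
    "DoseConversion",
    "beta_mass_range",
    "linear_range",
    "range_result",
    "atoms_per_nanoparticle",
    "gold_atom_density_cm3",
    "surface_activity",
    "dose_from_tally",
    "dose_rate_conversion_constant",
    "X_MCI_MEV_TO_GY_PER_H",
    "DIS_PER_S_PER_MCI",
]

#: disintegrations per second in one millicurie
DIS_PER_S_PER_MCI = 3.7e7
#: MeV -> J
MEV_TO_J = 1.602e-13
#: conversion constant of the dose-rate formula, (mCi MeV/g/dis) -> Gy/h
X_MCI_MEV_TO_GY_PER_H = 21.34

GOLD_DENSITY_G_CM3 = 19.3
GOLD_ATOMIC_WEIGHT = 197.0
AVOGADRO = 6.02214076e23

# range-energy branches (mass range in g/cm^2, E in MeV)
E_SEAM_MEV = 0.8
_HIGH_SLOPE, _HIGH_INTERCEPT = 0.542, -0.133
_KP_COEFF, _KP_A, _KP_B = 0.412, 1.265, 0.0954


def _mass_range_raw(e_mev: np.ndarray) -> np.ndarray:
    """Both branches as printed; the ~2.9% seam discontinuity is deliberate."""
    e = np.asarray(e_mev, dtype=float)
    high = _HIGH_SLOPE * e + _HIGH_INTERCEPT
    with np.errstate(divide="ignore", invalid="ignore"):
        low = _KP_COEFF * np.power(e, _KP_A - _KP_B * np.log(e))
    return np.where(e >= E_SEAM_MEV, high, low)


def beta_mass_range(e_max_mev) -> float | np.ndarray:
    """Mass range (g/cm^2) of a beta particle of maximum energy ``e_max_mev``.

    Uses the empirical linear relation for E >= 0.8 MeV and the
    Katz-Penfold form below.  The two branches disagree by ~2.9% at the
    0.8 MeV seam; both are kept as published (the discontinuity is
    documented, not hidden — see docs/methods.md).
    """
    e = np.asarray(e_max_mev, dtype=float)
    if np.any(e <= 0):
        raise ValueError("beta energy must be positive")
    out = _mass_range_raw(e)
    return float(out) if np.isscalar(e_max_mev) else out


def linear_range(mass_range_g_cm2, density_g_cm3: float) -> float | np.ndarray:
    """Linear range (cm) = mass range / medium density."""
    if density_g_cm3 <= 0:
        raise ValueError("density must be positive")
    r = np.asarray(mass_range_g_cm2, dtype=float) / density_g_cm3
    return float(r) if np.isscalar(mass_range_g_cm2) else r


@dataclass(frozen=True)
class RangeResult:
    """Mass and linear range of a beta endpoint in a given medium."""

    mass_range_g_cm2: float
    linear_range_cm: float
    medium_density_g_cm3: float


def range_result(e_max_mev: float, density_g_cm3: float) -> RangeResult:
    r = beta_mass_range(e_max_mev)
    return RangeResult(r, linear_range(r, density_g_cm3), density_g_cm3)


def atoms_per_nanoparticle(
    diameter_nm: float,
    density_g_cm3: float = GOLD_DENSITY_G_CM3,
    atomic_weight: float = GOLD_ATOMIC_WEIGHT,
) -> float:
    """Average number of atoms in a solid sphere of diameter ``diameter_nm``.

    N = (pi/6) (rho/M) N_A D^3; for gold this is ~30.896 D^3 with D in nm.
    Returned as a positive real, not rounded.
    """
    if diameter_nm <= 0 or density_g_cm3 <= 0 or atomic_weight <= 0:
        raise ValueError("diameter, density and atomic weight must be positive")
    d_cm = diameter_nm * 1e-7
    return (math.pi / 6.0) * (density_g_cm3 / atomic_weight) * AVOGADRO * d_cm**3


def gold_atom_density_cm3() -> float:
    """Number density of atoms in bulk gold, cm^-3 (rho N_A / M)."""
    return GOLD_DENSITY_G_CM3 * AVOGADRO / GOLD_ATOMIC_WEIGHT


@dataclass(frozen=True)
class SourceLoading:
    """How much radioactivity sits on the tumor surface.

    ``n_a = c_r * rho_molecule * (4 pi r^3 / 3)`` radioactive atoms per
    bound vector (nanoparticle), and the number of vectors is the tumor
    surface times the covering fraction divided by the per-vector footprint
    area (default: the close-packed PEG-shell disc, pi (hydro/2)^2).
    """

    c_r: float                      # radioactive atoms per molecule
    rho_molecule_cm3: float         # molecules per cm^3 of nanoparticle core
    np_radius_cm: float             # nanoparticle core radius, cm
    covering_fraction: float = 0.5
    uptake_fraction: float = 0.6
    footprint_area_cm2: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.c_r, self.rho_molecule_cm3, self.np_radius_cm) <= 0:
            raise ValueError("c_r, rho_molecule and np radius must be positive")
        if not (0.0 < self.covering_fraction <= 1.0):
            raise ValueError("covering_fraction must be in (0, 1]")
        if not (0.0 < self.uptake_fraction <= 1.0):
            raise ValueError("uptake_fraction must be in (0, 1]")
        if self.footprint_area_cm2 is not None and self.footprint_area_cm2 <= 0:
            raise ValueError("footprint area must be positive")

    @property
    def n_a(self) -> float:
        """Radioactive atoms per nanoparticle."""
        return (
            self.c_r
            * self.rho_molecule_cm3
            * (4.0 / 3.0) * math.pi * self.np_radius_cm**3
        )

    @classmethod
    def from_nanoparticle(
        cls,
        np_: NanoParticle,
        *,
        c_r: float = 1.0,
        specific_activity_fraction: float = 1.0,
        covering_fraction: float = 0.5,
        uptake_fraction: float = 0.6,
        footprint_area_cm2: Optional[float] = None,
    ) -> "SourceLoading":
        """Loading for a gold nanosphere.

        ``specific_activity_fraction`` scales the bulk gold atom density:
        1.0 treats every core atom as radio-gold-equivalent.  The footprint
        defaults to the hydrodynamic (PEG shell) disc area.
        """
        if footprint_area_cm2 is None:
            hydro_r_cm = 0.5 * np_.hydrodynamic_diameter_nm * 1e-7
            footprint_area_cm2 = math.pi * hydro_r_cm**2
        return cls(
            c_r=c_r,
            rho_molecule_cm3=specific_activity_fraction * gold_atom_density_cm3(),
            np_radius_cm=np_.radius_nm * 1e-7,
            covering_fraction=covering_fraction,
            uptake_fraction=uptake_fraction,
            footprint_area_cm2=footprint_area_cm2,
        )


def surface_activity(
    loading: SourceLoading, tumor_radius_cm: float, nuclide: NuclideData
) -> float:
    """Activity (mCi) bound on the surface of a spherical tumor.

    A = lambda_phys[s^-1] * n_a * n_bv * uptake / 3.7e7, with
    n_bv = 4 pi R^2 f_c / footprint the number of bound vectors.
    """
    if tumor_radius_cm <= 0:
        raise ValueError("tumor radius must be positive")
    if not loading.footprint_area_cm2 or loading.footprint_area_cm2 <= 0:
        raise ValueError("per-vector footprint area must be set and positive")
    n_bv = (
        4.0 * math.pi * tumor_radius_cm**2 * loading.covering_fraction
        / loading.footprint_area_cm2
    )
    dis_per_s = nuclide.lambda_phys_per_s * loading.n_a * n_bv
    return dis_per_s * loading.uptake_fraction / DIS_PER_S_PER_MCI


@dataclass(frozen=True)
class DoseConversion:
    """Inputs of the tally-to-dose formula D = X T p A / lambda_eff."""

    tally_mev_per_g: float          # T, MeV/g per emitted particle
    activity_mci: float             # A
    lambda_phys_per_h: float
    lambda_bio_per_h: float = 0.0
    particles_per_decay: float = 1.0
    x_constant: float = X_MCI_MEV_TO_GY_PER_H

    def __post_init__(self) -> None:
        if self.lambda_phys_per_h <= 0 or self.lambda_bio_per_h < 0:
            raise ValueError("decay constants must be positive / non-negative")

    @property
    def lambda_eff_per_h(self) -> float:
        return self.lambda_phys_per_h + self.lambda_bio_per_h


def dose_from_tally(conv: DoseConversion) -> float:
    """Total absorbed dose (Gy) from complete decay of the bound activity."""
    lam = conv.lambda_eff_per_h
    if lam <= 0:
        raise ValueError("lambda_eff must be positive")
    return (
        conv.x_constant
        * conv.tally_mev_per_g
        * conv.particles_per_decay
        * conv.activity_mci
        / lam
    )


def dose_rate_conversion_constant() -> float:
    """Derive X from first principles, (mCi MeV/g/dis) -> Gy/h.

    3.7e7 dis/s/mCi * 3600 s/h * 1.602e-13 J/MeV * 1e3 g/kg = 21.34.
    """
    return DIS_PER_S_PER_MCI * 3600.0 * MEV_TO_J * 1e3
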