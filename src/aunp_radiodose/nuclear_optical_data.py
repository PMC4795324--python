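"""Physical reference inputs for the nanoparticle diagnosis/therapy chain.

Everything downstream (plasmonics, dosimetry, transport) consumes records
defined here: the Au-198 decay data, a beta emission spectrum generated
from allowed-transition Fermi theory, the experimental gold dielectric
function, and bulk tissue constants.  All reference tables are embedded in
the package as plain-text CSV; nothing requires a download.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.interpolate import PchipInterpolator

__all__ = [
    "NuclideData",
    "BetaSpectrum",
    "DielectricTable",
    "TissueConstants",
    "load_au198",
    "beta_spectrum",
    "gold_dielectric",
]

LN2 = math.log(2.0)
#: fine-structure constant (dimensionless)
ALPHA_FS = 7.2973525693e-3
#: electron rest energy, MeV
ME_C2_MEV = 0.51099895
#: atomic number of the beta-decay daughter of Au-198 (mercury)
AU198_DAUGHTER_Z = 80

SMALL_INTESTINE_DENSITY_G_CM3 = 1.05


def _data_path(name: str):
    return resources.files("aunp_radiodose").joinpath("data", name)


@dataclass(frozen=True)
class NuclideData:
    """Beta-decay constants of a radionuclide.

    Parameters
    ----------
    half_life_h : physical half-life in hours.
    e_max_mev : beta endpoint (maximum) energy in MeV.
    e_mean_mev : mean beta energy in MeV, computed from the emission spectrum.
    particles_per_decay : average beta particles emitted per disintegration.
    """

    name: str
    half_life_h: float
    e_max_mev: float
    e_mean_mev: float
    particles_per_decay: float = 1.0

    def __post_init__(self) -> None:
        if self.half_life_h <= 0:
            raise ValueError("half_life_h must be positive")
        if self.e_max_mev <= 0:
            raise ValueError("e_max_mev must be positive")
        if not (0.0 < self.e_mean_mev < self.e_max_mev):
            raise ValueError("e_mean_mev must lie strictly inside (0, e_max)")
        if self.particles_per_decay <= 0:
            raise ValueError("particles_per_decay must be positive")

    @property
    def lambda_phys_per_h(self) -> float:
        """Physical decay constant, h^-1."""
        return LN2 / self.half_life_h

    @property
    def lambda_phys_per_s(self) -> float:
        """Physical decay constant, s^-1."""
        return self.lambda_phys_per_h / 3600.0


@dataclass(frozen=True)
class TissueConstants:
    """Bulk properties of the transport medium (soft tissue)."""

    density_g_cm3: float = SMALL_INTESTINE_DENSITY_G_CM3

    def __post_init__(self) -> None:
        if self.density_g_cm3 <= 0:
            raise ValueError("density must be positive")


@dataclass(frozen=True)
class BetaSpectrum:
    """Sampled beta emission spectrum on an energy grid.

    ``density`` is a probability density per MeV over ``energies`` (MeV),
    normalized so its trapezoid integral over the grid is 1.
    """

    energies: np.ndarray
    density: np.ndarray
    _cdf: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        e = np.asarray(self.energies, dtype=float)
        d = np.asarray(self.density, dtype=float)
        if e.ndim != 1 or e.shape != d.shape or e.size < 2:
            raise ValueError("energies/density must be matching 1-D arrays")
        if np.any(np.diff(e) <= 0):
            raise ValueError("energies must be strictly increasing")
        if np.any(d < 0):
            raise ValueError("density must be non-negative")
        norm = np.trapezoid(d, e)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"density must integrate to 1 (got {norm})")
        cdf = cumulative_trapezoid(d, e, initial=0.0)
        cdf /= cdf[-1]
        object.__setattr__(self, "energies", e)
        object.__setattr__(self, "density", d)
        object.__setattr__(self, "_cdf", cdf)

    @property
    def e_max_mev(self) -> float:
        return float(self.energies[-1])

    def mean_energy(self) -> float:
        """Mean emission energy in MeV (trapezoid quadrature on the grid)."""
        return float(np.trapezoid(self.energies * self.density, self.energies))

    def cdf(self, e) -> np.ndarray:
        """Piecewise-linear CDF used by the sampler (exact for chi^2 checks)."""
        return np.interp(e, self.energies, self._cdf)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` emission energies by inverse-CDF sampling."""
        u = rng.random(n)
        return np.interp(u, self._cdf, self.energies)


#: reduced electron Compton wavelength, m (nuclear-radius unit of the
#: relativistic Fermi function)
_LAMBDA_BAR_E_M = 3.8615926796e-13


def _fermi_allowed_shape(
    e_mev: np.ndarray, e_max: float, daughter_z: int, mass_number: int = 198
) -> np.ndarray:
    """Unnormalized allowed beta- shape p*W*(Q-E)^2*F(Z,W).

    F is the relativistic point-charge Fermi function

        F = 2(1+g0) (2 p R)^(2 g0 - 2) e^(pi eta) |Gamma(g0 + i eta)|^2
            / Gamma(2 g0 + 1)^2,

    with g0 = sqrt(1 - (alpha Z)^2), eta = alpha Z W / p (beta- sign:
    Coulomb attraction) and R the nuclear radius 1.2 A^(1/3) fm in units
    of the reduced electron Compton wavelength.  Evaluated in log space;
    for p -> 0 the finite limit of p*F (via the asymptotic
    |Gamma(g0+i eta)|^2 e^(pi eta) ~ 2 pi eta^(2 g0 - 1)) is used.
    """
    from scipy.special import loggamma

    w = 1.0 + e_mev / ME_C2_MEV          # total energy, units of m_e c^2
    p = np.sqrt(np.maximum(w * w - 1.0, 0.0))
    q2 = (e_max - e_mev) ** 2
    az = daughter_z * ALPHA_FS
    g0 = math.sqrt(1.0 - az * az)
    r_nuc = 1.2e-15 * mass_number ** (1.0 / 3.0) / _LAMBDA_BAR_E_M
    log_norm = math.log(2.0 * (1.0 + g0)) - 2.0 * float(loggamma(2.0 * g0 + 1.0))

    small = p < 1e-3
    p_safe = np.where(small, 1.0, p)
    eta = az * w / p_safe
    with np.errstate(divide="ignore", invalid="ignore"):
        log_pf_direct = (
            log_norm
            + (2.0 * g0 - 2.0) * np.log(2.0 * p_safe * r_nuc)
            + np.pi * eta
            + 2.0 * np.real(loggamma(g0 + 1j * eta))
            + np.log(p_safe)
        )
    # p -> 0 limit: p*F independent of p
    log_pf_limit = (
        log_norm
        + math.log(2.0 * np.pi)
        + (2.0 * g0 - 2.0) * np.log(2.0 * r_nuc)
        + (2.0 * g0 - 1.0) * np.log(az * w)
    )
    pf = np.exp(np.where(small, log_pf_limit, log_pf_direct))
    return pf * w * q2


def beta_spectrum(
    nuclide: NuclideData,
    n_points: int = 512,
    shape: str = "fermi",
    daughter_z: int = AU198_DAUGHTER_Z,
) -> BetaSpectrum:
    """Generate the beta emission spectrum of ``nuclide``.

    ``shape='fermi'`` (default) is the allowed-transition statistical shape
    with a nonrelativistic Fermi Coulomb correction for the daughter nucleus;
    ``shape='uniform'`` is a flat debugging spectrum (tapered to zero in the
    last grid cell so the endpoint condition still holds).
    """
    if nuclide.e_max_mev <= 0:
        raise ValueError("endpoint energy must be positive")
    if n_points < 10:
        raise ValueError("n_points must be at least 10")
    e = np.linspace(0.0, nuclide.e_max_mev, n_points)
    if shape == "fermi":
        d = _fermi_allowed_shape(e, nuclide.e_max_mev, daughter_z)
    elif shape == "uniform":
        d = np.ones_like(e)
        d[-1] = 0.0
    else:
        raise ValueError(f"unknown spectrum shape {shape!r}")
    d = d / np.trapezoid(d, e)
    return BetaSpectrum(energies=e, density=d)


def load_au198(
    half_life_d: float = 2.7,
    particles_per_decay: float = 1.0,
    n_points: int = 2048,
) -> NuclideData:
    """Load the Au-198 record (endpoint 0.96 MeV; half-life default 2.7 d).

    The half-life is overridable because the source literature quotes both
    2.7 d and 2.67 d.  The mean energy is computed from the generated
    allowed-shape spectrum rather than tabulated.
    """
    import csv

    with _data_path("nuclides.csv").open() as fh:
        row = next(r for r in csv.DictReader(fh) if r["nuclide"] == "Au-198")
    e_max = float(row["e_max_MeV"])
    half_life_h = (
        float(row["half_life_h"]) if half_life_d is None else half_life_d * 24.0
    )
    # provisional record to drive the spectrum (mean is then overwritten)
    stub = NuclideData("Au-198", half_life_h, e_max, 0.5 * e_max, particles_per_decay)
    e_mean = beta_spectrum(stub, n_points=n_points).mean_energy()
    return NuclideData("Au-198", half_life_h, e_max, e_mean, particles_per_decay)


@dataclass
class DielectricTable:
    """Tabulated complex relative permittivity of a metal vs wavelength.

    ``eps_medium`` is the (real) relative permittivity of the surrounding
    medium; the default 1.77 corresponds to water at visible wavelengths.
    Interpolation is monotone piecewise-cubic (PCHIP) on the real and
    imaginary parts separately; queries outside the tabulated span raise.
    """

    wavelengths_nm: np.ndarray
    eps_real: np.ndarray
    eps_imag: np.ndarray
    eps_medium: float = 1.77

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        er = np.asarray(self.eps_real, dtype=float)
        ei = np.asarray(self.eps_imag, dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(ei < 0):
            raise ValueError("Im(eps) must be >= 0 at every tabulated wavelength")
        if self.eps_medium <= 0:
            raise ValueError("eps_medium must be positive")
        self.wavelengths_nm, self.eps_real, self.eps_imag = wl, er, ei
        self._interp_re = PchipInterpolator(wl, er, extrapolate=False)
        self._interp_im = PchipInterpolator(wl, ei, extrapolate=False)

    @classmethod
    def load_gold(cls, eps_medium: float = 1.77) -> "DielectricTable":
        """Embedded experimental gold optical constants (see data/README.md)."""
        import csv

        wl, er, ei = [], [], []
        with _data_path("gold_dielectric_jc1972.csv").open() as fh:
            for row in csv.DictReader(fh):
                wl.append(float(row["wavelength_nm"]))
                er.append(float(row["eps_real"]))
                ei.append(float(row["eps_imag"]))
        return cls(np.array(wl), np.array(er), np.array(ei), eps_medium)

    @property
    def span_nm(self) -> tuple[float, float]:
        return float(self.wavelengths_nm[0]), float(self.wavelengths_nm[-1])

    def epsilon(self, wavelength_nm: float) -> complex:
        """Complex permittivity of the metal at ``wavelength_nm``."""
        lo, hi = self.span_nm
        wl = float(wavelength_nm)
        if not (lo <= wl <= hi):
            raise ValueError(
                f"wavelength {wl} nm outside tabulated span [{lo:.0f}, {hi:.0f}] nm"
            )
        return complex(self._interp_re(wl), self._interp_im(wl))

    __call__ = epsilon


_GOLD_TABLE: Optional[DielectricTable] = None


def gold_dielectric(wavelength_nm: float) -> complex:
    """Complex relative permittivity of gold at ``wavelength_nm`` (cached table)."""
    global _GOLD_TABLE
    if _GOLD_TABLE is None:
        _GOLD_TABLE = DielectricTable.load_gold()
    return _GOLD_TABLE.epsilon(wavelength_nm)
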