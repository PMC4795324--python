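"""Quasi-static plasmonics of gold nanospheres.

A sphere much smaller than the wavelength responds to an incident optical
field as a point dipole with polarizability

    alpha = a^3 (eps_p - eps_m) / (eps_p + 2 eps_m),

where ``a`` is the core radius, ``eps_p`` the metal permittivity at the
wavelength and ``eps_m`` the (real) permittivity of the surrounding medium.
The exterior field for a unit incident field polarized along x is the
incident field plus the static dipole field; near the particle surface the
field is enhanced, which is what makes bound nanoparticles optically
detectable.  Several particles are treated self-consistently: each dipole
is driven by the incident field plus the fields of all the others (one
dipole per particle — a coupled-dipole model, not a full polarizable
lattice).

Lengths are in nm throughout; fields are in units of the incident
amplitude E0, so enhancement |E|/E0 is dimensionless.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GeometryError, SingularResonanceError
from .nuclear_optical_data import DielectricTable

__all__ = [
    "NanoParticle",
    "GridSpec",
    "FieldMap",
    "polarizability",
    "dipole_field",
    "field_map",
]

_XHAT = np.array([1.0, 0.0, 0.0])


@dataclass(frozen=True)
class NanoParticle:
    """A spherical gold nanoparticle with an optional polymer shell.

    ``core_diameter_nm`` sets the optical radius a = core/2; the
    hydrodynamic diameter (core + PEG shell) matters for surface packing in
    the dosimetry chain, not for the quasi-static optics.
    """

    core_diameter_nm: float
    hydrodynamic_diameter_nm: float
    center_nm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not (0.0 < self.core_diameter_nm <= self.hydrodynamic_diameter_nm):
            raise ValueError("need 0 < core_diameter <= hydrodynamic_diameter")

    @property
    def radius_nm(self) -> float:
        return 0.5 * self.core_diameter_nm

    @property
    def center(self) -> np.ndarray:
        return np.asarray(self.center_nm, dtype=float)


def polarizability(a_nm: float, eps_particle: complex, eps_medium: float) -> complex:
    """Quasi-static sphere polarizability, nm^3.

    Raises :class:`SingularResonanceError` if the denominator
    eps_p + 2 eps_m vanishes (lossless Froehlich resonance) instead of
    returning an infinity.
    """
    if a_nm <= 0:
        raise ValueError("radius must be positive")
    if not np.isreal(eps_medium) or eps_medium <= 0:
        raise ValueError("eps_medium must be a positive real number")
    denom = eps_particle + 2.0 * eps_medium
    if abs(denom) < 1e-12 * max(1.0, abs(eps_particle)):
        raise SingularResonanceError(
            "eps_p + 2*eps_m = 0: lossless resonance, polarizability diverges"
        )
    return (a_nm**3) * (eps_particle - eps_medium) / denom


def _dipole_scatter(points: np.ndarray, center: np.ndarray, moment: np.ndarray) -> np.ndarray:
    """Static field of a point dipole with moment ``moment`` (units alpha*E0).

    E(r) = (3 rhat (rhat . m) - m) / r^3, for points of shape (N, 3).
    """
    rel = points - center
    r = np.linalg.norm(rel, axis=-1, keepdims=True)
    rhat = rel / r
    proj = np.sum(rhat * moment, axis=-1, keepdims=True)
    return (3.0 * rhat * proj - moment) / r**3


def dipole_field(np_: NanoParticle, alpha: complex, point) -> np.ndarray:
    """Exterior field at ``point`` for a unit x-polarized incident field.

    Returns the complex 3-vector E/E0 = xhat + (3 rhat (rhat.m) - m)/r^3
    with m = alpha*xhat; reduces to the incident field when alpha = 0.
    Interior points (r < a) are out of the quasi-static exterior contract
    and raise :class:`GeometryError`.
    """
    p = np.asarray(point, dtype=float)
    rel = p - np_.center
    r = float(np.linalg.norm(rel))
    if r < np_.radius_nm:
        raise GeometryError(
            f"point at r={r:.3g} nm is inside the particle (a={np_.radius_nm} nm)"
        )
    moment = alpha * _XHAT
    return _XHAT + _dipole_scatter(p[None, :], np_.center, moment)[0]


@dataclass(frozen=True)
class GridSpec:
    """Regular 3-D evaluation lattice: each axis is (min, max, n_points), nm."""

    x: tuple[float, float, int]
    y: tuple[float, float, int]
    z: tuple[float, float, int]

    def points(self) -> np.ndarray:
        axes = [np.linspace(lo, hi, int(n)) for lo, hi, n in (self.x, self.y, self.z)]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])

    @property
    def step_nm(self) -> float:
        steps = [
            (hi - lo) / (n - 1) if n > 1 else np.inf
            for lo, hi, n in (self.x, self.y, self.z)
        ]
        return float(min(steps))


@dataclass(frozen=True)
class FieldMap:
    """Complex field and |E|/E0 enhancement at a set of exterior points."""

    points_nm: np.ndarray
    field: np.ndarray          # complex, (N, 3), units of E0
    enhancement: np.ndarray    # |E|/E0, (N,)
    wavelength_nm: float
    moments: np.ndarray = field(default=None, repr=False, compare=False)

    def max_enhancement(self) -> tuple[float, np.ndarray]:
        i = int(np.argmax(self.enhancement))
        return float(self.enhancement[i]), self.points_nm[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_nm": self.points_nm[:, 0],
                "y_nm": self.points_nm[:, 1],
                "z_nm": self.points_nm[:, 2],
                "enhancement": self.enhancement,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plane_frame(self, axis: str = "z", value: float = 0.0) -> pd.DataFrame:
        """The map restricted to the grid plane nearest ``axis = value``."""
        df = self.to_frame()
        col = f"{axis}_nm"
        nearest = df[col].iloc[(df[col] - value).abs().argmin()]
        return df[df[col] == nearest].reset_index(drop=True)


def _coupled_moments(centers: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Solve the coupled-dipole system for unit x-polarized incident field.

    m_i = alpha_i [xhat + sum_{j!=i} G(r_i - r_j) m_j], with G the static
    dipole propagator; returns moments of shape (N, 3), units alpha*E0.
    """
    n = len(centers)
    A = np.eye(3 * n, dtype=complex)
    rhs = np.zeros(3 * n, dtype=complex)
    for i in range(n):
        rhs[3 * i : 3 * i + 3] = alphas[i] * _XHAT
        for j in range(n):
            if i == j:
                continue
            d = centers[i] - centers[j]
            r = np.linalg.norm(d)
            nhat = d / r
            G = (3.0 * np.outer(nhat, nhat) - np.eye(3)) / r**3
            A[3 * i : 3 * i + 3, 3 * j : 3 * j + 3] -= alphas[i] * G
    m = np.linalg.solve(A, rhs)
    return m.reshape(n, 3)


def field_map(
    particles,
    wavelength_nm: float,
    grid,
    *,
    table: DielectricTable | None = None,
    eps_medium: float | None = None,
    e0: float = 1.0,
) -> FieldMap:
    """Field map around one or more gold nanospheres.

    ``grid`` is a :class:`GridSpec` or an (N, 3) array of points in nm;
    points inside any particle core are dropped (the quasi-static dipole
    model has no exterior-valid interior field).  One particle evaluates
    the dipole field directly; several particles first solve the
    self-consistent coupled-dipole system.  ``e0`` scales the incident
    amplitude (fields are linear in it).
    """
    particles = list(particles)
    if not particles:
        raise ValueError("need at least one particle")
    if table is None:
        table = DielectricTable.load_gold()
    if eps_medium is None:
        eps_medium = table.eps_medium

    centers = np.array([p.center for p in particles])
    radii = np.array([p.radius_nm for p in particles])
    for i in range(len(particles)):
        for j in range(i + 1, len(particles)):
            gap = np.linalg.norm(centers[i] - centers[j]) - radii[i] - radii[j]
            if gap < 0:
                raise GeometryError(f"particles {i} and {j} overlap by {-gap:.3g} nm")

    eps_p = table.epsilon(wavelength_nm)
    alphas = np.array([polarizability(a, eps_p, eps_medium) for a in radii])
    moments = (
        alphas[:, None] * _XHAT[None, :]
        if len(particles) == 1
        else _coupled_moments(centers, alphas)
    ).astype(complex)

    pts = grid.points() if isinstance(grid, GridSpec) else np.asarray(grid, dtype=float)
    dist = np.linalg.norm(pts[:, None, :] - centers[None, :, :], axis=-1)
    exterior = np.all(dist >= radii[None, :], axis=1)
    pts = pts[exterior]

    field_ = np.tile(_XHAT.astype(complex), (len(pts), 1))
    for c, m in zip(centers, moments):
        field_ += _dipole_scatter(pts, c, m)
    field_ *= e0
    enhancement = np.linalg.norm(field_, axis=-1) / e0
    return FieldMap(
        points_nm=pts,
        field=field_,
        enhancement=enhancement,
        wavelength_nm=float(wavelength_nm),
        moments=moments,
    )
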