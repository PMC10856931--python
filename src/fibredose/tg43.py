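"""TG43-U1 dose-rate model for cylindrical brachytherapy sources.

The AAPM TG43-U1 formalism factorises the water-phantom dose rate around a
sealed source into

    D(r, theta) = s_k * Lambda * F(r, theta) * G(r, theta) / G(r0, theta0) * g(r)

where ``s_k`` is the air-kerma strength, ``Lambda`` the dose-rate constant,
``G`` the line-source geometry factor, ``g`` the radial dose function and
``F`` the 2-D anisotropy factor, interpolated from published look-up tables.
The reference point is ``(r0, theta0) = (2 cm, pi/2)`` by convention.

Coordinates: ``theta`` is measured from the long axis of the source capsule;
the transverse plane is ``theta = pi/2``.  Bench scans that move the source
along z while the sensor sits at a lateral distance y are converted with
:func:`yz_to_polar`.  Distances are in cm, angles in radians (anisotropy
table columns in degrees, the common published convention).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import ConfigurationError, InsideSourceError, InvalidGeometryError

__all__ = [
    "AnisotropyTable",
    "PolarPoint",
    "SourceSpec",
    "anisotropy_factor",
    "beta_angle",
    "dose_rate",
    "geometry_factor",
    "radial_dose_function",
    "yz_to_polar",
]

#: sin(theta) below this is treated as the on-axis (theta = 0 or pi) branch of G.
_SIN_THETA_EPS = 1e-9

#: |g(r0) - 1| above this triggers a normalisation warning on SourceSpec.
_G_R0_TOL = 1e-3


@dataclass(frozen=True)
class PolarPoint:
    """Evaluation point in source-centred polar coordinates.

    Parameters
    ----------
    r : float
        Distance from the source centre, cm. Must be positive.
    theta : float
        Polar angle from the source long axis, radians in [0, pi].
    """

    r: float
    theta: float = math.pi / 2

    def __post_init__(self) -> None:
        if not self.r > 0:
            raise InvalidGeometryError(f"r must be positive, got {self.r}")
        if not 0.0 <= self.theta <= math.pi + 1e-12:
            raise InvalidGeometryError(
                f"theta must lie in [0, pi], got {self.theta}"
            )


@dataclass(frozen=True)
class AnisotropyTable:
    """2-D anisotropy factor F(r, theta) on a rectangular grid.

    ``r_grid`` in cm and ``theta_grid`` in degrees must be strictly
    increasing; ``values`` has shape ``(len(r_grid), len(theta_grid))`` and
    all entries positive.  By TG43 convention the transverse row
    (theta = 90 deg) is 1; a deviation is accepted with a warning.
    """

    r_grid: np.ndarray
    theta_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r_grid, dtype=float)
        t = np.asarray(self.theta_grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "r_grid", r)
        object.__setattr__(self, "theta_grid", t)
        object.__setattr__(self, "values", v)
        if r.ndim != 1 or t.ndim != 1 or r.size < 2 or t.size < 2:
            raise ConfigurationError("anisotropy grids need at least 2 points per axis")
        if np.any(np.diff(r) <= 0) or np.any(np.diff(t) <= 0):
            raise ConfigurationError("anisotropy grids must be strictly increasing")
        if np.any(t < 0) or np.any(t > 180):
            raise ConfigurationError("theta grid must lie in [0, 180] degrees")
        if v.shape != (r.size, t.size):
            raise ConfigurationError(
                f"values shape {v.shape} does not match grids {(r.size, t.size)}"
            )
        if np.any(v <= 0) or not np.all(np.isfinite(v)):
            raise ConfigurationError("anisotropy values must be positive and finite")
        if np.any(t == 90.0):
            row = v[:, np.flatnonzero(t == 90.0)[0]]
            if np.any(np.abs(row - 1.0) > 1e-3):
                warnings.warn(
                    "anisotropy table is not 1 on the transverse plane "
                    "(TG43 convention F(r, 90deg) = 1)",
                    stacklevel=3,
                )


@dataclass(frozen=True)
class SourceSpec:
    """Description of a TG43 source.

    Parameters
    ----------
    air_kerma_strength : float
        s_k, in arbitrary dose units * cm^2 / h.
    dose_rate_constant : float
        Lambda, per unit of s_k, so s_k * Lambda is the dose rate at the
        reference point.
    capsule_length : float
        Active length L of the cylindrical source, cm. 0 selects the
        point-source geometry factor 1/r^2.
    radial_coeffs : tuple of 6 floats
        Polynomial coefficients a_n for n = -2..3 of the radial dose
        function g(r) = (sum a_n r^n) * exp(-a_e r).
    radial_decay : float
        Exponential decay constant a_e, 1/cm.
    anisotropy : AnisotropyTable or None
        None selects point-source mode, F == 1.
    r0, theta0 : float
        Reference point, default (2 cm, pi/2).
    """

    air_kerma_strength: float
    dose_rate_constant: float
    capsule_length: float = 0.0
    radial_coeffs: tuple = (0.0, 0.0, 1.0, 0.0, 0.0, 0.0)
    radial_decay: float = 0.0
    anisotropy: AnisotropyTable | None = None
    r0: float = 2.0
    theta0: float = math.pi / 2
    name: str = "source"

    def __post_init__(self) -> None:
        if self.capsule_length < 0:
            raise ConfigurationError("capsule_length must be >= 0")
        if not self.r0 > self.capsule_length / 2:
            raise ConfigurationError("reference r0 must lie outside the capsule")
        coeffs = tuple(float(c) for c in self.radial_coeffs)
        if len(coeffs) != 6:
            raise ConfigurationError(
                "radial_coeffs must hold the 6 coefficients a_n, n = -2..3"
            )
        object.__setattr__(self, "radial_coeffs", coeffs)
        g0 = radial_dose_function(self.r0, coeffs, self.radial_decay)
        if abs(g0 - 1.0) > _G_R0_TOL:
            warnings.warn(
                f"radial dose function is {g0:.4f} at the reference distance "
                f"r0 = {self.r0} cm (TG43 convention g(r0) = 1); "
                "values are used as given, not renormalised",
                stacklevel=3,
            )

    @property
    def is_point_source(self) -> bool:
        return self.anisotropy is None and self.capsule_length == 0.0


def yz_to_polar(y: float, z_source: float, z_sensor: float = 0.0) -> PolarPoint:
    """Convert bench coordinates to source-centred polar coordinates.

    The source travels along the z axis (its long axis); the sensor sits at
    lateral distance ``y > 0`` and axial position ``z_sensor``.  Returns the
    sensor position as seen from the source centre: ``r = sqrt(y^2 + dz^2)``
    with ``dz = z_source - z_sensor`` and ``theta = atan2(y, -dz)``, i.e.
    theta measured from the +z axis of the source, so a source moved to
    z_source > z_sensor maps to theta > pi/2.
    """
    if not y > 0:
        raise InvalidGeometryError(f"lateral distance y must be positive, got {y}")
    dz = z_source - z_sensor
    r = math.hypot(y, dz)
    theta = math.atan2(y, -dz)
    return PolarPoint(r=r, theta=theta)


def beta_angle(p: PolarPoint, length: float) -> float:
    """Angle subtended at the sensor by the active source segment.

    The segment of length ``L`` is centred on the origin along the z axis
    with endpoints A = -L/2 and B = +L/2; beta is the angle between the
    vectors from the sensor to A and to B.  On the transverse plane this
    reduces to ``2 * atan(L / 2r)``.
    """
    if length < 0:
        raise InvalidGeometryError("source length must be >= 0")
    if p.r <= length / 2:
        raise InsideSourceError(
            f"evaluation point r = {p.r} cm lies inside the capsule (L/2 = {length / 2})"
        )
    if length == 0.0:
        return 0.0
    # sensor in the (x, z) half-plane; endpoints on the z axis
    sx, sz = p.r * math.sin(p.theta), p.r * math.cos(p.theta)
    ax, az = -sx, -length / 2 - sz
    bx, bz = -sx, length / 2 - sz
    cross = ax * bz - az * bx
    dot = ax * bx + az * bz
    return abs(math.atan2(cross, dot))


def geometry_factor(p: PolarPoint, length: float) -> float:
    """Line-source geometry factor G(r, theta), 1/cm^2.

    ``beta / (L r sin theta)`` off axis, ``1 / (r^2 - L^2/4)`` on axis, and
    the point-source limit ``1 / r^2`` for L = 0.
    """
    if length == 0.0:
        return 1.0 / p.r**2
    if p.r <= length / 2:
        raise InsideSourceError(
            f"evaluation point r = {p.r} cm lies inside the capsule (L/2 = {length / 2})"
        )
    sin_theta = math.sin(p.theta)
    if sin_theta < _SIN_THETA_EPS:
        return 1.0 / (p.r**2 - length**2 / 4.0)
    return beta_angle(p, length) / (length * p.r * sin_theta)


def radial_dose_function(r, coeffs, a_e: float = 0.0):
    """Radial dose function g(r) = (sum_{n=-2..3} a_n r^n) * exp(-a_e r).

    ``coeffs`` lists a_n in order n = -2, -1, 0, 1, 2, 3.  Accepts scalar or
    array ``r``; r must be positive.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr <= 0):
        raise InvalidGeometryError("radial dose function requires r > 0")
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.shape != (6,):
        raise ConfigurationError("expected 6 radial coefficients (n = -2..3)")
    powers = np.arange(-2, 4)
    poly = np.sum(coeffs * r_arr[..., None] ** powers, axis=-1)
    out = poly * np.exp(-a_e * r_arr)
    return float(out) if np.isscalar(r) or r_arr.ndim == 0 else out


def anisotropy_factor(p: PolarPoint, table: AnisotropyTable | None) -> float:
    """Bilinear interpolation of F(r, theta) on the table grid.

    ``table=None`` means point-source mode and returns 1.  Queries outside
    the tabulated hull are clamped to the nearest edge with a warning
    (published tables rarely extend below r = 0.25 cm).
    """
    if table is None:
        return 1.0
    theta_deg = math.degrees(p.theta)
    r = p.r
    clamped = False
    if r < table.r_grid[0] or r > table.r_grid[-1]:
        r = float(np.clip(r, table.r_grid[0], table.r_grid[-1]))
        clamped = True
    if theta_deg < table.theta_grid[0] or theta_deg > table.theta_grid[-1]:
        theta_deg = float(np.clip(theta_deg, table.theta_grid[0], table.theta_grid[-1]))
        clamped = True
    if clamped:
        warnings.warn(
            f"anisotropy query ({p.r:.3g} cm, {math.degrees(p.theta):.3g} deg) "
            "outside the tabulated hull; clamped to the nearest edge",
            stacklevel=2,
        )
    i = int(np.searchsorted(table.r_grid, r, side="right") - 1)
    j = int(np.searchsorted(table.theta_grid, theta_deg, side="right") - 1)
    i = min(max(i, 0), table.r_grid.size - 2)
    j = min(max(j, 0), table.theta_grid.size - 2)
    r0, r1 = table.r_grid[i], table.r_grid[i + 1]
    t0, t1 = table.theta_grid[j], table.theta_grid[j + 1]
    u = (r - r0) / (r1 - r0)
    v = (theta_deg - t0) / (t1 - t0)
    f = table.values
    return float(
        f[i, j] * (1 - u) * (1 - v)
        + f[i + 1, j] * u * (1 - v)
        + f[i, j + 1] * (1 - u) * v
        + f[i + 1, j + 1] * u * v
    )


def dose_rate(p: PolarPoint, src: SourceSpec) -> float:
    """TG43-U1 dose rate at a point, in s_k dose units per hour.

    The geometry factor is normalised at the source's reference point, so at
    (r0, theta0) the dose rate is exactly
    s_k * Lambda * g(r0) * F(r0, theta0).
    """
    g_ref = geometry_factor(PolarPoint(src.r0, src.theta0), src.capsule_length)
    g_here = geometry_factor(p, src.capsule_length)
    return (
        src.air_kerma_strength
        * src.dose_rate_constant
        * anisotropy_factor(p, src.anisotropy)
        * (g_here / g_ref)
        * radial_dose_function(p.r, src.radial_coeffs, src.radial_decay)
    )
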