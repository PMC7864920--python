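"""Closed-form interface optics for water-container stimulus simulation.

Everything in this module is analytic: Snell refraction of ray directions,
Fresnel power splitting at a single dielectric interface, total internal
reflection (TIR) conditions, incoherent power accounting across a thin
container wall (a two-face slab), and Beer-Lambert absorption in water.

Conventions
-----------
* Angles are degrees at every public interface; radians are used internally.
* Power propagation is unpolarised: the effective reflectance is
  ``Reff = (Rs + Rp) / 2`` and per-polarisation values are reported but never
  propagated.
* Direction changes across a thin wall use the thin-wall approximation (the
  two wall faces are treated as locally parallel, so the wall index cancels
  from the exit direction); power uses the full two-interface accounting.
* Beam powers add incoherently; there is no phase or interference tracking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional


@dataclass(frozen=True)
class Medium:
    """An optical medium: a name, a refractive index and an attenuation.

    Parameters
    ----------
    name : str
        Human-readable label ("water", "polystyrene", ...).
    n : float
        Refractive index, must be positive (>= 1 for all shipped presets).
    absorption_coeff : float, default 0
        Attenuation coefficient in 1/m used for Beer-Lambert absorption.
    """

    name: str
    n: float
    absorption_coeff: float = 0.0

    def __post_init__(self) -> None:
        if not (self.n > 0):
            raise ValueError(f"refractive index must be positive, got {self.n}")
        if self.absorption_coeff < 0:
            raise ValueError("absorption_coeff must be >= 0")


# Material presets.  The water attenuation default (0.05 / m) is a pure-water
# value for green stimulus light near 520 nm; it is configurable.
AIR = Medium("air", 1.0)
WATER = Medium("water", 1.333, absorption_coeff=0.05)
POLYSTYRENE = Medium("polystyrene", 1.57)
ACRYLIC = Medium("acrylic", 1.49)
BOROSILICATE = Medium("borosilicate", 1.473)

MATERIALS = {m.name: m for m in (AIR, WATER, POLYSTYRENE, ACRYLIC, BOROSILICATE)}


@dataclass(frozen=True)
class FresnelResult:
    """Power splitting of a beam at a single dielectric interface.

    ``theta_t`` is None under total internal reflection.  Invariants:
    ``Reff == (Rs + Rp) / 2``, ``T == 1 - Reff`` and, under TIR,
    ``Reff == 1`` and ``T == 0``.
    """

    theta_i: float
    theta_t: Optional[float]
    Rs: float
    Rp: float
    Reff: float
    T: float
    tir: bool


def _deg(x: float) -> float:
    return math.degrees(x)


def _rad(x: float) -> float:
    return math.radians(x)


def fresnel_coefficients(theta_i: float, n_i: float, n_t: float) -> FresnelResult:
    """Unpolarised Fresnel power coefficients at one dielectric interface.

    Parameters are the incidence angle in degrees (``0 <= theta_i <= 90``)
    and the refractive indices on the incident and transmission sides.
    """
    if not (0.0 <= theta_i <= 90.0):
        raise ValueError(f"incidence angle must lie in [0, 90] deg, got {theta_i}")
    if n_i <= 0 or n_t <= 0:
        raise ValueError("refractive indices must be positive")

    if theta_i == 90.0:  # grazing limit: fully reflecting for any media pair
        sin_t = n_i / n_t
        theta_t = _deg(math.asin(sin_t)) if sin_t <= 1.0 else None
        return FresnelResult(theta_i, theta_t, 1.0, 1.0, 1.0, 0.0, sin_t >= 1.0)
    ti = _rad(theta_i)
    sin_t = (n_i / n_t) * math.sin(ti)
    if sin_t > 1.0:
        # Total internal reflection: all power returns to the incident side.
        return FresnelResult(theta_i, None, 1.0, 1.0, 1.0, 0.0, True)

    tt = math.asin(min(sin_t, 1.0))
    ci, ct = math.cos(ti), math.cos(tt)
    denom_s = n_i * ci + n_t * ct
    denom_p = n_i * ct + n_t * ci
    if denom_s == 0.0 or denom_p == 0.0:  # grazing incidence, theta_i == 90
        return FresnelResult(theta_i, _deg(tt), 1.0, 1.0, 1.0, 0.0, sin_t >= 1.0)
    rs = ((n_i * ci - n_t * ct) / denom_s) ** 2
    rp = ((n_i * ct - n_t * ci) / denom_p) ** 2
    rs = min(rs, 1.0)
    rp = min(rp, 1.0)
    reff = 0.5 * (rs + rp)
    tir = sin_t >= 1.0  # exactly the critical angle counts as TIR onset
    if tir:
        rs = rp = reff = 1.0
    return FresnelResult(theta_i, _deg(tt), rs, rp, reff, 1.0 - reff, tir)


def refract_direction(incident, normal, n_i: float, n_t: float):
    """Refract a unit direction vector across an interface (vector Snell law).

    ``normal`` must be a unit vector pointing into the incident medium (so
    ``incident . normal < 0``).  Returns the refracted unit 3-vector as a
    tuple, or ``None`` when the ray is totally internally reflected.
    """
    if n_i <= 0 or n_t <= 0:
        raise ValueError("refractive indices must be positive")
    ix, iy, iz = float(incident[0]), float(incident[1]), float(incident[2])
    nx, ny, nz = float(normal[0]), float(normal[1]), float(normal[2])
    for (x, y, z), what in (((ix, iy, iz), "incident"), ((nx, ny, nz), "normal")):
        norm = math.sqrt(x * x + y * y + z * z)
        if abs(norm - 1.0) > 1e-6:
            raise ValueError(f"{what} vector must be unit length (|v| = {norm:.6g})")
    cos_i = -(ix * nx + iy * ny + iz * nz)
    if cos_i <= 0:
        raise ValueError("normal must point into the incident medium")
    eta = n_i / n_t
    k = 1.0 - eta * eta * (1.0 - cos_i * cos_i)
    if k < 0:
        return None  # total internal reflection
    a = eta
    b = eta * cos_i - math.sqrt(k)
    tx = a * ix + b * nx
    ty = a * iy + b * ny
    tz = a * iz + b * nz
    norm = math.sqrt(tx * tx + ty * ty + tz * tz)
    return (tx / norm, ty / norm, tz / norm)


def reflect_direction(incident, normal):
    """Mirror a direction about an interface normal."""
    ix, iy, iz = float(incident[0]), float(incident[1]), float(incident[2])
    nx, ny, nz = float(normal[0]), float(normal[1]), float(normal[2])
    d = ix * nx + iy * ny + iz * nz
    return (ix - 2.0 * d * nx, iy - 2.0 * d * ny, iz - 2.0 * d * nz)


def critical_angle(n_i: float, n_t: float) -> float:
    """Critical angle ``arcsin(n_t / n_i)`` in degrees (requires n_i > n_t)."""
    if n_i <= 0 or n_t <= 0:
        raise ValueError("refractive indices must be positive")
    if n_i <= n_t:
        raise ValueError("no TIR possible: incident medium is not denser")
    return _deg(math.asin(n_t / n_i))


def snells_window_half_elevation(n_water: float) -> float:
    """Lowest elevation (deg above the horizon) still inside Snell's window.

    Underwater, the entire above-surface hemisphere is compressed into a cone
    around the zenith whose half-angle equals the critical angle; seen in
    elevation coordinates the window spans ``90 - arcsin(1/n)`` up to 90 deg.
    For water (n = 1.333) this is 41.4 deg.
    """
    if n_water <= 1.0:
        raise ValueError("n_water must exceed 1")
    return 90.0 - _deg(math.asin(1.0 / n_water))


def flat_side_wall_tir_limit(n_water: float) -> float:
    """Maximum external incidence angle on a thin vertical wall that feeds TIR.

    A ray entering a thin vertical flat wall at external incidence ``alpha``
    travels in the water at ``beta`` with ``sin(alpha) = n sin(beta)`` (the
    wall material cancels for parallel faces).  It strikes the horizontal
    water surface at ``90 - beta`` from the vertical, which exceeds the
    critical angle - hence undergoes TIR - whenever
    ``alpha < arcsin(sqrt(n^2 - 1))``.  For water this limit is ~62 deg.
    """
    if n_water <= 1.0:
        raise ValueError("n_water must exceed 1")
    s = math.sqrt(n_water * n_water - 1.0)
    if s >= 1.0:
        return 90.0
    return _deg(math.asin(s))


def beer_lambert_absorption(path_length: float, absorption_coeff: float) -> float:
    """Fraction of power absorbed over ``path_length`` metres of medium."""
    if path_length < 0 or absorption_coeff < 0:
        raise ValueError("path length and absorption coefficient must be >= 0")
    return 1.0 - math.exp(-absorption_coeff * path_length)


# ---------------------------------------------------------------------------
# Two-face slab (container wall) power accounting
# ---------------------------------------------------------------------------

def slab_power_coefficients(theta_i: float, near: Medium, wall: Medium,
                            far: Medium) -> tuple[float, float, Optional[float]]:
    """Incoherent reflectance/transmittance of a thin wall between two media.

    A beam in medium ``near`` strikes a wall of medium ``wall`` behind which
    lies medium ``far`` at incidence ``theta_i`` (deg).  Multiple internal
    bounces inside the wall are summed as a geometric series, giving

        R = r1 + (1 - r1)^2 r2 / (1 - r1 r2)
        T = (1 - r1)(1 - r2) / (1 - r1 r2)

    with r1, r2 the single-face unpolarised reflectances.  Returns
    ``(R, T, theta_out)`` where ``theta_out`` is the exit angle in ``far``
    (None when the stack is totally reflecting).  TIR at either face (r = 1)
    collapses the series to R = 1, T = 0.
    """
    f1 = fresnel_coefficients(theta_i, near.n, wall.n)
    if f1.tir:
        return 1.0, 0.0, None
    f2 = fresnel_coefficients(f1.theta_t, wall.n, far.n)
    r1, r2 = f1.Reff, f2.Reff
    denom = 1.0 - r1 * r2
    if denom <= 0:
        return 1.0, 0.0, None
    R = r1 + (1.0 - r1) ** 2 * r2 / denom
    T = (1.0 - r1) * (1.0 - r2) / denom
    if f2.tir or T <= 0.0:
        return 1.0, 0.0, None
    # Thin wall: parallel faces make the overall exit angle wall-independent.
    sin_out = (near.n / far.n) * math.sin(_rad(theta_i))
    theta_out = _deg(math.asin(min(sin_out, 1.0)))
    return R, T, theta_out


@dataclass(frozen=True)
class BeamEntry:
    label: str
    order: int              # number of internal reflections inside the wall
    exit_side: str          # "near" (reflected back) or "far" (transmitted)
    power: float            # fraction of the incident power
    exit_angle: float       # deg, in the exit medium


@dataclass
class BeamLedger:
    """Bookkeeping of every beam leaving a two-face wall stack.

    ``entries`` lists beams in enumeration order; R-labels are beams returned
    to the incident side, T-labels beams transmitted to the far side.
    ``truncated`` is the power still bouncing inside the wall when the
    expansion stops, ``absorbed`` the power lost to wall attenuation.
    """

    entries: list[BeamEntry] = field(default_factory=list)
    incident_power: float = 1.0
    truncated: float = 0.0
    absorbed: float = 0.0

    def total_exit_power(self, side: Optional[str] = None) -> float:
        return sum(e.power for e in self.entries
                   if side is None or e.exit_side == side)

    @property
    def reflected_power(self) -> float:
        return self.total_exit_power("near")

    @property
    def transmitted_power(self) -> float:
        return self.total_exit_power("far")

    def __getitem__(self, label: str) -> BeamEntry:
        for e in self.entries:
            if e.label == label:
                return e
        raise KeyError(label)


def wall_stack_beam_ledger(theta_i: float, outer: Medium, wall: Medium,
                           inner: Medium, max_order: int = 6,
                           thickness_mm: float = 0.0) -> BeamLedger:
    """Enumerate the beams produced by one wall for a beam incident from ``outer``.

    The beam splits at the outer and inner wall faces; internal bounces are
    expanded up to ``max_order`` reflections inside the wall.  With a nonzero
    ``thickness_mm`` and an absorbing wall material, each internal traversal
    is attenuated by Beer-Lambert absorption along the oblique path.
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    ledger = BeamLedger()
    f1 = fresnel_coefficients(theta_i, outer.n, wall.n)
    n_r = n_t = 0
    if f1.Reff > 0:
        n_r += 1
        ledger.entries.append(BeamEntry(f"R{n_r}", 0, "near", f1.Reff, theta_i))
    if f1.tir or f1.T <= 0:
        return ledger
    theta_w = f1.theta_t
    f_inner = fresnel_coefficients(theta_w, wall.n, inner.n)
    f_outer = fresnel_coefficients(theta_w, wall.n, outer.n)

    attenuation = 1.0
    if thickness_mm > 0 and wall.absorption_coeff > 0:
        path_m = thickness_mm / 1000.0 / max(math.cos(_rad(theta_w)), 1e-12)
        attenuation = math.exp(-wall.absorption_coeff * path_m)

    p = f1.T  # beam inside the wall heading for the inner face
    for order in range(max_order + 1):
        lost = p * (1.0 - attenuation)
        ledger.absorbed += lost
        p *= attenuation
        if order % 2 == 0:  # at the inner face
            out = p * f_inner.T
            if out > 0:
                n_t += 1
                ledger.entries.append(
                    BeamEntry(f"T{n_t}", order, "far", out, f_inner.theta_t))
            p *= f_inner.Reff
        else:  # back at the outer face
            out = p * f_outer.T
            if out > 0:
                n_r += 1
                ledger.entries.append(
                    BeamEntry(f"R{n_r}", order, "near", out, f_outer.theta_t))
            p *= f_outer.Reff
        if p <= 0:
            break
    ledger.truncated = p
    return ledger


def stack_reflectance(theta_i: float, near: Medium, wall: Medium,
                      far: Medium) -> float:
    """Total power returned toward ``near`` by the wall stack (closed form)."""
    R, _, _ = slab_power_coefficients(theta_i, near, wall, far)
    return R


def contralateral_reflection(theta_i: float = 0.0, outside: Medium = AIR,
                             wall: Medium = BOROSILICATE,
                             inside: Medium = WATER) -> float:
    """Fraction of near-normal stimulus light returned toward the far eye.

    A beam enters the container wall from ``outside`` at ``theta_i``, crosses
    the water volume, and strikes the opposite wall from inside; the fraction
    of the wall-stack reflection heading back toward the observer is the
    entry transmittance times the inside-out stack reflectance.  At near
    normal incidence this is ~4% for a glass bulb and ~5% for a polystyrene
    dish.
    """
    _, T_in, theta_inside = slab_power_coefficients(theta_i, outside, wall, inside)
    if theta_inside is None:
        return 0.0
    R_back = stack_reflectance(theta_inside, inside, wall, outside)
    return T_in * R_back


def bulb_crossing_beams(theta_i: float = 0.0, outer: Medium = AIR,
                        wall: Medium = BOROSILICATE,
                        inner: Medium = WATER) -> dict:
    """Strong-beam expansion of a beam crossing a walled water sphere.

    The beam enters through the near wall, crosses the water, and splits at
    the far wall; only the beams carrying appreciable power are labelled.
    Angles: ``alpha`` is the external incidence, ``beta`` the angle inside the
    wall, ``gamma`` the angle in the water (thin-wall approximation).  Powers
    are fractions of the source power:

    ========  ======================================================
    R1        reflection at the outer face of the entry wall
    T1        beam inside the entry wall
    T2        beam in the water after entry
    R2        entry wall-water face reflection (inside the glass)
    R3        R2 after exiting the outer entry face (back toward source)
    T3        beam inside the far wall
    R5        far water-wall face reflection (heads back toward the eye)
    T4        beam exiting the far outer face (leaves the container)
    R4        far wall-air face reflection (inside the far wall)
    T5        R4 transmitted back into the water (toward the eye)
    ========  ======================================================

    At near-normal incidence the triplets T1 = T2 = T3, R2 = R3 = R5 and the
    pair R4 = T5 are equal within a few percent; the total power heading back
    through the water toward the observer, R5 + T5, is ~4% for glass.
    """
    f_ow = fresnel_coefficients(theta_i, outer.n, wall.n)
    alpha, beta = theta_i, f_ow.theta_t
    if beta is None:
        raise ValueError("entry face is totally reflecting at this angle")
    f_wi = fresnel_coefficients(beta, wall.n, inner.n)
    gamma = f_wi.theta_t
    if gamma is None:
        raise ValueError("wall-water face is totally reflecting at this angle")
    r_ow, r_wi = f_ow.Reff, f_wi.Reff
    # Reciprocity at matched angle pairs: water->wall at gamma equals
    # wall->water at beta, wall->outer at beta equals outer->wall at alpha.
    r_iw = fresnel_coefficients(gamma, inner.n, wall.n).Reff
    r_wo = fresnel_coefficients(beta, wall.n, outer.n).Reff

    beams = {"alpha": alpha, "beta": beta, "gamma": gamma}
    beams["R1"] = r_ow
    beams["T1"] = 1.0 - r_ow
    beams["T2"] = beams["T1"] * (1.0 - r_wi)
    beams["R2"] = beams["T1"] * r_wi
    beams["R3"] = beams["R2"] * (1.0 - r_wo)
    beams["T3"] = beams["T2"] * (1.0 - r_iw)
    beams["R5"] = beams["T2"] * r_iw
    beams["T4"] = beams["T3"] * (1.0 - r_wo)
    beams["R4"] = beams["T3"] * r_wo
    beams["T5"] = beams["R4"] * (1.0 - r_wi)
    beams["returned_total"] = beams["R5"] + beams["T5"]
    return beams
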