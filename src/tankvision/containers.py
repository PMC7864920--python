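"""Container scenes: optical surfaces, water levels, observers and occluders.

Three container families are shipped as presets, all built around a small
aquatic animal (e.g. a zebrafish larva) immersed at a known position:

* ``petri_lid`` - a flat polystyrene Petri-dish lid (diameter 38.7 mm, depth
  4 mm) holding ~2.3 mm of water, animal 0.5 mm above the bottom;
* ``cylinder`` - an acrylic cylinder (diameter 40 mm, height 50 mm) filled
  with water, animal on a stage at mid-height;
* ``bulb_8cm`` / ``bulb_8cm_full`` - a borosilicate glass sphere of 80 mm
  diameter with a 48 mm top opening, animal at the centre, filled to the rim;
* ``bulb_10cm_low`` - a 100 mm glass sphere filled only to 10 mm above the
  animal (a low-water condition that makes the free surface visible);
* ``ideal`` - no container at all (reference condition).

Coordinates: the observer (animal eye) sits at the origin.  Azimuth 0 deg is
rostral (+x), positive clockwise seen from above (+y), range [-180, 180).
Elevation 0 deg is the horizontal equator, +90 deg straight up (+z).  All
lengths are millimetres.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional

from .optics_core import (AIR, WATER, MATERIALS, Medium)

_EPS = 1e-9


class ConfigError(ValueError):
    """A scene/preset configuration problem (unknown preset or override)."""


def direction_from_angles(azimuth_deg: float, elevation_deg: float):
    """Unit view vector for (azimuth, elevation) in the scene convention."""
    az, el = math.radians(azimuth_deg), math.radians(elevation_deg)
    return (math.cos(el) * math.cos(az), math.cos(el) * math.sin(az), math.sin(el))


def angles_from_direction(d) -> tuple[float, float]:
    """(azimuth, elevation) in degrees for a unit direction vector."""
    az = math.degrees(math.atan2(d[1], d[0]))
    el = math.degrees(math.asin(max(-1.0, min(1.0, d[2]))))
    if az >= 180.0:
        az -= 360.0
    return az, el


# ---------------------------------------------------------------------------
# Surfaces
# ---------------------------------------------------------------------------

@dataclass
class MeniscusProfile:
    """Circular-arc meniscus joining a flat water surface to a vertical wall.

    The arc is tangent to the flat surface at its inner edge and meets the
    wall with the given contact angle (measured through the water between the
    wall and the surface tangent).  ``contact_angle = 90`` degenerates to a
    flat surface (zero-width annulus, no optical deviation).
    """

    rim_radius: float
    contact_angle: float
    height: float
    r_start: float = field(init=False)
    arc_radius: float = field(init=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.contact_angle < 180.0):
            raise ValueError("contact angle must lie in (0, 180) deg")
        if self.height < 0:
            raise ValueError("meniscus height must be >= 0")
        phi = math.radians(90.0 - self.contact_angle)  # max surface slope angle
        if self.height == 0 or abs(phi) < 1e-12:
            self.arc_radius = math.inf
            self.r_start = self.rim_radius
            return
        self.arc_radius = self.height / (1.0 - math.cos(abs(phi)))
        width = self.arc_radius * math.sin(abs(phi))
        self.r_start = max(0.0, self.rim_radius - width)

    def slope_angle(self, r: float) -> float:
        """Surface slope angle (radians, >= 0) at radial distance r."""
        if not (self.r_start < r <= self.rim_radius) or math.isinf(self.arc_radius):
            return 0.0
        s = min(1.0, (r - self.r_start) / self.arc_radius)
        return math.asin(s)

    def normal_at(self, x: float, y: float):
        """Perturbed water-surface normal at point (x, y), pointing up."""
        r = math.hypot(x, y)
        psi = self.slope_angle(r)
        if psi == 0.0 or r == 0.0:
            return (0.0, 0.0, 1.0)
        # Surface rises toward the wall: the normal tilts toward the axis.
        s, c = math.sin(psi), math.cos(psi)
        return (-s * x / r, -s * y / r, c)


def meniscus_profile(rim_radius: float, contact_angle: float,
                     meniscus_height: float) -> MeniscusProfile:
    """Build the annular circular-arc meniscus patch for a wall rim."""
    return MeniscusProfile(rim_radius, contact_angle, meniscus_height)


@dataclass
class SurfacePatch:
    """Base class for optical surfaces.  ``wall`` is the wall material for
    thin-walled surfaces (None for a bare water-air surface); ``outer`` is
    the medium on the far side."""

    role: str = "surface"
    wall: Optional[Medium] = None
    outer: Medium = AIR

    shape = "abstract"

    def intersect(self, o, d) -> Optional[float]:  # pragma: no cover - abstract
        raise NotImplementedError

    def normal(self, p):  # pragma: no cover - abstract
        raise NotImplementedError


@dataclass
class Disc(SurfacePatch):
    """Horizontal annular disc at height z (r_inner <= r <= r_outer)."""

    z: float = 0.0
    r_outer: float = 1.0
    r_inner: float = 0.0
    meniscus: Optional[MeniscusProfile] = None
    shape = "disc"

    def __post_init__(self) -> None:
        if self.r_outer <= 0 or self.r_inner < 0:
            raise ValueError("disc radii must be positive")

    def intersect(self, o, d):
        if abs(d[2]) < 1e-14:
            return None
        t = (self.z - o[2]) / d[2]
        if t <= _EPS:
            return None
        x, y = o[0] + t * d[0], o[1] + t * d[1]
        r2 = x * x + y * y
        if self.r_inner ** 2 - 1e-12 <= r2 <= self.r_outer ** 2 + 1e-12:
            return t
        return None

    def normal(self, p):
        if self.meniscus is not None:
            return self.meniscus.normal_at(p[0], p[1])
        return (0.0, 0.0, 1.0)


@dataclass
class CylinderShell(SurfacePatch):
    """Vertical cylindrical wall about the z axis, z_min <= z <= z_max."""

    radius: float = 1.0
    z_min: float = 0.0
    z_max: float = 1.0
    shape = "cylinder-shell"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("cylinder radius must be positive")
        if self.z_max <= self.z_min:
            raise ValueError("z_max must exceed z_min")

    def intersect(self, o, d):
        a = d[0] * d[0] + d[1] * d[1]
        if a < 1e-16:
            return None
        b = o[0] * d[0] + o[1] * d[1]
        c = o[0] * o[0] + o[1] * o[1] - self.radius ** 2
        disc = b * b - a * c
        if disc < 0:
            return None
        sq = math.sqrt(disc)
        for t in ((-b - sq) / a, (-b + sq) / a):
            if t > _EPS and self.z_min - 1e-9 <= o[2] + t * d[2] <= self.z_max + 1e-9:
                return t
        return None

    def normal(self, p):
        r = math.hypot(p[0], p[1])
        return (p[0] / r, p[1] / r, 0.0)


@dataclass
class SphereShell(SurfacePatch):
    """Spherical shell centred at the origin, cut open above z_cut."""

    radius: float = 1.0
    z_cut: Optional[float] = None  # opening: no shell where z > z_cut
    shape = "sphere-shell"

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")

    def intersect(self, o, d):
        b = o[0] * d[0] + o[1] * d[1] + o[2] * d[2]
        c = o[0] ** 2 + o[1] ** 2 + o[2] ** 2 - self.radius ** 2
        disc = b * b - c
        if disc < 0:
            return None
        sq = math.sqrt(disc)
        for t in (-b - sq, -b + sq):
            if t > _EPS:
                z = o[2] + t * d[2]
                if self.z_cut is None or z <= self.z_cut + 1e-9:
                    return t
        return None

    def normal(self, p):
        return (p[0] / self.radius, p[1] / self.radius, p[2] / self.radius)


# ---------------------------------------------------------------------------
# Occluders (absorbing regions of the view field)
# ---------------------------------------------------------------------------

@dataclass
class ConeOccluder:
    """Microscope objective: blocks every view above the access elevation."""

    access_elevation: float = 39.2
    tag: str = "objective"

    def blocks(self, azimuth: float, elevation: float) -> bool:
        return elevation > self.access_elevation


@dataclass
class SectorOccluder:
    """Coarse absorbing silhouette (holder, stage) as an az/el sector."""

    az_center: float = 180.0
    az_halfwidth: float = 12.0
    el_min: float = -90.0
    el_max: float = -10.0
    tag: str = "holder"

    def blocks(self, azimuth: float, elevation: float) -> bool:
        daz = (azimuth - self.az_center + 180.0) % 360.0 - 180.0
        return abs(daz) <= self.az_halfwidth and self.el_min <= elevation <= self.el_max


# ---------------------------------------------------------------------------
# Scene
# ---------------------------------------------------------------------------

@dataclass
class ContainerScene:
    """A virtual tank: surfaces, water level and occluders around an observer.

    ``water_level`` is the height of the free water surface above the
    observer (mm); None means the observer is in air (ideal preset).
    ``observer_medium`` is the medium at the origin.
    """

    name: str
    surfaces: list = field(default_factory=list)
    occluders: list = field(default_factory=list)
    water_level: Optional[float] = None
    observer_medium: Medium = WATER
    stimulus_shell_radius: float = 10000.0
    params: dict = field(default_factory=dict)

    @property
    def water_surface(self) -> Optional[Disc]:
        for s in self.surfaces:
            if s.role == "water_surface":
                return s
        return None

    @property
    def sphere(self) -> Optional[SphereShell]:
        for s in self.surfaces:
            if isinstance(s, SphereShell):
                return s
        return None

    def blocked_by(self, azimuth: float, elevation: float) -> Optional[str]:
        for occ in self.occluders:
            if occ.blocks(azimuth, elevation):
                return occ.tag
        return None


@dataclass(frozen=True)
class Hit:
    surface: SurfacePatch
    t: float
    point: tuple
    normal: tuple  # geometric outward normal (not flipped)


def intersect_ray(scene: ContainerScene, origin, direction) -> Optional[Hit]:
    """Closest surface intersection of a ray, or None (far field)."""
    norm = math.sqrt(sum(c * c for c in direction))
    if norm < 1e-12:
        raise ValueError("degenerate (zero) ray direction")
    d = tuple(c / norm for c in direction)
    best_t, best_s = None, None
    for s in scene.surfaces:
        t = s.intersect(origin, d)
        if t is not None and (best_t is None or t < best_t):
            best_t, best_s = t, s
    if best_s is None:
        return None
    p = (origin[0] + best_t * d[0], origin[1] + best_t * d[1],
         origin[2] + best_t * d[2])
    return Hit(best_s, best_t, p, best_s.normal(p))


def occlusion_test(scene: ContainerScene, view_direction) -> tuple[bool, Optional[str]]:
    """Whether a view direction from the observer is blocked, and by what."""
    az, el = angles_from_direction(view_direction)
    tag = scene.blocked_by(az, el)
    return tag is not None, tag


def surface_rim_elevation(scene: ContainerScene) -> Optional[float]:
    """Elevation (deg) at which the free water surface meets a spherical shell.

    For a horizontal surface at height h above a centred observer inside a
    sphere of radius R the rim sits at ``arcsin(h / R)``; equivalently
    ``arccos(r_rim / R)`` for a rim of radius r_rim.  Returns None when no
    free surface exists in the field of view.
    """
    sphere = scene.sphere
    if sphere is None:
        raise TypeError("surface_rim_elevation requires a spherical container")
    if scene.water_level is None:
        return None
    h = scene.water_level
    if h >= sphere.radius:
        return None
    if abs(h) >= sphere.radius:
        raise ValueError("observer lies outside the sphere")
    return math.degrees(math.asin(h / sphere.radius))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

_PRESET_PARAMS = {
    "petri_lid": dict(diameter=38.7, depth=4.0, water_level=2.3,
                      observer_height=0.5, material="polystyrene",
                      wall_thickness=1.0, meniscus_contact_angle=None,
                      meniscus_height=1.0),
    "cylinder": dict(diameter=40.0, height=50.0, stage_height=25.0,
                     observer_above_stage=1.75, material="acrylic",
                     wall_thickness=2.0, meniscus_contact_angle=None,
                     meniscus_height=1.0),
    "bulb_8cm": dict(diameter=80.0, opening_diameter=48.0, water_level="full",
                     material="borosilicate", wall_thickness=1.5,
                     objective=False, objective_access=39.2, holder=False,
                     meniscus_contact_angle=None, meniscus_height=1.0),
    "bulb_8cm_full": dict(diameter=80.0, opening_diameter=48.0,
                          water_level="full", material="borosilicate",
                          wall_thickness=1.5, objective=False,
                          objective_access=39.2, holder=False,
                          meniscus_contact_angle=None, meniscus_height=1.0),
    "bulb_10cm_low": dict(diameter=100.0, opening_diameter=48.0,
                          water_level=10.0, material="borosilicate",
                          wall_thickness=1.5, objective=False,
                          objective_access=39.2, holder=False,
                          meniscus_contact_angle=None, meniscus_height=1.0),
    "ideal": dict(),
}

PRESET_NAMES = tuple(_PRESET_PARAMS)


def build_preset(name: str, **overrides) -> ContainerScene:
    """Construct one of the shipped container scenes, with optional overrides.

    Override keys must name existing preset parameters (strict); values keep
    the units of the defaults (mm, deg).
    """
    if name not in _PRESET_PARAMS:
        raise ConfigError(f"unknown preset {name!r}; known: {sorted(_PRESET_PARAMS)}")
    params = copy.deepcopy(_PRESET_PARAMS[name])
    for key, value in overrides.items():
        if key not in params:
            raise ConfigError(f"unknown override {key!r} for preset {name!r}")
        params[key] = value

    if name == "ideal":
        return ContainerScene("ideal", [], [], water_level=None,
                              observer_medium=AIR, params=params)
    if name == "petri_lid":
        return _build_petri(params)
    if name == "cylinder":
        return _build_cylinder(params)
    return _build_bulb(name, params)


def _material(params) -> Medium:
    try:
        return MATERIALS[params["material"]]
    except KeyError:
        raise ConfigError(f"unknown material {params['material']!r}")


def _maybe_meniscus(params, rim_radius) -> Optional[MeniscusProfile]:
    if params.get("meniscus_contact_angle") is None:
        return None
    return meniscus_profile(rim_radius, params["meniscus_contact_angle"],
                            params["meniscus_height"])


def _build_petri(params) -> ContainerScene:
    r = params["diameter"] / 2.0
    z_bottom = -params["observer_height"]
    z_water = params["water_level"] - params["observer_height"]
    z_rim = params["depth"] - params["observer_height"]
    if not (z_bottom < 0.0 < z_water):
        raise ConfigError("observer must lie inside the water volume")
    mat = _material(params)
    surfaces = [
        Disc(role="bottom", wall=mat, outer=AIR, z=z_bottom, r_outer=r),
        Disc(role="water_surface", wall=None, outer=AIR, z=z_water, r_outer=r,
             meniscus=_maybe_meniscus(params, r)),
        CylinderShell(role="side_wall", wall=mat, outer=AIR, radius=r,
                      z_min=z_bottom, z_max=z_rim),
    ]
    return ContainerScene("petri_lid", surfaces, [], water_level=z_water,
                          params=params)


def _build_cylinder(params) -> ContainerScene:
    r = params["diameter"] / 2.0
    z_obs = params["stage_height"] + params["observer_above_stage"]
    z_bottom = -z_obs
    z_top = params["height"] - z_obs
    if not (z_bottom < 0.0 < z_top):
        raise ConfigError("observer must lie inside the water volume")
    mat = _material(params)
    surfaces = [
        Disc(role="bottom", wall=mat, outer=AIR, z=z_bottom, r_outer=r),
        Disc(role="water_surface", wall=None, outer=AIR, z=z_top, r_outer=r,
             meniscus=_maybe_meniscus(params, r)),
        CylinderShell(role="side_wall", wall=mat, outer=AIR, radius=r,
                      z_min=z_bottom, z_max=z_top),
    ]
    return ContainerScene("cylinder", surfaces, [], water_level=z_top,
                          params=params)


def _build_bulb(name, params) -> ContainerScene:
    R = params["diameter"] / 2.0
    r_open = params["opening_diameter"] / 2.0
    if r_open >= R:
        raise ConfigError("opening must be smaller than the sphere")
    z_cut = math.sqrt(R * R - r_open * r_open)
    level = params["water_level"]
    z_water = z_cut if level == "full" else float(level)
    if not (-R < z_water <= z_cut):
        raise ConfigError("water level must lie inside the bulb")
    mat = _material(params)
    r_surface = math.sqrt(max(R * R - z_water * z_water, 0.0))
    surfaces = [
        SphereShell(role="side_wall", wall=mat, outer=AIR, radius=R, z_cut=z_cut),
        Disc(role="water_surface", wall=None, outer=AIR, z=z_water,
             r_outer=r_surface, meniscus=_maybe_meniscus(params, r_surface)),
    ]
    occluders = []
    if params.get("objective"):
        occluders.append(ConeOccluder(access_elevation=params["objective_access"]))
    if params.get("holder"):
        occluders.append(SectorOccluder())
    return ContainerScene(name, surfaces, occluders, water_level=z_water,
                          params=params)


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def scene_to_dict(scene: ContainerScene) -> dict:
    """Round-trippable description of a preset scene (units: mm, deg)."""
    return {
        "schema_version": SCHEMA_VERSION,
        "preset": scene.name,
        "units": {"length": "mm", "angle": "deg"},
        "params": copy.deepcopy(scene.params),
    }


def scene_from_dict(data: dict) -> ContainerScene:
    if data.get("schema_version") != SCHEMA_VERSION:
        raise ConfigError(f"unsupported scene schema: {data.get('schema_version')}")
    params = dict(data.get("params", {}))
    return build_preset(data["preset"], **params)


def save_scene(scene: ContainerScene, path) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(scene_to_dict(scene), fh, sort_keys=True)


def load_scene(path) -> ContainerScene:
    import yaml
    with open(path) as fh:
        return scene_from_dict(yaml.safe_load(fh))
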