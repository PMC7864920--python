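"""Backward ray tracing from the eye, panorama rendering and motion fields.

The tracer starts at the observer's eye and follows each viewing direction
out through the container.  At every interface the beam splits into a
reflected and a transmitted branch (unpolarised Fresnel power), branches
below a power floor are pruned, and surviving branches terminate on the
far-field stimulus shell.  Because the containers are small relative to the
stimulus arena, a branch's terminal *direction* identifies the stimulus
source it sees (far-field approximation).

A :class:`Panorama` collects one such trace per cell of an equirectangular
grid (azimuth x elevation), keeping every terminal contribution together
with its power, TIR count, reflection order and vertical-mirror parity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

import numpy as np

from .containers import (ContainerScene, Disc, angles_from_direction,
                         direction_from_angles, intersect_ray)
from .optics_core import (AIR, WATER, fresnel_coefficients, reflect_direction,
                          refract_direction, slab_power_coefficients)

_HORIZONTAL_ROLES = ("water_surface", "bottom")


@dataclass
class TracedPath:
    """One branch of a backward trace.

    ``terminal_direction`` is the unit direction on the stimulus shell (None
    for blocked/truncated branches); ``power`` the fraction of the eye-ward
    beam carried; ``tir_count`` counts TIR events at horizontal surfaces
    (free water surface and flat bottom); ``horizontal_reflections`` counts
    every reflection at a horizontal surface (TIR or partial) and determines
    the vertical mirror parity of the perceived image.
    """

    terminal_direction: Optional[tuple]
    power: float
    tir_count: int = 0
    horizontal_reflections: int = 0
    reflection_order: int = 0
    status: str = "exited"  # exited | blocked | truncated
    events: list = field(default_factory=list)


@dataclass
class TraceResult:
    """All branches traced for one viewing direction, plus power accounting."""

    branches: list
    absorbed_power: float = 0.0
    truncated_power: float = 0.0
    blocked_power: float = 0.0

    @property
    def terminal_power(self) -> float:
        return sum(b.power for b in self.branches if b.status == "exited")

    @property
    def dominant(self) -> Optional[TracedPath]:
        exited = [b for b in self.branches if b.status == "exited"]
        return max(exited, key=lambda b: b.power) if exited else None


def trace_from_eye(scene: ContainerScene, view_direction, max_events: int = 12,
                   min_power: float = 1e-3, absorption: bool = True,
                   record_events: bool = False) -> TraceResult:
    """Backward-trace one viewing direction from the observer.

    Branches split at every interface when both the reflected and the
    transmitted component carry at least ``min_power``; a branch ends on the
    stimulus shell (far field), on an occluder, after ``max_events``
    interface events, or when its power falls below the floor.
    """
    if max_events < 1:
        raise ValueError("max_events must be >= 1")
    if not (0.0 < min_power < 1.0):
        raise ValueError("min_power must lie in (0, 1)")
    norm = math.sqrt(sum(c * c for c in view_direction))
    if abs(norm - 1.0) > 1e-6:
        raise ValueError("view direction must be a unit vector")
    d0 = tuple(c / norm for c in view_direction)

    result = TraceResult(branches=[])

    az, el = angles_from_direction(d0)
    tag = scene.blocked_by(az, el)
    if tag is not None:
        result.blocked_power = 1.0
        result.branches.append(TracedPath(None, 1.0, status="blocked",
                                          events=[((0, 0, 0), tag, "blocked", 1.0)]
                                          if record_events else []))
        return result

    # state: (pos, dir, medium, power, tir, hrefl, order, n_events, events)
    stack = [((0.0, 0.0, 0.0), d0, scene.observer_medium, 1.0, 0, 0, 0, 0, [])]
    while stack:
        pos, d, medium, power, tir, hrefl, order, n_ev, events = stack.pop()
        hit = intersect_ray(scene, pos, d)
        if hit is None:
            result.branches.append(TracedPath(d, power, tir, hrefl, order,
                                              "exited", events))
            continue
        if absorption and medium.absorption_coeff > 0:
            keep = math.exp(-medium.absorption_coeff * hit.t / 1000.0)
            result.absorbed_power += power * (1.0 - keep)
            power *= keep
        if n_ev >= max_events:
            result.truncated_power += power
            result.branches.append(TracedPath(None, power, tir, hrefl, order,
                                              "truncated", events))
            continue

        surface = hit.surface
        n = hit.normal
        if n[0] * d[0] + n[1] * d[1] + n[2] * d[2] > 0:
            n = (-n[0], -n[1], -n[2])  # oppose the ray

        # Media on the two sides of this surface, seen from the current state.
        if surface.role == "water_surface":
            # bare interface: water below, air pocket above
            other = surface.outer if medium.name == "water" else WATER
            wall = None
        else:
            other = surface.outer
            wall = surface.wall

        cos_i = -(d[0] * n[0] + d[1] * n[1] + d[2] * n[2])
        theta_i = math.degrees(math.acos(max(-1.0, min(1.0, cos_i))))
        if wall is None:
            fr = fresnel_coefficients(theta_i, medium.n, other.n)
            R, T = fr.Reff, fr.T
        else:
            R, T, _ = slab_power_coefficients(theta_i, medium, wall, other)
        is_tir = T <= 0.0

        # Transmitted branch.
        if T > 0.0:
            pt = power * T
            if pt >= min_power:
                refr = refract_direction(d, n, medium.n, other.n)
                if refr is not None:
                    ev = events + [(hit.point, surface.role, "refract", pt)] \
                        if record_events else events
                    if surface.role == "water_surface":
                        # still inside the container (air pocket or water)
                        stack.append((hit.point, refr, other, pt, tir, hrefl,
                                      order, n_ev + 1, ev))
                    else:
                        # through a wall: leaves the container, far field
                        result.branches.append(TracedPath(refr, pt, tir, hrefl,
                                                          order, "exited", ev))
            else:
                result.truncated_power += power * T

        # Reflected branch.
        if R > 0.0:
            pr = power * R
            if pr >= min_power:
                refl = reflect_direction(d, n)
                horizontal = surface.role in _HORIZONTAL_ROLES
                kind = "tir" if is_tir else "reflect"
                ev = events + [(hit.point, surface.role, kind, pr)] \
                    if record_events else events
                stack.append((hit.point, refl, medium, pr,
                              tir + (1 if is_tir and horizontal else 0),
                              hrefl + (1 if horizontal else 0),
                              order + 1, n_ev + 1, ev))
            else:
                result.truncated_power += power * R
    return result


# ---------------------------------------------------------------------------
# Stimulus textures
# ---------------------------------------------------------------------------

# Quadrant hues of the reference checkerboard: the upper visual field is
# split into green (right) and purple (left) quarters, the lower field into
# blue (right) and orange (left).
QUADRANT_COLORS = {
    "upper_right": (0.20, 0.75, 0.30),
    "upper_left": (0.60, 0.25, 0.75),
    "lower_right": (0.20, 0.35, 0.85),
    "lower_left": (0.90, 0.55, 0.15),
}


def quadrant(azimuth, elevation) -> str:
    vert = "upper" if elevation >= 0 else "lower"
    side = "right" if azimuth >= 0 else "left"
    return f"{vert}_{side}"


class StimulusTexture:
    """Maps a stimulus-shell direction to an RGB colour in [0, 1]."""

    name = "texture"

    def color_at(self, azimuth: float, elevation: float):
        raise NotImplementedError

    def color_array(self, azimuth: np.ndarray, elevation: np.ndarray) -> np.ndarray:
        az = np.asarray(azimuth, dtype=float).ravel()
        el = np.asarray(elevation, dtype=float).ravel()
        out = np.empty((az.size, 3))
        for i in range(az.size):
            out[i] = self.color_at(az[i], el[i])
        return out


class CheckerboardTexture(StimulusTexture):
    """Quadrant-coloured checkerboard: 36 columns x 18 rows of 10 deg patches."""

    name = "checkerboard"

    def __init__(self, columns: int = 36, rows: int = 18):
        self.columns, self.rows = columns, rows
        self._daz = 360.0 / columns
        self._del = 180.0 / rows

    def patch_index(self, azimuth, elevation):
        col = int((azimuth + 180.0) // self._daz) % self.columns
        row = int((elevation + 90.0) // self._del) % self.rows
        return col, row

    def color_at(self, azimuth, elevation):
        col, row = self.patch_index(azimuth, elevation)
        base = np.array(QUADRANT_COLORS[quadrant(azimuth, elevation)])
        shade = 1.0 if (col + row) % 2 == 0 else 0.45
        return tuple(base * shade)

    def color_array(self, azimuth, elevation):
        az = np.asarray(azimuth, dtype=float)
        el = np.asarray(elevation, dtype=float)
        col = np.floor((az + 180.0) / self._daz).astype(int) % self.columns
        row = np.floor((el + 90.0) / self._del).astype(int) % self.rows
        shade = np.where((col + row) % 2 == 0, 1.0, 0.45)
        out = np.empty(az.shape + (3,))
        upper = el >= 0
        right = az >= 0
        for mask, key in (((upper & right), "upper_right"),
                          ((upper & ~right), "upper_left"),
                          ((~upper & right), "lower_right"),
                          ((~upper & ~right), "lower_left")):
            out[mask] = QUADRANT_COLORS[key]
        return out * shade[..., None]


class GratingTexture(StimulusTexture):
    """Sinusoidal grating: spatial frequency in cycles/deg along one axis."""

    name = "grating"

    def __init__(self, spatial_frequency: float = 0.033, orientation: float = 0.0,
                 phase: float = 0.0, contrast: float = 1.0):
        self.spatial_frequency = spatial_frequency
        self.orientation = orientation
        self.phase = phase
        self.contrast = contrast

    def color_at(self, azimuth, elevation):
        o = math.radians(self.orientation)
        coord = azimuth * math.cos(o) + elevation * math.sin(o)
        v = 0.5 + 0.5 * self.contrast * math.sin(
            2.0 * math.pi * self.spatial_frequency * coord
            + math.radians(self.phase))
        return (v, v, v)

    def color_array(self, azimuth, elevation):
        az = np.asarray(azimuth, dtype=float)
        el = np.asarray(elevation, dtype=float)
        o = math.radians(self.orientation)
        coord = az * math.cos(o) + el * math.sin(o)
        v = 0.5 + 0.5 * self.contrast * np.sin(
            2.0 * np.pi * self.spatial_frequency * coord
            + math.radians(self.phase))
        return np.repeat(v[..., None], 3, axis=-1)


class UniformTexture(StimulusTexture):
    name = "uniform"

    def __init__(self, value: float = 1.0):
        self.value = value

    def color_at(self, azimuth, elevation):
        return (self.value,) * 3

    def color_array(self, azimuth, elevation):
        az = np.asarray(azimuth, dtype=float)
        return np.full(az.shape + (3,), self.value)


TEXTURES = {"checkerboard": CheckerboardTexture, "grating": GratingTexture,
            "uniform": UniformTexture}


def make_texture(name: str, **kwargs) -> StimulusTexture:
    if name not in TEXTURES:
        raise ValueError(f"unknown texture {name!r}; known: {sorted(TEXTURES)}")
    return TEXTURES[name](**kwargs)


# ---------------------------------------------------------------------------
# Panorama
# ---------------------------------------------------------------------------

@dataclass
class Panorama:
    """Equirectangular map of what the observer perceives.

    Arrays are indexed ``[row, col]``; column 0 sits at azimuth -180 deg,
    row 0 at elevation +90 deg, values sampled at cell centres.  Each cell
    may carry several terminal contributions (flattened in ``contrib_*``
    arrays, addressed by flat cell index ``row * width + col``); the
    ``dominant_*`` arrays describe the highest-power contribution.
    """

    azimuths: np.ndarray          # (w,) cell-centre azimuths, deg
    elevations: np.ndarray        # (h,) cell-centre elevations, deg
    total_power: np.ndarray       # (h, w)
    dominant_src_az: np.ndarray   # (h, w) deg (nan where empty)
    dominant_src_el: np.ndarray   # (h, w)
    dominant_power: np.ndarray    # (h, w)
    tir_count: np.ndarray         # (h, w) int, of the dominant branch
    reflection_order: np.ndarray  # (h, w) int
    parity: np.ndarray            # (h, w) int, horizontal reflections (mod 2 matters)
    blocked: np.ndarray           # (h, w) bool
    contrib_cell: np.ndarray      # (k,) flat cell index of every contribution
    contrib_src_az: np.ndarray    # (k,)
    contrib_src_el: np.ndarray    # (k,)
    contrib_power: np.ndarray     # (k,)
    contrib_parity: np.ndarray    # (k,) int
    contrib_tir: np.ndarray       # (k,) int
    image: Optional[np.ndarray] = None  # (h, w, 3) floats in [0, 1]

    @property
    def shape(self):
        return self.total_power.shape

    @property
    def width(self):
        return self.azimuths.size

    @property
    def height(self):
        return self.elevations.size

    def solid_angle_weights(self) -> np.ndarray:
        """Per-cell solid-angle weights (cos elevation), shape (h, w)."""
        w = np.cos(np.radians(self.elevations))[:, None]
        return np.broadcast_to(w, self.shape).copy()


def render_panorama(scene: ContainerScene, texture: Optional[StimulusTexture] = None,
                    resolution: tuple = (720, 360), az_range: tuple = (-180.0, 180.0),
                    el_range: tuple = (-90.0, 90.0), max_events: int = 12,
                    min_power: float = 1e-3, absorption: bool = True) -> Panorama:
    """Trace one ray per cell centre and assemble the perceived panorama.

    ``resolution`` is (width, height) over the requested angular window.
    When a texture is given, a power-weighted RGB image of the perceived
    pattern is attached to the returned panorama.
    """
    w, h = int(resolution[0]), int(resolution[1])
    if w <= 0 or h <= 0:
        raise ValueError("resolution must be positive")
    daz = (az_range[1] - az_range[0]) / w
    dele = (el_range[1] - el_range[0]) / h
    azimuths = az_range[0] + (np.arange(w) + 0.5) * daz
    elevations = el_range[1] - (np.arange(h) + 0.5) * dele  # row 0 at the top

    total = np.zeros((h, w))
    dom_az = np.full((h, w), np.nan)
    dom_el = np.full((h, w), np.nan)
    dom_p = np.zeros((h, w))
    tirc = np.zeros((h, w), dtype=int)
    order = np.zeros((h, w), dtype=int)
    parity = np.zeros((h, w), dtype=int)
    blocked = np.zeros((h, w), dtype=bool)
    c_cell, c_az, c_el, c_p, c_par, c_tir = [], [], [], [], [], []

    for i in range(h):
        el = elevations[i]
        for j in range(w):
            az = azimuths[j]
            res = trace_from_eye(scene, direction_from_angles(az, el),
                                 max_events=max_events, min_power=min_power,
                                 absorption=absorption)
            idx = i * w + j
            if res.blocked_power > 0 and res.terminal_power == 0:
                blocked[i, j] = True
                continue
            best = None
            for b in res.branches:
                if b.status != "exited":
                    continue
                saz, sel = angles_from_direction(b.terminal_direction)
                c_cell.append(idx)
                c_az.append(saz)
                c_el.append(sel)
                c_p.append(b.power)
                c_par.append(b.horizontal_reflections)
                c_tir.append(b.tir_count)
                total[i, j] += b.power
                if best is None or b.power > best[0]:
                    best = (b.power, saz, sel, b.tir_count,
                            b.reflection_order, b.horizontal_reflections)
            if best is not None:
                dom_p[i, j], dom_az[i, j], dom_el[i, j] = best[0], best[1], best[2]
                tirc[i, j], order[i, j], parity[i, j] = best[3], best[4], best[5]

    pano = Panorama(azimuths, elevations, total, dom_az, dom_el, dom_p, tirc,
                    order, parity, blocked,
                    np.asarray(c_cell, dtype=int), np.asarray(c_az),
                    np.asarray(c_el), np.asarray(c_p),
                    np.asarray(c_par, dtype=int), np.asarray(c_tir, dtype=int))
    if texture is not None:
        pano.image = _compose_image(pano, texture)
    return pano


def _compose_image(p: Panorama, texture: StimulusTexture) -> np.ndarray:
    h, w = p.shape
    img = np.zeros((h, w, 3))
    if p.contrib_cell.size:
        colors = texture.color_array(p.contrib_src_az, p.contrib_src_el)
        colors = colors.reshape(-1, 3) * p.contrib_power[:, None]
        for ch in range(3):
            np.add.at(img.reshape(-1, 3)[:, ch], p.contrib_cell, colors[:, ch])
    return np.clip(img, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _angular_distance_deg(az1, el1, az2, el2):
    """Great-circle angle between two direction grids, degrees."""
    a1, e1 = np.radians(az1), np.radians(el1)
    a2, e2 = np.radians(az2), np.radians(el2)
    cosd = (np.sin(e1) * np.sin(e2)
            + np.cos(e1) * np.cos(e2) * np.cos(a1 - a2))
    return np.degrees(np.arccos(np.clip(cosd, -1.0, 1.0)))


def distortion_metrics(p: Panorama) -> dict:
    """Summary distortion statistics of a rendered panorama.

    Angular displacement compares each cell's dominant source direction with
    the viewing direction itself (zero for an undistorted view).  Fractions
    are solid-angle weighted (cos elevation).
    """
    az_grid = np.broadcast_to(p.azimuths[None, :], p.shape)
    el_grid = np.broadcast_to(p.elevations[:, None], p.shape)
    weights = p.solid_angle_weights()
    valid = (~p.blocked) & (p.total_power > 1e-9) & np.isfinite(p.dominant_src_az)

    disp = np.zeros(p.shape)
    disp[valid] = _angular_distance_deg(az_grid[valid], el_grid[valid],
                                        p.dominant_src_az[valid],
                                        p.dominant_src_el[valid])
    wsum = weights.sum()
    vweight = weights[valid].sum()
    reflected = p.total_power - p.dominant_power
    return {
        "max_displacement_deg": float(disp[valid].max()) if valid.any() else 0.0,
        "mean_displacement_deg": float((disp[valid] * weights[valid]).sum()
                                       / vweight) if valid.any() else 0.0,
        "tir_fraction": float(weights[valid & (p.tir_count >= 1)].sum() / wsum),
        "blocked_fraction": float(weights[p.blocked].sum() / wsum),
        "mean_reflected_power": float((reflected[valid] * weights[valid]).sum()
                                      / vweight) if valid.any() else 0.0,
        "max_reflected_power": float(reflected[valid].max()) if valid.any() else 0.0,
        "displacement_map": disp,
        "valid_mask": valid,
    }


MotionField = Union[float, Callable[[float, float], float]]


@dataclass
class MotionFieldResult:
    perceived_direction: np.ndarray  # (h, w) deg, nan where undefined
    inversion_fraction: float
    consistency_index: float


def flip_vertical(direction_deg):
    """Motion direction after one vertical mirror (horizontal preserved)."""
    return (-np.asarray(direction_deg)) % 360.0


def perceived_motion_field(p: Panorama, stimulus_motion: MotionField) -> MotionFieldResult:
    """Transport a stimulus motion direction through the optical mapping.

    Screen convention: 0 deg = horizontal (toward increasing azimuth),
    90 deg = upward.  Every reflection at a horizontal surface flips the
    vertical component, so the perceived direction of the dominant branch is
    the nominal direction mirrored ``parity`` times.  Returns the
    solid-angle fraction of the (unblocked, vertically moving) field whose
    perceived vertical component is inverted, and the mean cosine between
    perceived and nominal directions.
    """
    valid = (~p.blocked) & (p.total_power > 1e-9) & np.isfinite(p.dominant_src_az)
    if callable(stimulus_motion):
        nominal = np.full(p.shape, np.nan)
        nominal[valid] = np.vectorize(stimulus_motion)(p.dominant_src_az[valid],
                                                       p.dominant_src_el[valid])
    else:
        nominal = np.where(valid, float(stimulus_motion), np.nan)

    odd = (p.parity % 2) == 1
    perceived = np.where(odd, flip_vertical(nominal), nominal)
    perceived = np.where(valid, perceived, np.nan)

    weights = p.solid_angle_weights()
    sin_nom = np.sin(np.radians(nominal))
    sin_per = np.sin(np.radians(perceived))
    has_vert = valid & (np.abs(sin_nom) > 1e-9)
    inverted = has_vert & (np.sign(sin_per) != np.sign(sin_nom))
    denom = weights[has_vert].sum()
    inv_frac = float(weights[inverted].sum() / denom) if denom > 0 else 0.0

    cosdiff = np.cos(np.radians(perceived - nominal))
    wv = weights[valid].sum()
    consistency = float((cosdiff[valid] * weights[valid]).sum() / wv) if wv else 1.0
    return MotionFieldResult(perceived, inv_frac, consistency)
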