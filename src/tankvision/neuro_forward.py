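"""Forward model of calcium-imaging experiments seen through container optics.

Synthetic retinotopic, direction-tuned model neurons are driven by the
*perceived* stimulus: every optical contribution of the container mapping
(direct, totally internally reflected, partially reflected) delivers stimulus
power at a displaced location and possibly with a vertically mirrored motion
direction.  On top of the forward model, the module implements the standard
analysis chain for such experiments: receptive-field (RF) detection on a
patch grid with bipartite classification, direction/orientation selectivity
indices, Von Mises mixture fits to preferred-direction histograms, and a
two-proportion z-test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, optimize, stats

from .raytrace import Panorama, flip_vertical


# ---------------------------------------------------------------------------
# Arena and stimulus protocol
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ArenaSpec:
    """Geometry of the LED stimulation arena and the RF-mapping patch grid.

    The physical half-arena spans ``az_range`` x ``el_range`` (LED tiles in
    ``columns`` x ``rows``).  RF mapping uses a patch grid of
    ``patch_cols`` x ``patch_rows`` smallest patches, each
    ``patch_az_deg`` x ``patch_el_deg``; with the defaults the 36 smallest
    patches are exactly 30 x 13 deg and tile the mapped field, so the
    small-RF area threshold of 3 patches is 1170 deg^2.
    """

    az_range: tuple = (0.0, 168.0)
    el_range: tuple = (-40.0, 40.0)
    columns: int = 14
    rows: int = 8
    map_az_range: tuple = (0.0, 180.0)
    map_el_range: tuple = (-39.0, 39.0)
    patch_cols: int = 6
    patch_rows: int = 6
    grating_spatial_frequency: float = 0.033  # cycles/deg
    grating_speed: float = 30.0               # deg/s

    @property
    def patch_az_deg(self) -> float:
        return (self.map_az_range[1] - self.map_az_range[0]) / self.patch_cols

    @property
    def patch_el_deg(self) -> float:
        return (self.map_el_range[1] - self.map_el_range[0]) / self.patch_rows

    @property
    def patch_area_deg2(self) -> float:
        return self.patch_az_deg * self.patch_el_deg

    @property
    def n_patches(self) -> int:
        return self.patch_cols * self.patch_rows

    @property
    def small_rf_threshold_deg2(self) -> float:
        """Area of three smallest patches: the small-RF classification bound."""
        return 3.0 * self.patch_area_deg2


# Horizontal motion conventions for a right-eye field (azimuth > 0):
# nasal-temporal (NT) motion moves front-to-back (+azimuth, 0 deg on the
# screen), temporal-nasal (TN) back-to-front (180 deg).
NT_DIRECTION = 0.0
TN_DIRECTION = 180.0

DEFAULT_TIERS = ((1, 1), (2, 1), (2, 2), (3, 3), (6, 6))


@dataclass(frozen=True)
class StimulusPhase:
    """One stimulus presentation: a rectangular patch moving in a direction."""

    az0: float
    az1: float
    el0: float
    el1: float
    direction: float  # deg; 0 = toward +azimuth, 90 = upward
    tier: Optional[tuple] = None  # (cols, rows) of the tier, None for whole-field
    patch_index: Optional[tuple] = None  # (col, row) within the tier
    kind: str = "patch_motion"

    @property
    def area_deg2(self) -> float:
        return (self.az1 - self.az0) * (self.el1 - self.el0)


def generate_protocol(arena: ArenaSpec, mode: str, seed: Optional[int] = None,
                      shuffle: bool = False,
                      tiers: Sequence[tuple] = DEFAULT_TIERS) -> list:
    """Build the ordered stimulus phase list for one experiment.

    ``direction_tuning`` presents 8 whole-field motion directions at 45 deg
    spacing; ``rf_mapping`` presents a multi-scale patch set (whole field
    down to the smallest-tier patches), each patch with TN and NT horizontal
    motion.  With ``shuffle=True`` the phase order is permuted with ``seed``.
    """
    if mode == "direction_tuning":
        a0, a1 = arena.az_range
        e0, e1 = arena.el_range
        phases = [StimulusPhase(a0, a1, e0, e1, direction=45.0 * k,
                                kind="whole_field") for k in range(8)]
    elif mode == "rf_mapping":
        a0, a1 = arena.map_az_range
        e0, e1 = arena.map_el_range
        phases = []
        for cols, rows in tiers:
            daz = (a1 - a0) / cols
            dele = (e1 - e0) / rows
            for row in range(rows):
                for col in range(cols):
                    for direction in (TN_DIRECTION, NT_DIRECTION):
                        phases.append(StimulusPhase(
                            a0 + col * daz, a0 + (col + 1) * daz,
                            e0 + row * dele, e0 + (row + 1) * dele,
                            direction=direction, tier=(cols, rows),
                            patch_index=(col, row)))
    else:
        raise ValueError(f"unknown protocol mode {mode!r}")
    if shuffle:
        rng = np.random.default_rng(seed)
        phases = [phases[i] for i in rng.permutation(len(phases))]
    return phases


# ---------------------------------------------------------------------------
# Neurons and simulated responses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelNeuron:
    """A synthetic retinotopic direction-tuned unit.

    The receptive field is a 2-D Gaussian in viewing coordinates with widths
    ``rf_sigma`` (deg); direction tuning is Von Mises with concentration
    ``kappa`` around ``preferred_direction`` (kappa = 0: untuned).
    ``saturation`` is the half-saturation drive of a Michaelis-Menten
    response nonlinearity emulating calcium-indicator saturation (the
    response to a unit full-field drive stays 1); None disables it.
    """

    rf_center: tuple          # (azimuth, elevation) deg, viewing coordinates
    rf_sigma: tuple = (8.0, 5.0)
    preferred_direction: float = 0.0
    kappa: float = 4.0
    gain: float = 1.0
    baseline: float = 0.05
    saturation: Optional[float] = 0.5

    def tuning(self, direction_deg) -> np.ndarray:
        """Peak-normalised Von Mises tuning evaluated at a motion direction."""
        d = np.radians(np.asarray(direction_deg) - self.preferred_direction)
        return np.exp(self.kappa * (np.cos(d) - 1.0))


@dataclass
class ResponseRecord:
    """Simulated responses: neurons x stimulus phases, z-scored per neuron."""

    z: np.ndarray
    raw: np.ndarray
    phases: list
    neurons: list
    seed: Optional[int]
    mode: str


def simulate_responses(neurons: Sequence[ModelNeuron], protocol: list,
                       optics: Panorama, noise_sd: float = 0.01,
                       seed: Optional[int] = None) -> ResponseRecord:
    """Drive a neuron population with the perceived stimulus of a container.

    For each phase, every optical contribution whose *source* direction falls
    inside the stimulus patch deposits its power at the *viewing* direction
    of its panorama cell; contributions with odd mirror parity see the
    vertical motion component flipped.  A neuron's response is

        gain * S(sum_cells RF(cell) * [P_even(cell) * VM(dir)
                                       + P_odd(cell) * VM(mirrored dir)])
        + baseline + Gaussian noise,

    with S the neuron's saturating nonlinearity, then z-scored per neuron
    across phases.
    """
    if noise_sd > 0 and seed is None:
        raise ValueError("a seed is required when noise_sd > 0")
    h, w = optics.shape
    az_grid = np.broadcast_to(optics.azimuths[None, :], (h, w)).ravel()
    el_grid = np.broadcast_to(optics.elevations[:, None], (h, w)).ravel()
    omega = np.cos(np.radians(el_grid))  # relative solid angle per cell

    n_cells = h * w
    n_neurons = len(neurons)
    # RF weight matrix, normalised so a unit-power full-field stimulus -> 1.
    W = np.empty((n_neurons, n_cells))
    for i, nrn in enumerate(neurons):
        caz, cel = nrn.rf_center
        saz, sel = nrn.rf_sigma
        g = np.exp(-0.5 * ((az_grid - caz) / saz) ** 2
                   - 0.5 * ((el_grid - cel) / sel) ** 2) * omega
        total = g.sum()
        W[i] = g / total if total > 0 else 0.0

    cell = optics.contrib_cell
    saz_c = optics.contrib_src_az
    sel_c = optics.contrib_src_el
    pw = optics.contrib_power
    odd = (optics.contrib_parity % 2) == 1

    pd = np.array([n.preferred_direction for n in neurons])
    kappa = np.array([n.kappa for n in neurons])
    gain = np.array([n.gain for n in neurons])
    baseline = np.array([n.baseline for n in neurons])
    sat = np.array([np.inf if n.saturation is None else n.saturation
                    for n in neurons])
    finite_sat = np.isfinite(sat)
    sat_safe = np.where(finite_sat, sat, 1.0)

    raw = np.empty((n_neurons, len(protocol)))
    for j, ph in enumerate(protocol):
        in_patch = ((saz_c >= ph.az0) & (saz_c < ph.az1)
                    & (sel_c >= ph.el0) & (sel_c < ph.el1))
        p_even = np.bincount(cell[in_patch & ~odd],
                             weights=pw[in_patch & ~odd], minlength=n_cells)
        p_odd = np.bincount(cell[in_patch & odd],
                            weights=pw[in_patch & odd], minlength=n_cells)
        drive_e = W @ p_even
        drive_o = W @ p_odd
        vm = np.exp(kappa * (np.cos(np.radians(ph.direction - pd)) - 1.0))
        vm_f = np.exp(kappa * (np.cos(np.radians(
            flip_vertical(ph.direction) - pd)) - 1.0))
        drive = drive_e * vm + drive_o * vm_f
        drive = np.where(finite_sat,
                         (1.0 + sat_safe) * drive / (drive + sat_safe), drive)
        raw[:, j] = gain * drive + baseline

    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        raw = raw + rng.normal(0.0, noise_sd, raw.shape)

    mu = raw.mean(axis=1, keepdims=True)
    sd = raw.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (raw - mu) / sd
    mode = "rf_mapping" if protocol and protocol[0].kind == "patch_motion" \
        else "direction_tuning"
    return ResponseRecord(z, raw, list(protocol), list(neurons), seed, mode)


# ---------------------------------------------------------------------------
# Receptive-field detection
# ---------------------------------------------------------------------------

@dataclass
class RFResult:
    """Detected receptive-field structure of one neuron on the patch grid."""

    patch_z: np.ndarray            # (rows, cols) max z over motion directions
    supra: np.ndarray              # (rows, cols) bool
    n_components: int
    centers: list                  # [(az, el)] power-weighted centroids, deg
    area_deg2: float
    small_rf: bool
    bipartite: bool
    pair_orientation: Optional[float]  # deg; 0/180 = vertical pair


def detect_receptive_field(record: ResponseRecord, z_threshold: float = 1.96,
                           arena: Optional[ArenaSpec] = None,
                           min_response: float = 0.1) -> list:
    """Detect per-neuron RFs from the smallest-tier patches of an RF record.

    Neurons first pass a motion-responsiveness gate (raw response range,
    max minus median, of at least ``min_response``); unresponsive neurons -
    e.g. units whose preferred direction is orthogonal to the mapping
    motion - are returned unmapped, mirroring the motion-sensitive cell
    selection applied to real recordings.  Smallest-tier patches whose
    z-score (max over the two motion directions) reaches ``z_threshold``
    are marked supra-threshold; 4-connected components on the patch grid
    form RF components.  A neuron is *bipartite* when exactly two disjoint
    components are present; ``pair_orientation`` is the polar angle of the
    line joining the two centres, measured from the vertical (0/180 deg =
    vertically aligned).
    """
    if record.mode != "rf_mapping":
        raise ValueError("RF detection requires an rf_mapping record")
    arena = arena or ArenaSpec()
    finest = (arena.patch_cols, arena.patch_rows)
    idx = [(j, ph) for j, ph in enumerate(record.phases) if ph.tier == finest]
    if not idx:
        raise ValueError("record contains no smallest-tier phases")

    rows, cols = arena.patch_rows, arena.patch_cols
    a0 = arena.map_az_range[0]
    e0 = arena.map_el_range[0]
    daz, dele = arena.patch_az_deg, arena.patch_el_deg
    patch_area = arena.patch_area_deg2

    results = []
    for n in range(record.z.shape[0]):
        patch_z = np.full((rows, cols), -np.inf)
        for j, ph in idx:
            c, r = ph.patch_index
            patch_z[r, c] = max(patch_z[r, c], record.z[n, j])
        responsive = (record.raw[n].max()
                      - np.median(record.raw[n])) >= min_response
        supra = (patch_z >= z_threshold) if responsive \
            else np.zeros((rows, cols), dtype=bool)
        labels, n_comp = ndimage.label(supra)  # default: 4-connectivity
        centers = []
        for comp in range(1, n_comp + 1):
            rr, cc = np.nonzero(labels == comp)
            wz = patch_z[rr, cc]
            wz = np.clip(wz, 1e-9, None)
            az_c = a0 + (cc + 0.5) * daz
            el_c = e0 + (rr + 0.5) * dele
            centers.append((float((az_c * wz).sum() / wz.sum()),
                            float((el_c * wz).sum() / wz.sum())))
        area = float(supra.sum() * patch_area)
        bipartite = n_comp == 2
        orientation = None
        if bipartite:
            (az1, el1), (az2, el2) = centers
            orientation = math.degrees(math.atan2(az2 - az1, el2 - el1)) % 360.0
        results.append(RFResult(patch_z, supra, n_comp, centers, area,
                                0 < area <= arena.small_rf_threshold_deg2,
                                bipartite, orientation))
    return results


# ---------------------------------------------------------------------------
# Direction selectivity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TuningIndices:
    dsi: float
    osi: float
    preferred_direction: float
    defined: bool = True


def tuning_indices(tuning_curve, directions=None, method: str = "ratio") -> TuningIndices:
    """DSI/OSI and preferred direction from equally spaced direction responses.

    ``method='ratio'``: DSI = (R_pref - R_null) / (R_pref + R_null), with
    R_null the response 180 deg opposite the peak; ``method='vector'``:
    DSI = |sum R e^{i theta}| / sum R.  OSI uses the doubled-angle vector
    sum in both cases.  The preferred direction is the vector-sum angle.
    Responses are rectified at zero.
    """
    r = np.clip(np.asarray(tuning_curve, dtype=float), 0.0, None)
    k = r.size
    if directions is None:
        directions = np.arange(k) * (360.0 / k)
    theta = np.radians(np.asarray(directions, dtype=float))
    total = r.sum()
    if total <= 0:
        return TuningIndices(math.nan, math.nan, math.nan, defined=False)
    vec = (r * np.exp(1j * theta)).sum()
    pref = math.degrees(np.angle(vec)) % 360.0
    osi = float(abs((r * np.exp(2j * theta)).sum()) / total)
    if method == "vector":
        dsi = float(abs(vec) / total)
    elif method == "ratio":
        i_peak = int(np.argmax(r))
        i_null = int(np.argmin(np.abs(
            (np.degrees(theta) - (np.degrees(theta[i_peak]) + 180.0)) % 360.0)))
        rp, rn = r[i_peak], r[i_null]
        dsi = float((rp - rn) / (rp + rn)) if (rp + rn) > 0 else math.nan
    else:
        raise ValueError(f"unknown DSI method {method!r}")
    return TuningIndices(dsi, osi, pref)


# ---------------------------------------------------------------------------
# Von Mises mixture fits
# ---------------------------------------------------------------------------

@dataclass
class VonMisesMixtureFit:
    """Least-squares fit of k Von Mises components to a circular histogram."""

    k: int
    means: np.ndarray     # deg, in [0, 360)
    kappas: np.ndarray
    weights: np.ndarray   # component masses; sum equals the histogram mass
    amplitudes: np.ndarray
    rss: float

    def predict(self, theta_deg) -> np.ndarray:
        t = np.radians(np.asarray(theta_deg, dtype=float))
        out = np.zeros_like(t, dtype=float)
        for a, m, k in zip(self.amplitudes, np.radians(self.means), self.kappas):
            out += a * np.exp(k * (np.cos(t - m) - 1.0))
        return out


def histogram_preferred_directions(angles_deg, nbins: int = 12):
    """Circular histogram of preferred directions; returns (centers, counts)."""
    edges = np.linspace(0.0, 360.0, nbins + 1)
    counts, _ = np.histogram(np.asarray(angles_deg) % 360.0, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return centers, counts.astype(float)


def _vm_model(params, theta_rad, k):
    out = np.zeros_like(theta_rad)
    for j in range(k):
        a, mu, kap = params[3 * j:3 * j + 3]
        out += a * np.exp(kap * (np.cos(theta_rad - mu) - 1.0))
    return out


def fit_von_mises_mixture(bin_centers_deg, counts, k: int,
                          n_starts: int = 4) -> VonMisesMixtureFit:
    """Fit a sum of k Von Mises bumps to a binned direction histogram.

    Nonlinear least squares with periodic wrapping; initial means are seeded
    from the largest histogram peaks (multi-start with rotated inits), and
    amplitudes are bounded at zero so missing peaks collapse to near-zero
    weight components.
    """
    if k not in (1, 2, 4):
        raise ValueError("k must be one of 1, 2, 4")
    centers = np.asarray(bin_centers_deg, dtype=float)
    y = np.asarray(counts, dtype=float)
    if centers.size == 0 or y.sum() <= 0:
        raise ValueError("histogram must be nonempty")
    theta = np.radians(centers)
    nbins = centers.size

    # Candidate initial means: circular local maxima ordered by height.
    left, right = np.roll(y, 1), np.roll(y, -1)
    peak_idx = np.nonzero((y >= left) & (y >= right) & (y > 0))[0]
    peak_idx = peak_idx[np.argsort(y[peak_idx])[::-1]]
    init_means = list(centers[peak_idx[:k]])
    while len(init_means) < k:
        init_means.append((init_means[-1] + 360.0 / k) % 360.0
                          if init_means else 0.0)

    best = None
    for start in range(n_starts):
        rot = start * 360.0 / (k * n_starts)
        p0 = []
        for mu in init_means:
            p0.extend([max(y.max(), 1.0), math.radians((mu + rot) % 360.0), 4.0])
        lower = [0.0, -np.inf, 0.05] * k
        upper = [np.inf, np.inf, 200.0] * k
        try:
            sol = optimize.least_squares(
                lambda p: _vm_model(p, theta, k) - y, p0,
                bounds=(lower, upper), max_nfev=2000)
        except Exception:
            continue
        rss = float((sol.fun ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, sol.x)
    if best is None:
        raise RuntimeError("Von Mises mixture fit failed to converge")
    rss, p = best
    amps = p[0::3]
    means = np.degrees(p[1::3]) % 360.0
    kappas = p[2::3]
    # Component masses under the fitted curve, rescaled so they sum to the
    # total histogram mass.
    masses = np.array([
        a * np.exp(kap * (np.cos(theta - math.radians(mu)) - 1.0)).sum()
        for a, mu, kap in zip(amps, means, kappas)])
    if masses.sum() > 0:
        masses = masses * (y.sum() / masses.sum())
    order = np.argsort(means)
    return VonMisesMixtureFit(k, means[order], kappas[order], masses[order],
                              amps[order], rss)


# ---------------------------------------------------------------------------
# Proportion test
# ---------------------------------------------------------------------------

def two_proportion_test(n1: int, n2: int) -> tuple[float, float]:
    """z-test that two categories are equally likely among n1 + n2 cells.

    Under H0 (p = 1/2), z = (n1 - n2) / sqrt(n1 + n2); the two-sided p-value
    comes from the normal tail.
    """
    if n1 < 0 or n2 < 0:
        raise ValueError("counts must be non-negative")
    if n1 + n2 == 0:
        raise ValueError("at least one count must be positive")
    z = (n1 - n2) / math.sqrt(n1 + n2)
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)
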