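"""Synthetic contraction movies and 4-channel immunofluorescence stacks with ground truth.

Every downstream stage of the pipeline (PIV, force estimation, directionality,
3D object quantification, plate statistics) is exercised against scenes produced
here, for which the true displacement fields, object positions and engineered
colocalized pairs are known exactly.

Conventions used throughout the package
---------------------------------------
* Angles are in degrees in [0, 180), measured from the +x (column) axis,
  counterclockwise with y = row axis.  The nanofiber/contraction axis of an
  aligned culture maps to 90 degrees.
* Image axis order is (row, col) = (y, x) for movies and (z, y, x) for stacks,
  0-based voxel indexing.
* Identical spec + seed produce bit-identical output.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

__all__ = [
    "MovieSpec",
    "StackSpec",
    "SceneGroundTruth",
    "make_contraction_movie",
    "make_if_stack",
    "make_plate",
    "write_movie",
    "write_stack",
    "read_movie",
    "read_stack",
]

_WELL_RE = re.compile(r"^[A-H](?:[1-9]|1[0-2])$")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MovieSpec:
    """Parameters of a synthetic contracting speckle-sheet movie.

    The sheet is textured with dense Gaussian speckle and warped frame-to-frame
    by an analytic displacement field: a temporal activation waveform times a
    smooth radial taper (the sheet is anchored at the well edges) times a unit
    direction split between the contraction axis and its orthogonal according
    to ``axis_anisotropy`` (fraction of displacement energy on the principal
    axis; 1.0 means axis-pure motion).
    """

    height_px: int = 128
    width_px: int = 128
    n_frames: int = 40
    frame_rate_hz: float = 20.0
    pixel_size_um: float = 1.0
    texture_density: float = 40.0        # specks per 1000 px^2
    amplitude_um: float = 5.0            # peak displacement magnitude
    contraction_axis_deg: float = 90.0   # [0, 180), 90 = y axis
    axis_anisotropy: float = 0.8         # fraction of energy on principal axis
    waveform: str = "pulse"              # {"pulse", "sinusoid"}
    pulse_times_s: tuple[float, ...] = (0.5,)
    pulse_width_s: float = 0.5
    sinusoid_period_s: float = 1.0
    noise_sigma: float = 0.01            # additive Gaussian, intensity units
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.amplitude_um < 0:
            raise ValueError("amplitude_um must be >= 0")
        if not 0.0 <= self.axis_anisotropy <= 1.0:
            raise ValueError("axis_anisotropy must be in [0, 1]")
        if self.waveform not in ("pulse", "sinusoid"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_hz and pixel_size_um must be > 0")

    @property
    def dt_s(self) -> float:
        return 1.0 / self.frame_rate_hz

    def max_feasible_amplitude_um(self) -> float:
        """Largest peak displacement for which warping stays within bounds."""
        return 0.25 * min(self.height_px, self.width_px) * self.pixel_size_um


@dataclass(frozen=True)
class StackSpec:
    """Parameters of a synthetic 4-channel z-stack (TTN / TUBB3 / SV2 / AChR).

    Myofibers are oriented capsules in the TTN channel, axons are persistent
    random-walk filaments in the TUBB3 channel, and the two synaptic-marker
    channels contain spherical puncta.  ``colocalization_fraction`` of the
    pre-synaptic (SV2) puncta are placed on top of a post-synaptic (AChR)
    punctum; the remainder are kept clear of every AChR punctum so accidental
    overlaps cannot occur.  All channels are blurred with a Gaussian PSF and
    corrupted with Poisson + Gaussian noise.
    """

    shape_zyx: tuple[int, int, int] = (5, 256, 256)
    voxel_size_zyx_um: tuple[float, float, float] = (2.0, 0.65, 0.65)
    n_fibers: int = 12
    fiber_orientation_deg: float = 90.0
    orientation_kappa: float = 8.0       # axial von Mises concentration
    fiber_length_um: float = 70.0
    fiber_width_um: float = 6.0
    n_axons: int = 3
    axon_total_length_um: float = 600.0
    axon_width_um: float = 1.5
    n_pre_puncta: int = 30
    n_post_puncta: int = 30
    colocalization_fraction: float = 0.5
    punctum_radius_um: float = 1.0
    psf_sigma_um: float = 0.5
    photons_per_unit: float = 300.0      # Poisson scale at unit intensity
    background_photons: float = 5.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.colocalization_fraction <= 1.0:
            raise ValueError("colocalization_fraction must be in [0, 1]")
        if any(s < 1 for s in self.shape_zyx):
            raise ValueError("shape_zyx must be positive")
        if self.n_colocalized > self.n_post_puncta:
            raise ValueError(
                "colocalization_fraction * n_pre_puncta exceeds n_post_puncta"
            )
        fov_y = self.shape_zyx[1] * self.voxel_size_zyx_um[1]
        fov_x = self.shape_zyx[2] * self.voxel_size_zyx_um[2]
        if self.fiber_length_um > max(fov_y, fov_x):
            raise ValueError("fiber_length_um exceeds the field of view")

    @property
    def n_colocalized(self) -> int:
        return int(round(self.colocalization_fraction * self.n_pre_puncta))


CHANNEL_NAMES = ("ttn", "tubb3", "sv2", "achr")


@dataclass
class SceneGroundTruth:
    """Everything the generator knows about a scene.

    For movies: the analytic per-frame displacement field (px) at full pixel
    resolution, from which the per-frame-pair field follows by differencing.
    For stacks: one record per object and the engineered colocalized pairs.
    """

    movie_spec: MovieSpec | None = None
    stack_spec: StackSpec | None = None
    # (n_frames, 2, H, W): displacement of each pixel from its rest position,
    # in px, ordered (dx, dy).
    frame_displacements_px: np.ndarray | None = None
    objects: pd.DataFrame | None = None      # channel, id, z/y/x um, volume_um3
    colocalized_pairs: list[tuple[int, int]] = field(default_factory=list)
    fiber_angles_deg: np.ndarray | None = None

    def pair_displacement_px(self, pair_index: int) -> np.ndarray:
        """True displacement field (2, H, W), (dx, dy), between frames i, i+1."""
        d = self.frame_displacements_px
        if d is None:
            raise ValueError("no movie ground truth recorded")
        return d[pair_index + 1] - d[pair_index]

    @property
    def n_pairs(self) -> int:
        return len(self.frame_displacements_px) - 1

    def peak_pair_speed_px(self) -> float:
        """Maximum over pairs of the spatial-max frame-to-frame |displacement|."""
        peaks = [
            float(np.hypot(*self.pair_displacement_px(i)).max())
            for i in range(self.n_pairs)
        ]
        return max(peaks)


# ---------------------------------------------------------------------------
# Contraction movies
# ---------------------------------------------------------------------------

def _speckle_texture(spec: MovieSpec, rng: np.random.Generator) -> np.ndarray:
    """Dense Gaussian speckle on a quiet baseline, intensity roughly in [0, 1]."""
    h, w = spec.height_px, spec.width_px
    n_specks = max(1, int(round(spec.texture_density * h * w / 1000.0)))
    img = np.zeros((h, w), dtype=np.float64)
    ys = rng.uniform(0, h, n_specks)
    xs = rng.uniform(0, w, n_specks)
    amps = rng.uniform(0.5, 1.0, n_specks)
    np.add.at(img, (ys.astype(int), xs.astype(int)), amps)
    img = ndimage.gaussian_filter(img, sigma=1.2, mode="constant")
    peak = img.max()
    if peak > 0:
        img /= peak
    return 0.1 + 0.9 * img


def _activation(spec: MovieSpec, times: np.ndarray) -> np.ndarray:
    """Temporal waveform s(t) in [0, 1] (0 = rest, 1 = peak displacement)."""
    if spec.waveform == "sinusoid":
        return 0.5 * (1.0 - np.cos(2.0 * np.pi * times / spec.sinusoid_period_s))
    s = np.zeros_like(times)
    w = spec.pulse_width_s
    for t0 in spec.pulse_times_s:
        inside = (times >= t0) & (times <= t0 + w)
        s[inside] += 0.5 * (1.0 - np.cos(2.0 * np.pi * (times[inside] - t0) / w))
    return np.clip(s, 0.0, 1.0)


def _radial_taper(h: int, w: int) -> np.ndarray:
    """Smooth raised-cosine taper: 1 at the centre, 0 at the nearest border."""
    y = np.arange(h)[:, None]
    x = np.arange(w)[None, :]
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.sqrt(((y - cy) / cy) ** 2 + ((x - cx) / cx) ** 2)
    return 0.5 * (1.0 + np.cos(np.pi * np.clip(r, 0.0, 1.0)))


def _displacement_fields(spec: MovieSpec) -> np.ndarray:
    """Analytic per-frame displacement (n_frames, 2, H, W) in px, (dx, dy)."""
    h, w = spec.height_px, spec.width_px
    amp_px = spec.amplitude_um / spec.pixel_size_um
    times = np.arange(spec.n_frames) * spec.dt_s
    s = _activation(spec, times)
    taper = _radial_taper(h, w)
    theta = np.deg2rad(spec.contraction_axis_deg)
    p = np.array([np.cos(theta), np.sin(theta)])       # principal axis (x, y)
    q = np.array([-np.sin(theta), np.cos(theta)])      # orthogonal
    a = spec.axis_anisotropy
    direction = np.sqrt(a) * p + np.sqrt(1.0 - a) * q  # unit vector
    fields = np.empty((spec.n_frames, 2, h, w), dtype=np.float32)
    for k in range(spec.n_frames):
        mag = amp_px * s[k] * taper
        fields[k, 0] = mag * direction[0]
        fields[k, 1] = mag * direction[1]
    return fields


def make_contraction_movie(spec: MovieSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a contracting speckle-sheet movie and its exact ground truth.

    Returns
    -------
    movie : float32 array (n_frames, H, W)
    truth : SceneGroundTruth with the analytic displacement field per frame.

    Each frame is produced by backward warping: ``frame_k(x) = T(x - d_k(x))``
    with bilinear interpolation, where T is the rest texture and d_k the
    analytic displacement of frame k.  The true frame-pair displacement is
    ``d_{k+1} - d_k``; summed over all pairs it telescopes to the total drift.
    """
    amp_px = spec.amplitude_um / spec.pixel_size_um
    max_amp = spec.max_feasible_amplitude_um()
    if spec.amplitude_um > max_amp:
        raise ValueError(
            f"amplitude_um={spec.amplitude_um} would warp texture out of the "
            f"image; maximum feasible amplitude is {max_amp:.3f} um "
            f"({max_amp / spec.pixel_size_um:.1f} px) for this geometry"
        )
    rng = np.random.default_rng(spec.seed)
    texture = _speckle_texture(spec, rng)
    fields = _displacement_fields(spec)

    h, w = spec.height_px, spec.width_px
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    movie = np.empty((spec.n_frames, h, w), dtype=np.float32)
    for k in range(spec.n_frames):
        dx, dy = fields[k]
        coords = np.stack([yy - dy, xx - dx])
        movie[k] = ndimage.map_coordinates(
            texture, coords, order=1, mode="nearest"
        )
    if spec.noise_sigma > 0:
        movie += rng.normal(0.0, spec.noise_sigma, movie.shape).astype(np.float32)

    truth = SceneGroundTruth(movie_spec=spec, frame_displacements_px=fields)
    return movie, truth


# ---------------------------------------------------------------------------
# IF stacks
# ---------------------------------------------------------------------------

def _sample_axial_angles(
    mu_deg: float, kappa: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Axial (period-180) von Mises sample via the double-angle construction."""
    psi = rng.vonmises(np.deg2rad(2.0 * mu_deg), kappa, size=n)
    return np.rad2deg(psi / 2.0) % 180.0


def _capsule_mask(
    shape: tuple,
    spec: StackSpec,
    center_um: np.ndarray,
    angle_deg: float,
    radius_um: float,
) -> tuple[tuple, np.ndarray] | None:
    """Voxel mask of a 3D capsule; returns (bounding slices, local mask)."""
    vz, vy, vx = spec.voxel_size_zyx_um
    half = spec.fiber_length_um / 2.0
    r = radius_um
    theta = np.deg2rad(angle_deg)
    axis = np.array([0.0, np.sin(theta), np.cos(theta)])  # (z, y, x), in-plane
    p0 = center_um - half * axis
    p1 = center_um + half * axis

    lo_um = np.minimum(p0, p1) - r - 1.0
    hi_um = np.maximum(p0, p1) + r + 1.0
    voxel = np.array([vz, vy, vx])
    lo = np.maximum(0, np.floor(lo_um / voxel).astype(int))
    hi = np.minimum(shape, np.ceil(hi_um / voxel).astype(int) + 1)
    if np.any(lo >= hi):
        return None
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pts = np.stack([zz * vz, yy * vy, xx * vx], axis=-1)

    seg = p1 - p0
    seg_len2 = float(seg @ seg)
    t = np.clip(((pts - p0) @ seg) / seg_len2, 0.0, 1.0) if seg_len2 > 0 else 0.0
    nearest = p0 + t[..., None] * seg if seg_len2 > 0 else p0
    dist = np.linalg.norm(pts - nearest, axis=-1)
    slices = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    return slices, dist <= r


def _paint_sphere(
    volume: np.ndarray, spec: StackSpec, center_um: np.ndarray, radius_um: float
) -> None:
    voxel = np.array(spec.voxel_size_zyx_um)
    lo = np.maximum(0, np.floor((center_um - radius_um) / voxel).astype(int))
    hi = np.minimum(
        volume.shape, np.ceil((center_um + radius_um) / voxel).astype(int) + 1
    )
    if np.any(lo >= hi):
        return
    zz, yy, xx = np.mgrid[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    pts = np.stack([zz * voxel[0], yy * voxel[1], xx * voxel[2]], axis=-1)
    dist = np.linalg.norm(pts - center_um, axis=-1)
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]][dist <= radius_um] = 1.0


def _paint_axon(
    volume: np.ndarray,
    spec: StackSpec,
    rng: np.random.Generator,
    length_um: float,
) -> float:
    """Draw one persistent random-walk filament; returns the drawn length (um)."""
    nz, ny, nx = volume.shape
    vz, vy, vx = spec.voxel_size_zyx_um
    r_vox = max(1.0, spec.axon_width_um / 2.0 / vy)
    z = rng.integers(0, nz)
    pos = np.array([rng.uniform(0.1 * ny, 0.9 * ny), rng.uniform(0.1 * nx, 0.9 * nx)])
    heading = rng.uniform(0, 2 * np.pi)
    step_px = 1.0
    n_steps = int(round(length_um / (step_px * vy)))
    plane = np.zeros((ny, nx), dtype=bool)
    drawn = 0.0
    for _ in range(n_steps):
        heading += rng.normal(0.0, 0.15)
        nxt = pos + step_px * np.array([np.sin(heading), np.cos(heading)])
        iy, ix = int(round(nxt[0])), int(round(nxt[1]))
        if not (0 <= iy < ny and 0 <= ix < nx):
            heading += np.pi / 2.0  # turn away from the border
            continue
        plane[iy, ix] = True
        drawn += step_px * vy
        pos = nxt
    footprint = _disk_footprint(r_vox)
    plane = ndimage.binary_dilation(plane, structure=footprint)
    volume[z][plane] = 1.0
    return drawn


def _disk_footprint(radius_px: float) -> np.ndarray:
    r = int(np.ceil(radius_px))
    yy, xx = np.mgrid[-r:r + 1, -r:r + 1]
    return (yy**2 + xx**2) <= radius_px**2


def _min_dist_points(
    n: int,
    bounds_um: np.ndarray,
    margin_um: float,
    min_sep_um: float,
    rng: np.random.Generator,
    avoid: np.ndarray | None = None,
    avoid_dist_um: float = 0.0,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample n points with pairwise and avoidance separation."""
    pts: list[np.ndarray] = []
    tries = 0
    while len(pts) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                "could not place requested objects with the required separation; "
                "reduce counts or separation"
            )
        cand = np.array(
            [rng.uniform(min(margin_um, 0.45 * b), b - min(margin_um, 0.45 * b))
             for b in bounds_um]
        )
        if pts and np.min(np.linalg.norm(np.array(pts) - cand, axis=1)) < min_sep_um:
            continue
        if avoid is not None and len(avoid) and (
            np.min(np.linalg.norm(avoid - cand, axis=1)) < avoid_dist_um
        ):
            continue
        pts.append(cand)
    return np.array(pts) if pts else np.empty((0, 3))


def make_if_stack(spec: StackSpec) -> tuple[np.ndarray, SceneGroundTruth]:
    """Render a 4-channel IF stack (ttn, tubb3, sv2, achr) with ground truth.

    Returns
    -------
    stack : float32 array (4, Z, Y, X), channel order ``CHANNEL_NAMES``.
    truth : SceneGroundTruth listing every object (channel, centroid in um,
        nominal volume), the true fiber angles, and the engineered
        (pre_id, post_id) colocalized pairs.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape_zyx
    voxel = np.array(spec.voxel_size_zyx_um)
    bounds_um = np.array([nz, ny, nx]) * voxel

    fiber_vol_um3 = (
        np.pi * (spec.fiber_width_um / 2.0) ** 2 * spec.fiber_length_um
        + 4.0 / 3.0 * np.pi * (spec.fiber_width_um / 2.0) ** 3
    )
    sphere_vol_um3 = 4.0 / 3.0 * np.pi * spec.punctum_radius_um**3

    clean = np.zeros((4, nz, ny, nx), dtype=np.float64)
    records: list[dict] = []

    # --- myofibers (TTN) -------------------------------------------------
    angles = _sample_axial_angles(
        spec.fiber_orientation_deg, spec.orientation_kappa, spec.n_fibers, rng
    )
    # Rejection-sample capsules against a guard-widened union mask so fibers
    # never touch and counts survive blur + segmentation exactly.
    guard_um = 4.0 * spec.psf_sigma_um + 1.0
    union = np.zeros((nz, ny, nx), dtype=bool)
    fiber_centers = np.zeros((spec.n_fibers, 3))
    r_fiber = spec.fiber_width_um / 2.0
    for i in range(spec.n_fibers):
        placed = False
        for _ in range(5000):
            cand = np.array([
                rng.uniform(0.0, b) for b in bounds_um
            ])
            guarded = _capsule_mask(
                (nz, ny, nx), spec, cand, angles[i], r_fiber + guard_um
            )
            if guarded is None:
                continue
            g_sl, g_mask = guarded
            if union[g_sl][g_mask].any():
                continue
            sl, m = _capsule_mask((nz, ny, nx), spec, cand, angles[i], r_fiber)
            if not m.any():
                continue
            clean[0][sl][m] = 1.0
            union[sl][m] = True
            fiber_centers[i] = cand
            placed = True
            break
        if not placed:
            raise RuntimeError(
                "could not place all fibers without contact; reduce n_fibers "
                "or fiber size"
            )
        records.append(
            dict(channel="ttn", id=i, z_um=fiber_centers[i][0],
                 y_um=fiber_centers[i][1], x_um=fiber_centers[i][2],
                 volume_um3=fiber_vol_um3, angle_deg=angles[i])
        )

    # --- axons (TUBB3) ----------------------------------------------------
    per_axon = spec.axon_total_length_um / max(1, spec.n_axons)
    total_drawn = 0.0
    for i in range(spec.n_axons):
        total_drawn += _paint_axon(clean[1], spec, rng, per_axon)
        records.append(
            dict(channel="tubb3", id=i, z_um=np.nan, y_um=np.nan, x_um=np.nan,
                 volume_um3=np.nan, angle_deg=np.nan)
        )

    # --- puncta (AChR first, then SV2 with engineered colocalization) ----
    r = spec.punctum_radius_um
    sep = 6.0 * r

    def _snap_z(pts: np.ndarray) -> np.ndarray:
        # quantize punctum centres to the nearest z plane so a punctum
        # smaller than the plane spacing cannot fall between planes
        if len(pts):
            pts[:, 0] = np.clip(
                np.round(pts[:, 0] / voxel[0]) * voxel[0], 0, (nz - 1) * voxel[0]
            )
        return pts

    post_centers = _snap_z(_min_dist_points(
        spec.n_post_puncta, bounds_um, margin_um=2 * r, min_sep_um=sep, rng=rng
    )) if spec.n_post_puncta else np.empty((0, 3))
    n_coloc = spec.n_colocalized
    coloc_posts = rng.choice(spec.n_post_puncta, size=n_coloc, replace=False) \
        if n_coloc else np.array([], dtype=int)
    pre_centers = np.empty((spec.n_pre_puncta, 3))
    pairs: list[tuple[int, int]] = []
    for j, post_idx in enumerate(coloc_posts):
        jitter = rng.uniform(-0.2 * r, 0.2 * r, size=3)
        jitter[0] = 0.0  # stay on the partner's z plane
        pre_centers[j] = post_centers[post_idx] + jitter
        pairs.append((j, int(post_idx)))
    n_free = spec.n_pre_puncta - n_coloc
    if n_free:
        free = _snap_z(_min_dist_points(
            n_free, bounds_um, margin_um=2 * r, min_sep_um=sep, rng=rng,
            avoid=post_centers if len(post_centers) else None,
            avoid_dist_um=sep,
        ))
        pre_centers[n_coloc:] = free

    for i in range(spec.n_post_puncta):
        _paint_sphere(clean[3], spec, post_centers[i], r)
        records.append(
            dict(channel="achr", id=i, z_um=post_centers[i][0],
                 y_um=post_centers[i][1], x_um=post_centers[i][2],
                 volume_um3=sphere_vol_um3, angle_deg=np.nan)
        )
    for i in range(spec.n_pre_puncta):
        _paint_sphere(clean[2], spec, pre_centers[i], r)
        records.append(
            dict(channel="sv2", id=i, z_um=pre_centers[i][0],
                 y_um=pre_centers[i][1], x_um=pre_centers[i][2],
                 volume_um3=sphere_vol_um3, angle_deg=np.nan)
        )

    # --- PSF blur + Poisson/Gaussian noise -------------------------------
    sigma_vox = spec.psf_sigma_um / voxel
    stack = np.empty_like(clean, dtype=np.float32)
    for c in range(4):
        blurred = ndimage.gaussian_filter(clean[c], sigma=sigma_vox)
        lam = blurred * spec.photons_per_unit + spec.background_photons
        noisy = rng.poisson(lam).astype(np.float64)
        noisy += rng.normal(0.0, spec.read_noise_sd, noisy.shape)
        stack[c] = noisy.astype(np.float32)

    truth = SceneGroundTruth(
        stack_spec=spec,
        objects=pd.DataFrame.from_records(records),
        colocalized_pairs=pairs,
        fiber_angles_deg=angles,
    )
    return stack, truth


# ---------------------------------------------------------------------------
# Plate generation and TIFF I/O
# ---------------------------------------------------------------------------

def write_movie(path: Path, movie: np.ndarray, spec: MovieSpec) -> None:
    """Write a movie as multi-page TIFF plus a calibration sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, movie, photometric="minisblack")
    sidecar = {
        "kind": "movie",
        "axes": "TYX",
        "frame_rate_hz": spec.frame_rate_hz,
        "pixel_size_um": spec.pixel_size_um,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_movie(path: Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    movie = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return movie, meta


def write_stack(path: Path, stack: np.ndarray, spec: StackSpec) -> None:
    """Write a 4-channel stack as TIFF plus a calibration sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, stack, photometric="minisblack")
    sidecar = {
        "kind": "stack",
        "axes": "CZYX",
        "channels": list(CHANNEL_NAMES),
        "voxel_size_zyx_um": list(spec.voxel_size_zyx_um),
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_stack(path: Path) -> tuple[np.ndarray, dict]:
    path = Path(path)
    stack = tifffile.imread(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    return stack, meta


def validate_well_id(well: str) -> str:
    if not _WELL_RE.match(well):
        raise ValueError(f"invalid 96-well id {well!r} (expected A1..H12)")
    return well


def make_plate(
    layout: pd.DataFrame,
    out_dir: Path,
    movie_specs: dict[str, MovieSpec] | None = None,
    stack_specs: dict[str, StackSpec] | None = None,
    base_seed: int = 0,
) -> pd.DataFrame:
    """Generate one movie and/or stack per well and a binding manifest.

    Parameters
    ----------
    layout : DataFrame with columns ``well``, ``condition`` and optionally
        ``dose``; well ids in the standard A1..H12 scheme, unique.
    movie_specs, stack_specs : per-condition specs; each well's seed is
        derived deterministically from ``base_seed`` and its row index.

    Returns the manifest (also written to ``out_dir/manifest.csv``) with
    columns well, file, kind, condition, dose, seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    wells = [validate_well_id(w) for w in layout["well"]]
    if len(set(wells)) != len(wells):
        dupes = sorted({w for w in wells if wells.count(w) > 1})
        raise ValueError(f"duplicate well ids in layout: {dupes}")

    rows = []
    for idx, rec in enumerate(layout.to_dict("records")):
        well = rec["well"]
        cond = rec["condition"]
        dose = rec.get("dose", np.nan)
        seed = (base_seed + 7919 * idx) % (2**31 - 1)
        if movie_specs is not None and cond in movie_specs:
            spec = _reseed(movie_specs[cond], seed)
            movie, _ = make_contraction_movie(spec)
            fname = f"{well}_movie.tif"
            write_movie(out_dir / fname, movie, spec)
            rows.append(dict(well=well, file=fname, kind="movie",
                             condition=cond, dose=dose, seed=seed))
        if stack_specs is not None and cond in stack_specs:
            spec = _reseed(stack_specs[cond], seed + 1)
            stack, _ = make_if_stack(spec)
            fname = f"{well}_stack.tif"
            write_stack(out_dir / fname, stack, spec)
            rows.append(dict(well=well, file=fname, kind="stack",
                             condition=cond, dose=dose, seed=seed + 1))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def _reseed(spec, seed: int):
    kwargs = asdict(spec)
    kwargs["seed"] = seed
    if isinstance(spec, MovieSpec):
        kwargs["pulse_times_s"] = tuple(kwargs["pulse_times_s"])
        return MovieSpec(**kwargs)
    kwargs["shape_zyx"] = tuple(kwargs["shape_zyx"])
    kwargs["voxel_size_zyx_um"] = tuple(kwargs["voxel_size_zyx_um"])
    return StackSpec(**kwargs)
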