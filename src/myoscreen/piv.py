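"""Multipass window cross-correlation PIV for contraction movies.

The estimator follows standard time-resolved PIV practice: each consecutive
frame pair (A+B, B+C, ...) is divided into square interrogation windows laid
out coarse-to-fine (default 64/32/16 px, 50% overlap); each window's
displacement is the argmax of the zero-mean cross-correlation of the
(predictor-shifted) windows, refined to subpixel precision with a three-point
Gaussian fit per axis.  Vectors are validated by an n-sigma filter on each
velocity component, and valid vectors are reduced to a per-pair contraction
trace with peak detection and a compass/axis-decomposition summary.

Internally everything is computed in px/frame; the conversion to um/s happens
exactly once, when the final VelocityField is constructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "PivConfig",
    "VelocityField",
    "ContractionTrace",
    "correlate_pass",
    "multipass_piv",
    "validate_vectors",
    "contraction_trace",
    "detect_peaks",
    "direction_summary",
]


@dataclass(frozen=True)
class PivConfig:
    """Interrogation settings for multipass PIV."""

    window_sizes_px: tuple[int, ...] = (64, 32, 16)
    overlap_fraction: float = 0.5
    sd_threshold: float = 7.0
    subpixel_method: str = "gaussian3"  # three-point Gaussian per axis
    search_fraction: float = 1.0 / 3.0  # max |lag| as a fraction of the window

    def __post_init__(self) -> None:
        sizes = tuple(self.window_sizes_px)
        if not sizes or any(b >= a for a, b in zip(sizes, sizes[1:])):
            raise ValueError("window_sizes_px must be strictly decreasing")
        if not 0.0 <= self.overlap_fraction < 1.0:
            raise ValueError("overlap_fraction must be in [0, 1)")
        if self.sd_threshold <= 0:
            raise ValueError("sd_threshold must be > 0")


@dataclass
class VelocityField:
    """Per-frame-pair grid of 2D velocity vectors with a validity mask.

    ``grid_x``/``grid_y`` are window-centre coordinates in px; ``v_x``/``v_y``
    are velocities in um/s (displacement-per-pair divided by ``dt_s`` scaled by
    ``pixel_size_um``).
    """

    grid_x: np.ndarray      # (ny, nx) px
    grid_y: np.ndarray
    v_x: np.ndarray         # (ny, nx) um/s
    v_y: np.ndarray
    valid: np.ndarray       # (ny, nx) bool
    dt_s: float
    pixel_size_um: float
    warnings: list[str] = field(default_factory=list)

    @property
    def speed(self) -> np.ndarray:
        return np.hypot(self.v_x, self.v_y)

    @property
    def displacement_px(self) -> tuple[np.ndarray, np.ndarray]:
        scale = self.dt_s / self.pixel_size_um
        return self.v_x * scale, self.v_y * scale

    def n_valid(self) -> int:
        return int(self.valid.sum())


@dataclass
class ContractionTrace:
    """Per-frame-pair summary of the motion in a movie.

    Means are taken over valid vectors only; a pair with no valid vector is
    recorded as NaN.  ``mean_abs_vx/vy`` are means of the component magnitudes
    (the quantities fed to the axis-decomposed force estimate); ``mean_vx/vy``
    are signed means.
    """

    times_s: np.ndarray
    mean_speed_um_s: np.ndarray
    mean_vx_um_s: np.ndarray
    mean_vy_um_s: np.ndarray
    mean_abs_vx_um_s: np.ndarray
    mean_abs_vy_um_s: np.ndarray
    n_valid: np.ndarray
    dt_s: float
    pixel_size_um: float
    fields: list[VelocityField] | None = None
    peak_indices: np.ndarray | None = None
    peak_values: np.ndarray | None = None

    def __len__(self) -> int:
        return len(self.times_s)

    @property
    def peak_index(self) -> int:
        """Index of the frame pair with the largest mean speed."""
        speeds = np.where(np.isnan(self.mean_speed_um_s), -np.inf,
                          self.mean_speed_um_s)
        if np.all(np.isinf(speeds)):
            raise ValueError("trace has no valid summaries")
        return int(np.argmax(speeds))


# ---------------------------------------------------------------------------
# Correlation
# ---------------------------------------------------------------------------

def _window_starts(extent: int, window: int, step: int) -> np.ndarray:
    """Top-left offsets of fully inside windows (edge windows are dropped)."""
    if extent < window:
        return np.array([], dtype=int)
    return np.arange(0, extent - window + 1, step)


def _subpixel_offset(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian peak fit; falls back to parabolic, then 0."""
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm + lp - 2.0 * l0
        if denom < 0:
            return float(np.clip(0.5 * (lm - lp) / denom, -1.0, 1.0))
    denom = cm + cp - 2.0 * c0
    if denom < 0:
        return float(np.clip(0.5 * (cm - cp) / denom, -1.0, 1.0))
    return 0.0


def correlate_pass(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_px: int,
    overlap_fraction: float = 0.5,
    predictor: tuple[np.ndarray, np.ndarray] | None = None,
    search_fraction: float = 1.0 / 3.0,
) -> dict:
    """One interrogation pass; displacements in px of B-content relative to A.

    Parameters
    ----------
    predictor : optional integer-shift fields (pdx, pdy) on this pass's grid;
        the window in ``frame_b`` is extracted at the predicted offset and the
        correlation measures only the residual.

    Returns a dict with grid_x, grid_y (window centres, px), dx, dy (px,
    including the predictor) and valid.  A zero-variance window is flagged
    invalid; a predictor that would push a window outside the frame is
    clamped to the largest feasible offset.
    """
    if frame_a.shape != frame_b.shape:
        raise ValueError("frames must have the same shape")
    h, w = frame_a.shape
    if window_px > min(h, w):
        raise ValueError("window larger than frame")
    step = max(1, int(round(window_px * (1.0 - overlap_fraction))))
    ys = _window_starts(h, window_px, step)
    xs = _window_starts(w, window_px, step)
    ny, nx = len(ys), len(xs)
    grid_y, grid_x = np.meshgrid(
        ys + (window_px - 1) / 2.0, xs + (window_px - 1) / 2.0, indexing="ij"
    )
    dx = np.zeros((ny, nx))
    dy = np.zeros((ny, nx))
    valid = np.ones((ny, nx), dtype=bool)
    if predictor is None:
        pdx = np.zeros((ny, nx), dtype=int)
        pdy = np.zeros((ny, nx), dtype=int)
    else:
        pdx, pdy = (np.asarray(p).astype(int) for p in predictor)

    radius = max(2, int(round(window_px * search_fraction)))
    fa = frame_a.astype(np.float64)
    fb = frame_b.astype(np.float64)
    for i, y0 in enumerate(ys):
        for j, x0 in enumerate(xs):
            # clamp the predictor so the shifted window stays inside the
            # frame; the correlation measures the residual from the clamped
            # offset, keeping edge vectors valid at large displacements
            by0 = int(np.clip(y0 + pdy[i, j], 0, h - window_px))
            bx0 = int(np.clip(x0 + pdx[i, j], 0, w - window_px))
            px, py = bx0 - x0, by0 - y0
            wa = fa[y0:y0 + window_px, x0:x0 + window_px]
            wb = fb[by0:by0 + window_px, bx0:bx0 + window_px]
            wa0 = wa - wa.mean()
            wb0 = wb - wb.mean()
            if not wa0.any() or not wb0.any():
                valid[i, j] = False
                continue
            # Linear (zero-padded) cross-correlation of B against A; lag
            # (0,0) sits at index (window-1, window-1).  Dividing by the
            # overlap area removes the triangular weighting of zero padding,
            # which would otherwise drag wide peaks toward zero lag.
            corr = signal.fftconvolve(wb0, wa0[::-1, ::-1], mode="full")
            c = window_px - 1
            lags = np.arange(-radius, radius + 1)
            overlap = np.maximum(window_px - np.abs(lags), 1).astype(float)
            region = corr[c - radius:c + radius + 1, c - radius:c + radius + 1]
            region = region / np.outer(overlap, overlap)
            peak = region.max()
            cand = np.argwhere(region == peak) - radius
            # Deterministic tie-break toward the smaller displacement.
            order = np.lexsort((cand[:, 1], cand[:, 0],
                                (cand**2).sum(axis=1)))
            ldy, ldx = cand[order[0]]
            sx = sy = 0.0
            iy, ix = ldy + radius, ldx + radius
            if 0 < ix < region.shape[1] - 1:
                sx = _subpixel_offset(region[iy, ix - 1], region[iy, ix],
                                      region[iy, ix + 1])
            if 0 < iy < region.shape[0] - 1:
                sy = _subpixel_offset(region[iy - 1, ix], region[iy, ix],
                                      region[iy + 1, ix])
            dx[i, j] = px + ldx + sx
            dy[i, j] = py + ldy + sy
    return dict(grid_x=grid_x, grid_y=grid_y, dx=dx, dy=dy, valid=valid)


def _interp_to_grid(
    src: dict, tgt_x: np.ndarray, tgt_y: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Interpolate a pass's displacement field onto a finer grid (px units)."""
    ys = src["grid_y"][:, 0]
    xs = src["grid_x"][0, :]
    out = []
    for comp in ("dx", "dy"):
        vals = src[comp].copy()
        bad = ~src["valid"]
        if bad.any():
            fill = vals[~bad].mean() if (~bad).any() else 0.0
            vals[bad] = fill
        if len(ys) < 2 or len(xs) < 2:
            out.append(np.full(tgt_x.shape, vals.mean()))
            continue
        itp = RegularGridInterpolator(
            (ys, xs), vals, bounds_error=False, fill_value=None
        )
        pts = np.stack([
            np.clip(tgt_y, ys[0], ys[-1]).ravel(),
            np.clip(tgt_x, xs[0], xs[-1]).ravel(),
        ], axis=-1)
        out.append(itp(pts).reshape(tgt_x.shape))
    return out[0], out[1]


def multipass_piv(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    config: PivConfig = PivConfig(),
    dt_s: float = 1.0,
    pixel_size_um: float = 1.0,
) -> VelocityField:
    """Coarse-to-fine PIV between two frames.

    Each pass's displacement field, rounded to integers, serves as the next
    pass's predictor; only windows that fit fully inside the frame are used.
    Windows larger than the frame are skipped with a warning record.
    """
    notes: list[str] = []
    prev: dict | None = None
    sizes = [s for s in config.window_sizes_px if s <= min(frame_a.shape)]
    if not sizes:
        raise ValueError("no interrogation window fits inside the frame")
    if len(sizes) < len(config.window_sizes_px):
        notes.append("dropped window sizes larger than the frame")
    for size in sizes:
        step = max(1, int(round(size * (1.0 - config.overlap_fraction))))
        ys = _window_starts(frame_a.shape[0], size, step) + (size - 1) / 2.0
        xs = _window_starts(frame_a.shape[1], size, step) + (size - 1) / 2.0
        gy, gx = np.meshgrid(ys, xs, indexing="ij")
        predictor = None
        if prev is not None:
            pdx, pdy = _interp_to_grid(prev, gx, gy)
            predictor = (np.round(pdx).astype(int), np.round(pdy).astype(int))
        prev = correlate_pass(
            frame_a, frame_b, size, config.overlap_fraction,
            predictor=predictor, search_fraction=config.search_fraction,
        )
    scale = pixel_size_um / dt_s
    return VelocityField(
        grid_x=prev["grid_x"],
        grid_y=prev["grid_y"],
        v_x=prev["dx"] * scale,
        v_y=prev["dy"] * scale,
        valid=prev["valid"],
        dt_s=dt_s,
        pixel_size_um=pixel_size_um,
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# Validation and reduction
# ---------------------------------------------------------------------------

def validate_vectors(field_: VelocityField, sd_threshold: float = 7.0) -> VelocityField:
    """n-sigma outlier filter on each velocity component (single pass).

    A vector is invalidated when either component deviates from that
    component's mean (over the currently valid vectors) by more than
    ``sd_threshold`` times that component's standard deviation.  Invalid
    vectors are excluded, never interpolated.
    """
    out = replace(field_, valid=field_.valid.copy(),
                  warnings=list(field_.warnings))
    if out.n_valid() < 2:
        out.warnings.append("fewer than 2 valid vectors; SD filter skipped")
        return out
    keep = out.valid.copy()
    for comp in (out.v_x, out.v_y):
        vals = comp[out.valid]
        mu, sd = vals.mean(), vals.std()
        if sd == 0 or not np.isfinite(sd):
            continue
        keep &= np.abs(comp - mu) <= sd_threshold * sd
    out.valid = keep
    return out


def contraction_trace(
    movie: np.ndarray,
    config: PivConfig = PivConfig(),
    frame_rate_hz: float = 20.0,
    pixel_size_um: float = 1.0,
    store_fields: bool = False,
) -> ContractionTrace:
    """Time-resolved PIV over consecutive frame pairs (A+B, B+C, ...).

    For each pair the velocity field is estimated, validated with the
    ``sd_threshold`` filter, and summarised by the mean speed and mean
    (signed and absolute) components over valid vectors.  A pair with zero
    valid vectors yields NaN summaries and the trace continues.
    """
    movie = np.asarray(movie)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (n_frames >= 2, H, W)")
    dt = 1.0 / frame_rate_hz
    n_pairs = movie.shape[0] - 1
    cols = {k: np.full(n_pairs, np.nan) for k in
            ("speed", "vx", "vy", "avx", "avy")}
    n_valid = np.zeros(n_pairs, dtype=int)
    fields: list[VelocityField] = []
    for i in range(n_pairs):
        fld = multipass_piv(movie[i], movie[i + 1], config,
                            dt_s=dt, pixel_size_um=pixel_size_um)
        fld = validate_vectors(fld, config.sd_threshold)
        if store_fields:
            fields.append(fld)
        m = fld.valid
        n_valid[i] = m.sum()
        if n_valid[i] == 0:
            continue
        cols["speed"][i] = fld.speed[m].mean()
        cols["vx"][i] = fld.v_x[m].mean()
        cols["vy"][i] = fld.v_y[m].mean()
        cols["avx"][i] = np.abs(fld.v_x[m]).mean()
        cols["avy"][i] = np.abs(fld.v_y[m]).mean()
    return ContractionTrace(
        times_s=(np.arange(n_pairs) + 0.5) * dt,
        mean_speed_um_s=cols["speed"],
        mean_vx_um_s=cols["vx"],
        mean_vy_um_s=cols["vy"],
        mean_abs_vx_um_s=cols["avx"],
        mean_abs_vy_um_s=cols["avy"],
        n_valid=n_valid,
        dt_s=dt,
        pixel_size_um=pixel_size_um,
        fields=fields if store_fields else None,
    )


def detect_peaks(
    trace: ContractionTrace,
    min_prominence: float = 0.0,
    include_boundaries: bool = True,
) -> ContractionTrace:
    """Locate contraction peaks in the mean-speed trace.

    Peaks are local maxima with prominence >= ``min_prominence``; boundary
    maxima count as peaks by default (a monotone trace peaks at its end).
    Returns the trace with ``peak_indices``/``peak_values`` filled in; the
    global maximum is the peak velocity.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    y = trace.mean_speed_um_s
    floor = np.nanmin(y) if np.isfinite(y).any() else 0.0
    y = np.where(np.isnan(y), floor, y)
    if include_boundaries:
        # pad with the trace minimum so boundary maxima are detectable but
        # their prominence stays the in-trace rise, not infinity
        padded = np.concatenate([[floor], y, [floor]])
        idx, _ = signal.find_peaks(padded, prominence=min_prominence or None)
        idx = idx - 1
    else:
        idx, _ = signal.find_peaks(y, prominence=min_prominence or None)
    idx = idx[np.isfinite(y[idx]) & (y[idx] > 0)] if len(idx) else idx
    trace.peak_indices = idx
    trace.peak_values = trace.mean_speed_um_s[idx]
    return trace


def direction_summary(field_: VelocityField) -> dict:
    """Compass distribution and axis decomposition of one velocity field.

    Returns per-vector angles in [0, 360) degrees (from +x, toward +y) and
    magnitudes, plus the axis decomposition: mean |v| (XY), mean |v_x|
    (X-specific) and mean |v_y| (Y-specific) over valid vectors.
    """
    m = field_.valid
    if m.sum() < 1:
        raise ValueError("no valid vectors")
    vx = field_.v_x[m]
    vy = field_.v_y[m]
    angles = np.rad2deg(np.arctan2(vy, vx)) % 360.0
    mags = np.hypot(vx, vy)
    return dict(
        angles_deg=angles,
        magnitudes_um_s=mags,
        mean_speed_um_s=float(mags.mean()),
        mean_abs_vx_um_s=float(np.abs(vx).mean()),
        mean_abs_vy_um_s=float(np.abs(vy).mean()),
    )
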