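"""Two-pass window cross-correlation PIV for cell-surface time lapses.

The displacement field between consecutive frames is estimated by
normalized cross-correlation of square interrogation windows, in two
passes: a coarse pass (default 20 um windows) estimates large-scale
displacement, which pre-shifts the windows of a refining fine pass
(default 10 um) on a denser grid. Peaks are located to sub-pixel
precision with a three-point Gaussian fit. No window deformation and no
outlier substitution are applied by default; an optional normalized
median filter can flag spurious vectors.

Velocities are reported in um/s: displacement per frame pair divided by
the frame interval and scaled by the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.fft import next_fast_len
from scipy.interpolate import RegularGridInterpolator

from .errors import EmptyTracesError, InvalidSpecError

_MIN_WINDOW_PX = 4


@dataclass
class TimeLapse:
    """A calibrated single-plane movie: frames (T, H, W), pixel size in
    um/px and frame interval in s."""

    frames: np.ndarray
    pixel_size: float
    frame_interval: float

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise InvalidSpecError("need a (T, H, W) stack with T >= 2")
        if self.pixel_size <= 0 or self.frame_interval <= 0:
            raise InvalidSpecError("pixel_size and frame_interval must be > 0")

    @property
    def n_frames(self) -> int:
        return int(self.frames.shape[0])


@dataclass
class VectorField:
    """One PIV field: window-center grid (um) and velocities (um/s)."""

    x: np.ndarray  # (n_x,) window-center x positions, um
    y: np.ndarray  # (n_y,) window-center y positions, um
    u: np.ndarray  # (n_y, n_x) x-velocity, um/s
    v: np.ndarray  # (n_y, n_x) y-velocity, um/s
    valid: np.ndarray  # (n_y, n_x) bool


@dataclass
class VelocityTraces:
    """Per-grid-point velocity time series; one row per retained vector."""

    u: np.ndarray  # (n_points, n_pairs) um/s
    v: np.ndarray  # (n_points, n_pairs)
    positions: np.ndarray  # (n_points, 2) (x, y) um
    frame_interval: float

    @property
    def n_points(self) -> int:
        return int(self.u.shape[0])


def _grid_centers(length: int, window: int, step: int) -> np.ndarray:
    """Window-center pixel positions such that windows lie fully inside."""
    first = window // 2
    last = length - (window - window // 2)
    return np.arange(first, last + 1, step)


def _extract_windows(frame: np.ndarray, cys: np.ndarray, cxs: np.ndarray,
                     window: int) -> np.ndarray:
    half = window // 2
    out = np.empty((len(cys), window, window), dtype=np.float64)
    for i, (cy, cx) in enumerate(zip(cys, cxs)):
        out[i] = frame[cy - half:cy - half + window,
                       cx - half:cx - half + window]
    return out


def _correlate_and_peak(wa: np.ndarray, wb: np.ndarray,
                        search: int) -> tuple[np.ndarray, np.ndarray]:
    """Batched normalized cross-correlation peak with sub-pixel fit.

    wa, wb: (n, win, win). Returns (displacements (n, 2) as (dx, dy) in
    px of wb relative to wa, valid (n,) bool). Search is limited to
    +/- `search` px around zero lag.
    """
    n, win, _ = wa.shape
    mu_a = wa.mean(axis=(1, 2), keepdims=True)
    mu_b = wb.mean(axis=(1, 2), keepdims=True)
    a = wa - mu_a
    b = wb - mu_b
    sd_a = a.std(axis=(1, 2))
    sd_b = b.std(axis=(1, 2))
    valid = (sd_a > 1e-12) & (sd_b > 1e-12)

    size = next_fast_len(2 * win - 1)
    fa = np.fft.rfft2(a, s=(size, size))
    fb = np.fft.rfft2(b, s=(size, size))
    cc = np.fft.irfft2(np.conj(fa) * fb, s=(size, size))
    cc = np.fft.fftshift(cc, axes=(1, 2))
    center = size // 2
    search = min(search, center - 1)
    cc = cc[:, center - search:center + search + 1,
            center - search:center + search + 1]
    norm = np.where(valid, sd_a * sd_b, 1.0) * win * win
    cc = cc / norm[:, None, None]

    side = 2 * search + 1
    flat = cc.reshape(n, -1)
    idx = np.argmax(flat, axis=1)
    py, px = np.divmod(idx, side)

    disp = np.empty((n, 2))
    for i in range(n):
        if not valid[i]:
            disp[i] = (0.0, 0.0)
            continue
        yi, xi = py[i], px[i]
        # peak on the search border: keep the integer estimate
        dy = yi - search + _subpixel_offset(
            cc[i, max(yi - 1, 0), xi], cc[i, yi, xi],
            cc[i, min(yi + 1, side - 1), xi]) if 0 < yi < side - 1 else yi - search
        dx = xi - search + _subpixel_offset(
            cc[i, yi, max(xi - 1, 0)], cc[i, yi, xi],
            cc[i, yi, min(xi + 1, side - 1)]) if 0 < xi < side - 1 else xi - search
        disp[i] = (dx, dy)
    return disp, valid


def _subpixel_offset(cm: float, c0: float, cp: float) -> float:
    """Three-point Gaussian peak interpolation, parabolic fallback when
    the Gaussian fit is undefined (non-positive samples)."""
    if cm > 0 and c0 > 0 and cp > 0:
        lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
        denom = lm - 2 * l0 + lp
        if denom < 0:
            return float(np.clip((lm - lp) / (2 * denom), -1.0, 1.0))
    denom = cm - 2 * c0 + cp
    if denom < 0:
        return float(np.clip((cm - cp) / (2 * denom), -1.0, 1.0))
    return 0.0


def compute_piv_pair(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window_coarse: float = 20.0,
    window_fine: float = 10.0,
    overlap_fraction: float = 0.5,
    pixel_size: float = 1.0,
    frame_interval: float = 1.0,
    px_per_frame: bool = False,
) -> VectorField:
    """Two-pass PIV between one frame pair.

    Windows are given in um and converted to pixels; the fine pass runs
    on a grid with `overlap_fraction` window overlap, pre-shifted by the
    interpolated coarse-pass displacement. Featureless (zero-variance)
    windows yield vectors flagged invalid. Set px_per_frame to report
    raw displacements in px/frame instead of um/s.
    """
    frame_a = np.asarray(frame_a, dtype=np.float64)
    frame_b = np.asarray(frame_b, dtype=np.float64)
    if frame_a.shape != frame_b.shape:
        raise InvalidSpecError("frames must share one shape")
    win_c = int(round(window_coarse / pixel_size))
    win_f = int(round(window_fine / pixel_size))
    if not win_c > win_f >= _MIN_WINDOW_PX:
        raise InvalidSpecError(
            f"windows {win_c}/{win_f} px must satisfy coarse > fine >= "
            f"{_MIN_WINDOW_PX}")
    h, w = frame_a.shape
    step_c = max(1, int(round(win_c * (1 - overlap_fraction))))
    step_f = max(1, int(round(win_f * (1 - overlap_fraction))))

    # pass 1: coarse displacement field
    cx = _grid_centers(w, win_c, step_c)
    cy = _grid_centers(h, win_c, step_c)
    gyy, gxx = np.meshgrid(cy, cx, indexing="ij")
    wa = _extract_windows(frame_a, gyy.ravel(), gxx.ravel(), win_c)
    wb = _extract_windows(frame_b, gyy.ravel(), gxx.ravel(), win_c)
    disp_c, valid_c = _correlate_and_peak(wa, wb, win_c // 2)
    disp_c[~valid_c] = 0.0
    dxc = disp_c[:, 0].reshape(len(cy), len(cx))
    dyc = disp_c[:, 1].reshape(len(cy), len(cx))

    # pass 2: fine grid pre-shifted by the interpolated coarse field
    fx = _grid_centers(w, win_f, step_f)
    fy = _grid_centers(h, win_f, step_f)
    fyy, fxx = np.meshgrid(fy, fx, indexing="ij")
    if len(cy) >= 2 and len(cx) >= 2:
        interp_dx = RegularGridInterpolator((cy, cx), dxc, bounds_error=False,
                                            fill_value=None)
        interp_dy = RegularGridInterpolator((cy, cx), dyc, bounds_error=False,
                                            fill_value=None)
        pts = np.column_stack([fyy.ravel(), fxx.ravel()])
        shift_x = np.round(interp_dx(pts)).astype(int)
        shift_y = np.round(interp_dy(pts)).astype(int)
    else:
        shift_x = np.zeros(fyy.size, dtype=int)
        shift_y = np.zeros(fyy.size, dtype=int)

    half_f = win_f // 2
    bx = np.clip(fxx.ravel() + shift_x, half_f, w - (win_f - half_f))
    by = np.clip(fyy.ravel() + shift_y, half_f, h - (win_f - half_f))
    shift_x = bx - fxx.ravel()
    shift_y = by - fyy.ravel()
    wa = _extract_windows(frame_a, fyy.ravel(), fxx.ravel(), win_f)
    wb = _extract_windows(frame_b, by, bx, win_f)
    disp_f, valid_f = _correlate_and_peak(wa, wb, win_f // 2)
    dx = disp_f[:, 0] + shift_x
    dy = disp_f[:, 1] + shift_y
    dx[~valid_f] = np.nan
    dy[~valid_f] = np.nan

    scale = 1.0 if px_per_frame else pixel_size / frame_interval
    u = (dx * scale).reshape(len(fy), len(fx))
    v = (dy * scale).reshape(len(fy), len(fx))
    return VectorField(
        x=fx * pixel_size,
        y=fy * pixel_size,
        u=u,
        v=v,
        valid=valid_f.reshape(len(fy), len(fx)),
    )


def compute_piv_series(
    movie: TimeLapse,
    window_coarse: float = 20.0,
    window_fine: float = 10.0,
    overlap_fraction: float = 0.5,
    px_per_frame: bool = False,
) -> list[VectorField]:
    """PIV between every pair of consecutive frames (N frames -> N-1
    fields on one common grid)."""
    fields = []
    for i in range(movie.n_frames - 1):
        try:
            fields.append(compute_piv_pair(
                movie.frames[i], movie.frames[i + 1],
                window_coarse=window_coarse, window_fine=window_fine,
                overlap_fraction=overlap_fraction,
                pixel_size=movie.pixel_size,
                frame_interval=movie.frame_interval,
                px_per_frame=px_per_frame,
            ))
        except InvalidSpecError as exc:
            raise InvalidSpecError(f"frame pair {i}/{i + 1}: {exc}") from exc
    return fields


def vector_time_series(fields: list[VectorField],
                       min_valid_fraction: float = 0.9,
                       frame_interval: float = float("nan")) -> VelocityTraces:
    """Assemble per-grid-point velocity time series from a PIV sequence.

    A grid point is retained when it is valid in at least
    `min_valid_fraction` of the frame pairs; its sporadic invalid
    entries are linearly interpolated in time.
    """
    if not fields:
        raise InvalidSpecError("no vector fields")
    x0, y0 = fields[0].x, fields[0].y
    for f in fields[1:]:
        if not (np.array_equal(f.x, x0) and np.array_equal(f.y, y0)):
            raise InvalidSpecError("vector fields do not share a grid")
    u = np.stack([f.u for f in fields])  # (n_pairs, n_y, n_x)
    v = np.stack([f.v for f in fields])
    valid = np.stack([f.valid for f in fields])
    n_pairs = u.shape[0]
    frac = valid.mean(axis=0)
    keep = frac >= min_valid_fraction
    if not np.any(keep):
        raise EmptyTracesError(
            f"no grid point valid in >= {min_valid_fraction:.0%} of pairs")

    ky, kx = np.nonzero(keep)
    t = np.arange(n_pairs)
    u_out = np.empty((len(ky), n_pairs))
    v_out = np.empty((len(ky), n_pairs))
    for i, (r, c) in enumerate(zip(ky, kx)):
        ok = valid[:, r, c]
        for src, dst in ((u, u_out), (v, v_out)):
            trace = src[:, r, c]
            if ok.all():
                dst[i] = trace
            else:
                dst[i] = np.interp(t, t[ok], trace[ok])
    positions = np.column_stack([x0[kx], y0[ky]])
    return VelocityTraces(u=u_out, v=v_out, positions=positions,
                          frame_interval=frame_interval)


def movie_velocity_traces(movie: TimeLapse, **piv_kwargs) -> VelocityTraces:
    """Convenience: full PIV + trace assembly for one movie."""
    fields = compute_piv_series(movie, **piv_kwargs)
    return vector_time_series(fields, frame_interval=movie.frame_interval)


def median_filter_validate(field: VectorField, threshold: float = 2.0,
                           eps: float = 0.1) -> VectorField:
    """Optional normalized-median outlier test (flags, does not replace).

    A vector is flagged invalid when its residual to the median of its
    8-neighborhood, normalized by the median residual of that
    neighborhood, exceeds `threshold`.
    """
    u, v = field.u, field.v
    ny, nx = u.shape
    good = field.valid.copy()
    for comp in (u, v):
        for r in range(ny):
            for c in range(nx):
                if not good[r, c]:
                    continue
                rr = slice(max(r - 1, 0), min(r + 2, ny))
                cc = slice(max(c - 1, 0), min(c + 2, nx))
                neigh = comp[rr, cc].ravel()
                neigh = neigh[~np.isnan(neigh)]
                if len(neigh) < 3:
                    continue
                med = np.median(neigh)
                res = np.median(np.abs(neigh - med))
                if np.abs(comp[r, c] - med) / (res + eps) > threshold:
                    good[r, c] = False
    return VectorField(x=field.x, y=field.y, u=u, v=v, valid=good)
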