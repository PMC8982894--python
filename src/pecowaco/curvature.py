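"""Contour curvature kymographs and traveling-wave estimation.

The cell outline is extracted from a binary segmentation mask by
sub-pixel marching squares, resampled to uniform arclength. Local
signed curvature at each contour point is the inverse circumcircle
radius through the start, center and end point of a 10-um strip of the
surface centered there — positive where the surface bulges outward.
Profiles over time form a kymograph (normalized arclength x time) whose
2D Fourier power spectrum yields the wave period, spatial wave number,
and hence propagation velocity (wavelength x temporal frequency),
replacing a manual line fit on the kymograph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import measure

from ._geometry import (arclengths, ensure_counterclockwise, interp_periodic,
                        polygon_centroid, resample_closed)
from .errors import (BandError, GeometryError, InvalidSpecError, NoWaveError,
                     SegmentationError, StandingWaveError, StripError)
from .spectral import (DEFAULT_BAND, DEFAULT_THRESHOLD, OscillationCall,
                       PowerSpectrum, detect_oscillation)

DEFAULT_STRIP_LENGTH = 10.0  # um of cell surface per circle fit


@dataclass
class Contour:
    """Closed cell outline: points (N, 2) in um, counterclockwise
    (positive shoelace area in image coordinates), uniform arclength."""

    points: np.ndarray
    arclength_step: float

    @property
    def perimeter(self) -> float:
        return arclengths(self.points)[1]


@dataclass
class CurvatureProfile:
    s: np.ndarray  # arclength positions, um
    kappa: np.ndarray  # signed curvature, 1/um
    strip_length: float
    perimeter: float


@dataclass
class CurvatureKymograph:
    """Signed curvature over (normalized arclength bin x frame)."""

    values: np.ndarray  # (n_bins, n_frames)
    frame_interval: float
    perimeters: np.ndarray  # (n_frames,) um

    @property
    def n_bins(self) -> int:
        return int(self.values.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.values.shape[1])


@dataclass
class WaveEstimate:
    period: float  # s
    wave_number: int  # cycles per perimeter
    velocity: float  # um/s
    direction: int  # +1 toward increasing arclength
    quality: float  # peak/mean of the 2D power spectrum


def mask_to_contour(mask: np.ndarray, pixel_size: float,
                    smoothing_sigma: float = 0.5) -> Contour:
    """Sub-pixel iso-contour of a binary mask at level 0.5.

    The mask is optionally Gaussian-smoothed (sigma in um) before
    marching squares; the contour is resampled to an arclength step of
    one pixel (in um) and oriented counterclockwise.
    """
    mask = np.asarray(mask)
    if pixel_size <= 0:
        raise InvalidSpecError("pixel_size must be positive")
    fg = mask > 0
    labels, n_comp = ndimage.label(fg)
    if n_comp != 1:
        raise SegmentationError(f"expected one foreground component, got {n_comp}")
    border = np.concatenate([fg[0], fg[-1], fg[:, 0], fg[:, -1]])
    if border.any():
        raise GeometryError("foreground touches the image border")
    img = fg.astype(np.float64)
    if smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, smoothing_sigma / pixel_size)
    contours = measure.find_contours(img, 0.5)
    if not contours:
        raise SegmentationError("no iso-contour at level 0.5 after smoothing")
    rc = max(contours, key=len)  # (row, col) vertices, closed
    if np.allclose(rc[0], rc[-1]):
        rc = rc[:-1]
    pts = np.column_stack([rc[:, 1], rc[:, 0]]) * pixel_size  # (x, y) um
    pts = resample_closed(pts, step=pixel_size)
    pts = ensure_counterclockwise(pts)
    return Contour(points=pts, arclength_step=pixel_size)


def contour_from_points(points: np.ndarray, arclength_step: float) -> Contour:
    """Build a Contour from raw polygon vertices (um), resampling to the
    requested uniform arclength step and enforcing orientation."""
    pts = resample_closed(np.asarray(points, dtype=np.float64),
                          step=arclength_step)
    return Contour(points=ensure_counterclockwise(pts),
                   arclength_step=arclength_step)


def local_curvature(contour: Contour,
                    strip_length: float = DEFAULT_STRIP_LENGTH,
                    boundary_average: bool = False) -> CurvatureProfile:
    """Three-point circumcircle curvature along the contour.

    For each point (strip center) the two points strip_length/2 ahead
    and behind along arclength complete the triple; kappa is the signed
    Menger curvature 2 (b-a) x (c-b) / (|b-a| |c-b| |c-a|), positive for
    locally convex (outward-bulging) surface on a counterclockwise
    contour, zero for collinear triples. With `boundary_average`, the
    profile is instead the mean of the profiles evaluated at the two
    strip boundary points, an alternative reading of strip averaging.
    """
    pts = contour.points
    s, perim = arclengths(pts)
    if perim <= 2 * strip_length:
        raise StripError(
            f"perimeter {perim:.2f} um must exceed twice the strip "
            f"length {strip_length} um")
    # strip endpoints are actual contour vertices (the strip is moved
    # point by point along the segmented surface); with uniform spacing
    # the +/- strip/2 neighbours are a fixed index offset, so triples of
    # cocircular vertices give the circle's curvature exactly
    step = perim / len(pts)
    k = max(1, int(round(strip_length / 2.0 / step)))

    def kappa_at(shift: int) -> np.ndarray:
        a = np.roll(pts, k - shift, axis=0)  # point at s - strip/2 + shift
        b = np.roll(pts, -shift, axis=0)  # strip center at s + shift
        c = np.roll(pts, -k - shift, axis=0)  # point at s + strip/2 + shift
        ab = b - a
        bc = c - b
        ac = c - a
        cross = ab[:, 0] * bc[:, 1] - ab[:, 1] * bc[:, 0]
        denom = (np.linalg.norm(ab, axis=1) * np.linalg.norm(bc, axis=1)
                 * np.linalg.norm(ac, axis=1))
        with np.errstate(invalid="ignore", divide="ignore"):
            kappa = np.where(denom > 0, 2.0 * cross / denom, 0.0)
        return kappa

    if boundary_average:
        kappa = 0.5 * (kappa_at(-k) + kappa_at(k))
    else:
        kappa = kappa_at(0)
    return CurvatureProfile(s=s, kappa=kappa, strip_length=strip_length,
                            perimeter=perim)


def _anchor_arclength(contour: Contour) -> float:
    """Arclength position where the contour crosses the +x ray from its
    centroid — the per-frame registration origin of the kymograph."""
    pts = contour.points
    c = polygon_centroid(pts)
    d = pts - c
    s, perim = arclengths(pts)
    y = d[:, 1]
    y_next = np.roll(y, -1)
    x_mid_positive = (d[:, 0] + np.roll(d[:, 0], -1)) > 0
    crossing = (y <= 0) & (y_next > 0) & x_mid_positive
    idx = np.nonzero(crossing)[0]
    if len(idx) == 0:
        # fall back to the point of smallest |angle| with x > 0
        ang = np.arctan2(d[:, 1], d[:, 0])
        ok = d[:, 0] > 0
        if not ok.any():
            raise GeometryError("cannot anchor contour: centroid outside?")
        return float(s[np.argmin(np.where(ok, np.abs(ang), np.inf))])
    i = int(idx[0])
    j = (i + 1) % len(pts)
    frac = -y[i] / (y[j] - y[i]) if y[j] != y[i] else 0.0
    seg = np.linalg.norm(pts[j] - pts[i])
    return float((s[i] + frac * seg) % perim)


def build_kymograph(contours, strip_length: float = DEFAULT_STRIP_LENGTH,
                    n_bins: int = 360,
                    frame_interval: float | None = None,
                    boundary_average: bool = False) -> CurvatureKymograph:
    """Curvature kymograph of a contour series.

    Each frame's curvature profile is resampled onto `n_bins` equal
    normalized-arclength bins with the arclength origin anchored at the
    contour's crossing of the +x ray from its centroid, so the kymograph
    is invariant to the contour's starting index and frames with
    changing perimeter stay registered.

    `contours` is a ContourSeries (carries frame_interval) or a list of
    Contour / (N, 2) point arrays plus an explicit frame_interval.
    """
    if hasattr(contours, "contours"):
        frame_interval = contours.frame_interval
        frames = contours.contours
    else:
        frames = contours
    if frame_interval is None or frame_interval <= 0:
        raise InvalidSpecError("frame_interval required and positive")
    if len(frames) < 8:
        raise InvalidSpecError("need at least 8 frames for a kymograph")
    values = np.empty((n_bins, len(frames)))
    perimeters = np.empty(len(frames))
    for t, item in enumerate(frames):
        try:
            if isinstance(item, Contour):
                contour = item
            else:
                pts = np.asarray(item, dtype=np.float64)
                step = arclengths(pts)[1] / len(pts)
                contour = Contour(points=ensure_counterclockwise(pts.copy()),
                                  arclength_step=step)
            prof = local_curvature(contour, strip_length,
                                   boundary_average=boundary_average)
            s0 = _anchor_arclength(contour)
            targets = s0 + (np.arange(n_bins) / n_bins) * prof.perimeter
            values[:, t] = interp_periodic(targets, prof.s, prof.kappa,
                                           prof.perimeter)
            perimeters[t] = prof.perimeter
        except (StripError, GeometryError, SegmentationError) as exc:
            raise type(exc)(f"frame {t}: {exc}") from exc
    return CurvatureKymograph(values=values, frame_interval=frame_interval,
                              perimeters=perimeters)


def _temporal_marginal(kymo: CurvatureKymograph) -> PowerSpectrum:
    """1D temporal power spectrum of the kymograph: 2D FFT power of the
    mean-removed kymograph summed over spatial frequencies, normalized
    with the same 1/N convention as the trace spectra."""
    k = kymo.values - kymo.values.mean()
    n_bins, n_frames = k.shape
    spec2d = np.fft.fft2(k)
    power2d = np.abs(spec2d) ** 2
    kt = np.arange(1, n_frames // 2 + 1)
    freqs = kt / (n_frames * kymo.frame_interval)
    marginal = power2d.sum(axis=0)[1:n_frames // 2 + 1] / (n_frames * n_bins ** 2)
    # degenerate = no temporal variation (static discretization texture
    # along arclength alone carries no oscillation signal)
    temporal_dev = np.max(np.abs(
        kymo.values - kymo.values.mean(axis=1, keepdims=True)))
    scale = max(float(np.max(np.abs(kymo.values))), 1e-300)
    degenerate = bool(temporal_dev <= 1e-9 * scale)
    return PowerSpectrum(frequencies=freqs, power=marginal,
                         n_samples=n_frames, frame_interval=kymo.frame_interval,
                         degenerate=degenerate)


def kymograph_period(kymo: CurvatureKymograph,
                     band: tuple[float, float] = DEFAULT_BAND,
                     threshold: float = DEFAULT_THRESHOLD) -> OscillationCall:
    """Temporal oscillation call on a curvature kymograph.

    The 2D Fourier power is marginalized over spatial frequencies before
    the band-limited argmax, so the period definition matches the 1D
    PIV-route spectra, and the same peak/mean threshold rule applies.
    """
    record = kymo.n_frames * kymo.frame_interval
    if record < 2 * band[0]:
        raise BandError(f"record {record} s shorter than twice the band "
                        f"minimum {band[0]} s")
    return detect_oscillation(_temporal_marginal(kymo), band=band,
                              threshold=threshold)


def wave_velocity(kymo: CurvatureKymograph,
                  band: tuple[float, float] = DEFAULT_BAND,
                  threshold: float = DEFAULT_THRESHOLD,
                  standing_tolerance: float = 0.1) -> WaveEstimate:
    """Traveling-wave parameters from the dominant 2D spectral component.

    Finds the strongest (spatial frequency, temporal frequency) pair
    with nonzero wave number and in-band positive temporal frequency;
    velocity = (median perimeter / wave_number) * temporal frequency.
    When the counter-propagating component carries within
    `standing_tolerance` of the dominant power, the pattern is a
    standing wave and no velocity is defined.
    """
    call = kymograph_period(kymo, band=band, threshold=threshold)
    if not call.oscillating:
        raise NoWaveError("kymograph does not pass the oscillation call")
    k = kymo.values - kymo.values.mean()
    n_bins, n_frames = k.shape
    power = np.abs(np.fft.fft2(k)) ** 2
    k_spatial = np.fft.fftfreq(n_bins) * n_bins  # cycles per perimeter
    f_temporal = np.fft.fftfreq(n_frames, kymo.frame_interval)  # Hz
    periods = np.full(n_frames, np.inf)
    pos = f_temporal > 0
    periods[pos] = 1.0 / f_temporal[pos]
    sel_t = pos & (periods >= band[0] * (1 - 1e-9)) & (periods <= band[1] * (1 + 1e-9))
    sel_s = k_spatial != 0
    sub = power[np.ix_(sel_s, sel_t)]
    if sub.size == 0:
        raise BandError("no admissible 2D spectral component")
    i, j = np.unravel_index(np.argmax(sub), sub.shape)
    ks = k_spatial[sel_s][i]
    ft = f_temporal[sel_t][j]
    peak = sub[i, j]
    # counter-propagating partner: (-ks, ft)
    si = np.nonzero(sel_s)[0][i]
    partner_si = np.nonzero(np.isclose(k_spatial, -ks))[0]
    tj = np.nonzero(sel_t)[0][j]
    partner = float(power[partner_si[0], tj]) if len(partner_si) else 0.0
    if peak > 0 and partner / peak > 1.0 - standing_tolerance:
        raise StandingWaveError(
            "equal power in both travel directions (standing wave)")
    wave_number = int(round(abs(ks)))
    median_perimeter = float(np.median(kymo.perimeters))
    velocity = (median_perimeter / wave_number) * ft
    # a wave cos(2 pi f t - 2 pi m s / L) travelling toward increasing s
    # puts its positive-temporal-frequency power at spatial index -m
    direction = -int(np.sign(ks))
    quality = float(peak / power[np.ix_(sel_s, sel_t)].mean())
    return WaveEstimate(period=1.0 / ft, wave_number=wave_number,
                        velocity=float(velocity), direction=direction,
                        quality=quality)


def total_turning(profile: CurvatureProfile) -> float:
    """Integral of kappa ds around the contour; 2 pi for a convex
    counterclockwise curve (sign-convention check)."""
    ds = profile.perimeter / len(profile.s)
    return float(np.sum(profile.kappa) * ds)
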