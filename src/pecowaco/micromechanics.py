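"""Surface tension from micropipette aspiration and cortex thickness
from orthogonal line-scan FWHM.

Aspiration: a pipette of radius Rp applies stepwise increasing suction
to a cell of radius of curvature Rc until the aspirated tongue reaches
the pipette radius; at that critical pressure Pc the Young-Laplace law
gives the surface tension

    gamma = Pc / (2 (1/Rp - 1/Rc)),

in pN/um for Pc in Pa and radii in um (1 Pa um = 1 pN/um).

Thickness: intensity profiles are sampled along lines orthogonal to the
cell outline; the full width at half maximum of each profile above a
local baseline measures the cortical layer, aggregated as the median
over lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from ._geometry import arclengths, interp_periodic
from .errors import (GeometryError, InsufficientScanError, InvalidSpecError,
                     NoPeakError, NotReachedError)


@dataclass
class AspirationSeries:
    """Stepwise aspiration record: pressures (Pa, strictly increasing)
    and tongue lengths (um) for a pipette of radius Rp on a cell of
    radius Rc (both um)."""

    pressures: np.ndarray
    tongue_lengths: np.ndarray
    Rp: float
    Rc: float

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=np.float64)
        self.tongue_lengths = np.asarray(self.tongue_lengths, dtype=np.float64)
        if self.pressures.shape != self.tongue_lengths.shape:
            raise InvalidSpecError("pressures and lengths must align")
        if np.any(np.diff(self.pressures) <= 0):
            raise InvalidSpecError("pressures must be strictly increasing")
        if self.Rp <= 0 or self.Rc <= self.Rp:
            raise GeometryError("need 0 < Rp < Rc")
        if np.any(self.tongue_lengths < 0):
            raise InvalidSpecError("tongue lengths must be non-negative")


@dataclass
class TensionMeasurement:
    """One blastomere's tension: gamma = Pc / (2 (1/Rp - 1/Rc))."""

    Pc: float
    Rp: float
    Rc: float
    gamma: float = field(default=None)
    embryo_id: str = ""
    blastomere_id: str = ""

    def __post_init__(self) -> None:
        expected = laplace_tension(self.Pc, self.Rp, self.Rc)
        if self.gamma is None:
            self.gamma = expected
        elif not np.isclose(self.gamma, expected, rtol=1e-9):
            raise InvalidSpecError(
                f"gamma {self.gamma} inconsistent with Young-Laplace "
                f"value {expected}")


@dataclass
class CortexScan:
    """Per-line cortical FWHM values (nm) and their aggregate."""

    fwhm_per_line: np.ndarray  # nm, NaN where no peak was measurable
    aggregate_fwhm: float  # nm, median over defined lines by default
    n_lines: int  # number of sampled scan positions


def critical_pressure(series: AspirationSeries, mode: str = "step") -> float:
    """Critical pressure at which the tongue length reaches Rp.

    mode "step": first pressure step whose tongue length >= Rp (the
    literal protocol reading). mode "interpolate": linear interpolation
    in (length, pressure) between the bracketing steps at length = Rp.
    """
    reached = series.tongue_lengths >= series.Rp
    if not reached.any():
        raise NotReachedError(
            f"tongue never reached pipette radius {series.Rp} um")
    i = int(np.argmax(reached))
    if i == 0:
        warnings.warn("first pressure step already aspirated a full tongue; "
                      "critical pressure is under-resolved", stacklevel=2)
        return float(series.pressures[0])
    if mode == "step":
        return float(series.pressures[i])
    if mode == "interpolate":
        l0, l1 = series.tongue_lengths[i - 1], series.tongue_lengths[i]
        p0, p1 = series.pressures[i - 1], series.pressures[i]
        return float(p0 + (p1 - p0) * (series.Rp - l0) / (l1 - l0))
    raise InvalidSpecError(f"unknown mode {mode!r}")


def laplace_tension(Pc: float, Rp: float, Rc: float | None = None) -> float:
    """Young-Laplace surface tension in pN/um.

    gamma = Pc / (2 (1/Rp - 1/Rc)); pass Rc=None (or inf) for the
    flat-cell limit gamma = Pc Rp / 2.
    """
    if Rp <= 0:
        raise GeometryError("Rp must be positive")
    inv_rc = 0.0 if Rc is None or np.isinf(Rc) else 1.0 / Rc
    denom = 1.0 / Rp - inv_rc
    if denom <= 0:
        raise GeometryError("Rc must exceed Rp (1/Rp - 1/Rc must be positive)")
    return float(Pc / (2.0 * denom))


def fit_tension(series: AspirationSeries, mode: str = "step",
                embryo_id: str = "", blastomere_id: str = "") -> TensionMeasurement:
    """Critical pressure + Young-Laplace in one call."""
    pc = critical_pressure(series, mode=mode)
    return TensionMeasurement(Pc=pc, Rp=series.Rp, Rc=series.Rc,
                              embryo_id=embryo_id, blastomere_id=blastomere_id)


def aggregate_embryo_tension(
        measurements: list[TensionMeasurement]) -> pd.Series:
    """Mean tension per embryo id (individual blastomeres of one embryo
    are averaged and reported as a single value), ordered by id."""
    if not measurements:
        raise InvalidSpecError("no measurements")
    df = pd.DataFrame({
        "embryo_id": [m.embryo_id for m in measurements],
        "gamma": [m.gamma for m in measurements],
    })
    return df.groupby("embryo_id")["gamma"].mean().sort_index()


def fwhm(profile: np.ndarray, positions: np.ndarray | None = None,
         baseline_fraction: float = 0.2) -> float:
    """Full width at half maximum of an intensity profile.

    The baseline is the mean of the outer `baseline_fraction` of samples
    on each side; the half-max level is baseline + (peak - baseline)/2;
    the width spans the outermost half-max crossings around the peak,
    located by linear interpolation. `positions` defaults to sample
    index; pass positions in nm to get the width in nm.
    """
    profile = np.asarray(profile, dtype=np.float64)
    if profile.ndim != 1 or len(profile) < 7:
        raise InvalidSpecError("profile must be 1D with >= 7 samples")
    n = len(profile)
    if positions is None:
        positions = np.arange(n, dtype=np.float64)
    else:
        positions = np.asarray(positions, dtype=np.float64)
    k = max(1, int(round(baseline_fraction * n)))
    baseline = 0.5 * (profile[:k].mean() + profile[-k:].mean())
    peak_idx = int(np.argmax(profile))
    peak = profile[peak_idx]
    # relative margin: flat profiles carry float-level interpolation
    # noise that must not count as a peak
    margin = 1e-9 * max(abs(peak), abs(baseline), 1e-300)
    if peak <= baseline + margin:
        raise NoPeakError("profile peak does not rise above baseline")
    half = baseline + (peak - baseline) / 2.0

    def cross(idx_range, forward: bool) -> float | None:
        prev = peak_idx
        for i in idx_range:
            if profile[i] < half:
                x0, x1 = positions[i], positions[prev]
                y0, y1 = profile[i], profile[prev]
                return x0 + (half - y0) * (x1 - x0) / (y1 - y0)
            prev = i
        return None

    left = cross(range(peak_idx - 1, -1, -1), False)
    right = cross(range(peak_idx + 1, n), True)
    if left is None or right is None:
        raise NoPeakError("profile does not fall below half max on both sides")
    return float(abs(right - left))


def cortex_linescans(
    image: np.ndarray,
    contour,
    pixel_size: float,
    scan_length: float = 3.0,
    spacing: float = 0.5,
    sampling: float = 50.0,
    aggregate: str = "median",
    min_lines: int = 10,
) -> CortexScan:
    """Cortical thickness from line scans orthogonal to the cell outline.

    At points every `spacing` um along the contour, the image is sampled
    (bilinear) along the inward-outward surface normal over
    `scan_length` um at `sampling` nm per step; each profile's FWHM is
    measured and the aggregate is the median (or mean) over lines with a
    defined peak. `pixel_size` is the image calibration in um/px;
    contour coordinates are um. All widths are reported in nm.
    """
    image = np.asarray(image, dtype=np.float64)
    if pixel_size <= 0:
        raise InvalidSpecError("pixel_size must be positive")
    if sampling > pixel_size * 1000.0:
        raise InvalidSpecError("sampling must not be coarser than a pixel")
    pts = contour.points if hasattr(contour, "points") else np.asarray(contour)
    s, perim = arclengths(pts)
    n_lines = max(1, int(perim // spacing))
    centers_s = np.arange(n_lines) * spacing
    centers = interp_periodic(centers_s, s, pts, perim)
    ahead = interp_periodic(centers_s + 0.5, s, pts, perim)
    behind = interp_periodic(centers_s - 0.5, s, pts, perim)
    tangents = ahead - behind
    tangents /= np.linalg.norm(tangents, axis=1, keepdims=True)
    # outward normal of a counterclockwise contour in image coordinates
    normals = np.column_stack([tangents[:, 1], -tangents[:, 0]])

    step_um = sampling / 1000.0
    n_samp = int(round(scan_length / step_um)) + 1
    offsets = (np.arange(n_samp) - (n_samp - 1) / 2.0) * step_um
    dists_nm = offsets * 1000.0

    h, w = image.shape
    widths = np.full(n_lines, np.nan)
    for i in range(n_lines):
        pos = centers[i] + offsets[:, None] * normals[i]
        cols = pos[:, 0] / pixel_size
        rows = pos[:, 1] / pixel_size
        if (cols.min() < -0.5 or cols.max() > w - 0.5
                or rows.min() < -0.5 or rows.max() > h - 0.5):
            continue  # scan leaves the image
        prof = ndimage.map_coordinates(image, [rows, cols], order=1,
                                       mode="nearest")
        try:
            widths[i] = fwhm(prof, dists_nm)
        except NoPeakError:
            continue
    defined = widths[np.isfinite(widths)]
    if len(defined) < min_lines:
        raise InsufficientScanError(
            f"only {len(defined)} of {n_lines} scans produced a peak "
            f"(minimum {min_lines})")
    agg = float(np.median(defined) if aggregate == "median" else defined.mean())
    return CortexScan(fwhm_per_line=widths, aggregate_fwhm=agg,
                      n_lines=n_lines)
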