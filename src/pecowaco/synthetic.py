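"""Ground-truthed synthetic inputs for the wave-analysis pipeline.

Emulates the acquisition conditions of cleavage-stage embryo recordings:
single blastomeres of 10-30 um radius carrying sinusoidal cortical
traveling waves with 50-200 s periods, imaged every 5 s for about 10
minutes; stepwise micropipette-aspiration series for pipettes of 8-16 um
radius; and super-resolution cortical rings with Gaussian cross-sections
of 300-800 nm FWHM.

The deformation model is a single sinusoidal mode in polar form,

    r(theta, t) = R + A cos(2 pi t / T - m theta + phi0),

a modeling choice: the spatial profile of the real waves is not known
beyond their periodicity. Multi-mode superpositions can be built by
summing the contours of several specs that share a radius.

Every generator is a pure function of its spec and seed: identical
arguments give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from ._geometry import ensure_counterclockwise, interp_periodic, resample_closed
from .errors import GeometryError, InvalidSpecError, ResolutionError
from .micromechanics import AspirationSeries
from .piv import TimeLapse
from .spectral import LabeledRatios

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class WaveCellSpec:
    """Parameters of one synthetic wave-carrying blastomere.

    radius, amplitude and noise_sd are in um, period / frame_interval /
    duration in seconds, phase0 in radians; wave_number is the integer
    number of waves around the circumference.
    """

    radius: float
    amplitude: float
    period: float
    wave_number: int
    frame_interval: float = 5.0
    duration: float = 600.0
    phase0: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0
    point_spacing: float = 0.25  # um between contour points after resampling

    def validate(self) -> None:
        if self.radius <= 0:
            raise InvalidSpecError("radius must be positive")
        if self.amplitude < 0 or self.amplitude >= self.radius:
            raise InvalidSpecError("amplitude must satisfy 0 <= A < radius")
        if self.period <= 0:
            raise InvalidSpecError("period must be positive")
        if self.wave_number < 1:
            raise InvalidSpecError("wave_number must be >= 1")
        if self.frame_interval <= 0:
            raise InvalidSpecError("frame_interval must be positive")
        if self.duration < 2 * self.frame_interval:
            raise InvalidSpecError("duration must cover at least 2 frames")
        if self.noise_sd < 0:
            raise InvalidSpecError("noise_sd must be non-negative")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_interval))


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a wave-cell movie."""

    true_period: float
    true_velocity: float
    true_wave_number: int
    true_radius: float
    true_amplitude: float
    seed: int


@dataclass
class ContourSeries:
    """Per-frame closed cell outlines (um), counterclockwise, uniformly
    resampled in arclength."""

    contours: list[np.ndarray]
    frame_interval: float
    seed: int | None = None

    @property
    def n_frames(self) -> int:
        return len(self.contours)


def make_wave_cell(spec: WaveCellSpec) -> tuple[ContourSeries, GroundTruth]:
    """Generate the contour series of one wave-carrying cell.

    The phase velocity of the boundary wave is 2 pi R / (m T): one
    wavelength (perimeter / m) travels past a fixed point every period.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n_dense = max(720, int(round(8 * 2 * np.pi * spec.radius / spec.point_spacing / 8)))
    theta = np.arange(n_dense) * (2 * np.pi / n_dense)
    times = np.arange(spec.n_frames) * spec.frame_interval
    contours = []
    for t in times:
        r = spec.radius + spec.amplitude * np.cos(
            2 * np.pi * t / spec.period - spec.wave_number * theta + spec.phase0
        )
        if spec.noise_sd > 0:
            r = r + rng.normal(0.0, spec.noise_sd, n_dense)
        pts = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        pts = resample_closed(pts, step=spec.point_spacing)
        contours.append(ensure_counterclockwise(pts))
    truth = GroundTruth(
        true_period=spec.period,
        true_velocity=2 * np.pi * spec.radius / (spec.wave_number * spec.period),
        true_wave_number=spec.wave_number,
        true_radius=spec.radius,
        true_amplitude=spec.amplitude,
        seed=spec.seed,
    )
    return ContourSeries(contours, spec.frame_interval, spec.seed), truth


@dataclass(frozen=True)
class SpeckleTexture:
    """Speckle/membrane rendering parameters for synthetic movies.

    density is speckles per um^2 of cell area; blob_sigma the Gaussian
    footprint of one speckle (um); membrane_weight the line mass of the
    bright boundary relative to one speckle.
    """

    density: float = 0.3
    blob_sigma: float = 0.4
    membrane_weight: float = 3.0
    interior_level: float = 0.1
    background_noise_sd: float = 0.0


def _splat_bilinear(img: np.ndarray, x_px: np.ndarray, y_px: np.ndarray,
                    mass: np.ndarray) -> None:
    """Deposit point masses on the pixel grid with bilinear weights, so
    sub-pixel positions (and hence sub-pixel motion) are preserved."""
    h, w = img.shape
    x0 = np.floor(x_px).astype(int)
    y0 = np.floor(y_px).astype(int)
    fx = x_px - x0
    fy = y_px - y0
    for dx, dy, wgt in ((0, 0, (1 - fx) * (1 - fy)), (1, 0, fx * (1 - fy)),
                        (0, 1, (1 - fx) * fy), (1, 1, fx * fy)):
        xs = x0 + dx
        ys = y0 + dy
        ok = (xs >= 0) & (xs < w) & (ys >= 0) & (ys < h)
        np.add.at(img, (ys[ok], xs[ok]), mass[ok] * wgt[ok])


def render_movie(
    contours: ContourSeries,
    pixel_size: float,
    texture: SpeckleTexture = SpeckleTexture(),
    seed: int = 0,
    margin_px: int = 12,
    shape: tuple[int, int] | None = None,
) -> TimeLapse:
    """Rasterize a contour series into a speckle time-lapse.

    Each frame shows a bright membrane ring on the contour plus an
    interior speckle texture advected by the radial deformation field:
    an interior material point at normalized radius rho (fraction of the
    local boundary radius) stays at that fraction, so its displacement
    tapers linearly from the boundary displacement to zero at the
    centroid. This is a rendering convention chosen to give PIV-visible
    interior motion, not a physical model of cytoplasmic flow.
    """
    if pixel_size <= 0:
        raise InvalidSpecError("pixel_size must be positive")
    if margin_px < 10:
        raise GeometryError("margin must be at least 10 px")
    rng = np.random.default_rng(seed)

    ref = contours.contours[0]
    centroid = ref.mean(axis=0)
    max_r = max(
        float(np.max(np.linalg.norm(c - centroid, axis=1))) for c in contours.contours
    )
    if shape is None:
        half = int(np.ceil(max_r / pixel_size)) + margin_px
        shape = (2 * half + 1, 2 * half + 1)
    h, w = shape
    center_px = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y)
    if max_r / pixel_size + margin_px > min(h, w) / 2.0 + 0.5:
        raise GeometryError("contour does not fit inside the frame with margin")

    # reference boundary radius as a function of angle, for speckle seeding
    def radius_of_angle(contour: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = contour - centroid
        ang = np.mod(np.arctan2(d[:, 1], d[:, 0]), 2 * np.pi)
        order = np.argsort(ang)
        return ang[order], np.linalg.norm(d, axis=1)[order]

    ang0, r0 = radius_of_angle(ref)
    area = np.pi * float(np.mean(r0)) ** 2
    n_speckles = max(30, int(round(texture.density * area)))
    phi = rng.uniform(0.0, 2 * np.pi, n_speckles)
    rho = np.sqrt(rng.uniform(0.0, 1.0, n_speckles)) * 0.97
    mass = rng.uniform(0.5, 1.5, n_speckles)

    blob_sigma_px = texture.blob_sigma / pixel_size
    frames = np.empty((contours.n_frames, h, w), dtype=np.float32)
    for i, contour in enumerate(contours.contours):
        ang, r = radius_of_angle(contour)
        r_at = interp_periodic(phi, ang, r, 2 * np.pi)
        px = centroid[0] + rho * r_at * np.cos(phi)
        py = centroid[1] + rho * r_at * np.sin(phi)
        img = np.zeros((h, w), dtype=np.float64)
        _splat_bilinear(img, px / pixel_size + center_px[0],
                        py / pixel_size + center_px[1], mass)
        # membrane: dense resampling of the contour, splat as line mass
        dense = resample_closed(contour, step=0.3 * pixel_size)
        _splat_bilinear(img, dense[:, 0] / pixel_size + center_px[0],
                        dense[:, 1] / pixel_size + center_px[1],
                        np.full(len(dense), texture.membrane_weight * 0.3))
        img = ndimage.gaussian_filter(img, blob_sigma_px)
        if texture.interior_level > 0:
            yy, xx = np.mgrid[0:h, 0:w]
            pos_ang = np.arctan2(
                (yy - center_px[1]) * pixel_size - centroid[1],
                (xx - center_px[0]) * pixel_size - centroid[0],
            )
            pos_r = np.hypot(
                (xx - center_px[0]) * pixel_size - centroid[0],
                (yy - center_px[1]) * pixel_size - centroid[1],
            )
            inside = pos_r <= interp_periodic(
                np.mod(pos_ang.ravel(), 2 * np.pi), ang, r, 2 * np.pi
            ).reshape(h, w)
            img[inside] += texture.interior_level
        if texture.background_noise_sd > 0:
            img += rng.normal(0.0, texture.background_noise_sd, (h, w))
        frames[i] = img.astype(np.float32)
    return TimeLapse(frames=frames, pixel_size=pixel_size,
                     frame_interval=contours.frame_interval)


def make_aspiration_series(
    true_tension: float,
    Rp: float,
    Rc: float,
    pressure_step: float = 10.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    extra_steps: int = 2,
) -> AspirationSeries:
    """Stepwise aspiration series consistent with a known surface tension.

    The tongue length grows linearly with applied pressure and reaches
    the pipette radius Rp exactly at the critical pressure
    P* = 2 gamma (1/Rp - 1/Rc) from the Young-Laplace relation; the
    pressure steps bracket P*. true_tension in pN/um, radii in um,
    pressures in Pa (1 Pa um = 1 pN/um).
    """
    if Rp >= Rc:
        raise GeometryError("pipette radius must be smaller than cell radius")
    if Rp <= 0 or true_tension <= 0 or pressure_step <= 0:
        raise InvalidSpecError("tension, radii and pressure_step must be positive")
    rng = np.random.default_rng(seed)
    p_crit = 2.0 * true_tension * (1.0 / Rp - 1.0 / Rc)
    n_steps = int(np.ceil(p_crit / pressure_step)) + extra_steps
    pressures = pressure_step * np.arange(1, n_steps + 1)
    lengths = Rp * pressures / p_crit
    if noise_sd > 0:
        lengths = np.maximum(lengths + rng.normal(0.0, noise_sd, n_steps), 0.0)
    return AspirationSeries(pressures=pressures, tongue_lengths=lengths,
                            Rp=Rp, Rc=Rc)


def make_cortex_image(
    fwhm: float,
    pixel_size: float,
    ring_radius: float,
    peak_intensity: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    background: float = 10.0,
    margin_um: float = 3.0,
) -> tuple[np.ndarray, float]:
    """Synthetic super-resolution image of a cortical ring.

    The radial cross-section of the ring is Gaussian with
    sigma = fwhm / (2 sqrt(2 ln 2)) on a constant background. fwhm and
    pixel_size in nm, ring_radius in um. Returns (image, true fwhm).
    """
    if fwhm < 3 * pixel_size:
        raise ResolutionError(
            f"fwhm {fwhm} nm is not resolvable at {pixel_size} nm/px"
        )
    if ring_radius <= 0:
        raise InvalidSpecError("ring_radius must be positive")
    rng = np.random.default_rng(seed)
    pixel_um = pixel_size / 1000.0
    sigma_um = fwhm / _FWHM_PER_SIGMA / 1000.0
    half_px = int(np.ceil((ring_radius + margin_um) / pixel_um))
    n = 2 * half_px + 1
    axis = (np.arange(n) - half_px) * pixel_um
    dist = np.hypot(axis[:, None], axis[None, :])
    img = background + peak_intensity * np.exp(
        -0.5 * ((dist - ring_radius) / sigma_um) ** 2
    )
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, img.shape)
    return img.astype(np.float64), float(fwhm)


def make_labeled_ratios(
    n_pos: int,
    n_neg: int,
    pos_mean: float,
    neg_mean: float,
    sd: float,
    seed: int = 0,
) -> LabeledRatios:
    """Labeled peak/mean spectral ratios from two Gaussians truncated at 0,
    emulating visually classified oscillating (+) / non-oscillating (-)
    recordings used to calibrate the detection threshold."""
    if n_pos < 1 or n_neg < 1:
        raise InvalidSpecError("need at least one sample per class")
    if sd < 0:
        raise InvalidSpecError("sd must be non-negative")
    rng = np.random.default_rng(seed)

    def draw(n: int, mean: float) -> np.ndarray:
        if sd == 0:
            return np.full(n, mean)
        a = (0.0 - mean) / sd
        return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd,
                                   size=n, random_state=rng)

    ratios = np.concatenate([draw(n_pos, pos_mean), draw(n_neg, neg_mean)])
    labels = np.concatenate([np.ones(n_pos, bool), np.zeros(n_neg, bool)])
    return LabeledRatios(ratios=ratios, labels=labels)
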