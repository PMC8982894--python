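"""Fourier-spectrum oscillation detection on PIV velocity traces.

A recording is called oscillating when the power-spectrum peak within
the 50-200 s period band is at least 1.777 times the spectrum mean (the
"background"). The 1.777 cutoff is the published calibration of this
peak/mean statistic against visual classification of embryo recordings
(ROC-optimal, AUC 0.97 on that data set); `calibrate_threshold`
re-derives such a cutoff from any labeled ratio set.

Power convention: for a mean-removed trace of length N sampled every dt,
power[k] = |X_k|^2 / N at frequencies k/(N dt), k = 1..N//2, so that the
two-sided power sums to N times the trace variance (Parseval).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BandError, InvalidSpecError

DEFAULT_BAND = (50.0, 200.0)  # seconds
DEFAULT_THRESHOLD = 1.777  # peak/mean ratio
_REL_TOL = 1e-9


@dataclass
class PowerSpectrum:
    frequencies: np.ndarray  # Hz, positive, DC excluded, ascending
    power: np.ndarray  # a.u., >= 0
    n_samples: int
    frame_interval: float
    degenerate: bool = False  # constant input trace


@dataclass
class OscillationCall:
    oscillating: bool
    period: float  # s; nan when not oscillating for a degenerate reason
    peak_power: float
    background: float
    peak_to_mean: float
    band: tuple[float, float] = DEFAULT_BAND
    threshold: float = DEFAULT_THRESHOLD
    reason: str = ""  # "degenerate" when the spectrum carried no signal
    stage: str | None = None  # bookkeeping tag, e.g. "4-cell/early"


@dataclass
class LabeledRatios:
    """Peak/mean ratios with visual oscillating (True) / not (False) labels."""

    ratios: np.ndarray
    labels: np.ndarray


@dataclass
class RocResult:
    auc: float
    threshold: float
    sensitivity: float
    specificity: float
    thresholds: np.ndarray = field(repr=False, default=None)
    tpr: np.ndarray = field(repr=False, default=None)
    fpr: np.ndarray = field(repr=False, default=None)


def power_spectrum(trace: np.ndarray, frame_interval: float) -> PowerSpectrum:
    """One-sided power spectrum of a velocity trace.

    The trace mean is subtracted; no taper, zero-padding or detrending
    beyond that. A constant trace yields an all-zero spectrum with the
    degenerate flag set rather than an error.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.ndim != 1 or len(trace) < 8:
        raise InvalidSpecError("trace must be 1D with at least 8 samples")
    if not np.all(np.isfinite(trace)):
        raise InvalidSpecError("trace contains non-finite values")
    if frame_interval <= 0:
        raise InvalidSpecError("frame_interval must be positive")
    n = len(trace)
    x = trace - trace.mean()
    spec = np.fft.rfft(x)
    k = np.arange(1, n // 2 + 1)
    freqs = k / (n * frame_interval)
    power = np.abs(spec[1:n // 2 + 1]) ** 2 / n
    # constant up to float noise counts as constant
    scale = max(float(np.max(np.abs(trace))), 1e-300)
    degenerate = bool(np.max(np.abs(x)) <= 1e-12 * scale or power.max() == 0.0)
    if degenerate:
        power = np.zeros_like(power)
    return PowerSpectrum(frequencies=freqs, power=power, n_samples=n,
                         frame_interval=frame_interval, degenerate=degenerate)


def mean_power_spectrum(traces) -> PowerSpectrum:
    """Bin-wise mean of the power spectra of all vectors, x and y
    components together — the per-embryo spectrum of the detection test.

    Accepts a VelocityTraces object (uses u and v) or a plain sequence
    of equal-length 1D traces.
    """
    if hasattr(traces, "u"):
        arrays = [np.asarray(row) for row in traces.u] + \
                 [np.asarray(row) for row in traces.v]
        frame_interval = traces.frame_interval
    else:
        arrays = [np.asarray(t, dtype=np.float64) for t in traces[0]] \
            if isinstance(traces, tuple) else [np.asarray(t) for t in traces]
        frame_interval = traces[1] if isinstance(traces, tuple) else None
    if frame_interval is None or not np.isfinite(frame_interval):
        raise InvalidSpecError("traces must carry a frame interval; pass a "
                               "VelocityTraces or (list_of_traces, dt) tuple")
    if not arrays:
        raise InvalidSpecError("need at least one trace")
    n = len(arrays[0])
    if any(len(a) != n for a in arrays):
        raise InvalidSpecError("traces have mixed lengths")
    spectra = [power_spectrum(a, frame_interval) for a in arrays]
    power = np.mean([s.power for s in spectra], axis=0)
    return PowerSpectrum(
        frequencies=spectra[0].frequencies,
        power=power,
        n_samples=n,
        frame_interval=frame_interval,
        degenerate=all(s.degenerate for s in spectra),
    )


def detect_oscillation(
    spectrum: PowerSpectrum,
    band: tuple[float, float] = DEFAULT_BAND,
    threshold: float = DEFAULT_THRESHOLD,
    background_band_only: bool = False,
    background_exclude_peak: bool = False,
) -> OscillationCall:
    """Band-limited peak/mean oscillation call on a power spectrum.

    peak_power is the maximum power among bins whose period lies in
    `band` (inclusive); background is by default the mean power over all
    positive-frequency bins, peak included — the literal reading of
    "mean value of the power spectrum"; the two flags restrict the mean
    to the band and/or exclude the peak bin. Ties in the peak go to the
    lower frequency (longer period).
    """
    lo, hi = band
    if lo >= hi or lo <= 0:
        raise BandError("band must satisfy 0 < min < max")
    if lo < 2 * spectrum.frame_interval - _REL_TOL * lo:
        raise BandError(f"band minimum {lo} s below Nyquist period "
                        f"{2 * spectrum.frame_interval} s")
    record = spectrum.n_samples * spectrum.frame_interval
    if hi > record * (1 + _REL_TOL):
        raise BandError(f"band maximum {hi} s exceeds record length {record} s")
    if spectrum.degenerate:
        return OscillationCall(False, float("nan"), 0.0, 0.0, 0.0,
                               band=band, threshold=threshold,
                               reason="degenerate")
    periods = 1.0 / spectrum.frequencies
    in_band = (periods >= lo * (1 - _REL_TOL)) & (periods <= hi * (1 + _REL_TOL))
    if np.any(in_band):
        band_power = np.where(in_band, spectrum.power, -np.inf)
        # frequencies ascend, so the first argmax is the longest period
        peak_idx = int(np.argmax(band_power))
        peak_power = float(spectrum.power[peak_idx])
        period = float(periods[peak_idx])
    else:
        peak_idx = -1
        peak_power = 0.0
        period = float("nan")
    bg_mask = in_band if background_band_only else np.ones_like(in_band)
    if background_exclude_peak and peak_idx >= 0:
        bg_mask = bg_mask.copy()
        bg_mask[peak_idx] = False
    background = float(spectrum.power[bg_mask].mean()) if np.any(bg_mask) else 0.0
    ratio = peak_power / background if background > 0 else 0.0
    oscillating = ratio >= threshold
    return OscillationCall(
        oscillating=oscillating,
        period=period,
        peak_power=peak_power,
        background=background,
        peak_to_mean=ratio,
        band=band,
        threshold=threshold,
    )


def calibrate_threshold(data: LabeledRatios) -> RocResult:
    """ROC calibration of the peak/mean cutoff from labeled ratios.

    Candidate thresholds are the midpoints of consecutive sorted unique
    ratio values plus open boundaries; AUC is the trapezoid area under
    the (FPR, TPR) curve; the selected threshold maximizes Youden's
    J = sensitivity + specificity - 1, ties going to the lower threshold.
    """
    ratios = np.asarray(data.ratios, dtype=np.float64)
    labels = np.asarray(data.labels, dtype=bool)
    if ratios.shape != labels.shape:
        raise InvalidSpecError("ratios and labels must align")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise InvalidSpecError("both labels must be present")
    uniq = np.unique(ratios)
    mids = (uniq[:-1] + uniq[1:]) / 2.0
    thresholds = np.concatenate(([uniq[0] - 1.0], mids, [uniq[-1] + 1.0]))
    # classify positive when ratio >= threshold
    tpr = np.array([(ratios[labels] >= t).mean() for t in thresholds])
    fpr = np.array([(ratios[~labels] >= t).mean() for t in thresholds])
    order = np.lexsort((tpr, fpr))  # staircase: ties in FPR by ascending TPR
    auc = float(np.trapezoid(tpr[order], fpr[order]))
    youden = tpr + (1.0 - fpr) - 1.0
    # interior candidates only; ties -> lower threshold
    interior = slice(1, len(thresholds) - 1)
    j_int = youden[interior]
    if len(j_int):
        # thresholds ascend, so the first argmax is the lowest threshold
        best = 1 + int(np.argmax(j_int))
    else:  # single unique value: fall back to a boundary
        best = int(np.argmax(youden))
    return RocResult(
        auc=auc,
        threshold=float(thresholds[best]),
        sensitivity=float(tpr[best]),
        specificity=float(1.0 - fpr[best]),
        thresholds=thresholds,
        tpr=tpr,
        fpr=fpr,
    )
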