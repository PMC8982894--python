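"""Pipeline orchestration, group statistics and report emission.

`run_pipeline` chains the stages (movie -> PIV -> spectral call;
masks/contours -> kymograph -> wave; aspiration -> tension) over a set
of input files and collects one JSON-serializable report with full
provenance (config hash, seeds, package version). `compare_groups`
applies the routine statistics used for stage comparisons: chi-squared
on detection proportions and a one-tailed two-sample t test on periods
or tensions, flagged significant at p < 0.01.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import stats

from . import io as pio
from .curvature import build_kymograph, kymograph_period, wave_velocity
from .errors import InvalidSpecError, StandingWaveError
from .micromechanics import aggregate_embryo_tension, fit_tension
from .piv import movie_velocity_traces
from .spectral import (DEFAULT_BAND, DEFAULT_THRESHOLD, detect_oscillation,
                       mean_power_spectrum)

logger = logging.getLogger("pecowaco")

SIGNIFICANCE_LEVEL = 0.01


@dataclass
class AnalysisConfig:
    """All tunable parameters of one analysis run.

    Defaults are the published acquisition and analysis constants:
    20/10 um PIV windows, 50-200 s period band, 1.777 peak/mean cutoff,
    10 um curvature strip, 5 s frame interval.
    """

    piv_window_coarse: float = 20.0  # um
    piv_window_fine: float = 10.0  # um
    piv_overlap: float = 0.5
    band: tuple[float, float] = DEFAULT_BAND  # s
    threshold: float = DEFAULT_THRESHOLD
    strip_length: float = 10.0  # um
    n_bins: int = 360
    frame_interval: float = 5.0  # s
    seed: int = 0
    stages: dict = field(default_factory=dict)  # sample id -> "stage/half"

    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["band"] = list(data["band"])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        data["band"] = tuple(data["band"])
        return cls(**data)

    def content_hash(self) -> str:
        data = dataclasses.asdict(self)
        data["band"] = list(data["band"])
        blob = json.dumps(data, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    kind: str  # "proportions" | "means"
    statistic: float
    p_value: float
    significant: bool
    alternative: str = ""


def compare_groups(a, b, kind: str, labels: tuple[str, str] = ("a", "b"),
                   alternative: str = "two-sided") -> GroupComparison:
    """Routine two-group comparison.

    kind "proportions": a and b are (n_detected, n_total) pairs; plain
    chi-squared on the 2x2 detection table (no continuity correction).
    kind "means": a and b are value arrays; two-sample Student t with an
    explicitly declared tail ("less", "greater", or "two-sided" — the
    direction must be chosen per comparison, it is not inferred).
    """
    if kind == "proportions":
        (det_a, n_a), (det_b, n_b) = a, b
        if n_a == 0 or n_b == 0:
            raise InvalidSpecError("empty group")
        table = np.array([[det_a, n_a - det_a], [det_b, n_b - det_b]])
        if table.sum(axis=0).min() == 0:
            stat, p = 0.0, 1.0  # identical margins, nothing to test
        else:
            stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    elif kind == "means":
        a = np.asarray(a, dtype=np.float64)
        b = np.asarray(b, dtype=np.float64)
        if len(a) == 0 or len(b) == 0:
            raise InvalidSpecError("empty group")
        res = stats.ttest_ind(a, b, alternative=alternative)
        stat, p = float(res.statistic), float(res.pvalue)
    else:
        raise InvalidSpecError(f"unknown comparison kind {kind!r}")
    return GroupComparison(group_a=labels[0], group_b=labels[1], kind=kind,
                           statistic=float(stat), p_value=float(p),
                           significant=p < SIGNIFICANCE_LEVEL,
                           alternative=alternative if kind == "means" else "")


def _call_to_dict(call) -> dict:
    d = dataclasses.asdict(call)
    d["band"] = list(d["band"])
    return d


def run_pipeline(config: AnalysisConfig,
                 movies: dict[str, str | Path] | None = None,
                 contour_files: dict[str, str | Path] | None = None,
                 aspiration_files: dict[str, str | Path] | None = None) -> dict:
    """Run every applicable stage over the given inputs.

    Returns a JSON-serializable report: per-sample oscillation calls
    (PIV route), wave estimates (curvature route), tension measurements,
    and a provenance block. Deterministic for fixed config and inputs.
    """
    from . import __version__

    report: dict = {
        "provenance": {
            "config_hash": config.content_hash(),
            "config": json.loads(json.dumps(
                dataclasses.asdict(config), default=list)),
            "seed": config.seed,
            "package_version": __version__,
        },
        "samples": {},
    }

    for sample, path in sorted((movies or {}).items()):
        logger.info("stage=piv sample=%s input=%s", sample, path)
        movie = pio.read_movie(path)
        traces = movie_velocity_traces(
            movie, window_coarse=config.piv_window_coarse,
            window_fine=config.piv_window_fine,
            overlap_fraction=config.piv_overlap)
        call = detect_oscillation(mean_power_spectrum(traces),
                                  band=config.band,
                                  threshold=config.threshold)
        call.stage = config.stages.get(sample)
        report["samples"].setdefault(sample, {})["oscillation_call"] = \
            _call_to_dict(call)

    for sample, path in sorted((contour_files or {}).items()):
        logger.info("stage=curvature sample=%s input=%s", sample, path)
        contours = pio.read_contours(path)
        kymo = build_kymograph(contours, strip_length=config.strip_length,
                               n_bins=config.n_bins)
        call = kymograph_period(kymo, band=config.band,
                                threshold=config.threshold)
        entry = report["samples"].setdefault(sample, {})
        entry["kymograph_call"] = _call_to_dict(call)
        if call.oscillating:
            try:
                wave = wave_velocity(kymo, band=config.band,
                                     threshold=config.threshold)
                entry["wave"] = dataclasses.asdict(wave)
            except StandingWaveError:
                entry["wave"] = {"error": "standing-wave"}

    tensions = []
    for sample, path in sorted((aspiration_files or {}).items()):
        logger.info("stage=tension sample=%s input=%s", sample, path)
        series, meta = pio.read_aspiration(path)
        m = fit_tension(series, embryo_id=meta.get("embryo_id", sample),
                        blastomere_id=meta.get("blastomere_id", ""))
        tensions.append(m)
        report["samples"].setdefault(sample, {})["tension"] = \
            dataclasses.asdict(m)
    if tensions:
        report["per_embryo_tension"] = \
            aggregate_embryo_tension(tensions).to_dict()
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True, default=float)


def report_to_rows(report: dict) -> list[dict]:
    """Flatten a report into tidy rows (one per sample per metric)."""
    rows = []
    for sample, entry in sorted(report.get("samples", {}).items()):
        for metric, payload in sorted(entry.items()):
            if not isinstance(payload, dict):
                continue
            for key, value in sorted(payload.items()):
                if isinstance(value, (int, float, bool, str)) or value is None:
                    rows.append({"sample": sample, "metric": metric,
                                 "key": key, "value": value})
    return rows
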