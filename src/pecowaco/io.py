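"""File formats: multi-page TIFF movies with JSON sidecars, CSV tables
for contours, traces, spectra, kymographs and aspiration series."""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import InvalidSpecError
from .micromechanics import AspirationSeries
from .piv import TimeLapse, VectorField, VelocityTraces
from .spectral import OscillationCall, PowerSpectrum


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: TimeLapse, path: str | Path) -> None:
    """Multi-page TIFF plus a JSON sidecar with calibration metadata."""
    path = Path(path)
    tifffile.imwrite(path, np.asarray(movie.frames, dtype=np.float32),
                     photometric="minisblack")
    meta = {"pixel_size_um": movie.pixel_size,
            "frame_interval_s": movie.frame_interval}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_movie(path: str | Path) -> TimeLapse:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InvalidSpecError(f"missing sidecar metadata file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    frames = tifffile.imread(path)
    return TimeLapse(frames=frames, pixel_size=meta["pixel_size_um"],
                     frame_interval=meta["frame_interval_s"])


def write_contours(contours, path: str | Path) -> None:
    """Contour series as tidy CSV (frame, point, x_um, y_um) + sidecar."""
    path = Path(path)
    rows = []
    for t, pts in enumerate(contours.contours):
        for i, (x, y) in enumerate(pts):
            rows.append((t, i, x, y))
    pd.DataFrame(rows, columns=["frame", "point", "x_um", "y_um"]).to_csv(
        path, index=False)
    meta = {"frame_interval_s": contours.frame_interval,
            "seed": contours.seed}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_contours(path: str | Path):
    from .synthetic import ContourSeries  # local import: avoids a cycle

    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InvalidSpecError(f"missing sidecar metadata file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    frames = [grp.sort_values("point")[["x_um", "y_um"]].to_numpy()
              for _, grp in df.groupby("frame", sort=True)]
    return ContourSeries(frames, meta["frame_interval_s"], meta.get("seed"))


def write_vector_field(field: VectorField, path: str | Path) -> None:
    yy, xx = np.meshgrid(field.y, field.x, indexing="ij")
    pd.DataFrame({
        "x_um": xx.ravel(), "y_um": yy.ravel(),
        "u_um_s": field.u.ravel(), "v_um_s": field.v.ravel(),
        "valid": field.valid.ravel().astype(int),
    }).to_csv(path, index=False)


def write_traces(traces: VelocityTraces, path: str | Path) -> None:
    """One column per grid point per component (u_<i>, v_<i>)."""
    cols = {}
    for i in range(traces.n_points):
        cols[f"u_{i}"] = traces.u[i]
        cols[f"v_{i}"] = traces.v[i]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"frame_interval_s": traces.frame_interval,
            "positions_um": traces.positions.tolist()}
    _sidecar_path(Path(path)).write_text(json.dumps(meta, indent=2))


def read_traces(path: str | Path) -> VelocityTraces:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InvalidSpecError(f"missing sidecar metadata file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    n = len([c for c in df.columns if c.startswith("u_")])
    u = np.stack([df[f"u_{i}"].to_numpy() for i in range(n)])
    v = np.stack([df[f"v_{i}"].to_numpy() for i in range(n)])
    return VelocityTraces(u=u, v=v,
                          positions=np.asarray(meta["positions_um"]),
                          frame_interval=meta["frame_interval_s"])


def write_spectrum(spectrum: PowerSpectrum, path: str | Path) -> None:
    pd.DataFrame({"freq_hz": spectrum.frequencies,
                  "power": spectrum.power}).to_csv(path, index=False)


def write_call(call: OscillationCall, path: str | Path) -> None:
    payload = dataclasses.asdict(call)
    payload["band"] = list(payload["band"])
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def write_kymograph(kymo, path: str | Path) -> None:
    """Kymograph as CSV (bins x frames) + sidecar with calibration."""
    path = Path(path)
    pd.DataFrame(kymo.values).to_csv(path, index=False, header=False)
    meta = {"frame_interval_s": kymo.frame_interval,
            "perimeters_um": kymo.perimeters.tolist()}
    _sidecar_path(path).write_text(json.dumps(meta, indent=2))


def read_kymograph(path: str | Path):
    from .curvature import CurvatureKymograph

    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InvalidSpecError(f"missing sidecar metadata file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    values = pd.read_csv(path, header=None).to_numpy()
    return CurvatureKymograph(values=values,
                              frame_interval=meta["frame_interval_s"],
                              perimeters=np.asarray(meta["perimeters_um"]))


def write_aspiration(series: AspirationSeries, path: str | Path,
                     embryo_id: str = "", blastomere_id: str = "") -> None:
    pd.DataFrame({"pressure_pa": series.pressures,
                  "tongue_length_um": series.tongue_lengths}).to_csv(
        path, index=False)
    meta = {"Rp_um": series.Rp, "Rc_um": series.Rc,
            "embryo_id": embryo_id, "blastomere_id": blastomere_id}
    _sidecar_path(Path(path)).write_text(json.dumps(meta, indent=2))


def read_aspiration(path: str | Path) -> tuple[AspirationSeries, dict]:
    path = Path(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise InvalidSpecError(f"missing sidecar metadata file: {sidecar}")
    meta = json.loads(sidecar.read_text())
    df = pd.read_csv(path)
    series = AspirationSeries(pressures=df["pressure_pa"].to_numpy(),
                              tongue_lengths=df["tongue_length_um"].to_numpy(),
                              Rp=meta["Rp_um"], Rc=meta["Rc_um"])
    return series, meta
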