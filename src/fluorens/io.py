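"""Plain-text readers and writers for spectra, series, and peak tables.

The canonical interchange format is two-column CSV (ppm, intensity) with a
JSON sidecar (``<name>.meta.json``) holding acquisition metadata. A
read-only JCAMP-DX reader (AFFN ``XYDATA`` blocks) is provided for
interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import (
    DEFAULT_SPECTROMETER_FREQ_MHZ,
    DoseResponseCurve,
    FrequencyAxis,
    SaturationSeries,
    Spectrum,
)


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as CSV (ppm, intensity) plus a JSON metadata sidecar."""
    path = Path(path)
    df = pd.DataFrame({"ppm": spectrum.ppm, "intensity": spectrum.intensity})
    df.to_csv(path, index=False, float_format="%.9f")
    meta = dict(spectrum.metadata)
    meta["spectrometer_freq_MHz"] = spectrum.axis.spectrometer_freq
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_spectrum(path: str | Path, dialect: str = "csv") -> Spectrum:
    """Read a spectrum from CSV or JCAMP-DX.

    The ppm axis is normalized to monotone decreasing (flagging the
    reversal in metadata); malformed numeric rows are rejected with their
    line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        ppm, intensity, meta = _read_csv_spectrum(path)
    elif dialect in ("jcamp", "jcamp-dx", "jdx"):
        ppm, intensity, meta = _read_jcamp_spectrum(path)
    else:
        raise ValueError("dialect must be 'csv' or 'jcamp-dx'")

    freq = float(meta.get("spectrometer_freq_MHz", DEFAULT_SPECTROMETER_FREQ_MHZ))
    if ppm[0] < ppm[-1]:  # ascending file: reverse both
        ppm = ppm[::-1].copy()
        intensity = intensity[::-1].copy()
        meta["axis_reversed_on_read"] = True
    return Spectrum(FrequencyAxis(ppm, freq), intensity, meta)


def _read_csv_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    ppm, intensity = [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = [p.strip() for p in line.replace("\t", ",").split(",")]
            if lineno == 1 and any(not _is_number(p) for p in parts[:2]):
                continue  # header row
            if len(parts) < 2 or not (_is_number(parts[0]) and _is_number(parts[1])):
                raise ValueError(f"{path}: malformed numeric data at line {lineno}: {line!r}")
            ppm.append(float(parts[0]))
            intensity.append(float(parts[1]))
    if len(ppm) < 2:
        raise ValueError(f"{path}: fewer than 2 data rows")
    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return np.array(ppm), np.array(intensity), meta


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_jcamp_spectrum(path: Path) -> tuple[np.ndarray, np.ndarray, dict]:
    """Minimal JCAMP-DX reader: AFFN ``##XYDATA=(X++(Y..Y))`` blocks only."""
    header: dict[str, str] = {}
    ys: list[float] = []
    in_data = False
    firstx = lastx = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, val = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                val = val.strip()
                if key == "XYDATA":
                    in_data = True
                    continue
                if key == "END":
                    in_data = False
                    continue
                header[key] = val
                continue
            if in_data:
                toks = line.replace(",", " ").split()
                if not all(_is_number(t) for t in toks):
                    raise ValueError(f"{path}: malformed XYDATA at line {lineno}: {line!r}")
                ys.extend(float(t) for t in toks[1:])  # first token is the X of the row
    for key in ("FIRSTX", "LASTX", "NPOINTS"):
        if key not in header:
            raise ValueError(f"{path}: missing ##{key}= in JCAMP-DX header")
    firstx, lastx = float(header["FIRSTX"]), float(header["LASTX"])
    npoints = int(float(header["NPOINTS"]))
    if len(ys) != npoints:
        raise ValueError(f"{path}: NPOINTS={npoints} but {len(ys)} Y values read")
    xfac = float(header.get("XFACTOR", 1.0))
    yfac = float(header.get("YFACTOR", 1.0))
    ppm = np.linspace(firstx, lastx, npoints) * xfac
    intensity = np.array(ys) * yfac
    meta = {"jcamp_title": header.get("TITLE", ""), "format": "jcamp-dx"}
    if ".OBSERVEFREQUENCY" in header:
        meta["spectrometer_freq_MHz"] = float(header[".OBSERVEFREQUENCY"])
    return ppm, intensity, meta


def write_saturation_series(series: SaturationSeries, path: str | Path) -> Path:
    """Tidy CSV: time_s, intensity, channel in {on, off}."""
    path = Path(path)
    frames = [pd.DataFrame({"time_s": series.times, "intensity": series.on_intensity,
                            "channel": "on"})]
    if series.off_intensity is not None:
        frames.append(pd.DataFrame({"time_s": series.times,
                                    "intensity": series.off_intensity, "channel": "off"}))
    pd.concat(frames).to_csv(path, index=False)
    meta = {"r1": series.r1, "i0": series.i0, **series.metadata}
    _sidecar(path).write_text(json.dumps(meta, indent=1, default=str))
    return path


def read_saturation_series(path: str | Path, r1: float | None = None) -> SaturationSeries:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("time_s", "intensity", "channel"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    on = df[df["channel"] == "on"].sort_values("time_s")
    off = df[df["channel"] == "off"].sort_values("time_s")
    r1_val = r1 if r1 is not None else meta.get("r1")
    if r1_val is None:
        raise ValueError(f"{path}: R1 not given and absent from sidecar metadata")
    return SaturationSeries(
        times=on["time_s"].to_numpy(),
        on_intensity=on["intensity"].to_numpy(),
        off_intensity=off["intensity"].to_numpy() if len(off) else None,
        r1=float(r1_val),
        i0=meta.get("i0"),
        metadata=meta,
    )


def write_dose_response(curve: DoseResponseCurve, path: str | Path) -> Path:
    path = Path(path)
    curve.to_frame().to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(curve.metadata, indent=1, default=str))
    return path


def read_dose_response(path: str | Path) -> DoseResponseCurve:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("conc_M", "response"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    meta: dict = {}
    side = _sidecar(path)
    if side.exists():
        meta = json.loads(side.read_text())
    return DoseResponseCurve(
        df["conc_M"].to_numpy(), df["response"].to_numpy(),
        replicate=df["replicate"].to_numpy() if "replicate" in df.columns else None,
        outlier_truth=df["injected_outlier"].to_numpy()
        if "injected_outlier" in df.columns else None,
        metadata=meta,
    )
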