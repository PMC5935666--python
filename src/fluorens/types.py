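"""Core domain containers shared across the analysis stages.

Conventions
-----------
* Chemical shift axes are stored in ppm, strictly monotone **decreasing**
  (downfield on the left, upfield on the right, as spectra are plotted).
* Hz per ppm equals the spectrometer ¹⁹F frequency in MHz.
* "Upfield" means toward more negative ppm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

#: ¹⁹F basic transmitter frequency (MHz) of the instrument the defaults emulate.
DEFAULT_SPECTROMETER_FREQ_MHZ = 658.8462650

#: Defined chemical shift (ppm) of the internal coaxial KF reference signal.
KF_REFERENCE_SHIFT_PPM = -119.522


@dataclass(frozen=True)
class FrequencyAxis:
    """A calibrated chemical-shift grid.

    Parameters
    ----------
    ppm : ndarray
        Strictly monotone-decreasing chemical-shift values (ppm).
    spectrometer_freq : float
        ¹⁹F transmitter frequency in MHz; also the Hz-per-ppm conversion
        factor.
    """

    ppm: np.ndarray
    spectrometer_freq: float = DEFAULT_SPECTROMETER_FREQ_MHZ

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        object.__setattr__(self, "ppm", ppm)
        if ppm.ndim != 1 or ppm.size < 2:
            raise ValueError("axis needs at least 2 ppm values")
        if not np.all(np.diff(ppm) < 0):
            raise ValueError("ppm axis must be strictly monotone decreasing")
        if not self.spectrometer_freq > 0:
            raise ValueError("spectrometer_freq must be positive (MHz)")

    @classmethod
    def from_window(
        cls,
        downfield: float,
        upfield: float,
        n_points: int = 16384,
        spectrometer_freq: float = DEFAULT_SPECTROMETER_FREQ_MHZ,
    ) -> "FrequencyAxis":
        """Evenly spaced axis from `downfield` (max ppm) to `upfield` (min ppm)."""
        lo, hi = sorted((downfield, upfield))
        return cls(np.linspace(hi, lo, n_points), spectrometer_freq)

    @property
    def hz_per_ppm(self) -> float:
        return self.spectrometer_freq

    @property
    def step(self) -> float:
        """Median absolute grid step (ppm)."""
        return float(np.median(np.abs(np.diff(self.ppm))))

    @property
    def span(self) -> tuple[float, float]:
        """(min ppm, max ppm) covered by the grid."""
        return float(self.ppm.min()), float(self.ppm.max())

    def covers(self, center: float, margin: float = 0.0) -> bool:
        lo, hi = self.span
        return lo + margin <= center <= hi - margin

    def shifted(self, offset_ppm: float) -> "FrequencyAxis":
        return FrequencyAxis(self.ppm + offset_ppm, self.spectrometer_freq)

    def __len__(self) -> int:
        return int(self.ppm.size)


@dataclass
class LorentzianPeak:
    """A single fitted or simulated Lorentzian component.

    ``area`` is the integral of the absorptive component over ppm
    (intensity·ppm); ``phase`` in radians mixes absorptive and dispersive
    lineshapes.
    """

    center: float
    fwhm: float
    area: float
    phase: float = 0.0
    is_contaminant: bool = False
    label: str | None = None

    def __post_init__(self) -> None:
        if not self.fwhm > 0:
            raise ValueError("fwhm must be positive")
        if self.area < 0:
            raise ValueError("area must be non-negative")

    @property
    def height(self) -> float:
        """Peak height of the pure absorptive component: 2A/(πw)."""
        return 2.0 * self.area / (np.pi * self.fwhm)

    def fwhm_hz(self, spectrometer_freq: float) -> float:
        return self.fwhm * spectrometer_freq


class PeakSet:
    """An ordered collection of Lorentzian peaks with area bookkeeping."""

    def __init__(self, peaks: Sequence[LorentzianPeak] = ()):
        self.peaks: list[LorentzianPeak] = list(peaks)

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self) -> Iterator[LorentzianPeak]:
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def append(self, peak: LorentzianPeak) -> None:
        self.peaks.append(peak)

    def without_contaminants(self) -> "PeakSet":
        return PeakSet([p for p in self.peaks if not p.is_contaminant])

    def total_area(self, exclude_contaminant: bool = True) -> float:
        ps = self.without_contaminants() if exclude_contaminant else self
        return float(sum(p.area for p in ps))

    def area_fractions(self, exclude_contaminant: bool = True) -> np.ndarray:
        """Area fraction of each *included* peak, normalized over included peaks."""
        ps = self.without_contaminants() if exclude_contaminant else self
        areas = np.array([p.area for p in ps], dtype=float)
        total = areas.sum()
        if total <= 0:
            raise ValueError("total peak area is zero")
        return areas / total

    def sorted_by_center(self, descending: bool = True) -> "PeakSet":
        return PeakSet(sorted(self.peaks, key=lambda p: -p.center if descending else p.center))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        noncontam = self.total_area(exclude_contaminant=True)
        for p in self.peaks:
            rows.append(
                {
                    "center_ppm": p.center,
                    "fwhm_ppm": p.fwhm,
                    "area": p.area,
                    "area_fraction": (p.area / noncontam) if (noncontam > 0 and not p.is_contaminant) else np.nan,
                    "phase_rad": p.phase,
                    "is_contaminant": p.is_contaminant,
                    "label": p.label,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PeakSet":
        peaks = [
            LorentzianPeak(
                center=float(r["center_ppm"]),
                fwhm=float(r["fwhm_ppm"]),
                area=float(r["area"]),
                phase=float(r.get("phase_rad", 0.0)),
                is_contaminant=bool(r.get("is_contaminant", False)),
                label=None if pd.isna(r.get("label", None)) else str(r.get("label")),
            )
            for _, r in df.iterrows()
        ]
        return cls(peaks)


@dataclass
class Spectrum:
    """A 1D frequency-domain spectrum on a calibrated ppm axis."""

    axis: FrequencyAxis
    intensity: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.intensity.shape != self.axis.ppm.shape:
            raise ValueError("intensity and axis must have equal length")
        if not np.all(np.isfinite(self.intensity)):
            raise ValueError("intensity must be finite")

    @property
    def ppm(self) -> np.ndarray:
        return self.axis.ppm

    def integral(self) -> float:
        """Trapezoidal integral over ppm (positive for absorptive signal)."""
        # axis is decreasing, so negate to get a positive area
        return float(-np.trapezoid(self.intensity, self.axis.ppm))

    def slice(self, lo_ppm: float, hi_ppm: float) -> "Spectrum":
        lo, hi = sorted((lo_ppm, hi_ppm))
        mask = (self.ppm >= lo) & (self.ppm <= hi)
        if mask.sum() < 2:
            raise ValueError("requested ppm window contains fewer than 2 points")
        return Spectrum(
            FrequencyAxis(self.ppm[mask], self.axis.spectrometer_freq),
            self.intensity[mask],
            dict(self.metadata),
        )


@dataclass
class ExchangeModel:
    """An N-site chemical-exchange model.

    ``rate_matrix`` K holds first-order rates with K[i, j] = k(j→i) for
    i ≠ j and columns summing to zero, so dM/dt = K·M and K·p = 0 at
    stationarity.
    """

    site_shifts: np.ndarray
    site_r2: np.ndarray
    populations: np.ndarray
    rate_matrix: np.ndarray
    r1: float = 2.7

    def __post_init__(self) -> None:
        self.site_shifts = np.asarray(self.site_shifts, dtype=float)
        self.site_r2 = np.asarray(self.site_r2, dtype=float)
        self.populations = np.asarray(self.populations, dtype=float)
        self.rate_matrix = np.asarray(self.rate_matrix, dtype=float)
        n = self.site_shifts.size
        if self.site_r2.shape != (n,) or self.populations.shape != (n,):
            raise ValueError("site arrays must share a common length")
        if self.rate_matrix.shape != (n, n):
            raise ValueError("rate_matrix must be N x N")
        if np.any(self.site_r2 <= 0):
            raise ValueError("site R2 rates must be positive")
        if not self.r1 > 0:
            raise ValueError("R1 must be positive")
        if np.any(self.populations < 0) or not np.isclose(self.populations.sum(), 1.0):
            raise ValueError("populations must be non-negative and sum to 1")
        off = self.rate_matrix.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal exchange rates must be non-negative")
        if not np.allclose(self.rate_matrix.sum(axis=0), 0.0, atol=1e-10):
            raise ValueError("rate_matrix columns must sum to zero")
        if not np.allclose(self.rate_matrix @ self.populations, 0.0, atol=1e-8):
            raise ValueError("populations must be stationary under rate_matrix")

    @property
    def n_sites(self) -> int:
        return int(self.site_shifts.size)

    @classmethod
    def two_site(
        cls,
        shift_a: float,
        shift_b: float,
        r2_a: float,
        r2_b: float,
        p_a: float,
        k_ex: float,
        r1: float = 2.7,
    ) -> "ExchangeModel":
        """Two-site model parameterized by total exchange rate k_ex = k_ab + k_ba.

        Detailed balance fixes k_ab = p_b·k_ex and k_ba = p_a·k_ex.
        """
        if not 0.0 <= p_a <= 1.0:
            raise ValueError("p_a must lie in [0, 1]")
        if k_ex < 0:
            raise ValueError("k_ex must be non-negative")
        p_b = 1.0 - p_a
        k_ab = p_b * k_ex  # A -> B
        k_ba = p_a * k_ex  # B -> A
        rate = np.array([[-k_ab, k_ba], [k_ab, -k_ba]])
        return cls(
            site_shifts=np.array([shift_a, shift_b]),
            site_r2=np.array([r2_a, r2_b]),
            populations=np.array([p_a, p_b]),
            rate_matrix=rate,
            r1=r1,
        )


@dataclass
class SaturationSeries:
    """Saturation-transfer time course with its fixed R₁/I₀ context.

    ``on_intensity`` is the observed major-peak intensity while the exchange
    partner is saturated; ``off_intensity`` is the off-resonance control
    defining the t = 0 intensity I₀.
    """

    times: np.ndarray
    on_intensity: np.ndarray
    off_intensity: np.ndarray | None = None
    r1: float = 2.7
    i0: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.on_intensity = np.asarray(self.on_intensity, dtype=float)
        if self.off_intensity is not None:
            self.off_intensity = np.asarray(self.off_intensity, dtype=float)
        if np.any(self.times < 0):
            raise ValueError("saturation durations must be non-negative")
        if not self.r1 > 0:
            raise ValueError("R1 must be positive")

    def initial_intensity(self) -> float:
        """I₀: explicit if given, else the mean of the off-resonance control."""
        if self.i0 is not None:
            if not self.i0 > 0:
                raise ValueError("i0 must be positive")
            return float(self.i0)
        if self.off_intensity is None:
            raise ValueError("need i0 or an off-resonance control series")
        return float(np.mean(self.off_intensity))


@dataclass
class RelaxationSeries:
    """(delay, intensity) records from an inversion-recovery or CPMG experiment."""

    times: np.ndarray
    intensity: np.ndarray
    kind: str = "inversion_recovery"  # or "cpmg"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.kind not in ("inversion_recovery", "cpmg"):
            raise ValueError("kind must be 'inversion_recovery' or 'cpmg'")
        if self.times.shape != self.intensity.shape:
            raise ValueError("times and intensity must align")


@dataclass
class DoseResponseCurve:
    """Tidy concentration–response table (concentrations in M)."""

    concentrations: np.ndarray
    response: np.ndarray
    replicate: np.ndarray | None = None
    outlier_truth: np.ndarray | None = None  # generator-injected outlier flags
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.concentrations.shape != self.response.shape:
            raise ValueError("concentrations and response must align")
        if np.any(self.concentrations <= 0):
            raise ValueError("concentrations must be positive")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"conc_M": self.concentrations, "response": self.response})
        df["replicate"] = self.replicate if self.replicate is not None else 0
        if self.outlier_truth is not None:
            df["injected_outlier"] = self.outlier_truth
        return df
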