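"""Synthetic-data generators emulating the ¹⁹F NMR / plate-assay study design.

Every pipeline input can be generated here with the statistical structure
the downstream analysis assumes: exchange-broadened ¹⁹F spectra around
−83 to −84 ppm with a sharp free-BTFA contaminant and a coaxial KF
reference channel; saturation-transfer decays with R₁ ≈ 2.4–2.7 s⁻¹ and
exchange rates 0.3–1.4 s⁻¹; relaxation series; and 12-point
serial-dilution dose–response curves with occasional gross outliers.

Noise is iid Gaussian on frequency-domain points, the standard working
model for processed NMR spectra. All generators are reproducible under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .lineshape import exchange_lineshape, peakset_signal
from .types import (
    DEFAULT_SPECTROMETER_FREQ_MHZ,
    KF_REFERENCE_SHIFT_PPM,
    DoseResponseCurve,
    ExchangeModel,
    FrequencyAxis,
    LorentzianPeak,
    PeakSet,
    RelaxationSeries,
    SaturationSeries,
    Spectrum,
)

#: Position of the free-BTFA contaminant resonance (ppm).
FREE_BTFA_PPM = -83.3

LIGAND_CLASSES = ("full_agonist", "partial_agonist", "antagonist", "inverse_agonist", "apo")


def default_axis(n_points: int = 16384) -> FrequencyAxis:
    """Default simulation grid: −80 to −88 ppm, resolving 0.01-ppm linewidths."""
    return FrequencyAxis.from_window(-80.0, -88.0, n_points)


def simulate_static_spectrum(
    peaks: PeakSet | list[LorentzianPeak],
    axis: FrequencyAxis,
    noise_sd: float = 0.0,
    seed: int | None = None,
    metadata: dict | None = None,
) -> Spectrum:
    """Forward model of a deconvoluted spectrum: phased Lorentzians + noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    lo, hi = axis.span
    for p in peaks:
        if not axis.covers(p.center):
            raise ValueError(f"peak center {p.center} ppm outside axis [{lo}, {hi}]")
    signal = peakset_signal(axis.ppm, peaks)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    meta = dict(metadata or {})
    meta.setdefault("noise_sd", noise_sd)
    return Spectrum(axis, signal, meta)


def simulate_exchange_spectrum(
    model: ExchangeModel,
    axis: FrequencyAxis,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> Spectrum:
    """Exchange-broadened spectrum from the N-site matrix lineshape + noise."""
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    signal = exchange_lineshape(model, axis)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return Spectrum(axis, signal, {"noise_sd": noise_sd, "n_sites": model.n_sites})


def saturation_transfer_intensity(t: np.ndarray | float, r1: float, k: float) -> np.ndarray | float:
    """Forsén–Hoffman two-site saturation-transfer decay (relative intensity).

    I(t)/I₀ = R₁/(R₁+k) + k/(R₁+k)·exp(−(R₁+k)·t)
    """
    if not r1 > 0:
        raise ValueError("r1 must be positive")
    if k < 0:
        raise ValueError("k must be non-negative")
    lam = r1 + k
    return r1 / lam + (k / lam) * np.exp(-lam * np.asarray(t, dtype=float))


def simulate_saturation_series(
    r1: float,
    k: float,
    i0: float,
    times: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> SaturationSeries:
    """On/off-resonance saturation-transfer series at fixed R₁ and I₀."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("saturation durations must be non-negative")
    rng = np.random.default_rng(seed)
    on = i0 * np.asarray(saturation_transfer_intensity(times, r1, k))
    off = np.full_like(times, float(i0))
    if noise_sd > 0:
        on = on + rng.normal(0.0, noise_sd, size=on.shape)
        off = off + rng.normal(0.0, noise_sd, size=off.shape)
    return SaturationSeries(
        times=times, on_intensity=on, off_intensity=off, r1=r1, i0=None,
        metadata={"true_k": k, "true_i0": i0, "noise_sd": noise_sd},
    )


def simulate_relaxation_series(
    kind: str,
    rate: float,
    i0: float,
    times: np.ndarray,
    imperfection: float = 1.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> RelaxationSeries:
    """Inversion-recovery or CPMG decay.

    inversion_recovery: I(t) = I₀·(1 − (1 + f)·exp(−R·t)), f = inversion
    efficiency in [0, 1] (f = 1 is perfect inversion).
    cpmg: I(t) = I₀·exp(−R·t).
    """
    if not rate > 0:
        raise ValueError("rate must be positive")
    times = np.asarray(times, dtype=float)
    if kind == "inversion_recovery":
        if not 0.0 <= imperfection <= 1.0:
            raise ValueError("imperfection must lie in [0, 1]")
        y = i0 * (1.0 - (1.0 + imperfection) * np.exp(-rate * times))
    elif kind == "cpmg":
        y = i0 * np.exp(-rate * times)
    else:
        raise ValueError("kind must be 'inversion_recovery' or 'cpmg'")
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return RelaxationSeries(times, y, kind, {"true_rate": rate, "noise_sd": noise_sd})


def four_pl(conc: np.ndarray, bottom: float, top: float, logec50: float, hill: float) -> np.ndarray:
    """Variable-slope four-parameter logistic, concentration in M."""
    logc = np.log10(np.asarray(conc, dtype=float))
    return bottom + (top - bottom) / (1.0 + 10.0 ** ((logec50 - logc) * hill))


def simulate_dose_response(
    bottom: float,
    top: float,
    ec50: float,
    hill: float,
    concentrations: np.ndarray,
    noise_sd: float = 0.0,
    n_outliers: int = 0,
    seed: int | None = None,
) -> DoseResponseCurve:
    """4PL dose–response table; ``n_outliers`` points displaced by ≥10·noise_sd."""
    conc = np.asarray(concentrations, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    rng = np.random.default_rng(seed)
    y = four_pl(conc, bottom, top, np.log10(ec50), hill)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    flags = np.zeros(conc.size, dtype=bool)
    if n_outliers > 0:
        scale = noise_sd if noise_sd > 0 else 0.01 * max(abs(top - bottom), 1e-12)
        idx = rng.choice(conc.size, size=n_outliers, replace=False)
        signs = rng.choice([-1.0, 1.0], size=n_outliers)
        y[idx] = y[idx] + signs * (10.0 * scale + rng.uniform(0, 2 * scale, size=n_outliers))
        flags[idx] = True
    return DoseResponseCurve(
        conc, y, outlier_truth=flags,
        metadata={"true": {"bottom": bottom, "top": top, "ec50": ec50, "hill": hill},
                  "noise_sd": noise_sd, "n_outliers": int(n_outliers)},
    )


def serial_dilution(top_conc: float, n_points: int = 12, factor: float = 3.0) -> np.ndarray:
    """Descending serial-dilution concentration ladder (M)."""
    return top_conc / factor ** np.arange(n_points)


def competitive_bound_tracer(lo: float, ro: float, kd: float, ki: float, competitor: float) -> float:
    """Bound tracer at exact three-species competitive mass-action equilibrium.

    Solves for free receptor r in
    r + Lo·r/(Kd + r) + C·r/(Ki + r) = Ro, then Lb = Lo·r/(Kd + r).
    Accurate to ~1e-12 relative.
    """
    if min(lo, ro, kd, ki) <= 0:
        raise ValueError("lo, ro, kd, ki must all be positive")
    if competitor < 0:
        raise ValueError("competitor concentration must be non-negative")

    def residual(r: float) -> float:
        return r + lo * r / (kd + r) + competitor * r / (ki + r) - ro

    try:
        r_free = brentq(residual, 0.0, ro, xtol=1e-30, rtol=1e-15, maxiter=300)
    except (ValueError, RuntimeError) as exc:
        raise ValueError(f"competitive equilibrium solve failed: {exc}") from exc
    return lo * r_free / (kd + r_free)


def simulate_competition_assay(
    ki: float,
    kd: float,
    lo: float,
    ro: float,
    competitor_concs: np.ndarray,
    noise_sd: float = 0.0,
    seed: int | None = None,
) -> DoseResponseCurve:
    """Competitive-displacement curve from exact mass-action equilibrium."""
    concs = np.asarray(competitor_concs, dtype=float)
    bound = np.array([competitive_bound_tracer(lo, ro, kd, ki, c) for c in concs])
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        bound = bound + rng.normal(0.0, noise_sd, size=bound.shape)
    lb0 = competitive_bound_tracer(lo, ro, kd, ki, 0.0)
    return DoseResponseCurve(
        concs, bound,
        metadata={"true": {"ki": ki, "kd": kd, "lo": lo, "ro": ro, "lb0": lb0},
                  "noise_sd": noise_sd},
    )


# ---------------------------------------------------------------------------
# Ligand-class scenario templates
# ---------------------------------------------------------------------------

#: Per-class templates for the helix-12 probe resonances. Centers/widths in
#: ppm; drawn once per scenario with small class-internal jitter. The
#: qualitative pattern: full agonists, one narrow upfield peak; apo/partial
#: agonists/antagonists, two broad peaks; inverse agonists, a narrow
#: downfield peak plus a broad peak. Exchange rates (s⁻¹) and TR-FRET-like
#: coactivator/corepressor endpoints are class-linked.
CLASS_TEMPLATES: dict[str, dict] = {
    "full_agonist": {
        "peaks": [{"center": (-84.25, 0.06), "fwhm": (0.05, 0.09), "frac": (1.0, 1.0)}],
        "exchange_k": None,
        "med1": (0.85, 0.05),
        "ncor": (0.15, 0.04),
    },
    "partial_agonist": {
        "peaks": [
            {"center": (-83.65, 0.05), "fwhm": (0.18, 0.30), "frac": (0.35, 0.55)},
            {"center": (-84.05, 0.05), "fwhm": (0.20, 0.35), "frac": None},
        ],
        "exchange_k": (1.1, 1.4),
        "med1": (0.55, 0.05),
        "ncor": (0.35, 0.05),
    },
    "antagonist": {
        "peaks": [
            {"center": (-83.45, 0.05), "fwhm": (0.20, 0.32), "frac": (0.40, 0.60)},
            {"center": (-83.90, 0.05), "fwhm": (0.22, 0.36), "frac": None},
        ],
        "exchange_k": (0.8, 1.2),
        "med1": (0.38, 0.05),
        "ncor": (0.50, 0.05),
    },
    "inverse_agonist": {
        "peaks": [
            {"center": (-83.05, 0.04), "fwhm": (0.07, 0.11), "frac": (0.35, 0.55)},
            {"center": (-83.60, 0.05), "fwhm": (0.25, 0.40), "frac": None},
        ],
        "exchange_k": (0.3, 0.4),
        "med1": (0.15, 0.04),
        "ncor": (0.85, 0.05),
    },
    "apo": {
        "peaks": [
            {"center": (-83.55, 0.04), "fwhm": (0.25, 0.40), "frac": (0.40, 0.60)},
            {"center": (-83.95, 0.04), "fwhm": (0.25, 0.40), "frac": None},
        ],
        "exchange_k": (0.9, 1.1),
        "med1": (0.30, 0.04),
        "ncor": (0.55, 0.05),
    },
}

#: The default 16-"ligand" battery (class composition mirroring a diverse
#: panel of full/partial agonists, antagonists and inverse agonists) plus apo.
DEFAULT_BATTERY: tuple[tuple[str, str], ...] = tuple(
    [(f"full-{i}", "full_agonist") for i in range(1, 5)]
    + [(f"partial-{i}", "partial_agonist") for i in range(1, 6)]
    + [(f"antag-{i}", "antagonist") for i in range(1, 4)]
    + [(f"inverse-{i}", "inverse_agonist") for i in range(1, 4)]
    + [("apo", "apo")]
)


@dataclass
class ScenarioSpec:
    """Recipe for one synthetic ligand-condition spectrum."""

    ligand_class: str
    label: str | None = None
    noise_sd: float = 0.01
    seed: int = 0
    include_contaminant: bool = True
    include_reference: bool = True
    axis: FrequencyAxis | None = None
    total_area: float = 1.0

    def __post_init__(self) -> None:
        if self.ligand_class not in LIGAND_CLASSES:
            raise ValueError(f"unknown ligand class {self.ligand_class!r}; "
                             f"choose from {LIGAND_CLASSES}")


@dataclass
class ScenarioRealization:
    """A generated scenario: spectrum, reference channel, and ground truth."""

    spectrum: Spectrum
    reference_spectrum: Spectrum | None
    true_peaks: PeakSet
    label: str
    ligand_class: str
    med1_endpoint: float
    ncor_endpoint: float
    exchange_k: float | None
    metadata: dict = field(default_factory=dict)


def generate_ensemble_scenario(spec: ScenarioSpec) -> ScenarioRealization:
    """Generate one class-templated spectrum plus its ground-truth peak set.

    The returned spectrum includes (optionally) the sharp free-BTFA
    contaminant near −83.3 ppm, and a separate KF reference-channel
    spectrum whose raw peak position carries a random calibration offset.
    """
    rng = np.random.default_rng(spec.seed)
    tpl = CLASS_TEMPLATES[spec.ligand_class]
    axis = spec.axis if spec.axis is not None else default_axis()

    peaks = PeakSet()
    fracs: list[float] = []
    for entry in tpl["peaks"]:
        if entry["frac"] is not None:
            fracs.append(float(rng.uniform(*entry["frac"])))
        else:
            fracs.append(1.0 - sum(fracs))
    for entry, frac in zip(tpl["peaks"], fracs):
        mu, sd = entry["center"]
        center = float(rng.normal(mu, sd))
        fwhm = float(rng.uniform(*entry["fwhm"]))
        peaks.append(LorentzianPeak(center, fwhm, frac * spec.total_area))
    if spec.include_contaminant:
        peaks.append(
            LorentzianPeak(FREE_BTFA_PPM, 0.015, 0.03 * spec.total_area,
                           is_contaminant=True, label="free BTFA")
        )

    spectrum = simulate_static_spectrum(
        peaks, axis, noise_sd=spec.noise_sd, seed=int(rng.integers(2**31)),
        metadata={"label": spec.label or spec.ligand_class,
                  "ligand_class": spec.ligand_class,
                  "temperature_K": 298.2, "d2o_fraction": 0.10},
    )

    reference = None
    raw_offset = float(rng.uniform(-0.15, 0.15))
    if spec.include_reference:
        ref_axis = FrequencyAxis.from_window(
            -118.5, -120.5, 4096, spectrometer_freq=axis.spectrometer_freq
        )
        ref_peak = LorentzianPeak(KF_REFERENCE_SHIFT_PPM + raw_offset, 0.02, 1.0, label="KF")
        reference = simulate_static_spectrum(
            [ref_peak], ref_axis, noise_sd=spec.noise_sd * 0.5,
            seed=int(rng.integers(2**31)),
            metadata={"channel": "reference", "raw_offset_ppm": raw_offset},
        )
        # The sample axis carries the same (unknown-to-the-analyst) offset.
        spectrum = Spectrum(axis.shifted(raw_offset),
                            spectrum.intensity, dict(spectrum.metadata))
        peaks = PeakSet([
            LorentzianPeak(p.center + raw_offset, p.fwhm, p.area, p.phase,
                           p.is_contaminant, p.label)
            for p in peaks
        ])
        spectrum.metadata["true_raw_offset_ppm"] = raw_offset

    k_range = tpl["exchange_k"]
    k = float(rng.uniform(*k_range)) if k_range is not None else None
    med1 = float(rng.normal(*tpl["med1"]))
    ncor = float(rng.normal(*tpl["ncor"]))
    return ScenarioRealization(
        spectrum=spectrum,
        reference_spectrum=reference,
        true_peaks=peaks,
        label=spec.label or spec.ligand_class,
        ligand_class=spec.ligand_class,
        med1_endpoint=med1,
        ncor_endpoint=ncor,
        exchange_k=k,
        metadata={"seed": spec.seed, "raw_offset_ppm": raw_offset},
    )


def generate_battery(
    base_seed: int,
    noise_sd: float = 0.01,
    axis: FrequencyAxis | None = None,
    battery: tuple[tuple[str, str], ...] = DEFAULT_BATTERY,
) -> list[ScenarioRealization]:
    """Generate the full multi-ligand synthetic study (default: 16 ligands + apo)."""
    out = []
    for i, (label, cls) in enumerate(battery):
        spec = ScenarioSpec(
            ligand_class=cls, label=label, noise_sd=noise_sd,
            seed=(base_seed * 1000 + i) % (2**31), axis=axis,
        )
        out.append(generate_ensemble_scenario(spec))
    return out
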