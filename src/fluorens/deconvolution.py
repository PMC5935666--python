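"""Axis calibration and objective Lorentzian-mixture deconvolution.

A spectrum is decomposed into 1..max_peaks phased Lorentzian components by
bounded nonlinear least squares; the number of components is chosen by an
information criterion (BIC by default) computed from the Gaussian
log-likelihood at the independently estimated noise level. Per-peak phases
are constrained within ±π/50 rad of a shared global phase, matching the
near-uniform phasing expected of processed 1D spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import least_squares
from scipy.signal import argrelmax

from .lineshape import phased_lorentzian
from .types import FrequencyAxis, KF_REFERENCE_SHIFT_PPM, LorentzianPeak, PeakSet, Spectrum

PHASE_WINDOW_RAD = np.pi / 50.0  # allowed per-peak deviation from the global phase


@dataclass
class DeconvolutionResult:
    """Fitted mixture plus model-selection bookkeeping."""

    peaks: PeakSet
    global_phase: float
    baseline: float
    noise_sd: float
    residual: np.ndarray
    rss: float
    converged: bool
    criterion: str | None = None
    criterion_table: dict[int, float] = field(default_factory=dict)
    rss_table: dict[int, float] = field(default_factory=dict)
    selected_n: int | None = None

    @property
    def n_peaks(self) -> int:
        return len(self.peaks)

    def model_signal(self, ppm: np.ndarray) -> np.ndarray:
        out = np.full_like(np.asarray(ppm, dtype=float), self.baseline)
        for p in self.peaks:
            out += phased_lorentzian(ppm, p.center, p.fwhm, p.area, p.phase)
        return out


def find_reference_peak(
    spectrum: Spectrum,
    expected_position: float,
    search_window: float = 0.25,
    min_snr: float = 5.0,
) -> float:
    """Locate the reference peak near ``expected_position`` (ppm).

    Requires a local maximum at least ``min_snr`` times the robust noise of
    the spectrum; the position is refined by parabolic interpolation of the
    apex for sub-grid accuracy.
    """
    ppm, y = spectrum.ppm, spectrum.intensity
    mask = np.abs(ppm - expected_position) <= search_window
    if mask.sum() < 5:
        raise ValueError("search window around the reference position is off-grid")
    noise = 1.4826 * np.median(np.abs(y - np.median(y)))
    sub_y = y[mask]
    sub_ppm = ppm[mask]
    i = int(np.argmax(sub_y))
    height = sub_y[i] - np.median(y)
    if noise > 0 and height < min_snr * noise:
        raise ValueError(
            f"no reference peak >= {min_snr}x noise within "
            f"{search_window} ppm of {expected_position} ppm"
        )
    if height <= 0:
        raise ValueError("no reference peak found (flat data)")
    if 0 < i < sub_y.size - 1:
        y0, y1, y2 = sub_y[i - 1], sub_y[i], sub_y[i + 1]
        denom = y0 - 2 * y1 + y2
        if denom != 0:
            frac = 0.5 * (y0 - y2) / denom
            frac = float(np.clip(frac, -0.5, 0.5))
            return float(sub_ppm[i] + frac * (sub_ppm[min(i + 1, sub_y.size - 1)] - sub_ppm[i]))
    return float(sub_ppm[i])


def calibrate_axis(
    spectrum: Spectrum,
    reference_raw_position: float,
    reference_defined_shift: float = KF_REFERENCE_SHIFT_PPM,
    reference_spectrum: Spectrum | None = None,
    search_window: float = 0.25,
) -> Spectrum:
    """Calibrate the ppm axis against an internal reference signal.

    The reference peak is located near ``reference_raw_position`` in
    ``reference_spectrum`` (the coaxial reference channel) if given,
    otherwise in ``spectrum`` itself; every shift is then offset so the
    reference lands exactly at ``reference_defined_shift``.
    """
    source = reference_spectrum if reference_spectrum is not None else spectrum
    found = find_reference_peak(source, reference_raw_position, search_window)
    offset = reference_defined_shift - found
    meta = dict(spectrum.metadata)
    meta["calibration_offset_ppm"] = offset
    meta["reference_found_raw_ppm"] = found
    meta["reference_defined_ppm"] = reference_defined_shift
    return Spectrum(spectrum.axis.shifted(offset), spectrum.intensity.copy(), meta)


def estimate_noise(spectrum: Spectrum, signal_free_window: tuple[float, float]) -> float:
    """Robust noise level (MAD × 1.4826) in a signal-free ppm window.

    Rejects windows with fewer than 50 points or with apparent signal
    (any point more than 6 robust sd above the window median).
    """
    lo, hi = sorted(signal_free_window)
    mask = (spectrum.ppm >= lo) & (spectrum.ppm <= hi)
    if mask.sum() < 50:
        raise ValueError("signal-free window must contain at least 50 points")
    y = spectrum.intensity[mask]
    med = np.median(y)
    sd = 1.4826 * np.median(np.abs(y - med))
    peak_excursion = np.max(np.abs(y - med))
    if sd == 0.0:
        if peak_excursion > 0:
            raise ValueError("window contains signal structure but no noise floor")
        return 0.0
    if peak_excursion > 6.0 * sd:
        raise ValueError("signal-free window appears to overlap a peak")
    return float(sd)


def _auto_noise(spectrum: Spectrum) -> float:
    """Fallback noise estimate from the first-difference of the spectrum.

    Differencing suppresses smooth lineshape structure; Var(diff) = 2·σ²
    for iid noise.
    """
    d = np.diff(spectrum.intensity)
    return float(1.4826 * np.median(np.abs(d - np.median(d))) / np.sqrt(2.0))


def _pick_initial_peaks(
    spectrum: Spectrum, n_peaks: int, noise_sd: float, rng: np.random.Generator
) -> list[tuple[float, float, float]]:
    """Initial (center, fwhm, area) guesses from smoothed local maxima."""
    ppm, y = spectrum.ppm, spectrum.intensity
    step = spectrum.axis.step
    smooth = gaussian_filter1d(y, sigma=3.0)
    base = np.median(smooth)
    (idx,) = argrelmax(smooth, order=5)
    idx = idx[smooth[idx] > base + 3.0 * max(noise_sd, 1e-30)]
    idx = idx[np.argsort(smooth[idx])[::-1]]  # tallest first

    guesses: list[tuple[float, float, float]] = []
    for i in idx[:n_peaks]:
        height = smooth[i] - base
        # half-height width scan
        half = base + 0.5 * height
        left = i
        while left > 0 and smooth[left] > half:
            left -= 1
        right = i
        while right < smooth.size - 1 and smooth[right] > half:
            right += 1
        fwhm = max((right - left) * step, 2.0 * step)
        guesses.append((float(ppm[i]), float(fwhm), float(height * np.pi * fwhm / 2.0)))
    while len(guesses) < n_peaks:
        if guesses:
            c, w, a = guesses[len(guesses) % max(len(idx), 1) - 1 if idx.size else 0]
            guesses.append((c + float(rng.normal(0, max(w, 5 * step))), max(w, 2 * step), a / 2))
        else:
            lo, hi = spectrum.axis.span
            guesses.append((float(rng.uniform(lo, hi)), 20 * step, float(np.ptp(y)) * step * 10))
    return guesses[:n_peaks]


def _warm_init(spectrum: Spectrum, prev: "DeconvolutionResult") -> PeakSet:
    """Previous n-peak solution plus a small peak at the largest residual."""
    resid = prev.residual
    i = int(np.argmax(np.abs(resid)))
    step = spectrum.axis.step
    w = float(np.median([p.fwhm for p in prev.peaks])) if len(prev.peaks) else 10 * step
    height = abs(resid[i])
    new = LorentzianPeak(float(spectrum.ppm[i]), w,
                         max(height * np.pi * w / 2.0, 1e-12))
    return PeakSet(list(prev.peaks) + [new])


def _mixture_residual(theta: np.ndarray, ppm: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    baseline, gphase = theta[0], theta[1]
    model = np.full_like(y, baseline)
    for j in range(n):
        c, w, a, dphi = theta[2 + 4 * j : 6 + 4 * j]
        model += phased_lorentzian(ppm, c, w, a, gphase + dphi)
    return model - y


def _mixture_jacobian(theta: np.ndarray, ppm: np.ndarray, y: np.ndarray, n: int) -> np.ndarray:
    """Analytic Jacobian of the mixture residual (rows: points, cols: params)."""
    J = np.empty((ppm.size, 2 + 4 * n))
    J[:, 0] = 1.0  # baseline
    dgphase = np.zeros_like(ppm)
    for j in range(n):
        c, w, a, dphi = theta[2 + 4 * j : 6 + 4 * j]
        phi = theta[1] + dphi
        d = ppm - c
        h = 0.5 * w
        D = d * d + h * h
        D2 = D * D
        absorb = (a / np.pi) * h / D
        disp = (a / np.pi) * d / D
        cosp, sinp = np.cos(phi), np.sin(phi)
        dabs_dc = (a / np.pi) * 2.0 * h * d / D2
        ddisp_dc = (a / np.pi) * (d * d - h * h) / D2
        dabs_dh = (a / np.pi) * (d * d - h * h) / D2
        ddisp_dh = (a / np.pi) * (-2.0 * h * d) / D2
        dphi_term = -sinp * absorb + cosp * disp
        J[:, 2 + 4 * j] = cosp * dabs_dc + sinp * ddisp_dc  # center
        J[:, 3 + 4 * j] = 0.5 * (cosp * dabs_dh + sinp * ddisp_dh)  # fwhm
        with np.errstate(divide="ignore", invalid="ignore"):
            J[:, 4 + 4 * j] = (cosp * absorb + sinp * disp) / a if a > 0 else (
                (1.0 / np.pi) * (cosp * h + sinp * d) / D
            )
        J[:, 5 + 4 * j] = dphi_term  # per-peak phase offset
        dgphase += dphi_term
    J[:, 1] = dgphase  # global phase
    return J


def fit_lorentzian_mixture(
    spectrum: Spectrum,
    n_peaks: int,
    init: PeakSet | None = None,
    noise_sd: float | None = None,
    n_restarts: int = 5,
    max_peaks_allowed: int = 10,
    fixed_peaks: tuple[tuple[float, float] | None, ...] = (),
    restart_seed: int = 0,
) -> DeconvolutionResult:
    """Bounded least-squares fit of an n-component phased Lorentzian mixture.

    Areas are constrained non-negative, per-peak phases within ±π/50 rad of
    a shared global phase, FWHM between 2 grid steps and half the window.
    Multistart with jittered centers guards against local minima.
    """
    if n_peaks < 1:
        raise ValueError("n_peaks must be >= 1")
    if n_peaks > max_peaks_allowed:
        raise ValueError(f"n_peaks={n_peaks} exceeds configured maximum {max_peaks_allowed}")
    ppm, y = spectrum.ppm, spectrum.intensity
    lo, hi = spectrum.axis.span
    step = spectrum.axis.step
    w_min, w_max = 2.0 * step, (hi - lo) / 2.0
    sigma = noise_sd if noise_sd is not None else _auto_noise(spectrum)
    rng = np.random.default_rng(restart_seed + 7919 * n_peaks)

    if init is not None:
        base_guesses = [(p.center, p.fwhm, p.area) for p in init]
        if len(base_guesses) != n_peaks:
            raise ValueError("init peak count must equal n_peaks")
    else:
        base_guesses = _pick_initial_peaks(spectrum, n_peaks, sigma, rng)

    lower = [-np.inf, -np.pi / 4]
    upper = [np.inf, np.pi / 4]
    for _ in range(n_peaks):
        lower += [lo, w_min, 0.0, -PHASE_WINDOW_RAD]
        upper += [hi, w_max, np.inf, PHASE_WINDOW_RAD]
    lower, upper = np.array(lower), np.array(upper)

    best = None
    for trial in range(max(1, n_restarts)):
        theta0 = [float(np.median(y)), 0.0]
        for c, w, a in base_guesses:
            if trial > 0:
                c = c + float(rng.normal(0.0, 0.5 * w))
            theta0 += [
                float(np.clip(c, lo + step, hi - step)),
                float(np.clip(w, w_min * 1.01, w_max * 0.99)),
                max(a, 0.0),
                0.0,
            ]
        try:
            sol = least_squares(
                _mixture_residual, np.array(theta0), jac=_mixture_jacobian,
                bounds=(lower, upper), args=(ppm, y, n_peaks),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError(f"mixture fit with {n_peaks} peaks failed after restarts")

    rss, sol = best
    baseline, gphase = float(sol.x[0]), float(sol.x[1])
    peaks = []
    for j in range(n_peaks):
        c, w, a, dphi = sol.x[2 + 4 * j : 6 + 4 * j]
        peaks.append(LorentzianPeak(float(c), float(w), float(a), float(gphase + dphi)))
    peaks.sort(key=lambda p: -p.center)
    residual = -sol.fun  # data - model
    return DeconvolutionResult(
        peaks=PeakSet(peaks), global_phase=gphase, baseline=baseline,
        noise_sd=sigma, residual=residual, rss=rss,
        converged=bool(sol.status > 0),
    )


def information_criterion(
    rss: float, n_obs: int, n_params: int, noise_sd: float, criterion: str
) -> float:
    """AIC/AICc/BIC from the Gaussian log-likelihood at known noise sd."""
    sigma = max(noise_sd, 1e-300)
    loglik = -0.5 * rss / sigma**2 - n_obs * np.log(sigma * np.sqrt(2.0 * np.pi))
    crit = criterion.lower()
    if crit == "bic":
        return n_params * np.log(n_obs) - 2.0 * loglik
    if crit == "aic":
        return 2.0 * n_params - 2.0 * loglik
    if crit == "aicc":
        correction = 2.0 * n_params * (n_params + 1) / max(n_obs - n_params - 1, 1)
        return 2.0 * n_params - 2.0 * loglik + correction
    raise ValueError("criterion must be one of 'BIC', 'AIC', 'AICc'")


def deconvolve(
    spectrum: Spectrum,
    max_peaks: int = 6,
    criterion: str = "BIC",
    noise_sd: float | None = None,
    signal_free_window: tuple[float, float] | None = None,
    n_restarts: int = 5,
    contaminant_position: float | None = None,
    contaminant_tolerance: float = 0.05,
) -> DeconvolutionResult:
    """Objective deconvolution: fit 1..max_peaks mixtures, select by criterion.

    If ``contaminant_position`` is given, any fitted peak whose center falls
    within ``contaminant_tolerance`` ppm of it and whose width is below
    0.05 ppm is flagged as the free-BTFA contaminant so downstream ensemble
    metrics can exclude it.
    """
    if max_peaks < 1:
        raise ValueError("max_peaks must be >= 1")
    if noise_sd is None:
        if signal_free_window is not None:
            noise_sd = estimate_noise(spectrum, signal_free_window)
        else:
            noise_sd = _auto_noise(spectrum)
    if noise_sd <= 0:
        noise_sd = max(_auto_noise(spectrum), 1e-12 * max(np.max(np.abs(spectrum.intensity)), 1.0))

    table: dict[int, float] = {}
    rss_table: dict[int, float] = {}
    fits: dict[int, DeconvolutionResult] = {}
    prev: DeconvolutionResult | None = None
    for n in range(1, max_peaks + 1):
        fit = None
        try:
            fit = fit_lorentzian_mixture(
                spectrum, n, noise_sd=noise_sd, n_restarts=n_restarts
            )
        except RuntimeError:
            pass
        # hierarchical warm start: previous solution plus a peak at the
        # largest residual, so nested-model RSS is non-increasing in n
        if prev is not None:
            try:
                warm_fit = fit_lorentzian_mixture(
                    spectrum, n, init=_warm_init(spectrum, prev),
                    noise_sd=noise_sd, n_restarts=1,
                )
                if fit is None or warm_fit.rss < fit.rss:
                    fit = warm_fit
            except (RuntimeError, ValueError):
                pass
        if fit is None:
            table[n] = np.nan
            continue
        prev = fit
        rss_table[n] = fit.rss
        k = 4 * n + 2  # per-peak (c, w, A, dphi) + baseline + global phase
        table[n] = information_criterion(fit.rss, len(spectrum.ppm), k, noise_sd, criterion)
        fits[n] = fit
    if not fits:
        raise RuntimeError("all candidate deconvolution fits failed")

    finite = {n: v for n, v in table.items() if np.isfinite(v)}
    # argmin; ties broken toward fewer peaks by ascending-n iteration order
    selected = min(finite, key=lambda n: (finite[n], n))
    result = fits[selected]
    result.criterion = criterion
    result.criterion_table = table
    result.rss_table = rss_table
    result.selected_n = selected

    if contaminant_position is not None:
        for p in result.peaks:
            if abs(p.center - contaminant_position) <= contaminant_tolerance and p.fwhm < 0.05:
                p.is_contaminant = True
                p.label = "free BTFA"
    return result
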