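"""Lorentzian and chemical-exchange lineshape forward models.

Two independent routes to the two-site exchange lineshape are provided:
the general N-site matrix solve (`exchange_lineshape`) and a hand-expanded
scalar formula (`two_site_lineshape_closed_form`). The second exists so the
first can be verified against a different code path.
"""

from __future__ import annotations

import numpy as np

from .types import ExchangeModel, FrequencyAxis, LorentzianPeak, PeakSet


def lorentzian_absorptive(ppm: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    """Absorptive Lorentzian normalized so it integrates to ``area`` over ppm."""
    hw = 0.5 * fwhm
    return (area / np.pi) * hw / ((ppm - center) ** 2 + hw**2)


def lorentzian_dispersive(ppm: np.ndarray, center: float, fwhm: float, area: float) -> np.ndarray:
    """Dispersive Lorentzian companion of :func:`lorentzian_absorptive`."""
    hw = 0.5 * fwhm
    return (area / np.pi) * (ppm - center) / ((ppm - center) ** 2 + hw**2)


def phased_lorentzian(
    ppm: np.ndarray, center: float, fwhm: float, area: float, phase: float
) -> np.ndarray:
    """cos(φ)·absorptive + sin(φ)·dispersive mixed lineshape."""
    return np.cos(phase) * lorentzian_absorptive(ppm, center, fwhm, area) + np.sin(
        phase
    ) * lorentzian_dispersive(ppm, center, fwhm, area)


def peakset_signal(ppm: np.ndarray, peaks: PeakSet | list[LorentzianPeak]) -> np.ndarray:
    """Noise-free superposition of phased Lorentzian peaks."""
    out = np.zeros_like(np.asarray(ppm, dtype=float))
    for p in peaks:
        out += phased_lorentzian(ppm, p.center, p.fwhm, p.area, p.phase)
    return out


def exchange_lineshape(model: ExchangeModel, axis: FrequencyAxis) -> np.ndarray:
    """N-site exchange lineshape by the Bloch–McConnell matrix formalism.

    At each grid frequency ω the steady-state transverse response is

        S(ω) = −Re[ 1ᵀ (iΔΩ(ω) − R₂ + K)⁻¹ p ]

    with ΔΩ in rad/s obtained from ppm through the spectrometer frequency.
    An isolated site reduces to an absorptive Lorentzian with
    FWHM(Hz) = R₂/π.
    """
    n = model.n_sites
    omega_sites = 2.0 * np.pi * model.site_shifts * axis.spectrometer_freq  # rad/s
    omega_grid = 2.0 * np.pi * axis.ppm * axis.spectrometer_freq
    base = model.rate_matrix.astype(complex) - np.diag(model.site_r2.astype(complex))
    p = model.populations.astype(complex)

    # Batched solve: A(ω) = base + i·diag(Ω_site − ω)
    mats = np.broadcast_to(base, (omega_grid.size, n, n)).copy()
    idx = np.arange(n)
    mats[:, idx, idx] += 1j * (omega_sites[None, :] - omega_grid[:, None])
    try:
        rhs = np.broadcast_to(p[:, None], (omega_grid.size, n, 1))
        sol = np.linalg.solve(mats, rhs)[..., 0]
    except np.linalg.LinAlgError as exc:  # pragma: no cover - non-physical input
        raise ValueError(f"singular exchange matrix on the frequency grid: {exc}") from exc
    signal = -np.real(sol.sum(axis=1))
    if not np.all(np.isfinite(signal)):
        raise ValueError("non-finite exchange lineshape; check model parameters")
    return signal


def two_site_lineshape_closed_form(
    shift_a: float,
    shift_b: float,
    r2_a: float,
    r2_b: float,
    p_a: float,
    k_ex: float,
    axis: FrequencyAxis,
) -> np.ndarray:
    """Closed-form two-site McConnell lineshape (independent scalar algebra).

    Writes out the 2×2 resolvent by hand: with
    a = i(Ω_A − ω) − R₂A − k_AB and b = i(Ω_B − ω) − R₂B − k_BA,

        1ᵀ A⁻¹ p = [p_A(b − k_AB) + p_B(a − k_BA)] / (a·b − k_AB·k_BA)

    and S(ω) = −Re[·]. Shares no code with :func:`exchange_lineshape`.
    """
    p_b = 1.0 - p_a
    k_ab = p_b * k_ex
    k_ba = p_a * k_ex
    w_a = 2.0 * np.pi * shift_a * axis.spectrometer_freq
    w_b = 2.0 * np.pi * shift_b * axis.spectrometer_freq
    w = 2.0 * np.pi * axis.ppm * axis.spectrometer_freq
    a = 1j * (w_a - w) - r2_a - k_ab
    b = 1j * (w_b - w) - r2_b - k_ba
    det = a * b - k_ab * k_ba
    num = p_a * (b - k_ab) + p_b * (a - k_ba)
    return -np.real(num / det)
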