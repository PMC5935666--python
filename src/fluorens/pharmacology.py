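"""Dose–response fitting, outlier detection, Kᵢ, occupancy, and correlations.

Competitive-binding Kᵢ values follow the corrected Cheng–Prusoff relation

    Kᵢ = Lb·IC₅₀·K_d / [Lo·Ro + Lb·(Ro − Lo + Lb − K_d)]

where Lo and Ro are total tracer and receptor, K_d the tracer dissociation
constant, and Lb the tracer bound in the absence of competitor. Outliers in
plate data are flagged by the ROUT procedure (robust Lorentzian-loss fit
followed by FDR-controlled residual testing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.optimize import brentq, least_squares

from .synthetic import competitive_bound_tracer, four_pl
from .types import DoseResponseCurve


@dataclass
class FourPLFit:
    """Variable-slope four-parameter logistic fit."""

    bottom: float
    top: float
    logec50: float  # log10 M
    hill: float
    ci: dict[str, tuple[float, float]]
    rss: float
    n: int
    converged: bool
    orientation: str = "ascending"  # top >= bottom
    ec50_in_range: bool = True

    @property
    def ec50(self) -> float:
        return 10.0**self.logec50

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        return four_pl(np.asarray(conc, dtype=float), self.bottom, self.top,
                       self.logec50, self.hill)


def _fit_4pl_ls(conc, y, theta0, loss="linear", f_scale=1.0):
    logc = np.log10(conc)

    def resid(theta):
        bottom, top, logec50, hill = theta
        return bottom + (top - bottom) / (1 + 10 ** ((logec50 - logc) * hill)) - y

    return least_squares(
        resid, theta0, loss=loss, f_scale=f_scale, method="trf",
        bounds=([-np.inf, -np.inf, logc.min() - 6, -10], [np.inf, np.inf, logc.max() + 6, 10]),
        xtol=1e-14, ftol=1e-14,
    )


def fit_4pl(curve: DoseResponseCurve, mask: np.ndarray | None = None) -> FourPLFit:
    """Least-squares 4PL fit with multistart on log EC₅₀ and asymptotic CIs.

    ``mask`` selects the points used in the fit (e.g. to reproduce a
    biphasic-curve analysis that drops the top concentrations).
    """
    conc = curve.concentrations if mask is None else curve.concentrations[mask]
    y = curve.response if mask is None else curve.response[mask]
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    if np.ptp(y) == 0:
        raise ValueError("no dose dependence: all responses identical")
    logc = np.log10(conc)

    best = None
    for q in (0.25, 0.5, 0.75):
        theta0 = np.array([float(np.min(y)), float(np.max(y)),
                           float(np.quantile(logc, q)), 1.0])
        try:
            sol = _fit_4pl_ls(conc, y, theta0)
        except Exception:
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise RuntimeError("4PL fit failed from all starting points")
    rss, sol = best
    bottom, top, logec50, hill = (float(v) for v in sol.x)

    n, p = y.size, 4
    dof = max(n - p, 1)
    s2 = rss / dof
    J = sol.jac
    try:
        cov = s2 * np.linalg.inv(J.T @ J)
        se = np.sqrt(np.clip(np.diag(cov), 0, np.inf))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    tcrit = stats.t.ppf(0.975, dof)
    names = ("bottom", "top", "logec50", "hill")
    ci = {nm: (v - tcrit * s, v + tcrit * s)
          for nm, v, s in zip(names, sol.x, se)}
    return FourPLFit(
        bottom=bottom, top=top, logec50=logec50, hill=hill, ci=ci,
        rss=rss, n=n, converged=bool(sol.status > 0),
        orientation="ascending" if top >= bottom else "descending",
        ec50_in_range=bool(logc.min() <= logec50 <= logc.max()),
    )


@dataclass
class RoutResult:
    """ROUT outlier screen: flags plus the cleaned least-squares refit."""

    outlier_flags: np.ndarray
    cleaned_fit: FourPLFit
    robust_fit_params: np.ndarray
    rsdr: float
    q_percent: float
    fallback: bool = False


def rout_outliers(
    curve: DoseResponseCurve, q: float = 1.0, known_sd: float | None = None
) -> RoutResult:
    """Detect gross outliers in a dose–response table by the ROUT procedure.

    1. Robust 4PL fit with Lorentzian loss (multistart: the plain fit,
       quantile-spread log-EC₅₀ starts, and a leave-worst-point-out start;
       the candidate with the smallest trimmed squared-residual sum wins,
       which resists fits that "absorb" an outlier at a curve extreme).
    2. Residual scale RSDR = P68.27(|residuals|) · N/(N−K), or the known
       measurement sd when the caller supplies one (e.g. simulation
       studies with designed noise).
    3. FDR step-up on two-tailed t-tail probabilities of the scaled
       residuals at rate Q (percent).
    4. Plain least-squares refit on the retained points.

    Flagged points are reported, never silently dropped from the table.
    """
    conc, y = curve.concentrations, curve.response
    n = y.size
    if n < 8:
        raise ValueError("ROUT needs at least 8 points")
    if q < 0:
        raise ValueError("Q must be non-negative")

    flags = np.zeros(n, dtype=bool)
    fallback = False
    k_params = 4
    try:
        plain = fit_4pl(curve)
        resid0 = four_pl(conc, plain.bottom, plain.top, plain.logec50,
                         plain.hill) - y
        # outlier-resistant loss scale (MAD, not rms, of plain residuals)
        mad_scale = max(1.4826 * np.median(np.abs(resid0 - np.median(resid0))),
                        1e-9 * max(np.ptp(y), 1.0))
        scale = known_sd if known_sd is not None else mad_scale
        logc = np.log10(conc)
        starts = [np.array([plain.bottom, plain.top, plain.logec50, plain.hill])]
        starts += [np.array([float(np.min(y)), float(np.max(y)),
                             float(np.quantile(logc, qq)), 1.0])
                   for qq in (0.25, 0.5, 0.75)]
        try:
            worst = int(np.argmax(np.abs(resid0)))
            mask = np.ones(n, dtype=bool)
            mask[worst] = False
            lwo = fit_4pl(DoseResponseCurve(conc[mask], y[mask]))
            starts.append(np.array([lwo.bottom, lwo.top, lwo.logec50, lwo.hill]))
        except Exception:
            pass
        candidates = []
        for theta0 in starts:
            try:
                sol = _fit_4pl_ls(conc, y, theta0, loss="cauchy", f_scale=scale)
                candidates.append(sol.x)
            except Exception:
                continue
        if not candidates:
            raise RuntimeError("robust fit failed")

        def trimmed_ssr(th: np.ndarray) -> float:
            r2 = np.sort((four_pl(conc, *th) - y) ** 2)
            return float(np.sum(r2[: n - 1]))

        params = min(candidates, key=trimmed_ssr)
        resid = four_pl(conc, *params) - y
    except Exception:
        plain = fit_4pl(curve)
        return RoutResult(flags, plain, np.array([plain.bottom, plain.top,
                                                  plain.logec50, plain.hill]),
                          rsdr=float("nan"), q_percent=q, fallback=True)

    if known_sd is not None:
        rsdr = float(known_sd)
    else:
        rsdr = float(np.percentile(np.abs(resid), 68.27) * n / max(n - k_params, 1))
    if rsdr > 0 and q > 0:
        tvals = np.abs(resid) / rsdr
        pvals = 2.0 * stats.t.sf(tvals, df=max(n - k_params, 1))
        order = np.argsort(pvals)  # ascending p = descending |residual|
        alpha = q / 100.0
        cutoff = -1
        for rank, idx in enumerate(order, start=1):
            if pvals[idx] <= alpha * rank / n:
                cutoff = rank
        if cutoff > 0:
            flags[order[:cutoff]] = True
    if flags.all():
        flags[:] = False
        fallback = True

    retained = ~flags
    cleaned_curve = DoseResponseCurve(conc[retained], y[retained])
    cleaned = fit_4pl(cleaned_curve)
    return RoutResult(flags, cleaned, params, rsdr, q, fallback)


def bound_tracer(lo: float, ro: float, kd: float) -> float:
    """Bound tracer Lb from the two-species equilibrium quadratic.

    Lb = [(Ro+Lo+K_d) − sqrt((Ro+Lo+K_d)² − 4·Ro·Lo)] / 2, the physical root.
    """
    if min(lo, ro, kd) < 0 or ro <= 0:
        raise ValueError("lo, ro, kd must be non-negative, ro positive")
    s = ro + lo + kd
    return float((s - np.sqrt(s * s - 4.0 * ro * lo)) / 2.0)


@dataclass
class CompetitionAssay:
    """Constants of a competitive tracer-displacement assay (all in M)."""

    lo: float  # total tracer
    ro: float  # total receptor
    kd: float  # tracer dissociation constant
    ic50: float
    lb: float | None = None  # bound tracer with no competitor; computed if None

    def __post_init__(self) -> None:
        if min(self.lo, self.ro, self.kd, self.ic50) <= 0:
            raise ValueError("lo, ro, kd, ic50 must be positive")
        if self.lb is None:
            self.lb = bound_tracer(self.lo, self.ro, self.kd)
        if not 0 < self.lb <= min(self.lo, self.ro) + 1e-12:
            raise ValueError("lb must satisfy 0 < lb <= min(lo, ro)")


def ki_from_ic50(assay: CompetitionAssay) -> float:
    """Corrected Cheng–Prusoff inhibitor constant.

    Kᵢ = Lb·IC₅₀·K_d / [Lo·Ro + Lb·(Ro − Lo + Lb − K_d)]
    """
    lb = assay.lb
    denom = assay.lo * assay.ro + lb * (assay.ro - assay.lo + lb - assay.kd)
    if denom <= 0:
        raise ValueError("assay outside equation's validity (non-positive denominator)")
    return float(lb * assay.ic50 * assay.kd / denom)


def ki_from_ic50_exact(assay: CompetitionAssay) -> float:
    """Exact competitive-equilibrium inversion of a measured IC₅₀.

    At 50% displacement the bound tracer is Lb/2; the free-species
    bookkeeping then gives the inhibitor constant directly:

        P_f = K_d·b/(Lo − b),  C_b = Ro − P_f − b,  C_f = IC₅₀ − C_b,
        Kᵢ = C_f·P_f/C_b,   with b = Lb/2.

    Unlike the totals-based closed form (:func:`ki_from_ic50`), this
    inversion is exact for the three-species mass-action model at any
    degree of tracer or competitor depletion.
    """
    b = assay.lb / 2.0
    lf = assay.lo - b
    if lf <= 0:
        raise ValueError("bound tracer exceeds total tracer")
    pf = assay.kd * b / lf
    cb = assay.ro - pf - b
    if cb <= 0:
        raise ValueError("no competitor bound at 50% displacement; assay ill-posed")
    cf = assay.ic50 - cb
    if cf <= 0:
        raise ValueError("IC50 below bound-competitor level; assay outside validity")
    return float(cf * pf / cb)


def competition_ic50(lo: float, ro: float, kd: float, ki: float) -> float:
    """IC₅₀ (half-displacement concentration) from the exact equilibrium model."""
    lb0 = competitive_bound_tracer(lo, ro, kd, ki, 0.0)
    target = lb0 / 2.0

    def f(logc: float) -> float:
        return competitive_bound_tracer(lo, ro, kd, ki, 10.0**logc) - target

    lo_exp, hi_exp = np.log10(ki) - 8, np.log10(ki) + 8
    return float(10.0 ** brentq(f, lo_exp, hi_exp, xtol=1e-13))


@dataclass
class OccupancyResult:
    occupancy: float
    bound: float
    free_ligand: float


def predict_occupancy(ptot: float, ltot: float, ki: float) -> OccupancyResult:
    """Receptor fractional occupancy at total protein/ligand and affinity Kᵢ.

    Physical root of the two-species quadratic; also returns the free-ligand
    concentration used to read TR-FRET endpoints off fitted curves.
    """
    if ptot <= 0 or ki <= 0 or ltot < 0:
        raise ValueError("ptot and ki must be positive, ltot non-negative")
    if ltot == 0:
        return OccupancyResult(0.0, 0.0, 0.0)
    s = ptot + ltot + ki
    bound = (s - np.sqrt(s * s - 4.0 * ptot * ltot)) / 2.0
    return OccupancyResult(float(bound / ptot), float(bound), float(ltot - bound))


def trfret_at_free_ligand(
    fit: FourPLFit | None,
    free_ligand: float,
    curve: DoseResponseCurve | None = None,
) -> tuple[float, bool]:
    """Assay response at the free (NMR-sample) ligand concentration.

    Evaluates the fitted 4PL at ``free_ligand``; if the upstream fit failed
    (``fit is None``), substitutes the measured response nearest in
    log-concentration and flags the substitution.

    Returns (response, substituted).
    """
    if free_ligand <= 0:
        raise ValueError("free_ligand must be positive")
    if fit is not None and fit.converged:
        return float(fit.predict(free_ligand)), False
    if curve is None:
        raise ValueError("need the measured curve to substitute a nearest point")
    i = int(np.argmin(np.abs(np.log10(curve.concentrations) - np.log10(free_ligand))))
    return float(curve.response[i]), True


@dataclass
class CorrelationResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def correlate_shift_function(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """OLS line through paired (mean shift, functional endpoint) values."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in x")
    fit = stats.linregress(x, y)
    return CorrelationResult(float(fit.slope), float(fit.intercept),
                             float(fit.rvalue**2), int(x.size))
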