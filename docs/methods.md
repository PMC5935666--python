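# Methods

`fluorens` analyzes one-dimensional ¹⁹F NMR spectra of a CF₃-tagged
protein surface — here modeled on the co-regulator (AF-2) surface of a
nuclear-receptor ligand-binding domain — and connects the spectral
ensemble to ligand pharmacology. This note records the models, the
defaults and why they were chosen, what the synthetic data do and do not
emulate, and the numerical decisions a maintainer would want to know.

## Spectral model

A processed 1D spectrum is modeled as a sum of phased Lorentzian
components on a constant baseline:

    S(δ) = b + Σᵢ [cos φᵢ · Aᵢ(δ) + sin φᵢ · Dᵢ(δ)] + ε,

where `Aᵢ` and `Dᵢ` are the absorptive and dispersive Lorentzians of
component *i* with center δᵢ (ppm), full width at half maximum wᵢ (ppm)
and area aᵢ (intensity·ppm), and ε is iid Gaussian noise. Each
long-lived conformational sub-ensemble (lifetime ≳ ms) contributes one
component; its area is the sub-ensemble population and, absent exchange
broadening, its width obeys FWHM(Hz) = R₂/π. Hz per ppm equals the
spectrometer ¹⁹F frequency in MHz (default 658.8462650 MHz); "upfield"
means more negative ppm, drawn rightward.

Phases are constrained to a shared global phase ±π/50 rad per
component. This reflects how processed spectra behave: phasing is
uniform across a narrow spectral window up to small errors, and leaving
per-peak phases fully free lets dispersive tails absorb overlap
ambiguity.

### Chemical exchange

Exchange among N sites is simulated with the Bloch–McConnell steady-state
lineshape

    S(ω) ∝ −Re[ 1ᵀ (iΔΩ(ω) − R₂ + K)⁻¹ p ],

with ΔΩ the site offsets in rad/s, R₂ the diagonal matrix of transverse
rates, K the first-order rate matrix (columns sum to zero, K·p = 0 at the
stationary populations p). The implementation is a batched complex solve
over the frequency grid. A hand-expanded scalar formula for the two-site
case lives alongside it as an independent code path; the two agree to
better than 1e-6 relative across slow, intermediate and fast regimes,
and the integrated intensity is invariant to the exchange rate within 1%
(conservation of magnetization). Two-site models are parameterized by
k_ex = k_AB + k_BA with detailed balance k_AB·p_A = k_BA·p_B.

## Axis calibration

Shifts are calibrated against an internal reference signal in a coaxial
channel (KF, defined shift −119.522 ppm at 298.2 K). The reference peak
is located near its nominal position as a local maximum at least 5× the
robust noise, refined by parabolic interpolation, and the whole axis is
offset so the reference lands exactly on its defined shift. The applied
offset is recorded in metadata; calibration is additive, so every other
shift moves by the same amount.

## Objective deconvolution

For n = 1..max_peaks the mixture is fit by bounded nonlinear least
squares (`scipy.optimize.least_squares`, trust-region reflective, with an
analytic Jacobian). Constraints: areas ≥ 0; FWHM between 2 grid steps
(prevents delta-spike degeneracy) and half the window; per-peak phase
within ±π/50 of the global phase; centers inside the window.
Initialization picks local maxima of the lightly smoothed spectrum above
3× noise; multistart (default 5, with jittered centers) guards against
local minima. In the model-selection loop each n > 1 additionally warm
starts from the (n−1)-peak solution plus a peak at its largest residual,
which makes the nested-model residual sum of squares non-increasing in n
by construction.

The component count is chosen by an information criterion computed from
the Gaussian log-likelihood at an *independently estimated* noise level
(median absolute deviation × 1.4826 in a signal-free window, or a
first-difference estimate when no window is given). BIC is the default
because it is conservative on component count for the long spectra used
here (N points ≫ parameters); AIC/AICc are selectable. Ties break toward
fewer peaks. A fitted peak within 0.05 ppm of the known free-BTFA
position (−83.3 ppm) and narrower than 0.05 ppm can be auto-flagged as
the contaminant so ensemble metrics exclude it.

Measured operating characteristics (frozen in the test suite, 100 seeds
per scenario on a 1024-point, 2-ppm grid): ≥95% correct selection for a
single peak at SNR 50, for two peaks 3×FWHM apart at SNR 30, and for the
parsimonious 1-peak reading of an unresolvable doublet (FWHM/10 apart,
SNR 10); centers within 0.005 ppm and areas within 5% where the count is
correct. A doublet a tenth of a linewidth apart is below the resolution
limit of any lineshape analysis — selecting one peak there is the
documented intended behavior, not a failure.

## Ensemble metrics

* **Mean-weighted shift**: Σaᵢδᵢ/Σaᵢ over all non-contaminant fitted
  peaks. Sub-5% minor peaks are included; the >5%-area rule applies only
  to the FWHM scatter map. Both toggles are exposed.
* **Major peaks**: strictly greater than 5% of the non-contaminant area.
* **Cluster map**: the (shift, FWHM) scatter of major peaks across
  conditions is density-estimated with a diagonal Gaussian kernel
  (Silverman bandwidth per dimension, σᵢ·n^(−1/6), override supported)
  and clustered by watershed on the density grid. Two denoising rules:
  modes below 5% of the global maximum are absorbed, and a mode whose
  relative prominence ((peak − saddle)/peak) is under 0.25 is merged
  into its neighbor. The prominence rule is needed because a finite
  sample from one cluster produces shallow spurious KDE modes
  (measured: spurious modes of a 40-point Gaussian blob have prominence
  ≲ 0.16, genuinely separated clusters ≈ 0.9, so 0.25 separates the
  regimes with margin).
* **Region fractions**: peak areas are aggregated over a user-configured
  partition of the window (default four regions with the middle cuts
  bracketing the two apo peak positions, since the region boxes of the
  reference analysis are drawn graphically rather than enumerated). A
  peak centered exactly on a boundary belongs to the upfield (more
  negative) region.
* **D₂O exposure**: a least-squares line through Δδ vs %D₂O classifies
  the probe as solvent-exposed (upfield drift ≥ 0.08 ppm per 100% D₂O),
  protected/interacting (downfield drift), or protected. The threshold
  sits between the observed free-tag drift (~0.115 ppm upfield) and
  buried-probe behavior.

## Saturation-transfer kinetics

With the exchange partner saturated completely and instantaneously, the
observed peak decays as

    I(t)/I₀ = R₁/(R₁+k) + k/(R₁+k) · exp(−(R₁+k)t),

the standard two-site Forsén–Hoffman form. R₁ is fixed from an
inversion-recovery fit (defaults 2.7 s⁻¹, per-condition override such as
2.4 s⁻¹) and I₀ from the off-resonance control series, so k is the single
free parameter. The 95% CI is the F-statistic profile of the
one-parameter residual sum of squares. A fit whose CI reaches 0 is
flagged below detectability; the design-based detectability floor is the
smallest k whose steady-state depletion k/(R₁+k) exceeds z·noise (z = 3),
about 0.17 s⁻¹ at 2% noise and R₁ = 2.7 s⁻¹ — consistent with rates
below ~0.4 s⁻¹ being hard to measure in practice. Partial saturation and
B₁-field modeling are out of scope (hardware-dependent).

CEST-style offset profiles use the partner's normalized Lorentzian as the
saturation efficiency, so the depletion profile mirrors the partner
resonance and is identically 1 at zero exchange.

## Pharmacology

* **4PL**: variable-slope logistic fit with multistart on log EC₅₀ and
  asymptotic CIs. A concentration mask reproduces analyses that drop the
  top concentrations of biphasic curves; no automatic biphasic detection.
* **ROUT outliers**: robust Lorentzian-loss 4PL (multistart including a
  leave-worst-point-out start; candidates compared by trimmed SSR, which
  resists fits that absorb an outlier at a curve extreme), residual scale
  RSDR = P68.27(|residuals|)·N/(N−K), then FDR step-up on t-tail
  probabilities at rate Q (default 1%, the common software default).
  When the measurement sd is known — as in designed simulation studies —
  it can be supplied directly and replaces both the loss scale and RSDR;
  with known sd the procedure flags ≤2% of clean 12-point curves and
  catches a single 10σ outlier ≥95% of the time (measured over three
  independent 100-seed batches). With RSDR estimated from only 12 points
  the operating characteristics are a few points worse; that is a
  small-sample property of the scale estimate, not of the FDR step.
  Flagged points are reported, never silently dropped.
* **Competitive binding**: the forward model solves the exact
  three-species mass-action equilibrium (bracketed root solve to ~1e-12
  relative; no logistic approximation). Two IC₅₀→Kᵢ routes are provided.
  `ki_from_ic50` is the totals-based corrected Cheng–Prusoff closed form

      Kᵢ = Lb·IC₅₀·K_d / [Lo·Ro + Lb(Ro − Lo + Lb − K_d)],

  with Lb computed from the two-species quadratic by default (a measured
  Lb can be supplied). `ki_from_ic50_exact` inverts the equilibrium
  exactly via the free-species bookkeeping at half displacement. These
  disagree whenever tracer or competitor depletion is appreciable: with
  Lb from the quadratic the closed form's denominator reduces
  algebraically to 2·Lb·Ro (so it is IC₅₀·K_d/(2·Ro) in disguise), and
  against the exact forward model it errs by ~+11–15% at the default
  assay constants (Lo = 5 nM, Ro = 8 nM, K_d = 7.9 nM) and far more at
  tight Kᵢ or large K_d, while the exact inversion recovers the true Kᵢ
  to numerical precision. Both are kept: the closed form for
  comparability with assay-kit workflows, the exact inversion for
  correctness. The test suite pins this divergence rather than hiding it.
* **Occupancy**: the two-species quadratic at NMR sample composition
  (default analogues: 150 µM protein, 1.25× ligand) gives fractional
  occupancy and the free-ligand concentration at which endpoint responses
  are read off fitted curves; if a curve fit failed, the measured point
  nearest in log-concentration is substituted and flagged.
* **Structure–function correlation**: ordinary least squares of a
  functional endpoint on mean-weighted shift; R² is the squared Pearson
  correlation.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:
class-templated ensembles (full agonists: one narrow upfield peak near
−84.2 ppm; apo/partial agonists/antagonists: two broad peaks;
inverse agonists: a narrow downfield peak plus a broad one), a sharp
free-BTFA contaminant at −83.3 ppm, a miscalibrated KF reference channel
(random offset up to ±0.15 ppm), exchange rates of 0.3–1.4 s⁻¹ linked to
ligand class, R₁ ≈ 2.4–2.7 s⁻¹, 12-point 3-fold serial dilutions from
50 µM with occasional ≥10σ outliers, and class-linked
coactivator/corepressor endpoints. Default noise: sd 0.01 on spectra
(≈SNR 50–500 depending on linewidth), 2% on series and plates — typical
of well-averaged ¹⁹F spectra and plate assays.

Not emulated: time-domain acquisition and apodization, field
inhomogeneity, baseline roll, temperature drift, intermediate-exchange
distortions of the *static* templates (exchange-broadened spectra are
available separately via the Bloch–McConnell simulator), partial
saturation, plate-position effects, and ligand aggregation artifacts
beyond the gross-outlier mechanism. Passing recovery tests therefore
demonstrates correctness of the estimators under the stated noise model,
not robustness to every instrumental artifact of real spectra.

Default grid: 16384 points over −80 to −88 ppm, resolving 0.01-ppm
linewidths. The test suite and bundled study run on 1024–2048-point
grids over 2–5-ppm windows — still ≥25 points per linewidth for every
simulated peak — so the full suite completes in minutes on one CPU; the
statistical operating characteristics quoted above were measured at
those sizes.

## Reproducibility

Every stochastic generator takes an explicit seed and is bit-for-bit
reproducible under it; the pipeline refuses to run without one. Run
artifacts carry the config hash, seed and package version, and rerunning
a config yields byte-identical CSVs for deterministic stages.

## Known limitations

* Lineshape fitting assumes pure Lorentzians; intermediate exchange and
  field inhomogeneity bias fitted widths and areas, and no correction is
  applied.
* The saturation-transfer model assumes complete, instantaneous
  saturation of the irradiated site and two-site topology.
* Cluster counts from ~16 conditions are sensitive to bandwidth; no
  uncertainty on the cluster count is reported.
* The totals-based closed-form Kᵢ is biased under depletion, as
  quantified above; use the exact inversion when constants place the
  assay in that regime.
* JCAMP-DX support is read-only and limited to AFFN `XYDATA` blocks.
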