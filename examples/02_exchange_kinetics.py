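"""Estimate a slow conformational exchange rate from saturation transfer.

Saturating one resonance depletes its exchange partner at a rate set by
the conformational interconversion rate k (given the independently
measured R1). The fit has a single free parameter; the 95% CI comes from
the F-profile of the residual sum of squares.
"""

import numpy as np

import fluorens as fl

R1 = 2.7  # s^-1, fixed from an inversion-recovery measurement
K_TRUE = 1.2  # s^-1, a typical slow helix-12 interconversion rate

times = np.linspace(0.0, 1.6, 12)
series = fl.simulate_saturation_series(R1, K_TRUE, i0=1.0, times=times,
                                       noise_sd=0.02, seed=3)
fit = fl.fit_saturation_transfer(series)
print(f"true k = {K_TRUE} /s; fitted k = {fit.k:.2f} /s "
      f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f})")

limit = fl.detectability_limit(R1, noise_fraction=0.02)
print(f"detectability floor at 2% noise: k ≈ {limit:.2f} /s "
      "(slower exchange leaves too little steady-state depletion to see)")

# CEST profile: scanning the saturation offset maps out the partner peak
model = fl.ExchangeModel.two_site(-83.6, -84.2, 80.0, 80.0, p_a=0.7,
                                  k_ex=K_TRUE / 0.3, r1=R1)
offsets = np.linspace(-84.5, -83.9, 7)
profile = fl.cest_profile(model, observed_site=0, saturation_offsets=offsets)
for o, v in zip(offsets, profile):
    print(f"  saturate at {o:.2f} ppm -> observed peak at {v:.3f} of I0")
print("The dip mirrors the partner resonance: its minimum sits at the "
      "partner's chemical shift, direct evidence the two peaks exchange.")

# relaxation fits supply the fixed R1 and the T2 linewidth check
ir = fl.simulate_relaxation_series("inversion_recovery", R1, 1.0,
                                   np.linspace(0.01, 2.5, 10))
print(f"\ninversion-recovery refit of R1: {fl.fit_relaxation(ir).rate:.3f} /s")
fwhm_hz, pred_hz, ratio = fl.linewidth_consistency(0.0483, 658.8462650, 0.01)
print(f"linewidth check: fitted {fwhm_hz:.1f} Hz vs 1/(pi*T2) = {pred_hz:.1f} Hz "
      f"(ratio {ratio:.2f}; ~1 means no extra exchange broadening)")
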