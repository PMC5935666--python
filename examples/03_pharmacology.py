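"""Plate-assay calculations: 4PL, outlier screening, Ki, and occupancy.

A competitive tracer-displacement assay (Lo = 5 nM tracer, Ro = 8 nM
receptor, tracer Kd = 7.9 nM) is simulated at exact mass action, the
IC50 read off, and converted to an inhibitor constant two ways.
"""

import numpy as np

import fluorens as fl
from fluorens.pharmacology import CompetitionAssay, ki_from_ic50_exact
from fluorens.synthetic import serial_dilution

LO, RO, KD = 5e-9, 8e-9, 7.9e-9
KI_TRUE = 50e-9

lb0 = fl.bound_tracer(LO, RO, KD)
print(f"bound tracer without competitor: Lb = {lb0 * 1e9:.2f} nM")

ic50 = fl.competition_ic50(LO, RO, KD, KI_TRUE)
print(f"true Ki = {KI_TRUE * 1e9:.0f} nM -> IC50 = {ic50 * 1e9:.1f} nM")

assay = CompetitionAssay(lo=LO, ro=RO, kd=KD, ic50=ic50)
print(f"closed-form corrected Cheng-Prusoff: {fl.ki_from_ic50(assay) * 1e9:.1f} nM")
print(f"exact equilibrium inversion:         {ki_from_ic50_exact(assay) * 1e9:.1f} nM")
print("(the closed form drifts when tracer/competitor depletion matters; "
      "the exact inversion recovers the truth — see docs/methods.md)\n")

# dose-response with a gross outlier, screened by ROUT before fitting
concs = serial_dilution(5e-5, 12)
curve = fl.simulate_dose_response(bottom=0.2, top=0.9, ec50=1e-6, hill=1.0,
                                  concentrations=concs, noise_sd=0.02,
                                  n_outliers=1, seed=11)
res = fl.rout_outliers(curve, q=1.0)
fit = res.cleaned_fit
print(f"ROUT flagged {int(res.outlier_flags.sum())} of {len(concs)} points "
      f"(injected: {int(curve.outlier_truth.sum())})")
print(f"cleaned 4PL: EC50 = {fit.ec50 * 1e6:.2f} uM, top = {fit.top:.2f}, "
      f"bottom = {fit.bottom:.2f}, hill = {fit.hill:.2f}")

# are the NMR samples saturated with ligand?
occ = fl.predict_occupancy(ptot=150e-6, ltot=187.5e-6, ki=KI_TRUE)
print(f"\nNMR-sample occupancy at 150 uM protein / 187.5 uM ligand: "
      f"{occ.occupancy:.1%} (free ligand {occ.free_ligand * 1e6:.1f} uM)")
print("Occupancy near 100% means spectra report the ligand-bound ensemble, "
      "not a bound/apo mixture; the free-ligand value is where TR-FRET "
      "endpoints are read off the fitted curve.")
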