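"""Four-parameter logistic fitting: agonist EC50/EC90 and antagonist IC50.

Simulates the standard concentration-response design (12-point, 1:3 serial
dilution from 100 uM, four replicates per concentration, 5% well CV), fits
the 4PL model, and derives the EC90 used to anchor antagonist screens.
"""

import numpy as np

import nachr_hts as nh

grid = 100e-6 / 3.0 ** np.arange(12)  # 100 uM down to ~0.56 nM

# agonist curve at the alpha4beta2 assay's nicotine EC50 (19.44 nM)
true_ec50 = nh.NICOTINE_EC50["A4B2"]
tbl = nh.generate_dose_response(0, 100, true_ec50, hill=1.0, conc_grid=grid,
                                reps=4, cv=0.05, seed=1)
fit = nh.fit_4pl(tbl["conc_M"], tbl["response"], nh.AGONIST)
ec90 = nh.ec90_from_fit(fit)
print("agonist fit (alpha4beta2-like):")
print(f"  EC50 = {fit.ec50 * 1e9:.2f} nM   (true {true_ec50 * 1e9:.2f} nM)")
print(f"  hill = {fit.hill:.2f},  span = {fit.bottom:.1f}..{fit.top:.1f}")
print(f"  EC90 = {ec90 * 1e9:.1f} nM  (= EC50 x 9^(1/hill); anchors the antagonist screen)")

# antagonist curve at the mecamylamine-like IC50 for the same subtype
true_ic50 = nh.MECAMYLAMINE_IC50["A4B2"]
tbl = nh.generate_dose_response(0, 100, true_ic50, hill=1.0, conc_grid=grid,
                                reps=4, cv=0.05, seed=2,
                                direction=nh.ANTAGONIST)
ifit = nh.fit_4pl(tbl["conc_M"], tbl["response"], nh.ANTAGONIST)
print("antagonist fit (mecamylamine-like):")
print(f"  IC50 = {ifit.ec50 * 1e6:.3f} uM  (true {true_ic50 * 1e6:.2f} uM)")
# Reading: the declining-curve convention returns the IC50 (the antagonist
# concentration halving the agonist-evoked signal).
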