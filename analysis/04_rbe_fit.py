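#!/usr/bin/env python
"""Fit the RBE_M-vs-photon-energy calibration quadratic.

Loads the packaged (synthetic stand-in) dicentric calibration table, fits a
weighted quadratic in log10(E), writes the fit report as JSON and checks the
prediction at the 60Co reference energy.
"""

import json
from pathlib import Path

from letfield import rbe

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

points = rbe.load_calibration()
fit = rbe.fit_rbe_curve(points, scale="log10", weighted=True)

report = {
    "coefficients": fit.coefficients.tolist(),
    "covariance": fit.covariance.tolist(),
    "energy_scale": fit.energy_scale,
    "valid_range_MeV": list(fit.valid_range_mev),
    "weighted": fit.weighted,
}
(OUT / "rbe_fit.json").write_text(json.dumps(report, indent=2) + "\n")

c0, c1, c2 = fit.coefficients
print(f"RBE_M(x) = {c0:.3f} + {c1:.3f}·x + {c2:.3f}·x²   (x = log10 E/MeV)")
co60 = rbe.predict_rbem(fit, 1.25)
print(f"prediction at 60Co (1.25 MeV): {co60.value:.3f} ± {co60.std_uncertainty:.3f}")
for e in (0.05, 0.2, 1.0, 5.0):
    p = rbe.predict_rbem(fit, e)
    print(f"  E = {e:5.2f} MeV  RBE_M = {p.value:.2f} ± {p.std_uncertainty:.2f}")
print(f"wrote {OUT / 'rbe_fit.json'}")
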