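# letfield

Restricted-LET analysis of the electron fluence outside small megavoltage
photon fields, with an RBE_M photon-energy calibration.

## The problem

The absorbed dose outside a radiotherapy field edge is routinely assessed,
but biological damage also depends on radiation quality.  Past the edge of
a 6 MV field the photon spectrum softens, the electrons it liberates are
slower, and the ionisation density — measured by the **dose-average
restricted LET** of the electron fluence — rises.  This package computes
that quantity for organs-at-risk-style scoring points around small square
fields (0.7–4.5 cm plus the 10 cm reference) at four water depths, and maps
it to a maximum low-dose relative biological effectiveness (RBE_M, dicentric
chromosome aberrations in human lymphocytes, relative to ⁶⁰Co γ rays)
through a quadratic energy-response calibration.

For an electron fluence spectrum Φ(E) with delta-ray cutoff Δ (default
1 keV):

    L_Δ,T = [ ∫ L_Δ Φ dE + S(Δ)Φ(Δ)Δ ] / [ ∫ Φ dE + Φ(Δ)Δ ]
    L_Δ,D = [ ∫ L_Δ² Φ dE + S(Δ)²Φ(Δ)Δ ] / [ ∫ L_Δ Φ dE + S(Δ)Φ(Δ)Δ ]

where L_Δ and S are the restricted and unrestricted collision stopping
powers of electrons in liquid water (closed Bethe/Møller forms with the
Sternheimer density effect, implemented in `letfield.materials`) and the
S(Δ)Φ(Δ)Δ terms correct for electron track ends.

Because the original Monte Carlo fluence spectra are not publicly
deposited, the package ships two data routes:

* a transcription of the published LET/RBE_M tables (180 geometry points)
  with loaders and summary statistics (`letfield.pipeline`);
* a deterministic synthetic beam emulator — depth-hardened, edge-softened
  6 MV-like photon spectra, Klein–Nishina Compton electron sources, and
  slowing-down fluences with Møller knock-on secondaries iterated to
  convergence (`letfield.spectra`) — calibrated to land in the published
  LET bands and reproduce their orderings.

## Worked example

```python
from letfield import materials, moments, spectra, rbe
from letfield.geometry import GeometryPoint

table = materials.build_table(materials.default_energy_grid(), delta_kev=1.0)
beam = spectra.PhotonBeamModel()                      # default 6 MV-like beam

centre = GeometryPoint(2.7, 1.35, 0.0)                # 2.7 cm field, depth of max dose
outside = GeometryPoint(2.7, 1.35, 3.35)              # 2 cm past the field edge

for name, geom in [("centre ", centre), ("edge+2 ", outside)]:
    tef, se = spectra.generate_case(geom, beam, table)
    print(name,
          f"TEF L_D = {moments.dose_average_let(tef, table):.2f} keV/um,",
          f"SE L_D = {moments.dose_average_let(se, table):.2f} keV/um")

fit = rbe.fit_rbe_curve(rbe.load_calibration())       # quadratic in log10(E)
photon = spectra.generate_photon_spectrum(outside, beam)
pred = rbe.predict_rbem(fit, rbe.effective_photon_energy(photon))
print(f"RBE_M 2 cm past the edge: {pred.value:.2f} ± {pred.std_uncertainty:.2f}")
```

prints

```
centre  TEF L_D = 2.41 keV/um, SE L_D = 6.85 keV/um
edge+2  TEF L_D = 2.88 keV/um, SE L_D = 7.29 keV/um
RBE_M 2 cm past the edge: 1.58 ± 0.17
```

Reading: the dose-average LET of the total electron fluence rises ~19% from
the beam centre to 2 cm outside the edge at the depth of maximum dose, and
the secondary-electron (knock-on only) fluence is roughly three times more
densely ionising than the total fluence everywhere — the out-of-field
radiation is of measurably "harder" quality even though the dose there is
small.  The RBE_M value uses the packaged *synthetic* calibration table
(see `docs/methods.md`); replace it with measured data for quantitative use.

The numbered drivers under `analysis/` run the full study — stopping-power
tables, spectrum generation, the 180-point LET/RBE table, the calibration
fit, and the out-of-field summary — writing their outputs under `results/`.

## Layout

```
src/letfield/      library: materials, moments, rbe, spectra, pipeline, io
analysis/          numbered study drivers (write to results/)
tests/             pytest suite, including end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    model assumptions, parameter choices, limitations
```
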