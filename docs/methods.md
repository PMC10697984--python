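# Methods

## Problem and quantities

Outside the edge of a megavoltage radiotherapy field the absorbed dose is
small, but the photon spectrum is much softer than on the central axis, so
the electrons it sets in motion are slower and more densely ionising.  Two
scalar beam-quality descriptors capture this: the track-average and the
dose-average restricted LET of the electron fluence spectrum Φ(E),

    L_Δ,T = [ ∫_Δ^Emax L_Δ(E) Φ(E) dE + S(Δ) Φ(Δ) Δ ] / [ ∫_Δ^Emax Φ(E) dE + Φ(Δ) Δ ]
    L_Δ,D = [ ∫_Δ^Emax L_Δ²(E) Φ(E) dE + S(Δ)² Φ(Δ) Δ ] / [ ∫_Δ^Emax L_Δ(E) Φ(E) dE + S(Δ) Φ(Δ) Δ ]

with Δ the delta-ray cutoff (default 1 keV), L_Δ the restricted and S the
unrestricted collision stopping power of electrons in liquid water, and the
S(Δ)Φ(Δ)Δ terms a track-end correction for electrons that fall below Δ and
deposit the remainder locally.  By the Cauchy–Schwarz inequality
L_Δ,D ≥ L_Δ,T for any spectrum, with equality only when the spectrum is
effectively monoenergetic in L_Δ.

Each LET result carries a relative standard uncertainty (default 0.6%,
k = 1), metadata propagated to outputs rather than a computed quantity.

## Stopping powers (`materials`)

S(E) is the Bethe collision stopping power with the Møller close-collision
term in its standard closed form, the Sternheimer density-effect correction
δ(βγ), and radiative losses excluded (LET is collisional by definition).
L_Δ(E) is the matching restricted closed form; for Δ ≥ E/2 the two
indistinguishable outgoing electrons make the restriction vacuous and
L_Δ ≡ S exactly.

Constants for liquid water: I = 75 eV (the value contemporary with the
EGSnrc-era tabulations; newer recommendations are a few eV higher and would
shift S by well under 1%), ρ = 1.0 g/cm³, Z/A = 0.55509, and the standard
published Sternheimer coefficient set (a = 0.09116, m = 3.4773, x0 = 0.24,
x1 = 2.8004, C̄ = 3.5017, δ0 = 0), stored in a data file
(`data/materials.csv`), not hard-coded.  The closed forms reproduce standard
liquid-water tabulations to ~1% over 10 keV–10 MeV, and the identity
S − L_Δ = ∫_Δ^{E/2} W (dΣ/dW) dW against numerical integration of the Møller
cross section holds to better than 0.1% (it is exercised as a test).

Numerical conventions:

* validity floor 1 keV kinetic energy — below it the Bethe formula is
  unreliable and the code raises rather than extrapolates;
* tabulation on 200 log-spaced points from 1 keV to 6.5 MeV by default;
  consumers interpolate log-log linearly (energy off-grid agrees with
  direct evaluation to ≪0.5%);
* units: mass stopping power (MeV·cm²/g) × density × 0.1 = keV/μm;
* the published Sternheimer coefficients leave a residual δ(x0) ≈ 2·10⁻³
  (≈10⁻⁵ relative in S) at the lower breakpoint; at x1 the bridge term
  vanishes identically and S is exactly continuous.

## Moment evaluation (`moments`)

Integrals use the midpoint rule on the spectrum bins, with L_Δ evaluated at
*geometric* bin midpoints through the table interpolation — consistent with
log-spaced binning and the log-log interpolation contract.  Halving the bin
widths of a smooth spectrum moves either moment by <0.2%.

Φ(E) is treated as **particle fluence** differential in energy.  The
alternative reading (energy fluence as the weight) is exposed as
`weighting="energy"` for sensitivity checks, but the dimensional structure
of the moment definitions corresponds to the particle-fluence convention
and that is the default.

Φ(Δ) for the track-end terms is carried as a dedicated field of the
spectrum; if absent, the first bin's density is used and a warning logged.
Both averages are invariant under any positive rescaling of the fluence
(including Φ(Δ)), which is enforced to machine precision in tests.

## RBE_M calibration (`rbe`)

RBE_M (maximum low-dose RBE, relative to ⁶⁰Co γ rays) is calibrated against
photon energy with a degree-2 polynomial.  Design choices:

* default coordinate x = log10(E/MeV), because photon calibration sets span
  orders of magnitude; a linear coordinate is available by flag;
* default inverse-variance weighting by the reported uncertainties, with a
  warned fallback to unweighted when uncertainties are missing; the
  covariance is (XᵀWX)⁻¹ in the weighted (known-σ) case and residual-scaled
  otherwise;
* prediction uncertainty by first-order propagation, var = g Cov gᵀ with
  g = (1, x, x²);
* quadratics diverge outside the data, so predictions beyond the
  calibration range are clamped to the boundary value and flagged as
  extrapolations.

The packaged calibration table is a **synthetic stand-in** (see the header
of `data/synthetic_rbe_calibration.csv`): ten points from 10 keV to 5 MeV
built around a quadratic in log10(E) that passes ≈1.0 at the ⁶⁰Co energy
and rises toward low energies, with uncertainties of the magnitude typical
of dicentric-assay data (±0.3–0.45).  It reproduces the qualitative
energy response of published dicentric RBE_M measurements and is
user-replaceable; any quantitative RBE statement requires substituting
measured data.

The mapping from a geometry point to the calibration axis is the
fluence-weighted mean photon energy of the local spectrum.  This is an
explicit convention of this package — an effective-energy definition — not
a calibrated quantity.

## Synthetic spectra (`spectra`)

The generator replaces a Monte Carlo transport chain with deterministic
quadrature in three stages:

1. **Photon spectrum.**  In-field: φ(k) ∝ k^α e^(−k/θ) truncated at 6 MeV,
   hardened with depth by water attenuation e^(−μ(k)d) (μ from a small
   log-log-interpolated table).  Out-of-field: a scattered component of
   shape k·e^(−2k/⟨k_s⟩) is mixed in with fraction
   w(x) = w0 + (wmax − w0)(1 − e^(−x/λ)) of the total fluence, where x is
   the distance past the field edge.  Defaults: α = −0.5, θ = 0.6 MeV,
   ⟨k_s⟩ = 0.10 MeV, w0 = 0.25, wmax = 0.85, λ = 1.2 cm.
2. **Electron source.**  Klein–Nishina Compton recoil spectrum integrated
   over the photon fluence; Compton scattering dominates electron
   production in water at these energies, so photoelectric and pair
   production are neglected.  The source vanishes above each photon's
   Compton edge 2k²/(m_ec² + 2k).
3. **Slowing-down fluence.**  Equilibrium spectrum Φ(E) = Q(>E)/S(E) with
   Q(>E) the cumulative source above E (continuous-slowing-down picture).
   The total electron fluence (TEF) adds a Møller knock-on source — delta
   rays above Δ generated by the fluence itself — iterated until the
   fluence changes by <0.1% between sweeps (all generations; cap 50
   sweeps).  The secondary-only (SE) fluence is the converged TEF minus the
   primaries-only fluence.  Energy bookkeeping closes to ≈0.02%: the
   dissipated energy ∫ΦS dE plus the track-end residual equals the energy
   injected by all source terms.

**Calibration status.**  The true out-of-field photon spectra behind the
reference tables are not published, so the generator's shape parameters
were set once so that the default configuration lands inside the published
LET bands — in-field TEF dose-average ≈ 2.4 keV/μm, 2 cm past the edge up
to ≈ 2.9 keV/μm, SE ≈ 6.5–7.4 keV/μm at Δ = 1 keV — and reproduces the
qualitative orderings (hardening with depth, softening and rising LET past
the edge, SE > TEF everywhere).  The emulated photon spectra are therefore
*effective*: their in-field mean energy (~0.3 MeV fluence-weighted) is
softer than a real 6 MV in-field spectrum, because a single analytic
component has to stand in for the full scattered-photon build-up that a
transport code produces.  Consequences: LET comparisons are band/ordering
checks, not point reproductions, and RBE_M predictions from the pipeline
are systematically higher in-field (~1.3 vs ~1.08) than a transport-based
effective energy would give.  Passing tests show the moment machinery and
orderings are right, not that the generator reproduces any specific linac.

Contaminant electrons from the accelerator head, which flatten the
out-of-field LET trend very close to the surface, are available as an
optional additive high-energy source at depths ≤ 0.5 cm
(`contaminant_fraction`), off by default.

## Reference tables and summaries (`pipeline`)

The packaged fixture transcribes the published LET/RBE_M tables: 180 rows =
9 square fields (0.7–4.5 cm plus the 10 cm reference) × 5 off-axis
positions (centre, mid, edge, edge+1 cm, edge+2 cm) × 4 depths (0.15, 1.35,
9.85, 19.9 cm; the deepest plane is printed with two labels in the source
and is normalised to 19.9 cm).  Row invariants (dose > track for both
spectra, position label consistent with off-axis distance to 0.01 cm) are
enforced at load time.

`summarize_out_of_field` reports the edge+2 extrema of the dose-average
LET columns, the per-field percent increase of the TEF dose-average from
centre to edge+2, and the ratio of the maximum out-of-field RBE_M to the
minimum in-field RBE_M per depth (in-field reference = minimum over the
centre/mid/edge rows; the prose claim "a factor of two" does not specify
the in-field row, so the minimum is used and documented).  Published prose
percent ranges ("14–21%") are treated as approximate and tested with
explicit tolerances, restricted to the eight small fields where they hold.

## Problem sizes and determinism

The default grids (200 electron energy points, 150 photon bins, 180
geometry points) run the complete pipeline in roughly a second; the
knock-on iteration converges in a handful of sweeps.  Everything in the
default pipeline is deterministic; the only randomness in the package is
the optional noise-injection mode (seeded from the beam model) and the
simulated-noise studies in the tests and acceptance script (seeded
explicitly).

## Known limitations

* No angular or spatial transport: the slowing-down model assumes charged
  particle equilibrium, which genuinely fails at the shallowest depth and
  near field edges; the fixture tables embody that physics, the generator
  does not.
* Only Compton interactions produce primary electrons; bremsstrahlung
  photons from slowing electrons are ignored.
* The Møller knock-on model treats atomic electrons as free (no binding
  correction below a few keV beyond the Bethe validity floor).
* LET excludes radiative losses by definition; no microdosimetric spread
  (lineal-energy distributions) is computed — only the two scalar moments.
* The packaged RBE calibration is synthetic; quantitative RBE work needs
  measured calibration data in its place.
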