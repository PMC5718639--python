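# Methods

This note documents the models, parameter choices and numerical decisions
behind `selectron43`.  It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Source and applicator model

The Selectron pellet is a sphere: a 1.5 mm diameter active ceramic core
(modelled as Al₂O₃ at 3.97 g/cm³) inside a 0.5 mm stainless-steel shell,
2.5 mm overall.  Cs-137 emission is treated as the single 662 keV line,
sampled uniformly over the core volume and isotropically in direction;
emission is normalised per photon, so the extracted Λ and g(r) are
independent of source activity.  Dummy pellets share the active pellet's
geometry and composition.

The vaginal-applicator model is a steel tube of 0.3 cm outer radius along
the z axis with a flat tip cap, containing six touching pellets
(pitch 0.25 cm) whose first centre sits 0.4 cm from the tip; the tube
interior not occupied by pellets is air.  The published work this package
follows takes the applicator and pellet compositions from an external
reference it does not reproduce, so the wall material (stainless steel,
iron cross-sections), wall/cap thickness (0.025 cm) and interior medium
(air) are package assumptions, configurable in `ApplicatorConfig`.
Consequently the applicator-enabled dose-rate constant and per-position
anisotropy are validated as band/sign checks (Λ within a stated band;
F < 1 toward the tip), not as point comparisons.

## TG-43 engine

* **Reference point** r₀ = 1 cm, θ₀ = 90°; θ = 0° points from the pellet
  centre toward the applicator tip, used consistently by the train module.
* **Geometry function**: point model `r⁻²` (the packaged g(r) tables are
  point-source tables) or line model `β/(L·r·sinθ)` with the axial branch
  `(r² − L²/4)⁻¹`.  The active core is spherical, so the line-source active
  length is a modelling choice: the default L = 0.15 cm equals the core
  diameter.  Within ~10⁻⁷·r of the axis the subtended-angle form loses all
  significant digits to cancellation and the axial closed form is used.
* **Interpolation**: linear in r for g(r) (exactly hand-checkable on the
  sparse printed grids; log-linear is indistinguishable at this grid
  density), bilinear (linear in θ, then linear in r) for F(r, θ).  Missing
  table cells are stored as explicit NaN by the loader and bridged by the
  interpolator, never imputed in the fixtures.
* **Extrapolation policy**: F clamps to the nearest measured angle and
  radius (conservative where the measured grid stops at 15°/165°); g raises
  a range error outside its grid unless linear extrapolation is explicitly
  enabled.  Datasets without an anisotropy grid (the spherically symmetric
  bare pellet, and the per-position Monte Carlo fixtures whose anisotropy
  was published only graphically) are treated as isotropic, F ≡ 1.
* **Validity floor**: r > 0.2 cm.  Closer to the source electronic
  equilibrium fails for 662 keV photons and collision kerma no longer
  approximates dose, so the engine refuses the evaluation.

The inverse operations (`derive_g_from_transverse_profile`,
`derive_F_from_grid`) invert the formalism exactly; forward→inverse round
trips reproduce source tables to 10⁻¹² relative, which the suite asserts.

## Pellet-train superposition

Total dose is the sum of single-pellet TG-43 evaluations.  `naive` mode
uses the bare dataset for every active pellet (TPS behaviour); `aware` mode
maps each active position to its in-applicator dataset (positions beyond 6
reuse position 6 and are flagged in the result provenance).  No pairwise
shadowing between simultaneously active pellets is modelled: the aware mode
carries exactly the single-active-pellet attenuation, and configurations
with many active pellets genuinely require full transport.  Points inside
any pellet's validity floor are flagged per point (NaN) rather than failing
the batch.  The overestimation summary reports
(naive − aware)/aware × 100% separately over axial (|y| ≤ tol) and
transverse points.

## Monte Carlo kerma simulator

Analog photon transport with a track-length collision-kerma estimator:

* **Geometry**: nested analytic spheres (core, capsule, phantom) for the
  bare source — ray-sphere intersections are exact; Woodcock delta tracking
  when the applicator is enabled, with the steel coefficient as majorant
  (steel dominates every involved medium at all tabulated energies, and
  log-log interpolation preserves nodewise dominance), avoiding
  cylinder/sphere intersection edge cases entirely.
* **Phantoms**: 30 cm radius water sphere (full scatter at the tally radii);
  200 cm radius air sphere for the source-strength run.
* **Cross-sections**: total attenuation and mass energy-absorption
  coefficients for water, air, iron (stainless-steel proxy — AISI 316 is
  about two-thirds iron with Cr/Ni bracketing Fe in Z) and Al₂O₃
  (mass-fraction mix of elemental Al and O tables), transcribed from the
  standard NIST compilations on the 17-point reference grid
  0.01–1 MeV and interpolated log-log.
* **Interaction sampling**: the Compton probability is the free-electron
  Klein–Nishina cross-section (exact closed form, Kahn composition-
  rejection sampling) over the tabulated total.  The non-Compton remainder
  is photoelectric absorption below 0.3 MeV; above 0.3 MeV — where true
  photoelectric absorption in these media is negligible and the remainder
  is essentially Rayleigh plus binding corrections — it is treated as
  coherent forward transmission.  Known biases of this scheme: electron
  binding is ignored (KN overestimates scattering below ~50 keV, partly
  compensated by the cutoff), and coherent angular deflection is dropped.
  At 662 keV in water these effects perturb dose well under 1%.
* **Cutoff**: histories terminate below δ = 10 keV (configurable ≥ 1 keV);
  residual energy is not transported, consistent with the kerma
  approximation.  No electron transport: collision kerma ≈ dose for
  r > 2 mm, which is why the engine's validity floor exists.
* **Tallies**: per segment, the analytic chord length inside each thin
  spherical shell weights E·(μ_en/ρ)(E); shells of 0.05 cm thickness sit at
  the printed table radii.  For applicator runs the tally is 2-D
  (shell × 15° polar bin, full azimuth — the geometry is axisymmetric);
  each chord is assigned to the θ bin of its midpoint, exact in the
  thin-shell limit and a documented approximation for grazing chords.
  Cells that intersect the applicator are masked.  Errors are standard
  errors over 20 independent batches.
* **Air-kerma strength**: K(d)·d² is tallied from 50 to 150 cm in air
  (10 keV cutoff) and a per-batch log-linear fit is extrapolated to d = 0,
  where both the air attenuation and the scatter build-up vanish — the
  free-space plateau.  A diagnostic flags slopes inconsistent with air
  attenuation.
* **Units**: 1 U = 1 μGy·m²·h⁻¹ = 1 cGy·cm²·h⁻¹, so Λ in cGy·h⁻¹·U⁻¹ is
  numerically K_water(1 cm)/[K_air·d²] with both tallies in MeV/g per
  photon; the MeV/g → cGy constant (1.602×10⁻⁸) cancels.

**Problem sizes.**  The package's default run is 2×10⁷ water histories plus
5×10⁶ air histories (about five minutes on one core, vectorised NumPy),
which puts sub-0.1% statistical errors on the transverse-axis quantities —
small against the ~1% physics-approximation envelope of the simplified
interaction model.  The applicator (Woodcock) runs used by the test suite
are 2×10⁵ histories: the azimuthal ring tally makes the 90° cells good to
well under 1% there, while near-axis cells carry few-percent errors,
appropriate for the sign/band checks they feed.  Larger run sizes for
convergence studies are a config field, not a code change.

## TLD reduction

Ḋ(r, θ)/Sk = R·chip_factor / (T·Sk·ε·E(r)·d(T)·F_lin).  The published
equation is typeset without the division bar between the response terms and
the correction product; this implementation places every correction factor
in the denominator, which reproduces the stated units (ε in nC/cGy) and the
unity-correction behaviour the accompanying text describes.  E(r), d(T) and
F_lin default to 1 (Cs-137 calibration beam, 30 y half-life, 10–100 cGy
linear range); since E(r) = 1 here its numerator-vs-denominator placement
is untestable and simply documented.  Readings whose implied dose leaves the
linear range with F_lin = 1 trigger a warning, not an error.  Source
strength decays as Sk₀·2^(−t/T½), T½ = 30 y.  Chip sensitivity factors are
accepted as given; a helper derives them as group-mean/chip response ratios
from a co-irradiation table.  No Plexiglas→water medium conversion is
applied when comparing a measured constant against water values, mirroring
the direct comparison made in the source study.

## Synthetic data

The TLD generator inverts the reduction formula against a ground-truth
dataset: expected charge = Ḋ·Sk·T·ε·corrections/chip_factor, with
multiplicative lognormal reading noise (unit mean, stated CV — responses
are positive) and per-chip lognormal sensitivity factors drawn once and
recorded.  Defaults (3% reading CV, 5% chip spread) reproduce the scale of
the quoted measurement uncertainty (±0.08 on Λ ≈ 1.09).  The shell-tally
generator emulates simulator output without transport: means are forward
point-source values, relative errors follow c(r)/√N with c(r) linear in r
through the published anchors (0.3% at 1 cm and 1.5% at 5 cm for a
1.6×10⁸-history run).

What the generators deliberately do **not** emulate: TLD fading, annealing
and reader drift; energy-spectrum changes with depth (E(r) ≠ 1); correlated
shell-to-shell Monte Carlo errors.  Pipeline tests on synthetic data
therefore demonstrate correctness of the *reduction and inversion
arithmetic* and its statistical behaviour under the assumed noise model,
not robustness to those physical effects.

## Dataset fixtures

One sectioned text file per configuration (`[meta]`, `[radial]`,
`[anisotropy]`), diff-able against the printed tables they transcribe;
missing printed cells are explicit `-` tokens.  Validation enforces
g(1 cm) = 1 and F(r, 90°) = 1 exactly, positivity and strictly increasing
grids.  Known transcription decisions: the truncated 75° anisotropy row
(three printed values) is stored at r = 2, 3 and 5 cm with 1 and 7 cm
missing; Λ for positions 2–6 was not published and the position-1 value
1.095 is reused with a provenance note; the measured dataset (position 1,
TLD) reuses the position-1 Monte Carlo g(r) column because no measured
g table was published, also flagged in its provenance.

## Known limitations

* Interaction physics is deliberately minimal (no coherent deflection, no
  binding, no fluorescence, no electron transport); agreement with
  full-transport reference values is expected at the ~1% level on the
  transverse axis, not at the per-mille level.
* The applicator geometry (wall thickness, interior medium, tip shape) is
  an assumption; applicator-enabled quantities are qualitative.
* Near-axis anisotropy from the simulator at desk-scale history counts has
  few-percent statistical errors; resolving per-position F curves at
  publication precision requires two to three orders of magnitude more
  histories (a config change, at commensurate runtime).
* The superposition module cannot model mutual shadowing of several
  simultaneously active pellets.
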