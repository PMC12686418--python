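# Methods

This note documents the physics model, the numerical choices and the
limits of validity of the `ioert` package.

## Transport model

Electrons are transported in the condensed-history approximation:

* **Energy loss.** Collision stopping powers come from bundled smooth
  ESTAR-style tables per material (water, air, soft tissue, lung, compact
  bone, copper, titanium, aluminium) on a common 0.1–15 MeV grid,
  interpolated log–log and scaled linearly with density.  The radiative
  fraction S_rad/(S_col+S_rad) is interpolated the same way; radiative
  losses are removed from the electron but **not transported as photons**.
  This is the model's main fidelity limit: at 6–12 MeV the bremsstrahlung
  yield in water is a few percent, so in-field dosimetry is barely
  affected, but far out-of-field dose (which in reality is mostly photon
  leakage) is underestimated by orders of magnitude.
* **Elastic scattering.** One Gaussian deflection per step with the
  Highland width
  σ_θ = 13.6 MeV/(βcp) · √(t/X₀) · (1 + 0.038 ln(t/X₀)), floored at zero,
  applied after moving along the pre-scatter direction.
* **Stepping.** Step length ≤ `max_step` (default 1 mm, matching the
  default 1 mm voxel pitch) and never beyond the current voxel boundary.
  Below `energy_cutoff` (default 0.2 MeV, residual range ≲ 0.5 mm in
  water) the remaining energy is deposited locally.  Voxels use half-open
  intervals [iΔ, (i+1)Δ); z = 0 at the phantom entrance, beam along +z,
  inplane = x, crossplane = y.
* **Scoring.** Per-voxel deposited energy (float64) and per-voxel count of
  distinct electron entries (an electron entering a voxel increments its
  count once, matching the entries-based uncertainty model
  σ_rel = 1/√n; voxels never entered are flagged NaN, not zero).
  Every run satisfies the bookkeeping identity
  injected = phantom deposit + radiative + escaped + machine losses to
  better than 10⁻⁶ relative, checked in the tests.

Two scalar calibration factors stand in for physics the desk-scale model
does not track:

* `ms_scale` (default **1.70**) multiplies the Highland width inside the
  phantom, compensating the missing Molière large-angle tail and secondary
  electron transport;
* `energy_straggling` (default **0.11**) is the fractional width of a
  per-history stopping-power scale factor (clipped to [0.5, 1.5]), an
  unbiased surrogate for range straggling (Landau fluctuations and δ-ray
  production are not modelled).

Both were fixed **once**, against the reference depths of maximum below,
and are not tuned per run.  The per-history factor correlates all deposits
of one track, which inflates the variance of point-dose estimates by
roughly two; for pure ratio quantities (output factors) it cancels in the
mean and may be disabled to reduce variance without bias.

## Machine head and calibration

The true accelerator head is vendor-proprietary, so the default
`MachineStack` is a **calibration stand-in**: 0.05 mm titanium exit
window, 0.06 mm copper primary foil, 1.0 mm aluminium secondary foil
(density adjustable via `ssf_density`), 40 mm and 30 mm absorbing
apertures, and a 20 cm absorbing-walled cylindrical applicator ending at
SSD = 500 mm.  The applicator bevel (0°/15°/30°) tilts the exit plane;
walls absorb (no wall scatter).  The free thicknesses plus the two kernel
factors were calibrated once so that the default 6 and 9 MeV sources
(7.2 ± 0.7 and 9.8 ± 0.9 MeV, 1.6 mm spot FWHM, no divergence) place the
central-axis dose maximum at the reference depths 13 mm and 18 mm in
water.  The calibration was verified over six independent seeds at
3×10⁶ histories.  The 12 MeV beam's maximum comes out deeper than its
22 mm reference value under the same global calibration — a known limit
of using one energy-independent scattering scale; 12 mm-depth quantities
are therefore not used as anchors anywhere.

The source spectrum is Normal(Ē, σ_E) truncated at E > 0 (resampling);
the spot is an equal-width circular 2D Gaussian with
σ = FWHM/(2√(2 ln 2)); divergence is a Gaussian half-angle about +z.

## Curves, z_max and output factors

PDDs are extracted with a 1×6×6 mm³ = 36 mm³ parallel-plate-like volume
(thin axis along depth) and profiles with a 1×3×6 mm³ = 18 mm³ diode-like
volume (thin axis along the scan), averaging voxel energies over the
footprint; both extractors equal a brute-force voxel-loop oracle exactly.
`find_zmax` is the argmax with ties toward the smaller depth; an optional
moving-average smoothing (default 3 points, 11 used wherever engine noise
matters, because the physical maximum is a broad dome) stabilizes it.
Normalization for gamma comparisons is noise-robust: depth curves scale by
the smoothed maximum, profiles by the central flat-region mean — a raw
noisy spike would otherwise bias every point of the curve.

Measurement-grid resampling reproduces the commissioning sampling: 1 mm
everywhere except the central flat region of profiles (|x| ≤ 0.35 × field
diameter), sampled at 4 mm and linearly interpolated back to 2 mm, and
PDDs beyond the build-up (past z_max), sampled at 2 mm.

Output factors divide central-axis scoring-volume doses at the nominal
energy's **frozen** reference z_max (13/18/22 mm); the uncertainty is the
quadrature sum of the entries-based relative σ of numerator and
denominator.  A single-voxel readout mode is retained for comparison.
The air-gap factor OF_air-gap uses the same machinery with the phantom
surface shifted downstream of the applicator exit.

## Gamma analysis

1D global gamma: for each reference point the minimum of
√(Δr²/3mm² + ΔD²/(3% · max(reference))²) over the evaluated curve,
linearly interpolated on a 0.1 mm lattice anchored at the evaluated
curve's first position, within a ±3·DTA window (both configurable).  The
lattice anchoring makes a tighter window search an exact subset of a wider
one (monotonicity under shrinking tolerances holds to machine precision)
and lets a dense-grid brute-force oracle match the implementation to
1×10⁻⁶.  γ ≤ 1 passes; the boundary counts as passing; no low-dose
threshold by default.

## Source tuning

The commissioning loop alternates two exhaustive, gamma-gated grid
searches: (Ē, σ_E) against the PDD (default steps 0.05/0.01 MeV, box
±1/±0.3 MeV around the vendor values) and (spot FWHM, divergence) against
both profiles (0.5–8 mm by 0.1 mm; 0–5° by 0.5°), gated at 90% during
stages and 95% for final acceptance, up to `max_iterations` outer rounds.
Candidates are evaluated in **rings of increasing parameter change**; the
first ring containing a passing candidate wins (highest pass rate inside
the ring, ties lexicographic), so an already-passing starting point is
returned unchanged.  Each candidate gets a deterministic seed derived
from its index and every engine invocation is logged, making a tuning run
exactly reproducible.  Identifiability is physically weak for the
geometric parameters under large applicators (the foil system dominates
the penumbra), which is why the ring order — "change nothing that the
gamma gate cannot distinguish" — is the documented tie-break.

## Phase space

Records (type code, E, x, y, u, v, w, weight; float32) are captured on a
plane beneath the collimation system; the transport layer is split at the
plane so the recorded state is exactly the transported state there.
Replay renormalizes the float32 directions and feeds the records through
the remaining geometry.  The binary format is a 64-byte little-endian
header (magic, version, count, plane z) plus fixed 36-byte records, with
a CSV debug dialect; roundtrips are bit-identical.

## Thorax phantom and organ doses

The female thorax phantom is MIRD-style: geometric primitives
(ellipsoids, elliptic cylinders, shells, boxes) with organ-wise materials,
voxelized deterministically at 2 mm default pitch by voxel-centre test;
overlaps resolve by claim order (earlier wins) and the residual envelope
organs (Trunk, Head, Legs) take whatever their envelope has left.  The
left breast is remodelled as a flattened post-resection target bed
(z ≲ 24 mm under the applicator) so the beam range spans it, with the
8 cm copper shielding disk defaulting to 1 cm thickness directly beneath
(the literal reading of the ambiguous "which is 1 cm thick" description —
configurable).  Organ masses use the analytic primitive volume × density;
residual organs use their voxel count.  Distant organs exist so every row
of a standard MIRD relative-dose table has a home, not for accuracy.

Mean doses are D = E/m (1 MeV = 1.602176634×10⁻¹³ J), reported relative
to the left breast (the reference row is 100% by definition) with
entries-based relative uncertainties, and scaled to absolute mGy by the
21 Gy prescription.  The misalignment study runs paired simulations
(identical seed and configuration, disk present/absent) and reports the
per-organ deltas.  Because photons are not transported, organs outside
the electron range receive (correctly for this model) zero simulated
dose; published relative-dose tables are therefore treated as *inputs* to
the prescription-scaling arithmetic, not as quantities this engine can
reproduce.

## Synthetic commissioning data

`generate_reference_set` runs the engine at the requested truth
parameters, extracts and normalizes the three curves, resamples them to
the measurement grid and adds independent multiplicative Gaussian noise
of 2.1% (the aggregate experimental uncertainty level; no correlated-noise
model is attempted since only an aggregate figure is available).  Every
artifact carries a provenance record (truth, seed, noise, histories) and
regenerates bit-identically from it.  `generate_parametric_pdd` is an
engine-free fixture (quadratic build-up joined to a logistic falloff)
whose only contractual properties are: value 100 exactly at z_max, 50 at
R50, monotone beyond the maximum.  The film-image generator produces a
radially symmetric double-Gaussian fluence map (core at the configured
FWHM plus a broad scattered halo) tagged with the 18 mm acquisition
depth of the 9 MeV film setup.

## Problem sizes and statistics

Default test and acceptance runs use desk-scale statistics chosen so the
quantity of interest resolves cleanly: 2–3×10⁶ histories for z_max
(smoothed argmax stable to ±1 voxel), ~10⁷ per arm for air-gap output
factors (the OF's effective per-arm σ is ≈1–2%, dominated by per-track
correlation rather than raw entry counts), 10⁵–10⁶ for curve-level gamma
work, and 1–3×10⁵ on a 4–5 mm thorax grid for organ-dose comparisons.
The water phantom defaults to 30×30×30 cm³ at 1 mm (the voxel count is
always derived from dims × spacing); tests use smaller tanks that still
contain the full field and build-up/falloff.

## What passing tests do and do not show

The synthetic generator emulates the *statistical structure* of
commissioning data (sampling grids, detector-volume averaging, aggregate
noise), not real measurements: parameter-recovery results demonstrate the
tuning machinery is correct and reproducible, not that the stand-in
geometry matches any physical accelerator.  Quantities that depend only
on the pipeline's arithmetic (prescription scaling, gamma identities,
output-factor identities, file formats) transfer directly to real data;
quantities that depend on the head geometry (absolute OF values, 12 MeV
depth dose, organ-dose magnitudes) do not.
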