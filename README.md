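# ioert — desk-scale Monte Carlo dosimetry for intraoperative electron radiotherapy

Breast IOERT delivers a single large electron dose (typically 21 Gy
prescribed at the central-axis depth of maximum, z_max) to a surgically
exposed tumour bed through a cylindrical applicator, with a metal disk
beneath the target shielding the ribs, lung and heart.  Treatment planning
rests almost entirely on **output factors** —

    OF = D_non-reference(z_max) / D_reference(z_max)

the dose ratio between a given applicator/energy configuration and the
10 cm flat reference applicator — and on the commissioning curves (PDDs and
lateral profiles) they are read from.  This package implements that whole
dosimetric chain as a reusable, testable Python library for medical
physicists and simulation researchers:

* a **parametric electron source** (Gaussian spectrum Ē ± σ_E, Gaussian
  spot, angular divergence) behind a calibrated scattering-foil/collimator
  stack and an absorbing-walled applicator with optional bevel;
* a **condensed-history Monte Carlo engine** (CSDA energy loss from bundled
  stopping-power tables, Highland multiple scattering, per-voxel energy
  deposit and electron entry counts, strict energy bookkeeping);
* **dose metrics**: PDD/profile extraction with detector-volume averaging
  (36 mm³ chamber-like for PDDs, 18 mm³ diode-like for profiles), z_max
  location, measurement-grid resampling, and OFs with entry-count
  uncertainty propagation — including air-gap corrections OF_air-gap;
* **gamma-index analysis** (global 3%/3 mm, no low-dose threshold) with
  pass-rate reporting, validated against a brute-force oracle;
* **iterative source tuning**: the commissioning loop that grid-searches
  (Ē, σ_E) against the measured PDD and (spot FWHM, divergence) against the
  profiles, gamma-gated at 90%/95%, exposed as
  `BeamCommissioningModel(...).fit()` with a `summary()` table;
* **phase-space recording/replay** (binary + CSV formats) so non-reference
  applicators can be simulated without re-transporting the machine head;
* **out-of-field organ dosimetry** on a MIRD-style female thorax phantom
  with a copper shielding disk: per-organ mean doses D = E/m, doses
  relative to the left breast, 21 Gy prescription scaling, and
  disk-misalignment comparisons;
* a **synthetic-reference generator** that emulates commissioning
  measurements (1 mm sampling, 4 mm→2 mm central profile region, 2.1%
  Gaussian noise) so every stage is testable without proprietary data.

## Worked example

Simulate the 9 MeV reference field, read the depth-dose curve, and compare
two applicators:

```python
from ioert import (Applicator, BeamSource, TransportConfig, build_machine,
                   compute_of, default_stack, extract_pdd, find_zmax,
                   run_simulation, water_phantom)

source = BeamSource(mean_energy=9.8, sigma_e=0.9, spot_fwhm=1.6, divergence=0.0)
phantom = water_phantom(side_mm=140, depth_mm=80, spacing_mm=1.0)

ref_geo = build_machine(default_stack(), Applicator(diameter=10.0))
ref = run_simulation(source, ref_geo, phantom,
                     TransportConfig(seed=1, n_histories=2_000_000))
pdd = extract_pdd(ref).normalized()
print("z_max =", find_zmax(pdd, smooth=True, window=11), "mm")

small_geo = build_machine(default_stack(), Applicator(diameter=6.0))
small = run_simulation(source, small_geo, phantom,
                       TransportConfig(seed=1, n_histories=2_000_000))
of = compute_of(ref, small, zmax_ref_mm=18.0)
print(f"OF(6 cm / 10 cm) = {of.value:.3f} +- {of.uncertainty:.3f}")
```

Output from this exact script:

```
z_max = 19.5 mm
OF(6 cm / 10 cm) = 0.949 +- 0.021
```

`z_max` lands within one voxel of the 9 MeV reference depth of 18 mm
(voxel centres sit at half-millimetres, and the broad dose maximum jitters
by about a voxel at this statistics level).  The 6 cm output factor below
one reflects the smaller applicator's loss of scatter equilibrium at the
central axis; the quoted uncertainty is propagated from the per-voxel
electron entry counts.

A command-line surface wraps the same pipeline
(`ioert simulate|tune|gamma|of|organdose|synth`); see `ioert --help`.

## Limitations

The machine-head geometry of clinical IOERT accelerators is proprietary;
the stack shipped here is a calibrated stand-in (see `docs/methods.md`).
The engine transports electrons only — bremsstrahlung photons are removed
from the energy balance but not followed — so far out-of-field doses are
underestimated, and the published organ-dose tables are used as *inputs*
to the prescription-scaling arithmetic rather than re-simulated.
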