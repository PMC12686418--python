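"""Parametric electron source and machine-head/applicator geometry.

The accelerator head is modelled as an ordered stack of slabs (exit window,
dual scattering foils, air columns) and absorbing apertures, ended by an
absorbing-walled cylindrical applicator whose exit plane may be tilted by a
bevel angle.  The true head dimensions of clinical IOERT machines are
proprietary; the default stack shipped here is a calibrated stand-in whose
free lengths and thicknesses were fixed once so that the reference
depth-of-maximum values (13/18/22 mm in water for the 6/9/12 MeV beams) are
reproduced, mirroring the way such models are commissioned in practice.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

#: FWHM of a Gaussian = FWHM_TO_SIGMA^-1 ... conversion constant 2*sqrt(2 ln 2)
FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))

ALLOWED_BEVELS = (0.0, 15.0, 30.0)


@dataclass(frozen=True)
class BeamSource:
    """Gaussian electron source at the accelerator exit window.

    mean_energy, sigma_e in MeV; spot_fwhm in mm; divergence is the
    half-angle (degrees) of a Gaussian angular spread about +z.
    """

    mean_energy: float
    sigma_e: float = 0.0
    spot_fwhm: float = 0.0
    divergence: float = 0.0

    def __post_init__(self):
        if self.mean_energy <= 0:
            raise ValueError("mean_energy must be > 0")
        if self.sigma_e < 0 or self.spot_fwhm < 0 or self.divergence < 0:
            raise ValueError("sigma_e, spot_fwhm and divergence must be >= 0")


@dataclass(frozen=True)
class Applicator:
    """Cylindrical treatment applicator with absorbing walls."""

    diameter: float  # cm
    bevel: float = 0.0  # degrees, one of 0/15/30
    wall_material: str = "aluminum"
    length: float = 20.0  # cm

    def __post_init__(self):
        if self.diameter <= 0:
            raise ValueError("diameter must be > 0")
        if self.bevel not in ALLOWED_BEVELS:
            raise ValueError(f"bevel must be one of {ALLOWED_BEVELS}")
        if self.length <= 0:
            raise ValueError("length must be > 0")

    @property
    def radius_mm(self) -> float:
        return self.diameter * 10.0 / 2.0


@dataclass(frozen=True)
class StackElement:
    """One element of the machine head: a slab or an absorbing aperture.

    ``z`` is the upstream face position in mm (source plane at z=0),
    ``thickness`` in mm.  ``aperture_radius`` (mm), when set, absorbs any
    particle outside that radius while it traverses the element.
    """

    material: str
    thickness: float
    z: float
    aperture_radius: float | None = None

    def __post_init__(self):
        if self.thickness <= 0:
            raise ValueError("thickness must be > 0")


@dataclass(frozen=True)
class MachineStack:
    """Ordered element list of the machine head above the applicator."""

    elements: tuple[StackElement, ...]
    ssf_density: float = 2.70  # g/cm^3, adjustable secondary-foil density
    ssf_index: int | None = None  # which element the ssf_density applies to

    def __post_init__(self):
        if self.ssf_density <= 0:
            raise ValueError("ssf_density must be > 0")
        zs = [e.z for e in self.elements]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("elements must be ordered by strictly increasing z")
        for a, b in zip(self.elements, self.elements[1:]):
            if a.z + a.thickness > b.z + 1e-9:
                raise ValueError(
                    f"overlapping elements at z={a.z} (ends {a.z + a.thickness}) and z={b.z}"
                )

    def with_ssf_density(self, density: float) -> "MachineStack":
        return replace(self, ssf_density=density)


@dataclass(frozen=True)
class Layer:
    """Flattened transport layer: [z0, z1) of one material, optional wall."""

    z0: float
    z1: float
    material: str
    density_override: float | None = None
    aperture_radius: float | None = None
    # bevel handling: the wall is active only while z < bevel_z_ref - x*tan(bevel);
    # bevel_z_ref is the nominal (un-tilted) applicator exit plane.
    bevel_tan: float = 0.0
    bevel_z_ref: float = 0.0


@dataclass(frozen=True)
class MachineGeometry:
    """Transport-ready description: layers ending at the phantom surface."""

    layers: tuple[Layer, ...]
    phantom_z: float  # mm, z of the phantom entrance plane
    applicator: Applicator
    phase_space_z: float  # default recording plane (beneath the collimation)

    @property
    def total_length(self) -> float:
        return self.phantom_z


def sample_primary(source: BeamSource, rng: np.random.Generator, n: int = 1):
    """Sample primary electron states at the source plane (z=0).

    Returns dict of arrays: x, y [mm], u, v, w direction cosines, energy
    [MeV] (Normal truncated at > 0), weight (all ones).  The spot is a
    circular 2D Gaussian with the configured FWHM (equal transverse widths);
    the direction is Gaussian about +z with the configured half-angle.
    """
    sigma_xy = source.spot_fwhm * FWHM_TO_SIGMA
    x = rng.normal(0.0, sigma_xy, n) if sigma_xy > 0 else np.zeros(n)
    y = rng.normal(0.0, sigma_xy, n) if sigma_xy > 0 else np.zeros(n)

    if source.divergence > 0:
        sig = math.radians(source.divergence)
        tx = rng.normal(0.0, sig, n)
        ty = rng.normal(0.0, sig, n)
    else:
        tx = np.zeros(n)
        ty = np.zeros(n)
    norm = np.sqrt(1.0 + tx * tx + ty * ty)
    u, v, w = tx / norm, ty / norm, 1.0 / norm

    if source.sigma_e > 0:
        e = rng.normal(source.mean_energy, source.sigma_e, n)
        bad = e <= 0
        while np.any(bad):  # truncated normal: resample non-physical draws
            e[bad] = rng.normal(source.mean_energy, source.sigma_e, int(bad.sum()))
            bad = e <= 0
    else:
        e = np.full(n, source.mean_energy)

    return {"x": x, "y": y, "u": u, "v": v, "w": w,
            "energy": e, "weight": np.ones(n)}


def default_stack() -> MachineStack:
    """Calibrated stand-in machine head (exit window, dual foils, collimator).

    Dimensions are this package's own commissioning choices, not vendor data.
    """
    elements = (
        StackElement("titanium", 0.05, 0.0),              # exit window
        StackElement("copper", 0.06, 10.0),               # primary scattering foil
        StackElement("aluminum", 1.0, 60.0),              # secondary scattering foil
        StackElement("air", 88.6, 61.0, aperture_radius=40.0),   # head air column
        StackElement("air", 30.0, 150.0, aperture_radius=30.0),  # collimator bore
    )
    return MachineStack(elements=elements, ssf_index=2)


def build_machine(stack: MachineStack, applicator: Applicator,
                  ssd_mm: float = 500.0, air_gap_mm: float = 0.0) -> MachineGeometry:
    """Assemble the transport geometry from head stack + applicator.

    ``ssd_mm`` is the source-to-phantom-surface distance at zero air gap;
    ``air_gap_mm`` moves the phantom surface further downstream while the
    applicator exit stays put (air-gap output-factor configuration).
    Gaps between stack elements are filled with air; the applicator occupies
    the last ``applicator.length`` upstream of its nominal exit plane and is
    modelled as an absorbing-walled air cylinder with a bevel-tilted exit.
    """
    phantom_z = ssd_mm + air_gap_mm
    app_len = applicator.length * 10.0
    app_z0 = ssd_mm - app_len
    layers: list[Layer] = []
    cursor = 0.0
    for i, el in enumerate(stack.elements):
        if el.z > cursor + 1e-9:  # fill inter-element space with open air
            layers.append(Layer(cursor, el.z, "air"))
        dens = stack.ssf_density if (stack.ssf_index == i) else None
        z1 = el.z + el.thickness
        if z1 > app_z0 + 1e-9:
            raise ValueError("machine stack extends into the applicator region")
        layers.append(Layer(el.z, z1, el.material, density_override=dens,
                            aperture_radius=el.aperture_radius))
        cursor = z1
    if app_z0 > cursor + 1e-9:
        layers.append(Layer(cursor, app_z0, "air"))

    # applicator: absorbing cylinder; sub-divided so the wall is enforced
    # frequently along oblique tracks
    bevel_tan = math.tan(math.radians(applicator.bevel))
    n_sub = max(4, int(app_len // 50.0))
    edges = np.linspace(app_z0, ssd_mm, n_sub + 1)
    for a, b in zip(edges[:-1], edges[1:]):
        layers.append(Layer(float(a), float(b), "air",
                            aperture_radius=applicator.radius_mm,
                            bevel_tan=bevel_tan, bevel_z_ref=ssd_mm))
    if air_gap_mm > 0:
        layers.append(Layer(ssd_mm, phantom_z, "air"))

    phase_space_z = app_z0 - 1.0  # just beneath the collimation system
    return MachineGeometry(tuple(layers), phantom_z, applicator, phase_space_z)
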