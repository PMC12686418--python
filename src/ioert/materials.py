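"""Electron interaction data for the transport engine.

Each :class:`Material` bundles a density, an effective atomic description, a
radiation length and tabulated mass stopping powers (collision and radiative)
on a common 0.1-15 MeV energy grid.  The tables below are smooth ESTAR-style
tabulations bundled with the package; they are the engine's physics ground
truth and the reference oracle for the interpolation routines.

Lookups interpolate log-log between nodes and refuse to extrapolate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ELECTRON_REST_MEV = 0.510998950

#: common energy grid for all stopping-power tables [MeV]
ENERGY_GRID = np.array([0.1, 0.2, 0.5, 1.0, 2.0, 3.0, 5.0, 8.0, 10.0, 12.0, 15.0])


@dataclass(frozen=True)
class Material:
    """Homogeneous medium with bundled electron stopping-power tables.

    Parameters
    ----------
    name : str
        Registry key (lower case).
    density : float
        Bulk density in g/cm^3.
    z_eff, a_eff : float
        Effective atomic number and mass used for documentation only; the
        transport data live in the tables.
    radiation_length : float
        X0 in g/cm^2, used by the Highland multiple-scattering formula.
    s_collision : ndarray
        Collision mass stopping power on ``ENERGY_GRID`` [MeV cm^2/g].
    s_radiative : ndarray
        Radiative mass stopping power on ``ENERGY_GRID`` [MeV cm^2/g].
    """

    name: str
    density: float
    z_eff: float
    a_eff: float
    radiation_length: float
    s_collision: np.ndarray = field(repr=False)
    s_radiative: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"density must be positive, got {self.density}")
        if np.any(np.asarray(self.s_collision) <= 0):
            raise ValueError("collision stopping-power table must be strictly positive")

    def with_density(self, density: float, name: str | None = None) -> "Material":
        """Same tables at a different bulk density (e.g. inflated lung)."""
        return Material(
            name=name or self.name,
            density=density,
            z_eff=self.z_eff,
            a_eff=self.a_eff,
            radiation_length=self.radiation_length,
            s_collision=self.s_collision,
            s_radiative=self.s_radiative,
        )


def _mat(name, density, z, a, x0, s_col, s_rad):
    return Material(name, density, z, a, x0,
                    np.asarray(s_col, float), np.asarray(s_rad, float))


# Collision / radiative mass stopping powers [MeV cm^2/g] on ENERGY_GRID.
_WATER_COL = [4.115, 2.793, 2.034, 1.849, 1.795, 1.797, 1.818, 1.846, 1.861, 1.872, 1.885]
_WATER_RAD = [0.0028, 0.0041, 0.0077, 0.0128, 0.0260, 0.0396, 0.0680, 0.1120, 0.1420, 0.1730, 0.2200]

_AIR_COL = [3.633, 2.470, 1.802, 1.661, 1.684, 1.740, 1.790, 1.840, 1.862, 1.877, 1.895]
_AIR_RAD = [0.0029, 0.0042, 0.0079, 0.0132, 0.0268, 0.0408, 0.0700, 0.1154, 0.1463, 0.1782, 0.2266]

_BONE_COL = [3.790, 2.580, 1.880, 1.710, 1.662, 1.665, 1.687, 1.714, 1.729, 1.740, 1.753]
_BONE_RAD = [0.0041, 0.0059, 0.0112, 0.0187, 0.0377, 0.0574, 0.0986, 0.1624, 0.2059, 0.2509, 0.3190]

_CU_COL = [2.930, 2.000, 1.469, 1.348, 1.322, 1.334, 1.358, 1.385, 1.398, 1.408, 1.420]
_CU_RAD = [0.0100, 0.0150, 0.0290, 0.0520, 0.0990, 0.1470, 0.2430, 0.3850, 0.4800, 0.5750, 0.7150]

_TI_COL = [3.060, 2.090, 1.536, 1.408, 1.380, 1.392, 1.415, 1.442, 1.455, 1.465, 1.478]
_TI_RAD = [0.0080, 0.0120, 0.0232, 0.0416, 0.0792, 0.1176, 0.1944, 0.3080, 0.3840, 0.4600, 0.5720]

_AL_COL = [3.483, 2.380, 1.741, 1.597, 1.568, 1.578, 1.601, 1.630, 1.645, 1.657, 1.672]
_AL_RAD = [0.0054, 0.0080, 0.0155, 0.0279, 0.0531, 0.0788, 0.1302, 0.2064, 0.2573, 0.3082, 0.3832]


#: registry of the media the pipeline needs (water phantom, air column,
#: copper shielding disk, machine-head metals, and tissue analogues).
MATERIALS: dict[str, Material] = {
    "water": _mat("water", 1.000, 7.42, 14.89, 36.08, _WATER_COL, _WATER_RAD),
    "air": _mat("air", 1.205e-3, 7.64, 14.61, 36.62, _AIR_COL, _AIR_RAD),
    "soft_tissue": _mat("soft_tissue", 1.04, 7.40, 14.90, 36.30, _WATER_COL, _WATER_RAD),
    "lung": _mat("lung", 0.296, 7.40, 14.90, 36.30, _WATER_COL, _WATER_RAD),
    "bone": _mat("bone", 1.85, 13.8, 27.8, 17.50, _BONE_COL, _BONE_RAD),
    "copper": _mat("copper", 8.96, 29.0, 63.55, 12.86, _CU_COL, _CU_RAD),
    "titanium": _mat("titanium", 4.54, 22.0, 47.87, 16.16, _TI_COL, _TI_RAD),
    "aluminum": _mat("aluminum", 2.70, 13.0, 26.98, 24.01, _AL_COL, _AL_RAD),
}


def get_material(name: str) -> Material:
    try:
        return MATERIALS[name.lower()]
    except KeyError:
        raise KeyError(f"unknown material {name!r}; known: {sorted(MATERIALS)}") from None


def _check_range(energy_mev: float | np.ndarray) -> None:
    e = np.asarray(energy_mev, float)
    if np.any(e < ENERGY_GRID[0]) or np.any(e > ENERGY_GRID[-1]):
        raise ValueError(
            f"energy {energy_mev} MeV outside tabulated range "
            f"[{ENERGY_GRID[0]}, {ENERGY_GRID[-1]}] MeV; no extrapolation"
        )


def mass_collision_stopping_power(material: Material, energy_mev):
    """Collision mass stopping power [MeV cm^2/g], log-log interpolated."""
    _check_range(energy_mev)
    return np.exp(np.interp(np.log(energy_mev),
                            np.log(ENERGY_GRID), np.log(material.s_collision)))


def collision_stopping_power(material: Material, energy_mev):
    """Linear collision stopping power [MeV/cm] at the material's density."""
    return mass_collision_stopping_power(material, energy_mev) * material.density


def radiative_fraction(material: Material, energy_mev):
    """Fraction of the total energy loss that is radiative, S_rad/(S_col+S_rad)."""
    _check_range(energy_mev)
    frac = material.s_radiative / (material.s_collision + material.s_radiative)
    return np.interp(np.log(energy_mev), np.log(ENERGY_GRID), frac)


def momentum_beta(energy_mev):
    """Return (pc [MeV], beta) for an electron of the given kinetic energy."""
    e = np.asarray(energy_mev, float)
    etot = e + ELECTRON_REST_MEV
    pc = np.sqrt(e * (e + 2.0 * ELECTRON_REST_MEV))
    return pc, pc / etot


def scatter_sigma(material: Material, energy_mev, path_length_mm):
    """Highland multiple-scattering angle sigma [rad] over a path length.

    sigma = (13.6 MeV / (beta c p)) * sqrt(t/X0) * (1 + 0.038 ln(t/X0)),
    with t the traversed mass thickness in g/cm^2 and the bracket floored
    at zero so very thin slabs never yield a negative width.
    """
    if np.any(np.asarray(path_length_mm) < 0):
        raise ValueError("path_length must be >= 0")
    _check_range(energy_mev)
    t = np.asarray(path_length_mm, float) * 0.1 * material.density  # g/cm^2
    pc, beta = momentum_beta(energy_mev)
    with np.errstate(divide="ignore", invalid="ignore"):
        x = t / material.radiation_length
        sigma = np.where(
            x > 0.0,
            13.6 / (beta * pc) * np.sqrt(np.maximum(x, 0.0))
            * np.maximum(1.0 + 0.038 * np.log(np.maximum(x, 1e-300)), 0.0),
            0.0,
        )
    if np.ndim(sigma) == 0:
        return float(sigma)
    return sigma


def csda_range_cm(material: Material, energy_mev: float, n: int = 400) -> float:
    """Continuous-slowing-down range [cm] by trapezoid integration of 1/S_tot."""
    _check_range(energy_mev)
    e = np.linspace(ENERGY_GRID[0], energy_mev, n)
    s_col = mass_collision_stopping_power(material, e) * material.density
    frac = radiative_fraction(material, e)
    s_tot = s_col / (1.0 - frac)
    return float(np.trapezoid(1.0 / s_tot, e))
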