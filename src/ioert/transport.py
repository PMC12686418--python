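"""Simplified condensed-history electron transport and voxel dose scoring.

The engine transports electrons from the parametric source (or a replayed
phase space) through the machine-head layer stack semi-analytically —
deterministic CSDA energy loss plus one Highland deflection per layer, with
absorbing apertures and applicator walls — and then hands the survivors to
the voxel stepping kernel, which scores per-voxel deposited energy and
electron entry counts.

Electrons only: radiative (bremsstrahlung) losses are removed from the
electron energy but not transported as photons, an accepted bias at the
6-12 MeV energies of interest.  Neutrons and positrons are outside scope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import materials as mat
from ._kernel import transport_voxels
from .beam import BeamSource, MachineGeometry, sample_primary

#: fixed batching constant; part of the deterministic run contract
CHUNK = 262_144


@dataclass
class ParticleState:
    """Single transported electron (plumbing carrier, mostly for tests)."""

    energy: float
    position: tuple[float, float, float]
    direction: tuple[float, float, float]
    weight: float = 1.0

    def __post_init__(self):
        if self.energy < 0:
            raise ValueError("energy must be >= 0")
        if abs(sum(c * c for c in self.direction) - 1.0) > 1e-9:
            raise ValueError("direction must be unit length (1e-9)")


@dataclass(frozen=True)
class TransportConfig:
    """Stepping controls for the engine."""

    max_step: float = 1.0  # mm
    energy_cutoff: float = 0.2  # MeV, local deposition below this
    seed: int = 0
    n_histories: int = 0
    #: fractional width of the per-history stopping-power scale factor, an
    #: unbiased stand-in for range straggling (Landau fluctuations and
    #: delta rays are not tracked); one-time calibration, 0 disables it
    energy_straggling: float = 0.11
    #: scale factor on the Highland multiple-scattering width inside the
    #: phantom; compensates the missing large-angle (Moliere tail) and
    #: secondary-electron transport of the condensed-history model.
    #: One-time calibration against the reference depths of maximum.
    ms_scale: float = 1.7

    def __post_init__(self):
        if self.max_step <= 0:
            raise ValueError("max_step must be > 0")
        if self.energy_cutoff <= 0:
            raise ValueError("energy_cutoff must be > 0")
        if self.n_histories < 0:
            raise ValueError("n_histories must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Voxel grid specification in beam coordinates.

    z = 0 at the phantom entrance plane, beam along +z; x is the inplane
    and y the crossplane direction.  The grid is centred on the beam axis
    in x and y unless an explicit origin is given.  ``material`` is either
    a material name (uniform phantom) or an integer label grid paired with
    ``material_names`` mapping label -> material name.
    """

    dims: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    material: str | np.ndarray = "water"
    material_names: tuple[str, ...] | None = None
    origin: tuple[float, float, float] | None = None

    def __post_init__(self):
        if any(d <= 0 for d in self.dims):
            raise ValueError("dims must be positive")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be > 0")

    @property
    def grid_origin(self) -> tuple[float, float, float]:
        if self.origin is not None:
            return self.origin
        nx, ny, _ = self.dims
        sx, sy, _ = self.spacing
        return (-nx * sx / 2.0, -ny * sy / 2.0, 0.0)


def water_phantom(side_mm: float = 300.0, depth_mm: float = 300.0,
                  spacing_mm: float = 1.0) -> PhantomSpec:
    """Voxelized water tank (commissioning-style), centred on the beam axis."""
    n_lat = int(round(side_mm / spacing_mm))
    n_z = int(round(depth_mm / spacing_mm))
    return PhantomSpec(dims=(n_lat, n_lat, n_z),
                       spacing=(spacing_mm, spacing_mm, spacing_mm))


@dataclass
class DoseGrid:
    """Voxelized scoring result: deposited energy [MeV] and entry counts."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    dims: tuple[int, int, int]
    energy: np.ndarray  # float64 (nx, ny, nz)
    entries: np.ndarray  # int64 (nx, ny, nz)
    meta: dict = field(default_factory=dict)

    def axis_positions(self, axis: int) -> np.ndarray:
        """Voxel-centre coordinates along one axis (0=x, 1=y, 2=z) [mm]."""
        n = self.dims[axis]
        s = self.spacing[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * s

    def central_indices(self) -> tuple[int, int]:
        """(ix, iy) of the voxel containing the beam axis (x=y=0)."""
        ix = int(np.floor(-self.origin[0] / self.spacing[0]))
        iy = int(np.floor(-self.origin[1] / self.spacing[1]))
        return ix, iy

    def energy_balance(self) -> dict:
        m = self.meta
        total = (m["phantom_deposit"] + m["phantom_radiative"] + m["phantom_escaped"]
                 + m["machine_loss"] + m["machine_radiative"] + m["machine_absorbed"])
        return {"injected": m["injected"], "accounted": total,
                "relative_error": abs(total - m["injected"]) / max(m["injected"], 1e-300)}


def voxel_uncertainty(grid: DoseGrid) -> np.ndarray:
    """Per-voxel relative sigma = 1/sqrt(entries); NaN where no electron entered.

    The NaN flag (not zero) marks voxels whose dose estimate has undefined
    statistical quality.
    """
    with np.errstate(divide="ignore"):
        rel = 1.0 / np.sqrt(grid.entries.astype(float))
    rel[grid.entries == 0] = np.nan
    return rel


# ---------------------------------------------------------------------------
# machine-stack transport (semi-analytic, vectorized)

def _scatter_batch(u, v, w, sigma, rng):
    """Apply independent Gaussian deflections of width sigma per particle."""
    t1 = rng.standard_normal(u.shape[0]) * sigma
    t2 = rng.standard_normal(u.shape[0]) * sigma
    pp = u * u + v * v
    small = pp <= 1e-12
    inv = 1.0 / np.sqrt(np.where(small, 1.0, pp))
    e1x = np.where(small, 1.0, -v * inv)
    e1y = np.where(small, 0.0, u * inv)
    e1z = np.zeros_like(u)
    e2x = v * e1z - w * e1y
    e2y = w * e1x - u * e1z
    e2z = u * e1y - v * e1x
    nu = u + t1 * e1x + t2 * e2x
    nv = v + t1 * e1y + t2 * e2y
    nw = w + t1 * e1z + t2 * e2z
    norm = np.sqrt(nu * nu + nv * nv + nw * nw)
    return nu / norm, nv / norm, nw / norm


def transport_stack(states: dict, geometry: MachineGeometry, cutoff: float,
                    rng: np.random.Generator, z_start: float = 0.0,
                    record_plane_z: float | None = None):
    """Transport a particle batch through the machine layers to the phantom.

    ``states`` holds arrays x, y [mm at z_start], u, v, w, energy, weight.
    Returns (survivor states at the phantom surface, bookkeeping dict,
    records) where records is a structured array captured at
    ``record_plane_z`` (or None).
    """
    x = states["x"].copy()
    y = states["y"].copy()
    u = states["u"].copy()
    v = states["v"].copy()
    w = states["w"].copy()
    e = states["energy"].copy()
    wt = states["weight"].copy()
    z = z_start

    book = {"machine_loss": 0.0, "machine_radiative": 0.0, "machine_absorbed": 0.0}
    records = None

    layers = geometry.layers
    if record_plane_z is not None:
        # split the spanning layer so scattering is applied up to the plane
        # and the recorded state is exactly the transported state there
        layers = _split_layers(layers, record_plane_z)

    for layer in layers:
        if layer.z1 <= z_start + 1e-12:
            continue
        z0 = max(layer.z0, z_start)
        dz = layer.z1 - z0

        # downward-moving requirement: the stack model has no backscatter
        bad = w <= 1e-6
        if np.any(bad):
            book["machine_absorbed"] += float(np.sum(e[bad] * wt[bad]))
            keep = ~bad
            x, y, u, v, w, e, wt = (a[keep] for a in (x, y, u, v, w, e, wt))

        if record_plane_z is not None and records is None \
                and layer.z0 >= record_plane_z - 1e-9:
            records = _make_records(e, x, y, u, v, w, wt, record_plane_z)

        # drift across the layer
        t = dz / w
        x = x + u * t
        y = y + v * t

        # absorbing wall / aperture at the layer exit (and entry, since a
        # straight segment attains its maximal radius at an endpoint)
        if layer.aperture_radius is not None and x.size:
            r_exit = np.hypot(x, y)
            r_entry = np.hypot(x - u * t, y - v * t)
            hit = (r_exit > layer.aperture_radius) | (r_entry > layer.aperture_radius)
            if layer.bevel_tan != 0.0:
                # wall exists only upstream of the tilted exit plane
                wall_end = layer.bevel_z_ref - x * layer.bevel_tan
                hit &= (layer.z1 <= wall_end) | (z0 <= wall_end)
            if np.any(hit):
                book["machine_absorbed"] += float(np.sum(e[hit] * wt[hit]))
                keep = ~hit
                x, y, u, v, w, e, wt = (a[keep] for a in (x, y, u, v, w, e, wt))

        if x.size == 0:
            z = layer.z1
            continue

        material = mat.get_material(layer.material)
        rho = layer.density_override or material.density
        path_mm = dz / w
        e_clamped = np.clip(e, mat.ENERGY_GRID[0], mat.ENERGY_GRID[-1])
        s_mass = np.exp(np.interp(np.log(e_clamped), np.log(mat.ENERGY_GRID),
                                  np.log(material.s_collision)))
        frac = np.interp(np.log(e_clamped), np.log(mat.ENERGY_GRID),
                         material.s_radiative / (material.s_collision + material.s_radiative))
        de_col = s_mass * rho * path_mm * 0.1
        de_tot = de_col / (1.0 - frac)

        dead = (e - de_tot) <= cutoff
        if np.any(dead):
            book["machine_loss"] += float(np.sum(e[dead] * wt[dead]))
        live = ~dead
        book["machine_loss"] += float(np.sum(de_col[live] * wt[live]))
        book["machine_radiative"] += float(np.sum((de_tot - de_col)[live] * wt[live]))
        x, y, u, v, w, wt = (a[live] for a in (x, y, u, v, w, wt))
        e = (e - de_tot)[live]
        path_mm = path_mm[live]

        if x.size:
            sigma = _scatter_with_density(material, rho, e, path_mm)
            u, v, w = _scatter_batch(u, v, w, sigma, rng)
        z = layer.z1

    if record_plane_z is not None and records is None:
        # plane at (or beyond) the last layer boundary: record at the cursor
        if z <= record_plane_z <= geometry.phantom_z + 1e-9 and x.size:
            t = (record_plane_z - z) / w
            records = _make_records(e, x + u * t, y + v * t, u, v, w, wt,
                                    record_plane_z)
        else:
            records = _make_records(*[np.empty(0)] * 7, record_plane_z)

    out = {"x": x, "y": y, "u": u, "v": v, "w": w, "energy": e, "weight": wt}
    return out, book, records


def _split_layers(layers, z_split: float):
    """Return the layer tuple with any layer spanning ``z_split`` split in two."""
    out = []
    for layer in layers:
        if layer.z0 + 1e-9 < z_split < layer.z1 - 1e-9:
            from dataclasses import replace as _replace

            out.append(_replace(layer, z1=z_split))
            out.append(_replace(layer, z0=z_split))
        else:
            out.append(layer)
    return tuple(out)


def _scatter_with_density(material, rho, e, path_mm):
    t_gcm2 = path_mm * 0.1 * rho
    e_clamped = np.clip(e, mat.ENERGY_GRID[0], mat.ENERGY_GRID[-1])
    pc, beta = mat.momentum_beta(e_clamped)
    xx = t_gcm2 / material.radiation_length
    with np.errstate(divide="ignore"):
        bracket = np.maximum(1.0 + 0.038 * np.log(np.maximum(xx, 1e-300)), 0.0)
    return np.where(xx > 0, 13.6 / (beta * pc) * np.sqrt(np.maximum(xx, 0)) * bracket, 0.0)


def _make_records(e, x, y, u, v, w, wt, plane_z):
    from .phasespace import RECORD_DTYPE, ELECTRON

    rec = np.zeros(e.shape[0], dtype=RECORD_DTYPE)
    rec["ptype"] = ELECTRON
    rec["energy"] = e
    rec["x"] = x
    rec["y"] = y
    rec["u"] = u
    rec["v"] = v
    rec["w"] = w
    rec["weight"] = wt
    return rec


def _validate_records(records) -> None:
    norm = (records["u"].astype(float) ** 2 + records["v"].astype(float) ** 2
            + records["w"].astype(float) ** 2)
    # float32 storage: allow single-precision rounding of the unit norm
    if np.any(np.abs(norm - 1.0) > 1e-5):
        raise ValueError("phase-space records contain non-unit directions")
    if np.any(records["energy"] <= 0) or np.any(records["weight"] <= 0):
        raise ValueError("phase-space records must have positive energy and weight")


# ---------------------------------------------------------------------------
# full run

def _material_tables(spec: PhantomSpec):
    """Flattened per-material-label physics arrays for the kernel."""
    if isinstance(spec.material, str):
        names = (spec.material,)
        mat_id = np.zeros(int(np.prod(spec.dims)), dtype=np.uint8)
    else:
        if spec.material_names is None:
            raise ValueError("label-grid phantoms need material_names")
        names = tuple(spec.material_names)
        mat_id = np.ascontiguousarray(spec.material.reshape(-1)).astype(np.uint8)
    mats = [mat.get_material(n) for n in names]
    dens = np.array([m.density for m in mats])
    loge = np.log(mat.ENERGY_GRID)
    logscol = np.stack([np.log(m.s_collision) for m in mats])
    radfrac = np.stack([m.s_radiative / (m.s_collision + m.s_radiative) for m in mats])
    inv_x0 = np.array([1.0 / m.radiation_length for m in mats])
    za = np.array([m.z_eff / m.a_eff for m in mats])
    return mat_id, dens, loge, logscol, radfrac, inv_x0, za


def run_simulation(source, geometry: MachineGeometry, phantom: PhantomSpec,
                   config: TransportConfig, phase_space=None,
                   phase_space_plane_z: float | None = None,
                   record_plane_z: float | None = None):
    """Run a full engine simulation and return the scored :class:`DoseGrid`.

    ``source`` is a :class:`BeamSource` sampled for ``config.n_histories``
    primaries, or pass ``phase_space`` (a record array at its plane z) to
    replay instead.  Fixed ``config.seed`` gives a bit-identical grid.
    """
    nx, ny, nz = phantom.dims
    sx, sy, sz = phantom.spacing
    ox, oy, oz = phantom.grid_origin
    edep = np.zeros(nx * ny * nz, dtype=np.float64)
    entries = np.zeros(nx * ny * nz, dtype=np.int64)
    mat_id, dens, loge, logscol, radfrac, inv_x0, za = _material_tables(phantom)

    book = {"injected": 0.0, "machine_loss": 0.0, "machine_radiative": 0.0,
            "machine_absorbed": 0.0, "phantom_deposit": 0.0,
            "phantom_radiative": 0.0, "phantom_escaped": 0.0, "discarded": 0}
    all_records = []

    rng = np.random.default_rng(config.seed)
    if phase_space is not None:
        if len(phase_space) == 0:
            raise ValueError("phase_space must be non-empty")
        _validate_records(phase_space)
        batches = [phase_space[i:i + CHUNK] for i in range(0, len(phase_space), CHUNK)]
        replay_z = (phase_space_plane_z if phase_space_plane_z is not None
                    else geometry.phase_space_z)
        mode = "replay"
        n_total = len(phase_space)
    else:
        if not isinstance(source, BeamSource):
            raise TypeError("source must be a BeamSource (or pass phase_space=...)")
        n_total = config.n_histories
        batches = None
        mode = "source"

    done = 0
    chunk_idx = 0
    while done < n_total or (n_total == 0 and chunk_idx == 0 and False):
        n_batch = min(CHUNK, n_total - done)
        if mode == "source":
            states = sample_primary(source, rng, n_batch)
            z_start = 0.0
        else:
            rec = batches[chunk_idx]
            ru, rv, rw = (rec[c].astype(float) for c in ("u", "v", "w"))
            norm = np.sqrt(ru * ru + rv * rv + rw * rw)  # undo float32 rounding
            states = {"x": rec["x"].astype(float), "y": rec["y"].astype(float),
                      "u": ru / norm, "v": rv / norm, "w": rw / norm,
                      "energy": rec["energy"].astype(float),
                      "weight": rec["weight"].astype(float)}
            z_start = replay_z
        book["injected"] += float(np.sum(states["energy"] * states["weight"]))
        surv, sbook, records = transport_stack(
            states, geometry, config.energy_cutoff, rng, z_start=z_start,
            record_plane_z=record_plane_z)
        for k in ("machine_loss", "machine_radiative", "machine_absorbed"):
            book[k] += sbook[k]
        if records is not None:
            all_records.append(records)

        if surv["x"].size:
            gx = surv["x"] - ox
            gy = surv["y"] - oy
            gz = np.zeros_like(gx) + (0.0 - oz) + 1e-9  # entrance plane
            kseed = int((config.seed * 1_000_003 + chunk_idx * 7919 + 1) % 2_147_483_647)
            dep, rad, esc, escn = transport_voxels(
                gx, gy, gz, surv["u"], surv["v"], surv["w"],
                surv["energy"], surv["weight"],
                mat_id, dens, loge, logscol, radfrac, inv_x0, za,
                sx, sy, sz, nx, ny, nz,
                config.max_step, config.energy_cutoff,
                config.energy_straggling, config.ms_scale, kseed,
                edep, entries)
            book["phantom_deposit"] += dep
            book["phantom_radiative"] += rad
            book["phantom_escaped"] += esc
            book["discarded"] += escn
        done += n_batch
        chunk_idx += 1
        if n_total == 0:
            break

    book["n_histories"] = int(n_total)
    book["seed"] = int(config.seed)
    grid = DoseGrid(origin=(ox, oy, oz), spacing=(sx, sy, sz), dims=(nx, ny, nz),
                    energy=edep.reshape(nx, ny, nz), entries=entries.reshape(nx, ny, nz),
                    meta=book)
    if record_plane_z is not None:
        recs = (np.concatenate(all_records) if all_records
                else _make_records(*[np.empty(0)] * 7, record_plane_z))
        return grid, recs
    return grid
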