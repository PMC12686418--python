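"""MIRD-style female phantom, shielding disk and out-of-field organ dosimetry.

The phantom is a coarse anthropomorphic model built from geometric
primitives (ellipsoids, elliptic cylinders, shells, boxes) with organ-wise
materials, voxelized deterministically onto a label grid.  It is laid out
in beam coordinates for a left-breast IOERT treatment: the beam axis (+z)
enters the remodelled left-breast target at the grid origin, x points to
the patient's left and y toward the head.  Distant organs (legs, head) are
deliberately crude — they exist so that every organ of a standard MIRD
relative-dose table has a home, not to resolve intra-organ gradients.

Organ doses follow the mean-dose convention D_organ = E_organ / m_organ,
with masses from the analytic primitive volumes and nominal densities, and
relative doses are expressed in percent of the left-breast dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import materials as mat
from .transport import DoseGrid, PhantomSpec

MEV_TO_J = 1.602176634e-13

#: default prescription: single-fraction dose to the left breast at z_max [Gy]
PRESCRIPTION_GY = 21.0


# ---------------------------------------------------------------------------
# primitives

@dataclass(frozen=True)
class Ellipsoid:
    center: tuple[float, float, float]  # (x, y, z) mm, beam frame
    semi: tuple[float, float, float]

    def volume_mm3(self) -> float:
        a, b, c = self.semi
        return 4.0 / 3.0 * math.pi * a * b * c

    def bounds(self):
        c, s = self.center, self.semi
        return tuple(c[i] - s[i] for i in range(3)), tuple(c[i] + s[i] for i in range(3))

    def contains(self, x, y, z):
        cx, cy, cz = self.center
        ax, ay, az = self.semi
        return ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2 <= 1.0


@dataclass(frozen=True)
class EllipticCylinderY:
    """Elliptic cylinder with axis along y (cranio-caudal)."""

    cx: float
    cz: float
    ax: float
    az: float
    y0: float
    y1: float

    def volume_mm3(self) -> float:
        return math.pi * self.ax * self.az * (self.y1 - self.y0)

    def bounds(self):
        return (self.cx - self.ax, self.y0, self.cz - self.az), \
               (self.cx + self.ax, self.y1, self.cz + self.az)

    def contains(self, x, y, z):
        return (((x - self.cx) / self.ax) ** 2 + ((z - self.cz) / self.az) ** 2 <= 1.0) \
            & (y >= self.y0) & (y <= self.y1)


@dataclass(frozen=True)
class ShellY:
    """Region between two coaxial elliptic cylinders (e.g. the rib cage)."""

    outer: EllipticCylinderY
    inner_ax: float
    inner_az: float

    def volume_mm3(self) -> float:
        o = self.outer
        return math.pi * (o.ax * o.az - self.inner_ax * self.inner_az) * (o.y1 - o.y0)

    def bounds(self):
        return self.outer.bounds()

    def contains(self, x, y, z):
        o = self.outer
        inner = (((x - o.cx) / self.inner_ax) ** 2
                 + ((z - o.cz) / self.inner_az) ** 2) <= 1.0
        return o.contains(x, y, z) & ~inner


@dataclass(frozen=True)
class Box:
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def volume_mm3(self) -> float:
        return math.prod(h - l for l, h in zip(self.lo, self.hi))

    def bounds(self):
        return self.lo, self.hi

    def contains(self, x, y, z):
        return ((x >= self.lo[0]) & (x <= self.hi[0])
                & (y >= self.lo[1]) & (y <= self.hi[1])
                & (z >= self.lo[2]) & (z <= self.hi[2]))


@dataclass(frozen=True)
class CylinderX:
    """Circular cylinder with axis along x (e.g. clavicles)."""

    cy: float
    cz: float
    r: float
    x0: float
    x1: float

    def volume_mm3(self) -> float:
        return math.pi * self.r ** 2 * (self.x1 - self.x0)

    def bounds(self):
        return (self.x0, self.cy - self.r, self.cz - self.r), \
               (self.x1, self.cy + self.r, self.cz + self.r)

    def contains(self, x, y, z):
        return ((y - self.cy) ** 2 + (z - self.cz) ** 2 <= self.r ** 2) \
            & (x >= self.x0) & (x <= self.x1)


# ---------------------------------------------------------------------------
# organ registry

@dataclass(frozen=True)
class OrganDef:
    name: str
    material: str
    shape: object
    residual_of: str | None = None  # residual organs claim leftover envelope


# The layout is authored in patient coordinates (px: patient-left, py: toward
# head with the trunk base at 0, pz: depth from the anterior chest surface)
# and shifted so the beam axis hits the left-breast centre.
_X_SHIFT = -85.0  # beam x = px + _X_SHIFT ... i.e. px = 85 -> x = 0
_Y_SHIFT = -530.0
_Z_SHIFT = 30.0  # breast apex (pz = -30) -> z = 0


def _p(px, py, pz):
    return (px + _X_SHIFT, py + _Y_SHIFT, pz + _Z_SHIFT)


def _ell(px, py, pz, sx, sy, sz):
    return Ellipsoid(_p(px, py, pz), (sx, sy, sz))


def default_organ_defs() -> list[OrganDef]:
    """Claim-ordered organ list; earlier entries win voxel-overlap conflicts."""
    trunk_env = EllipticCylinderY(*_p(0, 0, 100)[::2], 200.0, 100.0, _p(0, 0, 0)[1],
                                  _p(0, 700, 0)[1])
    head_env = _ell(0, 850, 100, 78, 92, 98)
    neck = EllipticCylinderY(*_p(0, 0, 100)[::2], 50.0, 50.0, _p(0, 700, 0)[1],
                             _p(0, 762, 0)[1])
    left_leg_env = EllipticCylinderY(*_p(95, 0, 100)[::2], 78.0, 78.0,
                                     _p(0, -750, 0)[1], _p(0, 0, 0)[1])
    right_leg_env = EllipticCylinderY(*_p(-95, 0, 100)[::2], 78.0, 78.0,
                                      _p(0, -750, 0)[1], _p(0, 0, 0)[1])
    defs = [
        OrganDef("Brain", "soft_tissue", _ell(0, 865, 85, 60, 65, 72)),
        OrganDef("Skull", "bone", _ell(0, 865, 85, 68, 73, 80)),
        OrganDef("Thyroid", "soft_tissue", _ell(0, 715, 55, 18, 15, 12)),
        # the left breast is remodelled as a flattened post-resection target
        # bed under the applicator (thinner than the intact contralateral
        # breast) so the beam range spans it, as in a real tumour-bed setup
        OrganDef("Left Breast", "soft_tissue",
                 Ellipsoid((0.0, 0.0, 12.0), (50.0, 50.0, 12.0))),
        OrganDef("Right Breast", "soft_tissue", _ell(-85, 530, 0, 50, 50, 30)),
        OrganDef("Left Clavicle", "bone", CylinderX(_p(0, 688, 38)[1], _p(0, 688, 38)[2],
                                                    8.0, _p(20, 0, 0)[0], _p(150, 0, 0)[0])),
        OrganDef("Right Clavicle", "bone", CylinderX(_p(0, 688, 38)[1], _p(0, 688, 38)[2],
                                                     8.0, _p(-150, 0, 0)[0], _p(-20, 0, 0)[0])),
        OrganDef("Left Scapula", "bone", Box(_p(60, 560, 160), _p(160, 680, 185))),
        OrganDef("Right Scapula", "bone", Box(_p(-160, 560, 160), _p(-60, 680, 185))),
        OrganDef("Left Arm Bone", "bone",
                 EllipticCylinderY(*_p(185, 0, 100)[::2], 14.0, 14.0,
                                   _p(0, 250, 0)[1], _p(0, 690, 0)[1])),
        OrganDef("Right Arm Bone", "bone",
                 EllipticCylinderY(*_p(-185, 0, 100)[::2], 14.0, 14.0,
                                   _p(0, 250, 0)[1], _p(0, 690, 0)[1])),
        OrganDef("Upper Spine", "bone",
                 EllipticCylinderY(*_p(0, 0, 170)[::2], 18.0, 18.0,
                                   _p(0, 560, 0)[1], _p(0, 700, 0)[1])),
        OrganDef("Middle Lower Spine", "bone",
                 EllipticCylinderY(*_p(0, 0, 170)[::2], 18.0, 18.0,
                                   _p(0, 180, 0)[1], _p(0, 560, 0)[1])),
        OrganDef("Thymus", "soft_tissue", _ell(10, 640, 45, 20, 30, 15)),
        OrganDef("Heart", "soft_tissue", _ell(30, 560, 85, 55, 55, 48)),
        OrganDef("Rib Cage", "bone",
                 ShellY(EllipticCylinderY(*_p(0, 0, 100)[::2], 190.0, 100.0,
                                          _p(0, 380, 0)[1], _p(0, 690, 0)[1]),
                        180.0, 89.0)),
        OrganDef("Left Lung", "lung", _ell(85, 565, 83, 55, 120, 62)),
        OrganDef("Right Lung", "lung", _ell(-85, 565, 83, 55, 120, 62)),
        OrganDef("Stomach", "soft_tissue", _ell(70, 380, 70, 50, 60, 40)),
        OrganDef("Spleen", "soft_tissue", _ell(110, 360, 120, 35, 45, 30)),
        OrganDef("Left Kidney", "soft_tissue", _ell(60, 300, 150, 30, 55, 25)),
        OrganDef("Right Kidney", "soft_tissue", _ell(-60, 300, 150, 30, 55, 25)),
        OrganDef("Left Adrenal", "soft_tissue", _ell(60, 368, 142, 12, 25, 8)),
        OrganDef("Right Adrenal", "soft_tissue", _ell(-60, 368, 142, 12, 25, 8)),
        OrganDef("Pancreas", "soft_tissue", _ell(0, 350, 100, 60, 25, 20)),
        OrganDef("Upper Large Intestine", "soft_tissue", _ell(0, 280, 60, 90, 25, 30)),
        OrganDef("Small Intestine", "soft_tissue", _ell(0, 215, 80, 80, 55, 45)),
        OrganDef("Lower Large Intestine", "soft_tissue", _ell(-40, 140, 90, 40, 50, 35)),
        OrganDef("Urinary Bladder", "soft_tissue", _ell(0, 80, 55, 35, 30, 28)),
        OrganDef("Uterus", "soft_tissue", _ell(0, 110, 100, 25, 20, 35)),
        OrganDef("Left Ovary", "soft_tissue", _ell(50, 115, 100, 12, 8, 15)),
        OrganDef("Right Ovary", "soft_tissue", _ell(-50, 115, 100, 12, 8, 15)),
        OrganDef("Left Leg Bone", "bone",
                 EllipticCylinderY(*_p(95, 0, 100)[::2], 16.0, 16.0,
                                   _p(0, -750, 0)[1], _p(0, 0, 0)[1])),
        OrganDef("Right Leg Bone", "bone",
                 EllipticCylinderY(*_p(-95, 0, 100)[::2], 16.0, 16.0,
                                   _p(0, -750, 0)[1], _p(0, 0, 0)[1])),
        # envelope residuals claim whatever is left inside their envelope
        OrganDef("Head", "soft_tissue", head_env, residual_of="envelope"),
        OrganDef("Head-neck", "soft_tissue", neck, residual_of="Head"),
        OrganDef("Left Leg", "soft_tissue", left_leg_env, residual_of="envelope"),
        OrganDef("Right Leg", "soft_tissue", right_leg_env, residual_of="envelope"),
        OrganDef("Trunk", "soft_tissue", trunk_env, residual_of="envelope"),
    ]
    return defs


@dataclass(frozen=True)
class ShieldDisk:
    """Copper disk placed beneath the surgical target."""

    diameter: float = 8.0  # cm
    thickness: float = 1.0  # cm
    material: str = "copper"
    offset_mm: tuple[float, float] = (0.0, 0.0)  # centre offset from beam axis
    z_top_mm: float = 25.0  # top face depth in beam coordinates
    present: bool = True

    def __post_init__(self):
        if self.diameter <= 0 or self.thickness <= 0:
            raise ValueError("disk diameter and thickness must be > 0")


@dataclass
class OrganInfo:
    organ_id: int
    name: str
    material: str
    volume_cm3: float
    mass_g: float


@dataclass
class OrganPhantom:
    """Labelled voxel phantom plus the organ registry."""

    labels: np.ndarray  # uint8, 0 = air / unclaimed
    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    registry: dict[int, OrganInfo]
    meta: dict = field(default_factory=dict)

    @property
    def dims(self):
        return self.labels.shape

    def organ_id(self, name: str) -> int:
        for oid, info in self.registry.items():
            if info.name == name:
                return oid
        raise KeyError(f"no organ named {name!r}")

    def voxel_volume_cm3(self, organ: str | int) -> float:
        oid = organ if isinstance(organ, int) else self.organ_id(organ)
        n = int(np.sum(self.labels == oid))
        return n * math.prod(self.spacing) / 1000.0

    def disk_mask(self, disk: ShieldDisk) -> np.ndarray:
        """Boolean voxel mask of the shielding disk volume."""
        ox, oy, oz = self.origin
        sx, sy, sz = self.spacing
        nx, ny, nz = self.labels.shape
        xs = ox + (np.arange(nx) + 0.5) * sx - disk.offset_mm[0]
        ys = oy + (np.arange(ny) + 0.5) * sy - disk.offset_mm[1]
        zs = oz + (np.arange(nz) + 0.5) * sz
        r = disk.diameter * 10.0 / 2.0
        in_r = (xs[:, None] ** 2 + ys[None, :] ** 2) <= r ** 2
        in_z = (zs >= disk.z_top_mm) & (zs <= disk.z_top_mm + disk.thickness * 10.0)
        return in_r[:, :, None] & in_z[None, None, :]

    def material_grid(self, disk: ShieldDisk | None = None):
        """(material label grid uint8, material name tuple), disk overlaid."""
        mat_names = ["air"]
        mat_index = {"air": 0}
        id_to_mat = np.zeros(max(self.registry) + 1, dtype=np.uint8)
        for oid, info in self.registry.items():
            if info.material not in mat_index:
                mat_index[info.material] = len(mat_names)
                mat_names.append(info.material)
            id_to_mat[oid] = mat_index[info.material]
        grid = id_to_mat[self.labels]
        if disk is not None and disk.present:
            if disk.material not in mat_index:
                mat_index[disk.material] = len(mat_names)
                mat_names.append(disk.material)
            grid = grid.copy()
            grid[self.disk_mask(disk)] = mat_index[disk.material]
        return grid, tuple(mat_names)

    def phantom_spec(self, disk: ShieldDisk | None = None) -> PhantomSpec:
        grid, names = self.material_grid(disk)
        return PhantomSpec(dims=self.labels.shape, spacing=self.spacing,
                           material=grid, material_names=names, origin=self.origin)


DEFAULT_WORLD = ((-290.0, 120.0), (-1340.0, 420.0), (-10.0, 236.0))


def build_thorax_phantom(voxel_mm: float = 2.0,
                         organs: list[OrganDef] | None = None,
                         world: tuple = DEFAULT_WORLD) -> OrganPhantom:
    """Voxelize the organ list onto a labelled grid (deterministic).

    Overlaps are resolved by claim order (earlier organs win); residual
    envelope organs (Trunk, Head, Legs) claim the remaining voxels of their
    envelope primitive.  An organ whose bounding box leaves the world volume
    raises a configuration error.
    """
    organs = organs if organs is not None else default_organ_defs()
    (x0, x1), (y0, y1), (z0, z1) = world
    nx = int(round((x1 - x0) / voxel_mm))
    ny = int(round((y1 - y0) / voxel_mm))
    nz = int(round((z1 - z0) / voxel_mm))
    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    xs = x0 + (np.arange(nx) + 0.5) * voxel_mm
    ys = y0 + (np.arange(ny) + 0.5) * voxel_mm
    zs = z0 + (np.arange(nz) + 0.5) * voxel_mm

    registry: dict[int, OrganInfo] = {}
    name_to_id: dict[str, int] = {}
    next_id = 1
    voxel_cm3 = (voxel_mm ** 3) / 1000.0

    for od in organs:
        lo, hi = od.shape.bounds()
        if (lo[0] < x0 or hi[0] > x1 or lo[1] < y0 or hi[1] > y1
                or lo[2] < z0 or hi[2] > z1):
            raise ValueError(f"organ {od.name!r} extends outside the world volume")
        # bounding-box subgrid
        i0 = max(0, int((lo[0] - x0) / voxel_mm))
        i1 = min(nx, int(np.ceil((hi[0] - x0) / voxel_mm)) + 1)
        j0 = max(0, int((lo[1] - y0) / voxel_mm))
        j1 = min(ny, int(np.ceil((hi[1] - y0) / voxel_mm)) + 1)
        k0 = max(0, int((lo[2] - z0) / voxel_mm))
        k1 = min(nz, int(np.ceil((hi[2] - z0) / voxel_mm)) + 1)
        X = xs[i0:i1][:, None, None]
        Y = ys[j0:j1][None, :, None]
        Z = zs[k0:k1][None, None, :]
        mask = od.shape.contains(X, Y, Z)
        sub = labels[i0:i1, j0:j1, k0:k1]
        claim = mask & (sub == 0)

        # merged organs (e.g. head + neck) reuse the earlier id
        target = od.name.split("-")[0] if od.residual_of not in (None, "envelope") \
            else od.name
        if target in name_to_id:
            oid = name_to_id[target]
        else:
            oid = next_id
            next_id += 1
            if next_id > 255:
                raise ValueError("too many organs for a uint8 label grid")
            name_to_id[target] = oid
            registry[oid] = OrganInfo(oid, target, od.material, 0.0, 0.0)
        sub[claim] = oid

    for oid, info in registry.items():
        # analytic volume for primitives; voxel count for residual envelopes
        analytic = 0.0
        residual = False
        for od in organs:
            target = od.name.split("-")[0] if od.residual_of not in (None, "envelope") \
                else od.name
            if target != info.name:
                continue
            if od.residual_of is not None:
                residual = True
            analytic += od.shape.volume_mm3() / 1000.0
        if residual:
            vol = float(np.sum(labels == oid)) * voxel_cm3
        else:
            vol = analytic
        rho = mat.get_material(info.material).density
        registry[oid] = OrganInfo(oid, info.name, info.material, vol, vol * rho)
        if registry[oid].mass_g <= 0:
            raise ValueError(f"organ {info.name!r} has non-positive mass")

    return OrganPhantom(labels=labels, origin=(x0, y0, z0),
                        spacing=(voxel_mm, voxel_mm, voxel_mm),
                        registry=registry,
                        meta={"voxel_mm": voxel_mm, "world": world})


# ---------------------------------------------------------------------------
# scoring

class OrganDoseTable:
    """Per-organ dose table with the left breast as the 100% reference."""

    def __init__(self, frame: pd.DataFrame, reference_organ: str = "Left Breast"):
        self.frame = frame
        self.reference_organ = reference_organ

    def __getitem__(self, organ: str) -> pd.Series:
        return self.frame.loc[organ]

    def relative(self, organ: str) -> float:
        return float(self.frame.loc[organ, "relative_pct"])

    def to_csv(self, path) -> None:
        out = self.frame.copy()
        out["dose_mGy"] = out.pop("dose_Gy") * 1000.0
        cols = ["E_J", "mass_g", "dose_mGy", "relative_pct", "rel_unc_pct"]
        out[cols].to_csv(path, index_label="organ")


def score_organ_doses(phantom: OrganPhantom, grid: DoseGrid,
                      reference_organ: str = "Left Breast",
                      disk: ShieldDisk | None = None) -> OrganDoseTable:
    """Aggregate a dose grid into the per-organ mean-dose table.

    E_organ is the summed voxel energy deposit over the organ's labelled
    voxels, D_organ = E_organ / m_organ, and the relative dose is
    100 * D_organ / D_reference.  The relative statistical uncertainty per
    organ is 1/sqrt(sum of electron entries in the organ).  When a disk is
    present its voxels are excluded from the organ they displaced.
    """
    if grid.energy.shape != phantom.labels.shape:
        raise ValueError("dose grid does not match the phantom grid")
    labels = phantom.labels
    if disk is not None and disk.present:
        labels = labels.copy()
        labels[phantom.disk_mask(disk)] = 0
    flat_labels = labels.reshape(-1)
    n_ids = max(phantom.registry) + 1
    e_sum = np.bincount(flat_labels, weights=grid.energy.reshape(-1), minlength=n_ids)
    n_sum = np.bincount(flat_labels, weights=grid.entries.reshape(-1), minlength=n_ids)

    rows = {}
    for oid, info in sorted(phantom.registry.items()):
        e_j = float(e_sum[oid]) * MEV_TO_J
        dose_gy = e_j / (info.mass_g / 1000.0)
        n = float(n_sum[oid])
        rel_unc = 100.0 / math.sqrt(n) if n > 0 else float("nan")
        rows[info.name] = {"E_J": e_j, "mass_g": info.mass_g, "dose_Gy": dose_gy,
                           "entries": n, "rel_unc_pct": rel_unc}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    ref_dose = frame.loc[reference_organ, "dose_Gy"]
    if ref_dose <= 0:
        raise ValueError(f"reference organ {reference_organ!r} received no dose")
    frame["relative_pct"] = 100.0 * (frame["dose_Gy"] / ref_dose)
    frame.loc[reference_organ, "relative_pct"] = 100.0  # exact by definition
    return OrganDoseTable(frame, reference_organ)


def absolute_doses(table: OrganDoseTable,
                   prescription_gy: float = PRESCRIPTION_GY) -> pd.DataFrame:
    """Absolute organ doses [mGy] for a prescription to the reference organ.

    dose_mGy = prescription * relative/100 (in mGy), with the organ's
    relative statistical uncertainty propagated multiplicatively.
    """
    if prescription_gy <= 0:
        raise ValueError("prescription must be > 0")
    out = table.frame[["relative_pct", "rel_unc_pct"]].copy()
    out["dose_mGy"] = prescription_gy * out["relative_pct"] / 100.0 * 1000.0
    out["unc_mGy"] = out["dose_mGy"] * out["rel_unc_pct"] / 100.0
    return out


def relative_dose_from_fraction(relative_pct: float,
                                prescription_gy: float = PRESCRIPTION_GY) -> float:
    """Scale a tabulated relative dose [%] to absolute mGy (Eq.-style arithmetic)."""
    return prescription_gy * relative_pct / 100.0 * 1000.0


def misalignment_study(phantom: OrganPhantom, source, geometry, config,
                       disk: ShieldDisk, seed: int | None = None):
    """Paired with-disk / no-disk comparison (complete misalignment case).

    Runs two otherwise identical simulations — the same source, geometry,
    transport configuration and seed — with and without the shielding disk,
    and reports both organ tables plus per-organ relative-dose deltas.
    """
    from .transport import run_simulation

    if seed is not None:
        config = replace(config, seed=seed)
    spec_with = phantom.phantom_spec(disk)
    spec_without = phantom.phantom_spec(replace(disk, present=False))
    grid_with = run_simulation(source, geometry, spec_with, config)
    grid_without = run_simulation(source, geometry, spec_without, config)
    t_with = score_organ_doses(phantom, grid_with, disk=disk)
    t_without = score_organ_doses(phantom, grid_without)
    delta = (t_without.frame["relative_pct"] - t_with.frame["relative_pct"])
    return {"with_disk": t_with, "without_disk": t_without,
            "delta_relative_pct": delta}
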