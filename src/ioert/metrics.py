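"""Curve extraction and output-factor computation from dose grids.

PDDs are read with a 1x6x6 mm^3 parallel-plate-chamber-like volume (thin
axis along depth) and lateral profiles with a 1x3x6 mm^3 diode-like volume
(thin axis along the scanned direction), averaging the per-voxel deposited
energy over the scoring footprint and combining entry-count statistics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .transport import DoseGrid

#: frozen reference depth-of-maximum per nominal energy [mm]
REFERENCE_ZMAX_MM = {6: 13.0, 9: 18.0, 12: 22.0}


@dataclass
class Curve:
    """1D sampled dose distribution (PDD or lateral profile)."""

    positions: np.ndarray  # mm, strictly increasing
    values: np.ndarray
    uncertainties: np.ndarray | None = None
    axis: str = "depth"  # depth | inplane | crossplane
    normalization: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, float)
        self.values = np.asarray(self.values, float)
        if self.uncertainties is None:
            self.uncertainties = np.zeros_like(self.values)
        self.uncertainties = np.asarray(self.uncertainties, float)
        if self.positions.size != self.values.size:
            raise ValueError("positions and values must have equal length")
        if self.uncertainties.size != self.values.size:
            raise ValueError("uncertainties must match values in length")
        if self.positions.size and np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        if np.any(self.uncertainties < 0):
            raise ValueError("uncertainties must be >= 0")

    def __len__(self) -> int:
        return self.positions.size

    def normalized(self, at: float | None = None) -> "Curve":
        """Scale so the value at position ``at`` (default: the maximum) is 100."""
        if at is None:
            ref_val = float(np.max(self.values))
            ref_pos = float(self.positions[int(np.argmax(self.values))])
        else:
            ref_val = float(np.interp(at, self.positions, self.values))
            ref_pos = float(at)
        if ref_val <= 0:
            raise ValueError("cannot normalize to a non-positive reference value")
        scale = 100.0 / ref_val
        return replace(self, values=self.values * scale,
                       uncertainties=self.uncertainties * scale,
                       normalization={"position_mm": ref_pos, "value": ref_val})


@dataclass(frozen=True)
class ScoringVolume:
    """Rectangular detector-like averaging volume; edges in mm.

    dx/dy are transverse, dz is along depth.  For a scanned curve the
    1 mm (thin) axis must lie along the scan direction.
    """

    dx: float
    dy: float
    dz: float

    def __post_init__(self):
        if min(self.dx, self.dy, self.dz) <= 0:
            raise ValueError("scoring-volume edges must be > 0")


#: chamber-like volume for PDDs (thin along depth)
PDD_SCORING = ScoringVolume(6.0, 6.0, 1.0)
#: diode-like volume for profiles (thin along the scanned axis)
PROFILE_SCORING = ScoringVolume(1.0, 3.0, 6.0)


@dataclass(frozen=True)
class OFResult:
    """Output factor with its propagated statistical uncertainty."""

    value: float
    uncertainty: float
    applicator: str = ""
    energy: str = ""
    zmax_mm: float = float("nan")

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("OF must be > 0")
        if self.uncertainty < 0:
            raise ValueError("uncertainty must be >= 0")


def _half_extent(extent_mm: float, spacing_mm: float) -> int:
    """Number of voxels on each side of the centre voxel for a given extent."""
    n = max(1, int(round(extent_mm / spacing_mm)))
    return (n - 1) // 2


def _footprint_mean(grid: DoseGrid, ix, iy, iz, hx, hy, hz):
    """Mean energy and relative sigma over a voxel box (clipping is an error)."""
    nx, ny, nz = grid.dims
    if ix - hx < 0 or ix + hx >= nx or iy - hy < 0 or iy + hy >= ny \
            or iz - hz < 0 or iz + hz >= nz:
        raise ValueError("scoring footprint exceeds the dose grid")
    box = grid.energy[ix - hx:ix + hx + 1, iy - hy:iy + hy + 1, iz - hz:iz + hz + 1]
    ent = grid.entries[ix - hx:ix + hx + 1, iy - hy:iy + hy + 1, iz - hz:iz + hz + 1]
    val = float(np.mean(box))
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.where(ent > 0, box ** 2 / ent, 0.0)
    sig = float(np.sqrt(np.sum(var))) / box.size
    return val, sig


def extract_pdd(grid: DoseGrid, scoring: ScoringVolume = PDD_SCORING) -> Curve:
    """Central-axis depth-dose curve with detector-volume averaging."""
    sx, sy, sz = grid.spacing
    hx = _half_extent(scoring.dx, sx)
    hy = _half_extent(scoring.dy, sy)
    hz = _half_extent(scoring.dz, sz)
    ix, iy = grid.central_indices()
    zpos = grid.axis_positions(2)
    vals = np.empty(grid.dims[2] - 2 * hz)
    sigs = np.empty_like(vals)
    for k in range(hz, grid.dims[2] - hz):
        vals[k - hz], sigs[k - hz] = _footprint_mean(grid, ix, iy, k, hx, hy, hz)
    return Curve(zpos[hz:grid.dims[2] - hz], vals, sigs, axis="depth",
                 meta={"scoring_mm3": scoring.dx * scoring.dy * scoring.dz})


def extract_profile(grid: DoseGrid, depth_mm: float, axis: str = "inplane",
                    scoring: ScoringVolume = PROFILE_SCORING) -> Curve:
    """Lateral dose profile at a depth, thin scoring axis along the scan."""
    sx, sy, sz = grid.spacing
    oz = grid.origin[2]
    if not (oz <= depth_mm <= oz + grid.dims[2] * sz):
        raise ValueError(f"depth {depth_mm} mm outside the grid")
    iz = min(int((depth_mm - oz) / sz), grid.dims[2] - 1)
    ixc, iyc = grid.central_indices()
    # scoring.dx is the thin scanned axis, dy the other lateral, dz depth
    hz = _half_extent(scoring.dz, sz)
    if axis == "inplane":  # scan along x
        h_scan = _half_extent(scoring.dx, sx)
        h_other = _half_extent(scoring.dy, sy)
        n = grid.dims[0]
        pos = grid.axis_positions(0)
        vals = np.empty(n - 2 * h_scan)
        sigs = np.empty_like(vals)
        for i in range(h_scan, n - h_scan):
            vals[i - h_scan], sigs[i - h_scan] = _footprint_mean(
                grid, i, iyc, iz, h_scan, h_other, hz)
        pos = pos[h_scan:n - h_scan]
    elif axis == "crossplane":  # scan along y
        h_scan = _half_extent(scoring.dx, sy)
        h_other = _half_extent(scoring.dy, sx)
        n = grid.dims[1]
        pos = grid.axis_positions(1)
        vals = np.empty(n - 2 * h_scan)
        sigs = np.empty_like(vals)
        for j in range(h_scan, n - h_scan):
            vals[j - h_scan], sigs[j - h_scan] = _footprint_mean(
                grid, ixc, j, iz, h_other, h_scan, hz)
        pos = pos[h_scan:n - h_scan]
    else:
        raise ValueError("axis must be 'inplane' or 'crossplane'")
    return Curve(pos, vals, sigs, axis=axis, meta={"depth_mm": depth_mm})


def find_zmax(pdd: Curve, smooth: bool = False, window: int = 3) -> float:
    """Position of the curve maximum; ties resolved toward the smaller depth.

    With ``smooth=True`` a moving average (default 3 points, odd ``window``)
    is applied first, which stabilizes the argmax on noisy Monte Carlo
    curves with broad maxima.
    """
    if len(pdd) == 0:
        raise ValueError("empty curve")
    v = pdd.values
    if not np.any(v > 0):
        raise ValueError("all-zero curve has no maximum")
    if smooth and len(pdd) >= window:
        if window < 1 or window % 2 == 0:
            raise ValueError("window must be a positive odd number")
        half = window // 2
        v = np.convolve(v, np.ones(window) / window, mode="same")
        v[:half] = pdd.values[:half]  # edges: keep raw values
        if half:
            v[-half:] = pdd.values[-half:]
    # argmax returns the first index of the maximum -> smallest depth
    return float(pdd.positions[int(np.argmax(v))])


def robust_normalize(curve: Curve, window: int = 11,
                     flat_half_width: float | None = None) -> Curve:
    """Normalize to 100 using a noise-robust reference value.

    Depth curves are scaled by the maximum of a ``window``-point moving
    average (a raw noisy spike would otherwise bias the whole curve);
    lateral profiles are scaled by the mean over the central flat region
    (|x| <= 0.35 x field diameter, or ``flat_half_width``).
    """
    if curve.axis == "depth":
        v = curve.values
        if len(curve) >= window:
            half = window // 2
            sm = np.convolve(v, np.ones(window) / window, mode="same")
            sm[:half] = v[:half]
            if half:
                sm[-half:] = v[-half:]
            ref = float(sm.max())
        else:
            ref = float(v.max())
    else:
        if flat_half_width is None:
            field_mm = curve.meta.get("field_diameter_mm")
            flat_half_width = 0.35 * field_mm if field_mm else None
        if flat_half_width:
            mask = np.abs(curve.positions) <= flat_half_width
            ref = float(curve.values[mask].mean()) if mask.any() else float(
                np.interp(0.0, curve.positions, curve.values))
        else:
            ref = float(np.interp(0.0, curve.positions, curve.values))
    if ref <= 0:
        raise ValueError("cannot normalize to a non-positive reference value")
    scale = 100.0 / ref
    return replace(curve, values=curve.values * scale,
                   uncertainties=curve.uncertainties * scale,
                   normalization={"value": ref, "mode": "robust"})


def measurement_grid_profile(lo: float, hi: float, flat_half_width: float) -> np.ndarray:
    """Commissioning-style sampling positions for a lateral profile.

    1 mm pitch outside the central flat region, 4 mm inside it, then the
    flat region is linearly interpolated back to 2 mm pitch.
    """
    coarse = np.arange(0.0, flat_half_width + 1e-9, 4.0)
    coarse = np.unique(np.concatenate([-coarse[::-1], coarse]))
    fine2 = np.arange(coarse[0], coarse[-1] + 1e-9, 2.0)
    left = np.arange(coarse[0] - 1.0, lo - 1e-9, -1.0)[::-1]
    right = np.arange(coarse[-1] + 1.0, hi + 1e-9, 1.0)
    return np.concatenate([left, fine2, right]), coarse


def measurement_grid_pdd(lo: float, hi: float, buildup_end: float) -> np.ndarray:
    """1 mm pitch through the build-up region, 2 mm beyond it."""
    fine = np.arange(lo, buildup_end + 1e-9, 1.0)
    coarse = np.arange(fine[-1] + 2.0, hi + 1e-9, 2.0)
    return np.concatenate([fine, coarse])


def resample_to_measurement(curve: Curve, flat_half_width: float | None = None,
                            buildup_end: float | None = None) -> Curve:
    """Resample a finely sampled curve to the measurement sampling scheme.

    Profiles: 4 mm sampling inside the central flat region (|x| below
    0.35x the field diameter unless given explicitly) interpolated back to
    2 mm, 1 mm outside.  PDDs: 1 mm up to the depth of maximum (the
    build-up), 2 mm beyond.  Linear interpolation throughout, so any
    piecewise-linear input is reproduced exactly on the new grid.
    """
    lo, hi = float(curve.positions[0]), float(curve.positions[-1])
    if curve.axis == "depth":
        if buildup_end is None:
            buildup_end = find_zmax(curve, smooth=True)
        grid = measurement_grid_pdd(lo, hi, buildup_end)
        vals = np.interp(grid, curve.positions, curve.values)
        sigs = np.interp(grid, curve.positions, curve.uncertainties)
    else:
        if flat_half_width is None:
            field_mm = curve.meta.get("field_diameter_mm")
            if field_mm is None:
                raise ValueError("flat_half_width (or field_diameter_mm meta) required "
                                 "for profile resampling")
            flat_half_width = 0.35 * field_mm
        grid, coarse = measurement_grid_profile(lo, hi, flat_half_width)
        # sample at the measurement pitch first: 4 mm inside the flat region
        coarse_vals = np.interp(coarse, curve.positions, curve.values)
        vals = np.interp(grid, curve.positions, curve.values)
        sigs = np.interp(grid, curve.positions, curve.uncertainties)
        inside = (grid >= coarse[0] - 1e-9) & (grid <= coarse[-1] + 1e-9)
        # ... then linearly interpolate the 4 mm samples onto the 2 mm grid
        vals[inside] = np.interp(grid[inside], coarse, coarse_vals)
        sigs[inside] = np.interp(grid[inside], coarse,
                                 np.interp(coarse, curve.positions, curve.uncertainties))
    return Curve(grid, vals, sigs, axis=curve.axis,
                 normalization=dict(curve.normalization), meta=dict(curve.meta))


def central_axis_dose(grid: DoseGrid, zmax_mm: float,
                      scoring: ScoringVolume = PDD_SCORING,
                      mode: str = "volume") -> tuple[float, float]:
    """Central-axis dose estimate at a depth; (value, relative sigma).

    ``mode='volume'`` averages over the chamber-like scoring volume (the
    stable default); ``mode='voxel'`` reads the single central-axis voxel.
    """
    sx, sy, sz = grid.spacing
    ix, iy = grid.central_indices()
    iz = min(int((zmax_mm - grid.origin[2]) / sz), grid.dims[2] - 1)
    if mode == "voxel":
        val = float(grid.energy[ix, iy, iz])
        n = int(grid.entries[ix, iy, iz])
        rel = 1.0 / math.sqrt(n) if n > 0 else float("nan")
        return val, rel
    hx = _half_extent(scoring.dx, sx)
    hy = _half_extent(scoring.dy, sy)
    hz = _half_extent(scoring.dz, sz)
    val, sig = _footprint_mean(grid, ix, iy, iz, hx, hy, hz)
    rel = sig / val if val > 0 else float("nan")
    return val, rel


def compute_of(ref_grid: DoseGrid, nonref_grid: DoseGrid, zmax_ref_mm: float,
               scoring: ScoringVolume = PDD_SCORING, mode: str = "volume",
               applicator: str = "", energy: str = "") -> OFResult:
    """Output factor OF = D_nonref(zmax) / D_ref(zmax) at the reference depth.

    Both doses are central-axis scoring-volume estimates at the nominal
    energy's frozen reference z_max; the relative uncertainty is the
    quadrature sum of the entry-count uncertainties of numerator and
    denominator.
    """
    d_ref, s_ref = central_axis_dose(ref_grid, zmax_ref_mm, scoring, mode)
    d_non, s_non = central_axis_dose(nonref_grid, zmax_ref_mm, scoring, mode)
    if d_ref <= 0:
        raise ZeroDivisionError("reference central-axis dose is zero")
    of = d_non / d_ref
    unc = of * math.sqrt(s_ref ** 2 + s_non ** 2)
    return OFResult(value=of, uncertainty=unc, applicator=applicator,
                    energy=energy, zmax_mm=zmax_ref_mm)
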