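"""Synthetic commissioning data: reference curves and film-like images.

Real IOERT commissioning curves (water-tank PDDs and profiles) and film
profiles are not redistributable, so this module generates stand-ins with
the same sampling structure: engine-produced curves with detector-volume
scoring, resampled to the measurement grids (1 mm steps, 4 mm central
region interpolated to 2 mm) and perturbed by independent Gaussian noise
at the experimental uncertainty level (2.1% by default).  Every artifact
carries a machine-readable provenance record (truth parameters, noise,
seed) and regenerates bit-identically from it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .beam import Applicator, BeamSource, build_machine, default_stack, FWHM_TO_SIGMA
from .metrics import (Curve, PDD_SCORING, PROFILE_SCORING, extract_pdd,
                      extract_profile, find_zmax, resample_to_measurement,
                      robust_normalize)
from .transport import TransportConfig, run_simulation, water_phantom

#: aggregate experimental uncertainty of the commissioning measurements [%]
DEFAULT_NOISE_PCT = 2.1


@dataclass
class ReferenceCurveSet:
    """PDD + inplane + crossplane reference curves for one nominal energy."""

    pdd: Curve
    inplane: Curve
    crossplane: Curve
    provenance: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"pdd": self.pdd, "inplane": self.inplane, "crossplane": self.crossplane}


def generate_reference_set(truth: BeamSource, applicator: Applicator | None = None,
                           *, nominal_energy: float | None = None,
                           noise_pct: float = DEFAULT_NOISE_PCT, seed: int = 0,
                           n_histories: int = 1_000_000,
                           phantom=None, stack=None,
                           profile_depth_mm: float | None = None,
                           transport_kwargs: dict | None = None) -> ReferenceCurveSet:
    """Run the engine at the truth parameters and emit noisy measured-style curves.

    The noiseless curves are normalized to 100 at the central-axis maximum,
    resampled to the measurement sampling scheme, then perturbed point-wise
    by multiplicative Gaussian noise of relative width ``noise_pct`` %.
    """
    if noise_pct < 0:
        raise ValueError("noise_pct must be >= 0")
    applicator = applicator or Applicator(diameter=10.0)
    stack = stack or default_stack()
    phantom = phantom or water_phantom(side_mm=140.0, depth_mm=80.0, spacing_mm=1.0)
    geometry = build_machine(stack, applicator)
    config = TransportConfig(seed=seed, n_histories=n_histories,
                             **(transport_kwargs or {}))
    grid = run_simulation(truth, geometry, phantom, config)

    pdd = extract_pdd(grid, PDD_SCORING)
    zmax = find_zmax(pdd, smooth=True, window=11)
    pdd = robust_normalize(pdd)
    field_mm = applicator.diameter * 10.0
    depth = profile_depth_mm if profile_depth_mm is not None else zmax
    profiles = {}
    for axis in ("inplane", "crossplane"):
        prof = extract_profile(grid, depth, axis, PROFILE_SCORING)
        prof.meta["field_diameter_mm"] = field_mm
        profiles[axis] = robust_normalize(prof)

    rng = np.random.default_rng(seed + 7_777_777)
    curves = {}
    for name, curve in (("pdd", pdd), ("inplane", profiles["inplane"]),
                        ("crossplane", profiles["crossplane"])):
        res = resample_to_measurement(curve)
        if noise_pct > 0:
            noisy = res.values * (1.0 + noise_pct / 100.0 * rng.standard_normal(len(res)))
        else:
            noisy = res.values.copy()
        sig = np.abs(res.values) * noise_pct / 100.0
        curves[name] = Curve(res.positions, noisy, sig, axis=res.axis,
                             normalization=dict(res.normalization),
                             meta=dict(res.meta))

    provenance = {
        "truth": {"mean_energy": truth.mean_energy, "sigma_e": truth.sigma_e,
                  "spot_fwhm": truth.spot_fwhm, "divergence": truth.divergence},
        "nominal_energy": nominal_energy,
        "applicator": {"diameter_cm": applicator.diameter, "bevel": applicator.bevel},
        "noise_pct": noise_pct, "seed": seed, "n_histories": n_histories,
        "zmax_mm": zmax, "profile_depth_mm": depth,
        "noise_model": "independent multiplicative Gaussian",
    }
    return ReferenceCurveSet(curves["pdd"], curves["inplane"], curves["crossplane"],
                             provenance)


def generate_parametric_pdd(zmax_mm: float, r50_mm: float,
                            surface_ratio: float = 0.85,
                            grid: np.ndarray | None = None) -> Curve:
    """Engine-free closed-form PDD fixture: quadratic build-up + logistic falloff.

    The curve attains exactly 100 at ``zmax_mm``, ``100*surface_ratio`` at
    the surface, 50 at ``r50_mm``, and decreases monotonically beyond the
    maximum.  Only those constraints are contractual; the functional form
    is an internal convenience.
    """
    if not (0 < zmax_mm < r50_mm):
        raise ValueError("need 0 < zmax < R50")
    if not (0 <= surface_ratio < 1):
        raise ValueError("surface_ratio must be in [0, 1)")
    if grid is None:
        grid = np.arange(0.0, 2.0 * r50_mm + 1e-9, 1.0)
    grid = np.asarray(grid, float)

    # falloff: logistic g(z)=1/(1+exp((z-m)/s)), rescaled to 100 at zmax;
    # m solved so the value at R50 is exactly 50
    s = (r50_mm - zmax_mm) / 4.0

    def g(z, m):
        return 1.0 / (1.0 + np.exp((z - m) / s))

    def f50(m):
        return g(r50_mm, m) / g(zmax_mm, m) - 0.5

    m = brentq(f50, zmax_mm - 50.0 * s, r50_mm + 50.0 * s)
    vals = np.empty_like(grid)
    up = grid <= zmax_mm
    vals[up] = 100.0 - 100.0 * (1.0 - surface_ratio) * ((grid[up] - zmax_mm) / zmax_mm) ** 2
    vals[~up] = 100.0 * g(grid[~up], m) / g(zmax_mm, m)
    return Curve(grid, vals, np.zeros_like(vals), axis="depth",
                 meta={"zmax_mm": zmax_mm, "r50_mm": r50_mm,
                       "surface_ratio": surface_ratio, "synthetic": True})


def generate_film_image(spot_fwhm_mm: float, mm_per_px: float = 0.5,
                        size_px: int = 201, noise: float = 0.0, seed: int = 0,
                        halo_fraction: float = 0.15, halo_scale: float = 4.0,
                        depth_mm: float = 18.0) -> dict:
    """Parametric film-style fluence image of the bare (no-applicator) beam.

    A radially symmetric double Gaussian — core at the requested FWHM plus a
    broad scattered halo — with optional additive pixel noise, emulating a
    radiochromic film exposed at the 9 MeV depth of maximum (z = 18 mm by
    default).  Returns the image plus its row/column integral profiles and a
    provenance record.
    """
    if mm_per_px <= 0:
        raise ValueError("mm_per_px must be > 0")
    half = (size_px - 1) / 2.0
    ax = (np.arange(size_px) - half) * mm_per_px
    xx, yy = np.meshgrid(ax, ax, indexing="ij")
    r2 = xx ** 2 + yy ** 2
    sig = spot_fwhm_mm * FWHM_TO_SIGMA
    core = np.exp(-0.5 * r2 / sig ** 2)
    halo = np.exp(-0.5 * r2 / (halo_scale * sig) ** 2)
    img = (1.0 - halo_fraction) * core + halo_fraction * halo
    if noise > 0:
        rng = np.random.default_rng(seed)
        img = img + noise * rng.standard_normal(img.shape)
    return {
        "image": img,
        "positions_mm": ax,
        "row_profile": img.sum(axis=1),
        "col_profile": img.sum(axis=0),
        "provenance": {"spot_fwhm_mm": spot_fwhm_mm, "mm_per_px": mm_per_px,
                       "size_px": size_px, "noise": noise, "seed": seed,
                       "halo_fraction": halo_fraction, "halo_scale": halo_scale,
                       "depth_mm": depth_mm, "synthetic": True},
    }


def measure_fwhm(positions: np.ndarray, profile: np.ndarray) -> float:
    """Full width at half maximum by linear interpolation of the crossings."""
    profile = np.asarray(profile, float)
    top = float(np.max(profile))
    base = float(np.min(profile))
    half = base + (top - base) / 2.0
    above = profile >= half
    idx = np.where(above)[0]
    if idx.size == 0:
        raise ValueError("profile never reaches half maximum")
    i0, i1 = idx[0], idx[-1]
    left = positions[i0] if i0 == 0 else np.interp(
        half, [profile[i0 - 1], profile[i0]], [positions[i0 - 1], positions[i0]])
    right = positions[i1] if i1 == len(profile) - 1 else np.interp(
        half, [profile[i1 + 1], profile[i1]], [positions[i1 + 1], positions[i1]])
    return float(right - left)


def write_pgm(path, image: np.ndarray) -> None:
    """16-bit ASCII PGM export of a film image (values scaled to 0..65535)."""
    img = np.asarray(image, float)
    lo, hi = float(img.min()), float(img.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 0.0
    data = np.round((img - lo) * scale).astype(np.uint16)
    with open(path, "w") as fh:
        fh.write(f"P2\n{data.shape[1]} {data.shape[0]}\n65535\n")
        for row in data:
            fh.write(" ".join(str(int(v)) for v in row) + "\n")
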