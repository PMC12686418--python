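"""Dose-grid persistence: MetaImage (.mhd/.raw) pairs plus a JSON sidecar.

The energy and entry-count volumes are written as two float32 MetaImage
files (the medical-imaging interchange format readable by most TPS/research
tools) and the run metadata (seed, histories, energy bookkeeping, config
hash) goes into ``<base>.json``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import SimpleITK as sitk

from .transport import DoseGrid


def _to_image(array: np.ndarray, grid: DoseGrid) -> sitk.Image:
    # our arrays are (x, y, z); SimpleITK expects (z, y, x) in memory
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        array.transpose(2, 1, 0).astype(np.float32)))
    img.SetSpacing(tuple(float(s) for s in grid.spacing))
    img.SetOrigin(tuple(float(o) for o in grid.origin))
    return img


def write_dose_grid(base_path, grid: DoseGrid) -> dict:
    """Write ``<base>_energy.mhd``, ``<base>_entries.mhd`` and ``<base>.json``."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    paths = {"energy": str(base) + "_energy.mhd",
             "entries": str(base) + "_entries.mhd",
             "meta": str(base) + ".json"}
    sitk.WriteImage(_to_image(grid.energy, grid), paths["energy"])
    sitk.WriteImage(_to_image(grid.entries.astype(np.float64), grid), paths["entries"])
    meta = {"dims": list(grid.dims), "spacing": list(grid.spacing),
            "origin": list(grid.origin),
            "meta": {k: (int(v) if isinstance(v, (int, np.integer)) else float(v))
                     for k, v in grid.meta.items()
                     if isinstance(v, (int, float, np.integer, np.floating))}}
    with open(paths["meta"], "w") as fh:
        json.dump(meta, fh, indent=1, sort_keys=True)
    return paths


def write_phantom_labels(base_path, phantom) -> dict:
    """Export an organ phantom's label grid as MetaImage + ID-to-name JSON."""
    base = Path(base_path)
    base.parent.mkdir(parents=True, exist_ok=True)
    img = sitk.GetImageFromArray(np.ascontiguousarray(
        phantom.labels.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in phantom.spacing))
    img.SetOrigin(tuple(float(o) for o in phantom.origin))
    paths = {"labels": str(base) + "_labels.mhd",
             "names": str(base) + "_organs.json"}
    sitk.WriteImage(img, paths["labels"])
    id_map = {str(oid): info.name for oid, info in sorted(phantom.registry.items())}
    with open(paths["names"], "w") as fh:
        json.dump(id_map, fh, indent=1)
    return paths


def read_dose_grid(base_path) -> DoseGrid:
    base = Path(base_path)
    energy_img = sitk.ReadImage(str(base) + "_energy.mhd")
    entries_img = sitk.ReadImage(str(base) + "_entries.mhd")
    with open(str(base) + ".json") as fh:
        sidecar = json.load(fh)
    energy = sitk.GetArrayFromImage(energy_img).transpose(2, 1, 0).astype(np.float64)
    entries = sitk.GetArrayFromImage(entries_img).transpose(2, 1, 0)
    entries = np.round(entries).astype(np.int64)
    return DoseGrid(origin=tuple(sidecar["origin"]),
                    spacing=tuple(sidecar["spacing"]),
                    dims=tuple(sidecar["dims"]),
                    energy=energy, entries=entries,
                    meta=dict(sidecar.get("meta", {})))
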