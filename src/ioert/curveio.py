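"""Curve CSV dialect: lossless roundtrip of positions, values, uncertainties.

Header lines start with ``#`` and carry key=value metadata (axis,
normalization, energy, applicator, anything in ``curve.meta``); the data
columns are ``position_mm,value,sigma``.  Floats are written with repr
precision so a write -> read roundtrip is exact.
"""

from __future__ import annotations

import json
import warnings

import numpy as np

from .metrics import Curve


def write_curve_csv(path, curve: Curve) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# axis={curve.axis}\n")
        if curve.normalization:
            fh.write(f"# normalization={json.dumps(curve.normalization, sort_keys=True)}\n")
        for key in sorted(curve.meta):
            fh.write(f"# {key}={json.dumps(curve.meta[key])}\n")
        fh.write("position_mm,value,sigma\n")
        for p, v, s in zip(curve.positions, curve.values, curve.uncertainties):
            fh.write(f"{float(p)!r},{float(v)!r},{float(s)!r}\n")


def read_curve_csv(path) -> Curve:
    meta: dict = {}
    axis = "depth"
    normalization: dict = {}
    positions, values, sigmas = [], [], []
    missing_sigma = False
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                key = key.strip()
                val = val.strip()
                if key == "axis":
                    axis = val
                elif key == "normalization":
                    normalization = json.loads(val)
                else:
                    try:
                        meta[key] = json.loads(val)
                    except json.JSONDecodeError:
                        meta[key] = val
                continue
            if line.startswith("position_mm"):
                cols = line.split(",")
                if len(cols) < 3:
                    missing_sigma = True
                continue
            parts = line.split(",")
            positions.append(float(parts[0]))
            values.append(float(parts[1]))
            if len(parts) >= 3:
                sigmas.append(float(parts[2]))
            else:
                missing_sigma = True
                sigmas.append(0.0)
    if missing_sigma:
        warnings.warn(f"{path}: no sigma column; uncertainties read as zeros",
                      stacklevel=2)
    pos = np.asarray(positions)
    if pos.size and np.any(np.diff(pos) <= 0):
        raise ValueError(f"{path}: positions must be strictly increasing")
    return Curve(pos, np.asarray(values), np.asarray(sigmas), axis=axis,
                 normalization=normalization, meta=meta)
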