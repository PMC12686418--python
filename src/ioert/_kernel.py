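"""Numba condensed-history stepping kernel for voxelized phantoms.

One serial loop per electron: CSDA energy loss from tabulated stopping
powers, Highland Gaussian small-angle deflection per step, step length
capped by the voxel crossing and by ``max_step``, residual energy deposited
locally below the cutoff.  Radiative losses are removed from the electron
but not transported.  Deterministic for a fixed seed and particle order.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

ELECTRON_REST_MEV = 0.510998950


@njit(cache=True)
def _interp_loglin(le, loge, table_row):
    """Linear interpolation of table_row over loge at point le (clamped)."""
    n = loge.shape[0]
    if le <= loge[0]:
        return table_row[0]
    if le >= loge[n - 1]:
        return table_row[n - 1]
    lo = 0
    for k in range(1, n):
        if loge[k] >= le:
            lo = k - 1
            break
    f = (le - loge[lo]) / (loge[lo + 1] - loge[lo])
    return table_row[lo] + f * (table_row[lo + 1] - table_row[lo])


@njit(cache=True)
def _highland_sigma(e, t_gcm2, inv_x0):
    if t_gcm2 <= 0.0 or inv_x0 <= 0.0:
        return 0.0
    pc = math.sqrt(e * (e + 2.0 * ELECTRON_REST_MEV))
    beta = pc / (e + ELECTRON_REST_MEV)
    x = t_gcm2 * inv_x0
    bracket = 1.0 + 0.038 * math.log(x)
    if bracket < 0.0:
        bracket = 0.0
    return 13.6 / (beta * pc) * math.sqrt(x) * bracket


@njit(cache=True)
def transport_voxels(x, y, z, u, v, w, e, wt,
                     mat_id, dens, loge, logscol, radfrac, inv_x0, za,
                     sx, sy, sz, nx, ny, nz,
                     max_step, cutoff, straggling, ms_scale, seed,
                     edep, entries):
    """Transport electrons through a voxel grid, scoring energy and entries.

    Positions are grid-local (mm, voxel [0,0,0] spans [0,sx)x[0,sy)x[0,sz)).
    ``edep`` (float64) and ``entries`` (int64) are flat C-order arrays of
    length nx*ny*nz, modified in place.  Returns (deposited, radiative,
    escaped, n_escaped) energy sums in MeV (weighted).
    """
    np.random.seed(seed)
    dep_sum = 0.0
    rad_sum = 0.0
    esc_sum = 0.0
    esc_n = 0
    n = x.shape[0]
    nyz = ny * nz
    for i in range(n):
        px = x[i]
        py = y[i]
        pz = z[i]
        du = u[i]
        dv = v[i]
        dw = w[i]
        ei = e[i]
        wi = wt[i]
        # per-history stopping-power scale: a cheap, unbiased stand-in for
        # range straggling (Landau fluctuations and delta-ray losses are not
        # tracked explicitly); width is a one-time engine calibration
        fs = 1.0
        if straggling > 0.0:
            fs = 1.0 + straggling * np.random.normal()
            if fs < 0.5:
                fs = 0.5
            elif fs > 1.5:
                fs = 1.5
        ix = int(math.floor(px / sx))
        iy = int(math.floor(py / sy))
        iz = int(math.floor(pz / sz))
        if ix < 0 or ix >= nx or iy < 0 or iy >= ny or iz < 0 or iz >= nz:
            esc_sum += ei * wi
            esc_n += 1
            continue
        idx = ix * nyz + iy * nz + iz
        entries[idx] += 1
        alive = True
        while alive:
            m = mat_id[idx]
            rho = dens[m]
            # distance to the voxel boundary along the current direction
            tb = 1.0e30
            if du > 0.0:
                t = ((ix + 1) * sx - px) / du
                if t < tb:
                    tb = t
            elif du < 0.0:
                t = (ix * sx - px) / du
                if t < tb:
                    tb = t
            if dv > 0.0:
                t = ((iy + 1) * sy - py) / dv
                if t < tb:
                    tb = t
            elif dv < 0.0:
                t = (iy * sy - py) / dv
                if t < tb:
                    tb = t
            if dw > 0.0:
                t = ((iz + 1) * sz - pz) / dw
                if t < tb:
                    tb = t
            elif dw < 0.0:
                t = (iz * sz - pz) / dw
                if t < tb:
                    tb = t
            step = tb + 1.0e-6  # nudge across the boundary
            if step > max_step:
                step = max_step
            le = math.log(ei)
            s_lin = math.exp(_interp_loglin(le, loge, logscol[m])) * rho * fs
            de_col = s_lin * step * 0.1  # step mm -> cm
            f = _interp_loglin(le, loge, radfrac[m])
            de_tot = de_col / (1.0 - f)
            if ei - de_tot <= cutoff:
                # range end: residual energy deposited locally
                edep[idx] += ei * wi
                dep_sum += ei * wi
                alive = False
                break
            edep[idx] += de_col * wi
            dep_sum += de_col * wi
            rad_sum += (de_tot - de_col) * wi
            ei -= de_tot
            # move along the pre-scatter direction, then deflect
            px += du * step
            py += dv * step
            pz += dw * step
            sig = ms_scale * _highland_sigma(ei, rho * step * 0.1, inv_x0[m])
            if sig > 0.0:
                t1 = np.random.normal() * sig
                t2 = np.random.normal() * sig
                # orthonormal basis perpendicular to the direction
                pp = du * du + dv * dv
                if pp > 1.0e-12:
                    inv = 1.0 / math.sqrt(pp)
                    e1x = -dv * inv
                    e1y = du * inv
                    e1z = 0.0
                else:
                    e1x = 1.0
                    e1y = 0.0
                    e1z = 0.0
                e2x = dv * e1z - dw * e1y
                e2y = dw * e1x - du * e1z
                e2z = du * e1y - dv * e1x
                du = du + t1 * e1x + t2 * e2x
                dv = dv + t1 * e1y + t2 * e2y
                dw = dw + t1 * e1z + t2 * e2z
                inv = 1.0 / math.sqrt(du * du + dv * dv + dw * dw)
                du *= inv
                dv *= inv
                dw *= inv
            nix = int(math.floor(px / sx))
            niy = int(math.floor(py / sy))
            niz = int(math.floor(pz / sz))
            if nix < 0 or nix >= nx or niy < 0 or niy >= ny or niz < 0 or niz >= nz:
                esc_sum += ei * wi
                esc_n += 1
                alive = False
                break
            nidx = nix * nyz + niy * nz + niz
            if nidx != idx:
                entries[nidx] += 1
                idx = nidx
                ix = nix
                iy = niy
                iz = niz
    return dep_sum, rad_sum, esc_sum, esc_n
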