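"""1D gamma-index comparison of dose curves (global 3%/3 mm by default).

The measured curve is the reference, the simulated one is evaluated, as in
TPS commissioning.  For each reference point the gamma value is the minimum
over the evaluated curve of

    sqrt( |r' - r|^2 / dta^2  +  (D_e(r') - D_r(r))^2 / (dd * D_norm)^2 )

with the dose tolerance taken as a percentage of the global normalization
(the reference-curve maximum) and the evaluated curve linearly interpolated
on a fine grid inside a finite search window.  A point passes when
gamma <= 1; the boundary counts as passing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import Curve


@dataclass(frozen=True)
class GammaCriteria:
    """Acceptance criteria for the gamma comparison."""

    dose_difference: float = 3.0  # % of the global normalization
    distance_to_agreement: float = 3.0  # mm
    low_dose_threshold: float | None = None  # % of normalization, or None
    search_factor: float = 3.0  # window = +/- search_factor * DTA
    interp_step: float = 0.1  # mm

    def __post_init__(self):
        if self.dose_difference <= 0 or self.distance_to_agreement <= 0:
            raise ValueError("dose_difference and distance_to_agreement must be > 0")
        if self.interp_step <= 0 or self.search_factor <= 0:
            raise ValueError("interp_step and search_factor must be > 0")


@dataclass
class GammaResult:
    """Per-reference-point gamma values and the pass rate [%]."""

    gamma: np.ndarray
    pass_rate: float
    n_points: int
    n_evaluated: int
    criteria: GammaCriteria
    meta: dict = field(default_factory=dict)


def gamma_curve(reference: Curve, evaluated: Curve,
                criteria: GammaCriteria = GammaCriteria()) -> GammaResult:
    """Gamma analysis of an evaluated curve against a reference curve."""
    if len(reference) == 0 or len(evaluated) == 0:
        raise ValueError("gamma comparison needs non-empty curves")
    r_pos = reference.positions
    e_pos = evaluated.positions
    if r_pos[-1] < e_pos[0] or e_pos[-1] < r_pos[0]:
        raise ValueError("reference and evaluated position ranges do not overlap")

    d_norm = float(np.max(reference.values))
    if d_norm <= 0:
        raise ValueError("reference curve has a non-positive maximum")
    dd_abs = criteria.dose_difference / 100.0 * d_norm
    dta = criteria.distance_to_agreement
    half_window = criteria.search_factor * dta

    gammas = np.full(len(reference), np.inf)
    evaluated_mask = np.ones(len(reference), dtype=bool)
    if criteria.low_dose_threshold is not None:
        evaluated_mask = reference.values >= criteria.low_dose_threshold / 100.0 * d_norm

    for i, (rp, rv) in enumerate(zip(r_pos, reference.values)):
        if not evaluated_mask[i]:
            gammas[i] = np.nan
            continue
        lo = max(rp - half_window, e_pos[0])
        hi = min(rp + half_window, e_pos[-1])
        if hi < lo:
            # no evaluated data inside the window: dose-only comparison at
            # the nearest evaluated point is not defined -> gamma stays inf
            continue
        # fixed lattice anchored at the evaluated curve start, so a smaller
        # window searches an exact subset of a larger one (monotonicity) and
        # matches a dense-grid oracle point-for-point at equal step
        step = criteria.interp_step
        k0 = int(np.ceil((lo - e_pos[0]) / step - 1e-12))
        k1 = int(np.floor((hi - e_pos[0]) / step + 1e-12))
        grid = e_pos[0] + np.arange(k0, k1 + 1) * step
        if grid.size == 0:
            grid = np.array([0.5 * (lo + hi)])
        ev = np.interp(grid, e_pos, evaluated.values)
        g2 = (grid - rp) ** 2 / dta ** 2 + (ev - rv) ** 2 / dd_abs ** 2
        gammas[i] = np.sqrt(np.min(g2))

    valid = evaluated_mask
    n_eval = int(np.sum(valid))
    if n_eval == 0:
        raise ValueError("no reference points above the low-dose threshold")
    passed = np.sum(gammas[valid] <= 1.0 + 1e-12)  # boundary counts as pass
    pass_rate = 100.0 * passed / n_eval
    return GammaResult(gamma=gammas, pass_rate=float(pass_rate),
                       n_points=len(reference), n_evaluated=n_eval,
                       criteria=criteria)


def evaluate_configuration(ref_set: dict, eval_set: dict,
                           criteria: GammaCriteria = GammaCriteria(),
                           threshold: float = 95.0) -> dict:
    """Gamma pass rates for a matched curve set plus a combined verdict.

    ``ref_set`` and ``eval_set`` map curve names (e.g. 'pdd', 'inplane',
    'crossplane') to :class:`Curve`; every name must appear in both.  The
    verdict is true when every pass rate reaches ``threshold`` (90% is the
    tuning-stage gate, 95% the final acceptance gate).
    """
    if set(ref_set) != set(eval_set):
        raise ValueError(f"mismatched curve sets: {sorted(ref_set)} vs {sorted(eval_set)}")
    results = {name: gamma_curve(ref_set[name], eval_set[name], criteria)
               for name in sorted(ref_set)}
    pass_rates = {name: res.pass_rate for name, res in results.items()}
    verdict = all(rate >= threshold for rate in pass_rates.values())
    return {"pass_rates": pass_rates, "verdict": verdict,
            "threshold": threshold, "results": results}
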