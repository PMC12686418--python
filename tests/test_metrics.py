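"""Curve extraction, z_max, measurement resampling and output factors."""

import numpy as np
import pytest

from ioert.metrics import (Curve, OFResult, PDD_SCORING, PROFILE_SCORING,
                           ScoringVolume, central_axis_dose, compute_of,
                           extract_pdd, extract_profile, find_zmax,
                           measurement_grid_pdd, measurement_grid_profile,
                           resample_to_measurement)
from ioert.transport import DoseGrid


def make_grid(energy, entries=None, spacing=1.0):
    energy = np.asarray(energy, float)
    if entries is None:
        entries = np.full(energy.shape, 100, dtype=np.int64)
    nx, ny, nz = energy.shape
    s = spacing
    return DoseGrid(origin=(-nx * s / 2, -ny * s / 2, 0.0), spacing=(s, s, s),
                    dims=(nx, ny, nz), energy=energy, entries=entries,
                    meta={"injected": float(energy.sum())})


class TestExtraction:
    def test_uniform_grid_gives_flat_pdd(self):
        grid = make_grid(np.ones((21, 21, 30)))
        pdd = extract_pdd(grid)
        assert np.allclose(pdd.values, pdd.values[0])

    def test_pdd_matches_bruteforce_footprint_oracle(self, rng):
        """Scoring-volume average equals an explicit voxel-loop mean."""
        energy = rng.random((21, 21, 20))
        grid = make_grid(energy)
        pdd = extract_pdd(grid, ScoringVolume(6.0, 6.0, 1.0))
        ix, iy = grid.central_indices()
        for k, val in zip(range(len(pdd)), pdd.values):
            # centered window: 2 voxels on each side of the central one
            assert val == pytest.approx(np.mean([
                energy[i, j, k]
                for i in range(ix - 2, ix + 3)
                for j in range(iy - 2, iy + 3)]), rel=1e-12)

    def test_profile_matches_bruteforce_oracle(self, rng):
        energy = rng.random((25, 25, 20))
        grid = make_grid(energy)
        prof = extract_profile(grid, depth_mm=10.0, axis="inplane",
                               scoring=ScoringVolume(1.0, 3.0, 6.0))
        ix, iy = grid.central_indices()
        iz = 10
        i_test = 12
        val = prof.values[np.argmin(np.abs(prof.positions
                                           - grid.axis_positions(0)[i_test]))]
        oracle = np.mean([energy[i_test, j, k]
                          for j in range(iy - 1, iy + 2)
                          for k in range(iz - 2, iz + 3)])
        assert val == pytest.approx(oracle, rel=1e-12)

    def test_mirrored_grid_gives_mirrored_profile(self, rng):
        energy = rng.random((24, 24, 12))
        sym = energy + energy[::-1, :, :]
        prof = extract_profile(make_grid(sym), 6.0, "inplane")
        assert np.allclose(prof.values, prof.values[::-1], rtol=1e-12)

    def test_footprint_exceeding_grid_rejected(self):
        grid = make_grid(np.ones((4, 4, 10)))
        with pytest.raises(ValueError, match="footprint"):
            extract_pdd(grid, ScoringVolume(20.0, 20.0, 1.0))

    def test_depth_outside_grid_rejected(self, grid_9mev):
        with pytest.raises(ValueError, match="depth"):
            extract_profile(grid_9mev, depth_mm=500.0)


class TestFindZmax:
    def test_single_peak(self):
        c = Curve(np.arange(40.0), 100 - (np.arange(40.0) - 18.0) ** 2)
        assert find_zmax(c) == 18.0

    def test_plateau_tie_breaks_to_smaller_depth(self):
        v = np.zeros(30)
        v[12] = v[13] = 5.0
        assert find_zmax(Curve(np.arange(30.0), v)) == 12.0

    def test_all_zero_curve_rejected(self):
        with pytest.raises(ValueError):
            find_zmax(Curve(np.arange(10.0), np.zeros(10)))

    def test_smoothed_argmax_matches_exhaustive_scan(self, rng):
        pos = np.arange(60.0)
        vals = np.exp(-0.5 * ((pos - 21) / 10) ** 2) + 0.05 * rng.standard_normal(60)
        c = Curve(pos, vals)
        sm = np.convolve(vals, np.ones(3) / 3, mode="same")
        sm[0], sm[-1] = vals[0], vals[-1]
        expected = pos[int(np.argmax(sm))]  # independent scan oracle
        assert find_zmax(c, smooth=True) == expected

    def test_even_window_rejected(self):
        c = Curve(np.arange(10.0), np.arange(10.0))
        with pytest.raises(ValueError):
            find_zmax(c, smooth=True, window=4)


class TestResampling:
    def test_linear_ramp_reproduced_exactly(self):
        pos = np.arange(-60.0, 60.5, 0.5)
        c = Curve(pos, 3.0 * pos + 7.0, axis="inplane",
                  meta={"field_diameter_mm": 100.0})
        out = resample_to_measurement(c)
        assert np.allclose(out.values, 3.0 * out.positions + 7.0, atol=1e-9)

    def test_constant_curve_stays_constant(self):
        pos = np.arange(0.0, 60.5, 0.5)
        out = resample_to_measurement(Curve(pos, np.full(pos.size, 42.0)),
                                      buildup_end=18.0)
        assert np.allclose(out.values, 42.0)

    def test_profile_positions_match_documented_grid(self):
        """Output grid equals an independently constructed sampling scheme."""
        pos = np.arange(-60.0, 60.5, 0.5)
        c = Curve(pos, np.ones(pos.size), axis="inplane")
        out = resample_to_measurement(c, flat_half_width=20.0)
        expected, coarse = measurement_grid_profile(-60.0, 60.0, 20.0)
        assert np.array_equal(out.positions, expected)
        assert np.array_equal(coarse, np.arange(-20.0, 20.1, 4.0))
        inner = expected[(expected >= -20) & (expected <= 20)]
        assert np.allclose(np.diff(inner), 2.0)  # interpolated back to 2 mm
        outer = expected[expected < -20]
        assert np.allclose(np.diff(outer), 1.0)

    def test_pdd_grid_two_regimes(self):
        grid = measurement_grid_pdd(0.0, 60.0, buildup_end=18.0)
        fine = grid[grid <= 18.0]
        coarse = grid[grid > 18.0]
        assert np.allclose(np.diff(fine), 1.0)
        assert np.allclose(np.diff(coarse), 2.0)

    def test_normalization_max_is_100(self, grid_9mev):
        """After normalizing to the curve maximum the peak is exactly 100."""
        norm = extract_pdd(grid_9mev).normalized()
        assert norm.values.max() == pytest.approx(100.0, abs=1e-12)


class TestOutputFactor:
    def test_identity_of_is_exactly_one(self, grid_9mev):
        of = compute_of(grid_9mev, grid_9mev, zmax_ref_mm=18.0)
        assert of.value == 1.0

    def test_scaled_grid_of_and_uncertainty(self, grid_9mev):
        scaled = DoseGrid(grid_9mev.origin, grid_9mev.spacing, grid_9mev.dims,
                          grid_9mev.energy * 0.8, grid_9mev.entries,
                          dict(grid_9mev.meta))
        of = compute_of(grid_9mev, scaled, zmax_ref_mm=18.0)
        assert of.value == pytest.approx(0.8, rel=1e-12)
        _, rel = central_axis_dose(grid_9mev, 18.0)
        assert of.uncertainty == pytest.approx(0.8 * np.sqrt(2) * rel, rel=1e-9)

    def test_zero_denominator_rejected(self):
        zero = make_grid(np.zeros((21, 21, 30)))
        nonzero = make_grid(np.ones((21, 21, 30)))
        with pytest.raises(ZeroDivisionError):
            compute_of(zero, nonzero, 18.0)

    def test_voxel_mode_reads_single_voxel(self, grid_9mev):
        val, rel = central_axis_dose(grid_9mev, 18.0, mode="voxel")
        ix, iy = grid_9mev.central_indices()
        assert val == grid_9mev.energy[ix, iy, 18]

    def test_of_result_invariants(self):
        with pytest.raises(ValueError):
            OFResult(value=-0.5, uncertainty=0.0)
        with pytest.raises(ValueError):
            OFResult(value=1.0, uncertainty=-0.1)


class TestCurveValidation:
    def test_non_monotone_positions_rejected(self):
        with pytest.raises(ValueError):
            Curve(np.array([0.0, 2.0, 1.0]), np.zeros(3))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Curve(np.arange(3.0), np.zeros(4))
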