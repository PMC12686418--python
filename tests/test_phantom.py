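"""Thorax phantom construction, organ-dose scoring and the shielding disk."""

import math

import numpy as np
import pandas as pd
import pytest

from ioert.beam import Applicator, BeamSource, build_machine, default_stack
from ioert.phantom import (Ellipsoid, OrganDef, OrganPhantom, ShieldDisk,
                           absolute_doses, build_thorax_phantom,
                           misalignment_study, relative_dose_from_fraction,
                           score_organ_doses)
from ioert.transport import DoseGrid, TransportConfig, run_simulation

TABLE_ORGANS = [
    "Brain", "Head", "Heart", "Left Adrenal", "Left Arm Bone", "Left Breast",
    "Left Clavicle", "Left Kidney", "Left Leg", "Left Leg Bone", "Left Lung",
    "Left Ovary", "Left Scapula", "Lower Large Intestine", "Middle Lower Spine",
    "Pancreas", "Rib Cage", "Right Adrenal", "Right Arm Bone", "Right Breast",
    "Right Clavicle", "Right Kidney", "Right Leg", "Right Leg Bone",
    "Right Lung", "Right Ovary", "Right Scapula", "Skull", "Small Intestine",
    "Spleen", "Stomach", "Thymus", "Thyroid", "Trunk", "Upper Large Intestine",
    "Upper Spine", "Urinary Bladder", "Uterus",
]


@pytest.fixture(scope="module")
def phantom_2mm():
    return build_thorax_phantom(voxel_mm=2.0)


@pytest.fixture(scope="module")
def phantom_coarse():
    return build_thorax_phantom(voxel_mm=5.0)


@pytest.fixture(scope="module")
def treatment_setup():
    source = BeamSource(9.8, 0.9, 1.6, 0.0)
    geometry = build_machine(default_stack(), Applicator(diameter=6.0))
    return source, geometry


class TestBuild:
    def test_empty_organ_list_gives_all_air(self):
        p = build_thorax_phantom(voxel_mm=10.0, organs=[])
        assert np.all(p.labels == 0)

    def test_one_litre_sphere_has_unit_mass(self):
        """A 1 L water-density ellipsoid voxelizes to 1.000 +- 0.02 kg at 2 mm."""
        r = (1000.0 * 3.0 / (4.0 * math.pi)) ** (1.0 / 3.0) * 10.0  # mm
        organ = OrganDef("Blob", "water", Ellipsoid((-100.0, -100.0, 100.0),
                                                    (r, r, r)))
        p = build_thorax_phantom(voxel_mm=2.0, organs=[organ])
        voxel_kg = p.voxel_volume_cm3("Blob") / 1000.0  # water: 1 g/cm^3
        assert voxel_kg == pytest.approx(1.000, abs=0.02)
        assert p.registry[p.organ_id("Blob")].mass_g == pytest.approx(1000.0,
                                                                      rel=1e-6)

    def test_default_registry_covers_all_table_organs(self, phantom_2mm):
        names = {info.name for info in phantom_2mm.registry.values()}
        assert set(TABLE_ORGANS) <= names

    def test_voxelized_volume_near_analytic_for_convex_organs(self, phantom_2mm):
        """Convex, non-overlapped organs voxelize within 2% at 2 mm pitch."""
        for organ in ("Left Breast", "Right Breast", "Heart"):
            info = phantom_2mm.registry[phantom_2mm.organ_id(organ)]
            assert phantom_2mm.voxel_volume_cm3(organ) == pytest.approx(
                info.volume_cm3, rel=0.02), organ

    def test_organ_outside_world_rejected(self):
        rogue = OrganDef("Rogue", "water", Ellipsoid((0, 0, 500.0), (30, 30, 30)))
        with pytest.raises(ValueError, match="outside"):
            build_thorax_phantom(voxel_mm=5.0, organs=[rogue])

    def test_labels_fit_registry(self, phantom_coarse):
        used = set(np.unique(phantom_coarse.labels)) - {0}
        assert used <= set(phantom_coarse.registry)


class TestScoring:
    def _uniform_grid(self, phantom, organ, mev):
        energy = np.zeros(phantom.dims)
        energy[phantom.labels == phantom.organ_id(organ)] = \
            mev / np.sum(phantom.labels == phantom.organ_id(organ))
        entries = (phantom.labels > 0).astype(np.int64) * 100
        return DoseGrid(phantom.origin, phantom.spacing, phantom.dims,
                        energy, entries, {"injected": mev})

    def test_one_joule_per_kilogram_is_one_gray(self, phantom_coarse):
        """Unit check: 1 J deposited in an organ of mass m gives 1/m[kg] Gy."""
        joule_in_mev = 1.0 / 1.602176634e-13
        grid = self._uniform_grid(phantom_coarse, "Left Breast", joule_in_mev)
        table = score_organ_doses(phantom_coarse, grid)
        mass_kg = phantom_coarse.registry[
            phantom_coarse.organ_id("Left Breast")].mass_g / 1000.0
        assert table["Left Breast"]["dose_Gy"] == pytest.approx(1.0 / mass_kg,
                                                                rel=1e-9)

    def test_reference_organ_is_exactly_100_percent(self, phantom_coarse):
        grid = self._uniform_grid(phantom_coarse, "Left Breast", 1000.0)
        table = score_organ_doses(phantom_coarse, grid)
        assert table.relative("Left Breast") == 100.0
        assert table.relative("Uterus") == 0.0  # no deposits -> exactly zero

    def test_organ_energy_sum_bounded_by_injected(self, phantom_coarse,
                                                  treatment_setup):
        source, geometry = treatment_setup
        grid = run_simulation(source, geometry, phantom_coarse.phantom_spec(),
                              TransportConfig(seed=3, n_histories=60_000))
        table = score_organ_doses(phantom_coarse, grid)
        total_j = table.frame["E_J"].sum()
        injected_j = grid.meta["injected"] * 1.602176634e-13
        assert 0 < total_j <= injected_j


class TestAbsoluteDoses:
    def test_uterus_share_at_21_gray(self):
        """0.016% of a 21 Gy prescription is 3.36 mGy."""
        assert relative_dose_from_fraction(0.016) == pytest.approx(3.36, rel=1e-12)

    def test_left_lung_share_matches_rounded_hundred(self):
        assert relative_dose_from_fraction(0.472) == pytest.approx(99.12, rel=1e-12)

    def test_zero_relative_gives_zero_absolute(self):
        assert relative_dose_from_fraction(0.0) == 0.0

    def test_table_scaling_with_uncertainty(self, phantom_coarse):
        frame = pd.DataFrame({"relative_pct": [100.0, 0.016],
                              "rel_unc_pct": [0.2, 25.0]},
                             index=["Left Breast", "Uterus"])

        class FakeTable:
            pass

        t = FakeTable()
        t.frame = frame
        out = absolute_doses(t, prescription_gy=21.0)
        assert out.loc["Uterus", "dose_mGy"] == pytest.approx(3.36)
        assert out.loc["Uterus", "unc_mGy"] == pytest.approx(0.84)
        assert out.loc["Left Breast", "dose_mGy"] == pytest.approx(21_000.0)

    def test_bad_prescription_rejected(self, phantom_coarse):
        with pytest.raises(ValueError):
            absolute_doses(None, prescription_gy=0.0)


class TestDisk:
    def test_disk_absent_in_both_arms_gives_zero_deltas(self, phantom_coarse,
                                                        treatment_setup):
        source, geometry = treatment_setup
        config = TransportConfig(seed=9, n_histories=40_000)
        disk = ShieldDisk(present=False)
        res = misalignment_study(phantom_coarse, source, geometry, config, disk)
        assert np.allclose(res["delta_relative_pct"].to_numpy(), 0.0)

    def test_underlying_organs_increase_without_disk(self, phantom_coarse,
                                                     treatment_setup):
        """Rib cage, trunk and left lung take more dose on full misalignment."""
        source, geometry = treatment_setup
        config = TransportConfig(seed=9, n_histories=250_000)
        res = misalignment_study(phantom_coarse, source, geometry, config,
                                 ShieldDisk())
        delta = res["delta_relative_pct"]
        assert delta["Rib Cage"] > 0
        assert delta["Trunk"] > 0
        assert delta["Left Lung"] > 0

    def test_shadow_dose_monotone_in_disk_thickness(self, phantom_coarse,
                                                    treatment_setup):
        """Dose beneath the disk never increases with thickness (0/5/10 mm)."""
        source, geometry = treatment_setup
        config = TransportConfig(seed=17, n_histories=120_000)
        doses = []
        for thickness_cm in (None, 0.5, 1.0):  # None = no disk
            disk = (ShieldDisk(present=False) if thickness_cm is None
                    else ShieldDisk(thickness=thickness_cm))
            grid = run_simulation(source, geometry,
                                  phantom_coarse.phantom_spec(disk), config)
            table = score_organ_doses(phantom_coarse, grid,
                                      disk=disk if disk.present else None)
            doses.append(table["Rib Cage"]["dose_Gy"])
        assert doses[0] >= doses[1] >= doses[2]

    def test_disk_validation(self):
        with pytest.raises(ValueError):
            ShieldDisk(diameter=0.0)
        with pytest.raises(ValueError):
            ShieldDisk(thickness=-1.0)
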