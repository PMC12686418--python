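"""Source tuning: gamma-gated grid search, tie-breaking, recovery, logging."""

import numpy as np
import pytest

from ioert.beam import Applicator, BeamSource
from ioert.metrics import ScoringVolume
from ioert.tuning import (BeamCommissioningModel, SearchSpec, SimulationEngine,
                          tune_energy, tune_full, tune_geometry)
from ioert.transport import water_phantom

TRUTH = BeamSource(9.8, 0.9, 1.6, 0.0)

# a wide diode-like profile volume keeps candidate-curve MC noise well below
# the 3% gamma tolerance at the reduced per-candidate history budget
WIDE_DIODE = ScoringVolume(2.0, 6.0, 10.0)


def make_engine(n_histories=300_000):
    return SimulationEngine(applicator=Applicator(diameter=6.0),
                            phantom=water_phantom(100.0, 60.0, 2.0),
                            n_histories=n_histories,
                            profile_scoring=WIDE_DIODE,
                            profile_depth_mm=18.0)


@pytest.fixture(scope="module")
def reference_curves():
    """Self-generated reference set at higher statistics (known truth)."""
    engine = make_engine(n_histories=3_000_000)
    return engine.curves(TRUTH, seed=12345)


def narrow_spec(**overrides):
    defaults = dict(energy_halfwidth=0.05, sigma_halfwidth=0.01,
                    energy_step=0.05, sigma_step=0.01,
                    spot_range=(1.6, 1.6), spot_step=0.1,
                    divergence_range=(0.0, 0.0), divergence_step=0.5,
                    n_histories=300_000, max_iterations=2)
    defaults.update(overrides)
    return SearchSpec(**defaults)


class TestTuneEnergy:
    def test_initial_already_passing_is_returned_unchanged(self, reference_curves):
        engine = make_engine()
        res = tune_energy(reference_curves, TRUTH, narrow_spec(), engine)
        assert res.converged
        assert res.params == (TRUTH.mean_energy, TRUTH.sigma_e)
        assert res.pass_rate >= 90.0

    def test_recovery_within_one_grid_step(self, reference_curves):
        """Starting one step off the truth, the search lands within a step."""
        engine = make_engine()
        initial = BeamSource(10.0, 0.9, 1.6, 0.0)  # +0.2 MeV offset
        spec = narrow_spec(energy_step=0.2, energy_halfwidth=0.4,
                           sigma_halfwidth=0.0)
        res = tune_energy(reference_curves, initial, spec, engine)
        assert abs(res.params[0] - TRUTH.mean_energy) <= 0.2 + 1e-9

    def test_gross_energy_error_scores_lower_than_truth(self, reference_curves):
        """A 1.5 MeV mean-energy error visibly degrades the PDD gamma rate."""
        from ioert.gamma import gamma_curve

        engine = make_engine()
        good = engine.curves(TRUTH, seed=5, which=("pdd",))["pdd"]
        bad = engine.curves(BeamSource(11.3, 0.9, 1.6, 0.0), seed=6,
                            which=("pdd",))["pdd"]
        ref = reference_curves["pdd"]
        assert gamma_curve(ref, good).pass_rate > gamma_curve(ref, bad).pass_rate

    def test_missing_reference_pdd_rejected(self):
        with pytest.raises(ValueError, match="PDD"):
            tune_energy({}, TRUTH, narrow_spec(), make_engine())


class TestTuneGeometry:
    def test_single_candidate_is_returned_with_its_rate(self, reference_curves):
        engine = make_engine()
        res = tune_geometry(reference_curves, TRUTH, narrow_spec(), engine)
        assert res.params == (1.6, 0.0)
        assert len(res.log) == 1
        assert 0.0 <= res.pass_rate <= 100.0

    def test_divergence_grid_includes_and_accepts_zero(self, reference_curves):
        engine = make_engine()
        spec = narrow_spec(divergence_range=(0.0, 1.0), divergence_step=0.5)
        res = tune_geometry(reference_curves, TRUTH, spec, engine)
        divs = {entry["params"][1] for entry in res.log}
        assert 0.0 in divs  # boundary candidate evaluated
        assert res.params[1] in (0.0, 0.5, 1.0)


class TestTuneFull:
    def test_converges_on_self_generated_reference(self, reference_curves):
        result = tune_full(reference_curves, TRUTH,
                           narrow_spec(n_histories=1_000_000),
                           make_engine(n_histories=1_000_000))
        assert result.converged
        assert result.n_iterations <= 2
        assert all(rate > 95.0 for rate in result.pass_rates.values())
        assert result.source.mean_energy == pytest.approx(9.8, abs=0.05 + 1e-9)

    def test_max_iterations_zero_returns_initial_evaluation_only(self,
                                                                 reference_curves):
        engine = make_engine()
        result = tune_full(reference_curves, TRUTH,
                           narrow_spec(max_iterations=0), engine)
        assert result.n_iterations == 0
        assert not result.converged
        assert result.source == TRUTH
        assert set(result.pass_rates) == {"pdd", "inplane", "crossplane"}

    def test_log_records_every_engine_invocation(self, reference_curves):
        engine = make_engine()
        before = engine.n_runs
        result = tune_full(reference_curves, TRUTH, narrow_spec(), engine)
        assert len(result.log) == engine.n_runs - before
        assert all("seed" in e for e in result.log)

    def test_deterministic_given_spec_and_seeds(self, reference_curves):
        r1 = tune_full(reference_curves, TRUTH, narrow_spec(), make_engine(),
                       base_seed=7)
        r2 = tune_full(reference_curves, TRUTH, narrow_spec(), make_engine(),
                       base_seed=7)
        assert r1.source == r2.source
        assert r1.pass_rates == r2.pass_rates
        assert [e.get("pass_rate") for e in r1.log] == \
            [e.get("pass_rate") for e in r2.log]


class TestModelFacade:
    def test_fit_returns_summary_with_estimates(self, reference_curves):
        engine = make_engine()
        model = BeamCommissioningModel(reference_curves, engine, TRUTH,
                                       narrow_spec())
        result = model.fit(seed=3)
        text = result.summary()
        assert "mean energy" in text and "gamma pass rates" in text
        assert f"{result.source.mean_energy:.2f}" in text


class TestSearchSpecValidation:
    def test_bad_steps_rejected(self):
        with pytest.raises(ValueError):
            SearchSpec(energy_step=0.0)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ValueError):
            SearchSpec(final_threshold=0.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            SearchSpec(spot_range=(5.0, 1.0))
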