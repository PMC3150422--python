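"""Initialization, step loop, bookkeeping, replicates, calibration."""

import time

import numpy as np
import pandas as pd
import pytest

import rirrsim.particles as pt
from rirrsim import engine
from rirrsim.engine import SimulationParams, initialize, run_replicates
from rirrsim.exceptions import ParameterError
from rirrsim.fixtures import make_mini_fixture, make_mini_geometry, make_mini_params
from rirrsim.geometry import CYTOSOL, make_moving_layout, make_regular_layout
from rirrsim.respiration import LeakageRuleParams


class TestInitialize:
    def test_enzyme_counts_follow_percent_convention(self, cardiomyocyte_geometry, rng):
        world = initialize(SimulationParams(initial_h2o2=0), cardiomyocyte_geometry, rng)
        total = cardiomyocyte_geometry.total_pixels
        assert total == 972 * 684
        assert world.population(pt.MNSOD).n == round(0.769 / 100 * total)  # 5113
        assert world.population(pt.CUZNSOD).n == round(0.914 / 100 * total)
        assert world.population(pt.GPX_MITO).n == round(0.3 / 100 * total)
        assert world.population(pt.GPX_CYTO).n == round(0.549 / 100 * total)

    def test_zero_dose_and_zero_multipliers(self, cardiomyocyte_geometry, rng):
        params = SimulationParams(initial_h2o2=0)
        params.multipliers = {s: 0.0 for s in params.multipliers}
        world = initialize(params, cardiomyocyte_geometry, rng)
        assert world.population(pt.H2O2).n == 0
        for s in pt.ENZYME_SPECIES:
            assert world.population(s).n == 0

    def test_enzymes_start_in_home_compartment(self, cardiomyocyte_geometry, rng):
        world = initialize(SimulationParams(), cardiomyocyte_geometry, rng)
        lab = world.label_map
        for s in (pt.MNSOD, pt.GPX_MITO):
            labels = pt.pixel_labels(world.population(s).positions, lab)
            assert (labels != CYTOSOL).all()
        for s in (pt.CUZNSOD, pt.GPX_CYTO):
            labels = pt.pixel_labels(world.population(s).positions, lab)
            assert (labels == CYTOSOL).all()

    def test_bolus_lands_in_centered_square(self, cardiomyocyte_geometry, rng):
        params = SimulationParams(initial_h2o2=500, injection_side=108)
        world = initialize(params, cardiomyocyte_geometry, rng)
        pos = world.population(pt.H2O2).positions
        assert pos.shape == (500, 2)
        assert (np.abs(pos[:, 0] - 486) <= 54).all()
        assert (np.abs(pos[:, 1] - 342) <= 54).all()

    def test_oversized_injection_rejected(self, cardiomyocyte_geometry, rng):
        with pytest.raises(ParameterError):
            initialize(
                SimulationParams(injection_side=10_000), cardiomyocyte_geometry, rng
            )

    def test_mnsod_allocation_is_exact(self, rng):
        geo = make_mini_geometry()
        world = initialize(make_mini_params(), geo, rng)
        n_expected = round(0.769 / 100 * geo.total_pixels)
        assert world.population(pt.MNSOD).n == n_expected


class TestStepLoop:
    def test_no_sources_means_no_ros(self, rng):
        geo = make_mini_geometry()
        params = make_mini_params(initial_h2o2=0, n_steps=50)
        params.leakage = LeakageRuleParams(baseline=0.0, span=0.0)
        world = initialize(params, geo, rng)
        for _ in range(50):
            m = engine.step(world)
            assert m.n_o2minus == 0 and m.n_h2o2 == 0

    def test_determinism_bit_identical(self):
        geo = make_mini_geometry()
        params = make_mini_params(n_steps=100)
        a = engine.metrics_frame(engine.run(params, geo, seed=7))
        b = engine.metrics_frame(engine.run(params, geo, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_bookkeeping_counters_exact(self, rng):
        """Per-step count deltas equal source/sink event counters."""
        geo = make_mini_geometry()
        params = make_mini_params(n_steps=150)
        params.debug_checks = True  # engine asserts the identities internally
        world = initialize(params, geo, rng)
        prev_o2, prev_h = 0, world.population(pt.H2O2).n
        for _ in range(150):
            m = engine.step(world)
            assert m.n_o2minus - prev_o2 == m.leak_events - m.sod_conversions - m.o2_decays
            assert m.n_h2o2 - prev_h == m.sod_conversions - m.gpx_removals - m.h2o2_decays
            prev_o2, prev_h = m.n_o2minus, m.n_h2o2

    def test_total_count_constant_without_sinks_or_sources(self, rng):
        geo = make_mini_geometry()
        params = make_mini_params(initial_h2o2=200, n_steps=300)
        params.leakage = LeakageRuleParams(baseline=0.0, span=0.0)
        params.kinetics.spontaneous_decay = {s: 0.0 for s in params.kinetics.spontaneous_decay}
        params.multipliers = {s: 0.0 for s in params.multipliers}  # no enzymes
        world = initialize(params, geo, rng)
        for _ in range(300):
            m = engine.step(world)
            assert m.n_h2o2 + m.n_o2minus == 200

    def test_moving_layout_keeps_confinement(self, rng):
        geo = make_moving_layout()
        params = SimulationParams(initial_h2o2=1000, n_steps=40, debug_checks=True)
        world = initialize(params, geo, rng)
        for _ in range(40):  # crosses a motion turning point
            engine.step(world)


def test_populations_debug_dump(rng, tmp_path):
    geo = make_mini_geometry()
    world = initialize(make_mini_params(), geo, rng)
    df = engine.populations_frame(world)
    assert list(df.columns) == ["species", "x", "y"]
    assert (df["species"] == pt.H2O2).sum() == 300
    path = tmp_path / "pops.csv"
    df.to_csv(path, index=False)
    assert path.read_text().startswith("species,x,y")


class TestReplicates:
    def test_single_replicate_stats(self):
        geo = make_mini_geometry()
        params = make_mini_params(n_steps=50, n_replicates=1)
        res = run_replicates(params, geo)
        series = res.mean_series()
        assert np.array_equal(
            series["mean"].to_numpy(), res.replicates[0]["reactive_fraction"].to_numpy()
        )
        assert (series["sd"] == 0).all()

    def test_mean_recomputable_from_replicates(self):
        geo = make_mini_geometry()
        params = make_mini_params(n_steps=60, n_replicates=3)
        res = run_replicates(params, geo)
        stacked = np.stack([df["reactive_fraction"].to_numpy() for df in res.replicates])
        assert np.array_equal(res.mean_series()["mean"].to_numpy(), stacked.mean(axis=0))

    def test_same_base_seed_reproduces(self):
        geo = make_mini_geometry()
        params = make_mini_params(n_steps=40, n_replicates=2)
        r1 = run_replicates(params, geo)
        r2 = run_replicates(params, geo)
        for a, b in zip(r1.replicates, r2.replicates):
            pd.testing.assert_frame_equal(a, b)
        assert r1.seeds == [params.base_seed, params.base_seed + 1]


class TestCalibration:
    def test_resting_cell_stays_quiet(self, cardiomyocyte_geometry):
        """No spontaneous whole-cell RIRR: dose 0, defaults, 3000 steps."""
        params = SimulationParams(initial_h2o2=0, n_steps=3000, n_replicates=2, base_seed=42)
        res = run_replicates(params, cardiomyocyte_geometry)
        mean_frac = res.mean_series()["mean"].to_numpy()
        assert mean_frac.max() < 5.0

    def test_mini_fixture_dose_scaling_is_monotone(self):
        cfg, geo = make_mini_fixture()
        lo = run_replicates(cfg.params, geo).final_reactive_fractions.mean()
        cfg10, _ = make_mini_fixture(initial_h2o2=cfg.params.initial_h2o2 * 10)
        hi = run_replicates(cfg10.params, geo).final_reactive_fractions.mean()
        assert hi >= lo

    def test_mini_fixture_runs_fast(self):
        cfg, geo = make_mini_fixture()
        t0 = time.time()
        res = run_replicates(cfg.params, geo)
        assert time.time() - t0 < 5.0
        assert len(res.replicates[0]) == cfg.params.n_steps
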