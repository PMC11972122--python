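"""Unit tests for the 1D/2D signal simulators and rotation machinery."""

import numpy as np
import pytest

from s2map import (
    InvalidSignalError,
    Scenario1D,
    SignalMatrix,
    SimulationSpec2D,
    benchmark,
    cwsnr,
    di_derivative,
    map_metrics,
    random_matrix,
    rotate_map,
    rotation_sweep,
    scenario_catalog,
    signal_noise_ratio,
    sii,
    simulate_1d,
    simulate_2d,
    simulate_series,
)


class TestSimulate1D:
    def test_shaping_densities_and_snr(self):
        x = simulate_1d(Scenario1D("shaping", 1))
        assert x == pytest.approx([0, 0, 3, 2, 1])
        assert signal_noise_ratio(di_derivative(x))[2] == pytest.approx(2 / 3)

    def test_spreading_final_stage_uniform(self):
        x = simulate_1d(Scenario1D("spreading", 3))
        assert x == pytest.approx([1, 1, 1, 1, 1])
        dec = cwsnr(x)
        assert dec.di == 0.0 and dec.cwsnr == 0.0

    def test_shifting_first_stage_centered(self):
        x = simulate_1d(Scenario1D("shifting", 1))
        assert x == pytest.approx([0, 0, 1, 0, 0])
        assert cwsnr(x).di == pytest.approx(0.0)

    def test_propagating_reaches_endpoints(self):
        assert simulate_1d(Scenario1D("propagating", 3)) == pytest.approx(
            [1, 0, 0, 0, 1]
        )

    def test_invalid_scenarios_rejected(self):
        with pytest.raises(InvalidSignalError):
            Scenario1D("shifting", 4)
        with pytest.raises(InvalidSignalError):
            Scenario1D("melting", 1)
        with pytest.raises(InvalidSignalError):
            Scenario1D("shifting", 1, length=4)

    def test_catalog_has_ten_scenarios_with_one_metric_collision(self):
        cat = scenario_catalog()
        assert len(cat) == 10
        pairs = {
            name: (round(cwsnr(x).di, 10), round(cwsnr(x).cwsnr, 10))
            for name, x in cat.items()
        }
        assert len(set(pairs.values())) == 9
        # the collision is uniform spreading vs endpoint propagation, both (0, 0)
        assert pairs["c3"] == pairs["d3"] == (0.0, 0.0)

    def test_shaping_cwsnr_ranking(self):
        # uniform right-half coverage beats the decreasing ramp, the
        # increasing ramp (mass pushed to the weight-zero endpoint) is last
        values = {
            stage: cwsnr(simulate_1d(Scenario1D("shaping", stage))).cwsnr
            for stage in (1, 2, 3)
        }
        assert values[2] > values[1] > values[3]


class TestSimulate2D:
    def test_first_timepoint_is_center_point(self):
        for model in ("circular_propagation", "translation"):
            m = simulate_2d(SimulationSpec2D(model=model), 1)
            assert m.grid[25, 25] == 5000.0
            assert m.total() == 5000.0
            assert sii(m) == pytest.approx(0.0, abs=1e-12)

    def test_annulus_amplitude_and_distances(self):
        m = simulate_2d(SimulationSpec2D(model="circular_propagation"), 2)
        rows, cols = np.nonzero(m.grid)
        dist = np.hypot(rows - 25, cols - 25)
        assert np.all(m.grid[rows, cols] == 1000.0)
        assert np.all((dist >= 4) & (dist <= 5))

    def test_sector_mask_conditions(self):
        # at t=4 the annulus spans distances 12..15, so (dx, dy) = (15, 0)
        # satisfies both sector inequalities while (0, 15) is masked
        m = simulate_2d(SimulationSpec2D(model="circular_sector"), 4)
        assert m.grid[25, 40] > 0
        assert m.grid[40, 25] == 0.0

    def test_translation_displacements(self):
        spec = SimulationSpec2D(model="translation")
        for t, disp in ((2, 5), (3, 9), (4, 13)):
            m = simulate_2d(spec, t)
            rows, cols = np.nonzero(m.grid)
            assert (rows.tolist(), cols.tolist()) == ([25], [25 + disp])
            assert m.grid[25, 25 + disp] == pytest.approx(5000 / (5 * (t - 1)))

    def test_out_of_range_timepoint(self):
        with pytest.raises(InvalidSignalError):
            simulate_2d(SimulationSpec2D(model="translation"), 5)

    def test_directional_models_sii_strictly_increasing(self):
        for model in ("translation", "circular_with_direction"):
            series = simulate_series(SimulationSpec2D(model=model))
            values = [sii(f) for f in series.frames]
            assert all(b > a for a, b in zip(values, values[1:])), model

    def test_circular_frames_symmetric_with_positive_coverage(self, circular_series):
        for frame in circular_series.frames:
            mm = map_metrics(frame)
            assert mm.sii == pytest.approx(0.0, abs=1e-10)
            assert mm.sci > 0


class TestRotation:
    def test_identity_and_full_turns(self, rng):
        m = SignalMatrix(rng.random((9, 9)))
        assert np.array_equal(rotate_map(m, 0.0).grid, m.grid)
        r = m
        for _ in range(4):
            r = rotate_map(r, 90.0)
        assert np.array_equal(r.grid, m.grid)

    def test_half_turn_negates_dix(self):
        m = simulate_2d(SimulationSpec2D(model="translation"), 2)
        mm0 = map_metrics(m)
        mm180 = map_metrics(rotate_map(m, 180.0))
        assert mm180.axis_x.di == pytest.approx(-mm0.axis_x.di, abs=1e-12)

    @pytest.mark.parametrize("method", ["linear", "nearest"])
    def test_mass_conserved_for_sparse_patterns(self, method):
        m = simulate_2d(SimulationSpec2D(model="circular_propagation"), 2)
        for angle in (30, 45, 150, 285):
            r = rotate_map(m, angle, method=method)
            assert r.total() == pytest.approx(m.total(), rel=0.05)
            assert np.all(r.grid >= 0)

    def test_non_square_rejected(self):
        with pytest.raises(InvalidSignalError):
            rotate_map(SignalMatrix(np.ones((3, 4))), 30.0)


class TestRotationSweep:
    def test_structure_and_robustness(self, translation_spec):
        df = rotation_sweep(translation_spec, 2)
        assert list(df.columns) == ["DIx", "CWSNRx", "SII", "SCI"]
        assert len(df) == 14  # 12 angles + mean + variance
        assert df.loc["variance", "SII"] <= 1e-4
        assert abs(df.loc["mean", "DIx"]) <= 0.01

    def test_pure_translation_dix_carries_all_inequality(self, translation_spec):
        df = rotation_sweep(translation_spec, 4)
        assert df.loc[0, "DIx"] == pytest.approx(-df.loc[0, "SII"], abs=1e-12)


class TestRandomAndBenchmark:
    def test_random_matrix_determinism(self):
        a = random_matrix(40, seed=0)
        b = random_matrix(40, seed=0)
        c = random_matrix(40, seed=1)
        assert np.array_equal(a.grid, b.grid)
        assert not np.array_equal(a.grid, c.grid)
        assert np.all(a.grid >= 0)

    def test_benchmark_smoke(self):
        df = benchmark(dims=(16, 32), reps=2, seed0=0)
        assert len(df) == 4
        assert (df["seconds"] >= 0).all()
        assert set(df["dim"]) == {16, 32}
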