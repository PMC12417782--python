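"""Two-volume grid search: execution order, statistics, optimum selection."""

import numpy as np
import pandas as pd
import pytest

from ramanline import CalibrationGrid, MeasurementParams, select_optimum
from ramanline.calibration import (
    CalibrationResult,
    run_grid,
    scenario_rig_factory,
    true_optimum,
)


@pytest.fixture(scope="module")
def quiet_surface():
    """Noise-free single-round scenario surface over the full default grid."""
    grid = CalibrationGrid.for_substance("glucose", rounds=1)
    return run_grid(scenario_rig_factory(noise_sd=0.0), grid, rng_seed=0)


class TestRunGrid:
    def test_default_grid_dimensions_and_rounds(self):
        grid = CalibrationGrid()
        assert len(grid.v_sc_values) == 14
        assert len(grid.v_pb_values) == 11
        assert grid.rounds == 3

    def test_round_major_execution_order(self):
        small = CalibrationGrid(v_sc_values=(100.0, 110.0), v_pb_values=(380.0,),
                                rounds=2, substance="glucose",
                                concentration=80.0, band=(1000.0, 1500.0))
        result = run_grid(scenario_rig_factory(seed=0), small, rng_seed=0)
        rounds_sequence = result.replicates["round"].tolist()
        assert rounds_sequence == [0, 0, 1, 1]  # all cells once, then again

    def test_replicate_count(self, quiet_surface):
        assert len(quiet_surface.replicates) == 14 * 11

    def test_single_round_reports_no_std(self, quiet_surface):
        assert quiet_surface.std is None

    def test_deterministic_cells_have_zero_std(self):
        small = CalibrationGrid(v_sc_values=(100.0, 115.0), v_pb_values=(380.0, 400.0),
                                rounds=3, substance="glucose",
                                concentration=80.0, band=(1000.0, 1500.0))
        result = run_grid(scenario_rig_factory(kappa=0.0, noise_sd=0.0), small, rng_seed=0)
        assert np.allclose(result.std.to_numpy(), 0.0)

    def test_failure_annotated_with_cell(self):
        bad_params = MeasurementParams()
        grid = CalibrationGrid(v_sc_values=(100.0,), v_pb_values=(380.0,), rounds=1,
                               substance="glucose", concentration=80.0,
                               band=(4000.0, 4100.0))  # off-axis band
        with pytest.raises(RuntimeError, match=r"v_sc=100"):
            run_grid(scenario_rig_factory(seed=0), grid, bad_params, rng_seed=0)

    def test_long_format_export(self, quiet_surface, tmp_path):
        path = tmp_path / "cal.csv"
        quiet_surface.to_csv(path)
        frame = pd.read_csv(path)
        assert list(frame.columns) == ["v_sc", "v_pb", "round", "value"]


def _result_from_matrix(means: np.ndarray, v_sc, v_pb, jitter=0.0, rounds=3) -> CalibrationResult:
    rows = []
    rng = np.random.default_rng(0)
    for rnd in range(rounds):
        for i, a in enumerate(v_sc):
            for j, b in enumerate(v_pb):
                rows.append({"v_sc": a, "v_pb": b, "round": rnd,
                             "value": means[i, j] + jitter * rng.normal()})
    grid = CalibrationGrid(v_sc_values=tuple(v_sc), v_pb_values=tuple(v_pb),
                           rounds=rounds, substance="synthetic",
                           concentration=1.0, band=(1000.0, 1500.0))
    return CalibrationResult("synthetic", grid, pd.DataFrame(rows))


class TestSelectOptimum:
    V_SC = [100.0, 110.0, 120.0]
    V_PB = [380.0, 390.0]

    def test_unique_maximum_chosen(self):
        means = np.array([[1.0, 2.0], [3.0, 9.0], [4.0, 5.0]])
        result = _result_from_matrix(means, self.V_SC, self.V_PB)
        assert select_optimum(result) == (110.0, 390.0)

    def test_exact_tie_breaks_lexicographically(self):
        means = np.array([[1.0, 9.0], [9.0, 1.0], [0.0, 0.0]])
        result = _result_from_matrix(means, self.V_SC, self.V_PB)
        assert select_optimum(result) == (100.0, 390.0)

    def test_consensus_rank_resolves_near_ties(self):
        """Primary's top cells near-tie; the one ranking best on the second
        substance wins."""
        primary = np.array([[9.00, 8.99], [1.0, 1.0], [1.0, 1.0]])
        secondary = np.array([[2.0, 9.0], [1.0, 1.0], [1.0, 1.0]])
        a = _result_from_matrix(primary, self.V_SC, self.V_PB, jitter=0.05)
        b = _result_from_matrix(secondary, self.V_SC, self.V_PB, jitter=0.05)
        assert select_optimum([a, b]) == (100.0, 390.0)

    def test_high_variance_cells_rejected(self):
        means = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]])
        result = _result_from_matrix(means, self.V_SC, self.V_PB, jitter=0.01)
        # corrupt the top cell's replicates with huge spread
        mask = (result.replicates["v_sc"] == 120.0) & (result.replicates["v_pb"] == 390.0)
        result.replicates.loc[mask, "value"] = [100.0, -90.0, 8.0]
        assert select_optimum(result, std_reject_multiple=3.0) == (120.0, 380.0)

    def test_empty_results_rejected(self):
        with pytest.raises(ValueError):
            select_optimum([])

    def test_mismatched_grids_rejected(self):
        a = _result_from_matrix(np.ones((3, 2)), self.V_SC, self.V_PB)
        b = _result_from_matrix(np.ones((2, 2)), self.V_SC[:2], self.V_PB)
        with pytest.raises(ValueError, match="grid"):
            select_optimum([a, b])


class TestSurfaceShape:
    def test_unimodal_along_v_sc(self, quiet_surface):
        """Rise then fall (no interior valley) for every pull-back column."""
        mean = quiet_surface.mean
        for v_pb in mean.columns:
            column = mean[v_pb].to_numpy()
            peak = int(np.argmax(column))
            assert np.all(np.diff(column[: peak + 1]) >= -1e-9)
            assert np.all(np.diff(column[peak:]) <= 1e-9)

    def test_monotone_along_v_pb(self, quiet_surface):
        """Larger pull-back leaves less residual wash: non-decreasing rows.

        Holds in the sample-limited regime (V_sc up to the optimum); far
        beyond it the smaller, less-diluted plug overshoots the window and
        the trend legitimately reverses.
        """
        mean = quiet_surface.mean
        best_v_sc = mean.max(axis=1).idxmax()
        for v_sc in mean.index:
            if v_sc > best_v_sc:
                continue
            row = mean.loc[v_sc].to_numpy()
            assert np.all(np.diff(row) >= -1e-9)

    def test_true_optimum_is_interior_in_v_sc(self):
        v_sc, v_pb = true_optimum()
        grid = CalibrationGrid()
        assert grid.v_sc_values[0] < v_sc < grid.v_sc_values[-1]
        assert v_pb in grid.v_pb_values


def test_recovery_on_a_few_noisy_repeats():
    """Smoke version of the recovery experiment: 3 seeded repeats land within
    one grid step of the noise-free optimum (the full 20-repeat experiment
    runs in the acceptance suite)."""
    truth = true_optimum()
    grid = CalibrationGrid.for_substance("glucose")
    for seed in range(3):
        result = run_grid(scenario_rig_factory(seed=seed), grid, rng_seed=seed)
        est = select_optimum(result)
        assert abs(est[0] - truth[0]) <= 5.0
        assert abs(est[1] - truth[1]) <= 5.0
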