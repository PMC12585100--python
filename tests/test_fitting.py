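import numpy as np
import pytest

from wbsleep.errors import DegenerateInputError, ParameterRangeError, ShapeError
from wbsleep.fc import FCMatrix
from wbsleep.fitting import (
    SweepResult,
    compare_modalities,
    delta_grid,
    profile_similarity,
    run_sweep,
    select_optimum,
)
from wbsleep.neural import desk_config
from wbsleep.neuromodulation import ModulationMap
from wbsleep.synth import make_connectome


def _sweep_with_fit(fit, dg=None, ds=None):
    n_g, n_s, n_seeds = fit.shape
    return SweepResult(
        dg_values=np.asarray(dg if dg is not None else np.linspace(-0.5, 0.5, n_g)),
        dsigma_values=np.asarray(ds if ds is not None else np.linspace(-1, 1, n_s)),
        modality="homogeneous",
        baseline=(0.4, 4.0),
        fit=fit,
        seeds=list(range(n_seeds)),
    )


class TestDeltaGrid:
    def test_default_grid_matches_protocol(self):
        dg, ds = delta_grid()
        assert dg.size == ds.size == 50
        assert dg[0] == -0.5 and dg[-1] == 0.5
        assert ds[0] == -1.0 and ds[-1] == 1.0
        # printed optima like -0.02 on the endpoint-inclusive grid
        assert np.allclose(np.diff(dg), 1.0 / 49)

    def test_reduced_grid_contains_stage_truths(self):
        dg, ds = delta_grid(11, 11)
        for v in (0.0, 0.1, 0.2, 0.3):
            assert np.any(np.isclose(dg, v))
        for v in (0.0, -0.2, -0.4, -0.6):
            assert np.any(np.isclose(ds, v))


class TestSelectOptimum:
    def test_single_finite_point(self):
        fit = np.full((3, 3, 2), np.inf)
        fit[2, 0, :] = 5.0
        sweep = _sweep_with_fit(fit)
        assert select_optimum(sweep) == (sweep.dg_values[2], sweep.dsigma_values[0])

    def test_unique_minimum(self):
        fit = np.ones((4, 5, 3))
        fit[1, 3, :] = 0.2
        sweep = _sweep_with_fit(fit)
        select_optimum(sweep)
        assert sweep.optimum_index == (1, 3)
        assert np.allclose(sweep.optimum_fit, 0.2)

    def test_tie_breaks_toward_small_absolute_delta(self):
        # exact ties at deltaG = -0.1 and +0.1 -> |dG| equal -> then |ds|
        dg = np.array([-0.1, 0.0, 0.1])
        ds = np.array([-0.4, 0.2])
        fit = np.full((3, 2, 1), 1.0)
        fit[0, 0, 0] = 0.5  # (-0.1, -0.4)
        fit[2, 1, 0] = 0.5  # (+0.1, +0.2) same |dG|, smaller |ds|
        sweep = _sweep_with_fit(fit, dg=dg, ds=ds)
        assert select_optimum(sweep) == (0.1, 0.2)

    def test_full_tie_resolved_by_grid_index(self):
        dg = np.array([-0.2, 0.2])
        ds = np.array([-0.6, 0.6])
        fit = np.full((2, 2, 1), 1.0)
        fit[0, 0, 0] = 0.1
        fit[1, 1, 0] = 0.1
        sweep = _sweep_with_fit(fit, dg=dg, ds=ds)
        # |dG| and |ds| both tied -> earlier grid index wins
        assert select_optimum(sweep) == (-0.2, -0.6)

    def test_all_infeasible_raises(self):
        sweep = _sweep_with_fit(np.full((2, 2, 2), np.inf))
        with pytest.raises(ParameterRangeError):
            select_optimum(sweep)


@pytest.fixture(scope="module")
def tiny_setup():
    conn = make_connectome(8, n_modules=2, seed=0)
    cfg = desk_config(t_transient=10.0, t_settle=5.0, t_main=80.0)
    from wbsleep.forward import simulate_fc

    emp = simulate_fc(conn, cfg, seed=99)
    return conn, cfg, emp


class TestRunSweep:
    def test_shape_and_contract(self, tiny_setup):
        conn, cfg, emp = tiny_setup
        grid = (np.linspace(-0.1, 0.1, 3), np.linspace(-0.2, 0.2, 3))
        sweep = run_sweep(emp, conn, None, (0.44, 3.5), grid, 2, cfg, keep_optimum_fcs=False)
        assert sweep.fit.shape == (3, 3, 2)
        assert np.all((sweep.fit >= 0) | np.isinf(sweep.fit))
        i, j = sweep.optimum_index
        assert 0 <= i < 3 and 0 <= j < 3

    def test_infeasible_points_are_inf_not_errors(self, tiny_setup):
        conn, cfg, emp = tiny_setup
        # delta sigma = -4 drives the slope nonpositive everywhere
        grid = (np.array([0.0]), np.array([-4.0, 0.0]))
        sweep = run_sweep(emp, conn, None, (0.44, 3.5), grid, 1, cfg, keep_optimum_fcs=False)
        assert np.all(np.isinf(sweep.fit[0, 0]))
        assert np.all(np.isfinite(sweep.fit[0, 1]))

    def test_unit_maps_equal_homogeneous_bitwise(self, tiny_setup):
        conn, cfg, emp = tiny_setup
        unit = ModulationMap(values=np.ones(8), normalized=True)
        grid = (np.array([-0.1, 0.1]), np.array([0.0]))
        a = run_sweep(emp, conn, None, (0.44, 3.5), grid, 2, cfg, keep_optimum_fcs=False)
        b = run_sweep(emp, conn, (unit, unit), (0.44, 3.5), grid, 2, cfg, keep_optimum_fcs=False)
        assert np.array_equal(a.fit, b.fit)

    def test_optimum_fcs_reproduce_sweep_seeds(self, tiny_setup):
        conn, cfg, emp = tiny_setup
        grid = (np.array([0.0]), np.array([0.0]))
        sweep = run_sweep(emp, conn, None, (0.44, 3.5), grid, 2, cfg, keep_optimum_fcs=True)
        assert len(sweep.optimum_fcs) == 2
        from wbsleep.fc import euccorrelation, lower_triangle_vector

        refit = euccorrelation(
            lower_triangle_vector(emp), lower_triangle_vector(sweep.optimum_fcs[0])
        )
        assert refit == pytest.approx(sweep.fit[0, 0, 0], rel=1e-12)


class TestCompareModalities:
    def _sweep_with_opt_fit(self, values):
        sweep = _sweep_with_fit(np.ones((1, 1, len(values))))
        sweep.optimum_fit = np.asarray(values, dtype=float)
        return sweep

    def test_identical_distributions_zero(self):
        s = {"map": self._sweep_with_opt_fit([1.0, 2.0, 3.0]),
             "shuffle": self._sweep_with_opt_fit([1.0, 2.0, 3.0])}
        table = compare_modalities(s)
        assert table["d"].iloc[0] == 0.0

    def test_one_pooled_sd_shift(self, rng):
        x = rng.normal(0, 1, 2000)
        shift = np.sqrt((x.var(ddof=1) + x.var(ddof=1)) / 2)  # pooled sd
        s = {"map": self._sweep_with_opt_fit(x),
             "homogeneous": self._sweep_with_opt_fit(x + shift)}
        table = compare_modalities(s)
        row = table.iloc[0]
        assert abs(row["d"]) == pytest.approx(1.0, abs=1e-9)

    def test_unequal_seed_counts_rejected(self):
        s = {"a": self._sweep_with_opt_fit([1.0, 2.0]),
             "b": _sweep_with_fit(np.ones((1, 1, 3)))}
        s["b"].optimum_fit = np.ones(3)
        with pytest.raises(ShapeError):
            compare_modalities(s)


class TestProfileSimilarity:
    @staticmethod
    def _block_fc(strong_first=True):
        j = np.ones((3, 3))
        a, b = (0.8, 0.1) if strong_first else (0.1, 0.8)
        mat = np.block(
            [[a * j, 0.05 * np.ones((3, 3))], [0.05 * np.ones((3, 3)), b * j]]
        )
        np.fill_diagonal(mat, 1.0)
        return FCMatrix(values=mat)

    def test_identical_gives_unit_correlation(self):
        fc = self._block_fc()
        out = profile_similarity([fc, fc], fc)
        assert len(out) == 2
        assert np.allclose(out["r_integration"], 1.0)
        assert np.allclose(out["r_segregation"], 1.0)

    def test_rank_reversed_profile_negative(self):
        emp = self._block_fc(True)
        sim = self._block_fc(False)  # strong block swapped -> reversed profile
        out = profile_similarity([sim], emp)
        assert out["r_integration"].iloc[0] < 0

    def test_size_mismatch(self):
        emp = self._block_fc()
        sim = FCMatrix(values=np.eye(4))
        with pytest.raises(ShapeError):
            profile_similarity([sim], emp)
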