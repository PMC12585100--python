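import numpy as np
import pytest

from wbsleep.errors import ConvergenceError, ShapeError
from wbsleep.fc import compute_fc, lower_triangle_vector
from wbsleep.neural import desk_config
from wbsleep.neuromodulation import ModulationMap
from wbsleep.synth import (
    make_connectome,
    make_maps,
    make_nucleus_series,
    make_regions,
    simulate_stage_dataset,
)

FAST = dict(n_regions=8, duration=80.0, n_subjects=2)


def _fast_dataset(seed=0, **overrides):
    conn = make_connectome(FAST["n_regions"], seed=seed)
    ach, na = make_maps(conn.regions, 0.3, seed=seed + 1)
    kwargs = dict(
        stage_params=None,
        n_subjects=FAST["n_subjects"],
        duration=FAST["duration"],
        subject_noise_sd=0.02,
        seed=seed + 2,
    )
    kwargs.update(overrides)
    return conn, ach, na, simulate_stage_dataset(conn, ach, na, **kwargs)


class TestMakeConnectome:
    def test_homotopic_entries_pinned(self):
        conn = make_connectome(4, n_modules=2, homotopic_weight=0.5, row_sum=None, seed=0)
        # partners are (0,2) and (1,3)
        w = conn.weights
        assert w[0, 2] == w[2, 0] == w[1, 3] == w[3, 1] == 0.5

    def test_seed_determinism(self):
        a = make_connectome(30, seed=7)
        b = make_connectome(30, seed=7)
        c = make_connectome(30, seed=8)
        assert np.array_equal(a.weights, b.weights)
        assert not np.array_equal(a.weights, c.weights)

    def test_density_realized(self):
        conn = make_connectome(90, density=0.3, seed=1)
        off = conn.weights[np.triu_indices(90, 1)]
        frac = np.mean(off > 0)
        assert abs(frac - 0.3) < 0.05

    def test_hemispheric_mirror_symmetry(self):
        conn = make_connectome(30, seed=2)
        half = 15
        w = conn.weights
        assert np.allclose(w[:half, :half], w[half:, half:])

    def test_invalid_sizes_rejected(self):
        with pytest.raises(ShapeError):
            make_connectome(7)
        with pytest.raises(ShapeError):
            make_connectome(8, n_modules=9)


class TestMakeMaps:
    def test_mean_one_exactly(self, regions30):
        ach, na = make_maps(regions30, 0.4, seed=0)
        assert ach.values.mean() == pytest.approx(1.0, abs=1e-10)
        assert na.values.mean() == pytest.approx(1.0, abs=1e-10)
        assert np.all(ach.values > 0) and np.all(na.values > 0)

    def test_perfect_correlation_limit(self, regions30):
        ach, na = make_maps(regions30, 1.0, seed=1)
        assert np.allclose(ach.values, na.values)

    def test_zero_correlation_request(self):
        regions = make_regions(90)
        ach, na = make_maps(regions, 0.0, seed=2)
        assert abs(np.corrcoef(ach.values, na.values)[0, 1]) < 0.15

    def test_hemisphere_symmetry(self, regions30):
        ach, na = make_maps(regions30, 0.3, seed=3)
        partner = regions30.partner
        assert np.allclose(ach.values, ach.values[partner])
        assert np.allclose(na.values, na.values[partner])

    def test_unattainable_correlation_raises(self, regions30):
        # lognormal maps cannot realize corr -1 to within 0.01
        with pytest.raises(ConvergenceError):
            make_maps(regions30, -1.0, seed=4, max_attempts=5, tolerance=0.01)


class TestNucleusSeries:
    def test_uniform_map_is_global_mean(self, rng):
        s = rng.standard_normal((6, 40))
        m = ModulationMap(values=np.ones(6), normalized=True)
        out = make_nucleus_series(s, m, noise_sd=0.0, seed=0)
        assert np.allclose(out, s.mean(axis=0), atol=1e-12)

    def test_weighting_follows_map(self, rng):
        s = rng.standard_normal((5, 500))  # independent region signals
        values = np.array([5.0, 0.1, 0.1, 0.1, 0.1])
        m = ModulationMap(values=values / values.mean(), normalized=True)
        out = make_nucleus_series(s, m, noise_sd=0.0, seed=0)
        r_high = np.corrcoef(out, s[0])[0, 1]
        r_low = np.corrcoef(out, s[1])[0, 1]
        assert r_high > r_low

    def test_seed_determinism(self, rng):
        s = rng.standard_normal((4, 50))
        m = ModulationMap(values=np.ones(4), normalized=True)
        a = make_nucleus_series(s, m, noise_sd=0.5, seed=9)
        b = make_nucleus_series(s, m, noise_sd=0.5, seed=9)
        assert np.array_equal(a, b)

    def test_length_mismatch(self, rng):
        m = ModulationMap(values=np.ones(3), normalized=True)
        with pytest.raises(ShapeError):
            make_nucleus_series(rng.standard_normal((4, 50)), m, 0.0, 0)


class TestStageDatasetGeneration:
    def test_zero_jitter_shares_parameters(self):
        _, _, _, (datasets, truth) = _fast_dataset(subject_noise_sd=0.0)
        for stage in ["W", "N3"]:
            per_subj = {s: truth.subject_jitter[s][stage] for s in truth.subject_jitter}
            vals = set(per_subj.values())
            assert len(vals) == 1
            assert vals.pop() == truth.stage_params[stage]

    def test_fixed_seed_bitwise_identical(self):
        _, _, _, (d1, t1) = _fast_dataset(seed=5)
        _, _, _, (d2, t2) = _fast_dataset(seed=5)
        assert len(d1) == len(d2) == FAST["n_subjects"] * 4
        for a, b in zip(d1, d2):
            assert a.subject_id == b.subject_id and a.stage == b.stage
            assert np.array_equal(a.series, b.series)
            assert np.array_equal(a.nucleus_series["BF"], b.nucleus_series["BF"])
        assert t1.subject_jitter == t2.subject_jitter

    def test_ground_truth_records_generation_values(self):
        _, ach, na, (datasets, truth) = _fast_dataset(seed=3)
        assert np.array_equal(truth.ach_map, ach.values)
        assert np.array_equal(truth.na_map, na.values)
        assert set(truth.stage_params) == {"W", "N1", "N2", "N3"}

    def test_ground_truth_json_round_trip(self, tmp_path):
        import json

        _, _, _, (_, truth) = _fast_dataset(seed=4)
        p = tmp_path / "gt.json"
        truth.to_json(p)
        back = json.load(open(p))
        assert back["base_g"] == truth.base_g
        assert np.allclose(back["ach_map"], truth.ach_map)

    def test_higher_coupling_raises_mean_fc(self, connectome30):
        """Raising deltaG strengthens network co-fluctuation, hence FC."""
        from dataclasses import replace

        from wbsleep.forward import seed_mean_fc
        from wbsleep.neuromodulation import apply_modulation
        from wbsleep.synth import BASELINE_G, BASELINE_SIGMA

        means = {}
        for dg in [0.0, 0.2]:
            g, s = apply_modulation(BASELINE_G, BASELINE_SIGMA, dg, 0.0, None, None, n=30)
            cfg = replace(desk_config(t_main=120.0), g=g, sigma_e=s)
            fc = seed_mean_fc(connectome30, cfg, seeds=range(4))
            means[dg] = lower_triangle_vector(fc).mean()
        assert means[0.2] > means[0.0]
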