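import numpy as np
import pytest
from scipy import optimize

from wbsleep.errors import ParameterRangeError, ShapeError
from wbsleep.io import Connectome
from wbsleep.neural import SimulationConfig, derivatives, desk_config, sigmoid, simulate
from wbsleep.synth import make_regions


def single_node_fixed_point(cfg: SimulationConfig):
    """Root-finder oracle for the decoupled, noise-free 3-equation system.

    At equilibrium E = rho_E exactly (da/dt = 0 with I > 0), I solves its
    own sigmoid balance, and a_IE follows from the E equation.
    """

    def rhs(state):
        e, i, a = state
        s_e = 1.0 / (1.0 + np.exp(-((cfg.a_ee * e - a * i + cfg.p_ext) - cfg.mu) / cfg.sigma_e))
        s_i = 1.0 / (1.0 + np.exp(-((cfg.a_ei * e) - cfg.mu) / cfg.sigma_i))
        return [
            -e + (1.0 - cfg.r_e * e) * s_e,
            -i + (1.0 - cfg.r_i * i) * s_i,
            i * (e - cfg.rho_e),
        ]

    sol = optimize.root(rhs, x0=[cfg.rho_e, 0.2, 1.0], tol=1e-13)
    assert sol.success
    return sol.x


class TestSigmoid:
    def test_midpoint(self):
        assert sigmoid(1.0, mu=1.0, sigma=4.0) == pytest.approx(0.5)

    def test_closed_form_value(self):
        assert sigmoid(5.0, mu=1.0, sigma=4.0) == pytest.approx(1.0 / (1.0 + np.exp(-1.0)), rel=1e-12)

    def test_monotone_and_bounded(self):
        x = np.linspace(-100, 100, 401)
        y = sigmoid(x)
        assert np.all(np.diff(y) > 0)
        assert y[0] < 1e-10 and y[-1] > 1 - 1e-10

    def test_nonpositive_slope_rejected(self):
        with pytest.raises(ParameterRangeError):
            sigmoid(0.0, sigma=0.0)


class TestDerivatives:
    def test_plasticity_null_at_set_point(self, small_connectome):
        cfg = SimulationConfig()
        n = small_connectome.n
        e = np.full(n, cfg.rho_e)
        _, _, d_a = derivatives((e, np.full(n, 0.3), np.ones(n)), cfg, small_connectome)
        assert np.all(d_a == 0.0)

    def test_fixed_point_from_root_finder(self):
        cfg = SimulationConfig(g=0.0, noise_d=0.0)
        zero_conn = Connectome(weights=np.zeros((4, 4)), regions=make_regions(4))
        e, i, a = single_node_fixed_point(cfg)
        d = derivatives((np.full(4, e), np.full(4, i), np.full(4, a)), cfg, zero_conn)
        for comp in d:
            assert np.all(np.abs(comp) < 1e-8)

    def test_decoupled_nodes_independent(self, small_connectome, rng):
        cfg = SimulationConfig(g=0.0, noise_d=0.0)
        state = (rng.uniform(0.1, 0.3, 4), rng.uniform(0.1, 0.3, 4), rng.uniform(0.5, 1.5, 4))
        d1 = derivatives(state, cfg, small_connectome)
        e2 = state[0].copy()
        e2[1:] = rng.uniform(0.1, 0.3, 3)  # perturb all other nodes
        d2 = derivatives((e2, state[1], state[2]), cfg, small_connectome)
        assert d1[0][0] == pytest.approx(d2[0][0], rel=1e-14)

    def test_shape_validation(self, small_connectome):
        cfg = SimulationConfig()
        with pytest.raises(ShapeError):
            derivatives((np.zeros(3), np.zeros(4), np.zeros(4)), cfg, small_connectome)


class TestSimulate:
    def test_kernel_matches_reference_derivatives(self, small_connectome):
        """One Euler step of the compiled kernel equals the numpy RHS.

        Run two simulations that differ by one extra dt of main phase and
        compare the increment against `derivatives` evaluated with the
        same noise draw.  Noise-free to keep draws out of the picture.
        """
        cfg = SimulationConfig(
            g=0.3, noise_d=0.0, dt=1e-3, record_dt=1e-3,
            t_transient=0.0, t_settle=0.0, t_main=0.002,
        )
        traj = simulate(small_connectome, cfg, seed=0)
        e0, e1 = traj.e[:, 0].astype(float), traj.e[:, 1].astype(float)
        i0 = traj.i[:, 0].astype(float) if traj.i.shape[1] else None
        # reconstruct the step from the recorded state: need I and a at t0;
        # use aux records (stride 10 -> only final). Instead compare against
        # an explicit two-step hand integration of `derivatives`.
        e, i, a = np.full(4, cfg.e_init), np.full(4, cfg.i_init), np.full(4, cfg.a_init)
        for _ in range(2):
            d_e, d_i, d_a = derivatives((e, i, a), cfg, small_connectome, tau_ip=cfg.tau_ip_main)
            e = e + cfg.dt * d_e
            i = i + cfg.dt * d_i
            a = np.maximum(a + cfg.dt * d_a, 0.0)
        assert np.allclose(e1, e, atol=1e-6)  # float32 storage tolerance

    def test_seed_determinism(self, small_connectome):
        cfg = desk_config(t_transient=1.0, t_settle=0.0, t_main=2.0)
        t1 = simulate(small_connectome, cfg, seed=42)
        t2 = simulate(small_connectome, cfg, seed=42)
        t3 = simulate(small_connectome, cfg, seed=43)
        assert np.array_equal(t1.e, t2.e)
        assert np.array_equal(t1.a_ie, t2.a_ie)
        assert not np.array_equal(t1.e, t3.e)

    def test_homeostatic_set_point(self, connectome30):
        """Time-mean excitatory activity sits near rho_E under coupling."""
        cfg = desk_config()
        traj = simulate(connectome30, cfg, seed=1)
        node_means = traj.e.mean(axis=1)
        assert np.all(np.abs(node_means - 0.18) < 0.02)

    def test_decoupled_network_uncorrelated(self, connectome30):
        """With G = 0, noise-driven fluctuations are independent per node.

        All nodes share one deterministic relaxation path (identical
        parameters and initial state), so raw series trivially correlate;
        independence shows in the residuals after subtracting that path
        (the noise-free trajectory).  With coupling switched on the same
        residual correlations become large.
        """
        cfg = desk_config(g=0.0, t_main=120.0)
        det = simulate(connectome30, desk_config(g=0.0, t_main=120.0, noise_d=0.0), seed=0)
        traj = simulate(connectome30, cfg, seed=3)
        resid = (traj.e - det.e)[:, ::5].astype(float)
        off = np.corrcoef(resid)[np.triu_indices(30, 1)]
        assert np.mean(np.abs(off)) < 0.1
        # contrast: coupled network residuals are strongly correlated
        cfgc = desk_config(t_main=120.0)
        detc = simulate(connectome30, desk_config(t_main=120.0, noise_d=0.0), seed=0)
        trajc = simulate(connectome30, cfgc, seed=3)
        residc = (trajc.e - detc.e)[:, ::5].astype(float)
        offc = np.corrcoef(residc)[np.triu_indices(30, 1)]
        assert np.mean(np.abs(offc)) > np.mean(np.abs(off))

    def test_initialization_insensitivity(self, small_connectome):
        """The fast-plasticity transient erases the initial conditions."""
        base = desk_config(t_transient=30.0, t_settle=0.0, t_main=5.0, noise_d=0.0)
        alt = desk_config(
            t_transient=30.0, t_settle=0.0, t_main=5.0, noise_d=0.0,
            e_init=0.4, i_init=0.05, a_init=2.0,
        )
        t1 = simulate(small_connectome, base, seed=0)
        t2 = simulate(small_connectome, alt, seed=0)
        assert np.allclose(t1.e[:, -1], t2.e[:, -1], atol=1e-3)

    def test_trajectory_metadata(self, small_connectome):
        cfg = desk_config(t_transient=0.5, t_settle=0.0, t_main=1.0)
        traj = simulate(small_connectome, cfg, seed=9)
        assert traj.e.shape == (4, int(round(1.0 / cfg.record_dt)))
        assert traj.dt_record == pytest.approx(cfg.record_dt)
        assert np.all(np.isfinite(traj.e))
        assert np.all(traj.a_ie >= 0)
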