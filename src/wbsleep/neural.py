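"""Wilson-Cowan network with homeostatic inhibitory plasticity.

Each region carries an excitatory population E_i, an inhibitory population
I_i and a plastic inhibitory-to-excitatory weight a_i^IE:

    tau_E dE_i/dt = -E_i + (1 - r_E E_i) S_E(a_EE E_i - a_i^IE I_i
                                             + G_i sum_j C_ji E_j + P + D eps_i)
    tau_I dI_i/dt = -I_i + (1 - r_I I_i) S_I(a_EI E_i)
    tau_ip da_i^IE/dt = I_i (E_i - rho_E)

with the sigmoid transfer S(x) = 1 / (1 + exp(-(x - mu) / sigma)).  The
plasticity rule drives the time-average of E_i toward the homeostatic set
point rho_E = 0.18, which makes the network's operating point robust to
changes in coupling and slope.  The excitatory slope sigma_E and the
long-range coupling G may be region-heterogeneous (neuromodulation); the
inhibitory slope sigma_I stays fixed.

Integration is explicit Euler.  A transient with fast plasticity
(tau_ip = 0.05 s) is run first and discarded, then the analysis window is
integrated with slow plasticity (tau_ip = 2 s).  Noise enters the sigmoid
argument as D * eps with eps ~ N(0, 1) redrawn each step (an input
fluctuation, not a Wiener increment); an Euler-Maruyama convention with
1/sqrt(dt) scaling is available as a switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple, Union

import numpy as np

from wbsleep._kernels import wilson_cowan_euler
from wbsleep.errors import IntegrationDivergedError, ParameterRangeError, ShapeError
from wbsleep.io import Connectome

ArrayLike = Union[float, np.ndarray]


@dataclass
class SimulationConfig:
    """All constants of the neural network model (time units: seconds).

    ``g`` and ``sigma_e`` accept a scalar (homogeneous network) or a
    length-N vector (map-modulated network).  ``t_settle`` optionally
    inserts a discarded stretch integrated at the slow plasticity constant
    between the fast-plasticity transient and the recorded window, letting
    the plastic weights re-equilibrate before analysis.
    """

    r_e: float = 0.5
    r_i: float = 0.5
    tau_e: float = 0.01
    tau_i: float = 0.02
    a_ee: float = 3.5
    a_ei: float = 3.75
    p_ext: float = 0.4
    noise_d: float = 0.002
    rho_e: float = 0.18
    mu: float = 1.0
    sigma_i: float = 4.0
    g: ArrayLike = 0.44
    sigma_e: ArrayLike = 4.0
    tau_ip_transient: float = 0.05
    tau_ip_main: float = 2.0
    dt: float = 1e-4
    t_transient: float = 400.0
    t_settle: float = 0.0
    t_main: float = 600.0
    record_dt: float = 1e-3
    aux_record_dt: float = 1e-2
    euler_maruyama: bool = False
    e_init: float = 0.1
    i_init: float = 0.1
    a_init: float = 1.0

    def __post_init__(self):
        for name in ("tau_e", "tau_i", "tau_ip_transient", "tau_ip_main", "dt", "t_main"):
            if getattr(self, name) <= 0:
                raise ParameterRangeError(f"{name} must be positive")
        if self.t_transient < 0 or self.t_settle < 0:
            raise ParameterRangeError("durations must be nonnegative")
        if np.any(np.asarray(self.sigma_e) <= 0) or self.sigma_i <= 0:
            raise ParameterRangeError("sigmoid slopes must be positive")

    def resolve_fields(self, n: int) -> Tuple[np.ndarray, np.ndarray]:
        """Per-region (G_i, sigma_E,i) vectors for an N-region network."""
        g = np.broadcast_to(np.asarray(self.g, dtype=float), (n,)).copy()
        sig = np.broadcast_to(np.asarray(self.sigma_e, dtype=float), (n,)).copy()
        if np.any(sig <= 0):
            raise ParameterRangeError("sigma_e must be positive for every region")
        if np.any(g < 0):
            raise ParameterRangeError("negative coupling G is not admissible")
        return g, sig


@dataclass
class Trajectory:
    """Recorded state paths of one simulation.

    ``e`` is sampled every ``dt_record`` seconds; ``i`` and ``a_ie`` at the
    coarser ``dt_aux`` to bound memory.
    """

    e: np.ndarray
    i: np.ndarray
    a_ie: np.ndarray
    dt_record: float
    dt_aux: float
    rng_seed: int

    @property
    def n(self) -> int:
        return self.e.shape[0]


def sigmoid(x: ArrayLike, mu: float = 1.0, sigma: float = 4.0) -> ArrayLike:
    """Sigmoid transfer S(x) = 1 / (1 + exp(-(x - mu) / sigma))."""
    if sigma <= 0:
        raise ParameterRangeError("sigmoid slope sigma must be positive")
    return 1.0 / (1.0 + np.exp(-(np.asarray(x, dtype=float) - mu) / sigma))


def derivatives(
    state: Tuple[np.ndarray, np.ndarray, np.ndarray],
    config: SimulationConfig,
    connectome: Connectome,
    noise_draw: Optional[np.ndarray] = None,
    tau_ip: Optional[float] = None,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Right-hand side (dE/dt, dI/dt, da_IE/dt) at a given state.

    Reference (pure numpy) implementation of the model equations; the
    compiled integrator is cross-checked against one Euler step of this.
    """
    e, i, a = (np.asarray(v, dtype=float) for v in state)
    n = connectome.n
    if not (e.shape == i.shape == a.shape == (n,)):
        raise ShapeError("state vectors must each have length N")
    eps = np.zeros(n) if noise_draw is None else np.asarray(noise_draw, dtype=float)
    if eps.shape != (n,):
        raise ShapeError("noise draw must have length N")
    g_vec, sig_vec = config.resolve_fields(n)
    tau_ip = config.tau_ip_main if tau_ip is None else tau_ip

    noise_scale = config.noise_d / np.sqrt(config.dt) if config.euler_maruyama else config.noise_d
    net = connectome.weights.T @ e  # incoming term sum_j C_ji E_j
    x = config.a_ee * e - a * i + g_vec * net + config.p_ext + noise_scale * eps
    s_e = 1.0 / (1.0 + np.exp(-(x - config.mu) / sig_vec))
    s_i = sigmoid(config.a_ei * e, config.mu, config.sigma_i)
    d_e = (-e + (1.0 - config.r_e * e) * s_e) / config.tau_e
    d_i = (-i + (1.0 - config.r_i * i) * s_i) / config.tau_i
    d_a = i * (e - config.rho_e) / tau_ip
    return d_e, d_i, d_a


def simulate(connectome: Connectome, config: SimulationConfig, seed: int) -> Trajectory:
    """Integrate the network and return the recorded analysis window.

    The transient (fast plasticity) and optional settling stretch are
    discarded; the returned excitatory path is sampled every
    ``config.record_dt`` seconds.  Identical (connectome, config, seed)
    give bitwise-identical trajectories.
    """
    n = connectome.n
    g_vec, sig_vec = config.resolve_fields(n)
    record_stride = max(1, int(round(config.record_dt / config.dt)))
    aux_stride = max(1, int(round(config.aux_record_dt / config.dt)))
    n_transient = int(round(config.t_transient / config.dt))
    n_settle = int(round(config.t_settle / config.dt))
    n_main = int(round(config.t_main / config.dt))
    coupling_in = np.ascontiguousarray(connectome.weights.T)

    e_rec, i_rec, a_rec, bad_phase, bad_step = wilson_cowan_euler(
        coupling_in,
        g_vec,
        sig_vec,
        config.r_e,
        config.r_i,
        config.tau_e,
        config.tau_i,
        config.a_ee,
        config.a_ei,
        config.p_ext,
        config.noise_d,
        config.rho_e,
        config.mu,
        config.sigma_i,
        config.dt,
        1 if config.euler_maruyama else 0,
        n_transient,
        config.tau_ip_transient,
        n_settle,
        n_main,
        config.tau_ip_main,
        record_stride,
        aux_stride,
        int(seed),
        config.e_init,
        config.i_init,
        config.a_init,
    )
    if bad_phase >= 0:
        raise IntegrationDivergedError(
            f"non-finite state in phase {bad_phase} at step {bad_step} (t={bad_step * config.dt:.2f} s)"
        )
    return Trajectory(
        e=e_rec,
        i=i_rec,
        a_ie=a_rec,
        dt_record=record_stride * config.dt,
        dt_aux=aux_stride * config.dt,
        rng_seed=int(seed),
    )


def desk_config(**overrides) -> SimulationConfig:
    """Reduced-cost configuration for desk-scale runs and tests.

    Coarser integration step (2 ms), a short fast-plasticity transient plus
    a settling stretch, and a 180 s analysis window.  The model constants
    are unchanged.
    """
    base = dict(
        dt=2e-3,
        record_dt=2e-3,
        aux_record_dt=2e-2,
        t_transient=20.0,
        t_settle=10.0,
        t_main=180.0,
    )
    base.update(overrides)
    return SimulationConfig(**base)
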