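"""End-to-end forward model: neural network -> BOLD -> FC.

Shared by the synthetic-data generator, the parameter sweeps and the
homotopic connectome enhancement, so every consumer sees exactly the
same simulation chain.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Tuple

import numpy as np

from wbsleep.fc import FCMatrix, compute_fc
from wbsleep.hemodynamics import (
    BoldSeries,
    HemodynamicConfig,
    balloon_windkessel,
    bold_postprocess,
)
from wbsleep.io import Connectome
from wbsleep.neural import SimulationConfig, simulate

#: Initial BOLD stretch discarded before filtering (seconds).  The
#: Balloon-Windkessel state starts at rest and its step response to the
#: network's operating level is a large transient shared by all regions;
#: dropping it keeps FC from being dominated by that common component.
BOLD_DISCARD = 20.0

#: Default spacing (seconds) to which the neural drive is mean-pooled
#: before hemodynamic integration.  The Balloon-Windkessel time constants
#: are all >= 0.4 s and the analysis band ends at 0.1 Hz, so anti-aliased
#: pooling to 10 ms leaves the filtered BOLD (and FC) essentially
#: unchanged while cutting the hemodynamic stage's cost ~10x.  Pass
#: ``pool_dt=None`` to drive the hemodynamics at the neural recording
#: stride directly.
POOL_DT = 0.01


def _pool(e: np.ndarray, dt_in: float, pool_dt: Optional[float]) -> Tuple[np.ndarray, float]:
    if pool_dt is None:
        return e, dt_in
    factor = int(round(pool_dt / dt_in))
    if factor <= 1:
        return e, dt_in
    t = e.shape[1] // factor * factor
    pooled = e[:, :t].reshape(e.shape[0], -1, factor).mean(axis=2)
    return pooled, dt_in * factor


def simulate_bold(
    connectome: Connectome,
    sim_config: SimulationConfig,
    seed: int,
    hemo_config: Optional[HemodynamicConfig] = None,
    band: Tuple[float, float] = (0.01, 0.1),
    tr: float = 2.0,
    discard: float = BOLD_DISCARD,
    pool_dt: Optional[float] = POOL_DT,
) -> BoldSeries:
    """Simulate the network and return filtered, TR-sampled BOLD."""
    traj = simulate(connectome, sim_config, seed)
    drive, dt = _pool(traj.e.astype(float), traj.dt_record, pool_dt)
    hemo = hemo_config or HemodynamicConfig(dt=dt)
    if abs(hemo.dt - dt) > 1e-12:
        hemo = replace(hemo, dt=dt)
    raw = balloon_windkessel(drive, hemo)
    return bold_postprocess(raw, band=band, tr=tr, discard=discard)


def simulate_fc(
    connectome: Connectome,
    sim_config: SimulationConfig,
    seed: int,
    hemo_config: Optional[HemodynamicConfig] = None,
    band: Tuple[float, float] = (0.01, 0.1),
    tr: float = 2.0,
    discard: float = BOLD_DISCARD,
    pool_dt: Optional[float] = POOL_DT,
) -> FCMatrix:
    """Forward model all the way to a simulated FC matrix."""
    bold = simulate_bold(connectome, sim_config, seed, hemo_config, band, tr, discard, pool_dt)
    return compute_fc(bold.values)


def seed_mean_fc(
    connectome: Connectome,
    sim_config: SimulationConfig,
    seeds,
    **kwargs,
) -> FCMatrix:
    """Element-wise mean of simulated FC matrices over a seed ensemble."""
    seeds = list(seeds)
    acc = None
    for s in seeds:
        fc = simulate_fc(connectome, sim_config, s, **kwargs)
        acc = fc.values if acc is None else acc + fc.values
    mean = acc / len(seeds)
    np.fill_diagonal(mean, 1.0)
    return FCMatrix(values=mean)
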