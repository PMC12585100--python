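"""Homotopic enhancement of structural connectivity.

Diffusion tractography underestimates interhemispheric connections, which
shows up as a mismatch between empirical and simulated FC on homotopic
entries.  The correction iterates a fixed-point update over epochs t:

    SC_ij <- SC_ij + eta * (FC_ij^empirical - FC_ij^simulated(t))

restricted to homotopic pairs (i, partner(i)), with the simulated FC
taken as the mean over a seed ensemble each epoch.  Non-homotopic
entries are never touched; updated entries are floored at zero and kept
symmetric.  The forward engine is pluggable; the package's own
Wilson-Cowan + hemodynamics chain is the default.
"""

from __future__ import annotations

from typing import Callable, List, Optional

import numpy as np

from wbsleep.errors import ShapeError, WbsleepError
from wbsleep.fc import FCMatrix
from wbsleep.forward import simulate_fc
from wbsleep.io import Connectome
from wbsleep.neural import SimulationConfig

ForwardModel = Callable[[Connectome, int], FCMatrix]


def default_forward_model(sim_config: SimulationConfig) -> ForwardModel:
    """Forward engine running the package's simulation chain."""

    def run(connectome: Connectome, seed: int) -> FCMatrix:
        return simulate_fc(connectome, sim_config, seed)

    return run


def enhance_homotopic(
    sc: Connectome,
    fc_target: FCMatrix,
    forward_model: ForwardModel,
    eta: float = 0.05,
    epochs: int = 60,
    seeds_per_epoch: int = 20,
    seed0: int = 0,
    history: Optional[List[float]] = None,
) -> Connectome:
    """Iteratively match homotopic SC entries to empirical homotopic FC.

    ``history``, if given, collects the mean absolute homotopic FC error
    per epoch.  A divergence guard halves ``eta`` whenever that error
    grows two epochs in a row.
    """
    if eta < 0:
        raise ShapeError("eta must be nonnegative")
    if fc_target.n != sc.n:
        raise ShapeError("target FC and connectome sizes differ")
    if np.abs(fc_target.values).max() > 1.0 + 1e-9:
        raise ShapeError("target FC entries must lie in [-1, 1]")
    regions = sc.regions
    pairs = regions.homotopic_pairs()
    weights = sc.weights.copy()
    grew = 0
    prev_err = np.inf
    for epoch in range(epochs):
        if eta == 0.0:
            break
        acc = np.zeros_like(weights)
        for k in range(seeds_per_epoch):
            try:
                fc_sim = forward_model(Connectome(weights=weights, regions=regions), seed0 + k)
            except WbsleepError as exc:
                raise type(exc)(f"forward model failed at epoch {epoch}: {exc}") from exc
            acc += fc_sim.values
        fc_sim_mean = acc / seeds_per_epoch
        err = 0.0
        for i, j in pairs:
            delta = fc_target.values[i, j] - fc_sim_mean[i, j]
            err += abs(delta)
            w = max(weights[i, j] + eta * delta, 0.0)
            weights[i, j] = weights[j, i] = w
        err /= len(pairs)
        if history is not None:
            history.append(err)
        if err > prev_err:
            grew += 1
            if grew >= 2:
                eta *= 0.5
                grew = 0
        else:
            grew = 0
        prev_err = err
    return Connectome(weights=weights, regions=regions)
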