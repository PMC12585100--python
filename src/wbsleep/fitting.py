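"""(deltaG, delta-sigma) sweeps, optimum selection and modality comparison.

The model is fitted to an empirical FC matrix by sweeping neuromodulatory
offsets around a homogeneous baseline (G, sigma): at every grid point the
regional parameter fields are built from the ACh/NA maps, the forward
model is run for an ensemble of seeds, and the euccorrelation between
simulated and empirical FC lower triangles is recorded.  The optimum is
the argmin of the seed-mean fit.  Three modalities are compared -
homogeneous (no maps), map (empirical maps), shuffle (hemisphere-symmetric
surrogate maps) - via Cohen's D between their per-seed optimal fit
distributions and via correlations between simulated and empirical nodal
integration/segregation profiles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from wbsleep.errors import DegenerateInputError, ParameterRangeError, ShapeError, WbsleepError
from wbsleep.fc import FCMatrix, euccorrelation, lower_triangle_vector
from wbsleep.forward import simulate_fc
from wbsleep.hemodynamics import HemodynamicConfig
from wbsleep.hma import hma_decompose
from wbsleep.io import Connectome
from wbsleep.neural import SimulationConfig
from wbsleep.neuromodulation import ModulationMap, apply_modulation
from wbsleep.stats import cohens_d


def delta_grid(n_g: int = 50, n_sigma: int = 50,
               g_range: Tuple[float, float] = (-0.5, 0.5),
               sigma_range: Tuple[float, float] = (-1.0, 1.0)) -> Tuple[np.ndarray, np.ndarray]:
    """Endpoint-inclusive equidistant delta grids (defaults: 50 x 50)."""
    return np.linspace(*g_range, n_g), np.linspace(*sigma_range, n_sigma)


@dataclass
class SweepResult:
    """Fit tensor of one sweep plus the selected optimum."""

    dg_values: np.ndarray
    dsigma_values: np.ndarray
    modality: str
    baseline: Tuple[float, float]
    fit: np.ndarray  # (n_dg, n_dsigma, n_seeds); +inf marks infeasible points
    seeds: List[int]
    optimum: Tuple[float, float] = (np.nan, np.nan)
    optimum_index: Tuple[int, int] = (-1, -1)
    optimum_fit: Optional[np.ndarray] = None  # per-seed fits at the optimum
    optimum_fcs: List[FCMatrix] = field(default_factory=list)

    def seed_mean(self) -> np.ndarray:
        return self.fit.mean(axis=2)


def select_optimum(sweep: SweepResult, rule: str = "mean") -> Tuple[float, float]:
    """Argmin of the seed-aggregated fit with a deterministic tie-break.

    Ties go to the smallest |deltaG|, then the smallest |delta-sigma|,
    then the earlier grid index.
    """
    agg = sweep.fit.mean(axis=2) if rule == "mean" else np.median(sweep.fit, axis=2)
    if not np.any(np.isfinite(agg)):
        raise ParameterRangeError("no feasible grid point: all fits are infinite")
    best = None
    best_key = None
    for i, dg in enumerate(sweep.dg_values):
        for j, ds in enumerate(sweep.dsigma_values):
            v = agg[i, j]
            if not np.isfinite(v):
                continue
            key = (v, abs(dg), abs(ds), i, j)
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
    i, j = best
    sweep.optimum_index = (i, j)
    sweep.optimum = (float(sweep.dg_values[i]), float(sweep.dsigma_values[j]))
    sweep.optimum_fit = sweep.fit[i, j, :].copy()
    return sweep.optimum


def run_sweep(
    empirical_fc: FCMatrix,
    connectome: Connectome,
    maps: Optional[Tuple[Optional[ModulationMap], Optional[ModulationMap]]],
    baseline: Tuple[float, float],
    grid: Tuple[np.ndarray, np.ndarray],
    n_seeds: int,
    sim_config: SimulationConfig,
    hemo_config: Optional[HemodynamicConfig] = None,
    modality: str = "homogeneous",
    seed0: int = 0,
    keep_optimum_fcs: bool = True,
) -> SweepResult:
    """Evaluate the fit over a (deltaG, delta-sigma) grid and seed ensemble.

    Infeasible grid points (nonpositive slope or negative coupling) are
    recorded as +inf; individual simulation failures are likewise logged
    as +inf rather than aborting the sweep.
    """
    g0, s0 = baseline
    dg_values, dsigma_values = (np.asarray(g, dtype=float) for g in grid)
    if dg_values.size == 0 or dsigma_values.size == 0:
        raise ShapeError("sweep grid must be nonempty")
    ach, na = maps if maps is not None else (None, None)
    emp_vec = lower_triangle_vector(empirical_fc)
    seeds = [seed0 + k for k in range(n_seeds)]
    fit = np.full((dg_values.size, dsigma_values.size, n_seeds), np.inf)

    for i, dg in enumerate(dg_values):
        for j, ds in enumerate(dsigma_values):
            try:
                g_vec, sig_vec = apply_modulation(g0, s0, dg, ds, ach, na, n=connectome.n)
            except ParameterRangeError:
                continue
            cfg = replace(sim_config, g=g_vec, sigma_e=sig_vec)
            for k, seed in enumerate(seeds):
                try:
                    sim = simulate_fc(connectome, cfg, seed, hemo_config)
                    fit[i, j, k] = euccorrelation(emp_vec, lower_triangle_vector(sim))
                except WbsleepError:
                    fit[i, j, k] = np.inf

    result = SweepResult(
        dg_values=dg_values,
        dsigma_values=dsigma_values,
        modality=modality,
        baseline=(float(g0), float(s0)),
        fit=fit,
        seeds=seeds,
    )
    select_optimum(result)
    if keep_optimum_fcs:
        dg, ds = result.optimum
        g_vec, sig_vec = apply_modulation(g0, s0, dg, ds, ach, na, n=connectome.n)
        cfg = replace(sim_config, g=g_vec, sigma_e=sig_vec)
        result.optimum_fcs = [
            simulate_fc(connectome, cfg, seed, hemo_config) for seed in seeds
        ]
    return result


def fit_at_point(
    empirical_fc: FCMatrix,
    connectome: Connectome,
    maps: Optional[Tuple[Optional[ModulationMap], Optional[ModulationMap]]],
    baseline: Tuple[float, float],
    delta: Tuple[float, float],
    seeds,
    sim_config: SimulationConfig,
    hemo_config: Optional[HemodynamicConfig] = None,
    keep_fcs: bool = False,
) -> Tuple[np.ndarray, List[FCMatrix]]:
    """Per-seed euccorrelation fits at one (deltaG, delta-sigma) point.

    Used to sample the fit distribution at a selected optimum with a
    larger seed ensemble than the sweep itself used.
    """
    ach, na = maps if maps is not None else (None, None)
    g_vec, sig_vec = apply_modulation(*baseline, *delta, ach, na, n=connectome.n)
    cfg = replace(sim_config, g=g_vec, sigma_e=sig_vec)
    emp_vec = lower_triangle_vector(empirical_fc)
    fits = []
    fcs: List[FCMatrix] = []
    for seed in seeds:
        sim = simulate_fc(connectome, cfg, seed, hemo_config)
        fits.append(euccorrelation(emp_vec, lower_triangle_vector(sim)))
        if keep_fcs:
            fcs.append(sim)
    return np.asarray(fits), fcs


def run_baseline_sweep(
    empirical_fc: FCMatrix,
    connectome: Connectome,
    g_values: np.ndarray,
    sigma_values: np.ndarray,
    n_seeds: int,
    sim_config: SimulationConfig,
    hemo_config: Optional[HemodynamicConfig] = None,
    seed0: int = 0,
) -> SweepResult:
    """Absolute (G, sigma) sweep used to anchor the wake baseline.

    Implemented as a homogeneous delta sweep around baseline (0, 0), so
    the returned optimum IS the absolute (G*, sigma*) pair.
    """
    return run_sweep(
        empirical_fc,
        connectome,
        maps=None,
        baseline=(0.0, 0.0),
        grid=(np.asarray(g_values, dtype=float), np.asarray(sigma_values, dtype=float)),
        n_seeds=n_seeds,
        sim_config=sim_config,
        hemo_config=hemo_config,
        modality="baseline",
        seed0=seed0,
        keep_optimum_fcs=False,
    )


def compare_modalities(sweeps: Dict[str, SweepResult]) -> pd.DataFrame:
    """Cohen's D between per-seed optimal-fit distributions of modalities.

    Rows are ordered modality pairs (a, b); d < 0 means modality ``a``
    fits better (lower euccorrelation) than modality ``b``.
    """
    names = list(sweeps)
    n_seeds = {name: len(sweeps[name].seeds) for name in names}
    if len(set(n_seeds.values())) != 1:
        raise ShapeError(f"modalities have different seed counts: {n_seeds}")
    if next(iter(n_seeds.values())) < 2:
        raise DegenerateInputError("need at least 2 seeds per modality for effect sizes")
    rows = []
    for a in names:
        for b in names:
            if a >= b:
                continue
            fa = sweeps[a].optimum_fit
            fb = sweeps[b].optimum_fit
            eff = cohens_d(fa, fb, paired=False)
            rows.append({"a": a, "b": b, "d": eff.d, "bin": eff.bin})
    return pd.DataFrame(rows)


def profile_similarity(
    simulated_fcs: Sequence[FCMatrix],
    empirical_fc: FCMatrix,
) -> pd.DataFrame:
    """Per-seed correlation of simulated vs empirical nodal HMA profiles.

    Columns ``r_integration`` / ``r_segregation`` hold the Pearson
    correlations between the simulated and empirical nodal components.
    """
    emp = hma_decompose(empirical_fc)
    if emp.h_in_nodal.std() == 0 or emp.h_se_nodal.std() == 0:
        raise DegenerateInputError("empirical nodal profile is constant")
    rows = []
    for fc in simulated_fcs:
        if fc.n != empirical_fc.n:
            raise ShapeError("simulated and empirical FC sizes differ")
        sim = hma_decompose(fc)
        if sim.h_in_nodal.std() == 0 or sim.h_se_nodal.std() == 0:
            raise DegenerateInputError("simulated nodal profile is constant")
        rows.append(
            {
                "r_integration": float(np.corrcoef(sim.h_in_nodal, emp.h_in_nodal)[0, 1]),
                "r_segregation": float(np.corrcoef(sim.h_se_nodal, emp.h_se_nodal)[0, 1]),
            }
        )
    return pd.DataFrame(rows)
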