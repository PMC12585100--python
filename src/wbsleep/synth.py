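"""Synthetic study inputs with known neuromodulatory ground truth.

Generates everything the pipeline consumes: a modular, homotopically
symmetric connectome; mean-1 positive modulation maps with a controllable
spatial correlation; multi-subject, multi-stage BOLD datasets produced by
the package's own forward model at stage-specific (deltaG, delta-sigma)
with per-subject parameter jitter; and nucleus-like (BF/LC analogue)
signals built as map-weighted mixtures of regional BOLD.

Default study conditions emulate a night-sleep recording at desk scale:
30 regions, 180 s analysis windows at TR = 2 s, 8 subjects, and a
stage progression in which deeper NREM sleep raises the effective
coupling (cholinergic withdrawal) and lowers the excitatory slope
(noradrenergic withdrawal).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from wbsleep.errors import ConvergenceError, ParameterRangeError, ShapeError
from wbsleep.forward import simulate_bold
from wbsleep.hemodynamics import HemodynamicConfig
from wbsleep.io import Connectome, RegionTable, StageDataset, STAGES
from wbsleep.neural import SimulationConfig, desk_config
from wbsleep.neuromodulation import ModulationMap, apply_modulation

#: Homogeneous reference point of the synthetic study: the wake-state
#: operating point of the desk-scale network (see docs/methods.md for the
#: regime choice).
BASELINE_G = 0.44
BASELINE_SIGMA = 3.5

#: Stage-specific ground-truth offsets (deltaG, delta-sigma).  Deeper
#: sleep moves toward higher coupling and shallower slope; values sit on
#: the 11-point desk grid (steps 0.1 and 0.2).
DEFAULT_STAGE_PARAMS: Dict[str, Tuple[float, float]] = {
    "W": (0.0, 0.0),
    "N1": (0.1, -0.2),
    "N2": (0.2, -0.4),
    "N3": (0.3, -0.6),
}

#: Mean row sum of the generated connectome.  Sets the scale of the
#: recurrent input G * sum_j C_ji E_j: at the baseline coupling the
#: network input is of order one, which places the reference state in the
#: fluctuation-rich regime that produces structured FC.
CONNECTOME_ROW_SUM = 40.0


@dataclass
class GroundTruth:
    """Exact generation parameters of a synthetic dataset."""

    stage_params: Dict[str, Tuple[float, float]]
    base_g: float
    base_sigma: float
    subject_noise_sd: float
    subject_jitter: Dict[str, Dict[str, Tuple[float, float]]]
    ach_map: Optional[np.ndarray] = None
    na_map: Optional[np.ndarray] = None
    seed: int = 0

    def to_json(self, path) -> None:
        payload = {
            "stage_params": {k: list(v) for k, v in self.stage_params.items()},
            "base_g": self.base_g,
            "base_sigma": self.base_sigma,
            "subject_noise_sd": self.subject_noise_sd,
            "subject_jitter": {
                s: {st: list(v) for st, v in d.items()} for s, d in self.subject_jitter.items()
            },
            "ach_map": None if self.ach_map is None else self.ach_map.tolist(),
            "na_map": None if self.na_map is None else self.na_map.tolist(),
            "seed": self.seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def make_regions(n_regions: int, n_thalamus_pairs: int = 1) -> RegionTable:
    """Region table with mirror-symmetric labels and homotopic pairing.

    Regions 0..n/2-1 are the left hemisphere, i's partner is i + n/2.
    The first ``n_thalamus_pairs`` pairs counted from the end are flagged
    thalamic (mimicking a subcortical block at the tail of the table).
    """
    if n_regions % 2 != 0 or n_regions < 2:
        raise ShapeError("n_regions must be a positive even integer")
    half = n_regions // 2
    rows = []
    for i in range(n_regions):
        hemi = "left" if i < half else "right"
        base = i if i < half else i - half
        thal = base >= half - n_thalamus_pairs
        rows.append(
            {
                "label": f"SYN{base:02d}{'L' if hemi == 'left' else 'R'}",
                "hemisphere": hemi,
                "homotopic_partner": i + half if i < half else i - half,
                "is_thalamus": thal,
            }
        )
    return RegionTable(pd.DataFrame(rows))


def make_connectome(
    n_regions: int,
    n_modules: int = 3,
    homotopic_weight: float = 1.0,
    density: float = 0.6,
    seed: int = 0,
    row_sum: Optional[float] = CONNECTOME_ROW_SUM,
    regions: Optional[RegionTable] = None,
) -> Connectome:
    """Modular, hemispherically mirrored synthetic connectome.

    Within-hemisphere weights have a block-modular structure (strong
    within-module, weak between); the right hemisphere mirrors the left,
    and inter-hemispheric background is symmetric under the homotopic
    map.  Homotopic entries are then pinned to ``homotopic_weight`` (in
    units of the pre-scaling weights) and the whole matrix is rescaled to
    a mean row sum of ``row_sum``.
    """
    if n_regions % 2 != 0 or n_regions < 4:
        raise ShapeError("n_regions must be even and >= 4")
    half = n_regions // 2
    if not (1 <= n_modules <= half):
        raise ShapeError("need 1 <= n_modules <= n_regions/2")
    if not (0 < density <= 1):
        raise ParameterRangeError("density must lie in (0, 1]")
    rng = np.random.default_rng(seed)

    module_of = np.array([i * n_modules // half for i in range(half)])
    intra = np.zeros((half, half))
    for i in range(half):
        for j in range(i + 1, half):
            w = rng.uniform(0.5, 1.0) if module_of[i] == module_of[j] else rng.uniform(0.0, 0.3)
            intra[i, j] = intra[j, i] = w
    mask = np.zeros((half, half), dtype=bool)
    iu = np.triu_indices(half, 1)
    mask[iu] = rng.uniform(size=iu[0].size) < density
    mask |= mask.T
    intra = intra * mask

    # weak mirrored inter-hemispheric background
    inter = np.zeros((half, half))
    for i in range(half):
        for j in range(i + 1, half):
            if rng.uniform() < density:
                w = rng.uniform(0.0, 0.15)
                inter[i, j] = inter[j, i] = w

    weights = np.zeros((n_regions, n_regions))
    weights[:half, :half] = intra
    weights[half:, half:] = intra  # mirror-symmetric module structure
    weights[:half, half:] = inter
    weights[half:, :half] = inter.T
    for i in range(half):
        weights[i, i + half] = weights[i + half, i] = homotopic_weight
    np.fill_diagonal(weights, 0.0)
    if row_sum is not None:
        weights *= row_sum / weights.sum(axis=1).mean()

    regions = regions or make_regions(n_regions)
    return Connectome(weights=weights, regions=regions)


def make_maps(
    regions: RegionTable,
    spatial_correlation: float = 0.3,
    seed: int = 0,
    sigma_log: float = 0.45,
    max_attempts: int = 100,
    tolerance: float = 0.15,
) -> Tuple[ModulationMap, ModulationMap]:
    """Two positive, hemisphere-symmetric, mean-1 maps (ACh, NA analogues).

    Per-hemisphere log-values are drawn jointly Gaussian with the
    requested correlation, exponentiated (lognormal skew resembles
    transporter/projection densities), mirrored onto both hemispheres and
    mean-normalized.  Draws are repeated until the realized Pearson
    correlation lands within ``tolerance`` of the request.
    """
    if not (-1.0 <= spatial_correlation <= 1.0):
        raise ParameterRangeError("spatial_correlation must lie in [-1, 1]")
    if not regions.complete_pairing():
        raise ShapeError("map generation needs complete homotopic pairing")
    pairs = regions.homotopic_pairs()
    half = len(pairs)
    rng = np.random.default_rng(seed)
    rho = spatial_correlation
    for _ in range(max_attempts):
        z1 = rng.standard_normal(half)
        z2 = rho * z1 + np.sqrt(max(0.0, 1.0 - rho * rho)) * rng.standard_normal(half)
        v1 = np.exp(sigma_log * z1)
        v2 = np.exp(sigma_log * z2)
        ach = np.empty(regions.n)
        na = np.empty(regions.n)
        for (left, right), a, b in zip(pairs, v1, v2):
            ach[left] = ach[right] = a
            na[left] = na[right] = b
        ach /= ach.mean()
        na /= na.mean()
        ach /= ach.mean()  # second pass absorbs rounding
        na /= na.mean()
        realized = float(np.corrcoef(ach, na)[0, 1]) if half > 1 else 1.0
        if abs(rho) == 1.0 or abs(realized - rho) <= tolerance:
            if rho == 1.0:
                na = ach.copy()
            elif rho == -1.0 and half > 1:
                realized = float(np.corrcoef(ach, na)[0, 1])
                if abs(realized - rho) > tolerance:
                    continue
            return (
                ModulationMap(values=ach, kind="ACh", normalized=True),
                ModulationMap(values=na, kind="NA", normalized=True),
            )
    raise ConvergenceError(
        f"could not realize spatial correlation {rho} within {tolerance} in {max_attempts} draws"
    )


def make_nucleus_series(
    region_series: np.ndarray,
    mod_map: ModulationMap,
    noise_sd: float,
    seed: int,
) -> np.ndarray:
    """Map-weighted average of regional signals plus white noise.

    Emulates the BOLD trace of a neuromodulatory nucleus whose cortical
    projections follow the map.
    """
    s = np.asarray(region_series, dtype=float)
    if s.ndim != 2:
        raise ShapeError("region_series must be region x time")
    if mod_map.n != s.shape[0]:
        raise ShapeError(f"map has {mod_map.n} entries, series has {s.shape[0]} regions")
    weights = mod_map.values / mod_map.values.sum()
    mix = weights @ s
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        mix = mix + rng.normal(0.0, noise_sd, size=mix.size)
    return mix


def simulate_stage_dataset(
    connectome: Connectome,
    ach_map: Optional[ModulationMap],
    na_map: Optional[ModulationMap],
    stage_params: Optional[Dict[str, Tuple[float, float]]] = None,
    n_subjects: int = 8,
    subject_noise_sd: float = 0.02,
    duration: float = 180.0,
    seed: int = 0,
    base_g: float = BASELINE_G,
    base_sigma: float = BASELINE_SIGMA,
    sim_config: Optional[SimulationConfig] = None,
    tr: float = 2.0,
    nucleus_noise_sd: float = 0.0,
) -> Tuple[List[StageDataset], GroundTruth]:
    """Forward-simulate a multi-subject, multi-stage BOLD study.

    Every subject x stage combination runs the full neural + hemodynamic
    chain at the stage's (deltaG, delta-sigma) plus subject-level
    Gaussian jitter of SD ``subject_noise_sd``; BF/LC analogue nucleus
    signals are attached as map-weighted mixtures when maps are given.
    The returned :class:`GroundTruth` records the exact parameters used.
    """
    stage_params = dict(stage_params or DEFAULT_STAGE_PARAMS)
    missing = set(STAGES) - set(stage_params)
    if missing:
        raise ShapeError(f"stage_params missing stages: {sorted(missing)}")
    cfg = sim_config or desk_config(t_main=duration)
    if abs(cfg.t_main - duration) > 1e-9:
        cfg = replace(cfg, t_main=duration)

    rng = np.random.default_rng(seed)
    datasets: List[StageDataset] = []
    jitter_record: Dict[str, Dict[str, Tuple[float, float]]] = {}
    for subj_idx in range(n_subjects):
        subject = f"sub{subj_idx:02d}"
        jitter_record[subject] = {}
        for stage in STAGES:
            dg0, ds0 = stage_params[stage]
            if subject_noise_sd > 0:
                dg = dg0 + rng.normal(0.0, subject_noise_sd)
                ds = ds0 + rng.normal(0.0, subject_noise_sd)
            else:
                rng.normal(size=2)  # keep the stream position stable
                dg, ds = dg0, ds0
            jitter_record[subject][stage] = (float(dg), float(ds))
            g_vec, sig_vec = apply_modulation(
                base_g, base_sigma, dg, ds, ach_map, na_map, n=connectome.n
            )
            run_cfg = replace(cfg, g=g_vec, sigma_e=sig_vec)
            sim_seed = int(rng.integers(0, 2**31 - 1))
            bold = simulate_bold(connectome, run_cfg, sim_seed, tr=tr)
            nuclei: Dict[str, np.ndarray] = {}
            if ach_map is not None:
                nuclei["BF"] = make_nucleus_series(
                    bold.values, ach_map, nucleus_noise_sd, sim_seed + 1
                )
            if na_map is not None:
                nuclei["LC"] = make_nucleus_series(
                    bold.values, na_map, nucleus_noise_sd, sim_seed + 2
                )
            datasets.append(
                StageDataset(
                    subject_id=subject,
                    stage=stage,
                    series=bold.values,
                    tr=bold.sampling_interval,
                    nucleus_series=nuclei,
                )
            )
    truth = GroundTruth(
        stage_params=stage_params,
        base_g=base_g,
        base_sigma=base_sigma,
        subject_noise_sd=subject_noise_sd,
        subject_jitter=jitter_record,
        ach_map=None if ach_map is None else ach_map.values.copy(),
        na_map=None if na_map is None else na_map.values.copy(),
        seed=seed,
    )
    return datasets, truth
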