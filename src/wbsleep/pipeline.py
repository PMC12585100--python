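"""End-to-end workflows: empirical FC statistics and model fitting.

``empirical_workflow`` takes loaded stage datasets and produces, per
stage, subject FC matrices, the group-mean FC, nucleus-cortex FC vectors
(LC after PPN confound regression when a PPN trace is present), nodal
strengths and nodal HMA profiles, plus cross-stage paired tests and
effect sizes against wake.

``fitting_workflow`` anchors a homogeneous (G, sigma) fit on the wake FC,
then runs per-stage delta sweeps in the homogeneous / map / shuffle
modalities, selects optima, compares modalities by Cohen's D and scores
nodal integration/segregation profile similarity.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from wbsleep import __version__
from wbsleep.errors import ShapeError
from wbsleep.fc import (
    FCMatrix,
    compute_fc,
    group_mean_fc,
    lower_triangle_vector,
    nodal_strength,
    nucleus_fc,
    regress_confound,
)
from wbsleep.fitting import (
    SweepResult,
    compare_modalities,
    delta_grid,
    profile_similarity,
    run_baseline_sweep,
    run_sweep,
)
from wbsleep.hma import hma_decompose
from wbsleep.io import Connectome, RegionTable, StageDataset, STAGES, select_complete_subjects
from wbsleep.neural import SimulationConfig
from wbsleep.neuromodulation import ModulationMap, shuffle_map_hemisymmetric
from wbsleep.stats import cohens_d, paired_tests_bh


@dataclass
class RunManifest:
    """Provenance record written next to every workflow output."""

    command: str
    config: dict
    seeds: List[int]
    version: str = __version__
    input_digests: Dict[str, str] = field(default_factory=dict)
    started: float = field(default_factory=time.time)
    elapsed: float = 0.0

    def digest_array(self, name: str, arr: np.ndarray) -> None:
        self.input_digests[name] = hashlib.sha256(
            np.ascontiguousarray(arr).tobytes()
        ).hexdigest()[:16]

    def write(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.elapsed = time.time() - self.started
        with open(directory / "manifest.json", "w") as fh:
            json.dump(
                {
                    "command": self.command,
                    "config": self.config,
                    "seeds": self.seeds,
                    "version": self.version,
                    "input_digests": self.input_digests,
                    "elapsed_s": round(self.elapsed, 3),
                },
                fh,
                indent=1,
                default=str,
            )


@dataclass
class EmpiricalStageResult:
    stage: str
    subject_fcs: Dict[str, FCMatrix]
    group_fc: FCMatrix
    nodal_strength: np.ndarray  # per-subject mean strength profile
    nucleus_vectors: Dict[str, np.ndarray]  # nucleus -> subject x region
    h_in_nodal: np.ndarray
    h_se_nodal: np.ndarray


@dataclass
class EmpiricalResult:
    stages: Dict[str, EmpiricalStageResult]
    subjects: List[str]
    strength_tests: pd.DataFrame
    nucleus_tests: Dict[str, pd.DataFrame]
    nucleus_profile_correlations: pd.DataFrame


def _stage_grouped(datasets: Sequence[StageDataset], subjects: Sequence[str]):
    grouped: Dict[str, Dict[str, StageDataset]] = {s: {} for s in STAGES}
    for ds in datasets:
        if ds.subject_id in subjects and ds.subject_id not in grouped[ds.stage]:
            grouped[ds.stage][ds.subject_id] = ds
    return grouped


def empirical_workflow(
    datasets: Sequence[StageDataset],
    regions: Optional[RegionTable] = None,
    regress_ppn_from_lc: bool = True,
) -> EmpiricalResult:
    """Stage-wise FC statistics and cross-stage comparisons versus wake.

    Only subjects observed in all four stages enter the analysis.  Paired
    tests are area-paired: samples are per-region values averaged across
    subjects, compared between each sleep stage and W with
    Benjamini-Hochberg correction.
    """
    subjects = select_complete_subjects(datasets)
    if not subjects:
        raise ShapeError("no subject has data in all four stages")
    grouped = _stage_grouped(datasets, subjects)

    stage_results: Dict[str, EmpiricalStageResult] = {}
    strength_profiles: Dict[str, np.ndarray] = {}
    nucleus_profiles: Dict[str, Dict[str, np.ndarray]] = {}
    for stage in STAGES:
        per_subject = grouped[stage]
        fcs = {s: compute_fc(ds.series) for s, ds in per_subject.items()}
        group = group_mean_fc([fcs[s] for s in subjects])
        strengths = np.stack([nodal_strength(fcs[s]) for s in subjects])
        nucleus_vectors: Dict[str, np.ndarray] = {}
        names = sorted({n for ds in per_subject.values() for n in ds.nucleus_series})
        for name in names:
            vecs = []
            for s in subjects:
                ds = per_subject[s]
                if name not in ds.nucleus_series:
                    continue
                sig = ds.nucleus_series[name]
                if name == "LC" and regress_ppn_from_lc and "PPN" in ds.nucleus_series:
                    sig = regress_confound(sig, ds.nucleus_series["PPN"])
                vecs.append(nucleus_fc(sig, ds.series))
            nucleus_vectors[name] = np.stack(vecs)
        hma = hma_decompose(group)
        stage_results[stage] = EmpiricalStageResult(
            stage=stage,
            subject_fcs=fcs,
            group_fc=group,
            nodal_strength=strengths.mean(axis=0),
            nucleus_vectors=nucleus_vectors,
            h_in_nodal=hma.h_in_nodal,
            h_se_nodal=hma.h_se_nodal,
        )
        strength_profiles[stage] = strengths.mean(axis=0)
        nucleus_profiles[stage] = {k: v.mean(axis=0) for k, v in nucleus_vectors.items()}

    comparisons = [(s, "W") for s in STAGES if s != "W"]
    strength_tests = paired_tests_bh(strength_profiles, comparisons)
    nucleus_tests: Dict[str, pd.DataFrame] = {}
    for name in nucleus_profiles["W"]:
        groups = {st: nucleus_profiles[st][name] for st in STAGES if name in nucleus_profiles[st]}
        avail = [(s, "W") for s, _ in comparisons if s in groups]
        if avail:
            nucleus_tests[name] = paired_tests_bh(groups, avail)

    rows = []
    w = stage_results["W"]
    for name, vecs in w.nucleus_vectors.items():
        mean_vec = vecs.mean(axis=0)
        rows.append(
            {
                "nucleus": name,
                "r_integration": float(np.corrcoef(mean_vec, w.h_in_nodal)[0, 1]),
                "r_segregation": float(np.corrcoef(mean_vec, w.h_se_nodal)[0, 1]),
            }
        )
    profile_corr = pd.DataFrame(rows)

    return EmpiricalResult(
        stages=stage_results,
        subjects=subjects,
        strength_tests=strength_tests,
        nucleus_tests=nucleus_tests,
        nucleus_profile_correlations=profile_corr,
    )


@dataclass
class FittingResult:
    baseline: Tuple[float, float]
    baseline_sweep: Optional[SweepResult]
    sweeps: Dict[str, Dict[str, SweepResult]]  # stage -> modality -> sweep
    modality_effects: Dict[str, pd.DataFrame]
    profile_similarities: Dict[str, Dict[str, pd.DataFrame]]


def fitting_workflow(
    stage_fcs: Dict[str, FCMatrix],
    connectome: Connectome,
    maps: Tuple[ModulationMap, ModulationMap],
    sim_config: SimulationConfig,
    grid: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    n_seeds: int = 5,
    baseline: Optional[Tuple[float, float]] = None,
    baseline_grid: Optional[Tuple[np.ndarray, np.ndarray]] = None,
    baseline_seeds: Optional[int] = None,
    shuffle_seed: int = 0,
    modalities: Sequence[str] = ("homogeneous", "map", "shuffle"),
    stages: Sequence[str] = STAGES,
) -> FittingResult:
    """Wake-anchored delta sweeps across stages and modalities.

    When ``baseline`` is not given, an absolute homogeneous (G, sigma)
    sweep on the wake FC selects it first.  All stage optima are then
    expressed as offsets from that wake operating point.
    """
    if "W" not in stage_fcs:
        raise ShapeError("fitting requires a W (wake) FC to anchor the baseline")
    grid = grid if grid is not None else delta_grid()
    ach, na = maps
    baseline_sweep = None
    if baseline is None:
        if baseline_grid is None:
            baseline_grid = (np.linspace(0.0, 0.3, 11), np.linspace(1.0, 12.0, 11))
        baseline_sweep = run_baseline_sweep(
            stage_fcs["W"],
            connectome,
            baseline_grid[0],
            baseline_grid[1],
            baseline_seeds or n_seeds,
            sim_config,
        )
        baseline = baseline_sweep.optimum

    shuffled = (
        shuffle_map_hemisymmetric(ach, connectome.regions, seed=shuffle_seed),
        shuffle_map_hemisymmetric(na, connectome.regions, seed=shuffle_seed + 1),
    )
    modality_maps = {
        "homogeneous": None,
        "map": (ach, na),
        "shuffle": shuffled,
    }

    sweeps: Dict[str, Dict[str, SweepResult]] = {}
    effects: Dict[str, pd.DataFrame] = {}
    profiles: Dict[str, Dict[str, pd.DataFrame]] = {}
    for stage in stages:
        if stage not in stage_fcs:
            continue
        sweeps[stage] = {}
        profiles[stage] = {}
        for modality in modalities:
            sweep = run_sweep(
                stage_fcs[stage],
                connectome,
                modality_maps[modality],
                baseline,
                grid,
                n_seeds,
                sim_config,
                modality=modality,
            )
            sweeps[stage][modality] = sweep
            profiles[stage][modality] = profile_similarity(sweep.optimum_fcs, stage_fcs[stage])
        effects[stage] = compare_modalities(sweeps[stage])
    return FittingResult(
        baseline=tuple(baseline),
        baseline_sweep=baseline_sweep,
        sweeps=sweeps,
        modality_effects=effects,
        profile_similarities=profiles,
    )
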