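"""File formats, region metadata and empirical-data selection rules.

Matrices (connectomes, FC) travel as tab-separated square numeric text
files.  Region metadata is a tab-separated table with an explicit
``region_id`` column (0-based).  Per-subject, per-stage BOLD series are
tab-separated region x time matrices named ``<subject>_<stage>.tsv``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from wbsleep.errors import FormatError, PairingError, ShapeError

#: Closed set of vigilance stages the analysis is defined over.
STAGES = ("W", "N1", "N2", "N3")

_SYMMETRY_TOL = 1e-10


class RegionTable:
    """Parcellation metadata: labels, hemispheres and homotopic pairing.

    Parameters
    ----------
    table:
        DataFrame with columns ``label``, ``hemisphere`` (``left``/``right``),
        ``homotopic_partner`` (0-based region id) and ``is_thalamus``.
        The row position is the region id.
    """

    REQUIRED = ("label", "hemisphere", "homotopic_partner", "is_thalamus")

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in self.REQUIRED if c not in table.columns]
        if missing:
            raise FormatError(f"region table missing columns: {missing}")
        self.table = table.reset_index(drop=True)
        self._validate()

    def _validate(self) -> None:
        n = len(self.table)
        hemis = set(self.table["hemisphere"])
        if not hemis <= {"left", "right"}:
            raise FormatError(f"unknown hemisphere labels: {hemis - {'left', 'right'}}")
        partner = self.table["homotopic_partner"].to_numpy()
        for i, p in enumerate(partner):
            if p < 0 or p >= n:
                continue  # unpaired entries allowed (flagged as -1)
            if partner[p] != i:
                raise PairingError(f"homotopic pairing is not an involution at region {i}")
            if self.table.loc[i, "hemisphere"] == self.table.loc[p, "hemisphere"]:
                raise PairingError(f"regions {i} and {p} are paired within one hemisphere")

    @property
    def n(self) -> int:
        return len(self.table)

    @property
    def labels(self) -> List[str]:
        return list(self.table["label"])

    @property
    def partner(self) -> np.ndarray:
        """Homotopic partner ids (involution; -1 where unpaired)."""
        return self.table["homotopic_partner"].to_numpy().astype(int)

    @property
    def is_thalamus(self) -> np.ndarray:
        return self.table["is_thalamus"].to_numpy().astype(bool)

    @property
    def hemisphere(self) -> np.ndarray:
        return self.table["hemisphere"].to_numpy()

    def complete_pairing(self) -> bool:
        """True when every region has a valid homotopic partner."""
        p = self.partner
        return bool(np.all((p >= 0) & (p < self.n)))

    def homotopic_pairs(self) -> List[tuple]:
        """Unordered homotopic pairs as (left_id, right_id) tuples."""
        if not self.complete_pairing():
            raise PairingError("homotopic pairing is incomplete")
        pairs = []
        for i, p in enumerate(self.partner):
            if i < p:
                left, right = (i, p) if self.hemisphere[i] == "left" else (p, i)
                pairs.append((left, right))
        return pairs

    def to_tsv(self, path) -> None:
        out = self.table.copy()
        out.insert(0, "region_id", np.arange(len(out)))
        out.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "RegionTable":
        df = pd.read_csv(path, sep="\t")
        if "region_id" not in df.columns:
            raise FormatError(f"{path}: region table needs an explicit region_id column")
        df = df.sort_values("region_id").reset_index(drop=True)
        if not np.array_equal(df["region_id"].to_numpy(), np.arange(len(df))):
            raise FormatError(f"{path}: region_id must enumerate 0..N-1")
        return cls(df.drop(columns=["region_id"]))


@dataclass
class Connectome:
    """Structural connectivity: symmetric nonnegative weights with metadata."""

    weights: np.ndarray
    regions: RegionTable

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ShapeError(f"connectome weights must be square, got {w.shape}")
        if w.shape[0] != self.regions.n:
            raise ShapeError(
                f"weights are {w.shape[0]}x{w.shape[0]} but region table has {self.regions.n} rows"
            )
        if np.abs(w - w.T).max() > _SYMMETRY_TOL:
            raise ShapeError("connectome weights are not symmetric within 1e-10")
        if np.any(np.diag(w) != 0):
            raise ShapeError("connectome diagonal must be zero")
        if np.any(w < 0):
            raise ShapeError("connectome weights must be nonnegative")
        self.weights = w

    @property
    def n(self) -> int:
        return self.weights.shape[0]


@dataclass
class StageDataset:
    """One subject's BOLD recording in one vigilance stage.

    ``series`` is region x time at sampling interval ``tr`` seconds;
    ``nucleus_series`` holds optional auxiliary 1-D signals (BF, LC, PPN).
    """

    subject_id: str
    stage: str
    series: np.ndarray
    tr: float
    nucleus_series: Dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        if self.stage not in STAGES:
            raise FormatError(f"unknown stage label {self.stage!r}; expected one of {STAGES}")
        s = np.asarray(self.series, dtype=float)
        if s.ndim != 2:
            raise ShapeError("series must be a region x time matrix")
        if s.shape[1] < 2:
            raise ShapeError("series must have at least 2 time points")
        if not np.all(np.isfinite(s)):
            raise FormatError(f"{self.subject_id}/{self.stage}: series contains non-finite samples")
        if self.tr <= 0:
            raise FormatError("TR must be positive")
        self.series = s
        for name, sig in self.nucleus_series.items():
            sig = np.asarray(sig, dtype=float).ravel()
            if sig.size != s.shape[1]:
                raise ShapeError(
                    f"nucleus series {name!r} has length {sig.size}, expected {s.shape[1]}"
                )
            self.nucleus_series[name] = sig


def read_matrix(path, expected_n: Optional[int] = None) -> np.ndarray:
    """Read a tab/whitespace-separated square numeric matrix.

    Raises :class:`FormatError` naming the offending row/column when the
    file is non-square, non-numeric or does not match ``expected_n``.
    """
    rows: List[List[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.split()
            try:
                rows.append([float(x) for x in parts])
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric entry on row {lineno}: {exc}") from None
    if not rows:
        raise FormatError(f"{path}: empty matrix file")
    ncols = {len(r) for r in rows}
    if len(ncols) != 1:
        raise FormatError(f"{path}: ragged rows, column counts {sorted(ncols)}")
    mat = np.asarray(rows, dtype=float)
    if mat.shape[0] != mat.shape[1]:
        raise FormatError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, expected square")
    if expected_n is not None and mat.shape[0] != expected_n:
        raise FormatError(f"{path}: matrix is {mat.shape[0]}x{mat.shape[1]}, expected {expected_n}")
    return mat


def write_matrix(path, matrix: np.ndarray) -> None:
    """Write a 2-D array as a tab-separated text matrix (full precision)."""
    mat = np.asarray(matrix, dtype=float)
    if mat.ndim != 2:
        raise ShapeError("write_matrix expects a 2-D array")
    np.savetxt(path, mat, delimiter="\t", fmt="%.17g")


def read_timeseries(path, expected_n: Optional[int] = None) -> np.ndarray:
    """Read a (possibly rectangular) region x time tab-separated matrix."""
    mat = np.loadtxt(path, ndmin=2)
    if expected_n is not None and mat.shape[0] != expected_n:
        raise FormatError(f"{path}: {mat.shape[0]} regions, expected {expected_n}")
    return mat


def load_stage_datasets(
    directory,
    tr: float = 2.0,
    expected_n: Optional[int] = None,
) -> List[StageDataset]:
    """Load all ``<subject>_<stage>.tsv`` series found in ``directory``.

    Nucleus signals are picked up from optional sidecar files named
    ``<subject>_<stage>.nuclei.json`` mapping nucleus name -> sample list.
    """
    directory = Path(directory)
    datasets = []
    for path in sorted(directory.glob("*.tsv")):
        stem = path.stem
        if "_" not in stem:
            continue
        subject, stage = stem.rsplit("_", 1)
        if stage not in STAGES:
            continue
        series = read_timeseries(path, expected_n=expected_n)
        nuclei: Dict[str, np.ndarray] = {}
        sidecar = path.with_suffix("").with_suffix(".nuclei.json")
        if sidecar.exists():
            with open(sidecar) as fh:
                nuclei = {k: np.asarray(v, dtype=float) for k, v in json.load(fh).items()}
        datasets.append(
            StageDataset(subject_id=subject, stage=stage, series=series, tr=tr, nucleus_series=nuclei)
        )
    return datasets


def save_stage_dataset(directory, dataset: StageDataset) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    base = directory / f"{dataset.subject_id}_{dataset.stage}"
    np.savetxt(base.with_suffix(".tsv"), dataset.series, delimiter="\t", fmt="%.10g")
    if dataset.nucleus_series:
        with open(base.with_suffix(".nuclei.json"), "w") as fh:
            json.dump({k: v.tolist() for k, v in dataset.nucleus_series.items()}, fh)


def select_complete_subjects(datasets: Iterable[StageDataset]) -> List[str]:
    """Subjects with at least one dataset in every stage, in stable input order."""
    seen: Dict[str, set] = {}
    order: List[str] = []
    for ds in datasets:
        if ds.subject_id not in seen:
            seen[ds.subject_id] = set()
            order.append(ds.subject_id)
        seen[ds.subject_id].add(ds.stage)
    return [s for s in order if seen[s] >= set(STAGES)]


def concatenate_stage_volumes(segments: Sequence[np.ndarray]) -> np.ndarray:
    """Concatenate same-stage BOLD segments along time, in input order."""
    if not segments:
        raise ShapeError("no segments to concatenate")
    segs = [np.asarray(s, dtype=float) for s in segments]
    n = segs[0].shape[0]
    for k, s in enumerate(segs):
        if s.ndim != 2 or s.shape[0] != n:
            raise ShapeError(f"segment {k} has {s.shape[0] if s.ndim == 2 else '?'} regions, expected {n}")
    return np.concatenate(segs, axis=1)
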