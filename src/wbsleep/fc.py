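"""Functional connectivity matrices and the euccorrelation fit metric.

FC is the matrix of Pearson correlations between regional BOLD series.
Model fit is scored by the euccorrelation semi-metric between the strict
lower triangles of two FC matrices:

    euccorr(v1, v2) = ||v1 - v2||_2 / |rho(v1, v2)|

which is small only when the two patterns are both close in magnitude
(Euclidean term) and similar in shape (correlation term).  It is
invariant to a common reordering of regions and is minimized during
parameter sweeps.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from wbsleep.errors import DegenerateInputError, ShapeError


@dataclass
class FCMatrix:
    """Pearson correlation matrix over regions."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ShapeError("FC matrix must be square")
        if np.abs(v - v.T).max() > 1e-8:
            raise ShapeError("FC matrix must be symmetric")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]


def compute_fc(series: np.ndarray) -> FCMatrix:
    """Pairwise Pearson correlations of a region x time matrix."""
    s = np.asarray(series, dtype=float)
    if s.ndim != 2:
        raise ShapeError("series must be region x time")
    if s.shape[1] < 3:
        raise ShapeError("need at least 3 time points for correlations")
    sd = s.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateInputError(f"region {bad} has a constant series; correlation undefined")
    fc = np.corrcoef(s)
    np.fill_diagonal(fc, 1.0)
    return FCMatrix(values=fc)


def lower_triangle_vector(fc: FCMatrix) -> np.ndarray:
    """Strict lower triangle in row-major (i > j) order; length N(N-1)/2."""
    idx = np.tril_indices(fc.n, k=-1)
    return fc.values[idx]


def euccorrelation(v1: np.ndarray, v2: np.ndarray) -> float:
    """Euclidean distance divided by |Pearson correlation| (lower = better).

    Returns ``inf`` when the correlation vanishes, so argmin selection in
    sweeps simply never picks such a point.
    """
    a = np.asarray(v1, dtype=float).ravel()
    b = np.asarray(v2, dtype=float).ravel()
    if a.size != b.size:
        raise ShapeError(f"vector lengths differ: {a.size} vs {b.size}")
    if a.size < 3:
        raise ShapeError("need at least 3 entries")
    if a.std() == 0 and b.std() == 0:
        raise DegenerateInputError("both vectors constant; correlation undefined")
    if a.std() == 0 or b.std() == 0:
        return float("inf")
    dist = float(np.linalg.norm(a - b))
    if dist == 0.0:
        return 0.0
    rho = float(np.corrcoef(a, b)[0, 1])
    if abs(rho) < 1e-12:
        return float("inf")
    return dist / abs(rho)


def nodal_strength(fc: FCMatrix) -> np.ndarray:
    """Per-region sum of incoming FC values (off-diagonal row sums)."""
    return fc.values.sum(axis=1) - np.diag(fc.values)


def regress_confound(target: np.ndarray, confound: np.ndarray) -> np.ndarray:
    """OLS residual of ``target`` on ``confound`` plus intercept."""
    y = np.asarray(target, dtype=float).ravel()
    x = np.asarray(confound, dtype=float).ravel()
    if y.size != x.size:
        raise ShapeError("target and confound lengths differ")
    if x.std() == 0:
        raise DegenerateInputError("confound is constant; regression undefined")
    xc = x - x.mean()
    yc = y - y.mean()
    beta = float(xc @ yc) / float(xc @ xc)
    return yc - beta * xc


def nucleus_fc(nucleus: np.ndarray, regions_series: np.ndarray) -> np.ndarray:
    """Pearson correlation of a nucleus signal with every region's series."""
    sig = np.asarray(nucleus, dtype=float).ravel()
    s = np.asarray(regions_series, dtype=float)
    if s.ndim != 2 or s.shape[1] != sig.size:
        raise ShapeError("nucleus and region series must share time length")
    if sig.std() == 0:
        raise DegenerateInputError("nucleus signal is constant")
    sd = s.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise DegenerateInputError(f"region {bad} has a constant series")
    sig_c = (sig - sig.mean()) / sig.std()
    s_c = (s - s.mean(axis=1, keepdims=True)) / sd[:, None]
    return (s_c @ sig_c) / sig.size


def group_mean_fc(fcs: Sequence[FCMatrix], fisher: bool = False) -> FCMatrix:
    """Element-wise mean of per-subject FC matrices.

    The plain mean is the default; Fisher-z averaging is available behind
    the ``fisher`` flag.
    """
    if not fcs:
        raise ShapeError("no FC matrices to average")
    stack = np.stack([fc.values for fc in fcs])
    if fisher:
        z = np.arctanh(np.clip(stack, -0.999999, 0.999999))
        mean = np.tanh(z.mean(axis=0))
    else:
        mean = stack.mean(axis=0)
    np.fill_diagonal(mean, 1.0)
    return FCMatrix(values=mean)
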