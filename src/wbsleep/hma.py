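"""Hierarchical Modular Analysis of functional connectivity.

The FC matrix is eigendecomposed (symmetric decomposition, eigenvalues
sorted descending).  Level 1 is one module containing every region;
level i >= 2 refines the previous level by splitting each module
according to the sign of the i-th eigenvector's entries (a module whose
entries share one sign is carried forward unsplit).  With M_i modules of
sizes m_j at level i and a size-heterogeneity correction

    p_i = sum_j |m_j - N / M_i| / N,

each level contributes H_i = Lambda_i^2 M_i (1 - p_i) / N.  Global
integration is the first level, H_in = H_1 / N; segregation accumulates
the rest, H_se = sum_{i>=2} H_i / N.  Nodal components weight each level
by the squared eigenvector entries: H_in_j = H_1 u_1j^2 and
H_se_j = sum_{i>=2} H_i u_ij^2, so summing nodal components recovers the
global ones exactly (unit eigenvectors).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Set

import numpy as np

from wbsleep.errors import ShapeError

_DEGENERACY_RTOL = 1e-10


@dataclass
class HMAResult:
    eigenvalues: np.ndarray  # descending
    eigenvectors: np.ndarray  # column i = unit eigenvector of level i+1
    levels: List[List[Set[int]]]
    p: np.ndarray
    h: np.ndarray
    h_in: float
    h_se: float
    h_in_nodal: np.ndarray
    h_se_nodal: np.ndarray

    @property
    def n(self) -> int:
        return self.eigenvalues.size

    @property
    def module_counts(self) -> List[int]:
        return [len(lv) for lv in self.levels]


def _order_eigenpairs(eigvals: np.ndarray, eigvecs: np.ndarray):
    """Sort descending; inside numerically degenerate blocks order by the
    index of the largest-magnitude entry, and fix each vector's sign so
    its largest-magnitude entry is positive (ties toward the lower index).
    """
    order = np.argsort(eigvals)[::-1]
    vals = eigvals[order]
    vecs = eigvecs[:, order]
    scale = max(abs(vals[0]), 1.0) if vals.size else 1.0
    i = 0
    while i < vals.size:
        j = i + 1
        while j < vals.size and abs(vals[j] - vals[i]) <= _DEGENERACY_RTOL * scale:
            j += 1
        if j - i > 1:
            block = vecs[:, i:j]
            anchor = [int(np.argmax(np.abs(block[:, k]))) for k in range(j - i)]
            sub = np.argsort(anchor, kind="stable")
            vecs[:, i:j] = block[:, sub]
        i = j
    for k in range(vals.size):
        peak = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[peak, k] < 0:
            vecs[:, k] = -vecs[:, k]
    return vals, vecs


def hma_decompose(fc_values: np.ndarray) -> HMAResult:
    """Run the hierarchical decomposition on a symmetric FC matrix.

    Accepts a raw symmetric array or an object with a ``values``
    attribute (:class:`~wbsleep.fc.FCMatrix`).
    """
    mat = getattr(fc_values, "values", fc_values)
    mat = np.asarray(mat, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ShapeError("HMA input must be a square matrix")
    if np.abs(mat - mat.T).max() > 1e-8:
        raise ShapeError("HMA input must be symmetric")
    n = mat.shape[0]
    eigvals, eigvecs = np.linalg.eigh((mat + mat.T) / 2.0)
    eigvals, eigvecs = _order_eigenpairs(eigvals, eigvecs)

    levels: List[List[Set[int]]] = [[set(range(n))]]
    for i in range(1, n):
        u = eigvecs[:, i]
        new_level: List[Set[int]] = []
        for module in levels[-1]:
            # zero entries join the nonnegative-sign submodule (tie-break)
            pos = {j for j in module if u[j] >= 0}
            neg = module - pos
            if pos and neg:
                new_level.extend([pos, neg])
            else:
                new_level.append(set(module))
        levels.append(new_level)

    p = np.empty(n)
    h = np.empty(n)
    for i, level in enumerate(levels):
        m_i = len(level)
        sizes = np.array([len(mod) for mod in level], dtype=float)
        p[i] = np.abs(sizes - n / m_i).sum() / n
        h[i] = eigvals[i] ** 2 * m_i * (1.0 - p[i]) / n

    h_in = h[0] / n
    h_se = h[1:].sum() / n
    u_sq = eigvecs**2
    h_in_nodal = h[0] * u_sq[:, 0]
    h_se_nodal = u_sq[:, 1:] @ h[1:]
    return HMAResult(
        eigenvalues=eigvals,
        eigenvectors=eigvecs,
        levels=levels,
        p=p,
        h=h,
        h_in=float(h_in),
        h_se=float(h_se),
        h_in_nodal=h_in_nodal,
        h_se_nodal=h_se_nodal,
    )
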