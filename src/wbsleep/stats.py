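"""Statistical toolkit: Cohen's D, paired tests with BH correction, rmcorr.

Effect sizes are reported with the classical interpretation bins
(very small < 0.2 <= small < 0.5 <= medium < 0.8 <= large < 1.2 <=
very large < 2 <= huge); boundary values fall in the higher bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sst

from wbsleep.errors import DegenerateInputError, ShapeError

_BIN_EDGES = (0.2, 0.5, 0.8, 1.2, 2.0)
_BIN_NAMES = ("very small", "small", "medium", "large", "very large", "huge")


def effect_bin(d: float) -> str:
    """Interpretation bin for an effect size |d|."""
    mag = abs(d)
    for edge, name in zip(_BIN_EDGES, _BIN_NAMES):
        if mag < edge:
            return name
    return _BIN_NAMES[-1]


@dataclass
class EffectSize:
    d: float
    n1: int
    n2: int
    paired: bool
    bin: str


def cohens_d(x: Sequence[float], y: Sequence[float], paired: bool = False) -> EffectSize:
    """Cohen's D: pooled-SD standardized mean difference (x minus y).

    Paired form standardizes the mean difference by the SD of the
    differences.  The unpaired form pools variances with n-1 weights
    (classical Cohen form, not Hedges' g).
    """
    a = np.asarray(x, dtype=float).ravel()
    b = np.asarray(y, dtype=float).ravel()
    if a.size < 2 or b.size < 2:
        raise ShapeError("need at least 2 observations per sample")
    if paired:
        if a.size != b.size:
            raise ShapeError("paired samples must have equal lengths")
        diff = a - b
        sd = diff.std(ddof=1)
        if sd == 0:
            d = 0.0 if diff.mean() == 0 else np.inf * np.sign(diff.mean())
            if not np.isfinite(d):
                raise DegenerateInputError("zero SD of differences with nonzero mean")
        else:
            d = diff.mean() / sd
    else:
        va = a.var(ddof=1)
        vb = b.var(ddof=1)
        pooled = np.sqrt(((a.size - 1) * va + (b.size - 1) * vb) / (a.size + b.size - 2))
        if pooled == 0:
            if a.mean() == b.mean():
                d = 0.0
            else:
                raise DegenerateInputError("zero pooled SD with differing means")
        else:
            d = (a.mean() - b.mean()) / pooled
    d = float(d)
    return EffectSize(d=d, n1=a.size, n2=b.size, paired=paired, bin=effect_bin(d))


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """BH step-up adjusted p-values: min over j >= i of m p_(j) / j."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    return multipletests(p, method="fdr_bh")[1]


def paired_tests_bh(
    groups: Dict[str, np.ndarray],
    comparisons: Sequence[Tuple[str, str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided paired t-tests with Benjamini-Hochberg correction.

    ``groups`` maps condition name -> matched sample vector.  Returns one
    row per comparison with (t, p_raw, p_adj, d, bin, significant).
    """
    if len(comparisons) < 1:
        raise ShapeError("no comparisons requested")
    rows: List[dict] = []
    for a, b in comparisons:
        xa = np.asarray(groups[a], dtype=float)
        xb = np.asarray(groups[b], dtype=float)
        if xa.size != xb.size:
            raise ShapeError(f"{a} and {b} samples are not matched in length")
        if xa.size < 2:
            raise ShapeError("need at least 2 matched pairs")
        if np.allclose(xa, xb):
            t, p = 0.0, 1.0
        else:
            t, p = sst.ttest_rel(xa, xb)
        eff = cohens_d(xa, xb, paired=True)
        rows.append(
            {"comparison": f"{a}-{b}", "t": float(t), "p_raw": float(p), "d": eff.d, "bin": eff.bin}
        )
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table


def rmcorr(
    subject_ids: Sequence,
    x: Sequence[float],
    y: Sequence[float],
) -> Tuple[float, int, float]:
    """Repeated-measures correlation (common within-subject association).

    ANCOVA formulation: subject-specific intercepts, one shared slope.
    Subjects whose x (or y) is constant contribute no within-subject
    variation and are dropped with a warning.  Returns (r_rm, dof, p)
    with dof = N_obs - N_subjects - 1.
    """
    sid = np.asarray(subject_ids)
    xv = np.asarray(x, dtype=float).ravel()
    yv = np.asarray(y, dtype=float).ravel()
    if not (sid.size == xv.size == yv.size):
        raise ShapeError("subject_ids, x and y must have equal lengths")
    keep = np.ones(sid.size, dtype=bool)
    for s in pd.unique(sid):
        m = sid == s
        if m.sum() < 2 or xv[m].std() == 0 or yv[m].std() == 0:
            warnings.warn(f"subject {s!r} dropped from rmcorr (constant or singleton)")
            keep &= ~m
    sid, xv, yv = sid[keep], xv[keep], yv[keep]
    subjects = pd.unique(sid)
    if subjects.size < 2:
        raise DegenerateInputError("rmcorr needs at least 2 usable subjects")
    # Within-subject centering is the shared-slope, subject-intercept
    # ANCOVA: the correlation of the centered variables is r_rm.
    xc = xv.copy()
    yc = yv.copy()
    for s in subjects:
        m = sid == s
        xc[m] -= xv[m].mean()
        yc[m] -= yv[m].mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0 or syy == 0:
        raise DegenerateInputError("no within-subject variation left")
    r = float(xc @ yc / np.sqrt(sxx * syy))
    dof = int(xv.size - subjects.size - 1)
    if abs(r) >= 1.0 - 1e-15:
        p = 0.0
    else:
        t = r * np.sqrt(dof / (1.0 - r * r))
        p = float(2 * sst.t.sf(abs(t), dof))
    return r, dof, p
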