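"""Neuromodulatory maps: normalization, parameter fields, surrogates.

A modulation map is a positive per-region weight vector with mean 1 (after
normalization) describing where a neuromodulator acts: the cholinergic
(ACh) map scales changes of the long-range coupling G, the noradrenergic
(NA) map scales changes of the excitatory sigmoid slope sigma.  Regional
parameter fields follow

    G_i     = G     + deltaG     * ACh_i
    sigma_i = sigma + delta_sigma * NA_i

Lower cholinergic tone is modelled as HIGHER coupling (deltaG > 0) and
lower noradrenergic tone as a shallower slope (delta_sigma < 0), so the
coupling axis reads "flipped" relative to ACh tone.

Hemisphere-symmetric surrogate maps are produced by permuting homotopic
value pairs with one permutation applied identically to both hemispheres,
which preserves the value multiset, the per-hemisphere means, and the
map's correlation structure with a homotopically symmetric connectome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from wbsleep.errors import FormatError, PairingError, ParameterRangeError, ShapeError
from wbsleep.io import RegionTable

_MEAN_TOL = 1e-10


@dataclass
class ModulationMap:
    """Per-region positive weights for one neuromodulator."""

    values: np.ndarray
    kind: str = "ACh"  # {ACh, NA, surrogate}
    normalized: bool = False

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float).ravel()
        if np.any(v <= 0):
            raise ParameterRangeError("modulation map values must be positive")
        if self.normalized and abs(v.mean() - 1.0) > _MEAN_TOL:
            raise ParameterRangeError("map marked normalized but mean differs from 1")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.size

    def to_tsv(self, path, seed: Optional[int] = None) -> None:
        df = pd.DataFrame({"region_id": np.arange(self.n), "value": self.values})
        df.to_csv(path, sep="\t", index=False)
        if seed is not None:
            sidecar = Path(path).with_suffix(".json")
            with open(sidecar, "w") as fh:
                json.dump({"kind": self.kind, "shuffle_seed": seed}, fh)

    @classmethod
    def from_tsv(cls, path, kind: str = "ACh") -> "ModulationMap":
        df = pd.read_csv(path, sep="\t")
        if not {"region_id", "value"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns region_id, value")
        df = df.sort_values("region_id")
        values = df["value"].to_numpy(dtype=float)
        normalized = abs(values.mean() - 1.0) <= _MEAN_TOL
        return cls(values=values, kind=kind, normalized=normalized)


def normalize_map(
    raw: np.ndarray,
    regions: RegionTable,
    deescalate_thalamus: bool = False,
    kind: str = "ACh",
) -> ModulationMap:
    """Mean-1 normalization, optionally de-escalating thalamic outliers.

    With ``deescalate_thalamus``, thalamic entries are clipped to the
    maximum over non-thalamic regions before dividing by the mean; this
    keeps a single dominating structure (e.g. dense subcortical
    projections) from compressing the map everywhere else.
    """
    v = np.asarray(raw, dtype=float).ravel().copy()
    if v.size != regions.n:
        raise ShapeError(f"map has {v.size} entries, region table has {regions.n}")
    if np.any(v <= 0):
        raise ParameterRangeError("raw map values must be positive")
    if deescalate_thalamus:
        thal = regions.is_thalamus
        if thal.any() and (~thal).any():
            cap = v[~thal].max()
            v[thal] = np.minimum(v[thal], cap)
    v = v / v.mean()
    # guard against accumulated rounding: renormalize once more
    v = v / v.mean()
    return ModulationMap(values=v, kind=kind, normalized=True)


def apply_modulation(
    g: float,
    sigma: float,
    delta_g: float,
    delta_sigma: float,
    ach: Optional[ModulationMap] = None,
    na: Optional[ModulationMap] = None,
    n: Optional[int] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Regional (G_i, sigma_E,i) fields from baseline values and deltas.

    ``None`` maps mean homogeneous modulation (map identically 1).  Raises
    :class:`ParameterRangeError` when any resulting slope is nonpositive
    or any coupling negative - sweeps record such grid points as
    infeasible rather than clamping them.
    """
    if ach is None and na is None and n is None:
        raise ShapeError("need at least one map or an explicit region count n")
    if ach is not None and not ach.normalized:
        raise ParameterRangeError("ACh map must be normalized (mean 1)")
    if na is not None and not na.normalized:
        raise ParameterRangeError("NA map must be normalized (mean 1)")
    if ach is not None and na is not None and ach.n != na.n:
        raise ShapeError("ACh and NA maps have different lengths")
    size = n or (ach.n if ach is not None else na.n)
    ach_v = np.ones(size) if ach is None else ach.values
    na_v = np.ones(size) if na is None else na.values
    if ach_v.size != size or na_v.size != size:
        raise ShapeError("map length does not match requested region count")
    g_i = g + delta_g * ach_v
    sigma_i = sigma + delta_sigma * na_v
    if np.any(sigma_i <= 0):
        raise ParameterRangeError(
            f"delta_sigma={delta_sigma} drives sigma_E nonpositive (min {sigma_i.min():.4f})"
        )
    if np.any(g_i < 0):
        raise ParameterRangeError(
            f"delta_g={delta_g} drives coupling negative (min {g_i.min():.4f})"
        )
    return g_i, sigma_i


def shuffle_map_hemisymmetric(
    mod_map: ModulationMap,
    regions: RegionTable,
    seed: int,
    joint: bool = True,
) -> ModulationMap:
    """Surrogate map by permuting homotopic value pairs.

    With ``joint`` (default), one permutation of the N/2 pairs is applied
    identically in both hemispheres, preserving homotopic correspondence;
    with ``joint=False`` each hemisphere is permuted independently.
    Either way the value multiset and both per-hemisphere means are
    conserved exactly.
    """
    if mod_map.n != regions.n:
        raise ShapeError("map length does not match region table")
    if not regions.complete_pairing():
        raise PairingError("hemisphere-symmetric shuffling needs complete homotopic pairing")
    pairs = regions.homotopic_pairs()
    left = np.array([p[0] for p in pairs])
    right = np.array([p[1] for p in pairs])
    rng = np.random.default_rng(seed)
    out = mod_map.values.copy()
    if joint:
        perm = rng.permutation(len(pairs))
        out[left] = mod_map.values[left][perm]
        out[right] = mod_map.values[right][perm]
    else:
        out[left] = mod_map.values[left][rng.permutation(len(pairs))]
        out[right] = mod_map.values[right][rng.permutation(len(pairs))]
    return ModulationMap(values=out, kind="surrogate", normalized=mod_map.normalized)
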