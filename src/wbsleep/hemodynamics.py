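"""Balloon-Windkessel hemodynamics and BOLD post-processing.

Excitatory activity drives a vasodilatory signal s, inflow f, venous
volume v and deoxyhemoglobin content q per region:

    ds/dt = E - s/tau_s - (f - 1)/tau_f
    df/dt = s
    tau_v dv/dt = f - v^(1/kappa)
    tau_q dq/dt = f (1 - (1 - E0)^(1/f)) / E0 - q v^(1/kappa) / v

with BOLD readout B = V0 [k1 (1 - q) + k2 (1 - q/v) + k3 (1 - v)].
kappa is the Grubb-exponent stiffness parameter.  The raw BOLD series is
band-passed (2nd-order Bessel, zero-phase by default) and decimated to
the fMRI repetition time TR.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np
from scipy import signal as sps

from wbsleep._kernels import balloon_windkessel_euler
from wbsleep.errors import IntegrationDivergedError, ParameterRangeError, ShapeError


@dataclass
class HemodynamicConfig:
    """Balloon-Windkessel constants (seconds / dimensionless)."""

    tau_s: float = 0.65
    tau_f: float = 0.41
    tau_v: float = 0.98
    tau_q: float = 0.98
    kappa: float = 0.32
    e0: float = 0.4
    v0: float = 0.04
    k1: float = 2.77
    k2: float = 0.2
    k3: float = 0.5
    dt: float = 1e-3

    def __post_init__(self):
        for name in ("tau_s", "tau_f", "tau_v", "tau_q", "kappa", "dt", "k1", "k2", "k3"):
            if getattr(self, name) <= 0:
                raise ParameterRangeError(f"{name} must be positive")
        if not (0 < self.e0 < 1) or not (0 < self.v0 < 1):
            raise ParameterRangeError("e0 and v0 must lie in (0, 1)")


@dataclass
class BoldSeries:
    """A region x time BOLD matrix with its sampling interval."""

    values: np.ndarray
    sampling_interval: float
    filtered: bool = False
    band: Tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ShapeError("BOLD values must be region x time")
        if self.sampling_interval <= 0:
            raise ParameterRangeError("sampling interval must be positive")
        self.values = v


def balloon_windkessel(e_series: np.ndarray, config: HemodynamicConfig = None) -> BoldSeries:
    """Integrate the hemodynamic model over a region x time drive series.

    ``e_series`` is assumed sampled at ``config.dt`` seconds.  Initial
    conditions are the rest fixed point (s=0, f=v=q=1), so zero drive
    yields identically zero BOLD.
    """
    config = config or HemodynamicConfig()
    e_series = np.asarray(e_series, dtype=float)
    if e_series.ndim != 2:
        raise ShapeError("e_series must be region x time")
    if not np.all(np.isfinite(e_series)):
        raise IntegrationDivergedError("non-finite neural drive passed to hemodynamics")
    bold, bad_region, bad_step = balloon_windkessel_euler(
        e_series,
        config.dt,
        config.tau_s,
        config.tau_f,
        config.tau_v,
        config.tau_q,
        config.kappa,
        config.e0,
        config.v0,
        config.k1,
        config.k2,
        config.k3,
    )
    if bad_region >= 0:
        raise IntegrationDivergedError(
            f"hemodynamic state inadmissible at region {bad_region}, "
            f"t={bad_step * config.dt:.2f} s"
        )
    return BoldSeries(values=bold, sampling_interval=config.dt)


def steady_state(drive: float, config: HemodynamicConfig = None) -> Tuple[float, float, float, float, float]:
    """Algebraic fixed point (s, f, v, q, B) for a constant drive level.

    Setting the derivatives to zero gives s = 0, f = 1 + tau_f * drive,
    v = f^kappa, q = f (1 - (1-E0)^(1/f)) / E0 * v / v^(1/kappa).
    """
    config = config or HemodynamicConfig()
    s = 0.0
    f = 1.0 + config.tau_f * drive
    if f <= 0:
        raise ParameterRangeError("steady-state inflow must be positive")
    v = f ** config.kappa
    q = f * (1.0 - (1.0 - config.e0) ** (1.0 / f)) / config.e0 * v / (v ** (1.0 / config.kappa))
    b = config.v0 * (config.k1 * (1.0 - q) + config.k2 * (1.0 - q / v) + config.k3 * (1.0 - v))
    return s, f, v, q, b


def bold_postprocess(
    bold: BoldSeries,
    band: Tuple[float, float] = (0.01, 0.1),
    tr: float = 2.0,
    zero_phase: bool = True,
    detrend: bool = True,
    discard: float = 0.0,
) -> BoldSeries:
    """Band-pass the BOLD series and decimate to the repetition time.

    A 2nd-order Bessel band-pass is designed at the native sampling rate
    and applied forward-backward (zero-phase) by default; decimation then
    keeps every TR-th sample.  ``discard`` drops an initial stretch (in
    seconds) before filtering, removing the hemodynamic start-up
    transient.  ``detrend`` removes a per-region linear trend first, which
    suppresses slow drifts that would otherwise leak through the band
    edge.
    """
    fs = 1.0 / bold.sampling_interval
    low, high = band
    if fs <= 2 * high:
        raise ParameterRangeError(f"sampling rate {fs} Hz too low for band edge {high} Hz")
    values = bold.values
    if discard > 0:
        n_drop = int(round(discard / bold.sampling_interval))
        if n_drop >= values.shape[1]:
            raise ShapeError("discard window longer than the series")
        values = values[:, n_drop:]
    min_len = int(3.0 / low * fs)  # three periods of the slowest passband component
    if values.shape[1] < min_len // 10:
        raise ShapeError(
            f"series of {values.shape[1]} samples too short to band-pass at {low} Hz"
        )
    if detrend:
        values = sps.detrend(values, axis=1, type="linear")
    sos = sps.bessel(2, [low, high], btype="bandpass", fs=fs, output="sos")
    if zero_phase:
        filtered = sps.sosfiltfilt(sos, values, axis=1)
    else:
        filtered = sps.sosfilt(sos, values, axis=1)
    step = max(1, int(round(tr / bold.sampling_interval)))
    decimated = np.ascontiguousarray(filtered[:, ::step])
    return BoldSeries(
        values=decimated,
        sampling_interval=step * bold.sampling_interval,
        filtered=True,
        band=band,
    )
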