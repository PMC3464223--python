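"""Synthetic stimulus generators: current steps and Ornstein-Uhlenbeck noise.

The fluctuating stimulus used throughout is an Ornstein-Uhlenbeck (OU)
process: Gaussian colored noise with exponential autocorrelation of time
constant ``tau`` (default 300 ms), a stated mean and standard deviation in
pA.  All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Trace

__all__ = ["OUParams", "ou_process", "step_current", "staircase_ou"]


@dataclass(frozen=True)
class OUParams:
    """Parameters of a stationary OU current (pA)."""

    mean: float
    std: float
    duration: float
    dt: float
    tau: float = 300.0
    seed: int = 0

    def __post_init__(self):
        if self.std < 0:
            raise ValueError("std must be >= 0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.duration < self.dt:
            raise ValueError("duration must be at least one time step")


def ou_process(params: OUParams, euler: bool = False) -> Trace:
    """Stationary OU trace with the stated mean, std and correlation time.

    The default update is the exact discretization

        x <- mu + (x - mu) * e^{-dt/tau} + std * sqrt(1 - e^{-2 dt/tau}) * xi

    which has no time-step bias; ``euler=True`` uses the literal first-order
    update ``x <- x + (mu - x) dt/tau + std sqrt(2 dt/tau) xi`` instead.
    The process starts at the mean and is reproducible for a fixed seed.
    """
    n = int(round(params.duration / params.dt))
    rng = np.random.default_rng(params.seed)
    xi = rng.standard_normal(n - 1) if n > 1 else np.empty(0)
    x = np.empty(n)
    x[0] = params.mean
    if params.std == 0 or n == 1:
        x[:] = params.mean
        return Trace(params.dt, x, unit="pA")
    if euler:
        a = params.dt / params.tau
        noise = params.std * np.sqrt(2 * params.dt / params.tau) * xi
        cur = params.mean
        drift = a * params.mean
        from scipy.signal import lfilter

        # x[n] = (1-a) x[n-1] + drift + noise[n-1]
        inp = drift + noise
        x[1:] = lfilter([1.0], [1.0, -(1 - a)], inp, zi=[(1 - a) * cur])[0]
    else:
        decay = np.exp(-params.dt / params.tau)
        noise = params.std * np.sqrt(-np.expm1(-2 * params.dt / params.tau)) * xi
        from scipy.signal import lfilter

        # deviation from the mean follows d[n] = decay*d[n-1] + noise[n-1]
        d = lfilter([1.0], [1.0, -decay], noise, zi=[0.0])[0]
        x[1:] = params.mean + d
    return Trace(params.dt, x, unit="pA")


def step_current(
    baseline: float,
    amplitude: float,
    t_on: float,
    duration: float,
    dt: float,
) -> Trace:
    """Step current: ``baseline`` before ``t_on``, ``baseline+amplitude`` from
    ``t_on`` on (half-open convention: the bin containing t_on is stepped)."""
    if not (0 <= t_on <= duration):
        raise ValueError("t_on must lie in [0, duration]")
    n = int(round(duration / dt))
    vals = np.full(n, float(baseline))
    n_on = int(round(t_on / dt))
    vals[n_on:] += amplitude
    return Trace(dt, vals, unit="pA")


def staircase_ou(
    mean: float,
    stds,
    segment_ms: float,
    dt: float,
    tau: float = 300.0,
    seed: int = 0,
) -> Trace:
    """OU current whose standard deviation steps through ``stds`` every
    ``segment_ms`` while one continuous unit-variance OU path is shared
    across segments (each segment rescales the same path).
    """
    stds = [float(s) for s in stds]
    if not stds:
        raise ValueError("stds must be non-empty")
    if len(stds) == 1:
        return ou_process(
            OUParams(mean=mean, std=stds[0], duration=segment_ms, dt=dt, tau=tau, seed=seed)
        )
    total = segment_ms * len(stds)
    base = ou_process(
        OUParams(mean=0.0, std=1.0, duration=total, dt=dt, tau=tau, seed=seed)
    )
    n_seg = int(round(segment_ms / dt))
    scale = np.repeat(stds, n_seg)[: len(base)]
    if scale.size < len(base):
        scale = np.concatenate([scale, np.full(len(base) - scale.size, stds[-1])])
    return base.with_values(mean + scale * base.values, unit="pA")
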