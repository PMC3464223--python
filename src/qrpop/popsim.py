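"""Direct stochastic simulation of a population of independent SRM neurons.

This is the ground truth against which every population-activity theory is
validated.  Time is discretized in bins of ``dt``; in each bin a neuron with
conditional intensity ``lambda`` spikes with probability ``1 - exp(-lambda*dt)``
(the exact probability of at least one event of an inhomogeneous Poisson
process over the bin).  Each spike adds one term per SAP exponential to the
neuron's log-hazard, maintained by an O(1)-per-term recursive state; the
spike's effect on the hazard starts in the bin after emission, so two spikes
of the same neuron cannot interact within one bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter1d

from .model import NeuronModel, SpikeRaster, Trace, filtered_input

__all__ = ["SimResult", "simulate_population", "psth", "isi_statistics", "smooth_trace"]

DT_SUPPORTED = (0.005, 0.5)  # ms; simulation is first-order in dt outside this


@dataclass
class SimResult:
    """Raster plus the smoothed population activity (PSTH) of one run."""

    raster: SpikeRaster
    activity: Trace  # kHz, smoothed PSTH
    counts: np.ndarray  # raw spike counts per bin (all neurons)
    dt: float
    n_neurons: int
    seed: int
    window: float  # PSTH smoothing window, ms


def simulate_population(
    model: NeuronModel,
    current: Trace | None = None,
    n_neurons: int = 25_000,
    seed: int = 0,
    h: Trace | None = None,
    window: float = 2.0,
    record_spikes: bool = True,
) -> SimResult:
    """Simulate ``n_neurons`` independent SRM neurons driven by one stimulus.

    Either the raw current (filtered through ``model.kappa``) or a
    precomputed filtered input ``h`` must be given.  One seeded generator
    drives the whole population with a fixed per-neuron draw order, so a
    fixed seed yields a bit-identical raster regardless of platform.
    """
    if (current is None) == (h is None):
        raise ValueError("provide exactly one of current or h")
    if h is None:
        h = filtered_input(current, model.kappa)
    dt = h.dt
    if not (DT_SUPPORTED[0] <= dt <= DT_SUPPORTED[1]):
        warnings.warn(
            f"dt={dt} ms outside the supported range {DT_SUPPORTED}; "
            "discretization bias may be significant",
            stacklevel=2,
        )
    if n_neurons < 1:
        raise ValueError("n_neurons must be >= 1")
    n_bins = len(h)
    if n_neurons * n_bins > 5e10:
        raise ValueError("n_neurons * n_bins too large")

    rng = np.random.default_rng(seed)
    amps = model.eta.amplitudes
    decays = np.exp(-dt / model.eta.taus)
    g = np.zeros((n_neurons, amps.size))
    block_bins = int(np.floor(model.absolute_block / dt + 1e-9))
    age = np.full(n_neurons, np.iinfo(np.int64).max // 2, dtype=np.int64) if block_bins else None

    counts = np.zeros(n_bins, dtype=np.int64)
    spike_neurons: list[np.ndarray] = []
    spike_bins: list[np.ndarray] = []
    hv = h.values
    lam0 = model.lambda0
    for i in range(n_bins):
        if amps.size:
            g *= decays
            u = hv[i] + g.sum(axis=1)
        else:
            u = np.full(n_neurons, hv[i])
        lam = lam0 * np.exp(u)
        if age is not None:
            age += 1
            lam[age <= block_bins] = 0.0
        p = -np.expm1(-lam * dt)
        fired = rng.random(n_neurons) < p
        idx = np.nonzero(fired)[0]
        counts[i] = idx.size
        if idx.size:
            if amps.size:
                g[idx] += amps
            if age is not None:
                age[idx] = 0
            if record_spikes:
                spike_neurons.append(idx)
                spike_bins.append(np.full(idx.size, i, dtype=np.int64))

    duration = n_bins * dt
    if record_spikes and spike_neurons:
        neurons = np.concatenate(spike_neurons)
        times = h.t0 + dt * np.concatenate(spike_bins).astype(float)
    else:
        neurons = np.empty(0, dtype=np.int64)
        times = np.empty(0)
    raster = SpikeRaster(n_neurons=n_neurons, neurons=neurons, times=times, duration=duration)
    activity = Trace(
        dt,
        smooth(counts / (n_neurons * dt), dt, window),
        h.t0,
        unit="kHz",
    )
    return SimResult(
        raster=raster,
        activity=activity,
        counts=counts,
        dt=dt,
        n_neurons=n_neurons,
        seed=seed,
        window=window,
    )


def smooth(values: np.ndarray, dt: float, window: float) -> np.ndarray:
    """Centered moving average of width ``window`` ms (zero-padded ends)."""
    size = max(1, int(round(window / dt)))
    vals = np.asarray(values, dtype=float)
    if size == 1:
        return vals.copy()
    out = uniform_filter1d(vals, size, mode="constant", cval=0.0)
    if vals.min() >= 0.0:
        np.clip(out, 0.0, None, out=out)  # guard fp round-off below zero
    return out


def smooth_trace(trace: Trace, window: float) -> Trace:
    return trace.with_values(smooth(trace.values, trace.dt, window))


def psth(raster: SpikeRaster, dt: float, window: float = 2.0, t0: float = 0.0) -> Trace:
    """Population activity estimate: bin counts / (N*dt), then a centered
    moving average of width ``window``.  An empty raster gives a zero trace."""
    if window < dt:
        raise ValueError("window must be at least dt")
    n_bins = int(round((raster.duration - t0) / dt))
    counts, _ = np.histogram(
        raster.times, bins=n_bins, range=(t0, t0 + n_bins * dt)
    )
    a = counts / (raster.n_neurons * dt)
    return Trace(dt, smooth(a, dt, window), t0, unit="kHz")


@dataclass
class ISIStatistics:
    """Adaptation summary: first vs last interspike interval after ``t_split``."""

    mean_first: float
    mean_last: float
    sem_first: float
    sem_last: float
    n_neurons_used: int
    n_neurons_excluded: int
    hist_edges: np.ndarray
    hist_density: np.ndarray
    all_isis: np.ndarray


def isi_statistics(
    raster: SpikeRaster,
    t_split: float = 0.0,
    bin_ms: float = 10.0,
    max_isi: float | None = None,
) -> ISIStatistics:
    """Per-neuron first/last ISIs after ``t_split`` (adaptation makes the last
    interval longer than the first), plus the pooled ISI histogram."""
    if raster.n_spikes == 0:
        raise ValueError("raster is empty")
    firsts, lasts, pooled = [], [], []
    excluded = 0
    for train in raster.spike_trains():
        train = train[train >= t_split]
        if train.size < 2:
            excluded += 1
            continue
        isis = np.diff(train)
        firsts.append(isis[0])
        lasts.append(isis[-1])
        pooled.append(isis)
    if not firsts:
        raise ValueError("no neuron has two spikes after t_split")
    firsts = np.array(firsts)
    lasts = np.array(lasts)
    pooled = np.concatenate(pooled)
    if max_isi is None:
        max_isi = float(pooled.max())
    edges = np.arange(0.0, max_isi + bin_ms, bin_ms)
    density, _ = np.histogram(pooled, bins=edges, density=True)
    return ISIStatistics(
        mean_first=float(firsts.mean()),
        mean_last=float(lasts.mean()),
        sem_first=float(firsts.std(ddof=1) / np.sqrt(firsts.size)) if firsts.size > 1 else 0.0,
        sem_last=float(lasts.std(ddof=1) / np.sqrt(lasts.size)) if lasts.size > 1 else 0.0,
        n_neurons_used=int(firsts.size),
        n_neurons_excluded=int(excluded),
        hist_edges=edges,
        hist_density=density,
        all_isis=pooled,
    )
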