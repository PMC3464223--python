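"""Plain-text readers/writers: traces as two-column CSV (``time_ms,value``),
rasters as ``neuron,spike_time_ms``.  Comma separated, '.' decimal, one
header line."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .model import SpikeRaster, Trace

__all__ = ["write_trace", "read_trace", "write_raster", "read_raster"]


def write_trace(trace: Trace, path, value_name: str = "value") -> None:
    pd.DataFrame({"time_ms": trace.times, value_name: trace.values}).to_csv(
        path, index=False
    )


def read_trace(path, unit: str = "") -> Trace:
    df = pd.read_csv(path)
    t = df.iloc[:, 0].to_numpy(dtype=float)
    if t.size < 2:
        raise ValueError("trace file needs at least two samples")
    dts = np.diff(t)
    dt = float(dts[0])
    if not np.allclose(dts, dt, rtol=1e-6, atol=1e-9):
        raise ValueError("trace is not uniformly sampled")
    return Trace(dt, df.iloc[:, 1].to_numpy(dtype=float), t0=float(t[0]), unit=unit)


def write_raster(raster: SpikeRaster, path) -> None:
    pd.DataFrame({"neuron": raster.neurons, "spike_time_ms": raster.times}).to_csv(
        path, index=False
    )


def read_raster(path, n_neurons: int | None = None, duration: float | None = None) -> SpikeRaster:
    df = pd.read_csv(path)
    neurons = df.iloc[:, 0].to_numpy(dtype=np.int64)
    times = df.iloc[:, 1].to_numpy(dtype=float)
    if n_neurons is None:
        n_neurons = int(neurons.max()) + 1 if neurons.size else 0
    if duration is None:
        duration = float(times.max()) if times.size else 0.0
    return SpikeRaster(n_neurons=n_neurons, neurons=neurons, times=times, duration=duration)


def write_decode_result(result, path) -> None:
    """CSV with columns time_ms, h_hat, valid, upper_bound."""
    pd.DataFrame(
        {
            "time_ms": result.h_hat.times,
            "h_hat": result.h_hat.values,
            "valid": result.valid.astype(int),
            "upper_bound": result.upper_bounds,
        }
    ).to_csv(path, index=False)
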