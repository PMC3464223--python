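"""Domain types of the spike response model (SRM) population framework.

The single neuron is a generalized linear point-process model: its
conditional firing intensity given the input current I and its own past
spikes {t_i} is

    lambda(t | history) = lambda0 * exp( h(t) + sum_i eta(t - t_i) )

where ``h = kappa * I`` is the input current filtered by the membrane
kernel ``kappa`` (dimensionless), ``eta`` is the effective spike
after-potential (SAP) and ``lambda0`` (kHz) is the baseline excitability.
Negative SAP amplitudes produce refractoriness (short time constant) and
spike-frequency adaptation (long time constant).

Units: time in ms, rates in kHz, currents in pA.  Population activity is
reported in kHz internally (multiply by 1000 for Hz).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

from .kernels import ExpKernelSum, kernel_from_dicts

__all__ = [
    "Trace",
    "NeuronModel",
    "SpikeRaster",
    "filtered_input",
    "conditional_intensity",
]


@dataclass
class Trace:
    """Uniformly sampled time series (stimulus, filtered input or activity).

    ``values[n]`` is the value on the bin starting at ``t0 + n*dt``.
    """

    dt: float
    values: np.ndarray
    t0: float = 0.0
    unit: str = ""

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("values must be a non-empty 1-d sequence")

    @property
    def times(self) -> np.ndarray:
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def duration(self) -> float:
        return self.dt * self.values.size

    def __len__(self) -> int:
        return self.values.size

    def with_values(self, values, unit: str | None = None) -> "Trace":
        return Trace(self.dt, np.asarray(values, dtype=float), self.t0,
                     self.unit if unit is None else unit)

    def same_grid(self, other: "Trace", tol: float = 1e-9) -> bool:
        return (
            abs(self.dt - other.dt) < tol
            and abs(self.t0 - other.t0) < tol
            and len(self) == len(other)
        )


@dataclass
class SpikeRaster:
    """Spike times of a simulated population.

    ``neurons`` and ``times`` are parallel arrays: spike k was emitted by
    ``neurons[k]`` at ``times[k]`` (ms).  Per-neuron spike times are strictly
    increasing.
    """

    n_neurons: int
    neurons: np.ndarray
    times: np.ndarray
    duration: float

    def __post_init__(self):
        self.neurons = np.asarray(self.neurons, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        if self.neurons.shape != self.times.shape:
            raise ValueError("neurons and times must be parallel arrays")
        if self.neurons.size:
            if self.neurons.min() < 0 or self.neurons.max() >= self.n_neurons:
                raise ValueError("neuron index out of range")
            if self.times.min() < 0 or self.times.max() > self.duration:
                raise ValueError("spike time outside [0, duration]")

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def spike_trains(self) -> list[np.ndarray]:
        """Per-neuron sorted spike-time arrays."""
        order = np.lexsort((self.times, self.neurons))
        neu = self.neurons[order]
        tim = self.times[order]
        bounds = np.searchsorted(neu, np.arange(self.n_neurons + 1))
        return [tim[bounds[i]:bounds[i + 1]] for i in range(self.n_neurons)]


@dataclass(frozen=True)
class NeuronModel:
    """SRM neuron: baseline rate, membrane filter and spike after-potential."""

    lambda0: float  # kHz
    kappa: ExpKernelSum  # 1/(pA*ms) amplitudes; maps pA -> dimensionless
    eta: ExpKernelSum  # dimensionless SAP

    def __post_init__(self):
        if self.lambda0 <= 0:
            raise ValueError("lambda0 must be positive")

    @property
    def absolute_block(self) -> float:
        return self.eta.absolute_block

    def h_infinity(self, current_pa: float) -> float:
        """Steady-state filtered input for a constant current (``I * int kappa``)."""
        return float(current_pa) * self.kappa.integral()

    def with_eta_scaled(self, factor: float) -> "NeuronModel":
        return replace(self, eta=self.eta.scaled(factor))

    # ---- config round trip ------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "lambda0_khz": self.lambda0,
            "kappa": [{"amp": a, "tau_ms": tau} for a, tau in self.kappa.terms],
            "eta": [{"amp": a, "tau_ms": tau} for a, tau in self.eta.terms],
            "abs_refractory_ms": self.eta.absolute_block,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NeuronModel":
        return cls(
            lambda0=float(d["lambda0_khz"]),
            kappa=kernel_from_dicts(d["kappa"]),
            eta=kernel_from_dicts(d["eta"], absolute_block=d.get("abs_refractory_ms", 0.0)),
        )

    def save(self, path) -> None:
        path = Path(path)
        text = (
            json.dumps(self.to_dict(), indent=2)
            if path.suffix == ".json"
            else yaml.safe_dump(self.to_dict())
        )
        path.write_text(text)

    @classmethod
    def load(cls, path) -> "NeuronModel":
        path = Path(path)
        text = path.read_text()
        d = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls.from_dict(d)


def filtered_input(current: Trace, kappa: ExpKernelSum, dt: float | None = None) -> Trace:
    """Filtered input ``h = kappa * I`` computed causally.

    For a sum-of-exponentials ``kappa`` each term obeys a scalar linear ODE,
    so the convolution is advanced by the exact exponential-integrator
    recursion for piecewise-constant input (zero-order hold):

        s_k[n] = s_k[n-1] * exp(-dt/tau_k) + a_k*tau_k*(1 - exp(-dt/tau_k)) * I[n-1]

    ``h[n] = sum_k s_k[n]`` is then the exact continuous-time convolution of
    the held input, sampled at the bin start; it matches direct rectangle
    quadrature of ``kappa`` to O(dt).
    """
    if dt is not None and abs(dt - current.dt) > 1e-12:
        raise ValueError("dt must equal the current trace's dt")
    if current.unit not in ("pA", ""):
        raise ValueError(f"expected a current trace in pA, got unit {current.unit!r}")
    dt = current.dt
    n = len(current)
    h = np.zeros(n)
    vals = current.values
    for a, tau in kappa.terms:
        decay = np.exp(-dt / tau)
        gain = a * tau * -np.expm1(-dt / tau)
        s = 0.0
        term = np.empty(n)
        term[0] = 0.0
        # scipy.signal.lfilter would do the same; the explicit loop is kept
        # O(n) with numpy via the scan below.
        term[1:] = gain * vals[:-1]
        # cumulative first-order recursion: term[n] += decay * term[n-1]
        _scan_first_order(term, decay)
        h += term
    return Trace(dt, h, current.t0, unit="")


def _scan_first_order(x: np.ndarray, decay: float) -> None:
    """In place: x[n] <- x[n] + decay * x[n-1] (linear recurrence scan)."""
    from scipy.signal import lfilter

    x[:] = lfilter([1.0], [1.0, -decay], x)


def conditional_intensity(
    model: NeuronModel,
    h_t: float,
    spike_times_before_t,
    t: float,
) -> float:
    """Conditional firing intensity ``lambda(t | history)`` in kHz.

    Returns ``lambda0 * exp(h_t + sum_i eta(t - t_i))``; exactly zero inside
    an absolute refractory block after the most recent spike.
    """
    spikes = np.asarray(spike_times_before_t, dtype=float)
    if spikes.size and spikes.max() >= t:
        raise ValueError("all spike times must precede t")
    s = model.eta.eval(t - spikes) if spikes.size else np.array([])
    total = h_t + float(np.sum(s))
    if np.isneginf(total):
        return 0.0
    return model.lambda0 * float(np.exp(total))
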