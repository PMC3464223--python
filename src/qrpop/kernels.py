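"""Causal sum-of-exponentials kernels.

These kernels are the building blocks of the spike response model: the
membrane filter ``kappa`` (maps input current, pA, to the dimensionless
filtered input h) and the effective spike after-potential ``eta`` (the
dimensionless spike-triggered kernel whose negative amplitudes implement
refractoriness on short time scales and spike-frequency adaptation on long
ones).

All times are in milliseconds.  A kernel evaluates to exactly zero for
``t < 0`` (causality) and decays to zero as ``t`` grows.  An optional
absolute block of duration ``absolute_block`` marks an interval after a
spike during which the hazard is forced to zero; inside the block the
kernel evaluates to ``-inf`` so that ``exp(eta)`` vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad


@dataclass(frozen=True)
class ExpKernelSum:
    """Causal kernel ``k(t) = sum_i amp_i * exp(-t / tau_i)`` for ``t >= 0``.

    Parameters
    ----------
    terms
        Sequence of ``(amplitude, tau_ms)`` pairs; all ``tau_ms`` must be
        positive.  Amplitudes are dimensionless for the spike after-potential
        and carry units 1/(pA*ms) for the membrane filter.
    absolute_block
        Optional duration (ms).  For ``0 <= t < absolute_block`` the kernel
        value is ``-inf`` (hazard forced to zero).
    """

    terms: tuple[tuple[float, float], ...]
    absolute_block: float = 0.0

    def __init__(self, terms, absolute_block: float = 0.0):
        terms = tuple((float(a), float(tau)) for a, tau in terms)
        for _, tau in terms:
            if tau <= 0:
                raise ValueError(f"kernel time constants must be positive, got {tau}")
        if absolute_block < 0:
            raise ValueError("absolute_block must be >= 0")
        object.__setattr__(self, "terms", terms)
        object.__setattr__(self, "absolute_block", float(absolute_block))

    @property
    def amplitudes(self) -> np.ndarray:
        return np.array([a for a, _ in self.terms], dtype=float)

    @property
    def taus(self) -> np.ndarray:
        return np.array([tau for _, tau in self.terms], dtype=float)

    def __call__(self, times) -> np.ndarray:
        return self.eval(times)

    def eval(self, times) -> np.ndarray:
        """Evaluate the kernel; 0 for t<0, -inf inside the absolute block."""
        t = np.asarray(times, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        if not np.all(np.isfinite(t)):
            raise ValueError("times must be finite")
        out = np.zeros_like(t)
        causal = t >= 0
        if self.terms:
            tc = t[causal]
            vals = np.zeros_like(tc)
            for a, tau in self.terms:
                vals += a * np.exp(-tc / tau)
            out[causal] = vals
        if self.absolute_block > 0:
            out[causal & (t < self.absolute_block)] = -np.inf
        return out[0] if scalar else out

    def integral(self) -> float:
        """``int_0^inf k(t) dt = sum_i amp_i * tau_i`` (ignores the block)."""
        return float(np.sum(self.amplitudes * self.taus))

    def scaled(self, factor: float) -> "ExpKernelSum":
        """Kernel with every amplitude multiplied by ``factor``."""
        return ExpKernelSum(
            tuple((a * factor, tau) for a, tau in self.terms),
            absolute_block=self.absolute_block,
        )

    # ---- quantities used by the population-activity solvers -------------

    def exp_minus_one(self, times) -> np.ndarray:
        """``exp(k(t)) - 1`` for t>=0 and 0 for t<0 (the adaptation kernel).

        Inside an absolute block this is exactly -1.
        """
        t = np.asarray(times, dtype=float)
        scalar = t.ndim == 0
        t = np.atleast_1d(t)
        vals = self.eval(t)
        out = np.where(t >= 0, np.expm1(vals), 0.0)
        return out[0] if scalar else out

    def cutoff(self, eps: float = 1e-4, t_max: float = 1e6) -> float:
        """Smallest t with ``|exp(k(s)) - 1| < eps`` for all s >= t.

        This is the memory horizon T_c of the solvers: beyond it the kernel's
        effect on the hazard is below tolerance and the neuron is treated as
        'free'.
        """
        if eps <= 0:
            raise ValueError("eps must be positive")
        if not self.terms and self.absolute_block == 0:
            return 0.0
        # conservative analytic bound: |e^k - 1| <= e^{|k|} - 1 and
        # |k(t)| <= sum |a_i| e^{-t/tau_i}
        bound = 0.0
        thresh = np.log1p(eps) / max(len(self.terms), 1)
        for a, tau in self.terms:
            if a != 0:
                # |a| e^{-t/tau} < thresh  =>  t > tau*log(|a|/thresh)
                bound = max(bound, tau * np.log(abs(a) / thresh))
        t_hi = max(bound, self.absolute_block, 0.0)
        if t_hi > t_max:
            raise ValueError("kernel cutoff exceeds the supported horizon")
        # refine on a fine grid (handles cancellation between terms)
        grid = np.linspace(0.0, max(t_hi, 1.0), 4097)
        g = np.abs(self.exp_minus_one(grid))
        above = np.nonzero(g >= eps)[0]
        if above.size == 0:
            return 0.0
        return float(grid[above[-1] + 1]) if above[-1] + 1 < grid.size else float(grid[-1])

    def adaptation_integral(self) -> float:
        """``G = int_0^inf (1 - exp(k(t))) dt`` by adaptive quadrature.

        Positive for adapting (k <= 0) kernels; enters the Lambert-W gain
        function for the first-order moment expansion.
        """
        blk = self.absolute_block
        horizon = self.cutoff(eps=1e-12) + 1.0

        def f(t):
            return 1.0 - np.exp(self.eval(t))

        if horizon <= blk:
            return blk
        val, _ = quad(f, blk, horizon, limit=500)
        return float(val + blk)


def kernel_from_dicts(entries, absolute_block: float = 0.0) -> ExpKernelSum:
    """Build a kernel from ``[{'amp': ..., 'tau_ms': ...}, ...]`` config items."""
    return ExpKernelSum(
        tuple((e["amp"], e["tau_ms"]) for e in entries), absolute_block=absolute_block
    )
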