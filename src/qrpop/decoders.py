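"""Stimulus decoders: recover the filtered input h(t) (and, by inverting the
membrane filter, the current) from an observed population activity trace.

Both decoders exploit that the encoders are, per time bin, invertible in
``e^{h(t)}`` once the survival state / past-activity accumulator is advanced
from the *observed* activity:

* QR/renewal: the emitted mass ``A(t) dt = sum_j S_j dt (1 - e^{-x B_j dt})
  + free (1 - e^{-x B_free dt})`` with ``x = e^{h(t)}`` and
  ``B_j = lambda0 e^{eta_j + F_j}`` independent of h.  The right-hand side is
  concave and increasing in x, so Newton iteration from the small-dt ratio
  ``x0 = A / (dt sum B_j S_j + B_free free)`` (the direct-ratio decoder)
  converges monotonically to the exact inverse.  The survival state is
  advanced with the observed activity even through masked bins, so decoding
  resumes cleanly after gaps.
* EME1: ``h(t) = log(A(t)/lambda0) - int_0^T_c (e^eta(s)-1) A(t-s) ds`` --
  the exact algebraic inverse of the EME1 encoder (a logarithm of the
  momentary activity plus an accumulator of the past activity).

Where the activity is zero or below ``a_min`` the stimulus is undefined but
bounded from above; those bins are masked and the upper bound implied by
``A < a_min`` is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .encoders import DEFAULT_EME_BINS, DEFAULT_EPS, _EMEGrid, _SurvivalMachine
from .kernels import ExpKernelSum
from .model import NeuronModel, Trace

__all__ = ["DecodeResult", "decode_qr", "decode_eme1", "current_from_h", "auto_a_min"]


@dataclass
class DecodeResult:
    """Decoded filtered input with a per-bin validity mask."""

    h_hat: Trace  # dimensionless; NaN on masked bins
    valid: np.ndarray  # bool per bin
    upper_bounds: np.ndarray  # h upper bound on masked bins, NaN elsewhere
    a_min: float  # kHz threshold used

    @property
    def decodable_fraction(self) -> float:
        return float(self.valid.mean())

    def masked_values(self) -> np.ndarray:
        """h estimates on valid bins only."""
        return self.h_hat.values[self.valid]


def auto_a_min(n_neurons: int, window: float) -> float:
    """Smallest meaningful activity: one expected spike in the estimation
    window, ``1 / (n_neurons * window)`` kHz.  With a box smoothing window
    this coincides with 'the smoothed activity is nonzero'."""
    return 1.0 / (n_neurons * window)


def decode_qr(
    model: NeuronModel,
    A: Trace,
    eps: float = DEFAULT_EPS,
    a_min: float = 0.0,
    adaptation: bool = True,
) -> DecodeResult:
    """Invert the quasi-renewal encoder given an observed activity trace.

    ``adaptation=False`` inverts plain renewal theory instead.  Bins with
    ``A < a_min`` (or a non-positive denominator, which can only happen when
    the whole population sits inside an absolute refractory block) are
    masked; the state is advanced from the observed activity regardless.
    """
    if np.any(A.values < 0):
        raise ValueError("activity must be non-negative")
    machine = _SurvivalMachine(model, A.dt, eps, adaptation)
    dt = A.dt
    n = len(A)
    h_hat = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    upper = np.full(n, np.nan)
    av = A.values
    thresh = max(a_min, 0.0)
    for i in range(n):
        B, B_free = machine.hazard_factors()
        denom = machine.linear_denominator(B, B_free)
        a_t = av[i]
        if a_t >= thresh and a_t > 0:
            x, solved = _solve_exp_h(machine, B, B_free, a_t, denom)
            if solved and x > 0:
                h_hat[i] = np.log(x)
                valid[i] = True
            elif denom > 0:
                upper[i] = np.log(max(thresh, np.finfo(float).tiny) / denom)
        else:
            # masked bin: advance the state with the small-dt ratio estimate
            x = a_t / denom if denom > 0 else 0.0
            if denom > 0:
                upper[i] = np.log(max(thresh, np.finfo(float).tiny) / denom)
        _, p, p_free = machine.emission(x, B, B_free)
        machine.advance(a_t, p, p_free)
    return DecodeResult(
        h_hat=Trace(A.dt, h_hat, A.t0, unit=""),
        valid=valid,
        upper_bounds=upper,
        a_min=thresh,
    )


def _solve_exp_h(machine, B, B_free, a_t, denom, max_iter=60):
    """Solve the emitted-mass equation for ``x = e^h`` given observed A.

    The emitted mass is concave increasing in x, so Newton from the
    direct-ratio estimate converges monotonically from below.  Returns
    ``(x, solved)``; unsolvable bins (activity at or above the reachable
    population mass, or an empty denominator) report ``solved=False``.
    """
    dt = machine.dt
    target = a_t * dt
    if target <= 0 or denom <= 0:
        return 0.0, False
    Sdt = machine.S * dt
    reachable = float(Sdt.sum()) + machine.free
    if target >= reachable * (1.0 - 1e-12):
        return np.inf, False
    x = target / (denom * dt)  # direct ratio (small-dt limit)
    for _ in range(max_iter):
        eb = np.exp(-x * B * dt)
        ef = np.exp(-x * B_free * dt)
        f = float(Sdt @ (1.0 - eb)) + machine.free * (1.0 - ef) - target
        if abs(f) <= 1e-13 * target:
            return x, True
        df = float(Sdt @ (B * dt * eb)) + machine.free * B_free * dt * ef
        if df <= 0:
            return x, False
        x -= f / df
    return x, True


def decode_eme1(
    model: NeuronModel,
    A: Trace,
    eps: float = DEFAULT_EPS,
    a_min: float = 0.0,
    n_bins: int = DEFAULT_EME_BINS,
) -> DecodeResult:
    """Exact algebraic inverse of the first-order moment-expansion encoder:
    the log of the momentary activity minus the accumulated past activity."""
    if np.any(A.values < 0):
        raise ValueError("activity must be non-negative")
    grid = _EMEGrid(model, A.dt, eps, n_bins)
    n = len(A)
    av = A.values
    past = np.zeros(grid.M)
    w = grid.weights
    idx = grid.sample_idx
    h_hat = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    upper = np.full(n, np.nan)
    thresh = max(a_min, 0.0)
    log_lam0 = np.log(model.lambda0)
    for i in range(n):
        c_t = float(w @ past[idx])
        if av[i] >= thresh and av[i] > 0:
            h_hat[i] = np.log(av[i]) - log_lam0 - c_t
            valid[i] = True
        else:
            upper[i] = np.log(max(thresh, np.finfo(float).tiny)) - log_lam0 - c_t
        past[1:] = past[:-1]
        past[0] = av[i]
    return DecodeResult(
        h_hat=Trace(A.dt, h_hat, A.t0, unit=""),
        valid=valid,
        upper_bounds=upper,
        a_min=thresh,
    )


def current_from_h(h_hat: DecodeResult | Trace, kappa: ExpKernelSum) -> Trace:
    """Invert the membrane filter: recover I(t) from h = kappa * I.

    Inverts the zero-order-hold exponential-integrator recursion of
    ``filtered_input`` jointly over the kappa terms, so
    ``current_from_h(filtered_input(I)) == I`` on interior bins.  Masked
    gaps in a DecodeResult propagate to the output (the per-term filter
    states cannot be advanced through an unknown input).
    """
    if not kappa.terms or np.all(kappa.amplitudes == 0):
        raise ValueError("kappa must have a nonzero amplitude")
    if isinstance(h_hat, DecodeResult):
        h = h_hat.h_hat
        valid = h_hat.valid
    else:
        h = h_hat
        valid = np.isfinite(h.values)
    dt = h.dt
    decays = np.exp(-dt / kappa.taus)
    gains = kappa.amplitudes * kappa.taus * -np.expm1(-dt / kappa.taus)
    gain_sum = float(gains.sum())
    if gain_sum == 0:
        raise ValueError("kappa gains cancel; filter not invertible")
    n = len(h)
    out = np.full(n, np.nan)
    s = np.zeros(kappa.amplitudes.size)
    ok = True  # filter state known?
    hv = h.values
    for i in range(n - 1):
        # h[i+1] = sum_k (decay_k s_k + gain_k I[i])
        if valid[i + 1] and ok:
            I_i = (hv[i + 1] - float(decays @ s)) / gain_sum
            out[i] = I_i
            s = decays * s + gains * I_i
        elif valid[i + 1] and not ok:
            # re-anchor: treat the unknown history as a constant input that
            # would produce h[i+1] at steady state
            I_i = hv[i + 1] / kappa.integral()
            out[i] = np.nan  # first bin after a gap is not trustworthy
            s = kappa.amplitudes * kappa.taus * I_i
            ok = True
        else:
            ok = False
    return Trace(dt, out, h.t0, unit="pA")
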