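"""Population-activity encoders: renewal, quasi-renewal (QR), and the
first/second-order event-based moment expansions (EME1/EME2).

All four are causal iterative solvers mapping the filtered input ``h(t)`` to
the population activity ``A(t)`` in kHz.

Renewal and QR share one survival machinery.  The state is the density
``S_j`` of neurons whose last spike is ``j*dt`` old (ages ``j = 1..M`` up to
the kernel cutoff ``T_c``) plus the 'free' mass of neurons whose last spike
is older.  Per bin,

    A(t) = dt * sum_j K_j(t) S_j(t)  +  K_free(t) * free_mass(t)

with hazards ``K_j = lambda0 * exp(h(t) + eta(j dt) + F(t, t - j dt))``.
The adaptation factor ``F(t, t_hat) = int_-inf^t_hat (e^{eta(t-z)} - 1) A(z) dz``
averages the self-inhibition of all spikes before the last one over the past
activity; dropping it (F = 0) gives time-dependent renewal theory.  The free
population drops the last-spike kernel (below tolerance by construction) and
its F factor is likewise below tolerance.

Per bin, a cohort with hazard K emits the fraction ``1 - exp(-K dt)`` -- the
same per-bin spike probability the direct simulation draws from -- so the
emitted mass, the survival decay and the inserted first bin are mutually
consistent and total probability is conserved to machine precision; the
quoted hazard-times-density form is recovered as dt -> 0.  Ages then shift
by one bin and the newly fired mass enters the first bin.

EME1 treats no spike specially:

    A(t) = lambda0 * exp( h(t) + int_0^T_c (e^{eta(s)} - 1) A(t-s) ds )

evaluated on a nonlinear age grid (fine near the spike, coarse in the tail).
EME2 adds the second-order term of the moment expansion built from the
pair-correlation of a stationary renewal process at the momentary input (a
precomputed look-up table over h).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import NeuronModel, Trace
from .steady_state import renewal_density

__all__ = [
    "SurvivalState",
    "encode_renewal",
    "encode_qr",
    "encode_eme1",
    "encode_eme2",
    "steady_activity_curve",
    "EncoderDivergence",
]

DEFAULT_EPS = 1e-4
DEFAULT_EME_BINS = 200


class EncoderDivergence(RuntimeError):
    """Raised when the predicted activity exceeds one spike per bin."""


@dataclass
class SurvivalState:
    """Discretized last-spike density and hazard of a survival solver.

    ``S[j-1]`` is the probability density (1/ms) that the last spike was
    ``j*dt`` ago and the neuron has not spiked since; ``K`` is the hazard on
    the same grid (kHz); ``free_mass`` is the probability that the last spike
    is older than the cutoff ``M*dt``.
    """

    dt: float
    S: np.ndarray
    K: np.ndarray
    free_mass: float

    @property
    def M(self) -> int:
        return self.S.size

    def conservation_residual(self) -> float:
        return abs(self.dt * self.S.sum() + self.free_mass - 1.0)


class _SurvivalMachine:
    """Shared renewal/QR stepping kernel.

    The decoder reuses this machine: ``hazard_factors`` exposes the
    h-independent part ``B`` of the hazard (``K = e^h * B``), and ``advance``
    pushes either the encoder's own prediction or an observed activity.
    """

    def __init__(self, model: NeuronModel, dt: float, eps: float, adaptation: bool):
        if eps <= 0:
            raise ValueError("eps must be positive")
        self.model = model
        self.dt = dt
        self.adaptation = adaptation
        t_c = model.eta.cutoff(eps)
        self.M = max(1, int(np.ceil(t_c / dt - 1e-9)))
        ages = dt * np.arange(1, self.M + 1)
        ev = model.eta.eval(ages)
        self.exp_eta = np.where(np.isneginf(ev), 0.0, np.exp(ev))
        self.G = self.exp_eta - 1.0  # e^eta - 1 on the age grid
        self.S = np.zeros(self.M)
        self.free = 1.0
        self.past = np.zeros(self.M)  # past[i-1] = A(t - i*dt)
        self.max_residual = 0.0
        self._F = np.zeros(self.M)

    def hazard_factors(self) -> tuple[np.ndarray, float]:
        """h-independent hazard ``B_j = lambda0 e^{eta_j + F_j}``, and B_free."""
        lam0 = self.model.lambda0
        if self.adaptation:
            w = self.G * self.past
            suffix = np.cumsum(w[::-1])[::-1]  # suffix[j-1] = sum_{i>=j} w_i
            self._F[: self.M - 1] = self.dt * suffix[1:]
            self._F[self.M - 1] = 0.0
            B = lam0 * self.exp_eta * np.exp(self._F)
        else:
            B = lam0 * self.exp_eta
        return B, lam0

    def emission(self, exp_h: float, B: np.ndarray, B_free: float):
        """Per-bin spike probabilities and the resulting activity (kHz)."""
        dt = self.dt
        p = -np.expm1(-exp_h * B * dt)
        p_free = -np.expm1(-exp_h * B_free * dt)
        A_t = float(self.S @ p) + self.free * p_free / dt
        return A_t, p, p_free

    def emitted_mass(self, p: np.ndarray, p_free: float) -> float:
        return self.dt * float(self.S @ p) + self.free * p_free

    def linear_denominator(self, B: np.ndarray, B_free: float) -> float:
        """Small-dt limit of d(emitted mass)/d(e^h) divided by dt."""
        return self.dt * float(B @ self.S) + B_free * self.free

    def advance(self, A_t: float, p: np.ndarray, p_free: float) -> None:
        """Survive with 1-p, age by one bin, insert the emitted mass A_t*dt."""
        surv = self.S * (1.0 - p)
        self.free = self.free * (1.0 - p_free) + self.dt * surv[-1]
        self.S[1:] = surv[:-1]
        self.S[0] = A_t
        # conservation holds identically; track floating-point drift only
        self.max_residual = max(
            self.max_residual, abs(self.dt * float(self.S.sum()) + self.free - 1.0)
        )
        self.past[1:] = self.past[:-1]
        self.past[0] = A_t
        self._last_K = p  # per-bin probabilities; K = -log(1-p)/dt
        self._last_K_free = p_free

    def state(self) -> SurvivalState:
        p = getattr(self, "_last_K", np.zeros(self.M))
        with np.errstate(divide="ignore"):
            hazard = -np.log1p(-np.minimum(p, 1.0 - 1e-300)) / self.dt
        return SurvivalState(
            dt=self.dt, S=self.S.copy(), K=hazard, free_mass=self.free
        )


def _run_survival(
    model: NeuronModel, h: Trace, eps: float, adaptation: bool, full_output: bool
):
    machine = _SurvivalMachine(model, h.dt, eps, adaptation)
    n = len(h)
    out = np.empty(n)
    dt = h.dt
    hv = h.values
    for i in range(n):
        B, B_free = machine.hazard_factors()
        exp_h = np.exp(hv[i])
        A_t, p, p_free = machine.emission(exp_h, B, B_free)
        if A_t * dt > 1.0:
            raise EncoderDivergence(
                f"activity {A_t:.3g} kHz at t={h.t0 + i * dt:.1f} ms exceeds "
                f"one spike per bin (dt={dt} ms); reduce dt or the input"
            )
        machine.advance(A_t, p, p_free)
        out[i] = A_t
    trace = Trace(dt, out, h.t0, unit="kHz")
    if full_output:
        return trace, {
            "max_conservation_residual": machine.max_residual,
            "state": machine.state(),
            "M": machine.M,
        }
    return trace


def encode_renewal(
    model: NeuronModel, h: Trace, eps: float = DEFAULT_EPS, full_output: bool = False
):
    """Time-dependent renewal theory: last spike treated exactly, earlier
    spikes ignored.  Captures refractoriness (and the damped transient
    oscillations) but not adaptation, so its steady level on strong steps is
    systematically too high for adapting neurons."""
    return _run_survival(model, h, eps, adaptation=False, full_output=full_output)


def encode_qr(
    model: NeuronModel, h: Trace, eps: float = DEFAULT_EPS, full_output: bool = False
):
    """Quasi-renewal theory: last spike exact, earlier spikes averaged
    through the past activity (first history moment)."""
    return _run_survival(model, h, eps, adaptation=True, full_output=full_output)


# --------------------------------------------------------------------------
# event-based moment expansion
# --------------------------------------------------------------------------


def _nonlinear_grid(M: int, n_bins: int) -> np.ndarray:
    """Bin edges (integers, units of dt) covering ``M`` fine bins with at most
    ``n_bins`` geometrically growing bins, width_j = ceil(a^j)."""
    if M <= n_bins:
        return np.arange(M + 1)
    from scipy.optimize import brentq

    # a solves sum_{j=1..n} a^j = M (continuous surrogate of the ceil rule)
    f = lambda a: a * (a**n_bins - 1.0) / (a - 1.0) - M
    a = brentq(f, 1.0 + 1e-12, 2.0, xtol=1e-12)
    widths = np.ceil(a ** np.arange(1, n_bins + 1)).astype(np.int64)
    edges = np.concatenate([[0], np.cumsum(widths)])
    edges = edges[edges < M]
    return np.concatenate([edges, [M]])


class _EMEGrid:
    """Nonlinear age grid with exact per-bin weights of ``e^eta - 1``.

    The weights are the integrals of the adaptation kernel over each bin,
    computed on the fine ``dt`` grid at setup, so the coarse grid introduces
    no quadrature bias in the stationary limit; past activity is sampled at
    bin-end ages (explicit scheme).
    """

    def __init__(self, model: NeuronModel, dt: float, eps: float, n_bins: int):
        t_c = model.eta.cutoff(eps)
        self.M = max(1, int(np.ceil(t_c / dt - 1e-9)))
        self.dt = dt
        fine = dt * np.arange(self.M + 1)
        g = model.eta.exp_minus_one(fine)
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (g[1:] + g[:-1]) * dt)])
        self.edges = _nonlinear_grid(self.M, n_bins)  # ints, units of dt
        self.weights = cum[self.edges[1:]] - cum[self.edges[:-1]]  # ms
        self.sample_idx = self.edges[1:] - 1  # past[e_j - 1] = A(t - e_j dt)
        self.ages = dt * self.edges[1:].astype(float)

    @property
    def total_weight(self) -> float:
        return float(self.weights.sum())


def _run_eme(
    model: NeuronModel,
    h: Trace,
    eps: float,
    n_bins: int,
    correction=None,
    full_output: bool = False,
):
    grid = _EMEGrid(model, h.dt, eps, n_bins)
    n = len(h)
    dt = h.dt
    out = np.empty(n)
    past = np.zeros(grid.M)
    hv = h.values
    lam0 = model.lambda0
    w = grid.weights
    idx = grid.sample_idx
    for i in range(n):
        a_past = past[idx]
        c_t = float(w @ a_past)
        if correction is not None:
            c_t += correction(hv[i], w * a_past)
        A_t = lam0 * np.exp(hv[i] + c_t)
        if A_t * dt > 1.0:
            raise EncoderDivergence(
                f"activity {A_t:.3g} kHz at t={h.t0 + i * dt:.1f} ms exceeds "
                f"one spike per bin (dt={dt} ms)"
            )
        past[1:] = past[:-1]
        past[0] = A_t
        out[i] = A_t
    trace = Trace(dt, out, h.t0, unit="kHz")
    if full_output:
        return trace, {"grid": grid}
    return trace


def encode_eme1(
    model: NeuronModel,
    h: Trace,
    eps: float = DEFAULT_EPS,
    n_bins: int = DEFAULT_EME_BINS,
    full_output: bool = False,
):
    """First-order event-based moment expansion:

        A(t) = lambda0 exp( h(t) + int_0^T_c (e^eta(s) - 1) A(t-s) ds ).

    Accurate at low coupling between spikes (large ISIs or small SAP); misses
    the refractoriness-driven transient oscillations."""
    return _run_eme(model, h, eps, n_bins, correction=None, full_output=full_output)


class _CorrelationTable:
    """Look-up table of stationary-renewal pair-correlation matrices over h.

    For each tabulated filtered input the steady-state renewal process with
    hazard ``lambda0 e^{h + eta(s)}`` is solved; its renewal density ``m``
    yields the normalized connected pair correlation ``Q(s) = m(s)/A_h - 1``,
    evaluated at all pairwise age differences of the nonlinear grid.  The
    second-order correction is then ``0.5 * y^T Q y`` with
    ``y_j = w_j A(t - e_j)``.
    """

    def __init__(
        self,
        model: NeuronModel,
        grid: _EMEGrid,
        h_lo: float,
        h_hi: float,
        n_table: int = 33,
        dt_corr: float = 2.0,
    ):
        pad = 0.05 * max(h_hi - h_lo, 1e-6)
        self.hs = np.linspace(h_lo - pad, h_hi + pad, n_table)
        dt_corr = max(dt_corr, grid.dt)
        max_lag = grid.ages[-1]
        lag_matrix = np.abs(grid.ages[:, None] - grid.ages[None, :])
        self.Q: list[np.ndarray] = []
        self._warned = False
        for h0 in self.hs:
            ages, p0, rate = _renewal_isi(model, h0, dt_corr, max_lag)
            m = renewal_density(p0, dt_corr, int(np.ceil(max_lag / dt_corr)) + 1)
            q = m / rate - 1.0
            self.Q.append(np.interp(lag_matrix, ages[: m.size], q))

    def correction(self, h_t: float, y: np.ndarray) -> float:
        hs = self.hs
        if h_t <= hs[0] or h_t >= hs[-1]:
            if not self._warned:
                warnings.warn(
                    "filtered input outside the correlation look-up range; "
                    "clamping to the table edge",
                    stacklevel=2,
                )
                self._warned = True
            h_t = min(max(h_t, hs[0]), hs[-1])
        i = min(int(np.searchsorted(hs, h_t) - 1), hs.size - 2)
        i = max(i, 0)
        alpha = (h_t - hs[i]) / (hs[i + 1] - hs[i])
        qy = (1.0 - alpha) * (self.Q[i] @ y) + alpha * (self.Q[i + 1] @ y)
        return 0.5 * float(y @ qy)


def _renewal_isi(model: NeuronModel, h0: float, dt: float, min_span: float):
    """Stationary renewal ISI density at constant filtered input ``h0``.

    Returns (ages, P0, rate); the grid covers at least ``min_span`` and
    extends until the survival probability is negligible (capped)."""
    t_end = max(min_span, 1000.0)
    while True:
        ages = np.arange(0.0, t_end + dt, dt)
        ev = model.eta.eval(ages)
        lam = model.lambda0 * np.exp(np.where(np.isneginf(ev), -np.inf, h0 + ev))
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * dt)])
        surv = np.exp(-cum)
        if surv[-1] < 1e-10 or t_end > 240_000.0:
            break
        t_end *= 2.0
    p0 = lam * surv
    mean = np.trapezoid(ages * p0, ages)
    if surv[-1] > 0 and lam[-1] > 0:
        mean += surv[-1] * (ages[-1] + 1.0 / lam[-1])
    return ages, p0, 1.0 / mean


def encode_eme2(
    model: NeuronModel,
    h: Trace,
    eps: float = DEFAULT_EPS,
    n_bins: int = DEFAULT_EME_BINS,
    n_table: int = 33,
    zero_correction: bool = False,
    full_output: bool = False,
):
    """Second-order event-based moment expansion.

    Adds to the EME1 exponent the second cumulant of the spiking history,
    (1/2) * int int (e^eta - 1)(e^eta - 1) g2, with the connected two-point
    function g2 approximated at each time by the pair correlation of the
    stationary renewal process at the momentary filtered input (look-up
    table, linear interpolation).  ``zero_correction=True`` degenerates to
    EME1 bit-for-bit (the correction term is forced to 0.0)."""
    if zero_correction:
        corr = lambda h_t, y: 0.0
    else:
        grid = _EMEGrid(model, h.dt, eps, n_bins)
        table = _CorrelationTable(
            model, grid, float(h.values.min()), float(h.values.max()), n_table
        )
        corr = table.correction
    return _run_eme(model, h, eps, n_bins, correction=corr, full_output=full_output)


# --------------------------------------------------------------------------
# steady-state plateaus
# --------------------------------------------------------------------------

_ENCODERS = {
    "renewal": encode_renewal,
    "qr": encode_qr,
    "eme1": encode_eme1,
    "eme2": encode_eme2,
}


def steady_activity_curve(
    model: NeuronModel,
    I_values,
    method: str = "qr",
    dt: float = 0.5,
    eps: float = DEFAULT_EPS,
    rel_tol: float = 1e-6,
    t_budget: float = 120_000.0,
):
    """Steady-state activity vs input current for one encoder.

    Each constant input is run until the relative change of the activity over
    one second falls below ``rel_tol`` (the run is extended, doubling, up to
    ``t_budget`` ms; points that never converge are flagged).

    Returns a list of ``(I, A_inf_khz, converged)`` tuples.
    """
    if method not in _ENCODERS:
        raise ValueError(f"method must be one of {sorted(_ENCODERS)}")
    encoder = _ENCODERS[method]
    out = []
    for I in I_values:
        h_val = model.h_infinity(I)
        t_run = 16_000.0
        converged = False
        a_end = np.nan
        while True:
            n = int(round(t_run / dt))
            h = Trace(dt, np.full(n, h_val), unit="")
            a = encoder(model, h, eps=eps)
            k = int(round(1000.0 / dt))
            a_end = float(a.values[-1])
            prev = float(a.values[-1 - k])
            if a_end == 0.0 or abs(a_end - prev) <= rel_tol * max(a_end, 1e-300):
                converged = True
                break
            if t_run >= t_budget:
                break
            t_run = min(2 * t_run, t_budget)
        out.append((float(I), a_end, converged))
    return out
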