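"""Steady-state theory under constant input: averaged hazard, interspike
interval (ISI) distribution, stationary rate, autocorrelation and the
closed-form Lambert-W gain of the first-order moment expansion.

Under a constant filtered input ``h`` the quasi-renewal description of a
population settles to a stationary state characterized by the averaged
conditional intensity as a function of the age ``s`` since the last spike:

    lambda_bar(s) = lambda0 * exp( h + eta(s) + A_inf * int_s^inf (e^eta(x) - 1) dx )

The ISI density is ``P0(s) = lambda_bar(s) * exp(-int_0^s lambda_bar)`` and the
stationary activity solves the self-consistency ``A_inf = 1 / mean ISI``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import lambertw

from .kernels import ExpKernelSum
from .model import NeuronModel

__all__ = [
    "SteadyStateSolution",
    "averaged_hazard",
    "isi_density",
    "steady_rate",
    "autocorrelation",
    "renewal_density",
    "eme1_gain",
]


@dataclass
class SteadyStateSolution:
    """Full stationary solution at one constant input."""

    h_inf: float
    A_inf: float  # kHz
    ages: np.ndarray  # ms, uniform grid starting at 0
    isi_density: np.ndarray  # P0(s) on ages, 1/ms
    hazard_bar: np.ndarray  # averaged intensity on ages, kHz
    survival: np.ndarray  # exp(-int_0^s lambda_bar)
    n_iterations: int
    converged: bool

    @property
    def dt(self) -> float:
        return float(self.ages[1] - self.ages[0])

    @property
    def mean_isi(self) -> float:
        return float(np.trapezoid(self.ages * self.isi_density, self.ages))

    @property
    def isi_normalization(self) -> float:
        return float(np.trapezoid(self.isi_density, self.ages))

    @property
    def cv_isi(self) -> float:
        m1 = self.mean_isi
        m2 = float(np.trapezoid(self.ages**2 * self.isi_density, self.ages))
        var = max(m2 - m1**2, 0.0)
        return float(np.sqrt(var) / m1)


def _adaptation_tail(eta: ExpKernelSum, ages: np.ndarray) -> np.ndarray:
    """``R(s) = int_s^inf (e^eta(x) - 1) dx`` on a uniform age grid.

    The grid must extend past the kernel cutoff so that the tail beyond the
    grid end is negligible.
    """
    g = eta.exp_minus_one(ages)
    dt = ages[1] - ages[0]
    # reversed cumulative trapezoid; R(last) = 0
    seg = 0.5 * (g[1:] + g[:-1]) * dt
    r = np.zeros_like(ages)
    r[:-1] = seg[::-1].cumsum()[::-1]
    return r


def averaged_hazard(
    model: NeuronModel,
    h_inf: float,
    A_inf: float,
    ages: np.ndarray,
) -> np.ndarray:
    """Averaged conditional intensity ``lambda_bar(s)`` (kHz) on an age grid.

    ``A_inf = 0`` gives the pure renewal hazard ``lambda0*exp(h+eta(s))``;
    large ``s`` tends to ``lambda0*exp(h - A_inf*G)`` with ``G`` the
    adaptation integral.
    """
    if A_inf < 0:
        raise ValueError("A_inf must be >= 0")
    ages = np.asarray(ages, dtype=float)
    r = _adaptation_tail(model.eta, ages)
    log_h = h_inf + model.eta.eval(ages) + A_inf * r
    lam = model.lambda0 * np.exp(log_h)
    lam[~np.isfinite(log_h)] = 0.0  # absolute block
    return lam


def isi_density(
    model: NeuronModel,
    h_inf: float,
    A_inf: float,
    ages: np.ndarray,
) -> np.ndarray:
    """ISI density ``P0(s) = lambda_bar(s) exp(-int_0^s lambda_bar)`` (1/ms)."""
    ages = np.asarray(ages, dtype=float)
    if ages[0] != 0:
        raise ValueError("age grid must start at 0")
    lam = averaged_hazard(model, h_inf, A_inf, ages)
    return lam * _survival_from_hazard(lam, ages)


def _survival_from_hazard(lam: np.ndarray, ages: np.ndarray) -> np.ndarray:
    dt = ages[1] - ages[0]
    cum = np.concatenate([[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * dt)])
    return np.exp(-cum)


def _stationary_grid(
    lambda_drive: float,
    eta: ExpKernelSum,
    A: float,
    dt: float,
    t_max: float,
    survival_tol: float = 1e-9,
):
    """Age grid long enough for the survival function to decay below tol."""
    t_end = max(2.0 * eta.cutoff(1e-6) if eta.terms else 0.0, 1000 * dt, 100.0)
    while True:
        ages = np.arange(0.0, t_end + dt, dt)
        model = _DriveModel(lambda_drive, eta)
        lam = averaged_hazard(model, 0.0, A, ages)
        surv = _survival_from_hazard(lam, ages)
        if surv[-1] < survival_tol or t_end >= t_max:
            return ages, lam, surv
        t_end *= 2.0


class _DriveModel:
    """Minimal stand-in with the (lambda0, eta) pair; h is folded into lambda0."""

    def __init__(self, lambda0: float, eta: ExpKernelSum):
        self.lambda0 = lambda0
        self.eta = eta


def _rate_given_activity(
    lambda_drive: float, eta: ExpKernelSum, A: float, dt: float, t_max: float
) -> tuple[float, np.ndarray, np.ndarray, np.ndarray]:
    ages, lam, surv = _stationary_grid(lambda_drive, eta, A, dt, t_max)
    p0 = lam * surv
    mean = np.trapezoid(ages * p0, ages)
    if surv[-1] > 0 and lam[-1] > 0:
        # beyond the grid the kernel has decayed, so the hazard is constant:
        # the residual mass surv[-1] contributes t_end + 1/lambda_end exactly
        mean += surv[-1] * (ages[-1] + 1.0 / lam[-1])
    return 1.0 / mean, ages, lam, p0


def steady_rate(
    model: NeuronModel,
    I_const: float | None = None,
    h_inf: float | None = None,
    dt: float = 0.5,
    tol: float = 1e-8,
    max_iter: int = 500,
    t_max: float = 600_000.0,
) -> SteadyStateSolution:
    """Stationary activity from the fixed point ``A = 1/mean-ISI(A)``.

    Damped iteration (factor 0.5) from ``A=0`` with a bisection fallback.
    ``A`` enters the averaged hazard through the adaptation term, so for an
    adapting SAP (eta <= 0) the map is monotone decreasing in ``A`` and a
    unique root exists in ``[0, lambda0*e^h]``.
    """
    if (I_const is None) == (h_inf is None):
        raise ValueError("provide exactly one of I_const or h_inf")
    if h_inf is None:
        h_inf = model.h_infinity(I_const)
    drive = model.lambda0 * np.exp(h_inf)
    eta = model.eta

    A = 0.0
    converged = False
    n_it = 0
    for n_it in range(1, max_iter + 1):
        f, ages, lam, p0 = _rate_given_activity(drive, eta, A, dt, t_max)
        A_new = 0.5 * A + 0.5 * f
        if A > 0 and abs(A_new - A) <= tol * A:
            A = A_new
            converged = True
            break
        A = A_new
    if not converged:
        from scipy.optimize import brentq

        g = lambda a: a - _rate_given_activity(drive, eta, a, dt, t_max)[0]
        hi = drive * 1.0000001
        if g(0.0) >= 0 or g(hi) <= 0:
            raise RuntimeError(
                "no stationary-rate root bracketed; expected only for a "
                "facilitating (eta > 0) spike after-potential"
            )
        A = brentq(g, 0.0, hi, xtol=1e-14, rtol=1e-10)
        converged = True
    f, ages, lam, p0 = _rate_given_activity(drive, eta, A, dt, t_max)
    surv = _survival_from_hazard(lam, ages)
    return SteadyStateSolution(
        h_inf=float(h_inf),
        A_inf=float(A),
        ages=ages,
        isi_density=p0,
        hazard_bar=lam,
        survival=surv,
        n_iterations=n_it,
        converged=converged,
    )


def renewal_density(p0: np.ndarray, dt: float, n_out: int) -> np.ndarray:
    """Renewal density ``m(s)``: rate of events at lag ``s`` after an event.

    Solves the renewal integral equation ``m = P0 + P0 * m`` by a marching
    trapezoid discretization (exact quadrature semantics; no FFT wraparound).
    ``m(s) -> rate`` for large ``s``.
    """
    n = min(n_out, p0.size)
    m = np.zeros(n)
    m[0] = p0[0]
    half = 0.5 * dt * p0[0]
    for k in range(1, n):
        conv = dt * np.dot(p0[1:k], m[k - 1 : 0 : -1]) if k > 1 else 0.0
        conv += 0.5 * dt * p0[k] * m[0]
        m[k] = (p0[k] + conv) / (1.0 - half)
    return m


def autocorrelation(
    model: NeuronModel,
    I_const: float | None = None,
    lags: np.ndarray | None = None,
    h_inf: float | None = None,
    dt: float = 0.5,
    max_lag: float = 2000.0,
) -> tuple[np.ndarray, np.ndarray, float, SteadyStateSolution]:
    """Stationary autocorrelation of the population activity.

    Returns ``(lags, C, delta_weight, solution)`` where for ``s > 0``

        C(s) = A_inf * m(|s|)

    with ``m`` the renewal density built from the QR steady-state ISI
    distribution, plus a Dirac component ``delta_weight * delta(s)`` with
    ``delta_weight = A_inf`` reported separately.  ``C -> A_inf^2`` as
    ``s -> inf``; for a Poisson process C is flat at ``A_inf^2``.
    """
    sol = steady_rate(model, I_const=I_const, h_inf=h_inf, dt=dt)
    if lags is None:
        lags = np.arange(dt, max_lag + dt, dt)
    lags = np.asarray(lags, dtype=float)
    span = lags.max()
    if span < 10 * sol.mean_isi:
        span = 10 * sol.mean_isi  # aliasing/asymptote guard
    n = int(np.ceil(span / dt)) + 1
    m = renewal_density(sol.isi_density, dt, min(n, sol.ages.size))
    grid = sol.ages[: m.size]
    c = sol.A_inf * np.interp(np.abs(lags), grid, m, right=sol.A_inf)
    return lags, c, float(sol.A_inf), sol


def eme1_gain(
    model: NeuronModel,
    I_const: float | None = None,
    h_inf: float | None = None,
) -> float:
    """Closed-form steady-state activity of the first-order moment expansion.

    ``A_inf = W(G * lambda0 * e^h) / G`` with ``G = int (1 - e^eta) dx > 0``
    and W the principal-branch Lambert function; ``G -> 0`` recovers the
    Poisson rate ``lambda0 e^h``.  Valid on a restricted input range when the
    SAP is facilitating (G < 0).
    """
    if (I_const is None) == (h_inf is None):
        raise ValueError("provide exactly one of I_const or h_inf")
    if h_inf is None:
        h_inf = model.h_infinity(I_const)
    G = model.eta.adaptation_integral()
    drive = model.lambda0 * np.exp(h_inf)
    if abs(G) < 1e-12:
        return float(drive)
    arg = G * drive
    if arg < -np.exp(-1.0):
        raise ValueError(
            "Lambert-W argument outside the principal branch; the gain "
            "function is valid on a restricted range of input"
        )
    return float(np.real(lambertw(arg)) / G)
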