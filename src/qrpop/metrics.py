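"""Quantitative comparison of theory, simulation and decoded stimuli.

The headline statistic is the Pearson correlation coefficient (the
variance-normalized covariance, with the expectation taken over the
discretized time bins); the positive-error fraction measures bias.  Theory
traces are smoothed with the same window as the PSTH before comparison so
that discretization noise is matched.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .model import Trace
from .popsim import smooth_trace

__all__ = ["ComparisonReport", "corrcoef", "positive_error_fraction", "compare_traces"]


@dataclass
class ComparisonReport:
    pearson_r: float
    mean_squared_error: float
    positive_error_fraction: float
    n_bins_used: int
    decodable_fraction: float | None = None

    def to_json(self, **kw) -> str:
        return json.dumps(asdict(self), **kw)


def _as_values(x) -> np.ndarray:
    return x.values if isinstance(x, Trace) else np.asarray(x, dtype=float)


def _apply_mask(x, y, mask):
    xv, yv = _as_values(x), _as_values(y)
    if xv.shape != yv.shape:
        raise ValueError("traces must share one grid")
    if mask is None:
        mask = np.isfinite(xv) & np.isfinite(yv)
    else:
        mask = np.asarray(mask, dtype=bool) & np.isfinite(xv) & np.isfinite(yv)
    return xv[mask], yv[mask]


def corrcoef(x, y, mask=None) -> float:
    """Pearson correlation over unmasked bins; invariant under affine
    rescaling of either argument.  Undefined (ValueError) for fewer than two
    bins or zero variance."""
    xv, yv = _apply_mask(x, y, mask)
    if xv.size < 2:
        raise ValueError("need at least two unmasked bins")
    if xv.std() == 0 or yv.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    return float(np.corrcoef(xv, yv)[0, 1])


def positive_error_fraction(theory, reference, mask=None) -> float:
    """Fraction of unmasked bins where theory exceeds the reference,
    excluding exact ties.  An unbiased theory against a noisy reference
    gives 0.5."""
    tv, rv = _apply_mask(theory, reference, mask)
    diff = tv - rv
    nonties = diff != 0
    if not np.any(nonties):
        raise ValueError("all bins are ties; positive-error fraction undefined")
    return float((diff[nonties] > 0).mean())


def mean_squared_error(x, y, mask=None) -> float:
    xv, yv = _apply_mask(x, y, mask)
    return float(np.mean((xv - yv) ** 2))


def compare_traces(
    theory: Trace,
    reference: Trace,
    mask=None,
    window: float | None = None,
    decodable_fraction: float | None = None,
) -> ComparisonReport:
    """Full report; if ``window`` is given the theory trace is smoothed with
    the same moving average as the reference PSTH first."""
    if window is not None:
        theory = smooth_trace(theory, window)
    tv, rv = _apply_mask(theory, reference, mask)
    return ComparisonReport(
        pearson_r=corrcoef(tv, rv),
        mean_squared_error=float(np.mean((tv - rv) ** 2)),
        positive_error_fraction=positive_error_fraction(tv, rv),
        n_bins_used=int(tv.size),
        decodable_fraction=decodable_fraction,
    )
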