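"""Gompertz growth phenotyping of OD600 time series.

Microplate growth at near-freezing temperature (4 degC) is quantified by
fitting the log-ratio signal y = ln(OD_t / OD_0) to the reparameterized
Gompertz model of Zwietering:

    y(t) = D * exp(-exp(mumax * e / D * (lam - t) + 1))

with D = ln(OD_inf / OD_0) the asymptotic log fold-change (dimensionless),
mumax the maximum specific growth rate (h^-1) and lam the lag phase (h).
Segregants are then assigned to extreme pools by strict mumax thresholds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "GrowthCurve",
    "GompertzFit",
    "Pool",
    "PoolAssignment",
    "gompertz",
    "log_transform",
    "fit_gompertz",
    "fit_curve",
    "select_extreme_pools",
]

_E = np.e

#: parameter bounds used during fitting: physically plausible microplate ranges
D_BOUNDS = (1e-9, 10.0)
MUMAX_BOUNDS = (1e-9, 1.0)


@dataclass(frozen=True)
class GrowthCurve:
    """An OD600 time series with its blank (uninoculated-well) background."""

    times: np.ndarray  # hours, strictly increasing
    od: np.ndarray
    blank_od: np.ndarray | float = 0.0

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        if t.ndim != 1 or t.shape != od.shape:
            raise ValueError("times and od must be 1-D arrays of equal length")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "od", od)

    def corrected(self) -> np.ndarray:
        """Blank-subtracted OD readings."""
        return self.od - np.asarray(self.blank_od, dtype=float)


@dataclass(frozen=True)
class GompertzFit:
    D: float
    mumax: float
    lam: float
    rss: float
    converged: bool

    def predict(self, t: np.ndarray) -> np.ndarray:
        return gompertz(np.asarray(t, dtype=float), self.D, self.mumax, self.lam)


class Pool(str, Enum):
    HIGH = "HIGH"
    LOW = "LOW"
    NEITHER = "NEITHER"


@dataclass(frozen=True)
class PoolAssignment:
    """Per-segregant pool labels under strict mumax thresholds."""

    labels: dict[str, Pool]
    hi_threshold: float
    lo_threshold: float

    def members(self, pool: Pool) -> list[str]:
        return [k for k, v in self.labels.items() if v is pool]

    @property
    def counts(self) -> dict[Pool, int]:
        out = {p: 0 for p in Pool}
        for v in self.labels.values():
            out[v] += 1
        return out


def gompertz(t: np.ndarray, D: float, mumax: float, lam: float) -> np.ndarray:
    """Reparameterized Gompertz curve y(t); y is ln(OD_t/OD_0)."""
    return D * np.exp(-np.exp(mumax * _E / D * (lam - t) + 1.0))


def log_transform(curve: GrowthCurve) -> tuple[np.ndarray, np.ndarray]:
    """Blank-correct and convert a curve to (t, y) with y = ln(OD_t/OD_0).

    OD_0 is the first blank-corrected reading, so y at the first retained
    point is exactly zero. Points with non-positive corrected OD are dropped
    with a warning; a series with no usable points is an error.
    """
    od_c = curve.corrected()
    keep = od_c > 0
    if not keep.all():
        warnings.warn(
            f"dropped {int((~keep).sum())} non-positive blank-corrected OD readings",
            stacklevel=2,
        )
    if not keep.any():
        raise ValueError("no positive blank-corrected OD readings")
    t = curve.times[keep]
    od_c = od_c[keep]
    y = np.log(od_c / od_c[0])
    return t, y


def _initial_guess(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Tangent-line heuristic: D from the plateau, mumax from the steepest
    finite difference, lam from where that tangent crosses y = 0."""
    d0 = max(float(np.max(y)), 1e-3)
    dy = np.diff(y) / np.diff(t)
    k = int(np.argmax(dy))
    mu0 = max(float(dy[k]), 1e-6)
    # time where y first clears 5% of the plateau, pulled back along the tangent
    above = np.flatnonzero(y > 0.05 * d0)
    t_rise = float(t[above[0]]) if above.size else float(t[k])
    lam0 = float(np.clip(t_rise - y[min(k, len(y) - 1)] / mu0, 0.0, t[-1]))
    return d0, mu0, lam0


def fit_gompertz(t: np.ndarray, y: np.ndarray) -> GompertzFit:
    """Nonlinear least-squares fit of the Gompertz model to (t, y).

    A flat (non-growing) series — all y within numerical noise of zero, the
    "only grew slightly" case — returns a non-converged fit with mumax 0
    rather than an arbitrary optimizer artefact. Optimizer failure returns
    the best iterate with ``converged=False``.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t.size < 6:
        raise ValueError("need at least 6 timepoints to fit")
    if np.ptp(y) < 1e-9 or np.max(y) <= 0:
        return GompertzFit(D=0.0, mumax=0.0, lam=0.0, rss=float(np.sum(y**2)), converged=False)

    x0 = np.array(_initial_guess(t, y))
    lo = np.array([D_BOUNDS[0], MUMAX_BOUNDS[0], 0.0])
    hi = np.array([D_BOUNDS[1], MUMAX_BOUNDS[1], float(t[-1])])
    x0 = np.clip(x0, lo, hi)

    def resid(p: np.ndarray) -> np.ndarray:
        return gompertz(t, *p) - y

    try:
        res = least_squares(resid, x0, bounds=(lo, hi), xtol=1e-14, ftol=1e-14, gtol=1e-14)
    except Exception:
        return GompertzFit(*x0, rss=float(np.sum(resid(x0) ** 2)), converged=False)
    D, mumax, lam = res.x
    return GompertzFit(
        D=float(D),
        mumax=float(mumax),
        lam=float(lam),
        rss=float(2 * res.cost),
        converged=bool(res.success),
    )


def fit_curve(curve: GrowthCurve) -> GompertzFit:
    """Convenience: blank-correct, log-transform and fit in one call."""
    return fit_gompertz(*log_transform(curve))


def select_extreme_pools(
    fits: dict[str, GompertzFit | float],
    hi_threshold: float = 0.0135,
    lo_threshold: float = 0.0030,
) -> PoolAssignment:
    """Partition segregants into HIGH / LOW / NEITHER by mumax.

    Defaults are the study thresholds: superior segregants have
    mumax > 0.0135 h^-1, inferior ones mumax < 0.0030 h^-1. Inequalities are
    strict, so a value exactly at a threshold falls to NEITHER.
    """
    if hi_threshold <= lo_threshold:
        raise ValueError("hi_threshold must exceed lo_threshold")
    labels: dict[str, Pool] = {}
    for name, fit in fits.items():
        mu = fit.mumax if isinstance(fit, GompertzFit) else float(fit)
        if mu > hi_threshold:
            labels[name] = Pool.HIGH
        elif mu < lo_threshold:
            labels[name] = Pool.LOW
        else:
            labels[name] = Pool.NEITHER
    return PoolAssignment(labels=labels, hi_threshold=hi_threshold, lo_threshold=lo_threshold)
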