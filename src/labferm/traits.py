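"""Growth-trait extraction from simulated batch trajectories.

Implements the quantities a microbiologist reads off a growth curve: the
specific growth rate (log-phase slope of ln X), the lag time, the observed
growth yield, the volumetric lactic-acid productivity, and the Pirt
maintenance-energy decomposition 1/Y = 1/Y_G + m/mu.

Derivative-based quantities use centred finite differences smoothed over a
5-point moving window; trajectories are dense (default dt = 0.01 h) and the
model is smooth, so the window only suppresses float noise.  The "log phase"
is operationalised as the neighbourhood of the maximum of d(ln X)/dt, which
makes the extraction reproducible without a user-marked interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, NamedTuple, Sequence

import numpy as np

from .simulate import Trajectory

__all__ = [
    "GrowthTraits",
    "PirtFit",
    "ProductivitySeries",
    "InsufficientDataError",
    "DegenerateCurveError",
    "UndefinedYieldError",
    "specific_growth_rate",
    "lag_time",
    "growth_yield",
    "productivity",
    "pirt_fit",
    "extract_traits",
]

SMOOTH_WINDOW = 5
MIN_POINTS = 7
YIELD_CUTOFF_FRACTION = 0.01  # yield evaluated when S first drops below 1% of S0


class InsufficientDataError(ValueError):
    """Trajectory has too few points for derivative-based extraction."""


class DegenerateCurveError(ValueError):
    """Growth curve lacks the feature being extracted (e.g. no dX/dt peak)."""


class UndefinedYieldError(ValueError):
    """No measurable substrate consumption, so yield is undefined."""


class ProductivitySeries(NamedTuple):
    """Volumetric productivity P(t) = (A(t) - A0)/t on the grid (t > 0)."""

    times: np.ndarray
    values: np.ndarray
    t_max: float
    p_max: float


@dataclass(frozen=True)
class GrowthTraits:
    """Derived growth quantities for one trajectory."""

    mu: float  # specific growth rate, 1/h
    lag: float  # lag time, h
    Y: float  # observed growth yield, g biomass / g substrate
    productivity_series: ProductivitySeries
    final_productivity: float | None = None  # at a caller-stated cutoff, if any


@dataclass(frozen=True)
class PirtFit:
    """Least-squares line of 1/Y against 1/mu.

    ``m`` (slope) is the maintenance-energy coefficient, g substrate /
    (g biomass h); ``YG_inv`` (intercept) is 1/Y_G, the inverse theoretical
    growth yield.  ``local_slopes`` are consecutive pairwise slopes exposing
    any substrate dependence of m within the regime.
    """

    m: float
    YG_inv: float
    regime_points: np.ndarray  # columns (1/mu, 1/Y)
    regime_label: str
    local_slopes: np.ndarray


def _smooth(y: np.ndarray, window: int = SMOOTH_WINDOW) -> np.ndarray:
    if len(y) < window:
        return y
    kernel = np.ones(window) / window
    out = np.convolve(y, kernel, mode="same")
    # fix edge attenuation from zero padding
    norm = np.convolve(np.ones_like(y), kernel, mode="same")
    return out / norm


def _check_length(traj: Trajectory) -> None:
    if len(traj) < MIN_POINTS:
        raise InsufficientDataError(
            f"need >= {MIN_POINTS} grid points, got {len(traj)}"
        )


def specific_growth_rate(traj: Trajectory) -> float:
    """Log-phase specific growth rate mu = max of smoothed d(ln X)/dt, 1/h."""
    _check_length(traj)
    dlnX = np.gradient(np.log(traj.X), traj.times)
    return float(np.max(_smooth(dlnX)))


def lag_time(
    traj: Trajectory,
    method: Literal["derivative-peak", "tangent"] = "derivative-peak",
) -> float:
    """Lag time of the growth curve, h.

    ``derivative-peak`` (default): the time at which the finite-difference
    biomass rate dX/dt attains its maximum.  ``tangent``: the classical
    construction — the tangent to ln X at its steepest point is extended back
    to the inoculum level ln X0; the intercept time is the lag.
    """
    _check_length(traj)
    t = traj.times
    if method == "derivative-peak":
        dX = _smooth(np.gradient(traj.X, t))
        i = int(np.argmax(dX))
        # guard against float noise on a flat curve
        flat_tol = 1e-12 * float(np.max(traj.X)) / (t[-1] - t[0])
        if i == 0 or i == len(t) - 1 or dX[i] <= flat_tol:
            raise DegenerateCurveError("dX/dt has no interior maximum")
        return float(t[i])
    if method == "tangent":
        lnX = np.log(traj.X)
        dlnX = _smooth(np.gradient(lnX, t))
        i = int(np.argmax(dlnX))
        mu = dlnX[i]
        flat_tol = 1e-12 * max(float(np.max(np.abs(lnX))), 1.0) / (t[-1] - t[0])
        if mu <= flat_tol:
            raise DegenerateCurveError("non-growing curve: d(ln X)/dt <= 0")
        lag = t[i] - (lnX[i] - lnX[0]) / mu
        return float(max(lag, 0.0))
    raise ValueError(f"unknown lag method {method!r}")


def growth_yield(traj: Trajectory) -> float:
    """Observed growth yield Y = (X_end - X0)/(S0 - S_end).

    Evaluated at the first time S falls below 1% of S0, or at the end of the
    trajectory, whichever is earlier.
    """
    S0, X0 = traj.init.S0, traj.init.X0
    below = np.nonzero(traj.S < YIELD_CUTOFF_FRACTION * S0)[0]
    i = int(below[0]) if below.size else len(traj) - 1
    consumed = S0 - traj.S[i]
    if consumed <= 1e-6:
        raise UndefinedYieldError(
            f"substrate consumption {consumed:.3g} g/dm3 too small for a yield"
        )
    return float((traj.X[i] - X0) / consumed)


def productivity(traj: Trajectory) -> ProductivitySeries:
    """Volumetric productivity series P(t) = (A(t) - A0)/t, g/(dm3 h)."""
    mask = traj.times > 0
    t = traj.times[mask]
    P = (traj.A[mask] - traj.init.A0) / t
    if t.size == 0:
        return ProductivitySeries(t, P, float("nan"), float("nan"))
    i = int(np.argmax(P))
    return ProductivitySeries(t, P, float(t[i]), float(P[i]))


def pirt_fit(
    mu: Sequence[float],
    Y: Sequence[float],
    regime_label: str = "",
) -> PirtFit:
    """Fit the Pirt relation 1/Y = 1/Y_G + m/mu by ordinary least squares.

    Parameters are pairs of (specific growth rate, observed yield) from runs
    at different initial substrate concentrations within one regime (below or
    above the critical concentration Sc).
    """
    mu = np.asarray(mu, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if mu.size < 3 or np.unique(mu).size < 3:
        raise ValueError("need >= 3 points with distinct mu")
    x = 1.0 / mu
    y = 1.0 / Y
    if np.ptp(x) < 1e-12:
        raise ValueError("degenerate points: 1/mu values are collinear")
    slope, intercept = np.polyfit(x, y, 1)
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    local = np.diff(ys) / np.diff(xs)
    return PirtFit(
        m=float(slope),
        YG_inv=float(intercept),
        regime_points=np.column_stack([x, y]),
        regime_label=regime_label,
        local_slopes=local,
    )


def extract_traits(
    traj: Trajectory,
    lag_method: Literal["derivative-peak", "tangent"] = "derivative-peak",
    cutoff_time: float | None = None,
) -> GrowthTraits:
    """All scalar traits of one trajectory; productivity at ``cutoff_time`` if given."""
    series = productivity(traj)
    final_p = None
    if cutoff_time is not None:
        if cutoff_time <= 0:
            raise ValueError("cutoff_time must be > 0")
        final_p = float(
            np.interp(cutoff_time, series.times, series.values)
        )
    return GrowthTraits(
        mu=specific_growth_rate(traj),
        lag=lag_time(traj, lag_method),
        Y=growth_yield(traj),
        productivity_series=series,
        final_productivity=final_p,
    )
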