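"""Prediction scans over culture conditions.

Sweeps of initial substrate concentration S0, inoculum physiological state Q0
and inoculum size X0, each point simulated to stationarity and reduced to its
growth traits.  The S0 scan locates the critical substrate concentration Sc —
the S0 at which the specific growth rate peaks — by a 3-point parabolic
refinement around the grid argmax, matching the 0.1 g/dm3 precision at which
Sc is conventionally reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .kinetics import ModelParameters
from .simulate import (
    DEFAULT_DT,
    STATIONARY_T_CAP,
    STATIONARY_TOL,
    InitialConditions,
    simulate_to_stationarity,
)
from .traits import extract_traits

__all__ = [
    "ScanResult",
    "scan_S0",
    "scan_Q0",
    "scan_X0",
    "matched_rate_pair",
    "DEFAULT_S0_GRID",
]

#: default S0 grid: 0.5-80 g/dm3, 160 points (union of the plotted ranges)
DEFAULT_S0_GRID = np.linspace(0.5, 80.0, 160)

TRAITS_COLUMNS = [
    "S0", "Q0", "X0", "mu_1_per_h", "lag_h", "Y",
    "max_productivity", "argmax_t_h",
]


@dataclass(frozen=True)
class ScanResult:
    """Traits per grid point of a one-axis sweep.

    ``traits`` has one row per condition (columns ``S0, Q0, X0, mu_1_per_h,
    lag_h, Y, max_productivity, argmax_t_h``).  ``Sc`` is the refined argmax
    of mu over S0 when the swept axis is S0 (None otherwise); for grouped
    scans (X0 sweep) ``Sc_by_group`` maps group value to its Sc.
    """

    axis: str
    grid: np.ndarray
    traits: pd.DataFrame
    Sc: float | None = None
    Sc_by_group: dict | None = None
    meta: dict = field(default_factory=dict)

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# labferm scan axis={self.axis}\n")
            if self.Sc is not None:
                fh.write(f"# Sc_g_per_dm3={self.Sc:.6g}\n")
            if self.Sc_by_group:
                pairs = ",".join(f"{k:g}:{v:.6g}" for k, v in self.Sc_by_group.items())
                fh.write(f"# Sc_by_group={pairs}\n")
            self.traits.to_csv(fh, index=False)


def _validate_grid(grid: np.ndarray, name: str) -> np.ndarray:
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or np.any(np.diff(grid) <= 0):
        raise ValueError(f"{name} grid must be 1-D and strictly increasing")
    return grid


def _traits_row(params, S0, Q0, X0, dt, lag_method) -> dict:
    traj = simulate_to_stationarity(
        params, InitialConditions(S0=S0, Q0=Q0, X0=X0, A0=0.0), dt=dt,
        rate_tol=STATIONARY_TOL, t_cap=STATIONARY_T_CAP,
    )
    tr = extract_traits(traj, lag_method=lag_method)
    return {
        "S0": S0, "Q0": Q0, "X0": X0,
        "mu_1_per_h": tr.mu, "lag_h": tr.lag, "Y": tr.Y,
        "max_productivity": tr.productivity_series.p_max,
        "argmax_t_h": tr.productivity_series.t_max,
    }


def _refine_argmax(x: np.ndarray, y: np.ndarray) -> float:
    """Parabolic refinement of the grid argmax; falls back to the grid point
    at the hull boundary."""
    i = int(np.argmax(y))
    if i == 0 or i == len(x) - 1:
        return float(x[i])
    x0, x1, x2 = x[i - 1], x[i], x[i + 1]
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = (x0 - x1) * (x0 - x2) * (x1 - x2)
    a = (x2 * (y1 - y0) + x1 * (y0 - y2) + x0 * (y2 - y1)) / denom
    b = (x2**2 * (y0 - y1) + x1**2 * (y2 - y0) + x0**2 * (y1 - y2)) / denom
    if a >= 0:  # flat or degenerate parabola
        return float(x1)
    xv = -b / (2 * a)
    return float(np.clip(xv, x0, x2))


def scan_S0(
    params: ModelParameters,
    Q0: float,
    X0: float,
    grid: Sequence[float] = DEFAULT_S0_GRID,
    dt: float = DEFAULT_DT,
    lag_method: str = "derivative-peak",
) -> ScanResult:
    """Sweep initial substrate concentration and locate Sc.

    Each S0 on the grid is simulated to stationarity; mu, lag, yield and
    productivity are extracted per point; Sc is the parabola-refined argmax
    of mu(S0).
    """
    grid = _validate_grid(grid, "S0")
    rows = [_traits_row(params, S0, Q0, X0, dt, lag_method) for S0 in grid]
    df = pd.DataFrame(rows, columns=TRAITS_COLUMNS)
    Sc = _refine_argmax(grid, df["mu_1_per_h"].to_numpy())
    return ScanResult(axis="S0", grid=grid, traits=df, Sc=Sc,
                      meta={"Q0": Q0, "X0": X0, "dt": dt})


def scan_Q0(
    params: ModelParameters,
    S0: float,
    X0: float,
    grid: Sequence[float],
    dt: float = DEFAULT_DT,
    lag_method: str = "derivative-peak",
) -> ScanResult:
    """Sweep the inoculum physiological state Q0 at fixed S0 and X0."""
    grid = _validate_grid(grid, "Q0")
    rows = [_traits_row(params, S0, Q0, X0, dt, lag_method) for Q0 in grid]
    df = pd.DataFrame(rows, columns=TRAITS_COLUMNS)
    return ScanResult(axis="Q0", grid=grid, traits=df,
                      meta={"S0": S0, "X0": X0, "dt": dt})


def scan_X0(
    params: ModelParameters,
    Q0: float,
    S0_grid: Sequence[float],
    X0_grid: Sequence[float],
    dt: float = DEFAULT_DT,
    lag_method: str = "derivative-peak",
) -> ScanResult:
    """Sweep inoculum size: for each X0 in ``X0_grid``, sweep S0 and locate Sc.

    Returns one row per (X0, S0) pair and a per-X0 map of Sc values, which
    exposes how increasing inoculum size flattens the substrate-inhibition
    bell.
    """
    S0_grid = _validate_grid(S0_grid, "S0")
    X0_grid = _validate_grid(X0_grid, "X0")
    rows = []
    Sc_by = {}
    for X0 in X0_grid:
        block = [_traits_row(params, S0, Q0, X0, dt, lag_method) for S0 in S0_grid]
        mu = np.array([r["mu_1_per_h"] for r in block])
        Sc_by[float(X0)] = _refine_argmax(S0_grid, mu)
        rows.extend(block)
    df = pd.DataFrame(rows, columns=TRAITS_COLUMNS)
    return ScanResult(axis="X0", grid=X0_grid, traits=df, Sc_by_group=Sc_by,
                      meta={"Q0": Q0, "dt": dt})


def matched_rate_pair(
    scan: ScanResult,
    mu_fraction: float = 0.9,
) -> tuple[float, float]:
    """Find S0_L < Sc < S0_H with equal specific growth rate on a bell curve.

    Given an S0 scan whose mu(S0) is bell-shaped, returns the two initial
    substrate concentrations (one on each side of the peak) at which mu equals
    ``mu_fraction`` times the peak value, located by linear interpolation on
    the scan grid.  Cells inoculated at S0_H grow at the same rate as at S0_L
    but after a much longer lag — the hallmark of substrate inhibition.
    """
    if scan.axis != "S0":
        raise ValueError("matched_rate_pair needs an S0 scan")
    S0 = scan.traits["S0"].to_numpy()
    mu = scan.traits["mu_1_per_h"].to_numpy()
    i_pk = int(np.argmax(mu))
    if i_pk == 0 or i_pk == len(S0) - 1:
        raise ValueError("mu(S0) is monotone on this grid; no bell to match")
    target = mu_fraction * mu[i_pk]
    left = mu[: i_pk + 1]
    right = mu[i_pk:]
    if target < left.min() or target < right.min():
        raise ValueError(
            f"target rate {target:.3g} not attained on both flanks; "
            "raise mu_fraction or widen the grid"
        )
    # left flank: mu increasing; right flank: mu decreasing
    S_L = float(np.interp(target, left, S0[: i_pk + 1]))
    S_H = float(np.interp(target, right[::-1], S0[i_pk:][::-1]))
    return S_L, S_H
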