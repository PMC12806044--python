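"""Time integration of the batch-fermentation ODE system.

Two integrators are provided:

* :func:`simulate` — forward Euler on a uniform grid, the reference numerical
  method of the model.  The substrate update uses the substituted form of the
  balance equation, so the mass-balance identity

      S0 - S(t) = (X(t) - X0)/gamma_XS + (A(t) - A0)/gamma_AS

  is preserved exactly (to float roundoff) at every grid point.
* :func:`simulate_adaptive` — an adaptive, high-accuracy integrator
  (``scipy.integrate.solve_ivp``) used as an independent cross-check of the
  Euler trajectories, resampled onto the same uniform grid.

Substrate exhaustion is handled by clamping: when an Euler step would drive S
below zero, the step is shortened so that S lands exactly on zero (biomass and
product updates scaled by the same fraction, rates evaluated pre-step), and
from then on only the physiological state Q continues to evolve
(f_Q(0) = 1, so dQ/dt = nu*Q).  Death phase is out of scope.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from numba import njit
from scipy.integrate import solve_ivp

from .kinetics import BatchState, InvalidStateError, ModelParameters

__all__ = [
    "InitialConditions",
    "Trajectory",
    "IntegrationError",
    "simulate",
    "simulate_adaptive",
    "simulate_to_stationarity",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = ["time_h", "S_g_per_dm3", "Q", "X_g_per_dm3", "A_g_per_dm3"]

#: default Euler step, h
DEFAULT_DT = 0.01
#: stationarity threshold on dX/dt, g/(dm3 h), and hard time cap, h
STATIONARY_TOL = 1e-6
STATIONARY_T_CAP = 200.0


class IntegrationError(RuntimeError):
    """Integration failure (non-finite state or irrecoverable step)."""


@dataclass(frozen=True)
class InitialConditions:
    """Initial culture composition: S0, A0 >= 0 and Q0, X0 > 0 (g/dm3; Q0 dimensionless)."""

    S0: float
    Q0: float
    X0: float
    A0: float = 0.0

    def __post_init__(self) -> None:
        BatchState(self.S0, self.Q0, self.X0, self.A0).validate()
        if self.Q0 <= 0 or self.X0 <= 0:
            raise InvalidStateError(
                f"Q0 and X0 must be > 0, got Q0={self.Q0}, X0={self.X0}"
            )

    def as_state(self) -> BatchState:
        return BatchState(self.S0, self.Q0, self.X0, self.A0)


@njit(cache=False)
def _euler_core(
    mu_max, nu, K_S, K_Q, K_I, n_Q, n_A, alpha, beta, g_XS, g_AS,
    S0, Q0, X0, A0, n_steps, dt, stop_tol,
):  # pragma: no cover - exercised through simulate()
    S = np.empty(n_steps + 1)
    Q = np.empty(n_steps + 1)
    X = np.empty(n_steps + 1)
    A = np.empty(n_steps + 1)
    S[0], Q[0], X[0], A[0] = S0, Q0, X0, A0
    c_X = 1.0 / g_XS + alpha / g_AS
    c_B = beta / g_AS
    peak_rate = 0.0
    n_used = n_steps
    status = 0
    for i in range(n_steps):
        s, q, x, a = S[i], Q[i], X[i], A[i]
        if s > 0.0:
            f_Q = 1.0 / (1.0 + (s / K_Q) ** n_Q)
            mu = mu_max * (q / (1.0 + q)) * (s / (K_S + s)) / (1.0 + (a / K_I) ** n_A)
            dX = mu * x
            dQ = nu * f_Q * q
            dA = alpha * dX + beta * x
            dS = -c_X * dX - c_B * x
            s_new = s + dt * dS
            if s_new < 0.0:
                # shorten the step so S lands exactly on zero, scaling the
                # biomass/product updates by the same fraction (pre-step rates)
                theta = s / (-dS * dt)
                S[i + 1] = 0.0
                Q[i + 1] = q + dt * dQ
                X[i + 1] = x + theta * dt * dX
                A[i + 1] = a + theta * dt * dA
            else:
                S[i + 1] = s_new
                Q[i + 1] = q + dt * dQ
                X[i + 1] = x + dt * dX
                A[i + 1] = a + dt * dA
        else:
            # substrate exhausted: only the physiological state evolves
            dX = 0.0
            S[i + 1] = 0.0
            Q[i + 1] = q + dt * nu * q
            X[i + 1] = x
            A[i + 1] = a
        if not (
            np.isfinite(S[i + 1])
            and np.isfinite(Q[i + 1])
            and np.isfinite(X[i + 1])
            and np.isfinite(A[i + 1])
        ):
            n_used = i + 1
            status = 1
            break
        rate = dX
        if rate > peak_rate:
            peak_rate = rate
        if stop_tol > 0.0 and rate < stop_tol and rate < peak_rate:
            n_used = i + 1
            status = 2
            break
    return S, Q, X, A, n_used, status


def _params_tuple(p: ModelParameters):
    return (
        p.mu_max, p.nu, p.K_S, p.K_Q, p.K_I, p.n_Q, p.n_A,
        p.alpha, p.beta, p.gamma_XS, p.gamma_AS,
    )


@dataclass(frozen=True)
class Trajectory:
    """A simulated batch time course on a uniform grid.

    Attributes
    ----------
    times : ndarray
        Strictly increasing time grid starting at 0, h.
    S, Q, X, A : ndarray
        State series in canonical order (substrate, physiological state,
        biomass, lactic acid).
    params : ModelParameters
        Parameter set used for the run.
    init : InitialConditions
    meta : dict
        Integrator name, step size, and any caller-supplied annotations.
    """

    times: np.ndarray
    S: np.ndarray
    Q: np.ndarray
    X: np.ndarray
    A: np.ndarray
    params: ModelParameters
    init: InitialConditions
    meta: dict

    def __post_init__(self) -> None:
        t = np.asarray(self.times)
        if t.ndim != 1 or t[0] != 0.0 or (len(t) > 1 and np.any(np.diff(t) <= 0)):
            raise InvalidStateError("times must be strictly increasing and start at 0")

    def __len__(self) -> int:
        return len(self.times)

    def state_at(self, i: int) -> BatchState:
        return BatchState(self.S[i], self.Q[i], self.X[i], self.A[i])

    def mass_balance_residual(self) -> np.ndarray:
        """Pointwise residual of the substrate balance identity (g/dm3)."""
        p, ic = self.params, self.init
        return (
            ic.S0
            - self.S
            - (self.X - ic.X0) / p.gamma_XS
            - (self.A - ic.A0) / p.gamma_AS
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_h": self.times,
                "S_g_per_dm3": self.S,
                "Q": self.Q,
                "X_g_per_dm3": self.X,
                "A_g_per_dm3": self.A,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        """Write the trajectory with a metadata header; round-trips bit-exactly."""
        path = Path(path)
        header = {
            "params": self.params.to_dict(),
            "init": vars(self.init),
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            fh.write("# labferm trajectory\n")
            fh.write("# " + json.dumps(header) + "\n")
            fh.write(",".join(TRAJECTORY_COLUMNS) + "\n")
            for i in range(len(self)):
                fh.write(
                    "%.17g,%.17g,%.17g,%.17g,%.17g\n"
                    % (self.times[i], self.S[i], self.Q[i], self.X[i], self.A[i])
                )

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        header = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("# {"):
                    header = json.loads(line[2:])
                if not line.startswith("#"):
                    break
        if header is None:
            raise ValueError(f"{path} lacks a labferm trajectory header")
        df = pd.read_csv(path, comment="#", float_precision="round_trip")
        return cls(
            times=df["time_h"].to_numpy(),
            S=df["S_g_per_dm3"].to_numpy(),
            Q=df["Q"].to_numpy(),
            X=df["X_g_per_dm3"].to_numpy(),
            A=df["A_g_per_dm3"].to_numpy(),
            params=ModelParameters(**header["params"]),
            init=InitialConditions(**header["init"]),
            meta=header["meta"],
        )


def _finish(params, init, dt, t, S, Q, X, A, integrator, extra_meta=None) -> Trajectory:
    meta = {"integrator": integrator, "dt": dt}
    if extra_meta:
        meta.update(extra_meta)
    return Trajectory(
        times=t, S=S, Q=Q, X=X, A=A, params=params, init=init, meta=meta
    )


def simulate(
    params: ModelParameters,
    init: InitialConditions,
    t_end: float,
    dt: float = DEFAULT_DT,
    _stop_tol: float = 0.0,
) -> Trajectory:
    """Integrate the model by forward Euler on a uniform grid.

    Parameters
    ----------
    params, init : model parameters and initial conditions.
    t_end : float
        Final time, h.  ``t_end = 0`` returns a single-point trajectory.
    dt : float
        Euler step, h (default 0.01).  Must be well below the characteristic
        times 1/mu_max and 1/nu.

    Raises
    ------
    IntegrationError
        If the state becomes non-finite; the message names the offending time.
    """
    if t_end < 0 or dt <= 0:
        raise ValueError("t_end must be >= 0 and dt > 0")
    init.as_state().validate()
    n_steps = int(math.ceil(t_end / dt - 1e-9)) if t_end > 0 else 0
    if n_steps == 0:
        t = np.zeros(1)
        return _finish(
            params, init, dt, t,
            np.array([init.S0]), np.array([init.Q0]),
            np.array([init.X0]), np.array([init.A0]),
            "euler",
        )
    S, Q, X, A, n_used, status = _euler_core(
        *_params_tuple(params),
        init.S0, init.Q0, init.X0, init.A0,
        n_steps, dt, _stop_tol,
    )
    if status == 1:
        raise IntegrationError(
            f"non-finite state at t = {n_used * dt:.4g} h; "
            f"reduce dt (currently {dt} h) or check parameters"
        )
    n = n_used
    t = np.arange(n + 1) * dt
    return _finish(params, init, dt, t, S[: n + 1], Q[: n + 1], X[: n + 1], A[: n + 1], "euler")


def simulate_to_stationarity(
    params: ModelParameters,
    init: InitialConditions,
    dt: float = DEFAULT_DT,
    rate_tol: float = STATIONARY_TOL,
    t_cap: float = STATIONARY_T_CAP,
) -> Trajectory:
    """Integrate until biomass growth stalls (dX/dt < ``rate_tol`` past its
    peak) or ``t_cap`` is reached, whichever comes first."""
    traj = simulate(params, init, t_cap, dt, _stop_tol=rate_tol)
    return traj


def _rhs_np(t, y, p: ModelParameters):
    s, q, x, a = y
    s = max(s, 0.0)
    f_Q = 1.0 / (1.0 + (s / p.K_Q) ** p.n_Q)
    mu = (
        p.mu_max * (q / (1.0 + q)) * (s / (p.K_S + s))
        / (1.0 + (a / p.K_I) ** p.n_A)
    )
    dX = mu * x
    dQ = p.nu * f_Q * q
    dA = p.alpha * dX + p.beta * x
    dS = -(1.0 / p.gamma_XS + p.alpha / p.gamma_AS) * dX - (p.beta / p.gamma_AS) * x
    return (dS, dQ, dX, dA)


def simulate_adaptive(
    params: ModelParameters,
    init: InitialConditions,
    t_end: float,
    dt: float = DEFAULT_DT,
    rtol: float = 1e-9,
    atol: float = 1e-11,
) -> Trajectory:
    """High-accuracy adaptive reference integration, resampled to a uniform grid.

    Integrates with LSODA up to substrate exhaustion (event at S = 0), then
    continues analytically: S, X, A frozen and Q growing exponentially at rate
    nu (f_Q(0) = 1).  Used to validate the forward-Euler trajectories.
    """
    if t_end < 0 or dt <= 0:
        raise ValueError("t_end must be >= 0 and dt > 0")
    init.as_state().validate()
    n = int(math.ceil(t_end / dt - 1e-9)) if t_end > 0 else 0
    t_grid = np.arange(n + 1) * dt
    if n == 0:
        return _finish(
            params, init, dt, t_grid,
            np.array([init.S0]), np.array([init.Q0]),
            np.array([init.X0]), np.array([init.A0]),
            "lsoda",
        )

    def exhausted(t, y, p):
        return y[0] - 1e-12 * max(init.S0, 1.0)

    exhausted.terminal = True
    exhausted.direction = -1

    sol = solve_ivp(
        _rhs_np,
        (0.0, t_grid[-1]),
        [init.S0, init.Q0, init.X0, init.A0],
        args=(params,),
        method="LSODA",
        rtol=rtol,
        atol=atol,
        dense_output=True,
        events=exhausted,
    )
    if not sol.success:
        raise IntegrationError(f"adaptive solver failed: {sol.message}")
    y = np.empty((4, n + 1))
    if sol.t_events[0].size:
        t_ex = sol.t_events[0][0]
        before = t_grid <= t_ex
        y[:, before] = sol.sol(t_grid[before])
        y_ex = sol.y_events[0][0]
        after = ~before
        y[0, after] = 0.0
        y[1, after] = y_ex[1] * np.exp(params.nu * (t_grid[after] - t_ex))
        y[2, after] = y_ex[2]
        y[3, after] = y_ex[3]
        y[0, before & (y[0] < 0)] = 0.0
    else:
        y[:] = sol.sol(t_grid)
        y[0, y[0] < 0] = 0.0
    return _finish(params, init, dt, t_grid, y[0], y[1], y[2], y[3], "lsoda")
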