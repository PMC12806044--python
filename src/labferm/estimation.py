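"""Multi-condition parameter estimation for the two-pathway model.

The estimation problem mirrors how batch-fermentation kinetics are fitted in
practice: the ODE system is solved simultaneously from several initial
substrate concentrations with one shared parameter set, and the unweighted
sum of squared differences between simulated and measured substrate, biomass
and lactic-acid concentrations,

    F = sum_i (X(t_i)-X_E(t_i))^2 + (A(t_i)-A_E(t_i))^2 + (S(t_i)-S_E(t_i))^2,

is minimised over the eight quantities (mu_max, Q0, K_S, K_I, alpha, beta,
gamma_XS, gamma_AS).  The Hill exponents stay fixed (n_Q = 2, n_A = 5) and
the ties nu = mu_max, K_Q = K_S are maintained during the search.  Q0 is a
pseudo-parameter shared across datasets from the same inoculum.

The public surface follows the statsmodels idiom: build a
:class:`BatchFermentationModel` from experiment tables, call :meth:`fit`, and
read estimates, standard errors and diagnostics off the returned
:class:`FitResults` (``summary()`` prints the usual table).  Minimisation is
bounded trust-region nonlinear least squares (stacked residuals) with a
relative parameter-step tolerance of 1e-4 and a seeded Latin-hypercube
multi-start to guard against local minima.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetics import InvalidStateError, ModelParameters
from .simulate import (
    DEFAULT_DT,
    InitialConditions,
    IntegrationError,
    simulate,
)

__all__ = [
    "ExperimentTable",
    "BatchFermentationModel",
    "FitResults",
    "FitFailureError",
    "objective",
    "fit",
    "FIT_PARAMETER_NAMES",
    "DEFAULT_BOUNDS",
    "EXPERIMENT_COLUMNS",
]

logger = logging.getLogger(__name__)

EXPERIMENT_COLUMNS = ["time_h", "S_g_per_dm3", "X_g_per_dm3", "A_g_per_dm3"]
_OBS_MAP = {"S_g_per_dm3": "S", "X_g_per_dm3": "X", "A_g_per_dm3": "A"}

#: the eight searched quantities, in canonical order (Q0 is the shared
#: initial physiological state, a pseudo-parameter alongside the kinetic ones)
FIT_PARAMETER_NAMES = (
    "mu_max", "K_S", "K_I", "alpha", "beta", "gamma_XS", "gamma_AS", "Q0",
)

#: physically plausible default search bounds for LAB batch culture
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "mu_max": (0.01, 5.0),      # 1/h
    "K_S": (0.1, 200.0),        # g/dm3
    "K_I": (0.1, 200.0),        # g/dm3
    "alpha": (0.0, 20.0),       # g LA / g X
    "beta": (0.0, 5.0),         # g LA / (g X h)
    "gamma_XS": (0.01, 5.0),    # g X / g S
    "gamma_AS": (0.01, 5.0),    # g LA / g S
    "Q0": (0.01, 10.0),         # dimensionless
}

_PENALTY = 1e3  # residual magnitude substituted when a draw fails to integrate


class FitFailureError(RuntimeError):
    """All optimiser starts failed; carries per-start diagnostics."""

    def __init__(self, message: str, diagnostics: list | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


@dataclass(frozen=True)
class ExperimentTable:
    """One batch experiment: initial conditions plus a sparse observation table.

    ``observations`` has columns ``time_h, S_g_per_dm3, X_g_per_dm3,
    A_g_per_dm3``; any subset of the three observables may be missing (NaN)
    per row.  Times must be strictly increasing and non-negative, observed
    concentrations non-negative.
    """

    S0: float
    X0: float
    A0: float
    observations: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.observations
        missing = [c for c in EXPERIMENT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"observations missing columns {missing}")
        t = df["time_h"].to_numpy(dtype=float)
        if len(t) == 0:
            raise ValueError("observations must contain at least one row")
        if t[0] < 0 or np.any(np.diff(t) <= 0):
            raise ValueError("time_h must be strictly increasing and >= 0")
        for col in EXPERIMENT_COLUMNS[1:]:
            v = df[col].to_numpy(dtype=float)
            if np.any(v[np.isfinite(v)] < 0):
                raise ValueError(f"negative values in {col}")

    @property
    def n_observed(self) -> int:
        return int(
            self.observations[EXPERIMENT_COLUMNS[1:]].notna().to_numpy().sum()
        )

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = {"S0": self.S0, "X0": self.X0, "A0": self.A0,
                  "metadata": self.metadata}
        with open(path, "w") as fh:
            fh.write("# labferm experiment\n")
            fh.write("# " + json.dumps(header) + "\n")
            self.observations.to_csv(fh, index=False, columns=EXPERIMENT_COLUMNS)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExperimentTable":
        path = Path(path)
        header = None
        with open(path) as fh:
            for line in fh:
                if line.startswith("# {"):
                    header = json.loads(line[2:])
                if not line.startswith("#"):
                    break
        df = pd.read_csv(path, comment="#")
        if header is None:
            # headerless dialect: infer initial conditions from the t = 0 row
            row0 = df.iloc[0]
            if row0["time_h"] != 0:
                raise ValueError(
                    f"{path}: no metadata header and no t = 0 row to infer "
                    "initial conditions from"
                )
            header = {
                "S0": float(row0["S_g_per_dm3"]),
                "X0": float(row0["X_g_per_dm3"]),
                "A0": float(row0.get("A_g_per_dm3", 0.0) or 0.0),
                "metadata": {},
            }
        return cls(
            S0=header["S0"], X0=header["X0"], A0=header["A0"],
            observations=df[EXPERIMENT_COLUMNS].copy(),
            metadata=header.get("metadata", {}),
        )


def _residual_vector(
    params: ModelParameters,
    Q0: float,
    datasets: Sequence[ExperimentTable],
    dt: float,
    weights: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Stacked (simulated - observed) residuals over all datasets/observables."""
    chunks: list[np.ndarray] = []
    per_dataset: list[np.ndarray] = []
    for ds in datasets:
        t_obs = ds.observations["time_h"].to_numpy(dtype=float)
        try:
            init = InitialConditions(S0=ds.S0, Q0=Q0, X0=ds.X0, A0=ds.A0)
            traj = simulate(params, init, float(t_obs[-1]), dt)
        except (IntegrationError, InvalidStateError) as exc:
            logger.warning("simulation failed during fit (%s); penalising", exc)
            bad = np.full(ds.n_observed, _PENALTY)
            chunks.append(bad)
            per_dataset.append(bad)
            continue
        sim = {
            "S": np.interp(t_obs, traj.times, traj.S),
            "X": np.interp(t_obs, traj.times, traj.X),
            "A": np.interp(t_obs, traj.times, traj.A),
        }
        ds_chunks = []
        for col, key in _OBS_MAP.items():
            obs = ds.observations[col].to_numpy(dtype=float)
            mask = np.isfinite(obs)
            if not mask.any():
                continue
            r = sim[key][mask] - obs[mask]
            if weights is not None:
                r = r * weights.get(key, 1.0)
            ds_chunks.append(r)
        r_ds = np.concatenate(ds_chunks) if ds_chunks else np.empty(0)
        chunks.append(r_ds)
        per_dataset.append(r_ds)
    return np.concatenate(chunks), per_dataset


def objective(
    params: ModelParameters,
    Q0: float,
    datasets: Sequence[ExperimentTable],
    dt: float = DEFAULT_DT,
    weights: Mapping[str, float] | None = None,
) -> float:
    """The scalar least-squares objective F, (g/dm3)^2.

    Simulates each dataset from its own (S0, X0, A0) with the shared Q0,
    linearly interpolates the dense trajectory to the observation times, and
    accumulates unweighted squared differences over S, X and A.
    """
    r, _ = _residual_vector(params, Q0, datasets, dt, weights)
    return float(np.dot(r, r))


@dataclass(frozen=True)
class FitResults:
    """Estimates and diagnostics from :meth:`BatchFermentationModel.fit`.

    ``bse`` are Gauss-Newton standard errors from the residual Jacobian at
    the optimum (sigma^2 (J'J)^-1); NaN where a parameter sat at a bound or
    the information matrix is singular.
    """

    params: ModelParameters
    Q0: float
    F: float
    free_names: tuple[str, ...]
    theta: np.ndarray
    bse: dict[str, float]
    cov_params: np.ndarray | None
    n_obs: int
    n_iter: int
    converged: bool
    termination_reason: str
    n_starts: int
    start_costs: np.ndarray
    per_dataset_residuals: list[np.ndarray]
    fixed: dict[str, float]

    @property
    def estimates(self) -> dict[str, float]:
        d = {name: getattr(self.params, name) for name in FIT_PARAMETER_NAMES[:-1]}
        d["Q0"] = self.Q0
        return d

    def summary(self) -> str:
        lines = [
            "Two-pathway batch fermentation model — least-squares fit",
            "=" * 64,
            f"n observations: {self.n_obs:>6d}    objective F: {self.F:.6g} (g/dm3)^2",
            f"converged: {self.converged}    starts: {self.n_starts}    "
            f"func evals (best): {self.n_iter}",
            f"termination: {self.termination_reason}",
            "-" * 64,
            f"{'parameter':>10s} {'estimate':>12s} {'std err':>12s} {'status':>8s}",
        ]
        est = self.estimates
        for name in FIT_PARAMETER_NAMES:
            se = self.bse.get(name, float("nan"))
            status = "free" if name in self.free_names else "fixed"
            se_s = f"{se:12.4g}" if np.isfinite(se) else f"{'--':>12s}"
            lines.append(f"{name:>10s} {est[name]:12.6g} {se_s} {status:>8s}")
        lines.append("-" * 64)
        lines.append(
            f"ties: nu = mu_max = {self.params.nu:.6g}, "
            f"K_Q = K_S = {self.params.K_Q:.6g}; "
            f"n_Q = {self.params.n_Q:g}, n_A = {self.params.n_A:g} (fixed)"
        )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "bse": self.bse,
            "F": self.F,
            "free": list(self.free_names),
            "fixed": self.fixed,
            "n_obs": self.n_obs,
            "n_iter": self.n_iter,
            "converged": self.converged,
            "termination_reason": self.termination_reason,
            "n_starts": self.n_starts,
            "tied": {"nu": self.params.nu, "K_Q": self.params.K_Q},
            "hill": {"n_Q": self.params.n_Q, "n_A": self.params.n_A},
        }

    def save(self, path: str | Path) -> None:
        """Write a machine-readable JSON and a flat key=value sidecar."""
        path = Path(path)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
        flat = path.with_suffix(".txt")
        with open(flat, "w") as fh:
            for k, v in self.estimates.items():
                fh.write(f"{k} = {v:.10g}\n")
            fh.write(f"F = {self.F:.10g}\n")
            fh.write(f"converged = {self.converged}\n")


class BatchFermentationModel:
    """Two-pathway kinetic model bound to one or more batch experiments.

    Parameters
    ----------
    datasets : sequence of ExperimentTable
        Experiments fitted simultaneously with a shared parameter set and a
        shared initial physiological state Q0.
    free : sequence of str, optional
        Names from ``FIT_PARAMETER_NAMES`` to estimate.  Default: all eight.
    fixed : mapping, optional
        Name -> value for parameters held fixed (must cover the complement of
        ``free``).
    bounds : mapping, optional
        Name -> (lo, hi) overriding :data:`DEFAULT_BOUNDS`.
    dt : float
        Euler step used inside the objective, h.
    weighted : bool
        If True, residuals of each observable are divided by that
        observable's across-dataset RMS scale.  Off by default: the canonical
        objective is the plain unweighted sum of squares.

    Examples
    --------
    >>> model = BatchFermentationModel.from_csv(["s26.csv", "s43.csv"])
    >>> res = model.fit(seed=0)
    >>> print(res.summary())
    """

    def __init__(
        self,
        datasets: Sequence[ExperimentTable],
        free: Sequence[str] | None = None,
        fixed: Mapping[str, float] | None = None,
        bounds: Mapping[str, tuple[float, float]] | None = None,
        dt: float = DEFAULT_DT,
        weighted: bool = False,
    ):
        if not datasets:
            raise ValueError("need at least one dataset")
        self.datasets = list(datasets)
        fixed = dict(fixed or {})
        if free is None:
            free = [n for n in FIT_PARAMETER_NAMES if n not in fixed]
        unknown = (set(free) | set(fixed)) - set(FIT_PARAMETER_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter names {sorted(unknown)}")
        uncovered = set(FIT_PARAMETER_NAMES) - set(free) - set(fixed)
        if uncovered:
            raise ValueError(
                f"parameters neither free nor fixed: {sorted(uncovered)}"
            )
        self.free_names = tuple(n for n in FIT_PARAMETER_NAMES if n in set(free))
        self.fixed = fixed
        self.bounds = dict(DEFAULT_BOUNDS)
        self.bounds.update(bounds or {})
        self.dt = dt
        self.weighted = weighted
        self._weights = self._observable_weights() if weighted else None

    @classmethod
    def from_csv(cls, paths: Sequence[str | Path], **kwargs) -> "BatchFermentationModel":
        return cls([ExperimentTable.from_csv(p) for p in paths], **kwargs)

    @classmethod
    def from_dataframes(
        cls,
        frames: Sequence[tuple[pd.DataFrame, float, float, float]],
        **kwargs,
    ) -> "BatchFermentationModel":
        """Build from (observations, S0, X0, A0) tuples."""
        tables = [
            ExperimentTable(S0=S0, X0=X0, A0=A0, observations=df)
            for df, S0, X0, A0 in frames
        ]
        return cls(tables, **kwargs)

    # -- internal plumbing ---------------------------------------------------

    def _observable_weights(self) -> dict[str, float]:
        w = {}
        for col, key in _OBS_MAP.items():
            vals = np.concatenate(
                [ds.observations[col].to_numpy(dtype=float) for ds in self.datasets]
            )
            vals = vals[np.isfinite(vals)]
            rms = float(np.sqrt(np.mean(vals**2))) if vals.size else 1.0
            w[key] = 1.0 / rms if rms > 0 else 1.0
        return w

    def _theta_to_params(self, theta: np.ndarray) -> tuple[ModelParameters, float]:
        values = dict(self.fixed)
        values.update(dict(zip(self.free_names, theta)))
        Q0 = values.pop("Q0")
        # ties: nu follows mu_max, K_Q follows K_S
        return ModelParameters(**values), float(Q0)

    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        try:
            params, Q0 = self._theta_to_params(theta)
        except InvalidStateError:
            return np.full(self.n_obs, _PENALTY)
        r, _ = _residual_vector(params, Q0, self.datasets, self.dt, self._weights)
        return r

    @property
    def n_obs(self) -> int:
        return sum(ds.n_observed for ds in self.datasets)

    def objective(self, params: ModelParameters, Q0: float) -> float:
        return objective(params, Q0, self.datasets, self.dt, self._weights)

    def _starts(self, seed: int, n_starts: int, x0) -> np.ndarray:
        lo = np.array([self.bounds[n][0] for n in self.free_names])
        hi = np.array([self.bounds[n][1] for n in self.free_names])
        sampler = qmc.LatinHypercube(d=len(self.free_names), seed=seed)
        unit = sampler.random(n_starts)
        starts = qmc.scale(unit, lo, hi)
        if x0 is not None:
            x0 = np.asarray(
                [x0[n] if isinstance(x0, Mapping) else x0[i]
                 for i, n in enumerate(self.free_names)],
                dtype=float,
            )
            starts = np.vstack([x0, starts[:-1]] if n_starts > 1 else [x0])
        return starts

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        seed: int = 0,
        n_starts: int = 16,
        x0: Mapping[str, float] | Sequence[float] | None = None,
        xtol: float = 1e-4,
        max_nfev: int | None = None,
    ) -> FitResults:
        """Bounded least-squares estimation with seeded multi-start.

        Each start runs a trust-region-reflective least-squares solve of the
        stacked residual vector; termination when the relative parameter step
        falls below ``xtol`` (default 1e-4) or the evaluation cap is hit.  The
        best start by objective wins.  Fixed seed => bit-reproducible result.
        """
        if not self.free_names:
            params, Q0 = self._theta_to_params(np.empty(0))
            r, per_ds = _residual_vector(params, Q0, self.datasets, self.dt, self._weights)
            return FitResults(
                params=params, Q0=Q0, F=float(np.dot(r, r)),
                free_names=(), theta=np.empty(0), bse={}, cov_params=None,
                n_obs=self.n_obs, n_iter=0, converged=True,
                termination_reason="no free parameters",
                n_starts=0, start_costs=np.empty(0),
                per_dataset_residuals=per_ds, fixed=dict(self.fixed),
            )
        lo = np.array([self.bounds[n][0] for n in self.free_names])
        hi = np.array([self.bounds[n][1] for n in self.free_names])
        starts = self._starts(seed, n_starts, x0)
        best = None
        diagnostics = []
        costs = []
        for k, s0 in enumerate(starts):
            try:
                res = least_squares(
                    self._residuals, np.clip(s0, lo, hi),
                    bounds=(lo, hi), method="trf",
                    xtol=xtol, ftol=1e-12, gtol=1e-12,
                    max_nfev=max_nfev,
                )
                costs.append(res.cost)
                diagnostics.append((k, res.status, res.cost, res.message))
                if best is None or res.cost < best.cost:
                    best = res
            except Exception as exc:  # pragma: no cover - solver-internal failure
                costs.append(np.inf)
                diagnostics.append((k, -99, np.inf, str(exc)))
        if best is None:
            raise FitFailureError("all optimiser starts failed", diagnostics)
        params, Q0 = self._theta_to_params(best.x)
        F = float(2.0 * best.cost)
        r, per_ds = _residual_vector(params, Q0, self.datasets, self.dt, self._weights)
        bse, cov = self._standard_errors(best)
        return FitResults(
            params=params, Q0=Q0, F=F,
            free_names=self.free_names, theta=best.x.copy(),
            bse=bse, cov_params=cov,
            n_obs=self.n_obs, n_iter=int(best.nfev),
            converged=bool(best.status > 0),
            termination_reason=str(best.message),
            n_starts=len(starts), start_costs=np.asarray(costs),
            per_dataset_residuals=per_ds, fixed=dict(self.fixed),
        )

    def _standard_errors(self, res) -> tuple[dict[str, float], np.ndarray | None]:
        m, n = res.jac.shape
        dof = m - n
        if dof <= 0:
            return {name: float("nan") for name in self.free_names}, None
        s2 = 2.0 * res.cost / dof
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            try:
                cov = s2 * np.linalg.pinv(res.jac.T @ res.jac)
                se = np.sqrt(np.clip(np.diag(cov), 0, None))
            except np.linalg.LinAlgError:  # pragma: no cover
                return {name: float("nan") for name in self.free_names}, None
        return {name: float(se[i]) for i, name in enumerate(self.free_names)}, cov


def fit(
    datasets: Sequence[ExperimentTable],
    free: Sequence[str] | None = None,
    fixed: Mapping[str, float] | None = None,
    bounds: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
    **fit_kwargs,
) -> FitResults:
    """Functional wrapper: build a :class:`BatchFermentationModel` and fit it."""
    model = BatchFermentationModel(datasets, free=free, fixed=fixed, bounds=bounds)
    return model.fit(seed=seed, **fit_kwargs)
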