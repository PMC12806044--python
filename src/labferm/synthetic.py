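"""Synthetic batch-fermentation experiment tables.

Real LAB batch datasets are sparse time courses (a dozen-odd samples over a
day) of substrate, biomass and lactic-acid concentrations, positive and with
roughly proportional measurement error.  This module simulates the model
truth and degrades it to that shape, so parameter-recovery studies and demos
run without any external data.  The generating truth is recorded in each
table's metadata.

Defaults: 13 sampling points over 0-24 h (denser early, where the curve
bends) and multiplicative log-normal noise with a 5% coefficient of
variation.  The log-normal multiplier has mean 1 exactly, so the sample CV
of replicates converges to the nominal ``cv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .estimation import EXPERIMENT_COLUMNS, ExperimentTable
from .kinetics import ModelParameters
from .presets import StrainPreset, get_preset
from .simulate import DEFAULT_DT, InitialConditions, simulate

__all__ = ["NoiseSpec", "synthesize", "make_paper_like_suite", "DEFAULT_SAMPLING_TIMES"]

#: 13 points over 0-24 h, denser early
DEFAULT_SAMPLING_TIMES = (0.0, 1.0, 2.0, 3.0, 4.5, 6.0, 8.0, 10.0, 12.0, 15.0, 18.0, 21.0, 24.0)


@dataclass(frozen=True)
class NoiseSpec:
    """Measurement-noise model for synthetic tables.

    ``multiplicative-lognormal`` multiplies each true value by a mean-1
    log-normal factor with coefficient of variation ``cv``;
    ``additive-gaussian`` adds zero-mean noise with standard deviation
    ``cv`` times the across-time RMS of that observable.  Values are clamped
    at zero.
    """

    model: Literal["multiplicative-lognormal", "additive-gaussian"] = (
        "multiplicative-lognormal"
    )
    cv: float = 0.05
    seed: int = 0
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES
    observed: tuple[str, ...] = ("S", "X", "A")

    def __post_init__(self) -> None:
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        t = np.asarray(self.sampling_times, dtype=float)
        if t.ndim != 1 or t.size == 0 or np.any(np.diff(t) <= 0) or t[0] < 0:
            raise ValueError("sampling_times must be strictly increasing and >= 0")
        bad = set(self.observed) - {"S", "X", "A"}
        if bad:
            raise ValueError(f"unknown observables {sorted(bad)}")


def synthesize(
    params: ModelParameters,
    init: InitialConditions,
    noise: NoiseSpec,
    dt: float = DEFAULT_DT,
    t_end: float | None = None,
) -> ExperimentTable:
    """Simulate the truth and sample it into a noisy experiment table."""
    times = np.asarray(noise.sampling_times, dtype=float)
    if t_end is None:
        t_end = float(times[-1])
    elif times[-1] > t_end:
        raise ValueError(
            f"sampling time {times[-1]} h beyond simulation horizon {t_end} h"
        )
    traj = simulate(params, init, t_end, dt)
    truth = {
        "S": np.interp(times, traj.times, traj.S),
        "X": np.interp(times, traj.times, traj.X),
        "A": np.interp(times, traj.times, traj.A),
    }
    rng = np.random.default_rng(noise.seed)
    data = {"time_h": times}
    for col in EXPERIMENT_COLUMNS[1:]:
        key = col[0]
        if key not in noise.observed:
            data[col] = np.full(times.size, np.nan)
            continue
        v = truth[key].copy()
        if noise.cv > 0:
            if noise.model == "multiplicative-lognormal":
                sigma2 = np.log1p(noise.cv**2)
                z = rng.standard_normal(times.size)
                v = v * np.exp(np.sqrt(sigma2) * z - sigma2 / 2.0)
            elif noise.model == "additive-gaussian":
                scale = noise.cv * float(np.sqrt(np.mean(truth[key] ** 2)))
                v = v + scale * rng.standard_normal(times.size)
            else:  # pragma: no cover - guarded in NoiseSpec
                raise ValueError(f"unknown noise model {noise.model!r}")
        data[col] = np.clip(v, 0.0, None)
    return ExperimentTable(
        S0=init.S0, X0=init.X0, A0=init.A0,
        observations=pd.DataFrame(data),
        metadata={
            "synthetic": True,
            "truth_params": params.to_dict(),
            "truth_init": vars(init),
            "noise": {
                "model": noise.model, "cv": noise.cv, "seed": noise.seed,
                "observed": list(noise.observed),
            },
        },
    )


def make_paper_like_suite(
    strain_preset: str | StrainPreset,
    seed: int = 0,
    cv: float = 0.05,
    noise_model: str = "multiplicative-lognormal",
    sampling_times: Sequence[float] = DEFAULT_SAMPLING_TIMES,
) -> list[ExperimentTable]:
    """Two-condition dataset mirroring a strain's fitting setup.

    Each strain preset defines a truth parameter set, inoculum (Q0, X0) and a
    pair of initial substrate concentrations; the suite is one noisy table
    per condition, with distinct sub-seeds derived from ``seed``.
    """
    preset = get_preset(strain_preset) if isinstance(strain_preset, str) else strain_preset
    tables = []
    for k, S0 in enumerate(preset.S0_conditions):
        spec = NoiseSpec(
            model=noise_model, cv=cv,
            seed=(seed * 1009 + k) % (2**31 - 1),
            sampling_times=sampling_times,
        )
        init = InitialConditions(S0=S0, Q0=preset.Q0, X0=preset.X0, A0=0.0)
        table = synthesize(preset.params, init, spec)
        table.metadata["preset"] = preset.name
        tables.append(table)
    return tables
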