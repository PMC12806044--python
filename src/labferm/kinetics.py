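"""Model symbols and right-hand side of the two-pathway batch-fermentation model.

The model couples four state variables, always ordered (S, Q, X, A):

* ``S`` — substrate (lactose) concentration, g/dm3
* ``Q`` — dimensionless physiological state of the population, proportional to
  the intracellular level of a critical growth-gating enzyme
* ``X`` — biomass concentration, g/dm3
* ``A`` — lactic acid concentration, g/dm3

Growth proceeds through two pathways.  The assimilation pathway is classical
Monod growth with non-competitive product inhibition; the regulatory pathway
lets ``Q`` accumulate at a rate that is itself suppressed by substrate through
a Hill function, so that high initial substrate delays physiological
adaptation.  The specific growth rate is the product of a maximum rate and
three dimensionless factors,

    mu = mu_max * mu_Q * mu_S * mu_A,

with mu_Q = Q/(1+Q) (Baranyi-Roberts adjustment), mu_S = S/(K_S+S) (Monod) and
mu_A = 1/(1 + (A/K_I)^n_A).  The physiological state obeys
dQ/dt = nu * f_Q(S) * Q with f_Q(S) = 1/(1 + (S/K_Q)^n_Q), and product
formation follows Luedeking-Piret kinetics dA/dt = alpha*dX/dt + beta*X.

Units are fixed at g/dm3 and hours throughout; there is no unit-conversion
layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple

__all__ = [
    "ModelParameters",
    "BatchState",
    "GrowthFactors",
    "InvalidStateError",
    "growth_factors",
    "rhs",
    "STATE_ORDER",
]

#: Canonical ordering of the state vector everywhere in the package.
STATE_ORDER = ("S", "Q", "X", "A")


class InvalidStateError(ValueError):
    """Raised when a state or parameter set violates its invariants."""


@dataclass(frozen=True)
class ModelParameters:
    """Kinetic constants of the two-pathway model.

    Parameters
    ----------
    mu_max : float
        Maximum specific growth rate, 1/h.
    K_S : float
        Monod half-saturation constant, g/dm3.
    K_I : float
        Product (lactic acid) inhibition constant, g/dm3.
    alpha : float
        Growth-associated product coefficient, g LA per g biomass.
    beta : float
        Non-growth-associated product coefficient, g LA / (g biomass * h).
    gamma_XS : float
        Biomass yield on substrate routed to growth, g biomass / g substrate.
    gamma_AS : float
        Product yield on substrate routed to product, g LA / g substrate.
    nu : float, optional
        Adaptation rate of the physiological state, 1/h.  Defaults to
        ``mu_max`` (bottleneck growth assumption).
    K_Q : float, optional
        Substrate-inhibition constant for synthesis of the critical enzyme,
        g/dm3.  Defaults to ``K_S``.
    n_Q : float, optional
        Hill exponent of substrate inhibition on Q synthesis (default 2).
    n_A : float, optional
        Hill exponent of product inhibition on growth (default 5).

    Notes
    -----
    The ties ``nu = mu_max`` and ``K_Q = K_S`` are the model defaults and are
    kept tied during fitting unless explicitly untied.  Hill exponents are
    accepted as positive reals; the canonical values are the integers 2 and 5.
    """

    mu_max: float
    K_S: float
    K_I: float
    alpha: float
    beta: float
    gamma_XS: float
    gamma_AS: float
    nu: float | None = None
    K_Q: float | None = None
    n_Q: float = 2.0
    n_A: float = 5.0

    def __post_init__(self) -> None:
        if self.nu is None:
            object.__setattr__(self, "nu", self.mu_max)
        if self.K_Q is None:
            object.__setattr__(self, "K_Q", self.K_S)
        strictly_positive = {
            "mu_max": self.mu_max,
            "K_S": self.K_S,
            "K_I": self.K_I,
            "gamma_XS": self.gamma_XS,
            "gamma_AS": self.gamma_AS,
            "nu": self.nu,
            "K_Q": self.K_Q,
            "n_Q": self.n_Q,
            "n_A": self.n_A,
        }
        for name, value in strictly_positive.items():
            if not (math.isfinite(value) and value > 0):
                raise InvalidStateError(
                    f"parameter {name} must be finite and > 0, got {value!r}"
                )
        for name, value in (("alpha", self.alpha), ("beta", self.beta)):
            if not (math.isfinite(value) and value >= 0):
                raise InvalidStateError(
                    f"parameter {name} must be finite and >= 0, got {value!r}"
                )

    def replace(self, **changes) -> "ModelParameters":
        """Return a copy with the given fields replaced.

        Replacing ``mu_max`` (or ``K_S``) re-ties ``nu`` (or ``K_Q``) unless a
        new value is passed explicitly alongside.
        """
        fields_now = self.to_dict()
        # preserve ties when the tied partner is not overridden together
        if "mu_max" in changes and "nu" not in changes and self.nu == self.mu_max:
            fields_now["nu"] = None
        if "K_S" in changes and "K_Q" not in changes and self.K_Q == self.K_S:
            fields_now["K_Q"] = None
        fields_now.update(changes)
        return ModelParameters(**fields_now)

    def to_dict(self) -> dict:
        return {
            "mu_max": self.mu_max,
            "K_S": self.K_S,
            "K_I": self.K_I,
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma_XS": self.gamma_XS,
            "gamma_AS": self.gamma_AS,
            "nu": self.nu,
            "K_Q": self.K_Q,
            "n_Q": self.n_Q,
            "n_A": self.n_A,
        }


class BatchState(NamedTuple):
    """Instantaneous culture state (S, Q, X, A)."""

    S: float
    Q: float
    X: float
    A: float

    def validate(self) -> "BatchState":
        # X = 0 and Q = 0 are admissible instantaneous states (fixed points of
        # their own dynamics); initial conditions are stricter (X0, Q0 > 0).
        if not all(math.isfinite(v) for v in self):
            raise InvalidStateError(f"non-finite state {self!r}")
        if min(self) < 0:
            raise InvalidStateError(f"concentrations must be >= 0 in {self!r}")
        return self


class GrowthFactors(NamedTuple):
    """The dimensionless growth factors and the composite rate.

    ``mu`` is exactly ``mu_max * mu_Q * mu_S * mu_A``; ``f_Q`` is the Hill
    suppression of Q synthesis by substrate (it multiplies ``nu``, not ``mu``).
    """

    mu_Q: float
    f_Q: float
    mu_S: float
    mu_A: float
    mu: float


def growth_factors(state: BatchState, params: ModelParameters) -> GrowthFactors:
    """Evaluate the four growth factors and the composite specific growth rate.

    Returns mu_Q = Q/(1+Q), f_Q = 1/(1+(S/K_Q)^n_Q), mu_S = S/(K_S+S),
    mu_A = 1/(1+(A/K_I)^n_A), and mu = mu_max*mu_Q*mu_S*mu_A.
    """
    state = BatchState(*state).validate()
    S, Q, _, A = state
    mu_Q = Q / (1.0 + Q)
    f_Q = 1.0 / (1.0 + (S / params.K_Q) ** params.n_Q)
    mu_S = S / (params.K_S + S)
    mu_A = 1.0 / (1.0 + (A / params.K_I) ** params.n_A)
    mu = params.mu_max * mu_Q * mu_S * mu_A
    return GrowthFactors(mu_Q, f_Q, mu_S, mu_A, mu)


def rhs(state: BatchState, params: ModelParameters) -> tuple[float, float, float, float]:
    """Right-hand side of the coupled ODE system, in canonical (S, Q, X, A) order.

    dX/dt = mu*X, dQ/dt = nu*f_Q(S)*Q, dA/dt = alpha*dX/dt + beta*X, and the
    substrate balance with the product rate substituted in,

        dS/dt = -(1/gamma_XS + alpha/gamma_AS)*dX/dt - (beta/gamma_AS)*X,

    which removes any evaluation-order ambiguity between the coupled equations.
    Rates are g/(dm3 h) except dQ/dt (1/h scale on a dimensionless level).
    """
    f = growth_factors(state, params)
    S, Q, X, A = BatchState(*state)
    dX = f.mu * X
    dQ = params.nu * f.f_Q * Q
    dA = params.alpha * dX + params.beta * X
    dS = -(1.0 / params.gamma_XS + params.alpha / params.gamma_AS) * dX - (
        params.beta / params.gamma_AS
    ) * X
    return (dS, dQ, dX, dA)
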