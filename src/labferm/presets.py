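"""Strain presets for the three published LAB batch-fermentation systems.

Each preset bundles a truth parameter set, the inoculum state (Q0, X0) and
the pair of initial lactose concentrations the corresponding literature
experiments were fitted from.  The published anchor values are kept exactly:
K_S = 8 g/dm3 and Q0 = 0.6 with X0 = 0.02 g/dm3 for *L. bulgaricus*
(conditions 26 and 43 g/dm3); Q0 = 0.60 for *L. casei* (conditions 35.5 and
48.1 g/dm3); beta = 0 for *L. plantarum* (conditions 11 and 22 g/dm3,
inoculum sizes 0.0015-0.15 g/dm3).

The remaining kinetic constants are SYNTHETIC placeholder truths: the
original per-strain fitted tables are not redistributable, so these values
were calibrated once against the published regime descriptors (bulgaricus:
bell-shaped mu(S0) with critical concentration near 14.3 g/dm3 at Q0 = 0.6;
casei: monotone mu(S0) at Q0 = 0.6 but peaked near 17.1 g/dm3 at Q0 = 0.2,
with maximum volumetric productivity about 2.4 g dm^-3 h^-1 near 10 h at
S0 = 35.5 g/dm3; plantarum: purely growth-associated production) and then
frozen.  They are config-overridable via :meth:`StrainPreset.with_params`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

from .kinetics import ModelParameters

__all__ = ["StrainPreset", "STRAIN_PRESETS", "get_preset"]


@dataclass(frozen=True)
class StrainPreset:
    """Truth configuration for one strain's synthetic reproduction suite."""

    name: str
    params: ModelParameters
    Q0: float
    X0: float
    S0_conditions: tuple[float, ...]
    description: str
    placeholder: bool = True  # True: calibrated stand-in, not a published table

    def with_params(self, **overrides) -> "StrainPreset":
        return replace(self, params=self.params.replace(**overrides))


STRAIN_PRESETS: Mapping[str, StrainPreset] = {
    "bulgaricus": StrainPreset(
        name="bulgaricus",
        params=ModelParameters(
            mu_max=0.60,
            K_S=8.0,       # published value
            K_I=46.0,
            alpha=14.0,
            beta=0.50,
            gamma_XS=0.10,
            gamma_AS=0.95,
        ),
        Q0=0.6,            # published value
        X0=0.02,           # published value
        S0_conditions=(26.0, 43.0),
        description=(
            "Lactobacillus bulgaricus on lactose; synthetic placeholder truth "
            "calibrated to a bell-shaped mu(S0) with Sc near 14.3 g/dm3 at "
            "Q0 = 0.6"
        ),
    ),
    "casei": StrainPreset(
        name="casei",
        params=ModelParameters(
            mu_max=0.78,
            K_S=9.0,
            K_I=60.0,
            alpha=14.0,
            beta=0.50,
            gamma_XS=0.10,
            gamma_AS=0.95,
        ),
        Q0=0.60,           # published value
        X0=0.20,
        S0_conditions=(35.5, 48.1),
        description=(
            "Lactobacillus casei on whey lactose; synthetic placeholder truth "
            "calibrated to monotone mu(S0) at Q0 = 0.6, a peak near "
            "17.1 g/dm3 at Q0 = 0.2, and max productivity ~2.4 g dm^-3 h^-1 "
            "near 10 h at S0 = 35.5 g/dm3"
        ),
    ),
    "plantarum": StrainPreset(
        name="plantarum",
        params=ModelParameters(
            mu_max=0.50,
            K_S=6.0,
            K_I=40.0,
            alpha=10.0,
            beta=0.0,      # published: growth-associated production only
            gamma_XS=0.12,
            gamma_AS=0.90,
        ),
        Q0=0.6,
        X0=0.015,
        S0_conditions=(11.0, 22.0),
        description=(
            "Lactiplantibacillus plantarum AC 11S on lactose; synthetic "
            "placeholder truth with beta = 0 (growth-associated lactic acid "
            "production), inoculum-size studies at 0.0015-0.15 g/dm3"
        ),
    ),
}


def get_preset(name: str) -> StrainPreset:
    try:
        return STRAIN_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown strain preset {name!r}; available: {sorted(STRAIN_PRESETS)}"
        ) from None
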