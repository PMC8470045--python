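"""Pharmacokinetic endpoints, unit conversions and small physical-law utilities.

The headline quantities are the total absorbed amount and the absolute
bioavailability F.  Under an ideal impulse dose M0 into the GIT, the GIT
amount is x1(t) = M0 exp(-(ka+ke1) t), so

    total absorbed over [0, T] = ka int_0^T x1 dt
                               = M0 ka/(ka+ke1) (1 - exp(-(ka+ke1) T))
    F = total absorbed / M0 * 100 %

with the infinite-horizon limit M0 ka/(ka+ke1): the dose splits between
absorption (fraction ka/(ka+ke1)) and pre-systemic GIT elimination
(fraction ke1/(ka+ke1)).

Also provided: the total-blood-volume regression used to convert measured
concentrations into amounts, the half-life relation k = 0.693/t_half,
molecular-weight arithmetic, and the first-order flux laws
(Noyes-Whitney dissolution, membrane diffusion) that motivate the
first-order structure of the compartment model.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .model import RateConstants
from .series import UNITS_AMOUNT, UNITS_CONCENTRATION, Series

__all__ = [
    "SubjectInfo",
    "FluxParams",
    "EndpointReport",
    "CmcAsPrinted",
    "tbv_from_weight",
    "amounts_from_concentrations",
    "total_absorbed",
    "bioavailability",
    "endpoint_report",
    "percent_change",
    "rate_constant_from_half_life",
    "molecular_weight",
    "cmc_molar_as_printed",
    "noyes_whitney_rate",
    "membrane_flux",
]

# IUPAC standard atomic weights, g/mol, to 3 decimals.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "F": 18.998,
    "Na": 22.990,
    "Mg": 24.305,
    "P": 30.974,
    "S": 32.060,
    "Cl": 35.450,
    "K": 39.098,
    "Ca": 40.078,
    "Fe": 55.845,
    "Zn": 65.380,
    "Br": 79.904,
    "I": 126.904,
}

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


@dataclass(frozen=True)
class SubjectInfo:
    """Body weight and (derived or supplied) total blood volume of a subject."""

    body_weight: float  # g
    total_blood_volume: float | None = None  # mL

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValueError("body weight must be positive")
        if self.total_blood_volume is None:
            object.__setattr__(self, "total_blood_volume", tbv_from_weight(self.body_weight))
        elif self.total_blood_volume <= 0:
            raise ValueError("total blood volume must be positive")


@dataclass(frozen=True)
class FluxParams:
    """Parameters of the first-order dissolution / membrane-diffusion laws.

    D: diffusion coefficient (area/time); A_surface: particle or membrane
    area; h_layer: saturated-layer thickness; d_membrane: membrane
    thickness; V1, V2: distribution volumes (mL).  G = D A / d is the
    lumped membrane permeability.
    """

    D: float = 1.0
    A_surface: float = 1.0
    h_layer: float = 1.0
    d_membrane: float = 1.0
    V1: float = 1.0
    V2: float = 1.0

    @property
    def G(self) -> float:
        return self.D * self.A_surface / self.d_membrane


@dataclass(frozen=True)
class EndpointReport:
    """Total absorbed amount and absolute bioavailability for one branch."""

    total_absorbed: float  # mg
    bioavailability_percent: float
    horizon: float  # h (math.inf allowed)
    parameter_branch_used: RateConstants
    dose: float  # mg

    def __post_init__(self) -> None:
        if not 0.0 <= self.bioavailability_percent <= 100.0 + 1e-9:
            raise ValueError("bioavailability must lie in [0, 100] %")


@dataclass(frozen=True)
class CmcAsPrinted:
    """Reciprocal-molecular-weight CMC figure with its dimensional caveat."""

    value_mol_per_l: float
    dimensionally_consistent: bool
    note: str


def tbv_from_weight(body_weight: float) -> float:
    """Total blood volume (mL) from body weight (g): TBV = 0.06 BW + 0.77.

    Linear allometric relation for the rat; at 200 g it gives 12.77 mL.
    """
    if body_weight < 0:
        raise ValueError(f"body weight must be nonnegative, got {body_weight}")
    return 0.06 * body_weight + 0.77


def amounts_from_concentrations(series: Series, tbv: float) -> Series:
    """Convert a blood-concentration series (mg/mL) to amounts (mg).

    amount = concentration x total blood volume; the unit tag flips.
    """
    if tbv <= 0:
        raise ValueError("total blood volume must be positive")
    if series.units != UNITS_CONCENTRATION:
        raise ValueError(f"series must be in {UNITS_CONCENTRATION!r}, got {series.units!r}")
    if np.any(series.values < 0):
        raise ValueError("negative concentrations are not allowed")
    return series.with_values(series.values * tbv, UNITS_AMOUNT)


def total_absorbed(params: RateConstants, dose: float, horizon: float = math.inf) -> float:
    """Total amount absorbed into blood over [0, horizon] hours, mg.

    ka int_0^T x1 dt in closed form for an ideal impulse dose; the
    infinite-horizon value is dose * ka/(ka + ke1).
    """
    if dose < 0:
        raise ValueError("dose must be nonnegative")
    ka, ke1 = params.ka, params.ke1
    lam = ka + ke1
    if lam == 0.0:
        if dose > 0:
            # nothing can leave the GIT: x1 stays at the dose forever
            raise ValueError("ka + ke1 = 0: no disposition from the GIT")
        return 0.0
    if math.isinf(horizon):
        return dose * ka / lam
    if horizon < 0:
        raise ValueError("horizon must be nonnegative")
    return dose * ka / lam * -math.expm1(-lam * horizon)


def bioavailability(total_absorbed_mg: float, dose: float) -> float:
    """Absolute bioavailability F = absorbed / dose x 100 %."""
    if dose <= 0:
        raise ValueError("dose must be positive")
    return total_absorbed_mg / dose * 100.0


def endpoint_report(
    params: RateConstants, dose: float, horizon: float = 12.0
) -> EndpointReport:
    """Convenience wrapper bundling total absorbed and F for one branch."""
    total = total_absorbed(params, dose, horizon)
    return EndpointReport(
        total_absorbed=total,
        bioavailability_percent=bioavailability(total, dose),
        horizon=horizon,
        parameter_branch_used=params,
        dose=dose,
    )


def percent_change(before: float, after: float) -> float:
    """(after - before) / before x 100 %."""
    if before <= 0:
        raise ValueError("baseline value must be positive")
    return (after - before) / before * 100.0


def rate_constant_from_half_life(t_half: float) -> float:
    """First-order rate constant from a half-life: k = 0.693 / t_half (1/h)."""
    if t_half <= 0:
        raise ValueError("half-life must be positive")
    return 0.693 / t_half


def molecular_weight(formula: str) -> float:
    """Molecular weight (g/mol, 1 decimal) of a simple molecular formula.

    Supports element symbols with optional integer counts (no brackets);
    e.g. ``C24H44O12`` -> 524.6.
    """
    if not formula or not re.fullmatch(r"(?:[A-Z][a-z]?\d*)+", formula):
        raise ValueError(f"cannot parse molecular formula {formula!r}")
    total = 0.0
    for symbol, count in _FORMULA_TOKEN.findall(formula):
        if not symbol:
            continue
        if symbol not in ATOMIC_MASSES:
            raise ValueError(f"unknown element symbol {symbol!r} in {formula!r}")
        total += ATOMIC_MASSES[symbol] * (int(count) if count else 1)
    return round(total, 1)


def cmc_molar_as_printed(mw: float) -> CmcAsPrinted:
    """Reciprocal molecular weight quoted as a critical micellar concentration.

    Reproduces the arithmetic 1/MW mole/L as sometimes quoted alongside a
    0.001 % w/v surfactant solution.  The conversion is dimensionally
    questionable — 0.001 % w/v is 0.01 g/L, i.e. 0.01/MW mole/L — so the
    returned record carries an explicit caveat flag rather than silently
    endorsing the figure.
    """
    if mw <= 0:
        raise ValueError("molecular weight must be positive")
    return CmcAsPrinted(
        value_mol_per_l=1.0 / mw,
        dimensionally_consistent=False,
        note=(
            "1/MW treats the solution as 1 g/L; a 0.001 % w/v solution is "
            "0.01 g/L, which would give 0.01/MW mole/L"
        ),
    )


def noyes_whitney_rate(fp: FluxParams, Cs: float, C: float) -> float:
    """Dissolution rate dM/dt = (D A / h)(Cs - C): first order in the deficit."""
    if fp.h_layer <= 0:
        raise ValueError("saturated-layer thickness must be positive")
    return fp.D * fp.A_surface / fp.h_layer * (Cs - C)


def membrane_flux(fp: FluxParams, m1: float, m2: float) -> float:
    """Fick membrane flux G (m1/V1 - m2/V2): first order in the amounts."""
    if fp.V1 <= 0 or fp.V2 <= 0:
        raise ValueError("distribution volumes must be positive")
    return fp.G * (m1 / fp.V1 - m2 / fp.V2)
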