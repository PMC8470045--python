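"""Packaged study data: the in-vivo sampling table and identified parameter sets.

The in-vivo experiment dosed Wistar rats (mean 200 g) per-orally with
50 mg sulfathiazole, with and without 0.025 % monolaurin-of-sucrose
surfactant stabiliser plus the tenside under test, sampling six animals
destructively at each hour 0..6 and averaging.  Concentrations were
converted to amounts with the total-blood-volume relation
TBV = 0.06 BW + 0.77 mL.

Also packaged: the transfer-function coefficient triplets identified for
each condition and the two rate-constant branches each admits.
"""

from __future__ import annotations

from importlib import resources

from .model import RateConstants, TransferCoefficients
from .series import UNITS_AMOUNT, UNITS_CONCENTRATION, Series

__all__ = [
    "DOSE_MG",
    "BODY_WEIGHT_G",
    "N_ANIMALS_PER_TIME",
    "TABLE_TIMES_H",
    "CONC_WITHOUT_MG_PER_ML",
    "AMOUNT_WITHOUT_MG",
    "AMOUNT_WITH_MG",
    "COEFFS_WITHOUT",
    "COEFFS_WITH",
    "RATES_WITHOUT_BRANCH1",
    "RATES_WITHOUT_BRANCH2",
    "RATES_WITH_BRANCH1",
    "RATES_WITH_BRANCH2",
    "study_series",
    "fixture_path",
]

DOSE_MG = 50.0
BODY_WEIGHT_G = 200.0
N_ANIMALS_PER_TIME = 6

TABLE_TIMES_H = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)
CONC_WITHOUT_MG_PER_ML = (0.0, 0.0715, 0.0855, 0.0780, 0.0735, 0.0490, 0.0535)
AMOUNT_WITHOUT_MG = (0.0, 0.914, 1.093, 0.997, 0.952, 0.626, 0.684)
AMOUNT_WITH_MG = (0.0, 1.262, 1.403, 1.280, 1.222, 0.803, 0.878)

# Transfer-function coefficients identified from the study means.
COEFFS_WITHOUT = TransferCoefficients(b0=0.030272, a1=1.018397, a0=0.230137)
COEFFS_WITH = TransferCoefficients(b0=0.045815, a1=1.247769, a0=0.244092)

# The two rate-constant branches per condition (1/h), smaller-ke2 branch first.
RATES_WITHOUT_BRANCH1 = RateConstants(ka=0.030272, ke1=0.649656, ke2=0.338477)
RATES_WITHOUT_BRANCH2 = RateConstants(ka=0.030272, ke1=0.308204, ke2=0.679928)
RATES_WITH_BRANCH1 = RateConstants(ka=0.045815, ke1=0.959041, ke2=0.242913)
RATES_WITH_BRANCH2 = RateConstants(ka=0.045815, ke1=0.197097, ke2=1.004856)


def study_series(condition: str = "without", kind: str = "amount") -> Series:
    """The packaged study means as a :class:`Series`.

    condition: "without" or "with" (tenside); kind: "amount" (mg) or,
    for the without condition only, "concentration" (mg/mL).
    """
    if condition == "without":
        if kind == "amount":
            values, units = AMOUNT_WITHOUT_MG, UNITS_AMOUNT
        elif kind == "concentration":
            values, units = CONC_WITHOUT_MG_PER_ML, UNITS_CONCENTRATION
        else:
            raise ValueError(f"unknown kind {kind!r}")
    elif condition == "with":
        if kind != "amount":
            raise ValueError("only amounts are tabulated for the with-tenside condition")
        values, units = AMOUNT_WITH_MG, UNITS_AMOUNT
    else:
        raise ValueError(f"unknown condition {condition!r}")
    return Series(
        times=TABLE_TIMES_H, values=values, units=units, n_animals=N_ANIMALS_PER_TIME
    )


def fixture_path(name: str):
    """Filesystem path to a packaged CSV fixture (context-manager friendly)."""
    return resources.files("oralpk.data_files").joinpath(name)
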