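"""Synthetic destructive-sampling datasets with a biexponential mean response.

Emulates the in-vivo design the package analyses: rats receive a 50 mg
per-oral dose, a fresh group of ``animals_per_time`` animals is sampled
(destructively) at each time point 0..6 h, and the group-mean blood
concentration is recorded.  The mean curve is the exact impulse response
x2(t)/TBV of the two-compartment model; measurement noise is
multiplicative Gaussian with a configurable coefficient of variation,
truncated at -100 % so concentrations stay nonnegative (assay error
scales with concentration).

The surfactant (tenside) condition is modelled as a pure scaling of the
absorption rate constant ka — the mechanism the analysis attributes to a
sub-CMC surfactant — with ke1, ke2 unchanged.  Because each time point
uses different animals there is no within-animal correlation to model.

All randomness flows from the single integer seed in the design, so a
fixed seed reproduces the datasets bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .endpoints import tbv_from_weight
from .model import RateConstants, TransferCoefficients, transfer_function
from .series import UNITS_AMOUNT, Series
from .simulate import impulse_blood_amount

__all__ = ["ExperimentDesign", "SyntheticDataset", "generate", "write_dataset"]


@dataclass(frozen=True)
class ExperimentDesign:
    """Design of one destructive-sampling experiment."""

    sample_times: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.0)  # h
    animals_per_time: int = 6
    dose: float = 50.0  # mg
    body_weight_mean: float = 200.0  # g
    noise_cv: float = 0.05  # fractional CV of the concentration assay
    seed: int = 0

    def __post_init__(self) -> None:
        times = tuple(float(t) for t in self.sample_times)
        if any(t < 0 for t in times):
            raise ValueError("sample times must be nonnegative")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample times must be strictly increasing")
        if self.animals_per_time < 1:
            raise ValueError("need at least one animal per time point")
        if self.noise_cv < 0:
            raise ValueError("noise CV must be nonnegative")
        if self.dose < 0:
            raise ValueError("dose must be nonnegative")
        if self.body_weight_mean <= 0:
            raise ValueError("body weight must be positive")
        object.__setattr__(self, "sample_times", times)

    @property
    def tbv(self) -> float:
        return tbv_from_weight(self.body_weight_mean)


@dataclass(frozen=True)
class SyntheticDataset:
    """One generated condition: per-animal records, group means, and the truth."""

    per_animal: pd.DataFrame  # columns: time_h, animal, concentration_mg_per_ml
    means: Series  # group-mean amounts, mg
    mean_concentrations: np.ndarray  # mg/mL, aligned with means.times
    truth_rates: RateConstants
    truth_coefficients: TransferCoefficients
    design: ExperimentDesign
    label: str = field(default="synthetic")


def _one_condition(
    design: ExperimentDesign,
    truth: RateConstants,
    rng: np.random.Generator,
    label: str,
) -> SyntheticDataset:
    times = np.asarray(design.sample_times)
    tbv = design.tbv
    lam1 = truth.ka + truth.ke1
    mean_curve = impulse_blood_amount(times, truth.ka, lam1, truth.ke2, design.dose) / tbv

    eps = rng.normal(0.0, design.noise_cv, size=(times.size, design.animals_per_time))
    eps = np.maximum(eps, -1.0)  # truncate so concentrations stay nonnegative
    conc = mean_curve[:, None] * (1.0 + eps)

    per_animal = pd.DataFrame(
        {
            "time_h": np.repeat(times, design.animals_per_time),
            "animal": np.tile(np.arange(1, design.animals_per_time + 1), times.size),
            "concentration_mg_per_ml": conc.reshape(-1),
        }
    )
    empirical_mean_conc = conc.mean(axis=1)
    means = Series(
        times=times,
        values=empirical_mean_conc * tbv,
        units=UNITS_AMOUNT,
        n_animals=design.animals_per_time,
    )
    return SyntheticDataset(
        per_animal=per_animal,
        means=means,
        mean_concentrations=empirical_mean_conc,
        truth_rates=truth,
        truth_coefficients=transfer_function(truth),
        design=design,
        label=label,
    )


def generate(
    design: ExperimentDesign,
    truth: RateConstants,
    tenside_ka_factor: float = 1.0,
) -> tuple[SyntheticDataset, SyntheticDataset]:
    """Generate the (without-tenside, with-tenside) dataset pair.

    The with-tenside condition multiplies ka by ``tenside_ka_factor``
    (must be positive), leaving ke1 and ke2 unchanged.  Both conditions
    draw from one generator seeded by ``design.seed``, so the pair is a
    deterministic function of the design.
    """
    if tenside_ka_factor <= 0:
        raise ValueError("tenside_ka_factor must be positive")
    rng = np.random.default_rng(design.seed)
    without = _one_condition(design, truth, rng, "without_tenside")
    truth_with = RateConstants(
        ka=truth.ka * tenside_ka_factor, ke1=truth.ke1, ke2=truth.ke2
    )
    with_ = _one_condition(design, truth_with, rng, "with_tenside")
    return without, with_


def write_dataset(ds: SyntheticDataset, outdir, stem: str | None = None) -> dict[str, Path]:
    """Write means CSV, long-format per-animal CSV and a truth sidecar JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = stem or ds.label
    paths = {
        "means": outdir / f"{stem}_means.csv",
        "animals": outdir / f"{stem}_animals.csv",
        "truth": outdir / f"{stem}_truth.json",
    }
    pd.DataFrame(
        {
            "time_h": ds.means.times,
            "concentration_mg_per_ml": ds.mean_concentrations,
            "amount_mg": ds.means.values,
        }
    ).to_csv(paths["means"], index=False)
    ds.per_animal.to_csv(paths["animals"], index=False)
    truth = {
        "rate_constants": dict(zip(("ka", "ke1", "ke2"), ds.truth_rates.as_tuple())),
        "transfer_coefficients": dict(
            zip(("b0", "a1", "a0"), ds.truth_coefficients.as_tuple())
        ),
        "design": {
            "sample_times_h": list(ds.design.sample_times),
            "animals_per_time": ds.design.animals_per_time,
            "dose_mg": ds.design.dose,
            "body_weight_mean_g": ds.design.body_weight_mean,
            "noise_cv": ds.design.noise_cv,
            "seed": ds.design.seed,
        },
        "label": ds.label,
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True))
    return paths
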