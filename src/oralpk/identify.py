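"""Identification of the transfer function and recovery of rate constants.

Only the input/output coefficients (b0, a1, a0) of

    G(s) = b0 / (s^2 + a1 s + a0)

are identifiable from dose-response samples.  Inverting them for the
rate constants gives

    ka  = b0
    ke2 = (a1 +/- sqrt(a1^2 - 4 a0)) / 2
    ke1 = a1 - b0 - ke2

so ka is unique but (ke1, ke2) admit two branches whenever the
discriminant is positive: the model is structurally unidentifiable in
those two parameters.  Both branches produce *identical* blood curves
x2(t) — they differ only in the unobservable GIT trajectory x1(t).

Fitting is nonlinear least squares of the impulse response

    y(t) = b0 M0 (exp(-lam2 t) - exp(-lam1 t)) / (lam1 - lam2)

to observed amounts, parameterized internally by (b0, lam1, lam2) with
positivity enforced through bounds, and started from a deterministic
grid of decay-rate pairs bracketing the sampling window (biexponential
objectives are multi-modal, so a single start is not trustworthy).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .model import RateConstants, TransferCoefficients, transfer_function
from .series import UNITS_AMOUNT, Series
from .simulate import DoseEvent, impulse_blood_amount

__all__ = [
    "IdentifiabilityResult",
    "FitResult",
    "TransferFunctionFitter",
    "recover_rate_constants",
    "fit_transfer_coefficients",
]

#: |a1^2 - 4 a0| <= ZERO_DISCRIMINANT_RTOL * a1^2 is treated as a repeated pole.
ZERO_DISCRIMINANT_RTOL = 1e-9


@dataclass(frozen=True)
class IdentifiabilityResult:
    """Rate-constant branches consistent with one set of transfer coefficients.

    ``branches`` holds one triplet when the discriminant is zero (within
    tolerance) and two otherwise, minus-root branch (smaller ke2) first.
    ``unique_parameters`` names the parameters identical across branches;
    it always contains ``ka``.  Branches with a negative ke1 are retained
    but flagged in ``messages`` as non-compartmental.
    """

    coefficients: TransferCoefficients
    branches: list[RateConstants]
    unique_parameters: list[str]
    discriminant: float
    messages: list[str] = field(default_factory=list)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a transfer-coefficient fit."""

    coefficients: TransferCoefficients
    residual_sum_of_squares: float  # mg^2
    n_observations: int
    converged: bool
    n_starts_used: int

    def __post_init__(self) -> None:
        if self.residual_sum_of_squares < 0:
            raise ValueError("residual sum of squares must be nonnegative")


def recover_rate_constants(
    coeffs: TransferCoefficients, zero_disc_rtol: float = ZERO_DISCRIMINANT_RTOL
) -> IdentifiabilityResult:
    """Invert (b0, a1, a0) for all admissible rate-constant triplets.

    Raises ``ValueError`` when the poles are complex beyond tolerance
    (no real compartmental realization of the two-compartment structure
    exists); returns one branch for a repeated pole, two otherwise.
    """
    b0, a1, a0 = coeffs.b0, coeffs.a1, coeffs.a0
    disc = a1 * a1 - 4.0 * a0
    tol = zero_disc_rtol * a1 * a1

    if disc < -tol:
        raise ValueError(
            "complex poles: no real compartmental realization of the "
            f"two-compartment structure (discriminant {disc:g})"
        )

    messages: list[str] = []
    if abs(disc) <= tol:
        ke2 = 0.5 * a1
        roots = [ke2]
    else:
        sq = np.sqrt(disc)
        roots = [0.5 * (a1 - sq), 0.5 * (a1 + sq)]  # minus root first

    branches: list[RateConstants] = []
    for i, ke2 in enumerate(roots, start=1):
        ke1 = a1 - b0 - ke2
        if ke1 < 0:
            messages.append(
                f"branch {i}: ke1 = {ke1:.6f} < 0; retained but not a "
                "compartmental realization"
            )
            branches.append(RateConstants._unchecked(b0, ke1, ke2))
        else:
            branches.append(RateConstants(ka=b0, ke1=ke1, ke2=ke2))

    if len(branches) == 1:
        unique = ["ka", "ke1", "ke2"]
        messages.append("repeated pole: the rate constants are uniquely identified")
    else:
        unique = ["ka"]
        messages.append(
            "two admissible (ke1, ke2) branches: the model is not uniquely "
            "identifiable; only ka is unique"
        )

    return IdentifiabilityResult(
        coefficients=coeffs,
        branches=branches,
        unique_parameters=unique,
        discriminant=disc,
        messages=messages,
    )


class TransferFunctionFitter(RegressorMixin, BaseEstimator):
    """Least-squares estimator of the impulse-response transfer coefficients.

    Scikit-learn style: ``fit(X, y)`` takes sampling times (hours, shape
    (n,) or (n, 1)) and observed blood amounts (mg) after an impulse dose
    of ``dose`` mg at t = 0, and ``predict(X)`` returns model amounts.

    Parameters
    ----------
    dose : float, default 50.0
        Administered amount M0 in mg.
    n_starts : int, default 8
        Deterministic multi-starts over a log-spaced grid of decay-rate
        pairs spanning 1/t_max to 10/t_min of the positive sampling times.
    min_rate : float, default 1e-6
        Lower bound (1/h) on the decay rates, keeping the poles strictly
        in the left half plane.

    Attributes
    ----------
    coefficients_ : TransferCoefficients
        Fitted (b0, a1, a0), mapped back from the internal (b0, lam1, lam2).
    result_ : FitResult
        Full fit record (RSS, convergence, starts used).
    lambdas_ : tuple of float
        Fitted decay rates, largest first.
    """

    def __init__(self, dose: float = 50.0, n_starts: int = 8, min_rate: float = 1e-6):
        self.dose = dose
        self.n_starts = n_starts
        self.min_rate = min_rate

    # -- internal helpers -------------------------------------------------
    @staticmethod
    def _model(t: np.ndarray, b0: float, lam1: float, lam2: float, dose: float) -> np.ndarray:
        # impulse response of the blood compartment; b0 plays the role of ka
        return impulse_blood_amount(t, b0, lam1, lam2, dose)

    def _starts(self, t: np.ndarray, y: np.ndarray) -> list[np.ndarray]:
        tpos = t[t > 0]
        tmax, tmin = float(tpos.max()), float(tpos.min())
        grid = np.geomspace(1.0 / tmax, 10.0 / tmin, 4)
        pairs = [(grid[j], grid[i]) for i in range(4) for j in range(i + 1, 4)]
        pairs += [(1.5 * grid[1], grid[1]), (grid[2], grid[2] / 1.5)]
        peak = float(np.max(y))
        starts = []
        for lam1, lam2 in pairs[: self.n_starts]:
            b0 = max(peak * (lam1 - lam2) / self.dose, 1e-4)
            starts.append(np.array([b0, lam1, lam2]))
        return starts

    # -- estimator API ----------------------------------------------------
    def fit(self, X, y) -> "TransferFunctionFitter":
        t = np.asarray(X, dtype=float).reshape(-1)
        y = np.asarray(y, dtype=float).reshape(-1)
        if t.size != y.size:
            raise ValueError("X and y must have the same number of samples")
        if t.size < 4:
            raise ValueError("need at least 4 samples to identify 3 coefficients")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(y))):
            raise ValueError("inputs must be finite")
        if np.any(t < 0):
            raise ValueError("sampling times must be nonnegative")
        if self.dose <= 0:
            raise ValueError("dose must be positive")
        if np.all(y == 0):
            raise ValueError("observed series is identically zero; nothing to fit")

        order = np.argsort(t, kind="stable")
        t, y = t[order], y[order]

        dose = float(self.dose)

        def residual(theta: np.ndarray) -> np.ndarray:
            return self._model(t, theta[0], theta[1], theta[2], dose) - y

        lb = np.array([0.0, self.min_rate, self.min_rate])
        ub = np.array([np.inf, np.inf, np.inf])
        best = None
        n_used = 0
        converged = False
        for x0 in self._starts(t, y):
            n_used += 1
            sol = least_squares(
                residual,
                np.clip(x0, lb + 1e-12, None),
                bounds=(lb, ub),
                method="trf",
                ftol=1e-12,
                xtol=1e-12,
                gtol=1e-12,
                max_nfev=5000,
            )
            if best is None or sol.cost < best.cost:
                best = sol
            converged = converged or bool(sol.success)

        b0, lam_a, lam_b = best.x
        lam1, lam2 = (lam_a, lam_b) if lam_a >= lam_b else (lam_b, lam_a)
        self.coefficients_ = TransferCoefficients(
            b0=b0, a1=lam1 + lam2, a0=lam1 * lam2
        )
        self.lambdas_ = (float(lam1), float(lam2))
        rss = float(2.0 * best.cost)  # least_squares cost = RSS / 2
        self.result_ = FitResult(
            coefficients=self.coefficients_,
            residual_sum_of_squares=rss,
            n_observations=int(t.size),
            converged=converged,
            n_starts_used=n_used,
        )
        self.n_features_in_ = 1
        return self

    def predict(self, X) -> np.ndarray:
        if not hasattr(self, "coefficients_"):
            raise AttributeError("fit must be called before predict")
        t = np.asarray(X, dtype=float).reshape(-1)
        lam1, lam2 = self.lambdas_
        return self._model(np.maximum(t, 0.0), self.coefficients_.b0, lam1, lam2, self.dose)

    def identifiability_(self) -> IdentifiabilityResult:
        """Both rate-constant branches implied by the fitted coefficients."""
        if not hasattr(self, "coefficients_"):
            raise AttributeError("fit must be called first")
        return recover_rate_constants(self.coefficients_)


def fit_transfer_coefficients(series: Series, dose: DoseEvent) -> FitResult:
    """Fit (b0, a1, a0) to an amount series observed after an impulse dose.

    The series must already be in mg (convert concentrations with
    :func:`oralpk.endpoints.amounts_from_concentrations` first); times
    are shifted so the dose time is the model origin.
    """
    if series.units != UNITS_AMOUNT:
        raise ValueError(
            f"series must be in {UNITS_AMOUNT!r} (amounts); got {series.units!r}"
        )
    if dose.amount <= 0:
        raise ValueError("dose amount must be positive")
    fitter = TransferFunctionFitter(dose=dose.amount)
    fitter.fit(series.times - dose.start_time, series.values)
    return fitter.result_


def roundtrip_max_relative_error(params: RateConstants) -> float:
    """Max relative error of recovering ``params`` via its own transfer function.

    Convenience used by self-tests: one of the recovered branches must
    reproduce the generating triplet.
    """
    res = recover_rate_constants(transfer_function(params))
    errs = []
    for br in res.branches:
        scale = np.maximum(np.abs(params.as_tuple()), 1e-12)
        errs.append(
            float(np.max(np.abs(np.subtract(br.as_tuple(), params.as_tuple())) / scale))
        )
    return min(errs)
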