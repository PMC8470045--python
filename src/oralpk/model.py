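"""Two-compartment positive linear system for per-oral drug absorption.

The body is reduced to two well-mixed compartments: the gastrointestinal
tract (GIT), which receives the dose, and the blood, which is sampled.
Drug moves GIT -> blood with first-order absorption rate constant ``ka``
and is eliminated from each compartment with first-order constants
``ke1`` (GIT) and ``ke2`` (blood).  In state-space form::

    dx/dt = A x + b u,    y = c^T x
    A = [[-(ka + ke1), 0],
         [ ka,       -ke2]],    b = (1, 0),    c = (0, 1)

``x1`` is the drug amount in the GIT (unmeasurable in vivo), ``x2`` the
amount in blood (the observed output), and ``u`` the dosing input.

A physiologically admissible compartment system must be a *positive*
system: nonnegative doses must yield nonnegative states.  That holds iff
``b`` and ``c`` are componentwise nonnegative and ``A`` is a Metzler
matrix (nonnegative off-diagonal entries) with nonpositive diagonal;
column-wise diagonal dominance additionally guarantees that no
compartment emits more than it holds.  :func:`check_positive_compartmental`
verifies each of these conditions separately and reports violations.

The input/output behaviour is the strictly proper second-order transfer
function::

    G(s) = b0 / (s^2 + a1 s + a0)

with ``b0 = ka``, ``a1 = ka + ke1 + ke2`` and ``a0 = (ka + ke1) ke2``.
Only (b0, a1, a0) are identifiable from dose-response data; the module
:mod:`oralpk.identify` inverts this map and exposes its two-branch
ambiguity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np

__all__ = [
    "RateConstants",
    "SystemMatrices",
    "TransferCoefficients",
    "StructuralCheckReport",
    "SystemProperties",
    "build_system",
    "check_positive_compartmental",
    "transfer_function",
    "check_observability_controllability",
]


@dataclass(frozen=True)
class RateConstants:
    """First-order rate constants of the two-compartment oral model.

    Parameters
    ----------
    ka : float
        Absorption rate constant GIT -> blood, 1/h.
    ke1 : float
        Elimination rate constant from the GIT compartment, 1/h.
    ke2 : float
        Elimination rate constant from the blood compartment, 1/h.

    All three must be finite and nonnegative.
    """

    ka: float
    ke1: float
    ke2: float

    def __post_init__(self) -> None:
        for name in ("ka", "ke1", "ke2"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"rate constant {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"rate constant {name} must be nonnegative, got {value}")

    @classmethod
    def _unchecked(cls, ka: float, ke1: float, ke2: float) -> "RateConstants":
        # Bypass validation; used only to carry flagged non-compartmental
        # identification branches (e.g. negative ke1).
        obj = object.__new__(cls)
        object.__setattr__(obj, "ka", float(ka))
        object.__setattr__(obj, "ke1", float(ke1))
        object.__setattr__(obj, "ke2", float(ke2))
        return obj

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.ka, self.ke1, self.ke2)


@dataclass(frozen=True)
class TransferCoefficients:
    """Identifiable coefficients of G(s) = b0 / (s^2 + a1 s + a0).

    ``b0`` has units 1/h, ``a1`` 1/h and ``a0`` 1/h^2.  All must be
    nonnegative; whether the discriminant ``a1^2 - 4 a0`` admits a real
    (compartmental) realization is checked where the inversion happens,
    in :func:`oralpk.identify.recover_rate_constants`.
    """

    b0: float
    a1: float
    a0: float

    def __post_init__(self) -> None:
        for name in ("b0", "a1", "a0"):
            value = getattr(self, name)
            if not np.isfinite(value):
                raise ValueError(f"coefficient {name} must be finite, got {value!r}")
            if value < 0:
                raise ValueError(f"coefficient {name} must be nonnegative, got {value}")

    @property
    def discriminant(self) -> float:
        """a1^2 - 4 a0; nonnegative iff the poles are real."""
        return self.a1 * self.a1 - 4.0 * self.a0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.b0, self.a1, self.a0)


@dataclass(frozen=True)
class SystemMatrices:
    """Dense state-space triple (A, b, c) of a single-input single-output system."""

    A: np.ndarray
    b: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        A = np.atleast_2d(np.asarray(self.A, dtype=float))
        b = np.asarray(self.b, dtype=float).reshape(-1)
        c = np.asarray(self.c, dtype=float).reshape(-1)
        if A.shape[0] != A.shape[1]:
            raise ValueError(f"A must be square, got shape {A.shape}")
        n = A.shape[0]
        if b.shape != (n,):
            raise ValueError(f"b must have length {n}, got {b.shape}")
        if c.shape != (n,):
            raise ValueError(f"c must have length {n}, got {c.shape}")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "c", c)

    @property
    def n(self) -> int:
        return self.A.shape[0]


@dataclass(frozen=True)
class StructuralCheckReport:
    """Outcome of the positive-/compartmental-system structural checks.

    One flag per condition; ``violations`` holds a human-readable message
    for every failed condition, so all flags are true iff it is empty.
    """

    metzler_ok: bool
    diagonal_ok: bool
    bc_nonnegative_ok: bool
    column_dominance_ok: bool
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations


class SystemProperties(NamedTuple):
    observable: bool
    controllable: bool


def build_system(params: RateConstants) -> SystemMatrices:
    """Assemble the state-space matrices of the two-compartment oral model.

    A = [[-(ka+ke1), 0], [ka, -ke2]], b = (1, 0), c = (0, 1): the dose
    enters the GIT and the blood amount is observed.
    """
    ka, ke1, ke2 = params.as_tuple()
    A = np.array([[-(ka + ke1), 0.0], [ka, -ke2]], dtype=float)
    return SystemMatrices(A=A, b=np.array([1.0, 0.0]), c=np.array([0.0, 1.0]))


def check_positive_compartmental(
    sys: SystemMatrices, atol: float = 0.0
) -> StructuralCheckReport:
    """Check the structural conditions for a positive compartmental system.

    Four independent conditions are verified on (A, b, c), any size n:

    1. off-diagonal entries of A nonnegative (Metzler),
    2. diagonal entries of A nonpositive,
    3. entries of b and c nonnegative,
    4. column-wise diagonal dominance: -a_jj >= sum_{i != j} a_ij.

    A failing condition produces a report entry, never an exception.
    """
    A, b, c = sys.A, sys.b, sys.c
    n = sys.n
    violations: list[str] = []

    off = A - np.diag(np.diag(A))
    metzler_ok = bool(np.all(off >= -atol))
    if not metzler_ok:
        i, j = np.argwhere(off < -atol)[0]
        violations.append(
            f"off-diagonal entry A[{i},{j}] = {A[i, j]:g} is negative (not Metzler)"
        )

    diag = np.diag(A)
    diagonal_ok = bool(np.all(diag <= atol))
    if not diagonal_ok:
        i = int(np.argmax(diag > atol))
        violations.append(f"diagonal entry A[{i},{i}] = {A[i, i]:g} is positive")

    bc_nonnegative_ok = bool(np.all(b >= -atol) and np.all(c >= -atol))
    if not bc_nonnegative_ok:
        violations.append("control/observation vectors b, c contain negative entries")

    # column j: outflow -a_jj must cover the flows a_ij into other compartments
    col_sums = off.sum(axis=0)
    tol = atol + 1e-12 * max(1.0, float(np.abs(A).max()) if n else 1.0)
    column_dominance_ok = bool(np.all(-diag + tol >= col_sums))
    if not column_dominance_ok:
        j = int(np.argmax(col_sums > -diag + tol))
        violations.append(
            f"column {j} not diagonally dominant: -A[{j},{j}] = {-A[j, j]:g} "
            f"< off-diagonal column sum {col_sums[j]:g}"
        )

    return StructuralCheckReport(
        metzler_ok=metzler_ok,
        diagonal_ok=diagonal_ok,
        bc_nonnegative_ok=bc_nonnegative_ok,
        column_dominance_ok=column_dominance_ok,
        violations=violations,
    )


def transfer_function(params: RateConstants) -> TransferCoefficients:
    """Input/output coefficients of the two-compartment model.

    b0 = ka, a1 = ka + ke1 + ke2, a0 = (ka + ke1) ke2.  The poles are
    -(ka+ke1) and -ke2, both real, so the discriminant
    a1^2 - 4 a0 = (ka + ke1 - ke2)^2 is nonnegative by construction.
    """
    ka, ke1, ke2 = params.as_tuple()
    return TransferCoefficients(b0=ka, a1=ka + ke1 + ke2, a0=(ka + ke1) * ke2)


def _rank(M: np.ndarray, rtol: float) -> int:
    s = np.linalg.svd(M, compute_uv=False)
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def check_observability_controllability(
    sys: SystemMatrices, rtol: float = 1e-10
) -> SystemProperties:
    """Kalman rank tests on [b, Ab, ...] and [c; cA; ...].

    Rank is decided from singular values relative to the largest one
    (threshold ``rtol`` x sigma_max), which is scale-free.  For the oral
    model both tests succeed exactly when ka > 0: with ka = 0 the blood
    compartment is disconnected from the dosing path.
    """
    A, b, c = sys.A, sys.b, sys.c
    n = sys.n
    ctrb_cols = [b]
    obsv_rows = [c]
    for _ in range(n - 1):
        ctrb_cols.append(A @ ctrb_cols[-1])
        obsv_rows.append(obsv_rows[-1] @ A)
    ctrb = np.column_stack(ctrb_cols)
    obsv = np.vstack(obsv_rows)
    return SystemProperties(
        observable=_rank(obsv, rtol) == n,
        controllable=_rank(ctrb, rtol) == n,
    )
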