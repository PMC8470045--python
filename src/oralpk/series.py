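"""Time-ordered concentration / amount series.

A :class:`Series` is the in-memory form of one experimental condition:
drug concentration (mg/mL) or amount (mg) at each sampling time after
administration, optionally with the number of animals behind each mean
(the in-vivo design samples a fresh group of animals per time point).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

UNITS_AMOUNT = "mg"
UNITS_CONCENTRATION = "mg/mL"
_VALID_UNITS = (UNITS_AMOUNT, UNITS_CONCENTRATION)

__all__ = ["Series", "UNITS_AMOUNT", "UNITS_CONCENTRATION"]


@dataclass(frozen=True)
class Series:
    """Time-ordered values with a unit tag.

    Construction sorts by time and rejects duplicate or negative times;
    order of the supplied samples therefore never matters downstream.
    """

    times: np.ndarray  # h
    values: np.ndarray  # in `units`
    units: str
    n_animals: int | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float).reshape(-1)
        v = np.asarray(self.values, dtype=float).reshape(-1)
        if t.size != v.size:
            raise ValueError(f"times and values differ in length: {t.size} vs {v.size}")
        if self.units not in _VALID_UNITS:
            raise ValueError(f"units must be one of {_VALID_UNITS}, got {self.units!r}")
        if not np.all(np.isfinite(t)) or not np.all(np.isfinite(v)):
            raise ValueError("times and values must be finite")
        if np.any(t < 0):
            raise ValueError("negative sampling times are not allowed")
        order = np.argsort(t, kind="stable")
        t, v = t[order], v[order]
        if t.size > 1 and np.any(np.diff(t) == 0):
            dup = t[np.argmax(np.diff(t) == 0)]
            raise ValueError(f"duplicate sampling time {dup:g} h")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return int(self.times.size)

    def with_values(self, values: np.ndarray, units: str) -> "Series":
        return Series(times=self.times, values=values, units=units, n_animals=self.n_animals)
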