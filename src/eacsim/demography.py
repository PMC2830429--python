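"""Demographic inputs: life tables, cancer-specific mortality, standard weights,
and population counts.

The disease engine needs four demographic ingredients:

* a :class:`LifeTable` of annual all-cause death probabilities by single year
  of age (pre-cancerous states die at these rates);
* a :class:`CancerMortality` pair of annual death probabilities for the
  undetected and detected cancer states;
* :class:`StandardWeights` over 10-year age groups, used to age-adjust
  incidence rates;
* :class:`PopulationCounts` mapping (calendar year, age) to a head count,
  used only to scale per-100,000 rates to absolute case numbers.

All four have plain-CSV readers/writers; the readers validate strictly and
reject unknown columns so that silently misnamed inputs cannot slip through.
Defaults are synthetic stand-ins (a Gompertz–Makeham life table, a stationary
population) so the whole pipeline runs without external data.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoverageError, DemographyError

AGE_ENTRY = 20
AGE_GROUP_WIDTH = 10

#: Default Gompertz–Makeham parameters (per-year hazards). Implementation
#: fixtures giving plausible adult male mortality; any empirical table overrides.
DEFAULT_MAKEHAM_A = 5e-4
DEFAULT_GOMPERTZ_B = 3e-5
DEFAULT_GOMPERTZ_THETA = 0.09

#: Default annual death probabilities in the cancer states (fixtures; the
#: source epidemiology does not publish EAC survival, so these are
#: config-overridable stand-ins).
DEFAULT_DETECTED_CA_MORTALITY = 0.35
DEFAULT_UNDETECTED_CA_MORTALITY = 0.35

_LIFE_TABLE_COLUMNS = ("age", "annual_all_cause_probability")
_CANCER_COLUMNS = ("state", "annual_probability")
_WEIGHT_COLUMNS = ("age_group", "weight")
_COUNT_COLUMNS = ("year", "age", "count")


def age_group_labels(n_groups: int) -> tuple[str, ...]:
    """Labels like ``'20-29'`` for ``n_groups`` 10-year groups starting at 20."""
    return tuple(
        f"{AGE_ENTRY + AGE_GROUP_WIDTH * g}-{AGE_ENTRY + AGE_GROUP_WIDTH * (g + 1) - 1}"
        for g in range(n_groups)
    )


def age_group_index(age: int) -> int:
    """10-year age-group index of an integer age (20–29 -> 0, 30–39 -> 1, ...)."""
    if age < AGE_ENTRY:
        raise DemographyError(f"age {age} is below model entry age {AGE_ENTRY}")
    return (int(age) - AGE_ENTRY) // AGE_GROUP_WIDTH


def _check_columns(frame: pd.DataFrame, expected: tuple[str, ...], path: object) -> None:
    got = tuple(frame.columns)
    if set(got) != set(expected) or len(got) != len(expected):
        raise DemographyError(
            f"{path}: expected columns {list(expected)}, found {list(got)}"
        )


def _read_csv(path, expected: tuple[str, ...]) -> pd.DataFrame:
    try:
        # round_trip parsing keeps write -> read bit-identical for float64
        frame = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise DemographyError(f"{path}: file is empty") from None
    _check_columns(frame, expected, path)
    if len(frame) == 0:
        raise DemographyError(f"{path}: no data rows")
    return frame


@dataclass(frozen=True)
class LifeTable:
    """Annual all-cause death probability by single year of age.

    ``q[i]`` is the probability of dying during the year for a person aged
    ``age_min + i`` at the start of the year. Ages must be contiguous.
    """

    age_min: int
    q: np.ndarray

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        object.__setattr__(self, "q", q)
        if q.ndim != 1 or q.size == 0:
            raise DemographyError("life table must be a non-empty 1-D probability array")
        if np.any(~np.isfinite(q)) or np.any(q < 0.0) or np.any(q > 1.0):
            raise DemographyError("life-table probabilities must lie in [0, 1]")

    @property
    def age_max(self) -> int:
        return self.age_min + self.q.size - 1

    def prob(self, age):
        """Death probability at integer ``age`` (scalar or array)."""
        idx = np.asarray(age, dtype=int) - self.age_min
        if np.any(idx < 0) or np.any(idx >= self.q.size):
            raise DemographyError(
                f"age outside life-table support [{self.age_min}, {self.age_max}]"
            )
        out = self.q[idx]
        return float(out) if np.isscalar(age) else out

    def survival_from(self, age0: int, ages) -> np.ndarray:
        """P(alive at start of each ``age`` | alive at start of ``age0``)."""
        ages = np.asarray(ages, dtype=int)
        hi = int(ages.max())
        span = np.arange(age0, hi + 1)
        surv = np.concatenate([[1.0], np.cumprod(1.0 - self.prob(span[:-1]))])
        return surv[ages - age0]

    def to_csv(self, path) -> None:
        # %.17g preserves float64 exactly, so write -> read round-trips bit-identically
        pd.DataFrame(
            {
                "age": np.arange(self.age_min, self.age_max + 1),
                "annual_all_cause_probability": self.q,
            }
        ).to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        frame = _read_csv(path, _LIFE_TABLE_COLUMNS)
        ages = frame["age"].to_numpy()
        if not np.array_equal(ages, ages.astype(int)):
            raise DemographyError(f"{path}: non-integer age values")
        ages = ages.astype(int)
        order = np.argsort(ages)
        ages, q = ages[order], frame["annual_all_cause_probability"].to_numpy()[order]
        if np.any(np.diff(ages) != 1):
            raise DemographyError(f"{path}: ages are not contiguous (no interpolation is done)")
        return cls(age_min=int(ages[0]), q=q)


def load_life_table(path) -> LifeTable:
    """Read a life table CSV (columns ``age, annual_all_cause_probability``)."""
    return LifeTable.from_csv(path)


def make_gompertz_life_table(
    a: float = DEFAULT_MAKEHAM_A,
    b: float = DEFAULT_GOMPERTZ_B,
    theta: float = DEFAULT_GOMPERTZ_THETA,
    age_min: int = AGE_ENTRY,
    age_max: int = 100,
) -> LifeTable:
    """Gompertz–Makeham life table: ``q(age) = 1 − exp(−(a + b·e^{θ·age}))``.

    A synthetic stand-in for an empirical all-cause life table; ``q`` is capped
    at 1 and is non-decreasing in age.
    """
    if a < 0 or b <= 0 or theta <= 0:
        raise DemographyError("require a >= 0, b > 0, theta > 0")
    ages = np.arange(age_min, age_max + 1, dtype=float)
    hazard = a + b * np.exp(theta * ages)
    q = np.minimum(1.0 - np.exp(-hazard), 1.0)
    return LifeTable(age_min=age_min, q=q)


@dataclass(frozen=True)
class CancerMortality:
    """Annual death probabilities for the two cancer states."""

    undetected: float = DEFAULT_UNDETECTED_CA_MORTALITY
    detected: float = DEFAULT_DETECTED_CA_MORTALITY

    def __post_init__(self):
        for name, v in (("undetected", self.undetected), ("detected", self.detected)):
            if not (0.0 <= float(v) <= 1.0):
                raise DemographyError(f"cancer mortality '{name}' must lie in [0, 1]")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "state": ["UNDETECTED_CA", "DETECTED_CA"],
                "annual_probability": [self.undetected, self.detected],
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "CancerMortality":
        frame = _read_csv(path, _CANCER_COLUMNS)
        table = dict(zip(frame["state"], frame["annual_probability"]))
        unknown = set(table) - {"UNDETECTED_CA", "DETECTED_CA"}
        if unknown:
            raise DemographyError(f"{path}: unknown states {sorted(unknown)}")
        if set(table) != {"UNDETECTED_CA", "DETECTED_CA"}:
            raise DemographyError(f"{path}: both cancer states must be present")
        return cls(undetected=float(table["UNDETECTED_CA"]), detected=float(table["DETECTED_CA"]))


@dataclass(frozen=True)
class StandardWeights:
    """Non-negative weights over 10-year age groups, normalized to sum to 1."""

    labels: tuple[str, ...]
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size != len(self.labels):
            raise DemographyError("weights must be 1-D and match the age-group labels")
        if np.any(w < 0) or not np.all(np.isfinite(w)) or w.sum() <= 0:
            raise DemographyError("weights must be non-negative with a positive sum")
        object.__setattr__(self, "weights", w / w.sum())
        object.__setattr__(self, "labels", tuple(self.labels))

    @classmethod
    def equal(cls, n_groups: int = 6) -> "StandardWeights":
        return cls(age_group_labels(n_groups), np.ones(n_groups))

    def to_csv(self, path) -> None:
        pd.DataFrame({"age_group": list(self.labels), "weight": self.weights}).to_csv(
            path, index=False
        )

    @classmethod
    def from_csv(cls, path) -> "StandardWeights":
        frame = _read_csv(path, _WEIGHT_COLUMNS)
        return cls(tuple(frame["age_group"]), frame["weight"].to_numpy())


def stationary_age_group_weights(life_table: LifeTable, n_groups: int = 6) -> StandardWeights:
    """Age-group weights of the stationary population implied by a life table.

    With one same-sized cohort entering at age 20 every year, the standing
    population has age distribution proportional to survival from age 20;
    weights are that distribution summed within each 10-year group. This is the
    documented default weighting for *overall* (all-adult) prevalence figures.
    """
    ages = np.arange(AGE_ENTRY, AGE_ENTRY + AGE_GROUP_WIDTH * n_groups)
    surv = life_table.survival_from(AGE_ENTRY, ages)
    grouped = surv.reshape(n_groups, AGE_GROUP_WIDTH).sum(axis=1)
    return StandardWeights(age_group_labels(n_groups), grouped)


def age_adjust(incidence_by_group, weights: StandardWeights) -> float:
    """Directly age-standardized rate: ``Σ_g w_g · rate_g``.

    ``incidence_by_group`` is either a mapping from age-group label to rate or
    an array ordered like ``weights.labels``. Group keys must match exactly.
    """
    if isinstance(incidence_by_group, Mapping):
        if set(incidence_by_group) != set(weights.labels):
            raise CoverageError(
                f"age groups {sorted(incidence_by_group)} do not match weights "
                f"{sorted(weights.labels)}"
            )
        rates = np.array([incidence_by_group[g] for g in weights.labels], dtype=float)
    else:
        rates = np.asarray(incidence_by_group, dtype=float)
        if rates.shape != weights.weights.shape:
            raise CoverageError("rate vector length does not match the weight vector")
    return float(np.dot(weights.weights, rates))


@dataclass(frozen=True)
class PopulationCounts:
    """Head counts by (calendar year, single year of age).

    The default is a stationary 1,000,000 persons per single year of age in
    every calendar year, which makes absolute case counts deterministic and
    interpretable without external demographic data.
    """

    constant: float | None = 1_000_000.0
    table: pd.DataFrame | None = None  # columns: year, age, count

    @classmethod
    def stationary(cls, per_age: float = 1_000_000.0) -> "PopulationCounts":
        if per_age < 0:
            raise DemographyError("population count must be non-negative")
        return cls(constant=float(per_age), table=None)

    @classmethod
    def from_csv(cls, path) -> "PopulationCounts":
        frame = _read_csv(path, _COUNT_COLUMNS)
        if (frame["count"] < 0).any():
            raise DemographyError(f"{path}: negative counts")
        return cls(constant=None, table=frame)

    def counts(self, years, ages) -> np.ndarray:
        """Matrix of counts with shape ``(len(years), len(ages))``."""
        years = np.asarray(years, dtype=int)
        ages = np.asarray(ages, dtype=int)
        if self.constant is not None:
            return np.full((years.size, ages.size), self.constant, dtype=float)
        pivot = self.table.pivot_table(index="year", columns="age", values="count")
        try:
            block = pivot.loc[years, ages]
        except KeyError as exc:
            raise DemographyError(f"population counts missing requested cells: {exc}") from None
        out = block.to_numpy(dtype=float)
        if np.any(~np.isfinite(out)):
            raise DemographyError("population counts missing requested (year, age) cells")
        return out
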