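"""Calibration/validation targets and the synthetic target generator.

Three target endpoints drive calibration: age-specific GERD-symptom
prevalence, age-specific BE prevalence (both assumed constant over calendar
time) and age-specific EAC incidence (rising with calendar year). The
representative-year values printed in the source epidemiology ship as a
built-in fixture (:func:`table2_fixture`); users with a real SEER-style
incidence series can load it from CSV; and
:func:`generate_synthetic_targets` produces targets from a known ground-truth
parameter set so that calibration can be tested by parameter recovery without
any external data.

Prevalence targets may carry the year sentinel ``ALL``; they expand to every
year of the role they are scored under (constant-prevalence assumption).
Observation noise for synthetic targets is multiplicative mean-one lognormal:
rates are positive and their sampling error scales roughly with the rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    ENDPOINT_BE_PREV,
    ENDPOINT_EAC_INCIDENCE,
    ENDPOINT_GERD_PREV,
    ENDPOINTS,
    TransitionParameters,
    simulate_population,
)
from .demography import CancerMortality, LifeTable, age_group_labels
from .errors import CoverageError

ROLE_CALIBRATION = "CALIBRATION"
ROLE_VALIDATION = "VALIDATION"
ROLES = (ROLE_CALIBRATION, ROLE_VALIDATION)

YEAR_ALL = "ALL"

_TARGET_COLUMNS = ("endpoint", "year", "age_group", "value", "role")
_INCIDENCE_COLUMNS = ("year", "age_group", "rate_per_100k")


@dataclass(frozen=True)
class CalibrationTarget:
    """One empirical endpoint value the model is fitted (or validated) against."""

    endpoint: str
    year: int | str  # calendar year, or YEAR_ALL for time-constant prevalences
    age_group: str
    value: float
    role: str = ROLE_CALIBRATION

    def __post_init__(self):
        if self.endpoint not in ENDPOINTS:
            raise CoverageError(f"unknown endpoint {self.endpoint!r}")
        if self.role not in ROLES:
            raise CoverageError(f"unknown role {self.role!r}")
        if self.value < 0:
            raise CoverageError(f"target value must be non-negative, got {self.value}")
        if self.year == YEAR_ALL:
            if self.endpoint == ENDPOINT_EAC_INCIDENCE:
                raise CoverageError("incidence targets must carry an explicit calendar year")
        else:
            object.__setattr__(self, "year", int(self.year))


@dataclass(frozen=True)
class TargetSet:
    """A collection of targets plus the calibration/validation year split."""

    targets: tuple[CalibrationTarget, ...]
    calibration_years: tuple[int, ...]
    validation_years: tuple[int, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "targets", tuple(self.targets))
        object.__setattr__(self, "calibration_years", tuple(int(y) for y in self.calibration_years))
        object.__setattr__(self, "validation_years", tuple(int(y) for y in self.validation_years))
        if set(self.calibration_years) & set(self.validation_years):
            raise CoverageError("calibration and validation year ranges must be disjoint")
        missing = set(ENDPOINTS) - {
            t.endpoint for t in self.targets if t.role == ROLE_CALIBRATION
        }
        if missing:
            raise CoverageError(f"calibration role is missing endpoints: {sorted(missing)}")

    def years_for_role(self, role: str) -> tuple[int, ...]:
        return self.calibration_years if role == ROLE_CALIBRATION else self.validation_years

    def expanded(self, role: str) -> list[CalibrationTarget]:
        """Concrete (endpoint, year, group, value) cells for one role.

        ``ALL``-year prevalence targets are replicated across every year of the
        role, so a constant prevalence is scored once per year (and therefore
        carries per-year weight in the goodness of fit).
        """
        years = self.years_for_role(role)
        out: list[CalibrationTarget] = []
        for t in self.targets:
            if t.role != role:
                continue
            if t.year == YEAR_ALL:
                out.extend(
                    CalibrationTarget(t.endpoint, y, t.age_group, t.value, t.role) for y in years
                )
            else:
                out.append(t)
        return out

    def endpoints(self, role: str = ROLE_CALIBRATION) -> tuple[str, ...]:
        present = {t.endpoint for t in self.targets if t.role == role}
        return tuple(e for e in ENDPOINTS if e in present)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(t.endpoint, t.year, t.age_group, t.value, t.role) for t in self.targets],
            columns=list(_TARGET_COLUMNS),
        )

    def to_csv(self, path) -> None:
        # %.17g keeps float64 values exact through the write -> read round trip
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path, calibration_years, validation_years=()) -> "TargetSet":
        frame = pd.read_csv(path, float_precision="round_trip")
        if tuple(frame.columns) != _TARGET_COLUMNS:
            raise CoverageError(
                f"{path}: expected columns {list(_TARGET_COLUMNS)}, found {list(frame.columns)}"
            )
        targets = [
            CalibrationTarget(r.endpoint, r.year, r.age_group, float(r.value), r.role)
            for r in frame.itertuples()
        ]
        return cls(tuple(targets), tuple(calibration_years), tuple(validation_years))


# ---------------------------------------------------------------------------
# Built-in representative-year fixture
# ---------------------------------------------------------------------------

#: Representative-year (1986) calibration targets by 10-year age group, 20–79.
TABLE2_YEAR = 1986
TABLE2_EAC_INCIDENCE = (0.0, 0.3, 0.6, 3.3, 7.4, 9.3)  # per 100,000
TABLE2_BE_PREVALENCE = (1.7, 2.5, 3.3, 4.1, 5.0, 5.8)  # %
TABLE2_GERD_PREVALENCE = (17.6, 18.0, 18.4, 18.8, 19.1, 19.5)  # %


def table2_fixture(
    calibration_years=(TABLE2_YEAR,), validation_years=()
) -> TargetSet:
    """The built-in representative-year (1986) age-specific target fixture.

    EAC incidence carries the explicit year 1986; the two prevalence endpoints
    are time-constant (``ALL``) and expand over whatever calibration years the
    caller requests (default: representative-year mode, 1986 only).
    """
    labels = age_group_labels(6)
    targets: list[CalibrationTarget] = []
    for g, label in enumerate(labels):
        targets.append(
            CalibrationTarget(ENDPOINT_EAC_INCIDENCE, TABLE2_YEAR, label, TABLE2_EAC_INCIDENCE[g])
        )
        targets.append(CalibrationTarget(ENDPOINT_BE_PREV, YEAR_ALL, label, TABLE2_BE_PREVALENCE[g]))
        targets.append(
            CalibrationTarget(ENDPOINT_GERD_PREV, YEAR_ALL, label, TABLE2_GERD_PREVALENCE[g])
        )
    return TargetSet(tuple(targets), tuple(calibration_years), tuple(validation_years))


# ---------------------------------------------------------------------------
# Synthetic SEER-like targets from a known truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground-truth parameters plus an observation-noise level for recovery tests."""

    true_params: TransitionParameters
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.noise_cv < 0:
            raise CoverageError("noise_cv must be non-negative")


def generate_synthetic_targets(
    truth: SyntheticTruth,
    years,
    life_table: LifeTable,
    cancer_mortality: CancerMortality,
    validation_years=(),
    *,
    undetected_all_cause: bool = False,
) -> TargetSet:
    """Targets produced by the model itself under a known parameter set.

    Emulates the structure of the real calibration data: prevalences constant
    over calendar time (emitted once with year ``ALL``, taken from the first
    requested year — under stationary demography they are identical in every
    year) and an incidence series per (year, age group) rising through the
    secular multiplier. With ``noise_cv = 0`` the targets equal the model
    output exactly, so the truth's goodness of fit is zero.
    """
    cal_years = tuple(int(y) for y in years)
    val_years = tuple(int(y) for y in validation_years)
    all_years = sorted(set(cal_years) | set(val_years))
    output = simulate_population(
        truth.true_params,
        range(all_years[0], all_years[-1] + 1),
        life_table,
        cancer_mortality,
        undetected_all_cause=undetected_all_cause,
    )
    rng = np.random.default_rng(truth.seed)

    def _noisy(value: float) -> float:
        if truth.noise_cv == 0.0:
            return float(value)
        sigma = np.sqrt(np.log1p(truth.noise_cv**2))
        return float(value * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma))

    labels = age_group_labels(truth.true_params.n_groups)
    targets: list[CalibrationTarget] = []
    i0 = output.year_index(cal_years[0])
    gerd = output.gerd_prevalence()
    be = output.be_prevalence()
    inc = output.eac_incidence()
    for g, label in enumerate(labels):
        targets.append(CalibrationTarget(ENDPOINT_GERD_PREV, YEAR_ALL, label, _noisy(gerd[i0, g])))
        targets.append(CalibrationTarget(ENDPOINT_BE_PREV, YEAR_ALL, label, _noisy(be[i0, g])))
    for role, role_years in ((ROLE_CALIBRATION, cal_years), (ROLE_VALIDATION, val_years)):
        for y in role_years:
            iy = output.year_index(y)
            for g, label in enumerate(labels):
                targets.append(
                    CalibrationTarget(ENDPOINT_EAC_INCIDENCE, y, label, _noisy(inc[iy, g]), role)
                )
    if val_years:
        for g, label in enumerate(labels):
            targets.append(
                CalibrationTarget(
                    ENDPOINT_GERD_PREV, YEAR_ALL, label, _noisy(gerd[i0, g]), ROLE_VALIDATION
                )
            )
            targets.append(
                CalibrationTarget(
                    ENDPOINT_BE_PREV, YEAR_ALL, label, _noisy(be[i0, g]), ROLE_VALIDATION
                )
            )
    return TargetSet(tuple(targets), cal_years, val_years)


# ---------------------------------------------------------------------------
# Optional external incidence reader
# ---------------------------------------------------------------------------


def load_incidence_csv(path, role: str = ROLE_CALIBRATION) -> list[CalibrationTarget]:
    """Read an external age-specific incidence series (per 100,000).

    Expected columns: ``year, age_group, rate_per_100k`` with age-group labels
    exactly ``20-29`` … ``70-79``. Rows with unknown labels or negative rates
    are rejected with their row number.
    """
    frame = pd.read_csv(path)
    if tuple(frame.columns) != _INCIDENCE_COLUMNS:
        raise CoverageError(
            f"{path}: expected columns {list(_INCIDENCE_COLUMNS)}, found {list(frame.columns)}"
        )
    known = set(age_group_labels(6))
    targets = []
    for i, row in enumerate(frame.itertuples(), start=2):  # header is line 1
        if row.age_group not in known:
            raise CoverageError(f"{path}, line {i}: unknown age group {row.age_group!r}")
        if row.rate_per_100k < 0:
            raise CoverageError(f"{path}, line {i}: negative rate {row.rate_per_100k}")
        targets.append(
            CalibrationTarget(
                ENDPOINT_EAC_INCIDENCE, int(row.year), row.age_group, float(row.rate_per_100k), role
            )
        )
    return targets


def write_incidence_csv(targets, path) -> None:
    """Inverse of :func:`load_incidence_csv` (round-trips exactly)."""
    pd.DataFrame(
        [(t.year, t.age_group, t.value) for t in targets],
        columns=list(_INCIDENCE_COLUMNS),
    ).to_csv(path, index=False)
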