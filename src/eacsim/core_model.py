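"""Deterministic annual-cycle Markov cohort model of esophageal adenocarcinoma.

The natural-history model tracks a closed cohort of white men from age 20
through seven ordered health states::

    NORMAL -> GERD -> {BE_SSBE, BE_LSBE} -> UNDETECTED_CA -> DETECTED_CA -> DEATH

There is no regression: probability mass only ever moves forward in this
order. Normal mucosa can progress to Barrett's esophagus (BE) either through
GERD symptoms or directly (a significant share of BE patients never report
reflux symptoms). Incident BE splits 1:3 into long-segment (LSBE) and
short-segment (SSBE) disease; SSBE progresses to cancer at half the LSBE
rate (surface-area rationale). Undetected cancers surface clinically after an
exponentially distributed sojourn time, and a linear calendar-time (secular)
multiplier on the BE->cancer hazard reproduces the rising incidence.

Two propagation paths are provided and kept numerically identical:

* :func:`simulate_cohort` applies :func:`build_transition_matrix` cycle by
  cycle to a single birth cohort — the transparent reference path;
* :class:`PopulationEngine` sweeps a (calendar year x age) occupancy grid over
  all overlapping birth cohorts with vectorized updates — the fast path used
  inside calibration, where the model is evaluated tens of thousands of times.

Competing risks within a cycle are resolved death-first: the all-cause (or
cancer-specific) death probability is applied, then disease transitions are
distributed among survivors in proportion to their annual probabilities,
rescaled if they would sum above one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .demography import (
    AGE_ENTRY,
    AGE_GROUP_WIDTH,
    CancerMortality,
    LifeTable,
    StandardWeights,
    age_adjust,
    age_group_labels,
)
from .errors import CoverageError, DemographyError, ParameterDomainError, StructuralError

# ---------------------------------------------------------------------------
# States
# ---------------------------------------------------------------------------

STATES = (
    "NORMAL",
    "GERD",
    "BE_SSBE",
    "BE_LSBE",
    "UNDETECTED_CA",
    "DETECTED_CA",
    "DEATH",
)
N_STATES = len(STATES)
NORMAL, GERD, BE_SSBE, BE_LSBE, UNDETECTED_CA, DETECTED_CA, DEATH = range(N_STATES)

#: Calendar year at which the secular multiplier equals 1.
SECULAR_ANCHOR_YEAR = 1973

#: Constants from the model's structural assumptions.
LSBE_FRACTION = 0.25  # 1:3 LSBE:SSBE split of incident BE
SSBE_MULTIPLIER = 0.5  # SSBE progresses at half the LSBE rate (1:2)

SOJOURN_YEARS_MIN = 4.0
SOJOURN_YEARS_MAX = 9.0


def state_index(label: str) -> int:
    try:
        return STATES.index(label)
    except ValueError:
        raise StructuralError(f"unknown health state {label!r}") from None


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransitionParameters:
    """The calibrated unknowns of the natural-history model.

    The three pre-cancer transition probabilities and the BE->undetected-cancer
    base rate are piecewise-constant over 10-year age groups (one value per
    group); scalars are broadcast to all groups. ``r_lsbe_ca`` is the LSBE
    hazard at the secular anchor year (1973); SSBE progresses at
    ``ssbe_multiplier`` times the LSBE rate. The secular multiplier
    ``m(y) = max(0, 1 + secular_slope·(y − 1973))`` scales both BE->cancer
    hazards. ``mean_sojourn_years`` is the mean undetected->detected sojourn
    time, converted to an annual probability as ``1 − exp(−1/T)``.
    """

    p_normal_gerd: np.ndarray
    p_normal_be: np.ndarray
    p_gerd_be: np.ndarray
    r_lsbe_ca: np.ndarray
    secular_slope: float
    mean_sojourn_years: float
    lsbe_fraction: float = LSBE_FRACTION
    ssbe_multiplier: float = SSBE_MULTIPLIER

    def __post_init__(self):
        png = np.atleast_1d(np.asarray(self.p_normal_gerd, dtype=float))
        n_groups = png.size

        def _groupwise(name, value):
            arr = np.atleast_1d(np.asarray(value, dtype=float))
            if arr.size == 1:
                arr = np.full(n_groups, float(arr[0]))
            if arr.shape != (n_groups,):
                raise ParameterDomainError(
                    f"{name} must be scalar or length {n_groups}, got shape {arr.shape}"
                )
            return arr

        object.__setattr__(self, "p_normal_gerd", png)
        object.__setattr__(self, "p_normal_be", _groupwise("p_normal_be", self.p_normal_be))
        object.__setattr__(self, "p_gerd_be", _groupwise("p_gerd_be", self.p_gerd_be))
        object.__setattr__(self, "r_lsbe_ca", _groupwise("r_lsbe_ca", self.r_lsbe_ca))
        self.validate()

    def validate(self) -> None:
        for name in ("p_normal_gerd", "p_normal_be", "p_gerd_be", "r_lsbe_ca"):
            arr = getattr(self, name)
            if np.any(~np.isfinite(arr)) or np.any(arr < 0.0) or np.any(arr > 1.0):
                raise ParameterDomainError(f"{name} must lie in [0, 1]")
        if not np.isfinite(self.secular_slope):
            raise ParameterDomainError("secular_slope must be finite")
        if not (SOJOURN_YEARS_MIN <= self.mean_sojourn_years <= SOJOURN_YEARS_MAX):
            raise ParameterDomainError(
                f"mean_sojourn_years must lie in [{SOJOURN_YEARS_MIN}, {SOJOURN_YEARS_MAX}]"
            )
        if self.lsbe_fraction != LSBE_FRACTION:
            raise ParameterDomainError(f"lsbe_fraction is fixed at {LSBE_FRACTION} (1:3 split)")
        if self.ssbe_multiplier != SSBE_MULTIPLIER:
            raise ParameterDomainError(f"ssbe_multiplier is fixed at {SSBE_MULTIPLIER} (1:2 ratio)")

    @property
    def n_groups(self) -> int:
        return self.p_normal_gerd.size

    @property
    def max_age(self) -> int:
        """Oldest age covered by the age-group parameterization (inclusive)."""
        return AGE_ENTRY + AGE_GROUP_WIDTH * self.n_groups - 1

    @property
    def detection_probability(self) -> float:
        """Annual undetected->detected probability under the exponential-sojourn convention."""
        return 1.0 - np.exp(-1.0 / self.mean_sojourn_years)

    def secular_multiplier(self, year) -> np.ndarray | float:
        m = 1.0 + self.secular_slope * (np.asarray(year, dtype=float) - SECULAR_ANCHOR_YEAR)
        out = np.maximum(m, 0.0)
        return float(out) if np.isscalar(year) else out

    def group_of(self, age: int) -> int:
        """Age-group index; ages past the last group reuse its rates.

        Reported outputs only cover ages 20..max_age, but a single cohort may
        be propagated beyond the oldest parameterized group (e.g. past 79), in
        which case the last group's transition probabilities apply.
        """
        g = (int(age) - AGE_ENTRY) // AGE_GROUP_WIDTH
        if g < 0:
            raise ParameterDomainError(f"age {age} below model entry age {AGE_ENTRY}")
        return min(g, self.n_groups - 1)


def _aspirin_reduction(intervention, age, year):
    """Multiplier (1 − annual reduction) if chemoprevention is active, else 1."""
    if intervention is None:
        return 1.0
    active = (age >= intervention.start_age) & (np.asarray(year) >= intervention.start_year)
    return np.where(active, 1.0 - intervention.annual_reduction, 1.0)


# ---------------------------------------------------------------------------
# One-cycle transition matrix (reference path)
# ---------------------------------------------------------------------------


def build_transition_matrix(
    params: TransitionParameters,
    age: int,
    year: int,
    all_cause_q: float,
    cancer_q: float,
    intervention=None,
    *,
    undetected_q: float | None = None,
) -> np.ndarray:
    """Row-stochastic one-year transition matrix for a given age and calendar year.

    Death is resolved first (``all_cause_q`` in pre-cancer states, ``cancer_q``
    in cancer states — pass ``undetected_q`` to give the undetected state a
    different, e.g. all-cause, mortality); the annual disease probabilities are
    then applied to survivors, rescaled proportionally if they would sum above
    one. Incident BE splits ``lsbe_fraction`` : ``1 − lsbe_fraction`` into
    LSBE : SSBE.
    """
    params.validate()
    for name, q in (("all_cause_q", all_cause_q), ("cancer_q", cancer_q)):
        if not (0.0 <= q <= 1.0):
            raise ParameterDomainError(f"{name}={q} outside [0, 1]")
    if undetected_q is None:
        undetected_q = cancer_q
    elif not (0.0 <= undetected_q <= 1.0):
        raise ParameterDomainError(f"undetected_q={undetected_q} outside [0, 1]")
    if age < AGE_ENTRY:
        raise ParameterDomainError(f"age {age} below model entry age {AGE_ENTRY}")

    g = params.group_of(age)
    m = params.secular_multiplier(year)
    red = float(_aspirin_reduction(intervention, age, year))
    h_lsbe = float(np.clip(params.r_lsbe_ca[g] * m * red, 0.0, 1.0))
    h_ssbe = float(np.clip(params.ssbe_multiplier * params.r_lsbe_ca[g] * m * red, 0.0, 1.0))
    p_det = params.detection_probability
    fl, fs = params.lsbe_fraction, 1.0 - params.lsbe_fraction

    png, pnb, pgb = params.p_normal_gerd[g], params.p_normal_be[g], params.p_gerd_be[g]
    total = png + pnb
    if total > 1.0:  # proportional rescale keeps the row stochastic
        png, pnb = png / total, pnb / total

    q, qu, qd = all_cause_q, undetected_q, cancer_q
    mat = np.zeros((N_STATES, N_STATES))

    mat[NORMAL, DEATH] = q
    mat[NORMAL, GERD] = (1 - q) * png
    mat[NORMAL, BE_SSBE] = (1 - q) * fs * pnb
    mat[NORMAL, BE_LSBE] = (1 - q) * fl * pnb
    mat[NORMAL, NORMAL] = (1 - q) * (1 - png - pnb)

    mat[GERD, DEATH] = q
    mat[GERD, BE_SSBE] = (1 - q) * fs * pgb
    mat[GERD, BE_LSBE] = (1 - q) * fl * pgb
    mat[GERD, GERD] = (1 - q) * (1 - pgb)

    mat[BE_SSBE, DEATH] = q
    mat[BE_SSBE, UNDETECTED_CA] = (1 - q) * h_ssbe
    mat[BE_SSBE, BE_SSBE] = (1 - q) * (1 - h_ssbe)

    mat[BE_LSBE, DEATH] = q
    mat[BE_LSBE, UNDETECTED_CA] = (1 - q) * h_lsbe
    mat[BE_LSBE, BE_LSBE] = (1 - q) * (1 - h_lsbe)

    mat[UNDETECTED_CA, DEATH] = qu
    mat[UNDETECTED_CA, DETECTED_CA] = (1 - qu) * p_det
    mat[UNDETECTED_CA, UNDETECTED_CA] = (1 - qu) * (1 - p_det)

    mat[DETECTED_CA, DEATH] = qd
    mat[DETECTED_CA, DETECTED_CA] = 1 - qd

    mat[DEATH, DEATH] = 1.0
    return mat


# ---------------------------------------------------------------------------
# Single-cohort simulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortTrajectory:
    """Expected-fraction trajectory of one birth cohort entering at age 20.

    ``occupancy[t]`` is the state distribution at the start of calendar year
    ``birth_year + 20 + t``; ``new_detections[t]`` and ``deaths[t]`` are the
    fractions newly entering DETECTED_CA / DEATH during that year.
    """

    birth_year: int
    occupancy: np.ndarray  # (T+1, N_STATES)
    new_detections: np.ndarray  # (T,)
    deaths: np.ndarray  # (T,)

    @property
    def entry_year(self) -> int:
        return self.birth_year + AGE_ENTRY

    def age_at(self, t: int) -> int:
        return AGE_ENTRY + t

    def year_at(self, t: int) -> int:
        return self.entry_year + t


def simulate_cohort(
    params: TransitionParameters,
    birth_year: int,
    life_table: LifeTable,
    cancer_mortality: CancerMortality,
    end_year: int,
    intervention=None,
    *,
    undetected_all_cause: bool = False,
) -> CohortTrajectory:
    """Propagate one cohort from age 20 through ``end_year`` (inclusive).

    The whole cohort starts in NORMAL. Each cycle applies the transition
    matrix for the cohort's current age and calendar year; the matrix is
    rebuilt every cycle because mortality is age-dependent and the secular
    multiplier (and chemoprevention eligibility) are calendar-dependent.
    """
    entry_year = birth_year + AGE_ENTRY
    if entry_year > end_year:
        raise DemographyError(
            f"cohort enters in {entry_year}, after the requested end year {end_year}"
        )
    n_cycles = end_year - entry_year + 1
    final_age = AGE_ENTRY + n_cycles - 1
    if final_age > life_table.age_max:
        raise DemographyError(
            f"cohort reaches age {final_age}, beyond life-table support {life_table.age_max}"
        )

    occ = np.zeros((n_cycles + 1, N_STATES))
    occ[0, NORMAL] = 1.0
    detections = np.zeros(n_cycles)
    deaths = np.zeros(n_cycles)
    for t in range(n_cycles):
        age = AGE_ENTRY + t
        year = entry_year + t
        mat = build_transition_matrix(
            params,
            age,
            year,
            all_cause_q=life_table.prob(age),
            cancer_q=cancer_mortality.detected,
            intervention=intervention,
            undetected_q=life_table.prob(age) if undetected_all_cause else cancer_mortality.undetected,
        )
        occ[t + 1] = occ[t] @ mat
        detections[t] = occ[t, UNDETECTED_CA] * mat[UNDETECTED_CA, DETECTED_CA]
        deaths[t] = occ[t + 1, DEATH] - occ[t, DEATH]
    return CohortTrajectory(
        birth_year=birth_year, occupancy=occ, new_detections=detections, deaths=deaths
    )


# ---------------------------------------------------------------------------
# Population outputs
# ---------------------------------------------------------------------------

ENDPOINT_GERD_PREV = "GERD_PREV"
ENDPOINT_BE_PREV = "BE_PREV"
ENDPOINT_EAC_INCIDENCE = "EAC_INCIDENCE"
ENDPOINTS = (ENDPOINT_GERD_PREV, ENDPOINT_BE_PREV, ENDPOINT_EAC_INCIDENCE)


@dataclass(frozen=True)
class PopulationOutput:
    """Calendar-year cross-sections of the overlapping-cohort population.

    Per-age arrays have shape ``(n_years, n_ages)`` where ages run 20..max_age:
    ``alive``, ``gerd`` and ``be`` are start-of-year occupancy fractions per
    entering-cohort unit; ``detections`` is the fraction newly detected with
    cancer during the year. Prevalences are reported in percent among the
    alive, incidence per 100,000 alive person-years (person-years approximated
    by the start-of-year alive mass).
    """

    years: np.ndarray
    ages: np.ndarray
    alive: np.ndarray
    gerd: np.ndarray
    be: np.ndarray
    detections: np.ndarray

    @property
    def n_groups(self) -> int:
        return self.ages.size // AGE_GROUP_WIDTH

    @property
    def age_groups(self) -> tuple[str, ...]:
        return age_group_labels(self.n_groups)

    def _grouped(self, arr: np.ndarray) -> np.ndarray:
        return arr.reshape(arr.shape[0], self.n_groups, AGE_GROUP_WIDTH).sum(axis=2)

    def gerd_prevalence(self) -> np.ndarray:
        """% of alive in the GERD state, shape (n_years, n_groups)."""
        return 100.0 * self._grouped(self.gerd) / self._grouped(self.alive)

    def be_prevalence(self) -> np.ndarray:
        """% of alive in a BE state (cancer states excluded), shape (n_years, n_groups)."""
        return 100.0 * self._grouped(self.be) / self._grouped(self.alive)

    def eac_incidence(self) -> np.ndarray:
        """Detected cancers per 100,000 alive person-years, shape (n_years, n_groups)."""
        return 1e5 * self._grouped(self.detections) / self._grouped(self.alive)

    def endpoint(self, endpoint: str) -> np.ndarray:
        if endpoint == ENDPOINT_GERD_PREV:
            return self.gerd_prevalence()
        if endpoint == ENDPOINT_BE_PREV:
            return self.be_prevalence()
        if endpoint == ENDPOINT_EAC_INCIDENCE:
            return self.eac_incidence()
        raise CoverageError(f"unknown endpoint {endpoint!r}")

    def year_index(self, year: int) -> int:
        idx = int(year) - int(self.years[0])
        if idx < 0 or idx >= self.years.size:
            raise CoverageError(f"year {year} not simulated (have {self.years[0]}–{self.years[-1]})")
        return idx

    def age_adjusted_incidence(self, weights: StandardWeights | None = None) -> np.ndarray:
        """Directly standardized incidence per calendar year under ``weights``."""
        if weights is None:
            weights = StandardWeights.equal(self.n_groups)
        inc = self.eac_incidence()
        return np.array([age_adjust(dict(zip(self.age_groups, row)), weights) for row in inc])

    def overall_prevalence(self, endpoint: str, weights: StandardWeights) -> np.ndarray:
        """Age-standardized overall prevalence (%) per calendar year."""
        prev = self.endpoint(endpoint)
        return prev @ weights.weights if tuple(weights.labels) == self.age_groups else np.array(
            [age_adjust(dict(zip(self.age_groups, row)), weights) for row in prev]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy table with columns year, age_group, endpoint, value."""
        rows = []
        for endpoint in ENDPOINTS:
            values = self.endpoint(endpoint)
            for i, year in enumerate(self.years):
                for g, label in enumerate(self.age_groups):
                    rows.append((int(year), label, endpoint, values[i, g]))
        return pd.DataFrame(rows, columns=["year", "age_group", "endpoint", "value"])

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Population engine (fast path)
# ---------------------------------------------------------------------------


class PopulationEngine:
    """Vectorized multi-cohort sweep over a (calendar year x age) grid.

    One unit-sized cohort enters at age 20 every calendar year. The sweep
    starts early enough (``years[0] − (max_age − 20)``) that every age up to
    ``max_age`` is populated in every requested year. Demography-dependent
    quantities are precomputed once so the per-parameter-set cost during
    calibration is a short loop of small vector operations.
    """

    def __init__(
        self,
        life_table: LifeTable,
        cancer_mortality: CancerMortality,
        years,
        n_groups: int = 6,
        intervention=None,
        *,
        undetected_all_cause: bool = False,
    ):
        years = np.asarray(sorted(set(int(y) for y in np.asarray(years).ravel())))
        if years.size == 0:
            raise CoverageError("no calendar years requested")
        if np.any(np.diff(years) != 1):
            raise CoverageError("requested calendar years must be contiguous")
        self.years = years
        self.n_groups = int(n_groups)
        max_age = AGE_ENTRY + AGE_GROUP_WIDTH * self.n_groups - 1
        if max_age > life_table.age_max:
            raise DemographyError(
                f"need mortality up to age {max_age}, life table ends at {life_table.age_max}"
            )
        self.ages = np.arange(AGE_ENTRY, max_age + 1)
        self.life_table = life_table
        self.cancer_mortality = cancer_mortality
        self.intervention = intervention
        self.undetected_all_cause = undetected_all_cause

        self._q = life_table.prob(self.ages)
        self._group_idx = (self.ages - AGE_ENTRY) // AGE_GROUP_WIDTH
        self._sweep_start = int(years[0]) - (max_age - AGE_ENTRY)
        self._age_eligible = (
            self.ages >= intervention.start_age if intervention is not None else None
        )

    def run(self, params: TransitionParameters) -> PopulationOutput:
        if params.n_groups != self.n_groups:
            raise CoverageError(
                f"parameters have {params.n_groups} age groups, engine expects {self.n_groups}"
            )
        params.validate()
        A = self.ages.size
        q = self._q
        sN = 1.0 - q
        qu = q if self.undetected_all_cause else np.full(A, self.cancer_mortality.undetected)
        qd = np.full(A, self.cancer_mortality.detected)
        p_det = params.detection_probability

        gi = self._group_idx
        png = params.p_normal_gerd[gi]
        pnb = params.p_normal_be[gi]
        pgb = params.p_gerd_be[gi]
        r_l = params.r_lsbe_ca[gi]
        total = png + pnb
        scale = np.where(total > 1.0, 1.0 / np.maximum(total, 1e-300), 1.0)
        png = png * scale
        pnb = pnb * scale
        fl, fs = params.lsbe_fraction, 1.0 - params.lsbe_fraction
        slope = params.secular_slope
        asp = self.intervention
        r_annual = asp.annual_reduction if asp is not None else 0.0

        y0, y1 = self._sweep_start, int(self.years[-1])
        out_offset = int(self.years[0]) - y0
        nY = self.years.size

        # state occupancancy by age (start of current year)
        N = np.zeros(A)
        G = np.zeros(A)
        S = np.zeros(A)
        L = np.zeros(A)
        U = np.zeros(A)
        D = np.zeros(A)
        X = np.zeros(A)

        alive_out = np.empty((nY, A))
        gerd_out = np.empty((nY, A))
        be_out = np.empty((nY, A))
        det_out = np.empty((nY, A))

        for k, year in enumerate(range(y0, y1 + 1)):
            N[0] = 1.0  # new cohort enters at age 20
            G[0] = S[0] = L[0] = U[0] = D[0] = X[0] = 0.0

            m = max(0.0, 1.0 + slope * (year - SECULAR_ANCHOR_YEAR))
            if asp is not None and year >= asp.start_year:
                red = np.where(self._age_eligible, 1.0 - r_annual, 1.0)
            else:
                red = 1.0
            h_l = np.clip(r_l * m * red, 0.0, 1.0)
            h_s = np.clip(params.ssbe_multiplier * r_l * m * red, 0.0, 1.0)

            newdet = U * (1.0 - qu) * p_det
            i = k - out_offset
            if i >= 0:
                alive_out[i] = 1.0 - X
                gerd_out[i] = G
                be_out[i] = S + L
                det_out[i] = newdet

            be_in = N * sN * pnb + G * sN * pgb
            N2 = N * sN * (1.0 - png - pnb)
            G2 = G * sN * (1.0 - pgb) + N * sN * png
            S2 = S * sN * (1.0 - h_s) + fs * be_in
            L2 = L * sN * (1.0 - h_l) + fl * be_in
            U2 = U * (1.0 - qu) * (1.0 - p_det) + (S * h_s + L * h_l) * sN
            D2 = D * (1.0 - qd) + newdet
            X2 = X + (N + G + S + L) * q + U * qu + D * qd

            # age everyone one year; the oldest age drops off the grid
            N[1:] = N2[:-1]
            G[1:] = G2[:-1]
            S[1:] = S2[:-1]
            L[1:] = L2[:-1]
            U[1:] = U2[:-1]
            D[1:] = D2[:-1]
            X[1:] = X2[:-1]

        return PopulationOutput(
            years=self.years.copy(),
            ages=self.ages.copy(),
            alive=alive_out,
            gerd=gerd_out,
            be=be_out,
            detections=det_out,
        )


def simulate_population(
    params: TransitionParameters,
    years,
    life_table: LifeTable,
    cancer_mortality: CancerMortality,
    intervention=None,
    *,
    undetected_all_cause: bool = False,
) -> PopulationOutput:
    """Calendar-year cross-sections over all overlapping birth cohorts.

    ``years`` is a contiguous range of calendar years; enough earlier entry
    cohorts are instantiated automatically that every age 20..max_age is
    populated in every requested year.
    """
    engine = PopulationEngine(
        life_table,
        cancer_mortality,
        years,
        n_groups=params.n_groups,
        intervention=intervention,
        undetected_all_cause=undetected_all_cause,
    )
    return engine.run(params)
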