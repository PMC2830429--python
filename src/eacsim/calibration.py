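"""Empirical calibration: chi-squared goodness of fit, simulated annealing,
three-phase sequential calibration with bound narrowing, and hold-out
validation.

The unknown transition probabilities are estimated by searching the bounded
parameter space for sets whose simulated outputs fit the empirical targets.
Fit is scored with a Pearson-style chi-squared statistic per endpoint,
``Σ (O − M)² / max(O, ε)`` (the ε floor keeps zero-valued targets scoreable),
and endpoints are combined as a weighted sum.

The search runs in three sequential phases — one per endpoint, in biologic
Forward order (GERD -> BE -> EAC incidence) or Reverse — with a fixed budget
of simulated-annealing evaluations per phase. After each of the first two
phases, the bounds of the transition parameters that phase calibrates are
narrowed to the min–max envelope of the 10% best-scoring sets (an
uncertainty interval consistent with the phase's target; parameters the
endpoint cannot identify keep their bounds). After the third phase all of its
evaluations are
re-scored on the combined three-endpoint GOF and the best ``final_fraction``
(1% at full scale, i.e. the best 1,000 of 10^5) are retained as the parameter
ensemble; the ensemble's spread expresses parameter uncertainty.

Validation holds out later calendar years: the GOF of each ensemble member is
divided by the number of years in each period ("adjusted" GOF) and the model
validates when the ensemble-mean adjusted score on the hold-out years is
strictly below 150% of the calibration-years value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    ENDPOINT_BE_PREV,
    ENDPOINT_EAC_INCIDENCE,
    ENDPOINT_GERD_PREV,
    ENDPOINTS,
    PopulationEngine,
    PopulationOutput,
    SOJOURN_YEARS_MAX,
    SOJOURN_YEARS_MIN,
    TransitionParameters,
)
from .demography import CancerMortality, LifeTable, age_group_labels, make_gompertz_life_table
from .errors import CalibrationError, CoverageError, ParameterDomainError
from .targets import ROLE_CALIBRATION, ROLE_VALIDATION, TargetSet

ORDER_FORWARD = "FORWARD"
ORDER_REVERSE = "REVERSE"

#: Endpoint sequence of the Forward (biologic-progression) phase order.
FORWARD_ENDPOINTS = (ENDPOINT_GERD_PREV, ENDPOINT_BE_PREV, ENDPOINT_EAC_INCIDENCE)

#: The transition parameters each calibration phase estimates (and therefore
#: constrains when its bounds are narrowed). Prefixes of ParameterSpace names.
PHASE_PARAMETER_STEMS = {
    ENDPOINT_GERD_PREV: ("p_normal_gerd",),
    ENDPOINT_BE_PREV: ("p_normal_be", "p_gerd_be"),
    ENDPOINT_EAC_INCIDENCE: ("r_lsbe_ca", "secular_slope", "mean_sojourn_years"),
}

#: Denominator floor of the chi-squared statistic, in the endpoint's own units.
#: Needed because the youngest age group's incidence target is printed as 0.0.
DEFAULT_GOF_FLOOR = 0.5


# ---------------------------------------------------------------------------
# Parameter space and bounds
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ParameterBounds:
    """Per-parameter lower/upper bounds on the free calibration vector."""

    names: tuple[str, ...]
    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self):
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        object.__setattr__(self, "names", tuple(self.names))
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)
        if lower.shape != upper.shape or lower.shape != (len(self.names),):
            raise ParameterDomainError("bound arrays must match the parameter names")
        if np.any(lower > upper):
            raise ParameterDomainError("lower bounds must not exceed upper bounds")

    @property
    def width(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, vector: np.ndarray) -> bool:
        v = np.asarray(vector, dtype=float)
        return bool(np.all(v >= self.lower - 1e-12) and np.all(v <= self.upper + 1e-12))

    def nested_within(self, outer: "ParameterBounds") -> bool:
        return bool(np.all(self.lower >= outer.lower - 1e-12) and np.all(self.upper <= outer.upper + 1e-12))

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        return rng.uniform(self.lower, self.upper)


@dataclass(frozen=True)
class ParameterSpace:
    """Mapping between the flat calibration vector and :class:`TransitionParameters`.

    Vector layout: the three pre-cancer transition probabilities and the
    LSBE->cancer base rate, each with one entry per 10-year age group, followed
    by the secular slope and the mean sojourn time.
    """

    n_groups: int = 6

    @property
    def names(self) -> tuple[str, ...]:
        labels = age_group_labels(self.n_groups)
        out = []
        for stem in ("p_normal_gerd", "p_normal_be", "p_gerd_be", "r_lsbe_ca"):
            out.extend(f"{stem}[{lab}]" for lab in labels)
        out.extend(["secular_slope", "mean_sojourn_years"])
        return tuple(out)

    @property
    def n_params(self) -> int:
        return 4 * self.n_groups + 2

    def to_params(self, vector: np.ndarray) -> TransitionParameters:
        v = np.asarray(vector, dtype=float)
        if v.shape != (self.n_params,):
            raise ParameterDomainError(f"expected vector of length {self.n_params}, got {v.shape}")
        G = self.n_groups
        return TransitionParameters(
            p_normal_gerd=v[0:G],
            p_normal_be=v[G : 2 * G],
            p_gerd_be=v[2 * G : 3 * G],
            r_lsbe_ca=v[3 * G : 4 * G],
            secular_slope=float(v[4 * G]),
            mean_sojourn_years=float(v[4 * G + 1]),
        )

    def to_vector(self, params: TransitionParameters) -> np.ndarray:
        if params.n_groups != self.n_groups:
            raise ParameterDomainError("parameter group count does not match the space")
        return np.concatenate(
            [
                params.p_normal_gerd,
                params.p_normal_be,
                params.p_gerd_be,
                params.r_lsbe_ca,
                [params.secular_slope, params.mean_sojourn_years],
            ]
        )

    def default_bounds(self) -> ParameterBounds:
        """Literature-informed search ranges for the free parameters.

        Pre-cancer transition probabilities get generous upper bounds well above
        any value compatible with the observed prevalences; the BE->cancer base
        rate is bounded by the highest progression rates reported for Barrett's
        cohorts; the sojourn time keeps its published 4–9 year range.
        """
        G = self.n_groups
        lower = np.concatenate([np.zeros(4 * G), [0.0, SOJOURN_YEARS_MIN]])
        upper = np.concatenate(
            [
                np.full(G, 0.30),  # Normal -> GERD: ~20% prevalence reached by the mid-20s
                np.full(G, 0.005),  # Normal -> BE: lifetime BE prevalence at most ~25%
                np.full(G, 0.01),  # GERD -> BE: same prevalence ceiling applied to the GERD pool
                np.full(G, 0.01),  # LSBE -> undetected CA: upper end of BE progression reports
                [0.25, SOJOURN_YEARS_MAX],  # secular slope; sojourn range 4-9 y
            ]
        )
        return ParameterBounds(self.names, lower, upper)


# ---------------------------------------------------------------------------
# Goodness of fit
# ---------------------------------------------------------------------------


@dataclass
class ScoredParameterSet:
    """A parameter vector with its per-endpoint and total GOF scores."""

    vector: np.ndarray
    gof_by_endpoint: dict[str, float]
    gof_total: float
    space: ParameterSpace | None = None

    @property
    def params(self) -> TransitionParameters:
        if self.space is None:
            raise CalibrationError("no ParameterSpace attached to this scored set")
        return self.space.to_params(self.vector)


def _score_output(
    output: PopulationOutput,
    cells: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]],
    weights: dict[str, float],
) -> dict[str, float]:
    scores = {}
    for endpoint, (year_idx, group_idx, obs, denom) in cells.items():
        model = output.endpoint(endpoint)[year_idx, group_idx]
        scores[endpoint] = float(weights.get(endpoint, 1.0) * np.sum((obs - model) ** 2 / denom))
    return scores


def _compile_cells(
    targets: TargetSet,
    role: str,
    years: np.ndarray,
    n_groups: int,
    endpoints,
    floor: float,
):
    """Pre-index target cells against a simulated year/age-group grid."""
    labels = {lab: g for g, lab in enumerate(age_group_labels(n_groups))}
    by_endpoint: dict[str, list[tuple[int, int, float]]] = {}
    y0 = int(years[0])
    for t in targets.expanded(role):
        if endpoints is not None and t.endpoint not in endpoints:
            continue
        if t.age_group not in labels:
            raise CoverageError(f"target age group {t.age_group!r} not covered by the model")
        iy = int(t.year) - y0
        if iy < 0 or iy >= years.size:
            raise CoverageError(
                f"target year {t.year} not covered by simulated years {years[0]}–{years[-1]}"
            )
        by_endpoint.setdefault(t.endpoint, []).append((iy, labels[t.age_group], t.value))
    cells = {}
    for endpoint, rows in by_endpoint.items():
        arr = np.array(rows, dtype=float)
        obs = arr[:, 2]
        cells[endpoint] = (
            arr[:, 0].astype(int),
            arr[:, 1].astype(int),
            obs,
            np.maximum(obs, floor),
        )
    return cells


def chi_square_gof(
    model: PopulationOutput,
    targets: TargetSet,
    endpoints=None,
    weights: dict[str, float] | None = None,
    *,
    role: str = ROLE_CALIBRATION,
    floor: float = DEFAULT_GOF_FLOOR,
) -> tuple[dict[str, float], float]:
    """Chi-squared goodness of fit of a model output against a target set.

    ``score_e = w_e · Σ_i (O_i − M_i)² / max(O_i, ε)`` over the target cells of
    endpoint ``e``; returns (per-endpoint scores, their sum). A target cell not
    covered by the model output raises :class:`CoverageError` — cells are never
    silently skipped.
    """
    weights = weights or {}
    cells = _compile_cells(targets, role, model.years, model.n_groups, endpoints, floor)
    scores = _score_output(model, cells, weights)
    return scores, float(sum(scores.values()))


class GofEvaluator:
    """Callable objective: parameter vector -> per-endpoint GOF scores.

    Compiles the target cells against a :class:`PopulationEngine` once, then
    each call simulates the population and scores every endpoint present in
    the targets (scoring all endpoints costs nothing beyond the simulation, and
    lets the three-phase procedure re-rank on the combined GOF for free).
    """

    def __init__(
        self,
        targets: TargetSet,
        engine: PopulationEngine,
        space: ParameterSpace,
        *,
        role: str = ROLE_CALIBRATION,
        weights: dict[str, float] | None = None,
        floor: float = DEFAULT_GOF_FLOOR,
    ):
        self.space = space
        self.weights = dict(weights or {})
        self.engine = engine
        self.cells = _compile_cells(
            targets, role, engine.years, engine.n_groups, None, floor
        )
        if not self.cells:
            raise CoverageError(f"no targets with role {role!r}")

    def __call__(self, vector: np.ndarray) -> dict[str, float]:
        output = self.engine.run(self.space.to_params(vector))
        return _score_output(output, self.cells, self.weights)


# ---------------------------------------------------------------------------
# Simulated annealing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SAConfig:
    """Simulated-annealing schedule.

    The published search budget is 10^5 evaluations per calibration run;
    smaller budgets are used at test scale. ``initial_temperature='AUTO'``
    sets the starting temperature to the median absolute score difference
    among 50 random bound-uniform parameter pairs, so acceptance starts near
    50% regardless of the objective's scale. Cooling is geometric every
    ``steps_per_temperature`` evaluations; the default (``None``) uses
    ``n_iterations // 250`` so the whole run spans 250 cooling stages — about
    six orders of magnitude of temperature decay — regardless of the budget,
    which keeps small test-scale runs and full-scale runs on the same
    annealing profile. Proposals perturb one coordinate by a uniform step of
    ``proposal_width`` times the bound width, reflected at the bounds.
    """

    n_iterations: int = 100_000
    initial_temperature: float | str = "AUTO"
    cooling_factor: float = 0.95
    steps_per_temperature: int | None = None
    proposal_width: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_iterations < 1:
            raise ParameterDomainError("n_iterations must be >= 1")
        if not (0.0 < self.cooling_factor < 1.0):
            raise ParameterDomainError("cooling_factor must lie in (0, 1)")
        if not (0.0 < self.proposal_width <= 1.0):
            raise ParameterDomainError("proposal_width must lie in (0, 1]")
        if self.steps_per_temperature is not None and self.steps_per_temperature < 1:
            raise ParameterDomainError("steps_per_temperature must be >= 1")

    @property
    def resolved_steps_per_temperature(self) -> int:
        if self.steps_per_temperature is not None:
            return self.steps_per_temperature
        return max(1, self.n_iterations // 250)


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    if span <= 0.0:
        return lo
    z = (x - lo) % (2.0 * span)
    return lo + (z if z <= span else 2.0 * span - z)


def _as_scores(value) -> tuple[dict[str, float], float]:
    """Normalize an objective return value to (per-endpoint dict, total)."""
    if isinstance(value, dict):
        return value, float(sum(value.values()))
    return {}, float(value)


def sa_search(
    objective,
    bounds: ParameterBounds,
    config: SAConfig,
    *,
    rng: np.random.Generator | None = None,
    space: ParameterSpace | None = None,
    score_of=None,
) -> list[ScoredParameterSet]:
    """Simulated-annealing search; returns every evaluated parameter set in order.

    ``objective(vector)`` returns either a scalar score or a per-endpoint score
    dict; when a dict is returned, ``score_of(dict) -> float`` selects the
    quantity being minimized (default: the sum). Exactly ``config.n_iterations``
    evaluations are recorded; identical seed, config and bounds give an
    identical output sequence. A non-finite objective value aborts with the
    offending vector in the error message.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if score_of is None:
        score_of = lambda by_endpoint, total: total  # noqa: E731

    def evaluate(vec: np.ndarray) -> ScoredParameterSet:
        by_endpoint, total = _as_scores(objective(vec))
        score = float(score_of(by_endpoint, total)) if by_endpoint else total
        if not math.isfinite(score):
            raise CalibrationError(f"objective returned non-finite score {score} at {vec!r}")
        return ScoredParameterSet(vec.copy(), by_endpoint, score, space)

    width = bounds.width
    free = np.flatnonzero(width > 0.0)

    if config.initial_temperature == "AUTO":
        diffs = []
        for _ in range(50):
            a = evaluate(bounds.sample(rng)).gof_total
            b = evaluate(bounds.sample(rng)).gof_total
            diffs.append(abs(a - b))
        temperature = float(np.median(diffs)) or 1.0
    else:
        temperature = float(config.initial_temperature)

    current = evaluate(bounds.sample(rng))
    evaluated = [current]
    steps_at_temp = 0
    while len(evaluated) < config.n_iterations:
        vec = current.vector.copy()
        if free.size:
            j = int(free[rng.integers(free.size)])
            step = rng.uniform(-1.0, 1.0) * config.proposal_width * width[j]
            vec[j] = _reflect(vec[j] + step, bounds.lower[j], bounds.upper[j])
        candidate = evaluate(vec)
        evaluated.append(candidate)
        delta = candidate.gof_total - current.gof_total
        if delta <= 0.0 or (temperature > 0.0 and rng.random() < math.exp(-delta / temperature)):
            current = candidate
        steps_at_temp += 1
        if steps_at_temp >= config.resolved_steps_per_temperature:
            temperature *= config.cooling_factor
            steps_at_temp = 0
    return evaluated


def narrow_bounds(
    evaluated: list[ScoredParameterSet],
    keep_fraction: float = 0.10,
    bounds: ParameterBounds | None = None,
) -> ParameterBounds:
    """Bounds spanned by the best ``keep_fraction`` of the evaluated sets.

    The kept sets are those with the lowest total GOF (ties broken by
    evaluation order); per parameter the new bounds are their min–max
    envelope, which is nested within any bounds that generated them.
    Degenerate zero-width bounds are allowed.
    """
    if not evaluated:
        raise CalibrationError("cannot narrow bounds from an empty evaluation list")
    if not (0.0 < keep_fraction <= 1.0):
        raise ParameterDomainError("keep_fraction must lie in (0, 1]")
    scores = np.array([s.gof_total for s in evaluated])
    k = max(1, int(round(keep_fraction * len(evaluated))))
    order = np.argsort(scores, kind="stable")[:k]
    kept = np.stack([evaluated[i].vector for i in order])
    names = bounds.names if bounds is not None else tuple(
        f"p{i}" for i in range(kept.shape[1])
    )
    return ParameterBounds(names, kept.min(axis=0), kept.max(axis=0))


# ---------------------------------------------------------------------------
# Three-phase calibration
# ---------------------------------------------------------------------------


@dataclass
class PhaseResult:
    endpoint: str
    bounds_in: ParameterBounds
    bounds_out: ParameterBounds
    evaluations: list[ScoredParameterSet]


@dataclass
class CalibrationResult:
    """Phase-by-phase record plus the final best-fraction parameter ensemble."""

    order: str
    space: ParameterSpace
    phases: list[PhaseResult]
    ensemble: list[ScoredParameterSet]

    @property
    def best(self) -> ScoredParameterSet:
        return self.ensemble[0]

    def ensemble_envelope(self) -> ParameterBounds:
        vectors = np.stack([s.vector for s in self.ensemble])
        return ParameterBounds(self.space.names, vectors.min(axis=0), vectors.max(axis=0))

    def ensemble_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.ensemble:
            row = dict(zip(self.space.names, s.vector))
            for endpoint, score in s.gof_by_endpoint.items():
                row[f"gof_{endpoint}"] = score
            row["gof_total"] = s.gof_total
            rows.append(row)
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.ensemble_frame().to_csv(path, index=False)


def ensemble_from_frame(frame: pd.DataFrame, space: ParameterSpace) -> list[ScoredParameterSet]:
    """Rebuild a persisted ensemble (inverse of :meth:`CalibrationResult.to_csv`)."""
    members = []
    for _, row in frame.iterrows():
        vector = row[list(space.names)].to_numpy(dtype=float)
        gofs = {
            c[len("gof_"):]: float(row[c])
            for c in frame.columns
            if c.startswith("gof_") and c != "gof_total"
        }
        members.append(ScoredParameterSet(vector, gofs, float(row["gof_total"]), space))
    return members


def three_phase_calibrate(
    targets: TargetSet,
    order: str = ORDER_FORWARD,
    bounds0: ParameterBounds | None = None,
    sa_config: SAConfig | None = None,
    final_fraction: float = 0.01,
    *,
    space: ParameterSpace | None = None,
    life_table: LifeTable | None = None,
    cancer_mortality: CancerMortality | None = None,
    gof_weights: dict[str, float] | None = None,
    gof_floor: float = DEFAULT_GOF_FLOOR,
    narrow_fraction: float = 0.10,
    undetected_all_cause: bool = False,
) -> CalibrationResult:
    """Sequentially fit the three endpoints, then retain the best-fraction ensemble.

    Each phase runs a full SA budget. The phase objective is cumulative: phase
    1 scores its endpoint alone, phase 2 adds the second endpoint, phase 3
    scores all three — so earlier fits cannot drift while later endpoints are
    being fitted, and the final ranking is consistent with the phase-3 search.
    After phases 1 and 2 the bounds of the parameters that phase calibrates
    (GERD phase: the Normal->GERD probabilities; BE phase: the two BE-inflow
    probabilities) are narrowed to the min–max envelope of the 10% best sets;
    parameters a phase cannot identify keep their previous bounds, since their
    values in the best-scoring sets are arbitrary. After phase 3 all of its
    evaluations are re-ranked on the combined three-endpoint GOF and the best
    ``final_fraction`` are kept (ascending by combined score, ties broken by
    evaluation order). Per-phase random streams are spawned deterministically
    from ``sa_config.seed``.
    """
    if order not in (ORDER_FORWARD, ORDER_REVERSE):
        raise ParameterDomainError(f"order must be FORWARD or REVERSE, got {order!r}")
    space = space or ParameterSpace(n_groups=6)
    bounds = bounds0 or space.default_bounds()
    sa_config = sa_config or SAConfig()
    life_table = life_table or make_gompertz_life_table()
    cancer_mortality = cancer_mortality or CancerMortality()
    missing = set(ENDPOINTS) - set(targets.endpoints(ROLE_CALIBRATION))
    if missing:
        raise CoverageError(f"three-phase calibration needs all endpoints; missing {sorted(missing)}")

    years = range(min(targets.calibration_years), max(targets.calibration_years) + 1)
    engine = PopulationEngine(
        life_table,
        cancer_mortality,
        years,
        n_groups=space.n_groups,
        undetected_all_cause=undetected_all_cause,
    )
    evaluator = GofEvaluator(
        targets, engine, space, role=ROLE_CALIBRATION, weights=gof_weights, floor=gof_floor
    )

    endpoint_order = FORWARD_ENDPOINTS if order == ORDER_FORWARD else FORWARD_ENDPOINTS[::-1]
    phase_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(sa_config.seed).spawn(3)]

    phases: list[PhaseResult] = []
    for phase, endpoint in enumerate(endpoint_order):
        active = endpoint_order[: phase + 1]
        score_of = lambda by_endpoint, total, a=active: sum(by_endpoint[e] for e in a)  # noqa: E731
        evaluated = sa_search(
            evaluator,
            bounds,
            sa_config,
            rng=phase_rngs[phase],
            space=space,
            score_of=score_of,
        )
        if phase < 2:
            envelope = narrow_bounds(evaluated, narrow_fraction, bounds)
            scoped = np.array(
                [
                    any(name.startswith(stem) for stem in PHASE_PARAMETER_STEMS[endpoint])
                    for name in space.names
                ]
            )
            new_bounds = ParameterBounds(
                bounds.names,
                np.where(scoped, envelope.lower, bounds.lower),
                np.where(scoped, envelope.upper, bounds.upper),
            )
        else:
            new_bounds = bounds
        phases.append(PhaseResult(endpoint, bounds, new_bounds, evaluated))
        bounds = new_bounds

    final_evals = phases[-1].evaluations
    combined = np.array(
        [sum(s.gof_by_endpoint[e] for e in ENDPOINTS) for s in final_evals]
    )
    k = max(1, int(round(final_fraction * len(final_evals))))
    order_idx = np.argsort(combined, kind="stable")[:k]
    ensemble = [
        ScoredParameterSet(
            final_evals[i].vector, dict(final_evals[i].gof_by_endpoint), float(combined[i]), space
        )
        for i in order_idx
    ]
    return CalibrationResult(order=order, space=space, phases=phases, ensemble=ensemble)


# ---------------------------------------------------------------------------
# Hold-out validation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ValidationReport:
    """Adjusted (per-year) GOF comparison between calibration and hold-out years."""

    adjusted_gof_calibration: float
    adjusted_gof_validation: float
    n_calibration_years: int
    n_validation_years: int

    @property
    def ratio(self) -> float:
        return self.adjusted_gof_validation / self.adjusted_gof_calibration

    @property
    def passed(self) -> bool:
        """Strict 150% criterion on the adjusted scores."""
        return self.adjusted_gof_validation < 1.5 * self.adjusted_gof_calibration

    def to_dict(self) -> dict:
        return {
            "adjusted_gof_calibration": self.adjusted_gof_calibration,
            "adjusted_gof_validation": self.adjusted_gof_validation,
            "ratio": self.ratio,
            "passed": self.passed,
            "n_calibration_years": self.n_calibration_years,
            "n_validation_years": self.n_validation_years,
        }


def validate(
    ensemble: list[ScoredParameterSet],
    model_runner,
    targets: TargetSet,
    *,
    gof_weights: dict[str, float] | None = None,
    gof_floor: float = DEFAULT_GOF_FLOOR,
) -> ValidationReport:
    """Score an ensemble on held-out years and apply the 150% criterion.

    ``model_runner(params) -> PopulationOutput`` must cover both the
    calibration and the validation years. The adjusted score of each period is
    the total GOF divided by the number of years in it; both adjusted scores
    are averaged over the ensemble.
    """
    if not ensemble:
        raise CalibrationError("validation needs a non-empty ensemble")
    n_cal = len(targets.calibration_years)
    n_val = len(targets.validation_years)
    if n_val == 0:
        raise CoverageError("no validation years: refusing to produce a validation report")
    if not any(t.role == ROLE_VALIDATION for t in targets.targets):
        raise CoverageError("no validation-role targets present")
    cal_scores, val_scores = [], []
    for member in ensemble:
        output = model_runner(member.params)
        _, cal_total = chi_square_gof(
            output, targets, weights=gof_weights, role=ROLE_CALIBRATION, floor=gof_floor
        )
        _, val_total = chi_square_gof(
            output, targets, weights=gof_weights, role=ROLE_VALIDATION, floor=gof_floor
        )
        cal_scores.append(cal_total / n_cal)
        val_scores.append(val_total / n_val)
    return ValidationReport(
        adjusted_gof_calibration=float(np.mean(cal_scores)),
        adjusted_gof_validation=float(np.mean(val_scores)),
        n_calibration_years=n_cal,
        n_validation_years=n_val,
    )
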