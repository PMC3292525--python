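"""Global χ² minimization and flux confidence intervals.

Fitting minimizes the summed χ² of one or more experiments simulated with a
shared parameter set.  The optimizer is simulated annealing with
multiplicative log-normal proposals (the fluxes span six orders of
magnitude, so steps are taken on log-scale) and geometric cooling, followed
by a coordinate-descent polish around the best visited point.  Multiple
optimization runs form a :class:`FluxEnsemble`; applying a χ² threshold to
the ensemble (the χ² quantile with one degree of freedom above the ensemble
minimum — 6.63 at the 99% level, profile-likelihood convention) yields
confidence intervals for each metabolic flux.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .isodynamics import IsotopomerEngine, observables, simulate_labeling
from .kinetics import ParameterSet
from .measurement import ChiSquareReport, MeasurementTable, chi_square
from .network import NetworkScheme

__all__ = [
    "FitProblem",
    "AnnealSchedule",
    "FitResult",
    "FluxEnsemble",
    "objective",
    "anneal",
    "confidence_intervals",
]

logger = logging.getLogger(__name__)


@dataclass
class FitResult:
    params: ParameterSet
    chi2: float
    reports: dict[str, ChiSquareReport]
    fluxes: dict[str, dict[str, float]]  # experiment id -> reaction -> flux
    trace: list[tuple[int, float]]
    seed: int | None
    n_evals: int

    def flux(self, reaction_id: str, experiment: str | None = None) -> float:
        exp = experiment or next(iter(self.fluxes))
        return self.fluxes[exp][reaction_id]


@dataclass
class FluxEnsemble:
    members: list[FitResult]

    @property
    def chi2_min(self) -> float:
        return min(m.chi2 for m in self.members)

    @property
    def best(self) -> FitResult:
        return min(self.members, key=lambda m: m.chi2)


class FitProblem:
    """χ² objective for one scheme over one or more experiments.

    ``experiments`` pairs each experiment description with its measurement
    table; every evaluation simulates all of them with the same parameters
    and sums the χ².  Simulation failures yield +inf (annealing treats the
    move as rejected).
    """

    def __init__(
        self,
        scheme: NetworkScheme,
        experiments: Sequence[tuple[object, MeasurementTable]],
        sim_options: Mapping[str, float] | None = None,
    ):
        if not experiments:
            raise ValueError("at least one experiment is required")
        self.scheme = scheme
        self.experiments = list(experiments)
        self.engine = IsotopomerEngine(scheme)
        self.sim_options = dict(sim_options or {})
        self.sim_options.setdefault("rtol", 1e-6)
        self.sim_options.setdefault("atol", 1e-10)
        self.sim_options.setdefault("totals_rtol", 1e-7)
        self.n_points = sum(len(t) for _, t in self.experiments)

    def evaluate(
        self, params: ParameterSet | Mapping[str, float]
    ) -> tuple[float, dict[str, ChiSquareReport], dict[str, dict[str, float]]]:
        reports: dict[str, ChiSquareReport] = {}
        fluxes: dict[str, dict[str, float]] = {}
        total = 0.0
        for exp, table in self.experiments:
            try:
                sim = simulate_labeling(
                    self.scheme, params, exp, engine=self.engine, **self.sim_options
                )
                rep = chi_square(observables(sim), table)
            except (RuntimeError, ValueError, FloatingPointError) as err:
                logger.warning("simulation failed for %s: %s", exp.id, err)
                return math.inf, {}, {}
            reports[exp.id] = rep
            fluxes[exp.id] = {
                rid: sim.totals.time_averaged_flux(rid)
                for rid in sim.totals.reaction_ids
            }
            total += rep.total
        return total, reports, fluxes

    def __call__(self, params: ParameterSet | Mapping[str, float]) -> float:
        return self.evaluate(params)[0]


def objective(
    params: ParameterSet | Mapping[str, float],
    scheme: NetworkScheme,
    experiments: Sequence[tuple[object, MeasurementTable]],
) -> float:
    """Total χ² of ``params`` over ``experiments`` (convenience wrapper)."""
    return FitProblem(scheme, experiments)(params)


@dataclass
class AnnealSchedule:
    """Simulated-annealing hyperparameters.

    ``t0`` is the initial temperature in χ² units; cooling is geometric with
    factor ``alpha`` applied every ``steps_per_temp`` proposals.  Proposals
    multiply one randomly chosen free parameter by exp(N(0, step_scale²)).
    After the annealing budget, ``descent_passes`` rounds of coordinate
    descent refine the best visited point with multiplicative steps that
    shrink by half whenever a full pass yields no improvement.
    """

    n_steps: int = 300
    t0: float = 50.0
    alpha: float = 0.95
    steps_per_temp: int = 10
    step_scale: float = 0.35
    descent_passes: int = 2
    descent_step: float = 0.15

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_steps < 0 or self.t0 <= 0:
            raise ValueError("invalid schedule")


def anneal(
    problem,
    params0: ParameterSet,
    schedule: AnnealSchedule | None = None,
    seed: int | None = None,
) -> FitResult:
    """Minimize ``problem(params)`` by annealing + coordinate descent.

    ``problem`` is any callable mapping a :class:`ParameterSet` to a scalar
    (usually a :class:`FitProblem`).  Frozen parameters never move; bounds
    are enforced by clipping.  The best visited point is returned, with the
    accepted-move trace and the seed recorded for reproducibility.
    """
    schedule = schedule or AnnealSchedule()
    rng = np.random.default_rng(seed)
    free = params0.free_names()
    if not free:
        raise ValueError("no free parameters to fit")

    current = params0.copy()
    f_current = problem(current)
    best, f_best = current.copy(), f_current
    trace: list[tuple[int, float]] = [(0, f_current)]
    n_evals = 1
    temp = schedule.t0

    def clip(name: str, value: float) -> float:
        lo, hi = params0.bound(name)
        return min(max(value, lo), hi)

    for step in range(schedule.n_steps):
        name = free[rng.integers(len(free))]
        factor = math.exp(schedule.step_scale * rng.standard_normal())
        cand = current.updated({name: clip(name, current.values[name] * factor)})
        f_cand = problem(cand)
        n_evals += 1
        delta = f_cand - f_current
        if delta <= 0 or rng.random() < math.exp(-delta / temp):
            current, f_current = cand, f_cand
            trace.append((step + 1, f_current))
            if f_current < f_best:
                best, f_best = current.copy(), f_current
        if (step + 1) % schedule.steps_per_temp == 0:
            temp *= schedule.alpha

    # coordinate descent polish around the best visited point
    step_frac = schedule.descent_step
    for _ in range(schedule.descent_passes):
        improved = False
        for name in free:
            base = best.values[name]
            for factor in (1.0 + step_frac, 1.0 / (1.0 + step_frac)):
                cand = best.updated({name: clip(name, base * factor)})
                f_cand = problem(cand)
                n_evals += 1
                if f_cand < f_best:
                    best, f_best = cand, f_cand
                    improved = True
                    break
        if not improved:
            step_frac *= 0.5

    if isinstance(problem, FitProblem):
        f_final, reports, fluxes = problem.evaluate(best)
        n_evals += 1
    else:
        f_final, reports, fluxes = f_best, {}, {}
    return FitResult(
        params=best,
        chi2=float(f_final),
        reports=reports,
        fluxes=fluxes,
        trace=trace,
        seed=seed,
        n_evals=n_evals,
    )


def profile_ensemble(
    problem: FitProblem,
    best: FitResult,
    param_names: Sequence[str],
    level: float = 0.99,
    factor: float = 1.2,
    max_steps: int = 12,
    polish_passes: int = 1,
    polish_step: float = 0.2,
) -> FluxEnsemble:
    """Augment a best fit with threshold-probing parameter scans.

    For each named parameter, the fit is re-evaluated at geometrically spaced
    values up and down from the optimum until χ² exceeds the ensemble
    threshold (χ² quantile with one degree of freedom above the minimum).
    Because fluxes can be correlated (e.g. the two glucose-phosphorylation
    routes trade off against each other), a probe that crosses the threshold
    is first re-polished over the *other* free parameters (the scanned one
    held fixed — the profile-likelihood construction); the scan continues
    while the polished point stays acceptable.  Every point inside the
    threshold becomes an ensemble member, so the flux envelope explores the
    acceptable χ² region rather than just the scatter of optimization
    endpoints.
    """
    delta = float(chi2_dist.ppf(level, df=1))
    members = [best]
    threshold = best.chi2 + delta
    free_all = best.params.free_names()

    def mini_polish(params: ParameterSet, chi2: float, fixed: str):
        current, f_current = params, chi2
        for _ in range(polish_passes):
            improved = False
            for name in free_all:
                if name == fixed:
                    continue
                base_v = current.values[name]
                for fac in (1.0 + polish_step, 1.0 / (1.0 + polish_step)):
                    cand = current.updated({name: base_v * fac})
                    f_cand, rep, flx = problem.evaluate(cand)
                    if f_cand < f_current:
                        current, f_current = cand, f_cand
                        members.append(
                            FitResult(params=cand, chi2=f_cand, reports=rep,
                                      fluxes=flx, trace=[], seed=best.seed,
                                      n_evals=1)
                        )
                        improved = True
                        break
            if not improved:
                break
        return current, f_current

    for name in param_names:
        for direction in (factor, 1.0 / factor):
            point = best.params
            value = best.params.values[name]
            for _ in range(max_steps):
                value *= direction
                cand = point.updated({name: value})
                chi2, reports, fluxes = problem.evaluate(cand)
                if not math.isfinite(chi2):
                    break
                members.append(
                    FitResult(params=cand, chi2=chi2, reports=reports,
                              fluxes=fluxes, trace=[], seed=best.seed,
                              n_evals=1)
                )
                if chi2 > threshold:
                    cand, chi2 = mini_polish(cand, chi2, fixed=name)
                    if chi2 > threshold:
                        break
                point = cand
    return FluxEnsemble(members)


def confidence_intervals(
    ensemble: FluxEnsemble,
    flux_id: str,
    level: float = 0.99,
    experiment: str | None = None,
    min_members: int = 3,
) -> tuple[float, float]:
    """χ²-threshold confidence interval for one flux.

    The envelope (min, max) of the flux over ensemble members whose χ² lies
    within Δ(level) of the ensemble minimum, Δ being the one-degree-of-
    freedom χ² quantile (6.63 at 99%).  Warns when fewer than ``min_members``
    members qualify (the envelope then under-covers).
    """
    if not ensemble.members:
        raise ValueError("empty ensemble")
    delta = float(chi2_dist.ppf(level, df=1))
    threshold = ensemble.chi2_min + delta
    qualifying = [m for m in ensemble.members if m.chi2 <= threshold]
    if len(qualifying) < min_members:
        logger.warning(
            "only %d ensemble member(s) within the chi-square threshold; "
            "the %g%% interval for %s may under-cover",
            len(qualifying), 100 * level, flux_id,
        )
    values = [m.flux(flux_id, experiment) for m in qualifying]
    return min(values), max(values)
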