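"""Rate laws and the total-concentration ODE layer.

The kinetic layer integrates the ordinary differential equations for total
metabolite concentrations over the incubation (default 2 h = 120 min) and
exposes a dense time-resolved flux vector that the isotopomer layer consumes.
Units: minutes; mM referred to medium volume (glycogen in mM glucosyl-unit
equivalents); fluxes in mM·min⁻¹.

Rate laws are deliberately simple — irreversible mass action or
Michaelis–Menten, one or two fitted parameters per reaction — because the
discrimination analysis depends on the flux values and the network topology,
not on the rate-law algebra.  The aldolase / transketolase / transaldolase
fluxes are derived from six elementary-step constants each through the
three-step exchange-enzyme partition (:mod:`labeldyn.exchange`), so the
forward, reverse and half-exchange fluxes of one enzyme stay interdependent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exchange import ElementaryRates, exchange_fluxes
from .network import NetworkScheme

__all__ = [
    "ParameterSet",
    "TotalsTrajectory",
    "reaction_rate",
    "FluxEvaluator",
    "totals_rhs",
    "integrate_totals",
]

logger = logging.getLogger(__name__)

RATE_LAWS = ("mass_action", "michaelis_menten", "constant")


@dataclass
class ParameterSet:
    """Named positive parameters with bounds and an optional frozen subset.

    ``frozen`` parameters are treated as constants by the fitting machinery.
    Bounds default to four orders of magnitude around the value, which suits
    the multiplicative (log-scale) annealing proposals.
    """

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]] = field(default_factory=dict)
    frozen: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        for name, v in self.values.items():
            if v < 0:
                raise ValueError(f"parameter {name} must be >= 0, got {v}")
        for name, (lo, hi) in self.bounds.items():
            if not (0 <= lo <= hi):
                raise ValueError(f"bad bounds for {name}: ({lo}, {hi})")

    def bound(self, name: str) -> tuple[float, float]:
        if name in self.bounds:
            return self.bounds[name]
        v = self.values[name]
        if v == 0:
            return (0.0, 1.0)
        return (v / 100.0, v * 100.0)

    def free_names(self) -> list[str]:
        return [n for n in self.values if n not in self.frozen]

    def copy(self) -> "ParameterSet":
        return ParameterSet(dict(self.values), dict(self.bounds), set(self.frozen))

    def updated(self, changes: Mapping[str, float]) -> "ParameterSet":
        new = self.copy()
        new.values.update(changes)
        return new

    def __getitem__(self, name: str) -> float:
        return self.values[name]


def reaction_rate(
    rate_law: str | dict,
    params: Mapping[str, float] | Sequence[float],
    substrate_concs: Sequence[float],
) -> float:
    """Evaluate one rate law.

    ``rate_law`` is either a law id (then ``params`` is the positional
    parameter sequence) or a reaction's rate-law dict (then ``params`` maps
    names to values).  Unidirectional laws return 0 whenever any substrate
    concentration is 0.
    """
    if isinstance(rate_law, str):
        law, pvals = rate_law, list(params)
    else:
        law = rate_law["law"]
        pvals = [params[name] for name in rate_law["params"]]
    conc = [max(float(c), 0.0) for c in substrate_concs]
    if law == "mass_action":
        (k,) = pvals
        rate = k
        for c in conc:
            rate *= c
        return rate
    if law == "michaelis_menten":
        vmax, km = pvals
        s = conc[0]
        return vmax * s / (km + s) if s > 0 else 0.0
    if law == "constant":
        (k,) = pvals
        return k
    raise KeyError(f"unknown rate law {law!r}")


class FluxEvaluator:
    """Vectorized reaction-rate evaluation for one scheme.

    Callable as ``fluxes = ev(params_values, conc_vector)`` where the
    concentration vector follows ``scheme`` pool order (``ev.pool_index``).
    Enzyme-coupled reactions (rate law ``{"law": "enzyme", ...}``) receive
    the vf / vr / vhx components of the three-step partition; ``vhx`` is the
    symmetrized half-molecule exchange ``(vfg + vgf) / 2``.
    """

    def __init__(self, scheme: NetworkScheme):
        self.scheme = scheme
        self.pool_ids = list(scheme.pools)
        self.pool_index = {p: i for i, p in enumerate(self.pool_ids)}
        self.reaction_ids = list(scheme.reactions)
        self.reaction_index = {r: i for i, r in enumerate(self.reaction_ids)}
        self._warned_negative = False

        self._simple: list[tuple[int, dict, list[int]]] = []
        self._enzymatic: list[tuple[int, str, str]] = []
        for rid, rxn in scheme.reactions.items():
            j = self.reaction_index[rid]
            if rxn.rate_law["law"] == "enzyme":
                self._enzymatic.append(
                    (j, rxn.rate_law["enzyme"], rxn.rate_law["component"])
                )
            else:
                subs = [self.pool_index[p] for _, p in rxn.substrates]
                self._simple.append((j, rxn.rate_law, subs))

    def _elementary(
        self, enzyme: str, values: Mapping[str, float], conc: np.ndarray
    ) -> ElementaryRates:
        steps = self.scheme.enzymes[enzyme]
        out = {}
        for step in ("v1", "v2", "v3", "vm1", "vm2", "vm3"):
            pname, cpool = steps[step]
            v = values[pname]
            if cpool is not None:
                v *= max(float(conc[self.pool_index[cpool]]), 0.0)
            out[step] = v
        return ElementaryRates(**out)

    def __call__(self, values: Mapping[str, float], conc: np.ndarray) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        if not self._warned_negative and (conc < -1e-9).any():
            self._warned_negative = True
            worst = int(np.argmin(conc))
            logger.warning(
                "negative concentration clamped to zero during rate evaluation "
                "(pool %s = %.3e)", self.pool_ids[worst], conc[worst]
            )
        flux = np.zeros(len(self.reaction_ids))
        for j, law, subs in self._simple:
            flux[j] = reaction_rate(law, values, conc[subs])
        enz_cache: dict[str, object] = {}
        for j, enzyme, component in self._enzymatic:
            if enzyme not in enz_cache:
                rates = self._elementary(enzyme, values, conc)
                try:
                    enz_cache[enzyme] = exchange_fluxes(rates)
                except ZeroDivisionError:
                    enz_cache[enzyme] = None
            ex = enz_cache[enzyme]
            if ex is None:
                flux[j] = 0.0
            elif component == "vf":
                flux[j] = ex.vf
            elif component == "vr":
                flux[j] = ex.vr
            elif component == "vhx":
                flux[j] = 0.5 * (ex.vfg + ex.vgf)
            else:
                raise KeyError(f"unknown enzyme flux component {component!r}")
        return flux


def _stoichiometry(scheme: NetworkScheme, pool_index: dict[str, int],
                   reaction_index: dict[str, int]) -> np.ndarray:
    S = np.zeros((len(pool_index), len(reaction_index)))
    for rid, rxn in scheme.reactions.items():
        if rxn.kind == "exchange":
            continue  # isotope exchange only: no net mass flow
        j = reaction_index[rid]
        for _, p in rxn.substrates:
            S[pool_index[p], j] -= 1
        for _, p in rxn.products:
            S[pool_index[p], j] += 1
    return S


def totals_rhs(
    scheme: NetworkScheme,
    params: ParameterSet | Mapping[str, float],
    medium_volume_ratio: float = 1.0,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Right-hand side ``f(t, conc)`` of the total-concentration ODE system.

    Stoichiometric assembly ``d[P]/dt = Σ ν·rate``; exchange-only reactions
    contribute nothing.  ``medium_volume_ratio`` divides the rate of change
    of medium pools (a value > 1 expresses that the medium is that many times
    larger than the reference volume; the shipped convention keeps every
    concentration referred to medium volume, so the default is 1).
    """
    values = params.values if isinstance(params, ParameterSet) else dict(params)
    ev = FluxEvaluator(scheme)
    S = _stoichiometry(scheme, ev.pool_index, ev.reaction_index)
    scale = np.ones(len(ev.pool_ids))
    if medium_volume_ratio != 1.0:
        for pid, i in ev.pool_index.items():
            if scheme.pools[pid].location == "medium":
                scale[i] = 1.0 / medium_volume_ratio

    def rhs(t: float, conc: np.ndarray) -> np.ndarray:
        return scale * (S @ ev(values, conc))

    rhs.flux_evaluator = ev  # type: ignore[attr-defined]
    rhs.stoichiometry = S  # type: ignore[attr-defined]
    return rhs


@dataclass
class TotalsTrajectory:
    """Dense solution of the totals ODE plus the flux series along it."""

    scheme: NetworkScheme
    pool_ids: list[str]
    reaction_ids: list[str]
    times: np.ndarray
    conc: np.ndarray  # (n_times, n_pools)
    flux: np.ndarray  # (n_times, n_reactions)
    _sol: object = None
    _flux_of_conc: Callable[[np.ndarray], np.ndarray] | None = None

    def conc_at(self, t: float) -> np.ndarray:
        return np.maximum(np.asarray(self._sol(t), dtype=float), 0.0)

    def flux_at(self, t: float) -> np.ndarray:
        return self._flux_of_conc(self.conc_at(t))

    def pool_series(self, pool_id: str) -> np.ndarray:
        return self.conc[:, self.pool_ids.index(pool_id)]

    def flux_series(self, reaction_id: str) -> np.ndarray:
        return self.flux[:, self.reaction_ids.index(reaction_id)]

    def time_averaged_flux(self, reaction_id: str) -> float:
        """Flux integrated over the incubation divided by its duration."""
        j = self.reaction_ids.index(reaction_id)
        return float(np.trapezoid(self.flux[:, j], self.times) /
                     (self.times[-1] - self.times[0]))


def integrate_totals(
    scheme: NetworkScheme,
    params: ParameterSet | Mapping[str, float],
    experiment=None,
    grid: np.ndarray | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-10,
    method: str = "BDF",
    medium_volume_ratio: float = 1.0,
) -> TotalsTrajectory:
    """Integrate total concentrations over the incubation.

    ``experiment`` (an :class:`labeldyn.experiments.ExperimentSpec` or None)
    supplies the duration and initial medium concentrations; without one the
    scheme's ``conc0`` values are integrated for 120 min.  The returned
    trajectory carries a dense interpolant so the isotopomer layer can query
    concentrations and fluxes at arbitrary times.
    """
    values = params.values if isinstance(params, ParameterSet) else dict(params)
    duration = 120.0 if experiment is None else experiment.duration
    if duration <= 0:
        raise ValueError("experiment duration must be > 0")
    if grid is None:
        grid = np.linspace(0.0, duration, int(round(duration)) + 1)

    rhs = totals_rhs(scheme, values, medium_volume_ratio)
    ev = rhs.flux_evaluator
    c0 = np.array([scheme.pools[p].conc0 for p in ev.pool_ids])
    if experiment is not None:
        for pool, conc in experiment.medium.items():
            c0[ev.pool_index[pool]] = conc

    sol = solve_ivp(
        rhs, (0.0, duration), c0, method=method, rtol=rtol, atol=atol,
        dense_output=True, t_eval=grid,
    )
    if not sol.success:
        raise RuntimeError(f"totals integration failed: {sol.message}")
    conc = np.maximum(sol.y.T, 0.0)
    flux = np.array([ev(values, c) for c in conc])
    traj = TotalsTrajectory(
        scheme=scheme,
        pool_ids=list(ev.pool_ids),
        reaction_ids=list(ev.reaction_ids),
        times=np.asarray(grid, dtype=float),
        conc=conc,
        flux=flux,
        _sol=sol.sol,
        _flux_of_conc=lambda c: ev(values, c),
    )
    return traj
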