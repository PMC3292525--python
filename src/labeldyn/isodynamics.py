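"""Isotopomer dynamics on top of the total-concentration trajectory.

Every tracked pool with n carbons carries a vector of 2**n positional
isotopomer concentrations (bit i-1 of the index = carbon i is 13C).  Given
the time-resolved reaction fluxes from :mod:`labeldyn.kinetics`, each
reaction consumes substrate isotopomers in proportion to their fractional
abundance and forms product isotopomers according to its atom map;
condensation reactions draw their substrate molecules independently, and
scramble variants are weighted by probability.  Exchange-only reactions move
label with no net mass flow.

The engine compiles every (reaction, scramble variant, product) into flat
index arrays once per scheme, so the right-hand side and its analytic
Jacobian are plain gather/scatter numpy operations; the system is then
integrated with the same implicit stiff scheme (BDF) as the totals layer,
over the dense flux interpolant (totals first, then label).

Mass-isotopologue aggregation (what GC/MS measures) sums isotopomers by the
number of 13C atoms inside a carbon fragment, e.g. C1-C4 / C3-C6 of glucose
from glycogen or C2-C4 / C2-C5 of glutamate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.integrate import solve_ivp

from .experiments import ExperimentSpec
from .kinetics import ParameterSet, TotalsTrajectory, integrate_totals
from .network import NetworkScheme

__all__ = [
    "IsotopomerEngine",
    "IsotopologueDistribution",
    "LabelingSimulation",
    "isotopomer_rhs",
    "simulate_labeling",
    "to_isotopologues",
    "observables",
    "GLYCOGEN_MG_PER_ML_PER_MM",
]

#: mg glycogen per mL of cell pellet, per mM glucosyl units referred to medium
#: volume: 162 g/mol glucosyl residue divided by a 0.12 pellet-to-medium
#: volume fraction.  A reporting convention, not a fitted quantity.
GLYCOGEN_MG_PER_ML_PER_MM = 0.162 / 0.12

#: default mapping from measurement-table metabolite names to pools
OBSERVED_POOLS = {
    "glucose": "glc_med",
    "lactate": "lac_med",
    "glutamate": "glu",
    "glycogen": "glycogen",
}

_TINY = 1e-30


def _popcounts(n_states: int, mask: int) -> np.ndarray:
    idx = np.arange(n_states)
    return np.array([bin(i & mask).count("1") for i in idx])


@dataclass
class _ProductOp:
    offset: int
    size: int
    rows: np.ndarray  # product isotopomer index per (substrate combo, variant)
    weights: np.ndarray  # variant probabilities
    # substrate combo indices (for bimolecular ops; cols for unimolecular)
    i_idx: np.ndarray
    j_idx: np.ndarray | None
    dense: np.ndarray | None  # (size_p, size_1) for unimolecular ops
    # precomputed flat scatter indices for the bimolecular Jacobian blocks:
    # rows*n_slot + col_slot, one per slot
    flat0: np.ndarray | None = None
    flat1: np.ndarray | None = None
    n0: int = 0
    n1: int = 0


@dataclass
class _ReactionOp:
    flux_index: int
    # (offset, size) per tracked substrate role, in role order (0, 1 or 2)
    substrates: list[tuple[int, int]]
    products: list[_ProductOp]


class IsotopomerEngine:
    """Compiled isotopomer transition structure for one scheme."""

    def __init__(self, scheme: NetworkScheme):
        self.scheme = scheme
        self.pool_ids = [p.id for p in scheme.pools.values() if p.is_tracked]
        self.sizes = {p: 2 ** scheme.pools[p].n_carbons for p in self.pool_ids}
        self.offsets: dict[str, int] = {}
        off = 0
        for p in self.pool_ids:
            self.offsets[p] = off
            off += self.sizes[p]
        self.n_states = off
        self.reaction_ids = list(scheme.reactions)
        self._ops = [self._compile(rxn_id) for rxn_id in self.reaction_ids]
        self._popcount_all = {
            p: _popcounts(self.sizes[p], (1 << scheme.pools[p].n_carbons) - 1)
            for p in self.pool_ids
        }

    # -- compilation ------------------------------------------------------

    def _compile(self, rxn_id: str) -> _ReactionOp:
        scheme = self.scheme
        rxn = scheme.reactions[rxn_id]
        tracked_sub_roles = [
            (role, pid) for role, pid in rxn.substrates if scheme.pools[pid].is_tracked
        ]
        if len(tracked_sub_roles) > 2:
            raise NotImplementedError(
                f"reaction {rxn_id}: more than two tracked substrates"
            )
        sub_sizes = [self.sizes[pid] for _, pid in tracked_sub_roles]
        role_slot = {role: slot for slot, (role, _) in enumerate(tracked_sub_roles)}

        if len(sub_sizes) == 0:
            i_idx = np.zeros(1, dtype=np.intp)
            j_idx = None
        elif len(sub_sizes) == 1:
            i_idx = np.arange(sub_sizes[0], dtype=np.intp)
            j_idx = None
        else:
            i_idx = np.repeat(np.arange(sub_sizes[0], dtype=np.intp), sub_sizes[1])
            j_idx = np.tile(np.arange(sub_sizes[1], dtype=np.intp), sub_sizes[0])

        # collect tracked product roles (incl. CO2 release when tracked)
        prod_roles = [
            (role, pid) for role, pid in rxn.products if scheme.pools[pid].is_tracked
        ]
        co2_tracked = "co2" in scheme.pools and scheme.pools["co2"].is_tracked

        products: list[_ProductOp] = []
        for prole, ppid in prod_roles:
            rows_all, w_all, i_all, j_all = [], [], [], []
            for var in rxn.atom_map.variants:
                rows = np.zeros(len(i_idx), dtype=np.intp)
                for (srole, sc), (prole2, pc) in var.entries:
                    if prole2 != prole:
                        continue
                    if srole not in role_slot:
                        continue  # untracked substrate: unlabeled carbon
                    src = i_idx if role_slot[srole] == 0 else j_idx
                    rows |= ((src >> (sc - 1)) & 1) << (pc - 1)
                rows_all.append(rows)
                w_all.append(np.full(len(i_idx), var.prob))
                i_all.append(i_idx)
                if j_idx is not None:
                    j_all.append(j_idx)
            rows_cat = np.concatenate(rows_all)
            w_cat = np.concatenate(w_all)
            i_cat = np.concatenate(i_all)
            j_cat = np.concatenate(j_all) if j_idx is not None else None
            dense = None
            flat0 = flat1 = None
            n0 = n1 = 0
            if j_idx is None:
                dense = np.zeros((self.sizes[ppid], len(i_idx)))
                np.add.at(dense, (rows_cat, i_cat), w_cat)
            else:
                n0, n1 = sub_sizes
                flat0 = rows_cat * n0 + i_cat
                flat1 = rows_cat * n1 + j_cat
            products.append(
                _ProductOp(
                    offset=self.offsets[ppid],
                    size=self.sizes[ppid],
                    rows=rows_cat,
                    weights=w_cat,
                    i_idx=i_cat,
                    j_idx=j_cat,
                    dense=dense,
                    flat0=flat0,
                    flat1=flat1,
                    n0=n0,
                    n1=n1,
                )
            )
        if co2_tracked:
            # each released carbon forms one CO2 molecule carrying its bit
            for var_i, var in enumerate(rxn.atom_map.variants):
                for srole, sc in var.released:
                    if srole not in role_slot:
                        continue
                    src = i_idx if role_slot[srole] == 0 else j_idx
                    rows = ((src >> (sc - 1)) & 1).astype(np.intp)
                    w = np.full(len(i_idx), var.prob)
                    dense = None
                    flat0 = flat1 = None
                    n0 = n1 = 0
                    if j_idx is None:
                        dense = np.zeros((2, len(i_idx)))
                        np.add.at(dense, (rows, i_idx), w)
                    else:
                        n0, n1 = sub_sizes
                        flat0 = rows * n0 + i_idx
                        flat1 = rows * n1 + j_idx
                    products.append(
                        _ProductOp(
                            offset=self.offsets["co2"],
                            size=2,
                            rows=rows,
                            weights=w,
                            i_idx=i_idx,
                            j_idx=j_idx,
                            dense=dense,
                            flat0=flat0,
                            flat1=flat1,
                            n0=n0,
                            n1=n1,
                        )
                    )
        return _ReactionOp(
            flux_index=self.reaction_ids.index(rxn_id),
            substrates=[(self.offsets[pid], self.sizes[pid]) for _, pid in tracked_sub_roles],
            products=products,
        )

    # -- state helpers ----------------------------------------------------

    def initial_state(
        self,
        experiment: ExperimentSpec | None,
        totals0: Mapping[str, float] | None = None,
    ) -> np.ndarray:
        """All pools unlabeled except the tracer species of ``experiment``."""
        x = np.zeros(self.n_states)
        for pid in self.pool_ids:
            conc = self.scheme.pools[pid].conc0
            if totals0 is not None and pid in totals0:
                conc = totals0[pid]
            x[self.offsets[pid]] = conc
        if experiment is not None:
            for tr in experiment.tracers:
                if tr.pool not in self.offsets:
                    raise KeyError(f"tracer pool {tr.pool!r} not tracked")
                o = self.offsets[tr.pool]
                total = x[o]
                if tr.isotopomer >= self.sizes[tr.pool]:
                    raise ValueError(
                        f"tracer isotopomer {tr.isotopomer} out of range for {tr.pool}"
                    )
                x[o] = total * (1.0 - tr.fraction)
                x[o + tr.isotopomer] += total * tr.fraction
        return x

    def pool_state(self, x: np.ndarray, pool: str) -> np.ndarray:
        o = self.offsets[pool]
        return x[o : o + self.sizes[pool]]

    def pool_totals(self, x: np.ndarray) -> dict[str, float]:
        return {p: float(self.pool_state(x, p).sum()) for p in self.pool_ids}

    def total_label(self, x: np.ndarray) -> float:
        """Total 13C (mM carbon equivalents) in the tracked state."""
        return float(
            sum(self._popcount_all[p] @ self.pool_state(x, p) for p in self.pool_ids)
        )

    # -- dynamics ---------------------------------------------------------

    def rhs(self, x: np.ndarray, flux: np.ndarray) -> np.ndarray:
        dx = np.zeros_like(x)
        for op in self._ops:
            v = flux[op.flux_index]
            if v <= 0.0:
                continue
            fracs = []
            skip = False
            for o, n in op.substrates:
                xs = x[o : o + n]
                tot = xs.sum()
                if tot <= _TINY:
                    skip = True
                    break
                fracs.append(xs / tot)
            if skip:
                continue
            for (o, n), f in zip(op.substrates, fracs):
                dx[o : o + n] -= v * f
            for p in op.products:
                if p.j_idx is None:
                    if op.substrates:
                        g = v * (p.dense @ fracs[0])
                    else:
                        g = np.zeros(p.size)
                        g[0] = v * p.weights.sum()
                else:
                    contrib = p.weights * fracs[0][p.i_idx] * fracs[1][p.j_idx]
                    g = v * np.bincount(p.rows, weights=contrib, minlength=p.size)
                dx[p.offset : p.offset + p.size] += g
        return dx

    def jacobian(self, x: np.ndarray, flux: np.ndarray) -> np.ndarray:
        N = self.n_states
        if not hasattr(self, "_jac_buf"):
            self._jac_buf = np.zeros((N, N))
        J = self._jac_buf
        J.fill(0.0)
        for op in self._ops:
            v = flux[op.flux_index]
            if v <= 0.0 or not op.substrates:
                continue
            fracs, tots = [], []
            skip = False
            for o, n in op.substrates:
                xs = x[o : o + n]
                tot = xs.sum()
                if tot <= _TINY:
                    skip = True
                    break
                fracs.append(xs / tot)
                tots.append(tot)
            if skip:
                continue
            # consumption terms: d(-v f_i)/dx_j = -(v/tot)(δ_ij - f_i)
            for (o, n), f, tot in zip(op.substrates, fracs, tots):
                q = v / tot
                blk = J[o : o + n, o : o + n]
                blk += q * f[:, None]
                idx = np.arange(o, o + n)
                J[idx, idx] -= q
            for p in op.products:
                sl = slice(p.offset, p.offset + p.size)
                if p.j_idx is None:
                    (o, n), f, tot = op.substrates[0], fracs[0], tots[0]
                    g = v * (p.dense @ f)
                    J[sl, o : o + n] += (v / tot) * p.dense
                    J[sl, o : o + n] -= (g / tot)[:, None]
                else:
                    contrib = p.weights * fracs[0][p.i_idx] * fracs[1][p.j_idx]
                    g = v * np.bincount(p.rows, weights=contrib, minlength=p.size)
                    for slot, flat, n in ((0, p.flat0, p.n0), (1, p.flat1, p.n1)):
                        o = op.substrates[slot][0]
                        other = fracs[1 - slot]
                        ocols = p.j_idx if slot == 0 else p.i_idx
                        M = np.bincount(
                            flat, weights=p.weights * other[ocols],
                            minlength=p.size * n,
                        ).reshape(p.size, n)
                        J[sl, o : o + n] += (v / tots[slot]) * M
                        J[sl, o : o + n] -= (g / tots[slot])[:, None]
        return J.copy()


def isotopomer_rhs(
    engine: IsotopomerEngine | NetworkScheme,
    flux_at_t: np.ndarray,
    state: np.ndarray,
) -> np.ndarray:
    """Time derivative of the isotopomer state for a given flux vector."""
    if isinstance(engine, NetworkScheme):
        engine = IsotopomerEngine(engine)
    return engine.rhs(np.asarray(state, dtype=float), np.asarray(flux_at_t, dtype=float))


# ---------------------------------------------------------------------------
# simulation


@dataclass
class LabelingSimulation:
    scheme: NetworkScheme
    engine: IsotopomerEngine
    totals: TotalsTrajectory
    experiment: ExperimentSpec | None
    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)

    def state_at_end(self) -> np.ndarray:
        return self.states[-1]

    def pool_series(self, pool: str) -> np.ndarray:
        o = self.engine.offsets[pool]
        return self.states[:, o : o + self.engine.sizes[pool]]


def simulate_labeling(
    scheme: NetworkScheme,
    params: ParameterSet | Mapping[str, float],
    experiment: ExperimentSpec | None,
    engine: IsotopomerEngine | None = None,
    totals: TotalsTrajectory | None = None,
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-10,
    method: str = "BDF",
    totals_rtol: float = 1e-8,
) -> LabelingSimulation:
    """Two-stage simulation: totals first, then the isotopomer system.

    The totals ODE is integrated with BDF at tight tolerance, the flux series
    is interpolated with a cubic spline on a 1-min grid, and the isotopomer
    system is integrated over it (BDF with the engine's analytic Jacobian).
    """
    if totals is None:
        totals = integrate_totals(scheme, params, experiment, rtol=totals_rtol)
    if engine is None:
        engine = IsotopomerEngine(scheme)
    duration = totals.times[-1]

    _memo: dict[str, object] = {"t": None, "v": None}

    def flux_at(t: float) -> np.ndarray:
        # the solver evaluates fun and jac repeatedly at the same time point
        if t != _memo["t"]:
            _memo["t"] = t
            _memo["v"] = np.maximum(totals.flux_at(t), 0.0)
        return _memo["v"]

    totals0 = {p: totals.conc[0][i] for i, p in enumerate(totals.pool_ids)}
    x0 = engine.initial_state(experiment, totals0)
    if t_eval is None:
        t_eval = np.linspace(0.0, duration, 25)

    sol = solve_ivp(
        lambda t, x: engine.rhs(x, flux_at(t)),
        (0.0, duration),
        x0,
        method=method,
        rtol=rtol,
        atol=atol,
        jac=lambda t, x: engine.jacobian(x, flux_at(t)),
        t_eval=t_eval,
    )
    if not sol.success:
        raise RuntimeError(f"isotopomer integration failed: {sol.message}")
    return LabelingSimulation(
        scheme=scheme,
        engine=engine,
        totals=totals,
        experiment=experiment,
        times=sol.t,
        states=np.maximum(sol.y.T, 0.0),
    )


# ---------------------------------------------------------------------------
# isotopologue aggregation


@dataclass(frozen=True)
class IsotopologueDistribution:
    """Mass-isotopologue fractions of a metabolite or fragment.

    ``fragment`` is a 1-based inclusive carbon range such as ``"C1-C6"``;
    ``fractions[k]`` is the molar fraction with k 13C atoms in the fragment.
    """

    metabolite: str
    fragment: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        s = float(np.sum(self.fractions))
        if abs(s - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {s}, expected 1")
        if np.any(np.asarray(self.fractions) < -1e-12):
            raise ValueError("negative isotopologue fraction")

    def m(self, k: int) -> float:
        return float(self.fractions[k])


def _fragment_range(fragment: str) -> tuple[int, int]:
    lo, hi = fragment.split("-")
    return int(lo.lstrip("C")), int(hi.lstrip("C"))


def to_isotopologues(
    state: np.ndarray,
    pool: str,
    fragment_range: tuple[int, int] | str | None = None,
    engine: IsotopomerEngine | None = None,
    scheme: NetworkScheme | None = None,
    metabolite: str | None = None,
) -> IsotopologueDistribution:
    """Aggregate a pool's isotopomer vector into mass-isotopologue fractions.

    ``state`` may be the full engine state (with ``engine`` given) or the
    pool's own isotopomer vector.  ``fragment_range`` is a (lo, hi) 1-based
    inclusive carbon range or a string like ``"C2-C5"``; None means the whole
    molecule.
    """
    if engine is not None:
        vec = engine.pool_state(np.asarray(state, dtype=float), pool)
        n_carbons = engine.scheme.pools[pool].n_carbons
    else:
        vec = np.asarray(state, dtype=float)
        if scheme is not None:
            n_carbons = scheme.pools[pool].n_carbons
        else:
            n_carbons = int(np.log2(len(vec)))
    if isinstance(fragment_range, str):
        fragment_range = _fragment_range(fragment_range)
    if fragment_range is None:
        fragment_range = (1, n_carbons)
    lo, hi = fragment_range
    if not (1 <= lo <= hi <= n_carbons):
        raise ValueError(f"fragment C{lo}-C{hi} outside 1..{n_carbons}")
    total = vec.sum()
    if total <= _TINY:
        raise ValueError(f"pool {pool!r} is empty; isotopologue fractions undefined")
    mask = 0
    for c in range(lo, hi + 1):
        mask |= 1 << (c - 1)
    counts = _popcounts(len(vec), mask)
    k_max = hi - lo + 1
    fractions = np.bincount(counts, weights=vec, minlength=k_max + 1) / total
    fractions = np.clip(fractions, 0.0, None)
    fractions /= fractions.sum()
    return IsotopologueDistribution(
        metabolite=metabolite or pool,
        fragment=f"C{lo}-C{hi}",
        fractions=fractions,
    )


def observables(
    sim: LabelingSimulation,
    experiment: ExperimentSpec | None = None,
) -> dict[tuple[str, str, str], float]:
    """Endpoint observables in measurement-table layout.

    Returns a flat dict keyed ``(metabolite, fragment, quantity)`` with
    quantities ``"m0".."mk"`` (fractions) and ``"conc"`` (mM for glucose and
    lactate, mg/mL for glycogen), for: medium glucose, medium lactate,
    glutamate C2-C5 and C2-C4 fragments, and glycogen (whole molecule plus
    C1-C4 and C3-C6 fragments).
    """
    del experiment  # layout is fixed by the study design
    x = sim.state_at_end()
    eng = sim.engine
    out: dict[tuple[str, str, str], float] = {}

    def put(metabolite: str, pool: str, fragment: str | None) -> None:
        vec = eng.pool_state(x, pool)
        if vec.sum() <= _TINY:
            # a pool that never filled reports as unlabeled
            n = eng.scheme.pools[pool].n_carbons
            rng_ = _fragment_range(fragment) if isinstance(fragment, str) else (
                fragment or (1, n)
            )
            frag_str = f"C{rng_[0]}-C{rng_[1]}"
            out[(metabolite, frag_str, "m0")] = 1.0
            for k in range(1, rng_[1] - rng_[0] + 2):
                out[(metabolite, frag_str, f"m{k}")] = 0.0
            return
        dist = to_isotopologues(x, pool, fragment, engine=eng, metabolite=metabolite)
        for k, frac in enumerate(dist.fractions):
            out[(metabolite, dist.fragment, f"m{k}")] = float(frac)

    put("glucose", "glc_med", None)
    out[("glucose", "C1-C6", "conc")] = float(eng.pool_state(x, "glc_med").sum())
    put("lactate", "lac_med", None)
    out[("lactate", "C1-C3", "conc")] = float(eng.pool_state(x, "lac_med").sum())
    put("glutamate", "glu", "C2-C5")
    put("glutamate", "glu", "C2-C4")
    put("glycogen", "glycogen", None)
    put("glycogen", "glycogen", "C1-C4")
    put("glycogen", "glycogen", "C3-C6")
    out[("glycogen", "C1-C6", "conc")] = float(
        eng.pool_state(x, "glycogen").sum() * GLYCOGEN_MG_PER_ML_PER_MM
    )
    return out
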