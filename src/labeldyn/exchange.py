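"""Isotope-exchange fluxes of a three-step exchange enzyme.

Aldolase binds fbp (rate ``v1``), releases g3p keeping the dhap moiety
(``v2``), and finally releases dhap (``v3``); the reverse steps run at
``vm3`` (bind dhap), ``vm2`` (bind g3p) and ``vm1`` (release fbp).  At steady
state of the enzyme complexes, the elementary rates partition into

* ``vf``  — forward whole-cycle flux, carrying fbp-origin carbon into the
  triose pools: ``vf = v1·v2·v3 / D`` with ``D = v2·v1 + vm3·v1 + vm3·vm2``;
* ``vr``  — reverse whole-cycle flux: ``vr = vm1·vm2·vm3 / D``;
* ``vfg`` — forward half-molecule exchange, swapping the g3p-derived half of
  fbp with the free g3p pool without releasing dhap:
  ``vfg = v1·v2 / (v1 + vm2)``;
* ``vgf`` — the reverse half-exchange, ``vgf = vm1·vm2 / (v1 + vm2)`` (the
  mirror image of the same steady-state mixing construction: of the
  "bottom halves" entering the fbp-bound complex, a fraction
  ``vm2/(v1+vm2)`` came from the free g3p pool, and those leave inside fbp
  at rate ``vm1``).

``vf − vr`` equals the net chemical flux of the cycle; the half-exchanges
move label with no net mass flow.  The same treatment is applied to the
transketolase and transaldolase cycles with the donor half-molecule playing
fbp's role.

:func:`stochastic_oracle` simulates explicit single-molecule walks over the
cycle and classifies completed label-transfer events; it exists to validate
the closed forms and is used as an independent cross-check in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ElementaryRates",
    "ExchangeFluxes",
    "partition_fractions",
    "exchange_fluxes",
    "stochastic_oracle",
]


@dataclass(frozen=True)
class ElementaryRates:
    """Nonnegative steady-state rates of the six elementary steps."""

    v1: float
    v2: float
    v3: float
    vm1: float
    vm2: float
    vm3: float

    def __post_init__(self) -> None:
        for name in ("v1", "v2", "v3", "vm1", "vm2", "vm3"):
            if getattr(self, name) < 0:
                raise ValueError(f"elementary rate {name} must be >= 0")

    def as_tuple(self) -> tuple[float, ...]:
        return (self.v1, self.v2, self.v3, self.vm1, self.vm2, self.vm3)


@dataclass(frozen=True)
class ExchangeFluxes:
    vf: float
    vr: float
    vfg: float
    vgf: float

    @property
    def net(self) -> float:
        return self.vf - self.vr


def _cycle_denominator(r: ElementaryRates) -> float:
    return r.v2 * r.v1 + r.vm3 * r.v1 + r.vm3 * r.vm2


def partition_fractions(rates: ElementaryRates) -> tuple[float, float, float]:
    """(Pf_Edhap, Pf_Efbp, Pfg_Efbp) — steady-state origin fractions.

    ``Pf_Edhap`` is the fraction of enzyme-bound dhap moieties that originated
    from fbp; ``Pf_Efbp`` the fraction of bound fbp originating from fbp;
    ``Pfg_Efbp`` the fraction of bound g3p-halves originating from fbp.
    """
    D = _cycle_denominator(rates)
    half_D = rates.v1 + rates.vm2
    if D <= 0 or half_D <= 0:
        raise ZeroDivisionError(
            f"partition fractions undefined: cycle denominator {D}, "
            f"half-exchange denominator {half_D} (all-zero rate set?)"
        )
    pf_edhap = rates.v1 * rates.v2 / D
    pfg_efbp = rates.v1 / half_D
    # bound fbp originating from fbp: v1 direct plus recirculated via vm2
    pf_efbp = (rates.vm2 * pf_edhap + rates.v1) / half_D
    return pf_edhap, pf_efbp, pfg_efbp


def exchange_fluxes(rates: ElementaryRates) -> ExchangeFluxes:
    """Closed-form whole-cycle and half-molecule exchange fluxes."""
    D = _cycle_denominator(rates)
    half_D = rates.v1 + rates.vm2
    if D <= 0 or half_D <= 0:
        raise ZeroDivisionError(
            f"exchange fluxes undefined: cycle denominator {D}, "
            f"half-exchange denominator {half_D} (all-zero rate set?)"
        )
    vf = rates.v1 * rates.v2 * rates.v3 / D
    vr = rates.vm1 * rates.vm2 * rates.vm3 / D
    vfg = rates.v1 * rates.v2 / half_D
    vgf = rates.vm1 * rates.vm2 / half_D
    return ExchangeFluxes(vf=vf, vr=vr, vfg=vfg, vgf=vgf)


def stochastic_oracle(
    rates: ElementaryRates,
    n_events: int = 200_000,
    seed: int | None = None,
    urn_size: int = 64,
    with_stderr: bool = False,
) -> ExchangeFluxes | tuple[ExchangeFluxes, ExchangeFluxes]:
    """Empirical exchange fluxes from single-molecule event simulation.

    The closed forms treat the six elementary rates as given steady-state
    flows and mix the molecule origins at each enzyme node in proportion to
    those flows.  The oracle realizes that picture literally: the enzyme-bound
    "top" (dhap-derived) half-molecules at the E-fbp and E-dhap nodes and the
    "bottom" (g3p-derived) halves at E-fbp are each a finite well-mixed urn
    of tagged molecules.  Events are drawn with probability proportional to
    the elementary rates; binding events inject a tagged molecule (evicting a
    random resident so the urn size stays fixed), internal steps move a random
    resident between urns, and release events sample a random resident whose
    tag classifies the completed label transfer:

    * ``vf``  — dhap released (step v3) with an fbp-origin top;
    * ``vr``  — fbp released (step vm1) with a triose-origin top;
    * ``vfg`` — g3p released (step v2) with an fbp-origin bottom;
    * ``vgf`` — fbp released (step vm1) with a free-g3p-origin bottom.

    Each empirical flux is the elementary rate of the release step times the
    observed tag fraction among its events; stationary urn compositions
    satisfy the same flow-mixing balance as the analytic partition fractions,
    so the estimates converge to :func:`exchange_fluxes`.  With
    ``with_stderr=True`` a second :class:`ExchangeFluxes` of batch-means
    Monte-Carlo standard errors is returned.
    """
    if n_events < 10_000:
        raise ValueError("n_events must be >= 1e4 for a meaningful estimate")
    rng = np.random.default_rng(seed)
    v1, v2, v3, vm1, vm2, vm3 = rates.as_tuple()
    D = _cycle_denominator(rates)
    if D <= 0 or (v1 + vm2) <= 0:
        raise ZeroDivisionError("oracle undefined for this rate set")

    step_rates = np.array([v1, v2, v3, vm1, vm2, vm3], dtype=float)
    probs = step_rates / step_rates.sum()
    # urns hold the number of fbp-tagged molecules out of `urn_size`
    top_efbp = urn_size // 2
    top_edhap = urn_size // 2
    bot_efbp = urn_size // 2

    burn = n_events // 10
    n_batches = 20
    batch_len = (n_events - burn) // n_batches
    # per batch: [n_v3, n_v3_fbp, n_vm1, n_vm1_triose_top, n_vm1_pool_bot, n_v2, n_v2_fbp]
    stats = np.zeros((n_batches, 7), dtype=np.int64)

    draws = rng.choice(6, size=n_events, p=probs)
    unif = rng.random(n_events * 2).reshape(-1, 2)
    for i in range(n_events):
        ev = draws[i]
        u0, u1 = unif[i]
        if ev == 0:  # v1: bind fbp -> fbp-tagged top and bottom enter E-fbp
            if u0 * urn_size >= top_efbp:
                top_efbp += 1  # evicted an untagged one, inserted tagged
            if u1 * urn_size >= bot_efbp:
                bot_efbp += 1
        elif ev == 1:  # v2: E-fbp -> E-dhap, bottom released as g3p
            fbp_bot = u0 * urn_size < bot_efbp
            # a random top moves from E-fbp urn into E-dhap urn
            moved_tagged = u1 * urn_size < top_efbp
            if rng.random() * urn_size >= top_edhap:
                if moved_tagged:
                    top_edhap += 1
            elif not moved_tagged:
                top_edhap -= 1
            if i >= burn:
                b = min((i - burn) // batch_len, n_batches - 1)
                stats[b, 5] += 1
                stats[b, 6] += int(fbp_bot)
        elif ev == 2:  # v3: release dhap from E-dhap
            fbp_top = u0 * urn_size < top_edhap
            if i >= burn:
                b = min((i - burn) // batch_len, n_batches - 1)
                stats[b, 0] += 1
                stats[b, 1] += int(fbp_top)
        elif ev == 3:  # vm1: release fbp from E-fbp (top + bottom leave)
            fbp_top = u0 * urn_size < top_efbp
            fbp_bot = u1 * urn_size < bot_efbp
            if i >= burn:
                b = min((i - burn) // batch_len, n_batches - 1)
                stats[b, 2] += 1
                stats[b, 3] += int(not fbp_top)
                stats[b, 4] += int(not fbp_bot)
        elif ev == 4:  # vm2: bind free g3p, E-dhap -> E-fbp
            if u0 * urn_size < bot_efbp:
                bot_efbp -= 1  # evicted a tagged bottom, inserted pool-origin
            moved_tagged = u1 * urn_size < top_edhap
            if rng.random() * urn_size >= top_efbp:
                if moved_tagged:
                    top_efbp += 1
            elif not moved_tagged:
                top_efbp -= 1
        else:  # vm3: bind free dhap -> triose-tagged top enters E-dhap
            if u0 * urn_size < top_edhap:
                top_edhap -= 1

    def _flux(rate: float, hits: np.ndarray, events: np.ndarray) -> tuple[float, float]:
        tot_ev = events.sum()
        if rate == 0 or tot_ev == 0:
            return 0.0, 0.0
        est = rate * hits.sum() / tot_ev
        ok = events > 0
        if ok.sum() >= 2:
            per_batch = rate * hits[ok] / events[ok]
            se = float(per_batch.std(ddof=1) / np.sqrt(ok.sum()))
        else:
            se = float("nan")
        return float(est), se

    vf_e, vf_se = _flux(v3, stats[:, 1], stats[:, 0])
    vr_e, vr_se = _flux(vm1, stats[:, 3], stats[:, 2])
    vgf_e, vgf_se = _flux(vm1, stats[:, 4], stats[:, 2])
    vfg_e, vfg_se = _flux(v2, stats[:, 6], stats[:, 5])
    est = ExchangeFluxes(vf=vf_e, vr=vr_e, vfg=vfg_e, vgf=vgf_e)
    if with_stderr:
        return est, ExchangeFluxes(vf=vf_se, vr=vr_se, vfg=vfg_se, vgf=vgf_se)
    return est
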