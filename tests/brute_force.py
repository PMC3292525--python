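"""Independent brute-force isotopomer simulator used as a test oracle.

Deliberately naive: states are dicts of per-pool isotopomer dictionaries,
product isotopomers are assembled by looping over atom-map entries one
carbon at a time, and condensations enumerate every substrate combination
with ``itertools.product``.  No index precompilation, no numpy scatter —
a completely separate code path from the production engine.
"""

from itertools import product as iproduct

import numpy as np
from scipy.integrate import solve_ivp


def brute_rhs(scheme, flux: dict, state: dict) -> dict:
    d = {pool: {i: 0.0 for i in patterns} for pool, patterns in
         ((p, list(state[p])) for p in state)}
    for rxn in scheme.reactions.values():
        v = flux.get(rxn.id, 0.0)
        if v <= 0:
            continue
        tracked = [(role, pid) for role, pid in rxn.substrates
                   if scheme.pools[pid].is_tracked]
        fracs = {}
        empty = False
        for role, pid in tracked:
            tot = sum(state[pid].values())
            if tot <= 1e-30:
                empty = True
                break
            fracs[role] = {i: x / tot for i, x in state[pid].items()}
        if empty:
            continue
        for role, pid in tracked:
            for i, f in fracs[role].items():
                d[pid][i] -= v * f
        prod_pool = dict(rxn.products)
        combos = iproduct(*[list(fracs[role].items()) for role, _ in tracked])
        for combo in combos:
            w = 1.0
            iso_of_role = {}
            for (role, _pid), (iso, f) in zip(tracked, combo):
                w *= f
                iso_of_role[role] = iso
            if w == 0.0:
                continue
            for var in rxn.atom_map.variants:
                out = {prole: 0 for prole in prod_pool}
                for (srole, sc), (prole, pc) in var.entries:
                    if srole not in iso_of_role:
                        continue  # untracked substrate carbon: unlabeled
                    bit = (iso_of_role[srole] >> (sc - 1)) & 1
                    out[prole] |= bit << (pc - 1)
                for prole, iso in out.items():
                    pid = prod_pool[prole]
                    if scheme.pools[pid].is_tracked:
                        d[pid][iso] += v * w * var.prob
    return d


def brute_simulate(scheme, flux: dict, state0: dict, t_span, t_eval):
    """Integrate the brute-force system with constant fluxes."""
    pools = list(state0)
    sizes = {p: 2 ** scheme.pools[p].n_carbons for p in pools}
    offsets = {}
    off = 0
    for p in pools:
        offsets[p] = off
        off += sizes[p]

    def pack(state):
        x = np.zeros(off)
        for p in pools:
            for i, val in state[p].items():
                x[offsets[p] + i] = val
        return x

    def unpack(x):
        return {
            p: {i: x[offsets[p] + i] for i in range(sizes[p])} for p in pools
        }

    def rhs(_t, x):
        return pack(brute_rhs(scheme, flux, unpack(x)))

    sol = solve_ivp(rhs, t_span, pack(state0), t_eval=t_eval,
                    rtol=1e-10, atol=1e-12, method="LSODA")
    assert sol.success
    return sol


def brute_isotopologues(vec: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Popcount aggregation by explicit loop over all isotopomers."""
    k_max = hi - lo + 1
    out = np.zeros(k_max + 1)
    for iso, val in enumerate(vec):
        k = sum((iso >> (c - 1)) & 1 for c in range(lo, hi + 1))
        out[k] += val
    return out / vec.sum()
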