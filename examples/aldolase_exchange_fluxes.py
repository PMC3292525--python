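"""Aldolase isotope-exchange fluxes from elementary-step rates.

The three-step reaction cycle (bind fbp, release g3p, release dhap — and
the reverse steps) partitions into a forward cycle flux vf, a reverse cycle
flux vr and half-molecule exchanges vfg/vgf that move label without net
chemistry.  The closed forms are checked here against a single-molecule
Monte-Carlo simulation of the same cycle.
"""

from labeldyn import ElementaryRates, exchange_fluxes, stochastic_oracle

rates = ElementaryRates(v1=2.0, v2=3.0, v3=4.0, vm1=1.0, vm2=1.0, vm3=1.0)
analytic = exchange_fluxes(rates)
empirical, stderr = stochastic_oracle(
    rates, n_events=200_000, seed=1, with_stderr=True
)

print("elementary rates:", rates.as_tuple())
print(f"{'flux':>5s} {'closed form':>12s} {'Monte Carlo':>12s} {'MC stderr':>10s}")
for name in ("vf", "vr", "vfg", "vgf"):
    print(f"{name:>5s} {getattr(analytic, name):12.4f} "
          f"{getattr(empirical, name):12.4f} {getattr(stderr, name):10.4f}")
print(f"\nnet chemical flux vf - vr = {analytic.net:.4f}")
print("vf = v1·v2·v3 / (v2·v1 + v-3·v1 + v-3·v-2) = 24/9 for these rates;")
print("the Monte-Carlo estimates agree within a few standard errors, and the")
print("half-exchanges (vfg, vgf) shuttle fbp's C4-C6 half against the free")
print("g3p pool with no net fbp consumption.")
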