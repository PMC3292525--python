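"""Model discrimination with the incomplete-gamma Q test.

Given a fitted χ², the number of data points N and the number of effective
(identifiable) parameters P, the probability that a correct model exceeds
that χ² by chance is Q(F/2, χ²/2) with F = N − P.  Q > 0.05 accepts the
model; Q < 0.001 rejects it.  The numbers below are the published fits of
the two hexose-phosphate topologies to the hepatocyte data.
"""

from labeldyn import discrimination_report

cases = [
    ("single pool, whole molecules", 22, 16, 38.28),
    ("channeling,  whole molecules", 22, 18, 3.13),
    ("channeling,  with fragments", 29, 21, 12.52),
    ("single pool, with fragments", 29, 18, 74.9),
    ("channeling,  two experiments", 46, 24, 36.1),
    ("single pool, two experiments", 46, 24, 94.286),
]

print(f"{'model / data':32s} {'N':>3s} {'P':>3s} {'F':>3s} "
      f"{'chi2':>8s} {'Q':>10s}  verdict")
for label, n, p, chi2 in cases:
    rep = discrimination_report(n, p, chi2)
    print(f"{label:32s} {n:3d} {p:3d} {rep.dof:3d} "
          f"{chi2:8.2f} {rep.q:10.3g}  {rep.verdict}")

print()
print("The single-pool (well-mixed) topology is rejected at every data level")
print("while the channeled topology stays acceptable (at worst marginal, the")
print("band tolerating moderately underestimated errors) — the glycogen")
print("isotopologue pattern cannot be produced by a hexose-phosphate pool")
print("shared between glycolysis and glycogen synthesis.")
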