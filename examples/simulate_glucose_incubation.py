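"""Simulate the 2-h hepatocyte incubation with 50% [1,2-13C2]glucose.

Builds the channeled-topology scheme (two hexose-phosphate pools), runs the
totals + isotopomer simulation at the reference parameters and prints the
endpoint mass-isotopologue distributions that GC/MS would measure.
"""

from labeldyn import build_scheme, condition_a, default_parameters
from labeldyn import observables, simulate_labeling

scheme = build_scheme("B")
params = default_parameters(scheme)
sim = simulate_labeling(scheme, params, condition_a())
obs = observables(sim)

print("Endpoint observables after 120 min (glucose-only incubation):")
for metabolite, fragment in [
    ("glucose", "C1-C6"), ("lactate", "C1-C3"),
    ("glutamate", "C2-C5"), ("glycogen", "C1-C6"), ("glycogen", "C3-C6"),
]:
    ms = [
        f"m{k}={obs[(metabolite, fragment, f'm{k}')]:.4f}"
        for k in range(4)
        if (metabolite, fragment, f"m{k}") in obs
    ]
    print(f"  {metabolite:9s} {fragment}: {' '.join(ms)}")
print(f"  glucose concentration : {obs[('glucose', 'C1-C6', 'conc')]:.1f} mM")
print(f"  lactate concentration : {obs[('lactate', 'C1-C3', 'conc')]:.2f} mM")
print(f"  glycogen accumulated  : {obs[('glycogen', 'C1-C6', 'conc')]:.2f} mg/mL")
print()
print("The m2 channels dominate the labeled species: [1,2-13C2]glucose keeps")
print("its two-carbon label through glycolysis ([2,3-13C2]lactate) and into")
print("glycogen, while the C3-C6 glycogen fragment stays mostly unlabeled")
print("because the label sits on carbons 1-2.")
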