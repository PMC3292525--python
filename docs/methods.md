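# Methods

This note records the model, the numerical choices and the conventions the
package commits to, including the places where the design was genuinely
open and a choice had to be made.

## Model structure

The hepatocyte network covers upper and lower glycolysis/gluconeogenesis,
glycogen turnover, the pentose phosphate pathway, lactate exchange with the
medium, and a lumped TCA segment, with media pools (glucose, lactate,
glutamate) explicitly represented. Pools connected by fast equilibria are
lumped: glucose-6-P ≡ fructose-6-P as `hexP`, and the pentose phosphates
(ribose-5-P, ribulose-5-P, xylulose-5-P) as `p5p`. Dihydroxyacetone
phosphate and glyceraldehyde-3-P are kept distinct, coupled by a reversible
net isomerase flux (`tpif`/`tpir`) plus a label-only exchange (`aldex`).
Citrate and isocitrate are folded into the citrate-synthase lump `cs`
(oaa + accoa → akg + CO₂), and the span from 2-oxoglutarate through the
symmetric succinate/fumarate pool back to malate is one scrambled step
(`citmal`, orientation probability ½ each). Glutamate exchanges label with
2-oxoglutarate through a mass-neutral exchange flux (`akgglu`).

Carbon bookkeeping is explicit everywhere: every reaction carries an atom
map (1-based carbons; isotopomers indexed by bitmask with bit i−1 encoding
carbon i), symmetric intermediates get scramble variants, and a validator
checks that every map is a bijection from substrate carbons onto product
plus released carbons. The two scheme variants are shipped as JSON data
files; a builder module regenerates them and a test pins file ↔ builder
equality.

CO₂ is untracked by default — the bicarbonate buffer dominates the
dissolved pool, so carboxylation (pc) introduces an unlabeled C4 into
oxaloacetate. Building a scheme with a tracked CO₂ pool is supported (set
`is_tracked` on the pool); released carbons then feed it.

Conditions (b) and (c) of the incubation design contained 1 mM pyruvate
alongside 9 mM lactate; the model carries no separate medium-pyruvate pool,
so those media are represented by their lactate content only. This biases
the carbon supply by ≤ 10% of the lactate pool and none of the tracer
logic (the pyruvate was unlabeled).

## Kinetic layer

Rates are deliberately simple — irreversible mass action or
Michaelis–Menten with one or two parameters per reaction — because the
discrimination question lives in the flux values and the topology, not in
the rate-law algebra. Units are minutes and mM referred to medium volume;
glycogen is tracked in mM glucosyl-unit equivalents and reported as mg/mL
of cell pellet via 162 g/mol ÷ 0.12 pellet-to-medium volume fraction (a
reporting convention, stated here once; `GLYCOGEN_MG_PER_ML_PER_MM`).
The medium-to-cell volume normalization is the identity by default
(`medium_volume_ratio = 1`): all pools live on the medium-volume scale, so
intracellular "concentrations" are effective medium-referred values.

The totals ODE system is integrated with BDF (stiff-capable implicit
multistep) at rtol 1e-8/atol 1e-10 with dense output; the isotopomer layer
queries concentrations and fluxes through the dense interpolant, which is
what keeps the two layers consistent through the fast initial transient
(an interpolated 1-min flux grid leaves a ~10⁻³ offset; the dense
interpolant keeps per-pool isotopomer sums within 10⁻⁶ relative of the
kinetic totals at rtol 1e-8).

Exchange enzymes (aldolase, both transketolase steps, transaldolase) are
parameterized by six elementary-step constants each; the steady-state
partition of the three-step cycle yields the forward/reverse cycle fluxes
and the half-molecule exchange. The reverse half-exchange formula is not
derivable from the printed forward one alone; we use the mirror image of
the same influx-fraction construction, v_gf = v₋₁v₋₂/(v₁+v₋₂), and the
single-molecule Monte-Carlo oracle validates all four fluxes. The engine
wires vf/vr as the net reaction pair and drives the half-exchange reaction
at the symmetrized rate ½(v_fg+v_gf) (each half-exchange event swaps
material in both directions; the two path types are pooled). Reference
parameter values invert the partition closed forms from target cycle
fluxes under the convention that the four internal steps share the scale
s = 4(v_f+v_r), which determines the binding steps uniquely.

## Isotopomer engine

Each tracked pool with n carbons carries 2ⁿ isotopomer concentrations
(largest pool: sedoheptulose-7-P, 128 states; whole system ≈ 640). At
compile time every (reaction, scramble variant, product) is flattened into
index arrays, so the right-hand side is pure gather/scatter: substrates are
consumed in proportion to fractional abundance, condensations draw
substrate molecules independently (an outer product over the two substrate
distributions), and products are scattered through precomputed maps. The
analytic Jacobian of this bilinear system is assembled the same way —
normalizing by the *current* pool sums makes the fraction derivatives a
diagonal plus rank-one correction per block — and is what makes implicit
BDF integration of the label system affordable (a finite-difference
Jacobian would cost ~640 right-hand sides per factorization).

Glycogen is a single growing pool in the label system: synthesis deposits
glucosyl units carrying the instantaneous channel (or bulk) composition
and phosphorylase removes units at the pool's current average composition.
For an accumulating pool with proportional removal this is exactly the
cumulative bookkeeping of deposited units, without a separate data
structure; no claim is made about LIFO/FIFO polymer structure.

Natural ¹³C abundance is *not* simulated — the packaged measurement tables
are already abundance-corrected — but the measurement module provides the
binomial skeleton-carbon convolution and its inverse for raw data
(p(¹³C) = 0.0107 by default; correction applies to skeleton carbons only).

## Measurement model and χ²

Measurement tables are CSV rows of (experiment, metabolite, fragment,
quantity, mean, sd, units), where fragments are carbon ranges (the GC/MS
fragment ions: glucose C1-C4/C3-C6 from glycogen, glutamate C2-C4/C2-C5).
χ² sums squared sd-normalized deviations and is reported per
(metabolite, fragment) group exactly as the measured tables group rows;
concentration rows enter χ² with their printed sd on the same footing as
fraction rows (the tables list them inside the χ² groups). The packaged
glucose-only table has 28 quantitative rows — 22 whole-molecule and
concentration points plus 6 glycogen-fragment points. One printed value is
corrected in the fixtures (a glutamate C2-C4 simulated entry misprinted
×10; flagged in the file header), and the glutamate C2-C4 group's printed
χ² values are inconsistent with their own printed rows, so that group is
excluded from the recomputation checks.

## Fitting

Annealing proposes multiplicative log-normal steps on one randomly chosen
free parameter at a time (fluxes span six orders of magnitude, so
log-scale proposals are the only sensible move), with geometric cooling
(α = 0.95 per 10 proposals by default) and Metropolis acceptance, followed
by a coordinate-descent polish whose step halves when a pass yields no
improvement. Frozen parameters never move; bounds are enforced by
clipping; a failed simulation scores +∞ (the move is rejected). Every run
records its seed and accepted-move trace.

Confidence intervals follow the χ²-threshold convention: members of a fit
ensemble whose χ² lies within the one-degree-of-freedom quantile (6.63 at
99%) of the ensemble minimum define the envelope of each flux.  Because
short optimization runs cluster near the data optimum, `profile_ensemble`
adds threshold-probing scans: each flux parameter is stepped geometrically
from the optimum, and a probe that crosses the threshold is first
re-polished over the other free parameters (the profile-likelihood
construction) before the scan direction is declared exhausted. Fluxes are
reported as time averages over the incubation (∫v dt / T), since the
system is not at steady state.

## Effective parameters

The Gauss–Newton Hessian 2·Jᵀdiag(1/σ²)J is built from a central
finite-difference residual Jacobian (relative step 1e-4 by default; the
sign makes the matrix positive-semidefinite, as a curvature at a χ²
minimum must be). Effective-parameter counting is greedy forward
selection ordered by diagonal sensitivity (ties broken by name), adding
parameters while the selected submatrix's reciprocal condition number
stays above 1e-10 — a threshold chosen far from machine epsilon so the
count is stable across platforms. The covariance matrix is the SVD
pseudo-inverse when the full matrix is invertible.

## Synthetic data

The generator simulates a known truth (scheme variant + parameters) under
the study's incubation design and emits measurement tables in the same
28-row layout, with independent Gaussian noise per row: isotopologue sd
clip(0.08·value, 0.005, 0.05) and concentration sd 10% — the magnitudes of
the measured tables. Fractions are clipped to [0, 1]; a distribution is
renormalized only when clipping actually moved mass, so that unclipped
channels keep deviations distributed exactly as the recorded sd (blanket
renormalization would shrink dominant-channel deviations to ~1/√2 of sd).
No correlation between isotopologue channels is modeled (only per-channel
sds are reported in the study tables), and natural abundance is absent by
construction.

What passing synthetic tests shows — and what it does not: recovery and
discrimination results demonstrate that the estimator and test behave
correctly when the data-generating process *is* the model with independent
Gaussian noise. Real measurements carry channel correlations from
normalization, derivatization artifacts, and model misspecification that
these studies do not emulate.

Default truth parameters are calibrated so the initial flux distribution
matches the fitted glucose-only flux scale (glycogen synthesis ≈ 2·10⁻³,
glucose phosphorylation ≈ 2.7·10⁻³ mM·min⁻¹, TCA fluxes ≈ 10⁻⁷), i.e. the
dynamic range the method actually has to handle.

## Reduced-scale study protocols

The stochastic acceptance studies run at desk scale, sized once:

* **Topology recovery** — 5 seeds of truth-B data (28 rows each), fit with
  both topologies from jittered reference starts (jitter 0.25 in log
  space), annealing budget 40 proposals + 1 descent pass, 8 free
  parameters for scheme A and 12 for scheme B (the hexose-phosphate routes
  and main throughputs; all other parameters held at their starting
  values, hence counted as constants). Effective parameters come from the
  Hessian at the fit. Verdicts: accept for B and reject for A in ≥ 4/5
  seeds; 2 seeds of truth-A data fit with scheme A must not be rejected.
* **Flux-envelope coverage** — 2 seeds; one annealed fit (30 proposals)
  per seed plus profile scans (factor 1.3, ≤ 8 steps per direction) over
  the glycogen-synthesis, glucose-phosphorylation and phosphofructokinase
  rate constants; the truth's time-averaged fluxes must fall inside the
  99% envelopes.

## Known limitations

* Rate laws are minimal; fitted parameters are effective constants, not
  enzyme kinetic constants, and only flux values are interpretable.
* The pentose-phosphate half-exchanges not derivable from the three
  shipped enzyme cycles (`f6p-g3p`, `f6p-s7p`, `p5p-s7p`) are standalone
  exchange reactions with their own rate constants.
* Medium pyruvate is folded away (above); glutamate is a single pool
  exchanging with 2-oxoglutarate rather than a transaminase model.
* The Q test assumes Gaussian independent errors; the marginal band
  (0.001 < Q ≤ 0.05) exists precisely because real error models are
  heavier-tailed.
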