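# Methods

## The equilibrium model

`grcube` models transactivation by a nuclear receptor — the glucocorticoid
receptor (GR) is the motivating case — as a mass-action equilibrium between
the receptor R and three partners: a ligand L (e.g. dexamethasone), a
coregulator C (an LXXLL "NR-box" motif contacting the AF-2 surface of the
ligand-binding domain), and a DNA response element D (a GRE).  The receptor
is partitioned over the eight species at the corners of a cube,

```
R, LR, RC, RD, LRC, LRD, RCD, LRCD
```

following the cubic-ternary-complex family of receptor models.  Three
association constants (Ka, Kc, Kd, per molar) set the intrinsic affinity of
each partner; four dimensionless cooperativity factors couple the binding
events: `alpha` (ligand ↔ coregulator), `beta` (coregulator ↔ DNA), `gamma`
(ligand ↔ DNA), and `delta`, the third-order term expressing how the joint
effect of any two binding events depends on the third.  The statistical
weight of a species relative to free R is the product of K·concentration
factors for each bound partner and the cooperativity factor for each bound
pair, with the fully occupied complex carrying all three pairwise factors
times `delta`:

```
w(LRCD) = alpha * beta * gamma * delta * (Ka L)(Kc C)(Kd D)
```

This weight convention is a declared choice: whether `delta` multiplies all
three pairwise factors or replaces some of them is a modelling decision, and
it is isolated in a single function (`equilibrium.statistical_weights`) so an
alternative convention can be swapped in.  Equilibrium fractions are the
weights normalized by their sum (a partition function); species whose
partner is absent have exactly zero weight, and the computation switches to
log space when any weight exceeds 1e300.

Transcription is attributed to the fully assembled complex LRCD (the
multifactorial transcriptional complex); the response in fold-induction
units is `epsilon * Rtot * sum(coef_s * fraction_s)` with the default
coefficients {LRCD: 1}.  A nonzero RCD coefficient is available (off by
default) to represent ligand-independent activity of the apo receptor,
which the model permits but does not require.  `epsilon` is pure unit
plumbing: it maps receptor-weighted occupancy to the fold-induction scale
of qPCR readouts and is confounded with Rtot by construction (only the
product enters the response), which the mechanistic fitter enforces.

### Analytic mode vs conserved totals

The analytic mode treats L, C and D as non-depleted (free = total), the
regime of a cell or array experiment where partners are in large excess
over receptor.  `solve_conserved` is a validation mode only: it solves the
same equilibrium under conservation of all four totals with a damped
multiplicative fixed point on the free partner concentrations (budget
10,000 iterations, convergence at max relative mass-balance residual
1e-9) and a bounded least-squares root-finder as fallback.  The test suite
checks that with partner totals ≥ 10⁴ × Rtot the two modes agree within
relative 1e-3.

### Dose–response structure

For a single ligand the response is a Möbius function of dose,
`eps·Rtot·(n0 + n1 L)/(d0 + d1 L)`, where `d0 = 1 + KcC + KdD + β KcKd CD`
is the zero-dose binding polynomial and `d1 = Ka (1 + αKcC + γKdD +
αβγδ KcKd CD)` the high-dose one.  Consequences used throughout:

- curves are exactly hyperbolic (Hill slope 1, the mass-action /
  Michaelis–Menten shape);
- `basal = eps·Rtot·n0/d0`, `Rmax = eps·Rtot·n1/d1`, and the midpoint
  between them falls at **EC50 = d0/d1** for *any* efficacy coefficients
  (the midpoint of a Möbius function is numerator-free);
- at `alpha = beta = gamma = delta = 1` the cube factorizes into three
  independent occupancies and EC50 = 1/Ka exactly;
- the response is linear in Rtot, so receptor knockdown scales Rmax and
  cannot move EC50;
- coregulator knockdown (scaling C) moves Rmax always, and moves EC50 only
  through the cooperativities — strongly when `delta` is far from 1.

`summarize_curve` nonetheless locates EC50 numerically (bracketing on a
dense log-dose grid plus Brent bisection, relative tolerance 1e-6),
mirroring how EC50 is read off measured curves; the closed form
`ec50_analytic` serves as an independent oracle in the tests.

### Parameter-sensitivity classification

`classify_parameter_sensitivity` scans one parameter geometrically over a
total fold range F (default 100, 21 points, symmetric around the baseline)
and labels it by which summaries move: a summary "changes" when its max/min
ratio over the scan is ≥ 1.25.  The threshold is a declared convention —
the underlying dichotomy is qualitative — and is configurable and reported
in every `SensitivityReport`.

For `alpha`, `gamma` and `delta` the scanned parameter enters only `d1`
linearly, which forces an exact trade-off: (EC50 ratio) × (Rmax ratio) = F
over the scan.  Hence "both" requires the EC50 ratio to fall in
[1.25, F/1.25], and because `alpha` (and `gamma`) always has at least the
EC50 leverage of `delta` (it multiplies the LRC or LRD weight in addition
to LRCD), the only attainable pattern with `delta` as the sole "both"-mover
is `alpha`, `gamma`: EC50-only; `beta`: Rmax-only (`beta` cancels from
EC50 identically at unit `alpha·gamma·delta`).  The committed baseline
realizing this pattern (Kc·C = Kd·D = 10⁴, beta ≈ 5.6e-3, alpha = gamma =
delta = 1, Ka = 1e8 /M) was found by `scripts/find_baseline.py`, a grid
search maximizing the worst-case log-margin to the threshold; the scenario
file `grcube/scenarios/sensitivity-scan.json` records it.  The same script
finds the coregulator-knockdown demonstration regime (delta ≈ 49,
Kc·C = Kd·D = 0.3) in which a 10-fold C reduction moves EC50 2.7-fold and
Rmax 2.9-fold while the unit-cooperativity control moves Rmax only.

### Competition

Multiple ligands binding mutually exclusively at one pocket extend the cube
to 4 + 4·(number of ligands) species, each ligand carrying its own Ka,
alpha, gamma, delta and an efficacy coefficient on its fully assembled
complex.  A zero-efficacy, high-affinity competitor at saturating dose is a
pure antagonist: it right-shifts the agonist curve without changing the
asymptotic plateau (the agonist's species dominate as its dose → ∞), and
suppresses the response at intermediate doses.

## Curve fitting

`fit_logistic4` fits the standard four-parameter logistic

```
response = bottom + (top − bottom) / (1 + 10^(hill·(log10 EC50 − log10 dose)))
```

parameterized on pEC50, by Levenberg–Marquardt least squares (unweighted by
default, optional 1/variance weights).  Starting values: bottom/top from
the extreme mean responses, pEC50 by interpolation at half range, hill 1;
hill is free by default and fixable to the mass-action value 1.  Standard
errors are asymptotic (Wald) from the local curvature; a fit whose top
barely exceeds its bottom is flagged degenerate and a fit whose largest
dose is below the fitted EC50 is flagged as not spanning the plateau.
Simulation tests calibrate the fitter: exact recovery on noiseless data,
median |pEC50 error| ≤ 0.1 at 10% CV triplicates, and 95% Wald intervals
covering in [90%, 99%].

`compare_fit_parameters` is a normal-theory z-test on asymptotic SEs,
reported per comparison without multiplicity correction.  It deliberately
does not reproduce any particular t-test degrees-of-freedom convention; the
type-I error calibration (≈5% at nominal 0.05) is verified by simulation.

`fit_mechanism` fits the equilibrium model jointly across linked conditions
(e.g. a knockdown series sharing everything but an abundance scale) on log
parameters.  A structural screen refuses under-identified declarations: a
single curve pins at most two quantities (an effective EC50 and an Rmax),
so the free set may not exceed 2 × conditions; the first condition's scale
is anchored at 1 so `epsilon` stays identifiable; near-null singular
directions of the Jacobian are reported as confounded combinations.

## The array arm

On a coregulator peptide array no DNA is present, so the model reduces to
the D = 0 face {R, LR, RC, LRC}; the expected fluorescence on an
immobilized peptide is `gain · Rtot · (f_RC + f_LRC)` — everything the
anti-receptor fluorophore sees.  The modulation index is
`MI = log2(mean ligand / mean vehicle)`; base and aggregation order
(ratio-of-means) are declared conventions, configurable.  At saturating
ligand the model predicts `sign(MI) = sign(alpha − 1)` exactly, for any
receptor occupancy.  Calls (favored / unfavored / unchanged) come from
per-peptide unpaired equal-variance t-tests on log signals (fluorescence
noise is multiplicative) at a declared alpha level, without multiplicity
correction by default (Benjamini–Hochberg optional).

Because p-values under the null are uniform regardless of noise level,
*exact* recovery of a generated truth panel is only the model's prediction
at a strict test level: at 1% CV the truly modulated peptides in the
default panel have |t| ≳ 50, so the recovery checks run the classifier at
alpha = 1e-5, where the family-wise false-positive probability across the
159 per-peptide tests is ≈0.16% while every modulated peptide is still
detected with order-of-magnitude margin.  The shipped default panel places
Kc in 1e5–3e5 /M (3–10 µM dissociation, typical of isolated LXXLL
peptides), keeping spot occupancy at the 1 µM peptide concentration in the
sensitive region of the isotherm; a panel saturated at its spots would
show vanishing modulation regardless of alpha.

## qPCR quantification

Amplification efficiency comes from an OLS dilution standard curve,
`efficiency = 10^(−1/slope)` (slope in Cp per log10 template); curves with
non-negative slope are rejected, efficiencies above 2.2 or R² below 0.98
are flagged rather than fatal.  Fold induction is
`eff_target^dCp_target / eff_reference^dCp_reference` with dCp oriented
control − experimental (induction ⇒ positive dCp ⇒ fold > 1); replicates
are aggregated as mean Cp per group before differencing, and replicate
variability propagates to a fold CI by the delta method on the Cp means.

## Synthetic data

Every generator is a bit-reproducible function of (truth, design, seed) and
returns a truth record alongside the dataset, closing the loop for recovery
tests.  Noise families match each measurement's support: Gaussian with a
coefficient of variation (floored at 0) for fold-induction readouts,
lognormal (unit mean) for array fluorescence, additive Gaussian on Cp.
Default designs mirror the emulated experiments: 8 doses spanning
10 pM–1 µM, triplicates, 4PL truths with pEC50 near 9 and Rmax in the tens
of fold, 53-peptide panels probed with 1 nM receptor and 1 µM ligand,
triplicate qPCR plates with Cp SD 0.15.  The replicate noise magnitudes are
declared assumptions (chosen as plausible for these assay types), not
measured values.

What the generators do **not** emulate: plate/batch effects, heteroscedastic
floors at zero dose, image-level array artefacts (spot morphology,
background), qPCR outliers or failed wells, and biological (as opposed to
technical) replicate variation.  Passing recovery tests therefore shows the
analysis is correct and calibrated under the stated noise models, not that
those models exhaust real data.

## Numerical choices and limitations

- Problem sizes in the test suite and acceptance script (10,000 partition
  draws; 100-draw oracle comparisons; 200–500 simulation calibrations;
  1,000 comparison pairs) were chosen to make the Monte-Carlo bands tight
  relative to the tolerances they check while keeping the whole suite in
  the tens of seconds.
- The conserved-totals solver can be slow to converge in deeply depleted,
  strongly cooperative corners; the least-squares fallback covers these,
  and non-convergence raises with the residual attached.
- Only one coregulator species per model instance (the single-cube model);
  the API keeps per-ligand parameter structure so a multi-accessory
  "double-cube" extension would not break callers.
- Equilibrium only: no binding kinetics, no translocation dynamics.
- Hill slopes ≠ 1 are fit phenomenologically, never generated
  mechanistically (no oligomerization terms).
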