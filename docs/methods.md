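# Methods

## Competitive binding model

The equilibrium module models one receptor species (a methyllysine reader)
distributing among N ligands under three assumptions: 1:1 stoichiometry per
complex, exclusive binding (one ligand per receptor at a time — no
cooperative or bivalent terms), and a closed system at equilibrium (no
kinetics). Mass balance for the receptor and each ligand together with the
definition of each dissociation constant, `Kd_i = R_f·L_i,f/[R·L_i]`,
collapse to a single scalar equation in the free receptor `r`:

```
f(r) = r·(1 + Σ_i L_i,t/(Kd_i + r)) − R_t = 0
```

`f` is strictly increasing with `f(0) = −R_t ≤ 0` and `f(R_t) ≥ 0`, so a
unique physical root lies in `[0, R_t]`. We solve in the scaled variable
`x = r/R_t ∈ [0, 1]` with Brent's bracketed method (`xtol 1e-16`,
`rtol ~9e-16`, 200 iterations), which keeps accuracy relative and makes the
solver scale-invariant from sub-picomolar to millimolar totals. Complexes
follow as `C_i = r·L_i,t/(Kd_i + r)`; free ligand is computed as
`L_i,t·Kd_i/(Kd_i + r)` to avoid cancellation when a ligand is nearly
depleted. Mass balances close to a relative 1e−9 and the solve costs
microseconds. The N-ligand form is implemented even though the motivating
scenario has two ligands.

### Cellular scenario and the absolute scale

`StoichiometryScenario` encodes the published cellular estimates: reader
and LIG1 equimolar, H3 in 1000-fold molar excess over LIG1, 35 % of H3
di-methylated at K9, 50 % of LIG1 di-methylated at K126, and Kds of 0.19 µM
(H3K9me2) and 0.041 µM (LIG1K126me2). Proteomics gives only ratios, so the
absolute LIG1 total (`absolute_scale`) defaults to 1 µM — a typical nuclear
concentration for an abundant replication factor — and the partition is
always reported alongside a scale sweep: the H3K9me2-bound fraction stays
≥ 98.5 % for any scale in 0.1–1000 µM, so the headline 99 %/<1 % split is
not an artifact of the choice.

`excess_limit_ratio` gives the analytic no-depletion limit
`(L_i/Kd_i)/Σ_j(L_j/Kd_j)`; the full solve converges to it whenever both
ligands remain in large excess over the bound receptor, which is a useful
cross-check and intuition aid (with defaults: 1842 : 12.2, i.e. 99.3 %
vs 0.66 %).

`sweep_scenarios` grids any subset of scenario parameters (Cartesian
product or one axis at a time; Kds and the scale on log grids) and reports
the min/max envelope of each occupancy fraction — the prediction band. The
"350–1000-fold molar excess of H3K9 methylation over LIG1K126 methylation"
range is reproduced by sweeping `lig1_me2_fraction` over [0.35, 1.0] with
the H3 parameters fixed (1000 × 0.35 / x); which axes generate the band is
a configuration choice, not a model assertion, because the underlying
abundance estimates themselves span ranges.

## FP Kd estimation

`FluorescencePolarizationModel` fits `r0 + (rmax − r0)·φ(P)` to anisotropy
change versus protein concentration P, where φ is the bound fraction of the
labeled probe. The default φ is the exact single-site (ligand-depletion)
quadratic at the stated probe concentration; the hyperbola `P/(Kd+P)` is an
option. Rationale: tracer concentrations in FP are routinely comparable to
low-nM Kds, where the hyperbola biases Kd upward; the quadratic costs
nothing and is exact. The fit is nonlinear least squares over
(log10 Kd, r0, rmax) — the log parameterisation keeps Kd positive and makes
the optimisation well-scaled — with deterministic start values (r0 = min
response, rmax = max response, Kd = concentration nearest half-amplitude).

Confidence intervals: parametric bootstrap by default (Gaussian noise at
the residual scale added to the fitted curve, refit, percentile interval;
1000 resamples unless configured) or an asymptotic curvature interval on
log10 Kd. In the package's own coverage simulations (12 log-spaced points
spanning Kd/100–100·Kd, three replicates, 2 % amplitude noise, 200
repetitions with 200 bootstrap resamples each — sizes chosen to keep the
default suite at desk scale) both methods achieve ≥ 90 % empirical
coverage at the 95 % level.

Apparent Kds above ~5 µM are flagged non-saturating: such titrations do not
reach plateau in practice, and the results object reports the fit but marks
the point estimate unreliable rather than suppressing it silently.

## CAPA CP50 estimation

`PenetrationModel` operates on penetration fractions in [0, 1];
`normalize_capa` converts raw fluorescence using no-peptide (zero
penetration, maximal fluorescence) and full-block anchors, since the assay
readout is inversely related to penetration. A four-parameter logistic
(floor, ceiling, Hill slope, CP50) is fitted per replicate curve; CP50 is
the inflection concentration, i.e. half-maximal penetration for the
symmetric logistic. With ≥ 2 replicates the estimate is the mean of the
per-curve CP50s and the uncertainty is the standard error across those
independent fits (with a t-interval), matching how replicated penetration
experiments are conventionally summarised; a gross negative
concentration–response correlation in any replicate raises a warning flag
rather than an error.

## Array quantification

Spot intensities are aggregated per entity (mean over valid replicate
spots); the spread convention switches on replicate count — half-range for
≤ 2 spots, SEM for ≥ 3 — matching the two array formats (duplicate reader
arrays, sextuplicate peptide arrays) without a knob. Signals are normalized
to the brightest entity within each probe dataset (all-zero input returns
zeros with a degenerate flag). Normalized signals above 0.7 (configurable)
are flagged saturated: at saturating probe concentration their differences
reflect print variability, so ranking reports them as one tied class at
rank 1 and orders only the remainder. No background subtraction or
GST-loading correction is modeled; inputs are assumed quantified and
background-corrected upstream.

## Differential methylation

Beta values are methylation fractions in [0, 1]. The analysis selects
probes with control β strictly > 0.8 (confidently methylated probes, where
maintenance-methylation loss is visible), computes Δβ = treated − control
(so hypomethylation is negative — the sign convention is fixed and tested),
and summarises the distribution with mean, median and a 1000-bin histogram
over [−1, 1]; paired density scatters use 500 square bins over the unit
square (square bins are count-equivalent to hexagonal for this purpose).
Missing values are dropped pairwise with counts recorded.

The global-shift call is deliberately this package's own decision rule, not
an inherited test: verdict "shift" iff |mean Δβ| ≥ an effect floor (default
0.05, i.e. a 5-point average methylation change on the filtered set), with
a bootstrap CI of the mean reported regardless and an "indeterminate"
verdict below a minimum probe count. No per-probe testing or
multiple-testing correction is attempted because the scientific claim is
distributional, not probe-level.

## Synthetic data

Generators take explicit seeds (numpy `default_rng`) and are byte-identical
under a fixed seed.

- **FP titrations**: 12 log-spaced concentrations spanning Kd/100–100·Kd,
  depletion-form responses, additive Gaussian noise scaled to the curve
  amplitude (default 2 %), three replicates, default tracer 0.01 µM (a
  typical FAM-probe concentration; the experimental value is not pinned, so
  recovery simulations use this configurable default).
- **CAPA curves**: 9 log-spaced concentrations over CP50/30–30·CP50, 0→1
  logistic plus noise, clipped to [0, 1].
- **Arrays**: clean signal proportional to single-site occupancy at the
  1 µM hybridization concentration; occupancies below that of a 30 µM
  binder collapse to a noise-level floor (2 % of the ceiling occupancy
  signal), emulating the detection limit of peptide arrays; replicates get
  multiplicative lognormal spot noise.
- **Beta matrices**: control betas from a two-mode Gaussian mixture (modes
  0.05 and 0.9, SDs 0.03/0.05, weight 0.6 on the methylated mode — placing
  a realistic ~55–60 % of probes above the 0.8 filter), clipped to [0, 1].
  The treated column subtracts the effect magnitude on a random probe
  fraction (the knockdown surrogate), then adds truncated-Gaussian
  technical noise (default SD 0.03) and clips. `effect=None` is the null
  surrogate. Because subtraction clips at 0 on unmethylated probes, the
  programmed effect size is faithful (mean Δβ ≈ −fraction×magnitude) on the
  filtered >0.8 set, which is where the analysis operates; the unfiltered
  mean understates it by construction.

What the generators do *not* emulate: probe-type chemistry and batch
effects on methylation arrays, copy-number confounding, array print
geometry, G-factor corrections in FP, or cytotoxicity at high peptide dose
in CAPA. Passing calibration tests therefore shows the estimators and
decision rules are correct for data with the assumed statistical structure,
not that real-instrument systematics are handled.

## Numerical and interface choices

- Equilibrium solver tolerance 1e−12 on the residual (absolute, in units of
  the scaled equation), 200 iterations; mass balances verified to 1e−9
  relative in tests.
- Curve fits: `scipy.optimize.curve_fit` (Levenberg–Marquardt/TRF) with
  bounded log-parameterised midpoints; non-convergence returns a results
  object with `converged=False` rather than raising, except for flat
  responses which raise immediately.
- Simulation sizes in the test suite (200 coverage repetitions × 200
  bootstrap resamples; 100 null + 100 positive methylation runs at 20,000
  probes) are the package's chosen desk-scale study conditions; they are
  stated here so larger reruns can scale them deliberately.
- CSV everywhere; every output file carries a `# methylbind v…`,
  `# seed=…`, `# params=…` comment header. CLI exit codes: 0 success,
  2 configuration error, 3 data/schema error, 4 convergence failure.

## Known limitations

- The equilibrium model ignores kinetics, multivalent chromatin engagement
  (TTD–PHD cooperativity, DNA contacts) and nucleosome context; it answers
  only "where does the reader sit at equilibrium given totals and Kds".
- The shift call is a mean-effect rule; a perfectly balanced bimodal change
  (equal hyper- and hypomethylation) would be reported as "no-shift" even
  though the distribution changed shape. The histogram output exists
  precisely so such cases are visible.
- Real methylation arrays require upstream IDAT processing and
  normalization that are out of scope; `BetaMatrix.from_csv` expects
  already-computed beta values.
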