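# methylbind

Quantitative machinery for competitive methyllysine-reader biology: why can a
reader domain bind a non-histone substrate with nanomolar affinity in vitro
and still never touch it in cells?

The motivating system is the UHRF1 tandem Tudor domain (TTD), which reads
di-methylated lysines on both histone H3 (H3K9me2) and DNA ligase 1
(LIG1K126me2). The TTD binds LIG1K126me2 ~8-fold tighter than H3K9me2, yet
cellular perturbations of the LIG1 interaction leave DNA methylation
untouched. `methylbind` implements the quantitative analyses behind that
conclusion so each step can be exercised, stress-tested and reused on
synthetic or real tabular data:

- **`methylbind.equilibrium`** — a competitive mass-balance binding model.
  One receptor R partitions among N ligands, each bound 1:1 and exclusively:

  ```
  R_t = R_f + Σᵢ [R·Lᵢ]        L_i,t = L_i,f + [R·Lᵢ]        Kd_i = R_f·L_i,f / [R·Lᵢ]
  ```

  The system reduces to one monotone scalar equation in R_f, solved by
  bracketed root-finding. Helpers build the cellular scenario (reader:LIG1
  1:1, H3 1000× LIG1, 35 %/50 % di-methylation, Kds 0.19/0.041 µM), sweep
  parameter ranges into prediction bands, and evaluate the no-depletion
  limit `(Lᵢ/Kdᵢ)/Σⱼ(Lⱼ/Kdⱼ)`.
- **`methylbind.assays`** — statsmodels-style estimators for titration data:
  `FluorescencePolarizationModel` fits a single-site Kd to anisotropy curves
  (ligand-depletion quadratic by default, parametric-bootstrap or curvature
  CIs) and `PenetrationModel` fits a four-parameter logistic CP50 to
  chloroalkane-penetration dose–response curves, reporting the standard
  error across independent replicate fits.
- **`methylbind.arrays`** — reader/peptide microarray quantification:
  replicate aggregation (half-range for duplicates, SEM for ≥3 spots),
  normalize-to-brightest scaling, saturation flagging (> 0.7 of the peak is
  one tied class) and affinity ranking.
- **`methylbind.methylation`** — beta-value differential methylation:
  filter probes with control β > 0.8, Δβ = treated − control, fine-histogram
  and moment summaries, and a transparent global-shift decision rule with a
  bootstrap CI on the mean Δβ.
- **`methylbind.synth`** — seeded generators for every input: FP titrations,
  CAPA curves, array intensities driven by a ground-truth Kd matrix with a
  ~30 µM detection floor, and bimodal beta matrices with a configurable
  global hypomethylation effect or a pure-noise null.

## Worked example

The headline partition prediction, from the command line:

```sh
$ methylbind equilibrium predict
H3K9me2        occupancy:  99.30 %
LIG1K126me2    occupancy:   0.65 %
free reader    fraction :   0.05 %
```

Despite LIG1K126me2 being the tighter ligand, ~99 % of the reader is
histone-bound at cellular stoichiometry: H3K9me2 outnumbers LIG1K126me2
roughly 700-fold, which overwhelms the ~5-fold Kd advantage. The fractions
are stable for any absolute concentration scale from 0.1 to 1000 µM.

Fitting a Kd to a synthetic FP titration generated at the measured
LIG1K126me2 affinity (0.041 µM, 2 % noise, three replicates):

```python
>>> from methylbind.synth import gen_fp_titration
>>> from methylbind.assays import fit_kd
>>> t = gen_fp_titration(0.041, noise_sd=0.02, seed=7)
>>> print(fit_kd(t, n_boot=200, seed=1).summary())
FP single-site Kd (depletion) fit (36 points)
--------------------------------------------
estimate      : 0.0431 uM
95% CI        : [0.04007, 0.04617] uM
std. error    : 0.0017 uM
r0            : 0.049
rmax          : 0.2492
residual norm : 0.0192
converged     : True
```

The generating Kd (0.041 µM) lies inside the 95 % CI; `r0`/`rmax` are the
recovered baseline and plateau anisotropies.

A knockdown-style methylation comparison on a synthetic matrix where 60 %
of probes lose 0.2 beta units:

```python
>>> from methylbind.synth import gen_beta_matrix, GlobalHypo
>>> from methylbind.methylation import DifferentialMethylation
>>> bm = gen_beta_matrix(50_000, effect=GlobalHypo(0.6, 0.2), seed=7)
>>> print(DifferentialMethylation(bm, "control", "treated").fit(seed=1).summary())
Differential methylation (beta values)
--------------------------------------------
comparison    : treated - control
filter        : control beta > 0.8
probes (n)    : 29141
mean delta    : -0.1200
median delta  : -0.1708
bootstrap CI  : [-0.1212, -0.1188]
effect floor  : 0.05
verdict       : shift
```

The mean Δβ of −0.12 matches the programmed effect (0.6 × 0.2); with
`effect=None` the same pipeline returns `no-shift`.

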