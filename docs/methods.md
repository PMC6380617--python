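# Methods

## The problem

Genomic selection trains a prediction model on a *training set* of
individuals that are both genotyped and phenotyped and predicts the genetic
values of *test* individuals from their genotypes alone.  How accurate that
prediction will be — the Pearson correlation between test phenotypes and
their predicted genetic values — is not known a priori, yet it drives two
practical decisions: whether genomic selection is worth deploying for a
trait, and *which* subset of the available phenotyped material should serve
as the training set for a given group of selection candidates.  Everything
in this package is organized around estimating that accuracy *for a given
training set* and searching for the training set that maximizes it.

## Prediction model

The predictor is GBLUP, computed in its ridge-regression (RR-BLUP) form.
With `Xc_train` the column-centered training dosage matrix (T × M),

    y_train = 1 μ + Xc_train β + ε,
    β ~ N(0, σβ² I),  ε ~ N(0, σε² I),

the predicted genetic values of test individuals with (training-mean
centered) genotypes `Xc_test` are

    û_test = Xc_test Xc_train' H⁻¹ (y_train − ȳ_train),
    H = Xc_train Xc_train' + λ I,  λ = σε² / σβ².

All linear algebra goes through the T × T ridge matrix H rather than
Henderson's mixed-model equations: H is positive definite for every λ > 0,
whereas the marker-based VanRaden kinship matrix is typically singular, and
in plant-breeding panels (one record per individual) the H route is also
the cheaper one.  Column centering makes the marker design orthogonal to
the intercept, so centering `y_train` by its mean handles μ exactly.

Test genotypes are centered with the **training** column means.  The
alternative (test or combined means) would let the composition of the test
set leak into the training-side quantities; training means keep prediction
strictly a function of the training data.

### REML

σβ² and σε² are estimated by restricted maximum likelihood.  Because the
centered design satisfies `1'Xc = 0`, the covariance eigenproblem can be
solved once on the contrast space orthogonal to the intercept (Helmert
rotation, then one symmetric eigendecomposition of the rotated `Xc Xc'`).
The restricted likelihood is then profiled analytically in σβ² and
maximized over `log λ` on [−10, 10] by bounded Brent search with tolerance
1e-8.  Solutions at the interval bounds are flagged (`boundary=True`); the
upper bound is the no-detectable-signal case (e.g. a pure-noise phenotype).
A dense-grid oracle in the test suite confirms the optimum to 1e-6.

## Accuracy estimators

Four estimators answer "how well will this training set predict these
tests", all sharing the REML variance components of the current training
set unless stated otherwise:

* **TS accuracy** — the empirical correlation `corr(y_test, û_test)`.
  Requires test phenotypes; it is the ground truth the other estimators
  are compared against and the oracle criterion for optimal-start
  experiments.
* **CD** — per test individual, the coefficient of determination of its
  genetic value under the marker model,
  `CD_i = (x_i' Xc' H⁻¹ Xc x_i) / (x_i' x_i)`, averaged as
  `mean_i sqrt(h_i² · CD_i)` with `h_i² = Var(u_i)/(Var(u_i)+σε²)` and
  `Var(u_i) = σβ² x_i'x_i`.  The square root converts a genetic-value
  accuracy to a phenotype-level accuracy; a `sqrt_link=False` switch gives
  the literal squared form.
* **PEV** — the same quantity reached through the prediction error
  variance, `PEV_i = Var(u_i)(1 − CD_i)`.  CD and PEV are algebraically
  identical for a BLUP (`CD = 1 − PEV/Var`), and the implementation keeps
  them equal to 1e-10; both are reported because both circulate as
  optimization criteria in the literature.
* **EthAcc** — the theoretical accuracy of the RR-BLUP predictor under a
  *fixed causal-QTL model* `y = 1μ + Qθ + e`, evaluated with an estimated
  causal model.  With `w = Xc_train' H⁻¹ Q_train θ` and sample moments
  over the test set,

      value = Cov(g, x'w) / sqrt(noise + dispersion) / sqrt(σ̂g² + σ̂e²),
      noise = σ̂e² · mean_i ‖H⁻¹ Xc_train x_i‖²,
      dispersion = w' Var(x_test) w,   g_i = q_i' θ,

  where σ̂e² comes from the OLS fit of the causal model on the training
  set.  Every test-population moment is a *centered* sample moment
  (covariances, not raw cross-moments): the target quantity is a
  correlation, and centering is what makes the Cauchy–Schwarz bound
  |EthAcc| ≤ 1 hold structurally — with raw cross-moments the plug-in
  estimate can exceed 1 as soon as the test set's mean genotype drifts
  away from the training mean, exactly the structured-panel situation the
  estimator exists for.  Sample moments use divisor n_test (`ddof=0`),
  matching the plain plug-in convention; `ddof=1` is available.  An empty
  causal model yields 0 with a warning so optimization can proceed.
* **CDmean** — the training-set design criterion: the mean CD of the
  contrast `c_i = e_i − 1/N` between each test individual's genetic value
  and the mean of the combined (training + test) population.  The combined
  design is centered on the combined set because that is the population
  the contrast refers to.  Its variance components are estimated **once**
  on the entire candidate panel, not per training set — the criterion is
  meant to be computable before any phenotyping decision and to stay fixed
  during optimization.

The separation EthAcc makes between the instrumental prediction model
(every marker a QTL with iid Gaussian effects) and the causal model (a few
QTLs with fixed effects) is the substance: CD/PEV identify the two, which
systematically overstates achievable accuracy when the true architecture
is sparse and the panel is structured.

## Causal-QTL model estimation

The causal model is estimated in two steps: a multi-locus method locates
QTLs, then ordinary least squares re-estimates all selected effects
jointly along with σ̂e² (penalized effect estimates are biased by
shrinkage, so they are used for *location only*).

The selected locator is **MLMM forward selection**: a marker-by-marker
mixed-model scan with a VanRaden-kinship polygenic term and no structure
covariates; the minimum-p marker (ties → lowest column index) enters the
model as a fixed cofactor and the remaining markers are rescanned, until
the null model's pseudo-heritability `σu²/(σu²+σres²)` drops below
`h2_stop` or `max_qtls` is reached.  Defaults: `h2_stop = 0.01` (a
quantification of "polygenic variance close to zero") and
`max_qtls = floor(T/10)` (an OLS-feasibility guard that rarely binds).
Within a scan the variance components are held at the null fit (P3D) and
each marker is tested by a 1-df F test on the GLS-rotated model; the
components are re-estimated whenever a cofactor is added.  The kinship
eigendecomposition is computed once per training set and reused across
steps.

Under a null phenotype the REML polygenic-variance estimate has a point
mass at zero plus a positive sampling tail, so the variance-based stopping
rule occasionally admits a few spurious cofactors (the typical null
selection is empty; roughly three quarters of null runs select ≤ 2
markers at T=300).  This is inherent to the stated stopping rule, not a
tuning artifact.

LASSO and elastic-net locators are provided as alternates: a
coordinate-descent path with λ chosen over 10-fold CV curves by either the
minimum mean MSE (`cv_min`) or the one-standard-error rule (`cv_1se`,
sparser).  Fold assignment is seeded.

## Training-set optimization

`hill_climb` maximizes a criterion over fixed-size training sets by
exchange moves: each move swaps one uniformly drawn member for one
uniformly drawn non-member of the candidate pool and keeps the swap only
on strict improvement.  There is no stopping rule — exactly `n_moves`
moves are attempted (default 5000; a 20000-move diagnostic mode exists for
trajectory plots), every evaluation is recorded in the trace, and the run
is bit-for-bit reproducible from its seed.  A rejected (constraint) or
tied evaluation reverts the move; rejections consume a move like any other
evaluation.

The **EthAcc criterion** re-runs the whole pipeline for every candidate
training set: REML on the set, MLMM causal-model rediscovery on the set,
then EthAcc.  It requires the phenotype standardized to unit variance and
rejects any set whose estimated causal model gives the predicted test
genetic values a sample variance ≥ 1 (implemented as `≥ 1 − 1e-12`): an
estimated genetic variance exceeding the phenotypic variance is the
signature of the "false positive" training sets that random-start
optimization otherwise converges to.  Because each move re-runs MLMM, the
criterion accepts reduced `max_qtls`/`h2_stop` settings to bound per-move
cost.  The **CDmean criterion** uses the candidate-panel variance
components fixed for the whole run and needs no constraint.  The
**TS-oracle criterion** (realized accuracy; needs test phenotypes) exists
to construct the optimal starting sets of the evaluation protocol.

## Synthetic data

`simulate_genotypes` draws structured inbred (0/2) or outbred (0/1/2)
panels: ancestral allele frequencies Uniform(0.1, 0.9), cluster
frequencies Balding–Nichols Beta with divergence parameter Fst, local LD
by Markov copying (each marker inside an `ld_block` copies its left
neighbour with probability 0.7 per individual).  With `ld_phase_flip`
(default for multi-cluster panels) later clusters copy the *complement*
allele, reversing the local LD phase between clusters — the breakdown of
LD-phase persistence between diverged populations.  Without it, both
clusters share marker–QTL phase and training on a diverged cluster is
merely uninformative rather than misleading, and the
"smaller-but-closer training set wins" phenomenon does not appear.
`simulate_phenotype` plants `n_qtl` additive QTLs with standard-normal
effects and sets the noise variance to hit a target heritability exactly
in expectation; `hide_qtls` removes the causal columns from the marker
panel, so prediction must work through LD, as on a real genotyping array.

`structured_panel_scenario` freezes the study conditions used by the
comparative tests: 200 inbred lines in clusters of 70/130, 240 markers in
5-marker LD blocks with cluster-flipped phase, Fst = 0.3, 8 hidden QTLs,
h² = 0.5, and a between-cluster trait mean shift of 2 genetic standard
deviations (diverged breeding pools differ in trait means; the shift is
what makes mixed-model estimators absorb structure into apparent genetic
variance).  The generator does not model recombination maps, pedigrees,
multi-allelic markers or genotyping error, so passing tests demonstrate
the estimators' behavior under idealized cluster structure, not
performance on any particular crop.

## Numerical choices and sizes

- REML search interval `log λ ∈ [−10, 10]`, Brent tolerance 1e-8,
  boundary flagged; kinship-model REML (inside MLMM) uses the same
  interval for `log δ`.
- CD values are clipped to [0, 1] at round-off; a test individual whose
  genotype equals the training mean contributes 0 with a warning.
- Markers constant within the training rows can be dropped from the
  design on request (`drop_constant`); kinship on an all-monomorphic
  subset raises.
- Ties in the MLMM min-p selection break to the lowest marker index so
  runs are deterministic.
- Comparative studies run at desk scale: the estimator-comparison study
  uses 30 replicates of the canonical scenario; the optimal-start
  optimization study uses 20 replicates of a 60-line version (training
  size 15, 150 oracle moves, 100 criterion moves); the constraint study
  uses 6 adversarial runs per arm at h² = 0.2.  The Monte-Carlo
  calibration of the theoretical accuracy uses T=250 training lines,
  50 tests, 500 markers and 500 replicate noise draws; REML recovery uses
  T=500 over 50 seeds per heritability.

## Design notes

- The fit/predict-shaped components are exposed as sklearn-style
  estimators (`GBLUP` regressor, `MLMMSelector` feature selector) that
  compose with sklearn pipelines; the accuracy estimators and the
  optimizer are plain functions over immutable inputs, which matches how
  they are consumed (one value per training set, no state).
- Fixed-effect uncertainty beyond the intercept is ignored in CD/PEV
  (centering absorbs μ); projection-matrix variants with additional fixed
  effects are out of scope.
- Whether σε² in the CD heritability factor should be re-estimated per
  training set during optimization is an open modeling question; it is
  re-estimated per set here, consistent with "variance components from
  the current training set" everywhere except CDmean.

## Known limitations

- EthAcc's precision is bounded by the causal-model estimation step: with
  a random start the optimizer can still reach overestimated training
  sets (the constraint reduces, but does not eliminate, them), and
  individual estimates can be far from the realized accuracy even when
  the average error is small.
- The null behavior of the MLMM stopping rule admits occasional spurious
  cofactors (see above).
- The Balding–Nichols/Markov-copy generator induces exchangeable
  individuals within clusters; family structure within a breeding pool is
  not represented.
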