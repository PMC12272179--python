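# Methods

## The auto-regression task

All models solve the same task: given a window of `k` past time points of a
multivariate parcel signal `X` (time × P parcels), predict the signal at lag
`l` past the window's end,

    X[t+l] = f(X[t-k+1], …, X[t]) + ε[t+l],

trained by mean-squared error at `l = 1` only. Predictions at `l > 1` use
*iterated single-step prediction*: the window slides forward and the model's
own previous predictions stand in for the unavailable true values. An
optional *direct* mode trains one independent model per lag instead
(`fit_direct_multilag`); downstream evaluation is identical.

Accuracy is the coefficient of determination R², computed per parcel within
a run against the mean of that run's evaluated targets, then averaged over
the evaluation parcel mask (`r2_mean`), then over runs — never pooled across
runs. Negative values (worse than predicting the run mean) are kept in
averages; a mask-out flag exists for display purposes.

## Model zoo

* **linear_uni** — an independent linear filter per parcel over its own past
  (`P·(k+1)` parameters with bias). At the benchmark's reference scale of
  197 parcels and window 256 this is 50,629 parameters.
* **linear_multi** — the classical VAR form: one linear map from the full
  flattened window to all parcels (`P·(kP+1)`; 116,624 at 197 parcels,
  window 3).
* **mlp_uni / mlp_multi** — the same two wirings with hidden ReLU layers.
  The univariate MLP keeps per-parcel weights (a batched stack of P small
  networks), matching the univariate reading of the linear model.
* **chebnet** — Chebyshev spectral graph convolution. The k window steps
  enter as k channels per parcel node; each layer maps C_in → C_out channels
  through K polynomial filters of the scaled graph Laplacian
  (T₀x = x, T₁x = L̃x, T_j = 2 L̃ T_{j-1} − T_{j-2}, evaluated by the
  three-term recurrence, never by eigendecomposition), plus a shared bias per
  output channel. `nonlinear=False` removes the inter-layer ReLUs ("linear
  Chebnet"), collapsing the network to a single dense linear operator — an
  identity that the test suite asserts against an explicitly assembled
  operator.

Graphs are binary, symmetric, at a fixed edge density (default 10% of
off-diagonal pairs): **functional** (top-density pairs by signed Pearson
correlation of the training runs; an absolute-value mode is available behind
a flag), **spatial** (closest pairs by Euclidean centroid distance) and
**random** (uniform without replacement, seeded). The spectral operator is
the symmetric normalized Laplacian L = I − D^{-1/2} A D^{-1/2} rescaled by
its largest eigenvalue into the Chebyshev domain, L̃ = (2/λ_max) L − I.
Isolated nodes get D^{-1/2} = 0 (their L row is an identity row); an
edgeless graph uses the conventional fallback λ_max = 2, making L̃ = 0. Ties
in top-density selection are broken lexicographically by (row, col) for
bit-reproducibility; λ_max is computed by a dense symmetric eigensolve,
which is exact and cheap at the parcel counts this package targets (≤ 1000).

## Training

Adam without weight decay (β₁ = 0.9, β₂ = 0.999, ε = 1e-8), gradients by
analytic backpropagation in numpy, parameters initialized with uniform
fan-in scaling from the model seed, biases at zero. Mini-batch order is
reshuffled each epoch from the fit seed; training is single-threaded and
bitwise reproducible. Per-epoch train and validation losses are recorded and
the parameters of the best validation epoch are returned (checkpointing
rather than early stopping — the conservative choice when the stopping rule
is unspecified). A non-finite loss raises a divergence error naming the
epoch and learning rate. Grid search trains every configuration per subject
and scores it by the mean validation R² over subjects, parcels and the
requested lags; ties keep grid order.

## The synthetic cohort generator

The generator exists so every stage of the benchmark is exercisable with a
known ground truth. Each subject's signal follows a stable VAR(p) on a
sparse symmetric support graph, plus a *shared response* — a low-pass
(default cutoff 0.05 Hz) Gaussian signal identical across subjects within a
(condition, run) — plus i.i.d. Gaussian innovations. Conditions whose label
starts with `rest` carry no shared component. The recursion starts at zero
and discards a burn-in (default 200 points, > 5 autocorrelation time
constants at spectral radius ≤ 0.95).

**Coupling draw.** The lag-1 coupling mixes a *homogeneous diffusion* term
along the normalized adjacency (weight `coupling_homogeneity`, default 0.7)
with heterogeneous per-edge Gaussian weights; higher-lag matrices are purely
heterogeneous; self-couplings are always present. The homogeneous term is
what makes a connectome prior informative here: a Chebnet layer applies one
scalar polynomial of the graph Laplacian to every node, so it can exploit a
graph exactly insofar as the dynamics contain a component that is
homogeneous along that graph. A fully heterogeneous draw would produce data
on which the true graph confers almost no advantage over a random one — a
property of the model class, not of brains — whereas diffuse coupling along
a connectivity backbone with idiosyncratic edge weights is the standard
picture of large-scale BOLD spatial autocorrelation. The heterogeneous 30%
is what individual models can exploit and group models cannot. The stack is
rescaled so the VAR companion-matrix spectral radius hits the configured
target exactly (scaling lag-j matrices by c^j scales companion eigenvalues
by c), keeping every cohort stable by construction.

**Subject divergence.** Per-subject couplings are
`(1−d)·base + d·fresh` with the fresh draw on the base's own support, then
rescaled; `d = 0` gives identical subjects (the null for specificity
analyses), `d = 1` gives maximally distinct subjects that still share the
support graph and the diffusion backbone.

**Defaults** mirror the acquisition geometry of a dense individual fMRI
study: TR 1.49 s, runs of 480 time points (≈ 12 min), 6 subjects, one
movie-like condition of 68 runs (split 44 train / 12 validation / 12 test by
the configured train fraction and the even/odd remainder rule), innovation
SD 1, spectral radius 0.9, coupling density 0.1, shared amplitude 0.5 SD.
The desk-scale default of 30 parcels keeps every experiment minutes-fast;
a 197-parcel configuration is a parameter change only.

**What the generator does not emulate:** hemodynamic response convolution,
physiological noise and motion artifacts, scanner drifts, voxel-level
structure, non-stationarity, and non-linear neural dynamics. Passing tests
therefore demonstrate that the pipeline's machinery behaves as specified on
data with known linear space-time structure; they are not evidence about
real BOLD, where effect sizes and model rankings may differ.

## Preprocessing

Per-run z-scoring uses the population (ddof 0) standard deviation — a fixed
convention for bit-reproducibility. The optional high-pass filter projects
out discrete-cosine regressors with frequency below the cutoff (default
0.01 Hz) plus the constant, per run. Runs are split in acquisition order:
the first `ceil(train_fraction · n)` to training, the remainder alternating
validation/test by 0-based position (the 0-basis reading of an even/odd
split; configurable). Supervised windows are extracted after normalization
and never span run boundaries. The shared response is estimated
leave-one-subject-out as the element-wise mean of the other subjects'
normalized matched runs, and regressed out per run and per parcel with an
intercept (per-run granularity matches the per-run normalization; whether
to regress over concatenated runs instead is a flagged sensitivity).

## Statistics

Paired comparisons use the two-sided Wilcoxon signed-rank test: zero
differences dropped; exact null distribution for n ≤ 25 (computed by
dynamic programming over sign assignments on doubled midranks, so tied
absolute differences stay exact); normal approximation with tie correction
above; all-zero differences return p = 1 with a warning. Multiple
comparisons are corrected by Benjamini-Hochberg FDR (step-up). Experiment
summaries annotate successive groups (ranked by mean R²) per lag with these
tests.

## Experiment suite and reproducibility

`run_experiment_suite` executes the enabled experiments in dependency order
(simulate → preprocess → graphs → train → evaluate → analyze). All
randomness flows from one base seed through named substreams, CSVs are
written with a fixed float format, and a manifest records the seed and a
hash of the full configuration, so a rerun is byte-identical. Random-graph
comparisons average a configurable number of independent draws (default 5).
The CLI verbs `simulate / train / benchmark / analyze / report / all` are
thin wrappers; there is no separate `preprocess` verb because run tables on
disk are raw simulator output and every consumer re-applies the documented
normalization, avoiding duplicated state.

## Benchmark protocol sizes

The reference protocols in `neuroar.benchmarks` (used by the test suite and
`scripts/acceptance.py`) run at sizes chosen so the whole set completes in
minutes on one CPU while each effect stays clearly resolvable:

* VAR recovery: 10 parcels, 10,000 training points, 150 epochs — recovery
  error ~0.03–0.04 against the 0.05 bound; the R² ceiling
  `1 − noise_var/signal_var` is estimated on the evaluated run itself.
* Graph sensitivity: 10 cohort seeds, 30 parcels, 3 training + 2 test runs
  of 360 points, linear Chebnet (K = 3, window 3, 8 hidden channels), true
  support graph vs. 2 random graphs of equal density.
* Subject specificity: 3 subjects, 15 parcels, 3 training + 8 evaluation
  runs of 300 points, VAR(1) models, at coupling divergence 1 and 0.
* Lag-lowpass: 5 cohort seeds, 1 subject, predictions iterated to lag 6;
  high-frequency fraction above 0.025 Hz, median over runs and seeds. Run
  length 480 matters here: the property holds in expectation but short-run
  periodogram noise can break strict monotonicity at the flattening tail.

## Known limitations

* No GPU path and no attention/recurrent architectures; the benchmark
  harness accepts external plug-ins satisfying the forward/fit contract.
* The univariate MLP's per-parcel weight convention is one of two defensible
  readings of "univariate"; the shared-weight alternative would change
  parameter counts.
* Seed-based connectivity is parcel-level; voxel maps and surface rendering
  are out of scope.
* The generator's linearity means non-linear models can at best match linear
  ones on synthetic cohorts; experiments that rank non-linear against linear
  variants are therefore sanity checks of the harness, not of the
  architectures.
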