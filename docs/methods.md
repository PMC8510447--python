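# Methods

## Model and procedure

The imputer treats a metabolite × sample abundance matrix `X` (I × J,
strictly positive where observed, observed set Ω) as approximately low-rank
on the log10 scale: metabolite intensities co-vary because metabolites
participate in shared pathways and respond to shared sample-level factors.
A non-negative factorization `X ≈ B C` with K components captures that
structure; the non-negativity of `B` and `C` keeps components additive and
interpretable and makes the factorization adapt to local (per-component)
structure as well as the global one.

The pipeline is:

1. **Initialization.** NAs are filled with the metabolite's observed mean
   (this fill is used *only* to estimate the numerical rank of the data and
   never enters the factorization loss). The matrix is log10-transformed; a
   recorded offset `max(0, −floor(min observed log10))` lifts the log values
   to be non-negative so the `B, C ≥ 0` constraint is meaningful, and is
   subtracted again on output. Without the offset, datasets with observed
   intensities below 1 would violate the constraint after the log transform.
2. **Factorization.** For each K in a schedule of N = 20 consecutive values
   centred on the estimated rank (`k1 = max(rank − N/2, 1)`, clamped so no K
   exceeds `min(I, J)`; the schedule is shifted down rather than shortened
   when it hits the ceiling, and only truncated when `min(I, J) < N`), a
   masked NMF is fitted by multiplicative updates with a binary mask `W`
   (1 on Ω, 0 elsewhere):

       B ← B ∘ [(W∘X) Cᵀ] / [(W∘(BC)) Cᵀ]
       C ← C ∘ [Bᵀ (W∘X)] / [Bᵀ (W∘(BC))]

   These are the Lee–Seung rules restricted to the observed loss
   `Σ_{Ω}(x_ij − (BC)_ij)²` and keep it non-increasing; the test suite
   asserts monotonicity on every run. Missing cells contribute nothing.
3. **Ensemble.** Each model's error `d_K` is the mean absolute deviation
   `Σ_Ω |x̂_ij − x_ij| / |Ω|`. Reconstructions are averaged with softmax
   weights `w_K ∝ exp(−d_K)` (computed with max-subtraction, so extreme
   errors cannot underflow all weights at once).
4. **Imputation.** Observed entries are copied through unchanged (bit-exact
   on the raw scale); NAs take the ensemble value, inverse-transformed by
   `10^(· − offset)`.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `n_models` (N) | 20 | ensemble size; consecutive K values centred on the data rank |
| `tol` | 1e−6 | relative observed-loss change for convergence |
| `max_iter` | 500 | iteration cap per factorization |
| `seed` | — | master seed; per-model seeds are `seed + K` |
| `threshold` (30%-deletion) | 0.30 | metabolites with missing fraction strictly above are removed before imputation |
| `lod_q` | 0.30 | LOD = this quantile of observed log10 abundances |
| `k` (kNN) | 10 | donor-neighbour count |
| `r_min`, `alpha` (CCN) | 0.6, 0.05 | correlation magnitude and BH-adjusted significance gates |

## Design choices where the design was open

- **Solver and initialization.** No particular NMF solver is canonical for
  the masked loss; masked multiplicative updates are the standard adaptation
  and give the monotonicity guarantee the tests rely on. Factors are
  initialized i.i.d. uniform on (0, 1] scaled by `sqrt(mean observed / K)`,
  seeded, so runs are exactly reproducible. A 1e−12 guard in update
  denominators prevents division by zero; it can stall a factor entry at
  zero but cannot raise the loss above the 1e−9 slack asserted in tests.
- **d_K as mean absolute deviation.** A signed mean residual would cancel
  positive against negative errors and rank badly overfitted models as
  perfect; the absolute deviation matches the "reconstruction error" intent.
- **Exactly N models.** The schedule holds N models, `{k1, …, k1+N−1}`,
  rather than N+1; N is defined as the number of models in the ensemble.
- **LOD surrogate.** Instruments' signal-to-noise censoring thresholds are
  rarely published, so the LOD is a configurable quantile of the observed
  log10 intensities. The default `q = 0.30` reflects that untargeted LC–MS
  routinely censors the bottom third of its intensity range, and it leaves
  the MNAR/MM simulators feasible across their whole working range: at a
  total missingness of x = 30% with no original NAs, 80% × 30% = 24% of the
  grid must sit below the LOD, so any `q < 0.24` would make the simulator's
  own stated operating range unreachable.
- **Grid-relative percentages.** Target (x%) and original (r%) missingness
  are fractions of the full I × J grid; `|Θs| = round((x − r)/100 · I·J)`.
- **Largest-remainder allocation.** Below-LOD artificial NAs are apportioned
  across abundance intervals proportionally to the original data's
  per-interval missing percentage with largest-remainder rounding (counts
  sum exactly to the target; interval-capacity overflow spills to other
  below-LOD intervals). When the original data carry no missingness below
  the LOD, allocation is uniform over eligible cells.
- **Outlier model.** "Mean ± 5 SD" contamination is read as
  `Normal(μ_i, (5σ_i)²)` per metabolite on the raw scale; non-positive
  draws are redrawn so matrices stay valid for the log transform. The
  measurement routine used to verify the 5σ spread disables that rejection,
  since truncation would bias the sample SD.
- **NRMSE scale.** The relative-error form `((x − x̃)/x)²` is computed on the
  raw scale by default (natural for abundances, and scale-free); a log10
  option exists for users who impute and evaluate entirely in log space.
- **CCN thresholds.** Pearson correlation on log10 data; edges need
  |r| ≥ 0.6 *and* BH-adjusted p < 0.05. Published analyses of this kind
  rarely state their gates, so both are configurable and are recorded in
  every benchmark summary. "Original" networks are built after dropping any
  metabolite containing an NA.
- **MSR ties** receive the average of the tied ranks, so the rank-sum
  identity `Σ_p MSR_p = P(P+1)/2` holds exactly in the tie-free case.
- **kNN details.** Sample-wise, with pairwise-complete Euclidean distance
  (root *mean* squared difference over the metabolites observed in both
  samples, so unequal overlap does not bias the ordering); distance ties
  break by sample index; an NA with no eligible donor falls back to the
  metabolite mean.
- **Random forest** is an adapter over scikit-learn's iterative imputer with
  a random-forest regressor (the missForest scheme), never a
  reimplementation; samples are the observations and metabolites the
  variables.

## Synthetic data generator

`generate_fixture(i, j, rank, noise_sd, seed)` builds
`X = 10^(A S + ε)`: component scores `S` are |N(0,1)| with the first row
fixed at 1, loadings `A` are 0.3·|N(0,1)| with the first column holding each
metabolite's mean log10 abundance drawn from N(3.5, 0.75), and
`ε ~ N(0, noise_sd²)` is log-scale measurement noise. This emulates the
gross features the imputer exploits: strictly positive intensities,
log-normal per-metabolite abundance spread over ~2 decades across
metabolites, and low-rank co-variation. It does **not** emulate heavy-tailed
biological heterogeneity, batch effects, correlated (structured) noise,
truly absent compounds, or instrument-specific censoring — so green tests
on fixtures demonstrate algorithmic correctness and sensible ordering of
methods, not field performance on any particular cohort.

Benchmark-scale choices in the test suite (fixtures of ~100 × 30, ensembles
of 20 models, 10-seed replication for recovery checks, 3-seed for the slow
random-forest comparison) were picked as the smallest sizes at which the
studied effects are stable; the library itself has no size limits.

## Numerical notes and degenerate inputs

- Zeros in input files are coerced to missing at load (log10 undefined at
  0; a reported 0 in practice means "not detected"); configurable through
  `na_tokens`.
- The 30%-deletion comparison uses a 1e−12 slack so a metabolite at exactly
  the threshold (e.g. 3 of 10 samples) is retained despite floating-point
  representation of 0.3.
- A constant matrix yields a degenerate single-interval profile with a
  warning; constant metabolites are skipped (with a warning) in correlation
  networks; metabolites with fewer than two observed values cannot receive
  outliers (σ undefined) and are skipped with a warning.
- Rank estimation uses numpy's default singular-value tolerance
  `max(I, J)·eps·s_max`; with measurement noise the numerical rank rises
  toward `min(I, J)` and the K-schedule clamps accordingly — harmless, since
  the ensemble still spans 20 consecutive K values below the ceiling.

## Known limitations

- MNAR/MM simulation requires enough observed cells below the LOD; requests
  beyond capacity raise an error reporting the attainable maximum rather
  than silently placing NAs above the LOD.
- The ensemble weights reward observed-cell fit, so strongly over-
  parameterized models (K near `min(I, J)`) are not down-weighted by
  held-out error; in practice the limited iteration count and the averaging
  across 20 K values keep imputations stable, but K ≫ rank regimes are not
  where the method is designed to live.
- Correlation-network scores depend on the chosen gates (r_min, α);
  absolute sparsities are not comparable across gate settings, only between
  methods under the same setting.
- No mechanistic simulation of ion suppression or chromatographic artefacts;
  missingness is statistical only.
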