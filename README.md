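# nmfimpute

Missing-value (NA) imputation for mass-spectrometry metabolomics abundance
matrices, built around an ensemble of masked non-negative matrix
factorizations, together with the simulation and evaluation machinery needed
to benchmark imputers under realistic missingness.

MS metabolite tables routinely contain 10–20% NAs — from limit-of-detection
(LOD) censoring, ion suppression, spectral overlap, or preprocessing — and
most downstream statistics require a complete matrix. This package is for
metabolomics data analysts who need (a) a structure-aware imputer and (b) a
principled way to compare imputers on *their* data via simulated, recoverable
missingness.

## The method

Let `X = (x_ij)` be an I × J metabolite × sample matrix with observed index
set Ω. On log10 intensities, the imputer fits non-negative factorizations
`X ≈ B C` (`B ≥ 0` is I × K, `C ≥ 0` is K × J) by minimizing the
Ω-restricted loss

    L(B, C) = Σ_{(i,j)∈Ω} (x_ij − Σ_k b_ik c_kj)² ,  B, C ≥ 0,

via multiplicative updates with a binary observation mask. Because the right
component count K is unknown, N = 20 models are fitted at consecutive K
centred on the numerical rank of the mean-filled data, and combined by
softmax weighting on each model's mean absolute observed error d_K:

    X̂ = Σ_K w_K X̂^K ,   w_K = exp(−d_K) / Σ_K exp(−d_K).

Observed entries pass through bit-exactly; NAs are read off X̂ and
back-transformed to the raw scale.

Around the imputer:

- **Simulators** — MCAR (uniform NAs), MNAR (NAs only below an LOD,
  distributed across abundance intervals like the original data's
  missingness), MM (20% MCAR above / 80% MNAR below the LOD), and outlier
  injection from `Normal(μ_i, (5σ_i)²)` per metabolite.
- **Baselines** — metabolite mean, half-minimum, sample-wise kNN (k = 10),
  and iterative random-forest imputation (scikit-learn adapter).
- **Metrics** — NRMSE (relative error on the simulated missing set Θs),
  correlation-network precision/recall/F1 (Pearson on log10 data, |r| ≥ 0.6,
  Benjamini–Hochberg q < 0.05), and MSR, the mean per-NA rank of each
  method's absolute error (1 = best).

## Worked example

```python
import nmfimpute as ni
from nmfimpute.baselines import impute_half_min, impute_knn

truth = ni.generate_fixture(100, 30, rank=5, noise_sd=0.01, seed=1)  # complete
lod   = ni.determine_lod(truth)                        # log10 LOD = 3.488
sim   = ni.simulate_mm(truth, x_pct=20, r_pct=0, lod=lod, seed=2)
res   = ni.nmf_impute(sim.masked, seed=3)              # ensemble K = 11..30

print(ni.nrmse(truth, res, sim.theta_s))                       # 0.1183
print(ni.nrmse(truth, impute_knn(sim.masked, 10), sim.theta_s))  # 0.7404
print(ni.nrmse(truth, impute_half_min(sim.masked), sim.theta_s)) # 0.7186
print(ni.msr(truth, {"nmf": res,
                     "knn": impute_knn(sim.masked, 10),
                     "halfmin": impute_half_min(sim.masked)}, sim.theta_s))
# {'nmf': 1.123, 'knn': 2.115, 'halfmin': 2.762}
```

600 cells (20% of the grid) were hidden with mixed missingness; the ensemble
recovers them with ~12% relative error versus ~72–74% for the fixed-value
and kNN baselines, and wins the per-NA error ranking (MSR 1.12, where 1.0
would mean closest on every single NA). Correlation-network recovery on the
same run: F1 = 0.972 against the network built from the complete data.

The same operations are available from the shell:

```
nmfimpute simulate --pattern mm --x 20 --truth t.csv --out masked.csv --theta theta.json
nmfimpute impute nmf --input masked.csv --output imputed.csv --report report.json
nmfimpute evaluate --truth t.csv --theta theta.json --imputed imputed.csv ... --out report.json
nmfimpute benchmark --config bench.yaml --out results/
```

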