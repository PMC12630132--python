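# Methods

## Generative model

Each simulated omics layer is an `m_I × n` features-by-samples matrix

    X_I = Λ_Iᵀ Γ + E_I ,      x_ij = λ_iᵀ γ_j + ε_ij ,

with one score matrix `Γ` (`k × n`) drawn once per simulation and shared
by all layers, layer-specific loadings `Λ_I` (`k × m_I`), and i.i.d.
Gaussian noise `ε_ij ~ N(0, σ²_I)` with a constant variance per layer.
The model is Gaussian-linear by design: no count likelihoods, no
nonlinear factor–feature relationships, no correlated noise. Matrices
are generated mean-zero; per-feature offsets (from calibration) are an
additive vector applied after assembly, kept separate from the model.

The simulator retains every constituent (`Γ`, each `Λ_I`, each `E_I`,
the resolved configuration, the seed), so `X_I` can always be reassembled
bitwise from its parts — the property that makes recovery benchmarking
exact rather than approximate.

## Signal design

A factor declares, per layer, a *feature support*: either an explicit
index set or a count placed at validation time. Placement samples
without replacement from the layer's remaining free indices, in factor
declaration order, from a dedicated per-layer "placement" substream —
so resolution is a pure function of (config, seed) and the resolved,
fully explicit config re-simulates bit-exactly. Under the default
`disjoint` overlap policy, supports within a layer are pairwise
disjoint (explicit overlaps are an error naming the colliding factors);
a `free` policy lifts the restriction. Disjointness is scoped per layer:
two factors may both be active on a layer, on disjoint feature sets.

Distribution laws are serializable descriptors:

- **score laws** — `normal(mean, sd)` (default standard normal),
  `constant(value)`, and `two_group(means, sd, split)` for factors that
  separate two sample groups; an optional `sample_support` masks scores
  to a sample subset (zero elsewhere), which emulates FABIA-style
  bicluster blocks with the same mechanism.
- **loading laws** — `normal(mean, sd)` with optional `min_abs`
  magnitude floor and `random_sign`, or `constant`. Active features draw
  from the law; inactive features are exactly zero, giving a binary
  ground-truth activity label per (factor, layer, feature).

Defaults (scores standard normal; loadings `normal(mean=3, sd=1)`) put
the typical active-feature signal well above unit noise while leaving
recovery non-trivial at moderate SNR.

## Noise and SNR

Noise is specified per layer either as a variance `σ²_I` (data units²)
or as a target SNR, defined as the ratio of the empirical entry variance
of the noiseless signal matrix `Λ_Iᵀ Γ` to `σ²_I`. This layer-global,
variance-ratio definition is the simplest self-describing choice and is
recorded in the output manifest. An all-zero signal layer with a finite
SNR request is an error (the ratio is undefined); factor-free (`k = 0`)
configs therefore use explicit variances and serve as pure-noise nulls.
Requesting SNR → ∞ degenerates gracefully to near-noiseless data.

Noise, scores, loadings and placement each draw from named substreams of
the master seed (`SeedSequence` entropy mixing, one stream per factor
score row, per (layer, factor) loading block, per-layer noise and
placement), so adding a layer or factor leaves unrelated draws unchanged
and regression tests stay stable. A missing seed is an error — there is
no silent clock seeding.

## Calibration

`calibrate(X, k)` estimates from a reference matrix: per-feature means
and variances (sample statistics, `ddof=1`), per-sample means, and a
background-noise variance. The noise estimator is the residual mean
square after removing the best rank-`k` approximation (SVD truncation)
of the row-centered matrix, with divisor `m·n − k(m + n)` when positive
(adjusting for the parameters absorbed by the removed rank) and the
plain observation count otherwise. Missing entries are ignored
per-statistic (pairwise-available; no imputation); an all-missing
feature is an error naming it. The default `k` is the elbow of the
singular-value scree (largest consecutive drop ratio), always logged,
never silently applied. `config_from_calibration` transfers `σ̂²` and
the feature-mean offset vector into a config template, leaving all
signal structure to the user. Loading magnitudes are deliberately not
calibrated — signal structure is the user's declaration, not an estimate.

## Evaluation

Factor models are identifiable only up to row permutation and sign.
Matching therefore maximizes total `|Pearson r|` between true and
inferred score rows over one-to-one assignments (Hungarian algorithm via
`scipy.optimize.linear_sum_assignment`), recording the signed `r` per
pair; surplus factors on either side are reported unmatched, and
zero-variance rows correlate 0 with everything. Tests verify the
assignment against brute-force enumeration of all injective maps for
`k, k̂ ≤ 4`.

Loading recovery treats active-feature detection as a binary
classification: the true active set is the nonzero support of the true
loading row; the inferred active set is entries with `|value|` above 5%
of that row's maximum `|value|` (scale-free, overridable); sensitivity
and specificity come from the confusion matrix, pooled over the layers
a factor is truly active on. An empty true support leaves sensitivity
undefined (reported missing, not 0). Reported aggregates: mean matched
`|r|` (factor-level accuracy) and balanced accuracy (loading level).

The built-in baseline standardizes each feature row, concatenates layers
along the feature axis (early integration over the shared samples), and
takes the exact rank-`k` SVD; scores are `diag(s)·Vᵀ`, loadings are the
corresponding rows of `U` split back per layer, and each factor's sign
is fixed by making its largest-`|loading|` entry positive, so the result
is fully deterministic. External factorizations are read from TSV files
in the ground-truth layout; running MOFA/GFA/FABIA themselves is out of
scope.

## What the synthetic data does and does not show

The generator emulates exactly the structure FA methods assume: linear
signal, Gaussian noise, disjoint feature modules, a shared sample set.
It does not emulate heavy-tailed or count-valued measurements, batch
effects, feature–feature correlation beyond the factors, or nonlinear
dependencies — so passing benchmarks here demonstrates correct recovery
of *injected linear structure*, not performance on arbitrary real data.
Calibration narrows, but does not close, that gap: it matches first- and
second-moment structure and noise level only.

Two structural facts matter when interpreting recovery scores:

- **Rotation degeneracy.** Factors of equal strength produce (near-)equal
  singular values, and any SVD-based method is then free to rotate within
  the degenerate subspace; no matching procedure can undo that. Benchmark
  configurations therefore use unequal support sizes. After per-feature
  standardization a noiseless factor's strength is `√(support size)` —
  loading magnitudes cancel — which is why separation is engineered
  through support sizes rather than loading means.
- **Orthogonality ceiling.** SVD factors are exactly orthogonal in sample
  space while true score rows have sample correlation ρ ≈ O(1/√n), so
  matched `|r|` is capped near `√(1 − ρ²)` even without noise. Noiseless
  endpoint checks use large `n` (10⁴) so this ceiling sits safely above
  0.999; at `n = 100`, values around 0.99 are the expected ceiling, not
  a defect.

## Numerical choices

- TSV serialization uses `%.17g` (lossless for float64) and parsing uses
  round-trip float conversion, so write → read is bit-exact; matrices are
  kept C-contiguous because BLAS products differ at the ulp level across
  memory layouts, which would otherwise break bitwise report
  reproducibility.
- Numerical rank in noiseless tests: singular values below `10⁻⁸·σ₁`.
- `sigma2 = 0` short-circuits to an exact zero matrix (no degenerate
  normal draws).
- Feature standardization maps constant rows to zero rather than NaN.
- `n = 1` configs are rejected (no sample variance); `k = 0` is allowed
  as a null benchmark.
- Placement ties: explicit supports claim indices first, then count-style
  supports draw in declaration order — deterministic and documented.

## Problem sizes

Default test and acceptance workloads use layers of 100–200 features,
100–200 samples, 2–3 factors, 5 sweep replicates, and `n = 10⁴` samples
for the noiseless endpoint; these sizes give sampling errors comfortably
inside the asserted tolerances (e.g. variance ratios within 10–15%)
while keeping the full suite fast on a single CPU.
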