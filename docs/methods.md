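# Methods

## Problem and model

`thermograph` predicts the thermostability of a protein — either an
organism-level thermostability class or a melting temperature T_m in °C —
from two inputs that protein language models (PLMs) produce without any
atomic structure: a per-residue embedding matrix **P** ∈ ℝ^{L×F} and a
residue–residue contact map **A** ∈ [0,1]^{L×L}, interpreted as the weighted
adjacency of the protein graph.

The model has four stages:

1. **Sequence branch.** A per-residue MLP maps **P** to a learned sequence
   representation **X** ∈ ℝ^{L×D}:
   X = σ(…σ(P W⁽⁰⁾ + b⁽⁰⁾)… W⁽ˡ⁾ + b⁽ˡ⁾), σ = ReLU.
   Each output row depends only on its own residue.
2. **Structure branch.** A GCN propagates **X** through the symmetrically
   normalized contact adjacency
   Â = D^{−1/2}(A + I)D^{−1/2}, D_ii = Σ_j(A + I)_ij + c,
   with layer rule H⁽ˡ⁺¹⁾ = σ(Â H⁽ˡ⁾ W⁽ˡ⁾) and H⁽⁰⁾ = X, producing the
   structure representation **G** ∈ ℝ^{L×D}. The constant c > 0 guards
   against empty rows; with the self-loop added, row sums are already ≥ 1,
   so the default c = 10⁻⁶ is a pure safeguard.
3. **Contrastive alignment.** A triplet scheme guided by amino-acid type
   ties the branches together. From each protein, L_s residues with known
   type are sampled uniformly without replacement; the sampled sequence
   rows X_s act as anchors and the same residues' structure rows G_s as
   positives. Pair similarity is an ω-scaled cosine,
   Ψ[i,j] = ω·cos(x_i, g_j), 0 < ω < 1, and the diagonal (same residue in
   both branches) is pulled up by a logistic log-loss
   L_pos = −(1/L_s) Σ_i log σ_sig(Ψ[i,i]).
   For each anchor, K negatives are drawn from the sampled anchors of a
   *different* amino-acid type (without replacement when possible, with
   replacement when fewer than K candidates exist, skipped when none) and
   pushed away:
   L_neg = −(1/M) Σ log σ_sig(−ω·cos(x_i, x_neg)).
   The contrastive loss is L_cont = L_pos + L_neg, averaged over the
   proteins of a mini-batch; a fresh sample is drawn every forward pass.
   Residues of unknown type (wildcards, non-canonical letters) join neither
   role.
4. **Pooling and heads.** Each branch is pooled by grouped self-attention:
   A_g = softmax(W₂ tanh(W₁ Hᵀ)) over the residue axis, D″ independent
   groups; the pooled vector averages the group summaries (A_g H). Padded
   positions receive −∞ logits and exactly zero weight, so padding can never
   change a protein's prediction. The two pooled vectors are concatenated
   and a fully connected layer yields class logits or t̂_m. The training
   objective is
   L = L_pred + α·L_cont,
   with L_pred the mean cross-entropy (classification) or batch RMSE in °C
   (regression).

Training uses Adam with a fixed learning rate for a fixed number of epochs
(default 10); after every epoch all splits are evaluated and the parameters
of the best epoch on the selection split are kept (ties go to the earliest
epoch). Selection defaults to the validation split; selecting on the test
split is supported behind an explicit `--paper-protocol` flag that logs a
warning, because test-set selection biases the reported test metrics.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| D | 128 | learned representation width (both branches) |
| MLP depth | 2 (F→D→D) | sequence encoder layers, ReLU, no dropout |
| GCN depth | 2 (D→D) | structure encoder layers, no bias |
| c | 1e-6 | degree regulariser in the adjacency normalization |
| D″ | 4 | attention groups per pooling head |
| L_s | 64 | residues sampled per protein for contrast |
| K | 5 | negatives per anchor |
| ω | 0.5 | similarity scale, strictly in (0,1) |
| α | 0.1 | weight of the contrastive term |
| lr / batch | 1e-4 / 4 | optimisation defaults; presets for other regimes ship in `training.PROTOCOL_PRESETS` |

The MLP/GCN depths, D, D″, L_s, K, ω and α are not pinned down by the
method's defining equations; the values above are this package's defaults,
chosen to be conventional for protein-scale models and exercised by the
synthetic benchmark. The attention mechanism is realized as
W₂ tanh(W₁ Hᵀ) with D_a = D; the two branches use the *same mechanism* with
independent weights (a `share` flag is deliberately not offered — fuse at
the head instead). The similarity kernel is cosine by default; a raw
dot-product kernel is available via `ContrastiveConfig(kernel="dot")`
because the scaled-sigmoid family admits either reading.

## Numerical core

No GPU tensor framework is used. The package ships a compact reverse-mode
autodiff engine over numpy (`thermograph.autodiff`): a `Tensor` records the
primitive that produced it and `backward()` walks the tape in reverse
topological order. The primitive set is exactly what the model needs
(broadcast arithmetic, matmul including the 1-D vector cases, ReLU/tanh/
sigmoid/softplus in overflow-safe forms, reductions, row gather, stable
softmax/log-softmax, concatenation). Every primitive's gradient is verified
against central finite differences in the test suite, and dense linear
algebra at protein scale (L ≤ a few hundred, D = 128) keeps a full training
run on one CPU in seconds to minutes.

Numerical conventions worth knowing:

- Cosine similarity uses a 10⁻¹² norm guard so ReLU-dead (all-zero) rows
  yield similarity 0 instead of NaN.
- The masked softmax adds −10³⁰ to padded logits and then multiplies by the
  mask, so padded weights are *exactly* zero, not merely tiny.
- RMSE's gradient is guarded by a 10⁻³⁰ shift inside the square root so a
  perfect fit does not divide by zero during backprop.
- `normalize_adjacency` multiplies by the outer product of the inverse
  square-root degrees in one step, which keeps Â exactly symmetric in
  floating point.
- A nonzero contact-map diagonal would still get the +I self-loop added;
  the synthetic generator always emits zero diagonals.
- AUC uses the Mann–Whitney rank statistic with half credit for ties, so a
  constant scorer yields exactly 0.5; it coincides with the trapezoidal
  area under the ROC curve. R² may be negative for fits worse than the mean
  predictor. Precision returns NaN with a warning when nothing was
  predicted positive. Macro (not micro) averaging is used for multiclass
  ROC/AUC so each thermostability class counts equally under imbalance.

## Synthetic data: what it emulates and what it does not

The generator (`thermograph.synthetic`) emulates the three inputs at
controllable signal-to-noise. Residue i of type a in a protein with target
y gets the embedding row

    τ_a + μ(y) + ε_i,   ε_i ~ N(0, σ²I),

where the τ_a are fixed random unit vectors (norm `residue_scale`, default
1) per amino-acid type and μ(y) is a class prototype of norm δ
(`effect_size`, default 3) or, for regression, a fixed unit direction
scaled by (t_m − 45)/50·δ — linear in the centred melting temperature, so
correlation-recovery tests have a known monotone signal. Contact maps have
a chain band of width w = 2 plus sparse symmetric long-range contacts
(density ρ = 0.02, weights U(0.5, 1)), mimicking backbone locality plus
tertiary contacts. Targets use the standard organism-level bands —
Cryophilic −20–5 °C, Psychrophilic 5–25, Mesophilic 25–45, Thermophilic
45–75, Hyperthermophilic > 75 (sampled up to 95 °C) — with the binary
hot/cold split at 45 °C; classes are balanced to within one protein and
the 70/15/15 split is by protein.

This additive model deliberately lets each stage be tested in isolation:
the type component exercises the contrastive labels, the class component
the heads, the band structure the metrics. It does **not** reproduce real
PLM geometry — anisotropy, positional effects, correlated noise along the
chain, length-composition confounds — nor sequence evolution. Passing the
end-to-end benchmarks therefore shows the pipeline can extract a planted
signal of realistic dimensionality, not that it matches any published
benchmark accuracy on real corpora; real-data performance must be
established on real embeddings.

`check_separability` gives a sanity floor: a nearest-class-mean classifier
on mean-pooled *raw* embeddings. A trained model failing to beat it on
high-SNR data indicates a pipeline defect rather than a hard task.

## Benchmark problem sizes

The shipped end-to-end benchmarks train on 200 proteins (two-class), 250
(five-class) and 300 (regression), lengths 30–60, F = 32, δ = 3, σ = 0.5,
10 epochs, batch 8, Adam at 10⁻³ (the synthetic sets are small, so a
slightly larger rate than the real-data presets converges within the fixed
epoch budget). These sizes keep a full suite-plus-benchmark run in a few
minutes on one CPU while leaving the learning criteria comfortably met.

## Known limitations

- Embedding/contact extraction from actual PLMs (ESM-family, ProtT5) and
  from 3-D structures is out of scope; the package consumes those arrays
  from its HDF5 container. An adapter for public thermostability corpora is
  likewise not bundled.
- Exact functional details of the contrastive objective in the inspiring
  line of work (cosine vs scaled dot similarity; per-protein vs per-batch
  sampling) admit more than one reading; this package fixes ω-scaled cosine
  and per-protein sampling, and exposes the kernel as configuration.
- Training is single-process CPU; no mixed precision, schedulers, gradient
  clipping or early stopping beyond best-epoch selection.
- The 10-fold cross-validation protocols used by some published evaluations
  are not orchestrated here; splits come from the container.
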