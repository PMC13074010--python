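# Methods

This note documents the model, the numerical choices, and what the
desk-scale experiments do and do not demonstrate.

## The optimization problem

A vision transformer tokenizes an image into `N_p` patch vectors plus a
class token (`N = N_p + 1` tokens).  Token pruning seeks a binary
retention mask `M ∈ {0,1}^N` with `M[0] = 1` (the class token is the
classification read-out and is never pruned) that maximises

```
f(M) = w₁ A(M) + w₂ (1 − ‖M‖₀/N),   w₁ + w₂ = 1
```

`A(M)` is held-out classification accuracy using only retained tokens.
Defaults `w₁ = 0.7, w₂ = 0.3`.  Because any retained token costs
`w₂/N` of fitness, a token survives at the optimum only if it buys at
least that much accuracy — the sparsity term is a per-token
information threshold, not a soft regulariser.

## Quantum-inspired search

Each individual stores an amplitude pair `(α_j, β_j)` per token,
`α_j² + β_j² = 1`, initialised to the unbiased superposition
`(1/√2, 1/√2)`.  One generation comprises:

1. **Observation** — per position draw `r ~ U(0,1)`; bit = 0 if
   `r < α_j²`, else 1, so `P(1) = β_j²`.  Position 0 is forced to 1
   after sampling.
2. **Evaluation** — composite fitness with a pluggable accuracy
   evaluator; the best-so-far record updates before rotation, so
   rotation in generation *t* uses generation-*t* information.
3. **Elite selection** — top `N_b = max(2, ⌈P/5⌉)` by fitness; ties
   break toward fewer retained tokens, then lower index, making
   selection deterministic.
4. **Rotation** — every chromosome rotates toward the best-so-far mask
   by `Δθ = δ_k · sign(bit, best_bit, f_i, f*)` with the five-case
   direction table (disagreeing bits move toward the best mask when
   the individual is worse than the best, away otherwise; agreeing
   bits are untouched).  The 2×2 cosine/sine gate preserves
   normalisation exactly; accumulated float drift is renormalised
   beyond 1e-9.
5. **Refill** — non-elite slots are replaced by uniform crossover of
   elite parents (`p_c = 0.5`, amplitude pairs copied whole), so
   normalisation is inherited.
6. **Mutation** — per qubit an independent Bernoulli draw with
   probability `η (1 − F_i/F_max)(1 − H_k/H_max) S_j` triggers the
   phase flip `(α, β) → (α, −β)`.  The flip leaves `P(1)` unchanged
   and only alters how subsequent rotations move the qubit; it is a
   diversity mechanism, not a bit flip.  The literal formula makes
   *stable* tokens mutate more; a config switch `invert_stability`
   (default off) exposes the opposite convention for sensitivity
   analysis.  Offspring produced this generation have no own fitness
   yet; their mutation probability uses the mean of their parents'.

Rotation is applied before the refill (each evaluated individual has
its own observed mask and fitness; a just-created offspring does not),
and elites persist as post-rotation chromosomes.  Elitism operates on
records, so the best-so-far fitness trace is non-decreasing by
construction.

Amplitudes are real pairs, as in classical quantum-inspired
evolutionary practice; no complex phases or hardware semantics are
implied.

### Probability convention

The observation rule `bit = 0 if r < α²` implies `P(1) = β²`, while the
ket notation `α|1⟩ + β|0⟩` would imply `P(1) = α²`.  The operational
rule is implemented literally: it is self-consistent with the rotation
direction table (a `+1` rotation of a positive-amplitude qubit strictly
increases `β²` for steps below π/2, verified numerically).

## Clinical entropy guidance

`H_k` is the Shannon entropy (bits) of client `k`'s class-count
distribution; `H_max = log₂ C`.  Empty classes contribute zero
(continuity convention); a single-class client has `H = H_max = 0` and
its normalised entropy is defined as 0.  Guidance formulas:

| control | formula | default | range |
|---|---|---|---|
| population size | `round(P_B (1 + α H/H_max))` | `P_B = 10`, `α = 0.3` | `[P_B, 13]` |
| rotation step (rad) | `δ_base (1 + γ (1 − H/H_max))` | `δ_base = 0.05`, `γ = 0.3` | `[0.05, 0.065]` |
| mutation base | `η = 0.15` | — | `P_mut ∈ [0, η]` |
| consensus weight | `w_k = H_k / Σ H_l` | uniform fallback if all zero | sum to 1 |

The population-size rounding is to the nearest integer, never below
`P_B`.  The entropy-scaling factor is treated as an interval `[0,1]`
parameter.  The all-zero-entropy federation falls back to uniform
aggregation weights so single-class clients can still federate.

## Fitness evaluators

**Planted oracle** — `A(M) = |M ∩ T| / |T|` for a known informative
token set `T`.  Deterministic, enumerable, used wherever exact optima
are needed (for `N ≤ 10` all `2^{N−1}` masks are enumerated and the
evolutionary optimum is compared against brute force).  Under this
oracle the unique fitness maximiser is exactly `T ∪ {class token}`.

**MLP proxy** — the practical evaluator: a two-layer network
`d → hidden → C` with GELU, dropout 0.1 between the layers, trained
1–3 epochs (default 3) and scored on a held-out 80:20 split.  Because
the raw class-token embedding is mask-independent, the proxy's input
is a parameter-free uniform-attention pooling of the retained token
rows (the mean of retained embeddings, class token included) — the
cheapest mask-sensitive stand-in for the encoder's class-token mixing.
Numerical choices that matter on small clients: inputs are
standardised with train-split statistics; optimisation is Adam
(lr 1e-2, batch 8) so the permitted few epochs suffice; and
`n_splits` repeated 80:20 hold-outs (default 3 in the federation) are
averaged because a 20 % validation fold of an ~100-sample client has
accuracy granularity of several percent, which would otherwise
dominate the per-token sparsity margin `w₂/N ≈ 0.018`.

## The encoder

A standard pre-norm ViT in numpy with configurable dimensions:
bilinear aspect-preserving resize with zero padding, channel
normalisation (ImageNet statistics), non-overlapping `p × p` patches,
linear embedding, class token, positional embeddings, `L` layers of
LayerNorm → multi-head attention → residual, LayerNorm → GELU FFN
(hidden `4d`) → residual, and a softmax head on the final class token
(natural-log cross-entropy).  The `vit16b` preset names the full-scale
geometry (224/16, d=768, L=H=12, 197 tokens); tests and simulations
use the desk preset (32×32 images, 8-pixel patches, 17 tokens, d=32,
L=2, H=4).

Positional embeddings are fixed sinusoidal by default (deterministic
and testable); a learnable table is available by config.  They are
added *before* mask application, so in drop mode each retained token
keeps its positional identity.

Masks apply in two modes: `zero` (element-wise product, length
preserved) and `drop` (masked rows removed — the mode under which
attention cost actually falls to `K²`, and the default everywhere).
The forward pass can count pairwise attention scores per layer and
head; the instrumented count equals `K²` exactly, which ties the
implementation to the analytic accounting module.

Gradients for every parameter are derived by hand (reverse mode) and
verified against central finite differences in the test suite; SGD
with momentum 0.9 trains either all parameters or only the
classification head.  Elastic deformation augmentation is a documented
no-op placeholder.

## Federated protocol

Per round: the server broadcasts `(θ_t, m_t)`; two of the three
clients participate (uniform pair by default; an independent
Bernoulli(2/3) rule with a minimum of two is available); each
participant computes `H_k`, runs the evolutionary search, fine-tunes
the classification head for one epoch of SGD+momentum (batch 8) on its
masked features, and uploads `(θ_k, m_k, H_k, n_k,` elite masks`)`;
the server applies FedAvg (weights `n_k/Σn_k`) and entropy-weighted
mask consensus with threshold 0.6 (class token forced on).

Design choices where the protocol was open:

* **Population persistence** — the unbiased initialisation applies at
  round 0 only; each client's quantum population persists across
  rounds and the next round's search continues from it.  Ten rounds of
  ten generations therefore behave like one long search interleaved
  with model updates, which is what makes round-over-round mask
  convergence observable at desk scale.
* **Stability timing** — token stability scores for round *t* are
  computed from elite masks uploaded in round *t − 1*; round 0 uses
  the all-ones fallback.
* **Pretrained backbone stand-in** — the protocol assumes a pretrained
  encoder.  At desk scale the backbone is warmed up (200 full-model
  SGD steps) on a freshly drawn synthetic dataset from the same
  generative family, playing the role of public pretraining data; the
  federation itself then trains heads only.  Without this, mask search
  runs on random-projection features whose accuracy differences are
  too small to rank masks reliably.
* Non-participants keep their previous state and do not enter that
  round's FedAvg.  Tiny-model learning rate is 1e-2 (constant), a
  scaled-down substitution for the 1e-5 used at full ViT scale.
* The raw per-round best fitness and the cumulative best-so-far are
  both logged; the cumulative trace is non-decreasing by construction.

No real networking, encryption or differential privacy is simulated;
the privacy claim enforced in code is structural — the upload payload
is a fixed schema containing parameters, masks and scalars, never raw
samples or indices.

## Synthetic data

Images are `0.5 + N(0, σ)` noise (default σ = 0.3, 32×32×3) with the
class signal confined to four planted patches.  Each planted slot has
its own deterministic zero-mean texture (oriented gradients,
checkerboard, stripes, with distinct channel tilts), and class `c`
multiplies slot `i`'s texture by a ±1 code entry: class 0 is all `+`,
class `i ≤ |T|` flips slot `i − 1`.  Consequences, by construction:

* mutual information between the label and any non-planted patch is
  zero, so every token outside `T ∪ {0}` strictly lowers fitness at
  the optimum;
* every planted patch separates at least one class pair that the
  others cannot (classes 0 and *i* differ only at slot *i − 1*), so
  the planted set is *jointly* necessary — dropping any planted token
  costs roughly the merged pair's prior mass in accuracy, far above
  the sparsity reward for dropping it.  Without this property a
  redundant signal would make aggressive pruning of planted tokens
  optimal and mask recovery meaningless.

Defaults: 5 classes, 120 samples per client (360 pooled for the
three-client federation), uniform priors before Dirichlet(0.5)
partitioning.  The `preset_upper_gi_profile` class counts
`[999, 932, 764, 403, 260]` (5 classes, 3358 images, `H = 2.1724`
bits) serve as the entropy-realism preset for guidance formulas.

What the generator does **not** emulate: photorealistic texture,
illumination or endoscope artefacts, spatial correlation of noise,
intra-class appearance variation, or label noise.  Passing recovery
tests therefore demonstrates that the optimizer finds jointly
informative token subsets under a correct model of "signal confined to
few tokens", not that it ranks clinical saliency in real endoscopy.

## Problem sizes and tolerances

Desk-scale experiment sizes were chosen so the whole suite runs on one
CPU in minutes: oracle-equivalence at `N = 9` (512-mask enumeration,
50 generations, 5 seeds), single-client recovery at `N = 17` with four
planted tokens (30 generations, 5 seeds, Jaccard ≥ 0.8 in ≥ 4/5), and
the federation at 3 clients × 10 rounds × 10 generations (5 seeds,
global-mask Jaccard ≥ 0.6 in ≥ 4/5).  Monte-Carlo assertions use 3–4 σ
binomial bands; amplitude normalisation is asserted at 1e-9; exact
arithmetic (tokenization, complexity table, entropy formulas) is
asserted to printed precision with half-up rounding (one decimal for
percentages, two for speedups).

## Known limitations

* Accuracy proxies at ~100-sample clients remain noisy even with
  repeated hold-outs; recovered masks occasionally carry one spurious
  token or drop one weak planted token (the acceptance bands reflect
  this).
* The rotation schedule is constant; no annealing or amplitude
  clamping away from saturation is applied, so a converged population
  cannot re-explore without mutation.
* The numpy encoder is exact but not fast; full-scale (d = 768, L = 12)
  training is out of scope, and the `vit16b` preset exists for
  dimension bookkeeping only.
* Mask consensus can oscillate when participant pairs alternate;
  reported global masks are end-of-run snapshots, not fixed points.
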