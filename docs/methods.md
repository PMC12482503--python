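# Methods

## Model

The price model is a feed-forward network: fingerprint → hidden layers
(ReLU) → linear latent layer (N = 10) → affine readout f(z) = wᵀz + b
giving the natural-log price in USD/mmol. Defaults: hidden sizes
(256, 64), Adam (lr 10⁻³), batch 128, early stopping on validation MSE
with patience 10, best-checkpoint restore. All price targets stay on
the log scale throughout; nothing is re-exponentiated during training.
The network and its backpropagation are implemented directly in numpy;
the contrastive gradients (below) are hand-derived and verified against
finite differences in the test suite to ~10⁻¹⁰ relative error.

A 10-dimensional latent space is deliberately small: it keeps each
dimension informative, makes the frozen affine readout interpretable
(price is a fixed linear functional of z), and makes the per-dimension
Gaussian approximation used by the contrastive loss reasonable.

## Contrastive fine-tuning

After pretraining, the readout is frozen (its parameters are bit-frozen,
not merely down-weighted: the optimizer receives exactly zero gradient
for them, and tests assert bit-identity). Each fine-tuning step draws
one ES and one HS minibatch (1:1, the shorter stream reshuffled each
epoch), encodes both, computes per-dimension class means and standard
deviations within the minibatch, and minimizes

    MSE(ES batch) + λ · mean_j H_j  (+ optional HS price penalty)

with λ = 0.05 by default. Design choices:

- **Batch statistics, not running averages.** The per-batch estimator is
  the simplest differentiable one; the default batch of 128 gives ≥ 64
  molecules per class, enough to stabilize the per-dimension SD.
- **SD floor ε = 10⁻⁶** keeps the affinity defined when a latent
  dimension collapses within a class; floored dimensions contribute no
  SD gradient (the floor is a constant there).
- **Population SD** (ddof = 0) is used; its gradient
  ∂σ_j/∂z_ij = (z_ij − μ_j)/(B σ_j) is what the backward pass implements.
- **HS molecules contribute no MSE term** — they are unlabeled. They
  enter the loss only through the latent statistics and, if enabled, the
  soft price bound (1/L) Σ max(0, ŷ − X), X = 20 by default but disabled
  unless requested: in every study here the self-generated HS prices
  stayed finite without it.
- **Checkpoint selection:** the retained checkpoint minimizes the
  validation composite MSE_ES + λ·H̄ computed on held-out ES and HS sets.
  A pure-MSE criterion would ignore the separation objective; a pure-H̄
  criterion would allow the regressor to degrade.
- **Direction of separation is not enforced.** The loss only separates
  the latent clouds; which class ends up more expensive is an empirical
  outcome. The signed HS − ES mean-price difference is recorded in the
  training history and a warning is issued if it is negative.

## Synthetic study conditions

The synthetic-data module defines the study on which the pipeline is
validated:

- **ES library** (default n = 2000): molecules assembled from a fragment
  grammar (alkyl chains of 1–8 carbons, 0–3 small rings drawn from
  benzene/cyclohexane/pyridine/THF/thiophene/piperidine/furan/
  cyclopentane with simple linkers, common terminal groups, occasional
  defined stereocentres). The log-price is a linear combination of
  structural counts — 0.25·heavy atoms + 0.8·rings + 0.4·heteroatoms +
  1.0·stereocentres — plus Gaussian noise (SD 0.2), affinely mapped so
  the library spans [0, 12], matching the price range purchasable
  catalogs exhibit on the natural-log USD/mmol scale. The coefficients
  encode the monotone structure→price trend the method relies on; their
  absolute values are otherwise arbitrary.
- **HS library** (default n = 2000): each molecule starts from an ES
  molecule in the smaller half of the library (by heavy atoms, so HS
  sizes land inside the ES size range rather than trivially above it)
  and receives 3 graph edits, each grafting a complexity-raising
  fragment (spiro and bridged bicycles, adamantane, decalin, a
  12-membered macrocycle, stereo-defined chains and rings, dithiane,
  dioxane) at a random free valence, with sanitization and retry. HS
  molecules carry no prices.

What the generator does **not** emulate: the heavy-tailed supplier price
distribution of a real catalog, activity cliffs, reagent-market effects
decoupled from structure, and genuinely out-of-distribution chemistries
(organometallics, natural products). Passing the synthetic study shows
the machinery is correct — the fingerprint map can represent the
generating signal, the frozen-readout contract holds, and the Hellinger
loss separates classes that differ by substructure — not that the scores
transfer to real market data, which would require a real catalog.

The acceptance-level study uses Morgan fingerprints at radius 2 and 1024
bits with an n = 2000/2000 ES/HS split; library defaults are radius 3 /
2048 bits. The smaller setting is the package's standard desk-scale
configuration for the synthetic study, where the chemical diversity is
modest; both are exposed as parameters and recorded in every artifact's
sidecar/manifest.

## Evaluation

- Regression: MSE, R² (against the evaluation set's own mean), Spearman
  with average ranks for ties. A constant target flags R² as undefined
  (NaN + warning) instead of silently reporting 0.
- Classification: HS is the positive class, decision rule
  score ≥ threshold ⇒ HS. Threshold candidates are the midpoints of
  consecutive sorted unique scores plus ∓∞ sentinels — the exact
  maximizer set for step-wise objectives (MCC or F-score); ties break
  toward the lower threshold. ROC-AUC is computed over all thresholds
  and cross-checked against the Mann–Whitney U normalization. The CLI
  optimizes the threshold on the validation split and reports validation
  and test metrics side by side.
- Latent diagnostics: PCA on the latent vectors of a mixed ES/HS set.
  Successful contrastive training concentrates the between-class
  displacement in the leading component, so the first explained-variance
  ratio rises relative to the pretrained model.

## Preprocessing

Catalog cleaning applies, in order: parse/canonicalize (RDKit), price
normalization to USD/mmol (dropping entries with missing/unknown
units), per-molecule minimum price across suppliers, natural-log
transform, and removal of molecules cheaper than 2 USD/mmol on the raw
scale (stabilizing salts, metals, solvents). The cutoff acts on the raw
price — the log transform merely changes the stored scale. Removal
counts per step are returned and must sum, with survivors, to the input
count. Dot-disconnected SMILES are kept if parsable: the price filter,
not fragment stripping, removes cheap commodity salts. Splits are
uniform random (0.9, 0.05, 0.05) under a recorded seed; no scaffold
splitting.

## Numerical and degenerate-input policy

- Fingerprint lengths must be powers of two (hashing convention);
  SECFP uses RDKit's native encoder (radius 3, rings and kekulized
  environments included, minimum radius 1).
- Hybrid descriptors are z-scored with training-split statistics;
  constant descriptors pass through centred at zero.
- Single-class batches, zero-variance PCA inputs, non-finite losses and
  dimension mismatches raise typed errors rather than propagating NaNs.
- All randomness flows through seeded numpy generators; training is
  reproducible run-to-run on the same machine.

## Known limitations

- Desk-scale only: the numpy trainer is single-threaded and intended
  for 10³–10⁵ molecules, not multi-million-molecule catalogs.
- The Gaussian-per-dimension assumption is an approximation; strongly
  multi-modal latent dimensions would make the closed-form affinity a
  crude overlap measure.
- Price is a proxy: a separation learned against one HS source (here,
  complexity-grafted molecules) reflects that source's structural
  signature, not synthesis feasibility in general.
- The ES:HS sampling ratio is fixed at 1:1 per batch; heavily imbalanced
  real datasets may warrant resampling strategies not explored here.
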