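# Methods

## Model

The encoder is a single subnetwork applied twice (true weight sharing: both
pair sides pass through one parameter set in one batch):

1. **Token lookup.** A trainable table of shape (vocab + 1) × 256. Row 0 is
   reserved: it encodes both out-of-vocabulary tokens at prediction time and
   right-padding. No masking is applied to row 0; it is trained like any
   other row.
2. **LSTM, 64 units, tanh cell activation,** returning the state at every
   position (so the subsequent flatten is informative rather than a no-op).
   Forget-gate bias initialized to 1; other weights Glorot-uniform; lookup
   rows uniform(−0.05, 0.05). All initialization and shuffling derive from
   `ModelConfig.seed`.
3. **Flatten** to max_len × 64, then a **linear projection to 32** (no
   nonlinearity). 32 is the embedding dimension used throughout;
   `embedding_dim` is configurable.

**Distance head and loss.** For a pair (a, b) with target y (0 = same SDTM
class, 1 = different), d = ‖f(a) − f(b)‖₂ and the model output is
s = σ(γ(d − 1)) with `distance_scale` γ = 4, trained with binary
cross-entropy. The shift centers the decision boundary at d = 1 (s = 0.5),
so "same" pairs are pushed toward d ≈ 0 (s ≈ 0.02) and "different" pairs
toward d > 1; γ = 4 keeps gradients usable over d ∈ [0, 2]. The loss choice
is a design decision — the architecture statement (sigmoid final activation
over a Euclidean distance with 0/1 targets) does not pin one down — and a
margin-1 contrastive loss is available via `ModelConfig.loss =
"contrastive"`. Pair accuracy is thresholded at s ≥ 0.5 (BCE mode) or
d ≥ 0.5 (contrastive mode).

**Optimizer.** Adam, lr 1e-3, β = (0.9, 0.999). Implemented, like the whole
forward/backward pass (BPTT through the LSTM), in NumPy float32: the
environment ships no deep-learning framework, and at these model sizes a
hand-written implementation is fast and bitwise reproducible on one thread.
A finite-difference check in the test suite validates the gradients.

**Numerical notes.** d carries an ε = 1e-12 inside the square root so the
gradient at d = 0 is defined; BCE logs are ε-clamped; the batch loss is
checked finite every epoch and a divergence error reports the epoch. The
saturating LSTM makes organic divergence essentially impossible at sane
learning rates.

## Data pipeline

- **Normalization.** HTML is stripped with the stdlib parser (entities
  unescaped, whitespace collapsed); a regex sweep is the fallback for
  malformed markup. Stripping is idempotent.
- **Concatenation order** is FormOID, FieldOID, PreText, PostText (the
  column order of the corpus schema); empty fields are skipped.
- **Tokenization**: lowercase, whitespace split, edge punctuation stripped
  except underscore (OIDs like `AGT_ACTL_DOSE` stay single tokens);
  interior punctuation survives (`(dd/mm/yyyy)` → `dd/mm/yyyy`). These are
  artifact conventions; the method is not sensitive to them.
- **Dictionary encoding**: first-seen token → 1, 2, …; unknown → 0;
  sequences right-padded/truncated to `max_len`, which defaults to the
  longest concatenated training text (a cap is available for memory
  control).
- **Leakage discipline**: the split precedes everything. Vocabulary,
  `max_len` and pairs are computed from the training side only; a dedicated
  test verifies that deleting all test records leaves the trained encoder
  bitwise unchanged.
- **Pairing**: per record, `n_same` = 20 positive and `n_diff` = 20
  negative partners ("at least 20" is implemented as exactly 20), sampled
  uniformly with replacement across draws, never self-paired; negatives are
  uniform over all other-class records, so class prevalence shapes negative
  exposure. Records in singleton classes contribute negatives only.
- **Split**: per-label proportional allocation (±1 record), singleton-label
  records go to train with a warning. Cross-validation uses stratified
  k-fold with per-fold rebuilds.

## Suggestion and evaluation

Exact k-NN (k = 5) by the same Euclidean metric as the training head.
Distance ties break by record order; majority-vote ties resolve to the tied
class whose member ranks nearest — both arbitrary but reproducible
conventions. The three decision modes (top-k containment, nearest, majority)
are reported with accuracy and macro-F1; containment accuracy dominates the
other two by construction.

Macro-F1 averages per-class F1 over the classes present in the truth set,
zero-division → 0. For the containment mode, which answers a set question,
the per-record prediction is scored as the true label when contained and as
the nearest label otherwise. Test labels absent from training count as
misses in all modes and are flagged, not dropped.

The headline protocol is the 20% stratified holdout; 5-fold CV is a separate
entry point (the two protocols are near-equivalent here and both are
exposed).

PCA projection for visualization is mean-centered with each component's
sign fixed so its largest-magnitude loading is positive.

## Baseline

TF-IDF (scikit-learn: natural TF × smoothed IDF, L2 row normalization,
minimum document frequency 2) over the identical normalized, concatenated,
tokenized text, classified by `HistGradientBoostingClassifier` at library
defaults (the environment has no xgboost; histogram-based gradient-boosted
trees are the same model family). The baseline consumes the identical split
for any given seed. Note the default `min_samples_leaf = 20` makes the
classifier degenerate below a few dozen training rows.

## Synthetic corpus generator

The generator emulates the structure of proprietary annotated-CRF corpora:

- **Per class**: an SDTM-style label (domain prefix + variable suffix) and a
  pool of `tokens_per_class` prompt words, disjoint between non-confusable
  classes. A corpus-wide **shared pool** supplies filler words;
  `shared_token_fraction` (default 0.3) is the probability a prompt word is
  filler — the task-difficulty dial (separability falls as it rises).
- **Study-build variants** (`variants_per_class`, default 8): each class is
  collected by several distinct builds, each with its own FormOID/FieldOID
  (globally unique pseudo-words, so OID token sets are disjoint between
  classes) and its own sub-vocabulary of the class pool. This is the
  mechanism that makes training support matter: a class with 8 training
  records covers only ~5 of its 8 variants, and held-out records from
  uncovered variants present out-of-vocabulary OIDs. Without variants,
  class recovery saturates at every support level and no support-accuracy
  trend can exist.
- **Confusable groups** share prompt pools and format hints across classes
  and differ only in OIDs — the cross-domain near-duplicate failure mode.
- **Noise**: casing perturbation, optional trailing colon, HTML wrappers on
  `html_fraction` (default 0.15) of prompts (exercising the stripper), 10%
  empty post-texts, and `oov_injection_rate` (default 0.1) of records
  receive a globally unique `x`-prefixed token. The generator cannot know
  the eventual split, so injection applies to a random fraction of all
  records; any injected record landing in the test side is OOV with respect
  to the training vocabulary by construction.
- Profiles: `balanced` (all classes at `support`) and `figure4` (supports
  cycling 10/25/50/100/200, making support an independent variable).

Everything is driven by one seed; identical configs yield byte-identical
corpora.

**What a green test does and does not establish.** The generator's worlds
are separable by construction at the default settings, so end-to-end checks
establish that the pipeline recovers recoverable structure (top-5
containment ≥ 0.9, nearest ≥ 0.8 on the balanced 10 × 150 world), not that
any particular accuracy transfers to proprietary data. Real corpora differ
in ways the generator does not model: true linguistic synonymy, multi-study
label noise, pivoted/unpivoted representation artifacts, composite
(calculated) fields, and sequence lengths up to three orders of magnitude
longer. Token-overlap statistics of real corpora are unpublished; the
defaults are plausible, not calibrated.

## Performance and test-scale choices

Default-scale training (1,500 records → 60,000 pairs, 3 epochs) takes
~1 minute on one CPU. The test suite runs the full stated configuration
once and reuses its report; repeated-run properties (e.g. decision-mode
ordering across 20 seeds) use smaller corpora and fewer pairs per record,
which is valid because those properties are structural and scale-free.

## Known limitations

- One field maps to one SDTM variable; composite targets are supported only
  as opaque strings like `AESTDTC/CMSTDTC`.
- Word-level encoding only; no character-level mode, no pretrained
  embeddings (OID jargon defeats general-purpose vocabularies).
- No calculated/derived fields (BMI-style), no domain-then-variable
  two-step prediction, no interpretability layer.
- `max_len` scales memory linearly through the flatten layer; corpora with
  very long prompts should set `max_len_cap`.
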