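# Methods

itemforge implements construct-specific automatic item generation (AIG)
for rating-scale questionnaires at desk scale, together with the
psychometric battery used to evaluate the resulting item pools. This note
documents the models, the defaults, the numerical choices, and what the
synthetic fixtures do and do not show.

## The segmented training pattern

A training example pairs m construct labels ψ = (c₁, …, c_m) with an item
stem ι = (w₁, …, w_n). Both are flattened into a single delimited string

    u_A ∘ c₁ ∘ … ∘ u_A ∘ c_m ∘ u_B ∘ w₁ … w_n

with single-character delimiters u_A = `#` and u_B = `@` by default
(configurable; validated to be absent from all label and stem text). At
generation time the partial pattern up to and including u_B — e.g.
`#Pessimism@` — is the conditioning prompt, and the model completes the
stem. The codec is bijective on its collision-free domain, and every
encoded example begins with the prompt built from its labels.

Tokenization is word-level (whitespace split, punctuation attached, case
preserved) with a character-level option for very small experiments.
Registered construct labels enter the vocabulary as single tokens so a
label is learned as one unit. Byte-pair encoding is deliberately not
implemented: it is an efficiency device of large-vocabulary models and
contributes nothing to the method's logic at this scale. Each training
string ends with an explicit end-of-text token, which is the stop symbol
for every decoding strategy.

## The miniature causal transformer

A decoder-only transformer in pure numpy (float64, CPU): token plus
positional embeddings, M layers of masked multi-head self-attention
Z = softmax(QKᵀ/s)·V with concatenation and output projection, layer
normalization, and a position-wise feed-forward (GELU) network; the output
projection is weight-tied to the embedding matrix. Gradients are
hand-written reverse-mode passes over the forward caches and are verified
against central differences in the test suite.

Configurable conventions, with defaults chosen for fidelity to the GPT
family that the method targets:

- **Attention scaling** `scale`: `head_dim` (divide scores by √(d/n_h),
  default) or `seq_len` (divide by √n). Both appear in the literature;
  the per-head convention is what GPT-2 uses.
- **Masking** is causal: position i attends to j ≤ i; disallowed entries
  are −∞ before the softmax so their post-softmax weight is exactly zero.
- **Positional encodings**: learned (default) or sinusoidal.
- **Block ordering**: pre-norm (default; markedly more stable at tiny
  scale) or post-norm.
- **Optimizer**: Adam (default, lr 5e-4), momentum, or plain gradient
  descent. Plain GD at practical learning rates does not reach
  memorization on the toy corpora within a few thousand steps, so the
  adaptive default is used; the learning rate default matches the rate
  conventionally used for fine-tuning at full scale.
- **Initialization**: seeded Gaussian, σ = 0.02; norm gains start at 1.
  At this init the step-0 loss is ln V, the uniform-prediction baseline.

Training is full batch over the (padded) corpus; the loss is mean
next-token cross-entropy in natural log. With `prompt_lengths` supplied,
the loss is scored on the continuation only — the conditional objective of
predicting the stem given the label pattern. This distinction matters for
memorization checks: under full-sequence loss the label following the
first delimiter is inherently unpredictable, leaving an irreducible floor
of about ln(n_labels)/sequence-length (≈ 0.33 on the 20-label toy corpus),
whereas the conditional loss can reach zero on a memorizable corpus.
The default remains full-sequence loss.

Checkpoints are versioned archives of the config, a vocabulary reference,
and the named weight arrays; loading refuses incompatible versions.

## Decoding

Greedy search takes the single most probable token each step. Beam search
ranks hypotheses by joint (unnormalized) log-probability, keeps the best
n_beams per step, and carries completed hypotheses in the pool; with beam
width covering the whole sequence space it coincides with exhaustive
enumeration, which the tests exploit as an oracle. Ties break by
probability then lowest token id, making greedy and beam bit-reproducible.

Multinomial sampling draws from the next-token distribution after an
optional transformation pipeline applied in a fixed order: temperature
(log-space rescaling), then top-k, then nucleus (top-p). The nucleus rule
keeps the smallest probability-sorted prefix whose cumulative mass
*reaches* the threshold (≥ p); this convention guarantees a non-empty
support. Temperature, top-k and top-p compose rather than exclude each
other. Reported log-probabilities always refer to the untransformed model
distribution, so scores are comparable across strategies. All strategies
stop at end-of-text, the requested maximum length, or the model's context
bound, whichever comes first; malformed generations are returned flagged
with their parse-failure category, never dropped.

## Overfit screening

Each candidate stem is compared with every training stem by the similarity
index s = 1 − d/max(|a|, |b|), where d is unit-cost Levenshtein distance.
Candidates whose nearest training stem reaches s ≥ .90 (default threshold)
are discarded as near-verbatim reproductions. Normalizing by the *longer*
string length reproduces both canonical worked values when terminal
punctuation is retained ("I like/love to be the center of attention." →
0.9459 → .95 discarded; "I am easily angered./annoyed." → .85 kept); the
denominator is configurable (`max` | `mean`) and strings are compared as
stored, case and punctuation included. Two-decimal reporting uses
round-half-up; the raw index is always kept. Candidates are compared
against bare stems, not encoded pattern strings. Deduplication collapses
exact-duplicate stems to their first occurrence and removes items
generated under multi-label prompts before content-validity rating.

## Psychometric evaluation

Responses are N×J integers in 1..K (default K = 5). Negatively keyed items
are reverse-scored (K+1−x) before scale-level analysis; raw data are kept.

**Descriptives** per item from category frequencies: mean; SD with divisor
N−1; skewness m₃/s³ and excess kurtosis m₄/s⁴ − 3, where the central
moments use divisor N and s is the sample SD. This convention reproduces
printed reference rows exactly (e.g. frequencies 7/13/30/71/99 at N = 220
give 4.10 / 1.05 / −1.16 / 0.76) and is adopted as the implicit standard;
no claim is made about any particular software's internal path.

**Polychoric correlations** use the two-step estimator: thresholds from
the inverse normal CDF of marginal cumulative proportions, then ρ̂ by
maximizing the bivariate-normal contingency likelihood on (−0.999, 0.999)
with Brent's method. The bivariate normal CDF is evaluated as
Φ₂(h,k;ρ) = Φ(h)Φ(k) + ∫₀^ρ φ₂(h,k;r) dr by 24-node Gauss–Legendre
quadrature, vectorized over all table cells (agreement with scipy's
reference CDF is ~1e-8; the speed makes bootstrap pipelines of ~10⁵
polychoric fits tractable on one CPU). Boundary solutions (|ρ̂| ≥ 0.998)
are flagged. Vectors with fewer than two observed categories are rejected.

**One-factor model**: minimum-residual (ULS) fit minimizing the squared
off-diagonal residuals of R − λλᵀ, L-BFGS-B with analytic gradient,
initialized from the leading eigenvector. Loadings are box-bounded to
[−1, 1]: without the bound, near-null matrices admit unbounded
single-item spikes with negative residual variances, which destabilizes
every bootstrap replicate downstream. A solution pinned at the bound is
flagged as a Heywood case (ω is still computed, flagged).
Non-positive-definite inputs are eigenvalue-clipped back to a correlation
matrix and flagged; signs follow a majority-positive convention. Degenerate matrices (e.g. identity) admit single-spike
minimizers with the same off-diagonal fit as the null solution, so the
smaller-norm solution is preferred. On exact rank-1-plus-diagonal matrices
the fit recovers λ to numerical precision. This is a documented
approximation to full weighted least squares estimation: loadings-level
comparability is the supported claim; chi-square-based fit indices are
out of scope.

**Omega-total** ω = (Σλ)²/((Σλ)² + Σθ) with θ_j = 1 − λ_j². The bootstrap
resamples respondents, reruns the full polychoric → one-factor → ω chain
per replicate, and reports the percentile 95% CI; replicates that fail to
converge (or degenerate on resampling) are omitted and counted, aborting
if more than half fail. The two-sample comparison resamples both groups
independently per iteration and reports the two-sided p as twice the
smaller tail proportion of ω differences crossing zero — a deliberate,
labeled construction, since "bootstrapped probability of a difference" is
otherwise underspecified.

**Cohen's kappa** κ = (p_o − p_e)/(1 − p_e) with the Fleiss–Cohen–Everitt
asymptotic variance for the 95% CI (cross-checked against statsmodels).

**Parallel analysis** compares the observed correlation-matrix eigenvalues
with the 95th-percentile eigenvalues of seeded standard-normal datasets of
the same N×J, retaining leading factors until the first failure. Note the
rule spuriously retains a factor on pure noise about 5% of the time by
construction; tests therefore assert its behavior across seeded draws.

## Synthetic data

The grammar generator emulates a label-conditioned stem corpus: each
construct owns templates and a disjoint filler lexicon, so labels carry a
lexical signature a tiny model can learn. `memorization_grammar` maps each
of up to 20 labels to exactly one deterministic stem — the fixture for
memorization checks (conditional cross-entropy < 0.1; greedy decoding from
each label prompt reproduces that label's stem). What passing these checks
shows is that the architecture, training loop, and conditional prompting
work end-to-end; it does not show that generated items for *unseen* labels
are semantically valid — that property requires a large pretrained model
and human raters and is outside what synthetic fixtures can establish.

The response generator draws trait z ~ N(0,1) per respondent (one
independent factor per construct block when block structure is requested),
sets y*_j = λ_j z + √(1−λ_j²) e, and discretizes by ordered thresholds
(default −1.5, −0.5, 0.5, 1.5, giving K = 5 with plausibly bell-shaped
margins). It emulates the one-factor ordinal measurement model the
evaluation assumes — and therefore cannot speak to violations of that
model (correlated residuals, multidimensionality within a scale, careless
responding), which real questionnaire data exhibit.

The rater-table generator produces integer two-rater agreement tables with
requested marginals and observed agreement (or exact independence), used
to exercise kappa's edge cases.

## Problem sizes used by the checks

Worked-example checks are exact and instantaneous. Simulation-based
checks run at deliberately moderate sizes chosen once: polychoric recovery
at n = 5,000 (±0.05), loading recovery at N = 1,000 (±0.1), parallel
analysis at N = 220 / J = 25 over 10 seeded runs, and the omega-difference
bootstrap at K_boot = 150 with 80 null repetitions (type-I within
[.01, .12]) and 30 alternative repetitions (λ = .8 vs .3; power > .80).
The end-to-end pipeline check trains a d = 24 model for 400 steps on an
8-example corpus and verifies artifact-level determinism across two runs.

## Known limitations

- The transformer is a faithful miniature, not a pretrained model; it
  cannot generalize to untrained construct labels in any semantically
  meaningful way.
- Similarity screening is surface-level (edit distance); paraphrases with
  low character overlap pass the filter. Embedding-based semantic
  similarity is a natural extension and intentionally out of scope.
- The factor machinery is unidimensional per scale; multi-factor
  exploratory rotation is out of scope (parallel analysis is included).
- The omega-difference p-value is a bootstrap sign-crossing construction,
  not an analytic test; its operating characteristics are established by
  simulation in the test suite.
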