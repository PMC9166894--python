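# itemforge

Construct-specific automatic item generation (AIG) for rating-scale
questionnaires, at desk scale, with a full psychometric evaluation
pipeline. It is aimed at researchers in psychological assessment and
computational psychometrics who want a transparent, fully inspectable
implementation of the conditional-language-model approach to writing
questionnaire items — every stage from corpus encoding to omega
reliability runs in pure scientific Python on one CPU.

## What it does

Writing personality items by hand is slow and expensive. The
conditional-generation approach treats item writing as concept
elaboration: given a construct label ψ (e.g. *Pessimism*), generate an
item stem ι = (w₁, …, w_n) that is indicative of it, i.e. sample from
P(ι | ψ). itemforge implements that pipeline end to end:

1. **Encoding** — each training pair of construct labels and item stem is
   flattened into a delimited pattern
   `u_A∘c₁∘…∘u_A∘c_m∘u_B∘w₁…w_n`, e.g.
   `#Anxiety#Neuroticism@I worry about things`. At generation time the
   partial pattern `#Pessimism@` is the prompt. Construct labels are
   single vocabulary tokens.
2. **Model** — a miniature decoder-only causal transformer (numpy,
   hand-written backprop): masked multi-head self-attention
   Z = σ(QKᵀ/√(d/n_h))·V, temperature softmax σ(a) = e^{a/τ}/Σe^{aᵢ/τ},
   weight-tied output projection, trained by cross-entropy gradient
   descent.
3. **Decoding** — greedy search, beam search over joint sequence
   probability, and multinomial sampling with temperature, top-k, and
   nucleus (top-p) truncation.
4. **Overfit screening** — candidates too close to the training data are
   discarded by the similarity index s = 1 − d/max(|a|,|b|) (inverted,
   length-normalized Levenshtein distance), threshold s ≥ .90, plus
   deduplication and a single-label selection rule.
5. **Psychometrics** — Likert descriptives, polychoric correlations,
   one-factor minres loadings λ, McDonald's ω = (Σλ)²/((Σλ)²+Σθ) with a
   percentile bootstrap CI and a two-sample bootstrap comparison, Cohen's
   κ for rater agreement, and parallel analysis for factor retention.
6. **Synthetic data** — template-grammar item corpora and one-factor
   latent-normal Likert responses, so the whole pipeline is testable
   without any external download.

See `docs/methods.md` for the model details, conventions, and
limitations.

## Worked example

```python
from itemforge import (encode_example, build_prompt, fit_vocab, ModelConfig,
                       TrainSchedule, train, DecodingConfig, generate_items,
                       filter_overfit, likert_descriptives, gen_item_corpus)
from itemforge.synthetic import corpus_to_examples, memorization_grammar

print(encode_example(["Anxiety", "Neuroticism"], "I worry about things").encoded)
print(build_prompt(["Pessimism"]))

corpus = gen_item_corpus(memorization_grammar(5), 5, seed=1)
examples = corpus_to_examples(corpus)
vocab = fit_vocab(examples)
seqs = [vocab.encode_ids(e.encoded) for e in examples]
plens = [len(vocab.encode_ids(build_prompt(list(e.labels)))) for e in examples]
cfg = ModelConfig(vocab_size=vocab.size, d_model=32, n_heads=2, n_layers=2,
                  n_ctx=max(map(len, seqs)), d_ff=64, seed=0)
params, trace = train(seqs, cfg, TrainSchedule(steps=800), prompt_lengths=plens)
print(f"final conditional cross-entropy: {trace[-1]:.4f}")

items = generate_items(["Curiosity"], 1, params, cfg,
                       DecodingConfig(strategy="greedy", max_len=16), vocab)
print("generated:", items[0].stem)

kept, _, discarded, _ = filter_overfit(
    ["I like to be the center of attention.", "I am easily angered."],
    ["I love to be the center of attention.", "I am easily annoyed."])
print("kept:", kept)
print("discarded:", [(d.candidate, round(d.similarity, 2)) for d in discarded])

print({k: round(v, 2) for k, v in likert_descriptives((7, 13, 30, 71, 99)).items()})
```

prints

```
#Anxiety#Neuroticism@I worry about things
#Pessimism@
final conditional cross-entropy: 0.0258
generated: I ask many questions.
kept: ['I am easily angered.']
discarded: [('I like to be the center of attention.', 0.95)]
{'mean': 4.1, 'sd': 1.05, 'skewness': -1.16, 'kurtosis': 0.76, 'n': 220}
```

Reading the output: the five-label toy corpus is memorized (conditional
cross-entropy 0.026 ≈ 0), so greedy decoding from the `#Curiosity@`
prompt returns exactly the training stem for that label. The filter
discards the candidate whose similarity to a training stem is .95 (≥ the
.90 threshold) and keeps the one at .85. The final line recomputes an
item's descriptive statistics from its category frequencies (N = 220):
mean 4.10, SD 1.05, skewness −1.16, excess kurtosis 0.76.

## Command line

The same pipeline is available as subcommands:

```
itemforge simulate --n 20 --seed 1 --out corpus.csv
itemforge encode corpus.csv --encoded-out encoded.txt --vocab-out vocab.tsv
itemforge train corpus.csv --vocab vocab.tsv --checkpoint model.npz --steps 2000
itemforge generate --checkpoint model.npz --vocab vocab.tsv \
    --label Calmness --count 10 --strategy sample --tau 0.9 --out generated.csv
itemforge filter generated.csv --corpus corpus.csv --out filter_report.csv
itemforge evaluate likert.csv --k-boot 200 --out evaluation.csv
```

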