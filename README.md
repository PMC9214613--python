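# nevex — joint extraction of nested biomedical events

Biomedical text describes events — *gene expression*, *blood vessel
development*, *regulation* — anchored by a trigger word and linked to
participants through semantic roles (`Theme`, `Cause`). Events nest: a
regulation event's Theme may itself be an expression event, and pipeline
systems that first tag triggers and then classify arguments compound their
errors exactly on these nested structures. `nevex` is a research
implementation of a *joint* extractor for people studying event extraction
methods: a single network tags triggers and classifies argument roles
together, and the argument classifier is conditioned on the trigger
classifier's full probability distribution rather than on its argmax.

## Model

For a sentence w₁…wₙ with gold entity annotations and a dependency parse:

* per-token input xᵢ = [aᵢ; bᵢ; cᵢ]: frozen contextual embedding, trainable
  POS embedding, trainable entity-BIO embedding;
* context stream L = BiLSTM(X), n × 2φ;
* syntax stream: the parse is simplified to three edge classes (along-arc,
  reversed-arc, self-loop); k gated GCN layers over this multigraph,
  initialized from A = [a₁…aₙ], update
  h_v ← ReLU( agg₍u,v,r₎ σ(V_r h_u + d_r) · (W_r h_u + b_r) ),
  followed by H-head self-attention, giving M (n × m);
* a unidirectional tagger LSTM reads T = [L; M] into the source matrix O;
  trigger tagging is soft = rowsoftmax(O W^tri + b^tri) over the BIO
  trigger vocabulary;
* for each (trigger, candidate) pair — candidates are entities and other
  triggers — span vectors mean-pool [O_k; soft_k] and
  softmax(W^event [Tr; Can] + b^event) assigns `Theme` / `Cause` / `None`;
  a trigger-typed argument resolves to that trigger's event, which is what
  produces nested structures, with cycles broken in favour of
  higher-probability decisions.

Training minimizes a joint self-adjusting Dice loss (a soft-F1 surrogate
that down-weights easy examples by (1−p)^β and balances precision against
recall under heavy O-class imbalance) averaged equally over the token-level
and pair-level decisions; a cross-entropy baseline is included for
ablation. See `docs/methods.md` for assumptions, parameter semantics,
numerical choices and known limits.

Everything runs on numpy through a small reverse-mode autodiff core
(`nevex.autodiff`); there is no deep-learning framework dependency and no
checkpoint download — the contextual embedder ships as a deterministic
hash-based fallback.

## Worked example

Generate the default toy corpus (standoff `.txt/.a1/.a2` plus CoNLL-U),
train the joint extractor, and score it with strict recursive event
matching:

```python
from nevex import (GeneratorConfig, generate, write_corpus, load_corpus,
                   JointEventExtractor, evaluate_examples)

write_corpus(generate(GeneratorConfig(n_docs=10, sentences_per_doc=5, seed=7)), "toy")
docs, examples, dropped = load_corpus("toy")

est = JointEventExtractor(
    contextual_dim=48, pos_dim=8, entity_dim=8, lstm_hidden=24, tagger_hidden=48,
    batch_size=1, learning_rate=0.2, dropout=0.0,
    epochs=300, early_stop_f1=0.995, check_every=25, seed=0,
)
est.fit(examples)
report = evaluate_examples(examples, est.predict(examples))
```

On one CPU this trains for 125 epochs (~2 minutes) to final loss 0.3571 and
prints, per task and stratum (*simple* = entity arguments only, *nested* =
an event-typed argument):

```
trigger all     P 100.00  R 100.00  F1 100.00  (gold 52)
event   all     P 100.00  R 100.00  F1 100.00  (gold 52)
event   simple  P 100.00  R 100.00  F1 100.00  (gold 38)
event   nested  P 100.00  R 100.00  F1 100.00  (gold 14)
```

i.e. the model memorizes the 50-sentence corpus perfectly, nested events
included. Predictions are standoff-ready structures:

```
sentence: we confirmed angiogenesis of endothelial cells .
  trigger TR1: 'angiogenesis' [13,25) type=Blood_vessel_development
  event E1: Blood_vessel_development trigger=TR1 args=[('Theme', 'T1')]
```

The same workflow is available from the shell:

```bash
nevex simulate --seed 7 --out toy/
nevex validate toy/
nevex train --corpus toy/ --model model.npz
nevex predict --model model.npz --corpus toy/ --out pred/
nevex evaluate --gold toy/ --pred pred/ --report report.json
nevex attend --model model.npz --corpus toy/        # attention heat-map TSV
```

Real corpora in BioNLP-ST standoff format are read with the same
`load_corpus` entry point, given a CoNLL-U file with sentence `doc_id`
comments and character offsets.

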