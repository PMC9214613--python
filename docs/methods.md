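# Methods

`nevex` implements joint extraction of (possibly nested) biomedical events
from sentences that carry gold entity annotations and a dependency parse.
This note records the model, the choices made where the design was open, the
synthetic data the package is exercised on, and what the shipped experiments
do and do not demonstrate.

## Task and data model

A document is BioNLP-style standoff: raw text, typed entity spans (`.a1`),
and typed trigger spans plus event frames (`.a2`). An event has exactly one
trigger (whose label is the event type) and a list of role-labelled
arguments (core roles `Theme` and `Cause`); an argument filler is an entity
or another event, and event references must be acyclic. Offsets are 0-based,
end-exclusive, over Unicode code points, so every span's recorded surface
must equal the text slice — the reader enforces this, plus reference
resolution and acyclicity, and names the offending annotation id on failure.
Non-core roles, equivalence (`*`) lines and modification annotations are out
of scope; the role vocabulary is configurable, `{Theme, Cause}` by default.

Spans are tagged per token with the BIO scheme, for entities (model input)
and triggers (model output) alike. Encoding rejects spans that cut through a
token or cover a discontiguous token run (`Misaligned`). Decoding is
lenient, as predicted tag sequences can be malformed: an orphan `I-t` opens
a new span rather than being dropped.

Dependency parses arrive in CoNLL-U (produced externally; the package never
parses text). The ~50 relation labels are collapsed to three direction
classes: each arc head→dep yields an `along` edge (head, dep) and a `rev`
edge (dep, head), and every token gets a `loop` self-edge, so a sentence
with n tokens and a arcs has exactly 2a + n edges. Sentences are the
modelling unit; events whose participants span sentences are dropped (and
counted) when a corpus is loaded.

## Network

Per token i, the input is x_i = [a_i; b_i; c_i]: a frozen contextual
embedding a_i (m dims), a trainable POS embedding b_i and a trainable
entity-BIO embedding c_i (each with a reserved UNK row; unseen labels are
logged). Two streams are computed:

* **Context** L: a single-layer BiLSTM over X, phi hidden units per
  direction, L is n × 2·phi.
* **Syntax** M: k gated graph-convolution layers over the 3-relation
  multigraph, initialized from A = [a_1 … a_n]. Layer update:
  h_v ← ReLU( agg over incoming edges (u,v,r) of g_uv · (W_r h_u + b_r) ),
  with a scalar edge gate g_uv = sigmoid(V_r h_u + d_r). The result S feeds
  H-head scaled dot-product self-attention (d_k = m/H) with an output
  projection, giving M (n × m). The head-averaged attention matrix can be
  exported for heat maps (`nevex attend`).

A unidirectional tagger LSTM reads T = [L; M] row-wise and produces the
source matrix O (n × d_O). Trigger recognition is a per-token softmax over
the BIO trigger vocabulary: soft = rowsoftmax(O W^tri + b^tri). For
argument classification, candidate pairs are every (trigger, entity) and
every ordered (trigger, other trigger) pair in the sentence; for each span
the fused representation mean-pools [O_k; soft_k] over its tokens, and
softmax(W^event [Tr; Can] + b^event) yields a distribution over
{Theme, Cause, None}. Concatenating the trigger softmax into the pair
features is the *conditional* fusion that lets argument decisions see the
trigger classifier's uncertainty; `fusion="shared"` omits the soft blocks
and recovers the conventional shared-representation joint baseline used as
the ablation contrast.

Decoding is greedy: argmax BIO tags → trigger spans; argmax role per pair;
one event per predicted trigger, with trigger-typed arguments resolved to
that trigger's event. A decision that would close a reference cycle is
discarded in favour of higher-probability decisions (decisions are applied
in decreasing probability). Predicted documents always pass standoff
validation.

### Known representational limit

The argument scorer is linear in [Tr; Can]. If roles are a pure function of
(trigger type, candidate type) and both directions of every trigger pair are
scored, a type-deterministic nesting chain of depth ≥ 3 is not linearly
separable: the constraints score(t_i, t_{i+1}) > 0 > score(t_i, t_{i+2}),
score(t_{i+1}, t_i) force a cyclic ordering of the per-type functionals.
Real corpora are not type-deterministic, so this does not bind there, but it
dictates that the synthetic learnability corpus uses single-level nesting
(see below).

## Loss

Training minimizes a joint self-adjusting Dice loss. For one decision with
gold-class probability p (indicator y = 1):

    loss = 1 − (2·(1−p)^β·p·y + λ) / ((1−p)^β·p + y + λ)

Per sentence, the mean over the n_p token-level trigger decisions and the
mean over the e_p pair-level role decisions are added with equal weight, and
the batch loss is the mean over sentences (scale-free in sentence length —
the within-sentence reduction is an average, not a sum). A cross-entropy
baseline with the same reduction supports the loss ablation.

Numerical behaviour of the Dice form worth knowing:

* The per-decision loss is minimized at p\* = 1/(1+β), not at p = 1. With
  β = 1 the optimum sits exactly on the two-class decision boundary, so a
  converged model's argmax decisions have no margin; the package default is
  **β = 0.3** (p\* ≈ 0.77). λ (smoothing) defaults to 1.0.
* In logit space the gradient of a confidently wrong class vanishes
  (∝ p·(2+λ)/(1+λ)² as p → 0), unlike cross-entropy whose logit gradient
  stays bounded away from zero. Rare classes squashed early in training
  therefore recover slowly; this is intrinsic to Dice-over-softmax and is
  the mechanism behind its precision/recall balancing (it stops pushing
  easy negatives once they pass p\*).

## Training

SGD with momentum 0.9, per the reference conditions learning rate 0.01 and
dropout 0.3 (applied to the fused input X and the tagger input T); batches
are sentences sorted by length then chunked; gradients are globally norm-
clipped at 5.0. A non-finite loss aborts with `NonFiniteLoss`. Fixed seed ⇒
identical parameters across runs. Optional early stopping monitors training
F1 every `check_every` epochs.

The reference hyperparameters (768-dim contextual embeddings, 64-dim POS
and entity embeddings, phi = 128, 2 GCN layers, 2 heads, d_O = 256, lr
0.01) describe a GPU-scale configuration. The shipped experiments run a
reduced geometry chosen once for single-CPU runtimes — contextual 48, POS
and entity 8, phi = 24, d_O = 48, 2 layers, 2 heads — and a matching
optimization scale: lr 0.2, batch size 1, ≤ 300 epochs. At this scale the
bounded Dice gradients need the larger step (lr 0.01 plateaus far from
convergence within 300 epochs), and the contextual fallback dimension must
comfortably exceed the template lexicon size so random word vectors stay
near-orthogonal. The overfitting experiment sets dropout = 0: dropout is a
regularizer against memorization, and the experiment's objective is
memorization; directional ablations keep the configuration of the runs they
compare identical apart from the ablated component.

Two deliberate departures from a literal reading of the layer equations,
both load-bearing and both verified by the shipped tests:

* **GCN aggregation is normalized by in-degree** (a raw-sum mode remains
  available). With unnormalized sums the two stacked layers scale with
  fan-in squared; the syntax stream reached ~40× the context stream's
  magnitude, saturating the downstream tagger and systematically costing
  trigger recall.
* **β < 1 in the Dice loss**, for the decision-margin reason above.

## Contextual embedder

Only the deterministic fallback embedder ships: token surface → md5-keyed,
seed-mixed unit-variance Gaussian vector, frozen. It preserves exactly what
the architecture needs from a contextual encoder at toy scale — a stable,
distinct vector per word — and none of what it cannot have offline
(subword pooling, context sensitivity, domain knowledge). Requesting the
pretrained-transformer embedder raises a clear error; wordpiece-to-token
mean pooling is the documented intention for that integration.

## Synthetic corpus

The generator emits seed-deterministic standoff triples plus CoNLL-U with
document-level character offsets in MISC. Templated sentences contain typed
entities (Gene / Cell / Drug), nominal triggers (two simple event types, one
with a three-token variant, and four regulatory types), projective
dependency trees built by the templates themselves, a closed toy POS set,
and distractor sentences without events. Gold roles follow a fixed
type-level rule — e.g. a regulatory trigger takes a simple event as Theme
and the sentence's Drug as Cause — so event structure is exactly learnable
from (trigger type, candidate type), which is what makes the ≥ 0.99
overfitting check meaningful.

Nesting is single-level (regulation → simple event → entity, the canonical
regulation-of-expression pattern), required by the linear-separability limit
above. A sentence's chain is nested with probability p/(1−p) so the fraction
of *events* that are nested converges to `nesting_prob` (each nested event
brings one simple event along); `nesting_prob` is therefore capped at 0.5.
The emission log records exact gold counts, which the readers must recover.

What the generator does **not** emulate: lexical diversity, parser errors,
ambiguous trigger words, multi-chain sentences, cross-sentence events,
discontinuous spans, non-core roles. Passing the shipped experiments
demonstrates that the implementation is internally correct and trainable,
not that it reproduces corpus-scale published performance — that would
require the licensed corpora, a pretrained biomedical encoder and GPU-scale
training, all outside this package's footprint.

## Evaluation

Trigger match: exact character span and type. Event match: recursive
structural equality (trigger match, same multiset of (role, filler), event
fillers compared recursively) — strict rather than the shared tasks'
approximate-span matching, which keeps the scorer reproducible and
conservative. Micro P/R/F1 in percent, with undefined ratios reported as 0.
Events are stratified into *simple* (all fillers entities) and *nested* (an
event filler), computed structurally by default; the coarse type-based rule
(regulation-like and planned-process types count as nested) is available as
`stratify="by_type"`. A trigger inherits the stratum of the events it
anchors. A per-event-type P/R/F1 table is always included.

## Shipped experiments (tests + acceptance script)

* Sparse gated-GCN layers and multi-head attention against dense
  brute-force oracles (≤ 1e-6 on random graphs, n ≤ 10), plus analytic
  cases (saturated gates, self-loop-only closed form, permutation
  equivariance).
* Standoff write∘read∘write fixed points and BIO round trips over seeded
  generated documents.
* Dice/cross-entropy closed-form values and numeric gradient checks.
* Learnability: the full model reaches trigger and event F1 ≥ 0.99 on the
  default 50-sentence corpus (10 docs × 5 sentences, generator seed 7)
  within 300 epochs on one CPU.
* Direction-only ablations over 5 seeds: conditional fusion vs. shared
  representations on held-out synthetic event F1, and Dice vs.
  cross-entropy |precision − recall| gap on a ~95%-O tagging corpus.

## Limitations

* No pretrained encoder: absolute scores on real corpora are not
  meaningful with hash embeddings; the package's claims are structural and
  behavioural.
* Greedy decoding; no beam or ILP consistency constraints beyond cycle
  breaking.
* Gold entities are required inputs at train and test time (as in the
  evaluation protocol the architecture targets).
* Single-sentence scope by construction.
* The Dice loss's vanishing logit gradient makes very rare classes fragile
  at small scale; the shipped configuration is calibrated for the toy
  corpus sizes above.
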