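"""Joint extraction of triggers and (nested) events, sklearn-estimator style.

The network has three stages.  An input stage concatenates, per token, a
frozen contextual embedding a_i, a trainable POS embedding b_i and a
trainable entity-BIO embedding c_i into x_i = [a_i; b_i; c_i].  An
information-extraction stage runs a BiLSTM over X for the context matrix L,
and, in parallel, a gated GCN over the dependency multigraph initialized
from the contextual embeddings A followed by multi-head self-attention for
the syntax matrix M.  A joint-extraction stage feeds T = [L; M] through a
unidirectional tagger LSTM to the source matrix O; a softmax over O yields
per-token BIO trigger distributions, and for every (trigger, candidate)
pair the argument-role classifier mean-pools [O_k; soft_k] over each span
and classifies the concatenated pair vector — so argument decisions
condition on the trigger classifier's probability distribution
(``fusion="conditional"``).  ``fusion="shared"`` drops the soft blocks,
recovering the conventional shared-representation joint baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator

from .autodiff import Tensor, concat
from .corpus import SentenceExample
from .graphs import SentenceGraph
from .losses import DiceConfig, joint_loss
from .nn import BiLSTM, EmbeddingTable, GatedGCN, HashEmbedder, Linear, LSTM, MultiHeadAttention
from .standoff import AnnotatedDocument, EventRecord, TriggerSpan, bio_to_spans

__all__ = [
    "TokenSpan",
    "CandidatePair",
    "JointEventExtractor",
    "enumerate_candidates",
    "assemble_events",
    "predictions_to_document",
    "NonFiniteLoss",
    "ShapeMismatch",
]


class NonFiniteLoss(RuntimeError):
    pass


class ShapeMismatch(ValueError):
    pass


@dataclass(frozen=True)
class TokenSpan:
    """A contiguous token run [first, last] with a type label."""

    first: int
    last: int
    type: str

    @property
    def n_tokens(self):
        return self.last - self.first + 1


@dataclass(frozen=True)
class CandidatePair:
    """A trigger paired with a candidate argument span (entity or trigger)."""

    trigger: TokenSpan
    candidate: TokenSpan
    candidate_is_trigger: bool


def enumerate_candidates(triggers, entities) -> list[CandidatePair]:
    """All intra-sentence (trigger, candidate) pairs.

    Candidates of a trigger are every entity plus every *other* trigger; the
    list is ordered by (trigger start, candidate start) with entities before
    triggers at ties, so enumeration is deterministic.  For k_t triggers and
    k_e entities this yields k_t*k_e + k_t*(k_t-1) pairs.
    """
    pairs = []
    for t in sorted(triggers, key=lambda s: (s.first, s.last, s.type)):
        cands = [(e, False) for e in entities] + [(o, True) for o in triggers if o != t]
        cands.sort(key=lambda c: (c[0].first, c[0].last, c[1], c[0].type))
        for cand, is_trig in cands:
            pairs.append(CandidatePair(t, cand, is_trig))
    return pairs


def assemble_events(triggers, decisions, entity_ids=None) -> list[EventRecord]:
    """Build one event per trigger from per-pair role decisions.

    ``decisions`` is a list of (pair, role, probability) with the None role
    already filtered out.  A trigger-typed argument resolves to that
    trigger's event (nesting).  Decisions are applied in decreasing
    probability; any decision that would close a reference cycle (including
    self-reference) is discarded, i.e. of two mutually-nesting decisions the
    lower-probability one loses.  Argument-less triggers still yield events
    with empty argument lists.  ``entity_ids`` maps candidate TokenSpans to
    annotation ids; unmapped entity candidates get synthetic N-ids.
    """
    order = sorted(set(triggers), key=lambda s: (s.first, s.last, s.type))
    event_id = {t: f"E{i + 1}" for i, t in enumerate(order)}
    trig_id = {t: f"TR{i + 1}" for i, t in enumerate(order)}
    adj = {eid: set() for eid in event_id.values()}

    def reaches(src, dst):
        stack, seen = [src], set()
        while stack:
            x = stack.pop()
            if x == dst:
                return True
            for y in adj[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return False

    accepted = {t: [] for t in order}
    synth = {}
    ordered = sorted(
        decisions,
        key=lambda d: (-d[2], d[0].trigger.first, d[0].candidate.first, d[1]),
    )
    for pair, role, prob in ordered:
        if pair.candidate_is_trigger:
            src, dst = event_id[pair.trigger], event_id[pair.candidate]
            if src == dst or reaches(dst, src):
                continue
            adj[src].add(dst)
            accepted[pair.trigger].append((role, dst))
        else:
            if entity_ids is not None and pair.candidate in entity_ids:
                fid = entity_ids[pair.candidate]
            else:
                fid = synth.setdefault(pair.candidate, f"N{len(synth) + 1}")
            accepted[pair.trigger].append((role, fid))
    return [
        EventRecord(event_id[t], t.type, trig_id[t], tuple(sorted(accepted[t])))
        for t in order
    ]


def _char_span_to_tokens(start, end, typ, token_spans):
    covered = [i for i, (ts, te) in enumerate(token_spans) if ts < end and te > start]
    if not covered:
        return None
    return TokenSpan(covered[0], covered[-1], typ)


def predictions_to_document(gold_doc: AnnotatedDocument, examples, preds) -> AnnotatedDocument:
    """Merge per-sentence predictions into a standoff document.

    Keeps the gold entities (they are inputs), renumbers predicted triggers
    after the last a1 id and renumbers events document-wide; the result
    passes standoff validation (resolvable references, acyclic events).
    """
    next_t = 1 + max(
        (int(e.id[1:]) for e in gold_doc.entities if e.id[1:].isdigit()), default=0
    )
    triggers, events = [], []
    next_e = 1
    for ex, pred in zip(examples, preds):
        tmap, emap = {}, {}
        for t in pred["triggers"]:
            tid = f"T{next_t}"
            next_t += 1
            tmap[t.id] = tid
            triggers.append(TriggerSpan(tid, t.type, t.start, t.end, t.surface))
        for ev in pred["events"]:
            emap[ev.id] = f"E{next_e}"
            next_e += 1
        for ev in pred["events"]:
            args = tuple(
                (role, emap.get(fid, fid)) for role, fid in ev.args
            )
            events.append(
                EventRecord(emap[ev.id], ev.type, tmap[ev.trigger_id], args)
            )
    return AnnotatedDocument(
        doc_id=gold_doc.doc_id,
        text=gold_doc.text,
        entities=list(gold_doc.entities),
        triggers=triggers,
        events=events,
    ).validate()


class JointEventExtractor(BaseEstimator):
    """Syntax-aware joint trigger/argument extractor for nested events.

    Parameters mirror the architecture: ``contextual_dim`` m (frozen,
    seed-deterministic hash embedder), ``pos_dim``/``entity_dim`` for the
    trainable lookup tables, ``lstm_hidden`` phi per BiLSTM direction,
    ``gcn_layers`` k gated GCN layers on the m-dimensional syntax stream,
    ``attention_heads`` H (must divide m), and ``tagger_hidden`` for the
    unidirectional tagger LSTM producing the source matrix O.  Training is
    plain SGD (learning rate 0.01, dropout 0.3 by default) under the
    self-adjusting Dice loss; ``loss="ce"`` switches to the cross-entropy
    baseline.

    Fitted attributes end in an underscore: ``params_`` (name -> Tensor),
    ``trigger_labels_``, ``role_labels_``, ``pos_vocab_``, ``entity_vocab_``,
    ``loss_curve_``, ``n_iter_``.
    """

    def __init__(
        self,
        contextual_dim: int = 768,
        pos_dim: int = 64,
        entity_dim: int = 64,
        lstm_hidden: int = 128,
        gcn_layers: int = 2,
        gcn_activation: str = "relu",
        attention_heads: int = 2,
        tagger_hidden: int = 256,
        fusion: str = "conditional",
        loss: str = "dice",
        dice_lambda: float = 1.0,
        dice_beta: float = 0.3,
        learning_rate: float = 0.01,
        momentum: float = 0.9,
        dropout: float = 0.3,
        batch_size: int = 16,
        epochs: int = 50,
        max_grad_norm: float = 5.0,
        early_stop_f1: float | None = None,
        check_every: int = 10,
        trigger_types: tuple | None = None,
        role_labels: tuple = ("Theme", "Cause"),
        embedder: str = "deterministic_fallback",
        seed: int = 0,
        verbose: int = 0,
    ):
        self.contextual_dim = contextual_dim
        self.pos_dim = pos_dim
        self.entity_dim = entity_dim
        self.lstm_hidden = lstm_hidden
        self.gcn_layers = gcn_layers
        self.gcn_activation = gcn_activation
        self.attention_heads = attention_heads
        self.tagger_hidden = tagger_hidden
        self.fusion = fusion
        self.loss = loss
        self.dice_lambda = dice_lambda
        self.dice_beta = dice_beta
        self.learning_rate = learning_rate
        self.momentum = momentum
        self.dropout = dropout
        self.batch_size = batch_size
        self.epochs = epochs
        self.max_grad_norm = max_grad_norm
        self.early_stop_f1 = early_stop_f1
        self.check_every = check_every
        self.trigger_types = trigger_types
        self.role_labels = role_labels
        self.embedder = embedder
        self.seed = seed
        self.verbose = verbose

    # --------------------------------------------------------------- building
    def _build(self, pos_vocab, entity_vocab, trigger_type_vocab):
        if self.fusion not in ("conditional", "shared"):
            raise ValueError("fusion must be 'conditional' or 'shared'")
        if self.embedder == "pretrained_transformer":
            raise NotImplementedError(
                "no pretrained transformer checkpoint is bundled; "
                "use embedder='deterministic_fallback'"
            )
        if self.embedder != "deterministic_fallback":
            raise ValueError(f"unknown embedder kind {self.embedder!r}")
        rng = np.random.default_rng(self.seed)
        self.embedder_ = HashEmbedder(self.contextual_dim, seed=self.seed)
        self.pos_vocab_ = sorted(pos_vocab)
        self.entity_vocab_ = sorted(entity_vocab)
        types = sorted(trigger_type_vocab)
        self.trigger_labels_ = ["O"] + [f"{p}-{t}" for t in types for p in ("B", "I")]
        self.role_labels_ = list(self.role_labels) + ["None"]

        m, phi = self.contextual_dim, self.lstm_hidden
        self.pos_table_ = EmbeddingTable(self.pos_vocab_, self.pos_dim, rng, "pos")
        self.entity_table_ = EmbeddingTable(self.entity_vocab_, self.entity_dim, rng, "ent")
        mu = m + self.pos_dim + self.entity_dim
        self.bilstm_ = BiLSTM(mu, phi, rng, "bilstm")
        self.gcn_ = GatedGCN(m, self.gcn_layers, rng, "gcn", self.gcn_activation)
        self.attention_ = MultiHeadAttention(m, self.attention_heads, rng, "attn")
        self.tagger_ = LSTM(2 * phi + m, self.tagger_hidden, rng, "tagger")
        self.trigger_head_ = Linear(self.tagger_hidden, len(self.trigger_labels_), rng, "tri")
        fused = self.tagger_hidden + (
            len(self.trigger_labels_) if self.fusion == "conditional" else 0
        )
        self.role_head_ = Linear(2 * fused, len(self.role_labels_), rng, "event")
        self.params_ = {}
        for mod in (self.pos_table_, self.entity_table_, self.bilstm_, self.gcn_,
                    self.attention_, self.tagger_, self.trigger_head_, self.role_head_):
            self.params_.update(mod.params())
        self._trig_index = {lab: i for i, lab in enumerate(self.trigger_labels_)}
        self._role_index = {lab: i for i, lab in enumerate(self.role_labels_)}

    def _build_from_examples(self, X):
        pos = {p for ex in X for p in ex.graph.pos}
        ent = {t for ex in X for t in ex.graph.entity_bio}
        if self.trigger_types is not None:
            types = set(self.trigger_types)
        else:
            types = {t[2:] for ex in X for t in ex.graph.trigger_bio if t != "O"}
        self._build(pos, ent, types)

    # ------------------------------------------------------------ forward pass
    def embed_tokens(self, graph: SentenceGraph) -> tuple[Tensor, Tensor]:
        """Per-token fused input X = [a; b; c] and the contextual matrix A."""
        A = self.embedder_(graph.surfaces)
        if len(graph) == 0:
            mu = self.contextual_dim + self.pos_dim + self.entity_dim
            return Tensor(np.zeros((0, mu))), A
        B = self.pos_table_(graph.pos)
        C = self.entity_table_(graph.entity_bio)
        return concat([A, B, C], axis=1), A

    def _forward(self, ex: SentenceExample, train: bool = False, rng=None):
        X, A = self.embed_tokens(ex.graph)
        if train and self.dropout > 0:
            keep = (rng.random(X.shape) >= self.dropout) / (1.0 - self.dropout)
            X = X * Tensor(keep)
        L = self.bilstm_(X)
        S = self.gcn_(A, ex.graph)
        M = self.attention_(S)
        if L.shape[0] != M.shape[0]:
            raise ShapeMismatch("context and syntax streams disagree on token count")
        T = concat([L, M], axis=1)
        if train and self.dropout > 0:
            keep = (rng.random(T.shape) >= self.dropout) / (1.0 - self.dropout)
            T = T * Tensor(keep)
        O = self.tagger_(T)
        soft = self.trigger_head_(O).softmax_rows()
        return O, soft

    def role_distributions(self, O: Tensor, soft: Tensor, pairs):
        """Row-stochastic role distribution per candidate pair (None if no pairs).

        For each span the representation is the arithmetic mean over its
        tokens of [O_k; soft_k] (or of O_k alone under shared fusion); the
        trigger and candidate vectors are concatenated and classified.
        """
        if not pairs:
            return None
        F = concat([O, soft], axis=1) if self.fusion == "conditional" else O
        rows = []
        for pair in pairs:
            if pair.trigger.last < pair.trigger.first or pair.candidate.last < pair.candidate.first:
                raise ValueError("empty span in candidate pair")
            tr = F[pair.trigger.first : pair.trigger.last + 1].mean(axis=0, keepdims=True)
            can = F[pair.candidate.first : pair.candidate.last + 1].mean(axis=0, keepdims=True)
            rows.append(concat([tr, can], axis=1))
        return self.role_head_(concat(rows, axis=0)).softmax_rows()

    # ----------------------------------------------------------------- helpers
    def _gold_spans(self, ex: SentenceExample):
        token_spans = ex.graph.token_spans
        trig, ents = {}, {}
        for t in ex.triggers:
            ts = _char_span_to_tokens(t.start, t.end, t.type, token_spans)
            if ts is not None:
                trig[t.id] = ts
        for e in ex.entities:
            ts = _char_span_to_tokens(e.start, e.end, e.type, token_spans)
            if ts is not None:
                ents[e.id] = ts
        return trig, ents

    def _gold_pairs(self, ex: SentenceExample):
        """Candidate pairs from gold triggers/entities with gold role indices."""
        trig, ents = self._gold_spans(ex)
        pairs = enumerate_candidates(list(trig.values()), list(ents.values()))
        evmap = {ev.id: ev for ev in ex.events}
        gold = {}
        for ev in ex.events:
            if ev.trigger_id not in trig:
                continue
            for role, filler in ev.args:
                if filler in evmap:
                    fspan = trig.get(evmap[filler].trigger_id)
                elif filler in ents:
                    fspan = ents[filler]
                else:
                    fspan = trig.get(filler)
                if fspan is not None:
                    gold[(trig[ev.trigger_id], fspan)] = role
        idx = [
            self._role_index.get(gold.get((p.trigger, p.candidate), "None"))
            for p in pairs
        ]
        return pairs, idx

    def _decode(self, ex: SentenceExample, O, soft):
        """Greedy argmax decoding of one sentence into triggers and events."""
        token_spans = ex.graph.token_spans
        tags = [self.trigger_labels_[i] for i in soft.data.argmax(axis=1)]
        trig_spans, trig_records = [], []
        for k, (start, end, typ) in enumerate(bio_to_spans(tags, token_spans)):
            ts = _char_span_to_tokens(start, end, typ, token_spans)
            trig_spans.append(ts)
            surface = " ".join(
                ex.graph.surfaces[i] for i in range(ts.first, ts.last + 1)
            )
            trig_records.append((ts, start, end, surface))
        _, gold_ents = self._gold_spans(ex)
        ent_ids = {span: eid for eid, span in gold_ents.items()}
        pairs = enumerate_candidates(trig_spans, list(ent_ids))
        dists = self.role_distributions(O, soft, pairs)
        decisions, pair_probs = [], []
        if dists is not None:
            none_idx = self._role_index["None"]
            for pair, row in zip(pairs, dists.data):
                k = int(row.argmax())
                pair_probs.append(
                    (pair, {lab: float(p) for lab, p in zip(self.role_labels_, row)})
                )
                if k != none_idx:
                    decisions.append((pair, self.role_labels_[k], float(row[k])))
        events = assemble_events(trig_spans, decisions, entity_ids=ent_ids)
        # char-level trigger records with the local TR ids the events reference
        order = sorted(set(trig_spans), key=lambda s: (s.first, s.last, s.type))
        local_id = {t: f"TR{i + 1}" for i, t in enumerate(order)}
        triggers = [
            TriggerSpan(local_id[ts], ts.type, start, end, surface)
            for ts, start, end, surface in trig_records
        ]
        return {
            "tags": tags,
            "trigger_spans": trig_spans,
            "triggers": triggers,
            "events": events,
            "pairs": pair_probs,
        }

    # ---------------------------------------------------------------- sklearn
    def fit(self, X, y=None):
        """Train on a list of :class:`SentenceExample` carrying gold labels."""
        X = list(X)
        self._build_from_examples(X)
        self._velocity = {k: np.zeros_like(p.data) for k, p in self.params_.items()}
        rng = np.random.default_rng(np.random.SeedSequence([self.seed & 0x7FFFFFFF, 1]))
        order = sorted(range(len(X)), key=lambda i: (len(X[i]), i))
        batches = [order[i : i + self.batch_size] for i in range(0, len(order), self.batch_size)]
        cfg = DiceConfig(self.dice_lambda, self.dice_beta)
        self.loss_curve_ = []
        self.n_iter_ = 0

        gold_cache = {}
        for i in order:
            ex = X[i]
            tgold = [self._trig_index.get(t, 0) for t in ex.graph.trigger_bio]
            pairs, rgold = self._gold_pairs(ex)
            gold_cache[i] = (tgold, pairs, rgold)

        for epoch in range(self.epochs):
            epoch_loss, n_seen = 0.0, 0
            for batch in batches:
                tri_dists, tri_gold, role_dists, role_gold = [], [], [], []
                for i in batch:
                    ex = X[i]
                    if len(ex) == 0:
                        continue
                    tgold, pairs, rgold = gold_cache[i]
                    O, soft = self._forward(ex, train=True, rng=rng)
                    tri_dists.append(soft)
                    tri_gold.append(tgold)
                    role_dists.append(self.role_distributions(O, soft, pairs))
                    role_gold.append(rgold)
                if not tri_dists:
                    continue
                loss = joint_loss(tri_dists, tri_gold, role_dists, role_gold, cfg, kind=self.loss)
                if not np.isfinite(loss.data):
                    raise NonFiniteLoss(f"loss became non-finite at epoch {epoch + 1}")
                loss.backward()
                self._sgd_step()
                epoch_loss += float(loss.data) * len(tri_dists)
                n_seen += len(tri_dists)
            self.loss_curve_.append(epoch_loss / max(n_seen, 1))
            self.n_iter_ = epoch + 1
            if self.verbose:
                print(f"epoch {epoch + 1}: loss {self.loss_curve_[-1]:.4f}")
            if (
                self.early_stop_f1 is not None
                and (epoch + 1) % self.check_every == 0
                and self._train_f1(X) >= self.early_stop_f1
            ):
                break
        return self

    def _sgd_step(self):
        gsq = 0.0
        for p in self.params_.values():
            if p.grad is not None:
                gsq += float((p.grad**2).sum())
        scale = 1.0
        gnorm = float(np.sqrt(gsq))
        if self.max_grad_norm and gnorm > self.max_grad_norm:
            scale = self.max_grad_norm / gnorm
        if not hasattr(self, "_velocity"):
            self._velocity = {k: np.zeros_like(p.data) for k, p in self.params_.items()}
        for k, p in self.params_.items():
            if p.grad is not None:
                v = self._velocity[k]
                v *= self.momentum
                v += scale * p.grad
                p.data -= self.learning_rate * v
            p.zero_grad()

    def _train_f1(self, X):
        from .metrics import evaluate_examples

        report = evaluate_examples(X, self.predict(X))
        return min(report["trigger"]["all"]["f1"], report["event"]["all"]["f1"]) / 100.0

    def predict(self, X):
        """Decode each sentence example into predicted triggers and events."""
        out = []
        for ex in X:
            if len(ex) == 0:
                out.append({"tags": [], "trigger_spans": [], "triggers": [],
                            "events": [], "pairs": []})
                continue
            O, soft = self._forward(ex, train=False)
            out.append(self._decode(ex, O, soft))
        return out

    def score(self, X, y=None):
        """Event-extraction micro F1 (0..1) against the examples' gold events."""
        from .metrics import evaluate_examples

        return evaluate_examples(X, self.predict(X))["event"]["all"]["f1"] / 100.0

    # ------------------------------------------------------------- inspection
    def trigger_distribution(self, ex: SentenceExample) -> np.ndarray:
        """Row-stochastic per-token BIO trigger distribution (n x |V_tri|)."""
        _, soft = self._forward(ex, train=False)
        return soft.data

    def attention_scores(self, ex: SentenceExample) -> np.ndarray:
        """Head-averaged n x n attention score matrix (each row sums to 1)."""
        _, A = self.embed_tokens(ex.graph)
        S = self.gcn_(A, ex.graph)
        return self.attention_.averaged_scores(S)

    # ----------------------------------------------------------- serialization
    def save(self, path):
        """Serialize fitted weights and vocabularies to an .npz checkpoint."""
        meta = {
            "params": self.get_params(),
            "pos_vocab": self.pos_vocab_,
            "entity_vocab": self.entity_vocab_,
            "trigger_types": sorted({lab[2:] for lab in self.trigger_labels_ if lab != "O"}),
        }
        arrays = {k: v.data for k, v in self.params_.items()}
        np.savez(path, __meta__=np.array(json.dumps(meta)), **arrays)

    @classmethod
    def load(cls, path):
        blob = np.load(path, allow_pickle=False)
        meta = json.loads(str(blob["__meta__"]))
        est = cls(**meta["params"])
        est._build(meta["pos_vocab"], meta["entity_vocab"], meta["trigger_types"])
        for k in est.params_:
            est.params_[k].data = np.asarray(blob[k], dtype=np.float64)
        est.loss_curve_ = []
        est.n_iter_ = 0
        return est
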