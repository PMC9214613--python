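"""Seed-deterministic toy corpora: standoff triples plus CoNLL-U parses.

The generator emulates the shape of a multilevel biomedical event corpus at
toy scale: templated sentences mentioning typed entities, single- or
multi-token nominal triggers, events whose arguments follow a fixed
type-level role rule, nested events (a trigger filling another event's
Theme), and a projective dependency tree per sentence.

Nesting is single-level: a regulatory trigger (Regulation,
Positive_regulation, Negative_regulation or Planned_process) whose Theme is
a simple event, which in turn takes an entity Theme — the canonical
regulation-of-expression pattern.  Within any sentence the correct role of a
(trigger, candidate) pair is therefore a deterministic function of the two
types alone; deeper chains are deliberately not generated because, with both
directions of every trigger pair enumerated, a depth>=3 type-deterministic
chain is provably not linearly separable for the pair classifier, so such a
corpus could not serve as a learnability fixture.  A sentence's chain is
nested with probability nesting_prob/(1-nesting_prob), which makes the
fraction of *events* that are nested converge to ``nesting_prob`` (each
nested event brings one simple inner event along).  The regulatory event
takes the sentence's Cause drug when one is present.

Not emulated: lexical/syntactic diversity of real text, parser errors,
cross-sentence events, discontinuous or overlapping annotations.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .standoff import AnnotatedDocument, EntitySpan, EventRecord, TriggerSpan

__all__ = ["GeneratorConfig", "GeneratedCorpus", "generate", "write_corpus", "DEFAULT_ROLE_RULE"]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------- toy schema

ENTITY_LEXICON = {
    "Gene": [("IL-8",), ("TNF-alpha",), ("VEGF",), ("STAT3",), ("p53",)],
    "Cell": [("endothelial", "cells"), ("fibroblasts",), ("lymphocytes",)],
    "Drug": [("aspirin",), ("spironolactone",), ("tamoxifen",)],
}

# simple event types with their Theme entity type
SIMPLE_TRIGGERS = {
    "Gene_expression": {"theme": "Gene", "words": [("expression",), ("overexpression",)]},
    "Blood_vessel_development": {
        "theme": "Cell",
        "words": [("angiogenesis",), ("blood", "vessel", "development")],
    },
}

# nesting-capable types: their Theme may be another (simple) event
NESTING_HIERARCHY = ["Regulation", "Positive_regulation", "Negative_regulation", "Planned_process"]
NESTING_WORDS = {
    "Regulation": [("regulation",), ("modulation",)],
    "Positive_regulation": [("activation",), ("induction",)],
    "Negative_regulation": [("inhibition",), ("suppression",)],
    "Planned_process": [("treatment",), ("administration",)],
}

FILLER_SENTENCES = [
    # (tokens, pos, arcs as (head, dep)), optionally with an entity slot "~ENT~"
    (["the", "~ENT~", "levels", "were", "measured", "."],),
    (["no", "significant", "change", "was", "seen", "."],),
    (["~ENT~", "was", "analyzed", "in", "this", "study", "."],),
]

WRAP_VERBS = ["observed", "detected", "reported", "confirmed"]

POS_OF = {"of": "IN", "by": "IN", "the": "DT", "we": "PRP", ".": "PU"}


def default_role_rule() -> dict:
    """(trigger type, candidate kind) -> role; pairs absent from the map are None.

    Candidate kind is an entity type for entity candidates and the trigger
    type for event candidates.
    """
    rule = {}
    for ttype, info in SIMPLE_TRIGGERS.items():
        rule[(ttype, info["theme"])] = "Theme"
    for ttype in NESTING_HIERARCHY:
        for simple in SIMPLE_TRIGGERS:
            rule[(ttype, simple)] = "Theme"
        rule[(ttype, "Drug")] = "Cause"
    return rule


DEFAULT_ROLE_RULE = default_role_rule()


@dataclass
class GeneratorConfig:
    n_docs: int = 10
    sentences_per_doc: int = 5
    entity_types: tuple = tuple(ENTITY_LEXICON)
    trigger_types: tuple = tuple(SIMPLE_TRIGGERS) + tuple(NESTING_HIERARCHY)
    nesting_types: tuple = tuple(NESTING_HIERARCHY)
    nesting_prob: float = 0.3
    multi_token_trigger_prob: float = 0.3
    cause_prob: float = 0.5
    distractor_prob: float = 0.2
    role_rule: dict | None = None  # informational; defaults to DEFAULT_ROLE_RULE
    seed: int = 0

    @property
    def hierarchy(self):
        return [t for t in NESTING_HIERARCHY if t in self.nesting_types and t in self.trigger_types]

    @property
    def simple_types(self):
        return [t for t in SIMPLE_TRIGGERS if t in self.trigger_types]

    def validate(self):
        for name in ("multi_token_trigger_prob", "cause_prob", "distractor_prob"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must be in [0,1], got {v}")
        if not (0.0 <= self.nesting_prob <= 0.5):
            raise ConfigError(
                "nesting_prob must be in [0, 0.5]: with single-level nesting every "
                "nested event is paired with the simple event filling its Theme, so "
                "at most half of all events can be nested"
            )
        if self.n_docs < 1 or self.sentences_per_doc < 1:
            raise ConfigError("need at least one document and one sentence per document")
        if self.nesting_prob > 0 and not self.hierarchy:
            raise ConfigError("nesting_prob > 0 requires a nonempty nesting-capable type set")
        if not self.simple_types:
            raise ConfigError("at least one simple trigger type is required")
        unknown = set(self.trigger_types) - set(SIMPLE_TRIGGERS) - set(NESTING_HIERARCHY)
        if unknown:
            raise ConfigError(f"trigger types outside the template lexicon: {sorted(unknown)}")
        for t in self.simple_types:
            if SIMPLE_TRIGGERS[t]["theme"] not in self.entity_types:
                raise ConfigError(f"{t} needs entity type {SIMPLE_TRIGGERS[t]['theme']}")
        if self.role_rule is None:
            self.role_rule = dict(DEFAULT_ROLE_RULE)
        return self


@dataclass
class GeneratedCorpus:
    docs: list  # of AnnotatedDocument
    conllu: str
    log: dict  # emission log with exact gold counts


# ------------------------------------------------------------ sentence pieces


@dataclass
class _Sent:
    tokens: list = field(default_factory=list)  # surfaces
    pos: list = field(default_factory=list)
    arcs: list = field(default_factory=list)  # (head, dep), local indices
    entities: list = field(default_factory=list)  # (first_tok, last_tok, type)
    triggers: list = field(default_factory=list)  # (first_tok, last_tok, type)
    events: list = field(default_factory=list)  # (trigger_idx, [(role, ("T", i) | ("E", j))])

    def add(self, surface, pos=None):
        self.tokens.append(surface)
        self.pos.append(pos or POS_OF.get(surface, "NN"))
        return len(self.tokens) - 1


def _add_np(sent: _Sent, words) -> int:
    """Append a noun phrase; internal tokens attach to the last (head) token."""
    idxs = [sent.add(w, "NN") for w in words]
    for i in idxs[:-1]:
        sent.arcs.append((idxs[-1], i))
    return idxs[-1]


def _add_entity(sent: _Sent, etype: str, rng) -> tuple[int, int]:
    words = ENTITY_LEXICON[etype][rng.integers(len(ENTITY_LEXICON[etype]))]
    first = len(sent.tokens)
    _add_np(sent, words)
    last = len(sent.tokens) - 1
    sent.entities.append((first, last, etype))
    return first, last


def _pick_trigger_words(ttype: str, rng, multi_prob: float):
    options = SIMPLE_TRIGGERS[ttype]["words"] if ttype in SIMPLE_TRIGGERS else NESTING_WORDS[ttype]
    multi = [w for w in options if len(w) > 1]
    single = [w for w in options if len(w) == 1]
    if multi and rng.random() < multi_prob:
        return multi[rng.integers(len(multi))]
    pool = single or multi
    return pool[rng.integers(len(pool))]


def _add_trigger(sent: _Sent, ttype: str, rng, multi_prob: float) -> int:
    words = _pick_trigger_words(ttype, rng, multi_prob)
    first = len(sent.tokens)
    head = _add_np(sent, words)
    sent.triggers.append((first, len(sent.tokens) - 1, ttype))
    return head


def _event_chain(sent: _Sent, cfg: GeneratorConfig, rng) -> tuple[int, int]:
    """Emit one (possibly nested) event chain; returns (phrase head, outer event idx)."""
    # one nesting level at most: a regulatory event whose Theme is a simple
    # event.  Drawing "nested" with probability p/(1-p) per chain makes the
    # fraction of nested events among all events equal nesting_prob (a chain
    # with a regulatory layer holds one nested + one simple event).
    hierarchy = cfg.hierarchy
    p = cfg.nesting_prob
    p_chain = 1.0 if p >= 0.5 else p / (1.0 - p)
    chain_types = []
    if hierarchy and rng.random() < p_chain:
        chain_types = [hierarchy[rng.integers(len(hierarchy))]]
    simple_type = cfg.simple_types[rng.integers(len(cfg.simple_types))]

    heads, trig_idx = [], []
    for ttype in chain_types + [simple_type]:
        if heads:
            of = sent.add("of")
        head = _add_trigger(sent, ttype, rng, cfg.multi_token_trigger_prob)
        if heads:
            sent.arcs.append((heads[-1], head))  # nmod: inner phrase under outer trigger
            sent.arcs.append((head, of))  # case marker under its noun
        heads.append(head)
        trig_idx.append(len(sent.triggers) - 1)

    # theme entity of the innermost (simple) event
    of = sent.add("of")
    efirst, elast = _add_entity(sent, SIMPLE_TRIGGERS[simple_type]["theme"], rng)
    sent.arcs.append((heads[-1], elast))
    sent.arcs.append((elast, of))
    ent_idx = len(sent.entities) - 1

    # optional shared Cause drug for the regulatory events
    drug_idx = None
    if chain_types and rng.random() < cfg.cause_prob:
        by = sent.add("by")
        dfirst, dlast = _add_entity(sent, "Drug", rng)
        sent.arcs.append((heads[0], dlast))
        sent.arcs.append((dlast, by))
        drug_idx = len(sent.entities) - 1

    # events, innermost first so fillers exist before use
    inner_event = None
    for k in range(len(trig_idx) - 1, -1, -1):
        args = []
        if k == len(trig_idx) - 1:
            args.append(("Theme", ("T", ent_idx)))
        else:
            args.append(("Theme", ("E", inner_event)))
            if drug_idx is not None:
                args.append(("Cause", ("T", drug_idx)))
        sent.events.append((trig_idx[k], args))
        inner_event = len(sent.events) - 1
    return heads[0], inner_event


def _event_sentence(cfg: GeneratorConfig, rng) -> _Sent:
    sent = _Sent()
    style = rng.integers(2)
    verb = WRAP_VERBS[rng.integers(len(WRAP_VERBS))]
    if style == 0:
        # "the <phrase> was <verb> ."
        the = sent.add("the")
        head, _ = _event_chain(sent, cfg, rng)
        was = sent.add("was", "VB")
        v = sent.add(verb, "VB")
        dot = sent.add(".")
        sent.arcs += [(head, the), (v, head), (v, was), (v, dot)]
    else:
        # "we <verb> <phrase> ."
        we = sent.add("we")
        v = sent.add(verb, "VB")
        head, _ = _event_chain(sent, cfg, rng)
        dot = sent.add(".")
        sent.arcs += [(v, we), (v, head), (v, dot)]
    return sent


def _distractor_sentence(cfg: GeneratorConfig, rng) -> _Sent:
    sent = _Sent()
    mentionable = [t for t in ("Gene", "Drug") if t in cfg.entity_types]
    style = rng.integers(3) if mentionable else 1
    if style == 0:
        the = sent.add("the")
        efirst, elast = _add_entity(sent, mentionable[rng.integers(len(mentionable))], rng)
        lv = sent.add("levels", "NN")
        were = sent.add("were", "VB")
        v = sent.add("measured", "VB")
        dot = sent.add(".")
        sent.arcs += [(lv, the), (lv, elast), (v, lv), (v, were), (v, dot)]
    elif style == 1:
        no = sent.add("no", "DT")
        sig = sent.add("significant", "JJ")
        ch = sent.add("change", "NN")
        was = sent.add("was", "VB")
        v = sent.add("seen", "VB")
        dot = sent.add(".")
        sent.arcs += [(ch, no), (ch, sig), (v, ch), (v, was), (v, dot)]
    elif style == 2:
        efirst, elast = _add_entity(sent, mentionable[rng.integers(len(mentionable))], rng)
        was = sent.add("was", "VB")
        v = sent.add("analyzed", "VB")
        dot = sent.add(".")
        sent.arcs += [(v, elast), (v, was), (v, dot)]
    return sent


# ----------------------------------------------------------------- generation


def generate(cfg: GeneratorConfig) -> GeneratedCorpus:
    """Generate a corpus; byte-identical output for a fixed config."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    docs, conllu_chunks = [], []
    log = {"docs": {}, "sentences": [], "totals": {"entities": 0, "triggers": 0, "events": 0, "nested_events": 0}}

    for d in range(cfg.n_docs):
        doc_id = f"doc{d:04d}"
        sents = []
        for _ in range(cfg.sentences_per_doc):
            if rng.random() < cfg.distractor_prob:
                sents.append(_distractor_sentence(cfg, rng))
            else:
                sents.append(_event_sentence(cfg, rng))

        # assemble document text and character offsets (sentences joined by \n)
        text_parts, offset = [], 0
        entities, triggers, events = [], [], []
        tid, eid = 0, 0
        doc_nested = 0
        for s_i, sent in enumerate(sents):
            spans, cur = [], offset
            for tok in sent.tokens:
                spans.append((cur, cur + len(tok)))
                cur += len(tok) + 1
            sent_text = " ".join(sent.tokens)
            text_parts.append(sent_text)

            ent_ids, trig_ids = [], []
            for first, last, etype in sent.entities:
                tid += 1
                start, end = spans[first][0], spans[last][1]
                entities.append(
                    EntitySpan(f"T{tid}", etype, start, end, " ".join(sent.tokens[first : last + 1]))
                )
                ent_ids.append(f"T{tid}")
            for first, last, ttype in sent.triggers:
                tid += 1
                start, end = spans[first][0], spans[last][1]
                triggers.append(
                    TriggerSpan(f"T{tid}", ttype, start, end, " ".join(sent.tokens[first : last + 1]))
                )
                trig_ids.append(f"T{tid}")
            local_event_ids = []
            for trig_local, args in sent.events:
                eid += 1
                resolved = []
                nested = False
                for role, (kind, idx) in args:
                    if kind == "T":
                        resolved.append((role, ent_ids[idx]))
                    else:
                        resolved.append((role, local_event_ids[idx]))
                        if role == "Theme":
                            nested = True
                ttype = next(t.type for t in triggers if t.id == trig_ids[trig_local])
                events.append(EventRecord(f"E{eid}", ttype, trig_ids[trig_local], tuple(resolved)))
                local_event_ids.append(f"E{eid}")
                if nested:
                    doc_nested += 1

            # CoNLL-U block with document-level character offsets in MISC
            lines = [f"# doc_id = {doc_id}", f"# sent_id = {doc_id}.{s_i}", f"# text = {sent_text}"]
            head_of = {dep: head for head, dep in sent.arcs}
            root = next(i for i in range(len(sent.tokens)) if i not in head_of)
            for i, tok in enumerate(sent.tokens):
                head = head_of.get(i, -1) + 1 if i in head_of else 0
                misc = f"start_char={spans[i][0]}|end_char={spans[i][1]}"
                deprel = "root" if head == 0 else "dep"
                lines.append(
                    f"{i + 1}\t{tok}\t_\t{sent.pos[i]}\t_\t_\t{head}\t{deprel}\t_\t{misc}"
                )
            conllu_chunks.append("\n".join(lines) + "\n\n")
            log["sentences"].append(
                {"doc_id": doc_id, "sent_id": f"{doc_id}.{s_i}", "n_tokens": len(sent.tokens),
                 "arcs": [[h, dep] for h, dep in sent.arcs]}
            )
            offset = cur  # cur already includes the separator position

        doc = AnnotatedDocument(
            doc_id=doc_id,
            text="\n".join(text_parts),
            entities=entities,
            triggers=triggers,
            events=events,
        ).validate()
        docs.append(doc)
        log["docs"][doc_id] = {
            "entities": len(entities),
            "triggers": len(triggers),
            "events": len(events),
            "nested_events": doc_nested,
        }
        for key, val in (("entities", len(entities)), ("triggers", len(triggers)),
                         ("events", len(events)), ("nested_events", doc_nested)):
            log["totals"][key] += val

    return GeneratedCorpus(docs=docs, conllu="".join(conllu_chunks), log=log)


def write_corpus(corpus: GeneratedCorpus, out_dir) -> None:
    """Write standoff triples, corpus.conllu and the emission log to a directory."""
    from .standoff import write_standoff_dir

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for doc in corpus.docs:
        write_standoff_dir(doc, out_dir)
    (out_dir / "corpus.conllu").write_text(corpus.conllu, encoding="utf-8")
    (out_dir / "emission_log.json").write_text(json.dumps(corpus.log, indent=1), encoding="utf-8")
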