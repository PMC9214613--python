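"""Assemble model-ready sentence examples from standoff + CoNLL-U inputs.

The model is sentence-level: entities, triggers and events are attached to
the sentence whose token span covers them, and events whose participants
cross a sentence boundary are dropped (and counted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

from .graphs import SentenceGraph, build_graph, read_conllu
from .standoff import AnnotatedDocument, read_standoff, spans_to_bio

__all__ = ["SentenceExample", "load_corpus", "sentences_from_doc"]


@dataclass
class SentenceExample:
    """One sentence with its graph, gold annotations, and provenance."""

    doc_id: str
    sent_id: str
    graph: SentenceGraph
    entities: list = field(default_factory=list)  # EntitySpan, document offsets
    triggers: list = field(default_factory=list)  # TriggerSpan (gold)
    events: list = field(default_factory=list)  # EventRecord, intra-sentence

    def __len__(self):
        return len(self.graph)


def sentences_from_doc(doc: AnnotatedDocument, conllu_sentences) -> tuple[list, int]:
    """Split a document's annotations over its parsed sentences.

    Returns (examples, n_cross_sentence_events_dropped).
    """
    examples = []
    dropped = 0
    ranges = []
    for sent in conllu_sentences:
        spans = sent["spans"]
        if any(s is None for s in spans):
            raise ValueError(f"{doc.doc_id}: sentence without character offsets")
        ranges.append((spans[0][0], spans[-1][1]))

    def sent_of(start, end):
        for i, (lo, hi) in enumerate(ranges):
            if start >= lo and end <= hi:
                return i
        return None

    ent_sent = {e.id: sent_of(e.start, e.end) for e in doc.entities}
    trig_sent = {t.id: sent_of(t.start, t.end) for t in doc.triggers}
    evmap = doc.event_map()

    def event_sent(ev, seen=()):
        s = trig_sent.get(ev.trigger_id)
        for _, filler in ev.args:
            if filler in evmap:
                fs = event_sent(evmap[filler], seen + (ev.id,))
            else:
                fs = ent_sent.get(filler, trig_sent.get(filler))
            if fs != s:
                return None
        return s

    ev_sent = {ev.id: event_sent(ev) for ev in doc.events}

    for i, sent in enumerate(conllu_sentences):
        token_spans = sent["spans"]
        ents = [e for e in doc.entities if ent_sent[e.id] == i]
        trigs = [t for t in doc.triggers if trig_sent[t.id] == i]
        evs = [ev for ev in doc.events if ev_sent[ev.id] == i]
        graph = build_graph(
            list(zip(sent["tokens"], token_spans)),
            sent["pos"],
            sent["arcs"],
            entity_bio=spans_to_bio(token_spans, ents),
            trigger_bio=spans_to_bio(token_spans, trigs),
        )
        examples.append(
            SentenceExample(
                doc_id=doc.doc_id,
                sent_id=sent["meta"].get("sent_id", f"{doc.doc_id}.{i}"),
                graph=graph,
                entities=ents,
                triggers=trigs,
                events=evs,
            )
        )
    dropped = sum(1 for ev in doc.events if ev_sent[ev.id] is None)
    return examples, dropped


def load_corpus(directory, conllu_path=None):
    """Load every standoff triple in a directory plus its CoNLL-U parses.

    Returns (docs, examples, n_dropped_cross_sentence_events).  The CoNLL-U
    file defaults to ``<directory>/corpus.conllu``; sentences are matched to
    documents through their ``# doc_id`` comments.
    """
    directory = Path(directory)
    conllu_path = Path(conllu_path) if conllu_path else directory / "corpus.conllu"
    sentences = read_conllu(conllu_path)
    by_doc: dict[str, list] = {}
    for sent in sentences:
        doc_id = sent["meta"].get("doc_id")
        if doc_id is None:
            raise ValueError("corpus CoNLL-U sentences need '# doc_id =' comments")
        by_doc.setdefault(doc_id, []).append(sent)

    docs, examples, dropped = [], [], 0
    for txt in sorted(directory.glob("*.txt")):
        doc = read_standoff(txt, txt.with_suffix(".a1"), txt.with_suffix(".a2"))
        docs.append(doc)
        ex, d = sentences_from_doc(doc, by_doc.get(doc.doc_id, []))
        examples.extend(ex)
        dropped += d
    return docs, examples, dropped
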