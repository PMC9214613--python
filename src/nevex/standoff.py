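"""BioNLP-ST style standoff annotation: reading, validation, writing, BIO tags.

A document is a plain-text file (.txt) plus entity annotations (.a1) and
trigger/event annotations (.a2).  Offsets are 0-based, end-exclusive, over
Unicode code points, so ``text[start:end]`` must equal the recorded surface
string.  Entity and trigger annotations are ``T``-lines::

    T1<TAB>Protein 0 9<TAB>TNF-alpha

and events are ``E``-lines whose first field binds the event type to its
trigger and whose remaining fields are role:filler pairs, where a filler may
be an entity, or another event (nesting)::

    E1<TAB>Positive_regulation:T3 Theme:E2 Cause:T1
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "EntitySpan",
    "TriggerSpan",
    "EventRecord",
    "AnnotatedDocument",
    "StandoffError",
    "OffsetMismatch",
    "DanglingReference",
    "CyclicEvent",
    "Misaligned",
    "read_standoff",
    "write_standoff",
    "spans_to_bio",
    "bio_to_spans",
    "validate_bio",
]


class StandoffError(ValueError):
    """Base class for standoff validation failures."""


class OffsetMismatch(StandoffError):
    """Recorded surface string differs from the text slice at its offsets."""


class DanglingReference(StandoffError):
    """A trigger or argument id does not resolve within the document."""


class CyclicEvent(StandoffError):
    """The event reference graph contains a cycle."""


class Misaligned(StandoffError):
    """A character span does not align with token boundaries."""


@dataclass(frozen=True)
class EntitySpan:
    id: str
    type: str
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class TriggerSpan:
    id: str
    type: str
    start: int
    end: int
    surface: str


@dataclass(frozen=True)
class EventRecord:
    id: str
    type: str
    trigger_id: str
    args: tuple  # of (role, filler_id); filler is a T (entity) or E (event) id


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    entities: list = field(default_factory=list)
    triggers: list = field(default_factory=list)
    events: list = field(default_factory=list)

    def entity_map(self):
        return {e.id: e for e in self.entities}

    def trigger_map(self):
        return {t.id: t for t in self.triggers}

    def event_map(self):
        return {ev.id: ev for ev in self.events}

    def validate(self) -> "AnnotatedDocument":
        n = len(self.text)
        for span in list(self.entities) + list(self.triggers):
            if not (0 <= span.start < span.end <= n):
                raise OffsetMismatch(
                    f"{self.doc_id}:{span.id}: span [{span.start},{span.end}) "
                    f"outside text of length {n}"
                )
            if self.text[span.start : span.end] != span.surface:
                raise OffsetMismatch(
                    f"{self.doc_id}:{span.id}: surface {span.surface!r} != "
                    f"text slice {self.text[span.start:span.end]!r}"
                )
        tmap = self.trigger_map()
        emap = self.entity_map()
        evmap = self.event_map()
        for ev in self.events:
            if ev.trigger_id not in tmap:
                raise DanglingReference(f"{self.doc_id}:{ev.id}: trigger {ev.trigger_id}")
            for role, filler in ev.args:
                if filler not in emap and filler not in evmap and filler not in tmap:
                    raise DanglingReference(f"{self.doc_id}:{ev.id}: {role}:{filler}")
        _check_acyclic(self.events)
        return self


def _check_acyclic(events: Sequence[EventRecord]):
    """DFS cycle check over event->event argument references."""
    evmap = {ev.id: ev for ev in events}
    state = {}  # id -> 1 visiting, 2 done

    def visit(eid, stack):
        if state.get(eid) == 2:
            return
        if state.get(eid) == 1:
            raise CyclicEvent(f"event reference cycle through {eid}")
        state[eid] = 1
        for _, filler in evmap[eid].args:
            if filler == eid:
                raise CyclicEvent(f"event {eid} fills its own argument slot")
            if filler in evmap:
                visit(filler, stack + [filler])
        state[eid] = 2

    for ev in events:
        visit(ev.id, [ev.id])


def event_topological_order(events: Sequence[EventRecord]) -> list:
    """Events ordered so every event-typed filler precedes its user."""
    evmap = {ev.id: ev for ev in events}
    order, done = [], set()

    def visit(ev):
        if ev.id in done:
            return
        done.add(ev.id)
        for _, filler in ev.args:
            if filler in evmap:
                visit(evmap[filler])
        order.append(ev)

    for ev in events:
        visit(ev)
    return order


# --------------------------------------------------------------------- parsing


def _parse_t_line(line: str, lineno: int, path: str):
    try:
        tid, mid, surface = line.rstrip("\n").split("\t")
        typ, start, end = mid.split(" ")
        return tid, typ, int(start), int(end), surface
    except ValueError as exc:
        raise StandoffError(f"{path}:{lineno}: malformed T line: {line!r}") from exc


def _parse_e_line(line: str, lineno: int, path: str) -> EventRecord:
    try:
        eid, rest = line.rstrip("\n").split("\t")
        fields = rest.split(" ")
        etype, trigger_id = fields[0].split(":")
        args = []
        for f in fields[1:]:
            if not f:
                continue
            role, filler = f.split(":")
            args.append((role, filler))
        return EventRecord(id=eid, type=etype, trigger_id=trigger_id, args=tuple(args))
    except ValueError as exc:
        raise StandoffError(f"{path}:{lineno}: malformed E line: {line!r}") from exc


def parse_standoff(doc_id: str, text: str, a1: str, a2: str | None = None) -> AnnotatedDocument:
    """Build and validate a document from standoff file contents."""
    doc = AnnotatedDocument(doc_id=doc_id, text=text)
    for lineno, line in enumerate(a1.splitlines(), 1):
        if not line.strip() or line.startswith("#"):
            continue
        tid, typ, start, end, surface = _parse_t_line(line, lineno, f"{doc_id}.a1")
        doc.entities.append(EntitySpan(tid, typ, start, end, surface))
    if a2:
        for lineno, line in enumerate(a2.splitlines(), 1):
            if not line.strip() or line.startswith(("#", "*", "M")):
                continue
            if line.startswith("T"):
                tid, typ, start, end, surface = _parse_t_line(line, lineno, f"{doc_id}.a2")
                doc.triggers.append(TriggerSpan(tid, typ, start, end, surface))
            elif line.startswith("E"):
                doc.events.append(_parse_e_line(line, lineno, f"{doc_id}.a2"))
    return doc.validate()


def read_standoff(txt_path, a1_path, a2_path=None) -> AnnotatedDocument:
    """Read a standoff triple from disk; ``a2_path`` may be None or missing
    (prediction mode)."""
    txt_path = Path(txt_path)
    text = txt_path.read_text(encoding="utf-8")
    a1 = Path(a1_path).read_text(encoding="utf-8") if Path(a1_path).exists() else ""
    a2 = None
    if a2_path is not None and Path(a2_path).exists():
        a2 = Path(a2_path).read_text(encoding="utf-8")
    doc_id = txt_path.stem
    return parse_standoff(doc_id, text, a1, a2)


def write_standoff(doc: AnnotatedDocument) -> tuple[str, str, str]:
    """Serialize a document to (txt, a1, a2) contents.

    Event lines are emitted in topological order so that every referenced
    event id appears before its use; output is deterministic.
    """
    doc.validate()
    a1_lines = [
        f"{e.id}\t{e.type} {e.start} {e.end}\t{e.surface}" for e in doc.entities
    ]
    a2_lines = [
        f"{t.id}\t{t.type} {t.start} {t.end}\t{t.surface}" for t in doc.triggers
    ]
    for ev in event_topological_order(doc.events):
        parts = [f"{ev.type}:{ev.trigger_id}"] + [f"{r}:{f}" for r, f in ev.args]
        a2_lines.append(f"{ev.id}\t{' '.join(parts)}")
    a1 = "\n".join(a1_lines) + ("\n" if a1_lines else "")
    a2 = "\n".join(a2_lines) + ("\n" if a2_lines else "")
    return doc.text, a1, a2


def write_standoff_dir(doc: AnnotatedDocument, out_dir) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    text, a1, a2 = write_standoff(doc)
    (out_dir / f"{doc.doc_id}.txt").write_text(text, encoding="utf-8")
    (out_dir / f"{doc.doc_id}.a1").write_text(a1, encoding="utf-8")
    (out_dir / f"{doc.doc_id}.a2").write_text(a2, encoding="utf-8")


# ------------------------------------------------------------------- BIO tags


def spans_to_bio(tokens: Sequence[tuple[int, int]], spans: Iterable) -> list[str]:
    """Encode typed character spans as per-token BIO tags.

    ``tokens`` are (start, end) character spans, sorted and non-overlapping;
    ``spans`` are objects with .start/.end/.type.  The first token of a span
    gets ``B-type``, the rest ``I-type``.  A span whose boundary cuts through
    a token, or that does not cover a contiguous token run, raises
    :class:`Misaligned`.
    """
    tags = ["O"] * len(tokens)
    starts = [s for s, _ in tokens]
    ends = [e for _, e in tokens]
    for span in spans:
        covered = [
            i for i, (ts, te) in enumerate(tokens) if ts < span.end and te > span.start
        ]
        if not covered:
            raise Misaligned(f"span [{span.start},{span.end}) covers no token")
        first, last = covered[0], covered[-1]
        if covered != list(range(first, last + 1)):
            raise Misaligned(f"span [{span.start},{span.end}) is discontiguous over tokens")
        if starts[first] != span.start or ends[last] != span.end:
            raise Misaligned(
                f"span [{span.start},{span.end}) splits token boundaries "
                f"[{starts[first]},{ends[last]})"
            )
        if any(tags[i] != "O" for i in covered):
            raise Misaligned(f"span [{span.start},{span.end}) overlaps a previous span")
        tags[first] = f"B-{span.type}"
        for i in covered[1:]:
            tags[i] = f"I-{span.type}"
    return tags


def bio_to_spans(tags: Sequence[str], tokens: Sequence[tuple[int, int]]) -> list[tuple[int, int, str]]:
    """Decode BIO tags to (start_char, end_char, type) spans.

    Lenient on predicted sequences: an orphan ``I-t`` (no preceding B-t/I-t of
    the same type) opens a new span rather than being dropped.
    """
    if len(tags) != len(tokens):
        raise ValueError("tags and tokens must be aligned")
    spans = []
    cur_type, cur_first, cur_last = None, None, None
    for i, tag in enumerate(tags):
        if tag == "O":
            prefix, typ = "O", None
        else:
            prefix, typ = tag.split("-", 1)
        continues = prefix == "I" and cur_type == typ
        if continues:
            cur_last = i
            continue
        if cur_type is not None:
            spans.append((tokens[cur_first][0], tokens[cur_last][1], cur_type))
            cur_type = None
        if prefix in ("B", "I"):
            cur_type, cur_first, cur_last = typ, i, i
    if cur_type is not None:
        spans.append((tokens[cur_first][0], tokens[cur_last][1], cur_type))
    return spans


def validate_bio(tags: Sequence[str]) -> bool:
    """True iff every I-t is preceded by B-t or I-t of the same type."""
    prev = "O"
    for tag in tags:
        if tag.startswith("I-"):
            typ = tag[2:]
            if prev not in (f"B-{typ}", f"I-{typ}"):
                return False
        prev = tag
    return True
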