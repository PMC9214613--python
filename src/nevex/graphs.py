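"""Per-sentence syntactic graphs over dependency parses.

Dependency parses arrive in CoNLL-U.  The ~50 distinct dependency relation
labels a parser emits are collapsed to three direction classes: for every
arc head->dependent the graph holds one ``along`` edge (head, dep) and one
``rev`` edge (dep, head), and every token carries a ``loop`` self edge, so a
sentence of n tokens with a arcs yields exactly 2a + n edges.  Only the
direction of syntactic information flow is retained; the relation labels are
discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

__all__ = ["RELATIONS", "SentenceGraph", "ParseError", "read_conllu", "build_graph"]

# the closed set of relation tags after simplification
RELATIONS = ("along", "rev", "loop")


class ParseError(ValueError):
    """Malformed CoNLL-U input; message carries the line number."""


@dataclass
class SentenceGraph:
    """Tokens plus aligned tag sequences and the simplified dependency graph.

    edges are (u, v, rel) with rel in {along, rev, loop}; an edge carries
    information from token u into token v.
    """

    tokens: list  # of (surface, (start_char, end_char))
    pos: list
    edges: list  # of (u, v, rel)
    entity_bio: list = field(default_factory=list)
    trigger_bio: list = field(default_factory=list)

    def __len__(self):
        return len(self.tokens)

    @property
    def surfaces(self):
        return [t[0] for t in self.tokens]

    @property
    def token_spans(self):
        return [t[1] for t in self.tokens]


def read_conllu(path_or_text) -> list[dict]:
    """Parse CoNLL-U into a list of sentence dicts.

    Returns, per sentence: ``tokens`` (surface strings), ``pos`` (UPOS),
    ``arcs`` (0-based (head, dependent) pairs, root arcs dropped), ``spans``
    (character offsets if recoverable, else None) and ``meta`` (comment
    key-values).  Multiword-token ranges (``1-2``) and empty nodes (``1.1``)
    are skipped.  Character offsets are taken from ``start_char=``/
    ``end_char=`` MISC attributes when present, otherwise reconstructed by
    matching surfaces against the ``# text`` comment.
    """
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text(encoding="utf-8")
    else:
        text = str(path_or_text)

    sentences = []
    cur_rows, cur_meta = [], {}

    def flush(lineno):
        if not cur_rows and not cur_meta:
            return
        tokens, pos, spans, heads = [], [], [], []
        for row_lineno, cols in cur_rows:
            tid = cols[0]
            if "-" in tid or "." in tid:
                continue
            try:
                idx = int(tid)
                head = int(cols[6]) if cols[6] != "_" else 0
            except ValueError as exc:
                raise ParseError(f"line {row_lineno}: bad ID/HEAD in {cols!r}") from exc
            if idx != len(tokens) + 1:
                raise ParseError(f"line {row_lineno}: non-consecutive token id {tid}")
            tokens.append(cols[1])
            pos.append(cols[3])
            heads.append(head)
            spans.append(_misc_span(cols[9] if len(cols) > 9 else "_"))
        if any(s is None for s in spans):
            spans = _spans_from_text(tokens, cur_meta.get("text"))
        arcs = [(h - 1, i) for i, h in enumerate(heads) if h > 0]
        for h, d in arcs:
            if not (0 <= h < len(tokens)):
                raise ParseError(f"line {lineno}: head index out of range")
        sentences.append(
            {"tokens": tokens, "pos": pos, "arcs": arcs, "spans": spans, "meta": dict(cur_meta)}
        )

    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.rstrip("\n")
        if not line.strip():
            flush(lineno)
            cur_rows, cur_meta = [], {}
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                cur_meta[key.strip()] = val.strip()
            continue
        cols = line.split("\t")
        if len(cols) < 8:
            raise ParseError(f"line {lineno}: expected >=8 tab-separated columns")
        cur_rows.append((lineno, cols))
    flush(len(text.splitlines()))
    return sentences


def _misc_span(misc: str):
    start = end = None
    for item in misc.split("|"):
        if item.startswith("start_char="):
            start = int(item.split("=", 1)[1])
        elif item.startswith("end_char="):
            end = int(item.split("=", 1)[1])
    if start is not None and end is not None:
        return (start, end)
    return None


def _spans_from_text(tokens, sent_text):
    if sent_text is None:
        return [None] * len(tokens)
    spans, cursor = [], 0
    for tok in tokens:
        pos = sent_text.find(tok, cursor)
        if pos < 0:
            return [None] * len(tokens)
        spans.append((pos, pos + len(tok)))
        cursor = pos + len(tok)
    return spans


def build_graph(
    tokens: Sequence,
    pos: Sequence[str],
    arcs: Sequence[tuple[int, int]],
    entity_bio: Sequence[str] | None = None,
    trigger_bio: Sequence[str] | None = None,
) -> SentenceGraph:
    """Build the 3-relation multigraph for one sentence.

    Every arc (head, dep) contributes one ``along`` and one ``rev`` edge and
    every token a ``loop`` edge; the edge list is returned in a canonical
    sorted order so construction is a pure function of its inputs.
    """
    n = len(tokens)
    toks = [t if isinstance(t, tuple) else (t, None) for t in tokens]
    edges = []
    for h, d in arcs:
        if not (0 <= h < n and 0 <= d < n):
            raise IndexError(f"arc ({h},{d}) out of range for {n} tokens")
        if h == d:
            raise ValueError(f"self-arc ({h},{d}) in input")
        edges.append((h, d, "along"))
        edges.append((d, h, "rev"))
    for i in range(n):
        edges.append((i, i, "loop"))
    edges.sort(key=lambda e: (e[0], e[1], RELATIONS.index(e[2])))
    return SentenceGraph(
        tokens=toks,
        pos=list(pos),
        edges=edges,
        entity_bio=list(entity_bio) if entity_bio is not None else ["O"] * n,
        trigger_bio=list(trigger_bio) if trigger_bio is not None else ["O"] * n,
    )
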