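"""Precision / recall / F1 for trigger recognition and event extraction.

Matching is strict: a trigger matches on exact character span and type; an
event matches by recursive structural equality — same trigger match, same
multiset of (role, filler) pairs, with event-typed fillers compared
recursively.  Metrics are micro-averaged over documents, reported in
percent, and stratified into *simple* events (all argument fillers are
entities) and *nested* events (at least one filler is an event); the
coarse type-based stratification (regulation-like types count as nested)
is available with ``stratify="by_type"``.
"""

from __future__ import annotations

from collections import Counter

__all__ = ["AlignmentError", "evaluate", "evaluate_examples", "prf"]

NESTED_CAPABLE = (
    "Regulation",
    "Positive_regulation",
    "Negative_regulation",
    "Planned_process",
)


class AlignmentError(ValueError):
    pass


def prf(tp: int, n_pred: int, n_gold: int) -> dict:
    """Micro precision/recall/F1 in percent; undefined ratios reported as 0."""
    p = 100.0 * tp / n_pred if n_pred else 0.0
    r = 100.0 * tp / n_gold if n_gold else 0.0
    f = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return {"precision": p, "recall": r, "f1": f, "tp": tp, "pred": n_pred, "gold": n_gold}


def _trigger_sig(t):
    return (t.start, t.end, t.type)


def _event_sigs(entities, triggers, events):
    """Canonical recursive signature per event (requires acyclic references)."""
    entmap = {e.id: e for e in entities}
    tmap = {t.id: t for t in triggers}
    evmap = {ev.id: ev for ev in events}
    memo = {}

    def sig(eid):
        if eid in memo:
            return memo[eid]
        ev = evmap[eid]
        trig = tmap[ev.trigger_id]
        parts = []
        for role, fid in ev.args:
            if fid in evmap:
                parts.append((role, ("EVT",) + sig(fid)))
            elif fid in entmap:
                e = entmap[fid]
                parts.append((role, ("ENT", e.start, e.end, e.type)))
            elif fid in tmap:
                f = tmap[fid]
                parts.append((role, ("ENT", f.start, f.end, f.type)))
            else:
                parts.append((role, ("MISSING", fid)))
        memo[eid] = (trig.start, trig.end, ev.type, tuple(sorted(parts)))
        return memo[eid]

    return [sig(ev.id) for ev in events]


def _is_nested_sig(sig) -> bool:
    return any(filler[0] == "EVT" for _, filler in sig[3])


def _stratum(sig, stratify: str) -> str:
    if stratify == "by_type":
        return "nested" if sig[2] in NESTED_CAPABLE else "simple"
    return "nested" if _is_nested_sig(sig) else "simple"


def _tally(gold_items, pred_items):
    g, p = Counter(gold_items), Counter(pred_items)
    tp = sum(min(g[k], p[k]) for k in g)
    return tp, sum(p.values()), sum(g.values())


def _stratified(gold_items, pred_items):
    """Items are (comparable tuple, stratum) pairs; strata partition both sides."""
    out = {}
    for stratum in ("all", "simple", "nested"):
        gsel = [it for it, s in gold_items if stratum == "all" or s == stratum]
        psel = [it for it, s in pred_items if stratum == "all" or s == stratum]
        out[stratum] = prf(*_tally(gsel, psel))
    return out


def evaluate(gold_docs, pred_docs, stratify: str = "structural") -> dict:
    """Compare predicted documents against gold, by document id.

    Both sides are (entities, triggers, events) standoff documents.  Returns
    a report dict: ``trigger`` and ``event`` blocks with ``all`` / ``simple``
    / ``nested`` strata, plus an ``event_by_type`` table.  A trigger's
    stratum is that of the events it anchors (nested if any is nested).
    """
    gold_by_id = {d.doc_id: d for d in gold_docs}
    pred_by_id = {d.doc_id: d for d in pred_docs}
    if set(gold_by_id) != set(pred_by_id):
        raise AlignmentError(
            f"document ids differ: {sorted(set(gold_by_id) ^ set(pred_by_id))}"
        )

    gold_trig, pred_trig = [], []  # ((doc, start, end, type), stratum)
    gold_ev, pred_ev = [], []  # ((doc,) + sig, stratum)
    for doc_id in sorted(gold_by_id):
        for doc, trig_acc, ev_acc in (
            (gold_by_id[doc_id], gold_trig, gold_ev),
            (pred_by_id[doc_id], pred_trig, pred_ev),
        ):
            sigs = _event_sigs(doc.entities, doc.triggers, doc.events)
            ev_acc.extend(((doc_id,) + s, _stratum(s, stratify)) for s in sigs)
            trig_stratum = {}
            for s in sigs:
                key = (s[0], s[1], s[2])
                if _stratum(s, stratify) == "nested":
                    trig_stratum[key] = "nested"
                else:
                    trig_stratum.setdefault(key, "simple")
            for t in doc.triggers:
                stratum = trig_stratum.get(
                    _trigger_sig(t), _stratum((t.start, t.end, t.type, ()), stratify)
                )
                trig_acc.append(((doc_id, t.start, t.end, t.type), stratum))

    report = {
        "trigger": _stratified(gold_trig, pred_trig),
        "event": _stratified(gold_ev, pred_ev),
    }
    by_type = {}
    types = sorted({it[3] for it, _ in gold_ev} | {it[3] for it, _ in pred_ev})
    for typ in types:
        by_type[typ] = prf(*_tally(
            [it for it, _ in gold_ev if it[3] == typ],
            [it for it, _ in pred_ev if it[3] == typ],
        ))
    report["event_by_type"] = by_type
    return report


def evaluate_examples(examples, predictions, stratify: str = "structural") -> dict:
    """Evaluate per-sentence predictions against the examples' gold annotations.

    Thin adapter over :func:`evaluate`: each sentence example becomes a
    pseudo-document keyed by its sentence id.
    """
    from .standoff import AnnotatedDocument

    if len(examples) != len(predictions):
        raise AlignmentError("one prediction per example required")
    gold_docs, pred_docs = [], []
    for ex, pred in zip(examples, predictions):
        gold_docs.append(
            AnnotatedDocument(ex.sent_id, "", list(ex.entities), list(ex.triggers),
                              list(ex.events))
        )
        pred_docs.append(
            AnnotatedDocument(ex.sent_id, "", list(ex.entities), list(pred["triggers"]),
                              list(pred["events"]))
        )
    return evaluate(gold_docs, pred_docs, stratify=stratify)
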