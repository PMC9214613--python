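"""Standoff reading/writing and BIO span codecs."""

import pytest

from nevex.standoff import (
    AnnotatedDocument,
    CyclicEvent,
    DanglingReference,
    EntitySpan,
    EventRecord,
    Misaligned,
    OffsetMismatch,
    TriggerSpan,
    bio_to_spans,
    parse_standoff,
    spans_to_bio,
    validate_bio,
    write_standoff,
)
from nevex.synthetic import GeneratorConfig, generate


def test_minimal_document_parses():
    doc = parse_standoff("d", "AB", "T1\tProtein 0 2\tAB\n")
    assert len(doc.entities) == 1
    assert doc.entities[0].surface == "AB"
    assert doc.events == []


def test_offset_mismatch_names_offending_id():
    with pytest.raises(OffsetMismatch, match="T1"):
        parse_standoff("d", "AB", "T1\tProtein 0 2\tXY\n")


def test_dangling_reference_detected():
    a2 = "T2\tReg 0 2\tAB\nE1\tReg:T2 Theme:T9\n"
    with pytest.raises(DanglingReference, match="T9"):
        parse_standoff("d", "AB", "", a2)


def test_smallest_event_cycle_rejected():
    a2 = (
        "T1\tReg 0 2\tAB\nT2\tReg 3 5\tCD\n"
        "E1\tReg:T1 Theme:E2\nE2\tReg:T2 Theme:E1\n"
    )
    with pytest.raises(CyclicEvent):
        parse_standoff("d", "AB CD", "", a2)


def test_self_argument_rejected():
    a2 = "T1\tReg 0 2\tAB\nE1\tReg:T1 Theme:E1\n"
    with pytest.raises(CyclicEvent, match="E1"):
        parse_standoff("d", "AB", "", a2)


def test_empty_document_round_trip():
    doc = AnnotatedDocument("d", "nothing here")
    text, a1, a2 = write_standoff(doc)
    assert (a1, a2) == ("", "")
    assert parse_standoff("d", text, a1, a2) == doc


def test_nested_event_written_with_event_reference():
    doc = AnnotatedDocument(
        "d",
        "regulation of expression of X",
        entities=[EntitySpan("T1", "Gene", 28, 29, "X")],
        triggers=[
            TriggerSpan("T2", "Regulation", 0, 10, "regulation"),
            TriggerSpan("T3", "Gene_expression", 14, 24, "expression"),
        ],
        events=[
            EventRecord("E1", "Regulation", "T2", (("Theme", "E2"),)),
            EventRecord("E2", "Gene_expression", "T3", (("Theme", "T1"),)),
        ],
    )
    _, _, a2 = write_standoff(doc)
    lines = a2.strip().splitlines()
    # the inner event must be written before the event that references it
    assert lines.index("E2\tGene_expression:T3 Theme:T1") < lines.index(
        "E1\tRegulation:T2 Theme:E2"
    )


@pytest.mark.parametrize("seed", range(100))
def test_write_read_write_fixed_point(seed):
    """write -> read -> write is byte-identical for generated documents."""
    corpus = generate(GeneratorConfig(n_docs=1, sentences_per_doc=3, seed=seed))
    doc = corpus.docs[0]
    text, a1, a2 = write_standoff(doc)
    again = parse_standoff(doc.doc_id, text, a1, a2)
    assert write_standoff(again) == (text, a1, a2)
    assert again == doc


def test_generator_counts_recovered_by_reader(toy_corpus):
    log = toy_corpus["corpus"].log
    docs = toy_corpus["docs"]
    assert sum(len(d.entities) for d in docs) == log["totals"]["entities"]
    assert sum(len(d.triggers) for d in docs) == log["totals"]["triggers"]
    assert sum(len(d.events) for d in docs) == log["totals"]["events"]
    for doc in docs:
        assert len(doc.entities) == log["docs"][doc.doc_id]["entities"]


# ------------------------------------------------------------------- BIO tags


def _tok(text):
    spans, cur = [], 0
    for w in text.split(" "):
        spans.append((cur, cur + len(w)))
        cur += len(w) + 1
    return spans


def test_no_spans_is_all_outside():
    assert spans_to_bio(_tok("a b c"), []) == ["O", "O", "O"]


def test_multi_token_trigger_bio_encoding():
    # a three-token trigger phrase gets B- then I- continuations
    tokens = _tok("blood vessel development increased")
    span = TriggerSpan("T1", "BVD", 0, 24, "blood vessel development")
    assert spans_to_bio(tokens, [span]) == ["B-BVD", "I-BVD", "I-BVD", "O"]


def test_adjacent_same_type_spans_both_open_with_b():
    tokens = _tok("aa bb")
    spans = [
        EntitySpan("T1", "t", 0, 2, "aa"),
        EntitySpan("T2", "t", 3, 5, "bb"),
    ]
    assert spans_to_bio(tokens, spans) == ["B-t", "B-t"]


def test_span_splitting_token_is_misaligned():
    with pytest.raises(Misaligned):
        spans_to_bio(_tok("abc def"), [EntitySpan("T1", "t", 0, 2, "ab")])


def test_bio_decode_trivial_cases():
    assert bio_to_spans([], []) == []
    assert bio_to_spans(["O", "O"], _tok("a b")) == []
    assert bio_to_spans(["B-a", "I-a", "O", "B-b"], _tok("x y z w")) == [
        (0, 3, "a"),
        (6, 7, "b"),
    ]


def test_orphan_inside_tag_opens_a_span():
    # lenient decoding: I-a with no preceding B-a starts a new span; an I of a
    # different type closes the current span and opens another
    assert bio_to_spans(["I-a", "I-a"], _tok("x y")) == [(0, 3, "a")]
    assert bio_to_spans(["B-a", "I-b"], _tok("x y")) == [(0, 1, "a"), (2, 3, "b")]


@pytest.mark.parametrize("seed", range(25))
def test_bio_round_trip_on_generated_sentences(seed):
    corpus = generate(GeneratorConfig(n_docs=1, sentences_per_doc=2, seed=seed))
    doc = corpus.docs[0]
    # token spans reconstructed from the document text
    spans = []
    cur = 0
    for line in doc.text.split("\n"):
        for w in line.split(" "):
            spans.append((cur, cur + len(w)))
            cur += len(w) + 1
    tags = spans_to_bio(spans, doc.triggers)
    assert validate_bio(tags)
    decoded = bio_to_spans(tags, spans)
    assert sorted(decoded) == sorted((t.start, t.end, t.type) for t in doc.triggers)
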