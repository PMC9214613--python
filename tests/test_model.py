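"""Joint-head mechanics: tagger, candidate pairing, fusion, event assembly."""

import numpy as np
import pytest

from nevex.autodiff import Tensor
from nevex.model import (
    CandidatePair,
    JointEventExtractor,
    TokenSpan,
    assemble_events,
    enumerate_candidates,
    predictions_to_document,
)
from nevex.standoff import write_standoff

from conftest import SMALL_MODEL


@pytest.fixture(scope="module")
def built(toy_corpus):
    est = JointEventExtractor(**SMALL_MODEL, seed=0)
    est._build_from_examples(toy_corpus["examples"])
    return est


def test_default_fused_embedding_width_is_896():
    est = JointEventExtractor()
    assert est.contextual_dim + est.pos_dim + est.entity_dim == 896


def test_embed_tokens_shapes_and_determinism(built, toy_corpus):
    ex = toy_corpus["examples"][0]
    X1, A1 = built.embed_tokens(ex.graph)
    X2, A2 = built.embed_tokens(ex.graph)
    mu = SMALL_MODEL["contextual_dim"] + SMALL_MODEL["pos_dim"] + SMALL_MODEL["entity_dim"]
    assert X1.shape == (len(ex), mu)
    assert A1.shape == (len(ex), SMALL_MODEL["contextual_dim"])
    assert np.array_equal(X1.data, X2.data)


def test_unknown_labels_map_to_reserved_unk_row(built, toy_corpus):
    ex = toy_corpus["examples"][0]
    out_known = built.pos_table_(ex.graph.pos).data
    out_unk = built.pos_table_(["NOT-A-TAG"] * len(ex)).data
    assert np.allclose(out_unk, built.pos_table_.weight.data[0])
    assert "NOT-A-TAG" in built.pos_table_.unseen
    assert not np.allclose(out_known[0], out_unk[0]) or ex.graph.pos[0] not in built.pos_vocab_


def test_forward_shapes_and_eval_determinism(built, toy_corpus):
    ex = max(toy_corpus["examples"], key=len)
    O1, soft1 = built._forward(ex)
    O2, soft2 = built._forward(ex)
    assert O1.shape == (len(ex), SMALL_MODEL["tagger_hidden"])
    assert soft1.shape == (len(ex), len(built.trigger_labels_))
    assert np.array_equal(O1.data, O2.data)
    assert np.allclose(soft1.data.sum(axis=1), 1.0, atol=1e-9)


def test_mlee_style_schema_gives_39_trigger_labels():
    est = JointEventExtractor(trigger_types=tuple(f"T{i}" for i in range(19)))
    est._build({"NN"}, {"O"}, set(est.trigger_types))
    assert len(est.trigger_labels_) == 2 * 19 + 1


def test_uniform_trigger_distribution_under_zero_head(built, toy_corpus):
    ex = toy_corpus["examples"][0]
    saved = built.trigger_head_.W.data.copy()
    built.trigger_head_.W.data[:] = 0.0
    _, soft = built._forward(ex)
    k = len(built.trigger_labels_)
    assert np.allclose(soft.data, 1.0 / k)
    built.trigger_head_.W.data[:] = saved


def test_candidate_enumeration_counts():
    t = [TokenSpan(0, 0, "Reg"), TokenSpan(3, 3, "Exp")]
    e = [TokenSpan(5, 5, "Gene"), TokenSpan(7, 8, "Drug")]
    assert len(enumerate_candidates(t, e)) == 2 * 2 + 2 * 1
    assert len(enumerate_candidates([], e)) == 0
    assert len(enumerate_candidates(t[:1], e[:1])) == 1
    # deterministic ordering by (trigger start, candidate start)
    pairs = enumerate_candidates(t, e)
    assert pairs[0].trigger.first <= pairs[-1].trigger.first
    assert [p.candidate.first for p in pairs if p.trigger == t[0]] == [3, 5, 7]


def test_role_pooling_single_token_is_identity(built, toy_corpus):
    ex = max(toy_corpus["examples"], key=len)
    O, soft = built._forward(ex)
    pair = CandidatePair(TokenSpan(0, 0, "A"), TokenSpan(1, 1, "B"), False)
    dist = built.role_distributions(O, soft, [pair])
    F = np.concatenate([O.data, soft.data], axis=1)
    manual = np.concatenate([F[0], F[1]])[None, :] @ built.role_head_.W.data + built.role_head_.b.data
    e = np.exp(manual - manual.max())
    assert np.allclose(dist.data, e / e.sum(), atol=1e-9)


def test_uniform_roles_under_zero_event_head(built, toy_corpus):
    ex = max(toy_corpus["examples"], key=len)
    O, soft = built._forward(ex)
    saved = built.role_head_.W.data.copy()
    built.role_head_.W.data[:] = 0.0
    pair = CandidatePair(TokenSpan(0, 1, "A"), TokenSpan(2, 2, "B"), False)
    dist = built.role_distributions(O, soft, [pair])
    assert np.allclose(dist.data, 1.0 / 3.0)
    built.role_head_.W.data[:] = saved


def test_fusion_pathway_carries_trigger_distribution(built, toy_corpus):
    """Flipping the trigger softmax flips the role decision while O is fixed."""
    ex = max(toy_corpus["examples"], key=len)
    O, _ = built._forward(ex)
    n = len(ex)
    k = len(built.trigger_labels_)
    d = SMALL_MODEL["tagger_hidden"]
    # route probability mass of label 1 (trigger block) to role 0
    built_W = np.zeros_like(built.role_head_.W.data)
    built_W[d + 1, 0] = 10.0  # trigger-span soft_k[label 1] -> role 0 logits
    saved = built.role_head_.W.data.copy()
    built.role_head_.W.data = built_W
    pair = CandidatePair(TokenSpan(0, 0, "A"), TokenSpan(1, 1, "B"), False)

    soft_a = np.zeros((n, k))
    soft_a[:, 1] = 1.0
    soft_b = np.zeros((n, k))
    soft_b[:, 2] = 1.0
    dist_a = built.role_distributions(O, Tensor(soft_a), [pair]).data
    dist_b = built.role_distributions(O, Tensor(soft_b), [pair]).data
    assert dist_a[0, 0] > 0.99
    assert np.allclose(dist_b, 1.0 / 3.0)
    built.role_head_.W.data = saved


def test_fusion_gradient_flows_into_trigger_softmax(built, toy_corpus):
    ex = max(toy_corpus["examples"], key=len)
    O, soft = built._forward(ex)
    pair = CandidatePair(TokenSpan(0, 0, "A"), TokenSpan(1, 1, "B"), False)
    dist = built.role_distributions(O.detach(), soft, [pair])
    dist[0, 0].backward()
    # gradient reaches the trigger-head parameters through soft alone
    assert any(
        p.grad is not None and np.abs(p.grad).max() > 0
        for p in built.trigger_head_.params().values()
    )
    for p in built.params_.values():
        p.zero_grad()


def test_shared_fusion_has_no_soft_block(toy_corpus):
    est = JointEventExtractor(**SMALL_MODEL, fusion="shared", seed=0)
    est._build_from_examples(toy_corpus["examples"])
    assert est.role_head_.W.shape[0] == 2 * SMALL_MODEL["tagger_hidden"]


# ------------------------------------------------------------ event assembly


def test_every_trigger_yields_an_event_even_without_args():
    t = [TokenSpan(0, 0, "Reg"), TokenSpan(2, 2, "Exp")]
    events = assemble_events(t, [])
    assert len(events) == 2
    assert all(ev.args == () for ev in events)


def test_nested_assembly_resolves_trigger_argument_to_event():
    reg, exp = TokenSpan(0, 0, "Pos_Reg"), TokenSpan(2, 2, "Exp")
    gene = TokenSpan(4, 4, "Gene")
    decisions = [
        (CandidatePair(reg, exp, True), "Theme", 0.9),
        (CandidatePair(exp, gene, False), "Theme", 0.8),
        (CandidatePair(reg, gene, False), "Cause", 0.7),
    ]
    events = assemble_events([reg, exp], decisions, entity_ids={gene: "T1"})
    by_type = {ev.type: ev for ev in events}
    inner = by_type["Exp"]
    outer = by_type["Pos_Reg"]
    assert ("Theme", inner.id) in outer.args
    assert ("Cause", "T1") in outer.args
    assert inner.args == (("Theme", "T1"),)


def test_cycle_broken_by_keeping_higher_probability_decision():
    a, b = TokenSpan(0, 0, "Reg"), TokenSpan(2, 2, "Reg")
    decisions = [
        (CandidatePair(a, b, True), "Theme", 0.9),
        (CandidatePair(b, a, True), "Theme", 0.6),
    ]
    events = assemble_events([a, b], decisions)
    ev_a = next(ev for ev in events if ev.trigger_id == "TR1")
    ev_b = next(ev for ev in events if ev.trigger_id == "TR2")
    assert ev_a.args == (("Theme", ev_b.id),)
    assert ev_b.args == ()


def test_predicted_documents_pass_standoff_validation(toy_corpus):
    est = JointEventExtractor(**SMALL_MODEL, epochs=2, seed=0)
    examples = toy_corpus["examples"]
    est.fit(examples)
    preds = est.predict(examples)
    for doc in toy_corpus["docs"]:
        idx = [i for i, ex in enumerate(examples) if ex.doc_id == doc.doc_id]
        pred_doc = predictions_to_document(doc, [examples[i] for i in idx],
                                           [preds[i] for i in idx])
        write_standoff(pred_doc)  # validates offsets, references, acyclicity


def test_sklearn_param_round_trip():
    est = JointEventExtractor(epochs=3, dice_beta=0.25)
    params = est.get_params()
    clone = JointEventExtractor(**params)
    assert clone.get_params() == params
    clone.set_params(epochs=5)
    assert clone.epochs == 5


def test_save_load_round_trip(tmp_path, toy_corpus):
    examples = toy_corpus["examples"][:10]
    est = JointEventExtractor(**SMALL_MODEL, epochs=2, seed=3)
    est.fit(examples)
    path = tmp_path / "ckpt.npz"
    est.save(path)
    loaded = JointEventExtractor.load(path)
    ex = examples[0]
    assert np.allclose(
        est.trigger_distribution(ex), loaded.trigger_distribution(ex), atol=1e-12
    )
    assert loaded.trigger_labels_ == est.trigger_labels_
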