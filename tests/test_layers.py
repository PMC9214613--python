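"""Network layers against dense brute-force oracles and analytic cases."""

import numpy as np
import pytest

from nevex.autodiff import Tensor
from nevex.graphs import RELATIONS, build_graph
from nevex.nn import (
    BiLSTM,
    DimensionError,
    GatedGCN,
    GatedGCNLayer,
    HashEmbedder,
    LSTM,
    MultiHeadAttention,
)


def random_tree_graph(rng, n):
    arcs = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    return build_graph([f"w{i}" for i in range(n)], ["NN"] * n, arcs)


def dense_gcn_oracle(H, graph, layer, force_gates_one=False):
    """Triple loop over (u, v, r) edges; independent of the sparse path."""
    n, m = H.shape
    out = np.zeros((n, m))
    indeg = np.zeros(n)
    for u, v, r in graph.edges:
        W, b = layer.W[r].data, layer.b[r].data
        V, d = layer.V[r].data, layer.d[r].data
        gate = 1.0 if force_gates_one else 1.0 / (1.0 + np.exp(-(H[u] @ V + d)))
        out[v] += gate * (H[u] @ W + b)
        indeg[v] += 1
    if layer.normalize:
        out /= np.maximum(indeg, 1.0)[:, None]
    return np.maximum(out, 0.0)


@pytest.mark.parametrize("seed", range(40))
@pytest.mark.parametrize("normalize", [True, False])
def test_gcn_layer_equals_dense_oracle(seed, normalize):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 11))
    m = 6
    graph = random_tree_graph(rng, n)
    layer = GatedGCNLayer(m, rng, "l", normalize=normalize)
    H = rng.standard_normal((n, m))
    got = layer(Tensor(H), graph).data
    want = dense_gcn_oracle(H, graph, layer)
    assert np.max(np.abs(got - want)) < 1e-6


@pytest.mark.parametrize("seed", range(10))
def test_gcn_with_saturated_gates_equals_ungated_relational_gcn(seed):
    # V_r = 0, d_r = 30 forces every gate to sigmoid(30) ~ 1
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 11))
    m = 5
    graph = random_tree_graph(rng, n)
    layer = GatedGCNLayer(m, rng, "l", normalize=False)
    for r in RELATIONS:
        layer.V[r].data[:] = 0.0
        layer.d[r].data[:] = 30.0
    H = rng.standard_normal((n, m))
    got = layer(Tensor(H), graph).data
    want = dense_gcn_oracle(H, graph, layer, force_gates_one=True)
    assert np.max(np.abs(got - want)) < 1e-6


def test_single_node_zero_parameters_gives_zero():
    rng = np.random.default_rng(0)
    layer = GatedGCNLayer(4, rng, "l")
    for r in RELATIONS:
        layer.W[r].data[:] = 0.0
        layer.b[r].data[:] = 0.0
        layer.V[r].data[:] = 0.0
        layer.d[r].data[:] = 0.0
    graph = build_graph(["x"], ["NN"], [])
    out = layer(Tensor(np.ones((1, 4))), graph).data
    assert np.allclose(out, 0.0)  # relu(sigmoid(0) * 0)


def test_gcn_self_loop_only_matches_closed_form():
    # with no arcs every layer is the per-token map relu(g * (W h + b))
    rng = np.random.default_rng(1)
    m, n = 5, 4
    graph = build_graph([f"w{i}" for i in range(n)], ["NN"] * n, [])
    layer = GatedGCNLayer(m, rng, "l")
    H = rng.standard_normal((n, m))
    g = 1.0 / (1.0 + np.exp(-(H @ layer.V["loop"].data + layer.d["loop"].data)))
    want = np.maximum(g * (H @ layer.W["loop"].data + layer.b["loop"].data), 0.0)
    assert np.allclose(layer(Tensor(H), graph).data, want, atol=1e-12)


def test_stacked_gcn_composes_layers():
    rng = np.random.default_rng(2)
    graph = random_tree_graph(rng, 6)
    gcn = GatedGCN(5, 2, rng, "g")
    H = rng.standard_normal((6, 5))
    out1 = gcn.layers[0](Tensor(H), graph)
    out2 = gcn.layers[1](out1, graph)
    assert np.allclose(gcn(Tensor(H), graph).data, out2.data)
    one = GatedGCN(5, 1, rng, "g1")
    assert np.allclose(one(Tensor(H), graph).data, one.layers[0](Tensor(H), graph).data)
    with pytest.raises(ValueError):
        GatedGCN(5, 0, rng, "bad")


def test_gates_strictly_inside_unit_interval():
    rng = np.random.default_rng(3)
    layer = GatedGCNLayer(4, rng, "l")
    H = rng.standard_normal((5, 4)) * 10
    for r in RELATIONS:
        g = 1.0 / (1.0 + np.exp(-(H @ layer.V[r].data + layer.d[r].data)))
        assert np.all((g > 0) & (g < 1))


# -------------------------------------------------------------- attention


def attention_oracle(S, att):
    """Naive per-row softmax/matmul recomputation."""
    heads = []
    for i in range(att.heads):
        Q, K, V = S @ att.Wq[i].data, S @ att.Wk[i].data, S @ att.Wv[i].data
        scores = Q @ K.T / np.sqrt(att.dk)
        e = np.exp(scores - scores.max(axis=1, keepdims=True))
        A = e / e.sum(axis=1, keepdims=True)
        heads.append(A @ V)
    return np.concatenate(heads, axis=1) @ att.Wo.data


@pytest.mark.parametrize("seed", range(20))
def test_attention_equals_naive_oracle(seed):
    rng = np.random.default_rng(seed)
    n, m, h = int(rng.integers(1, 8)), 8, 2
    att = MultiHeadAttention(m, h, rng, "a")
    S = rng.standard_normal((n, m))
    assert np.max(np.abs(att(Tensor(S)).data - attention_oracle(S, att))) < 1e-6


def test_attention_rows_sum_to_one_and_single_token_is_certain():
    rng = np.random.default_rng(4)
    att = MultiHeadAttention(6, 2, rng, "a")
    S = rng.standard_normal((5, 6))
    for A in att.head_scores(Tensor(S)):
        assert np.allclose(A.data.sum(axis=1), 1.0, atol=1e-9)
    one = att.head_scores(Tensor(rng.standard_normal((1, 6))))
    assert all(np.allclose(A.data, [[1.0]]) for A in one)


def test_head_count_must_divide_model_dim():
    with pytest.raises(DimensionError):
        MultiHeadAttention(7, 2, np.random.default_rng(0), "a")


def test_averaged_scores_is_head_mean_and_uniform_for_zero_queries():
    rng = np.random.default_rng(5)
    att = MultiHeadAttention(6, 2, rng, "a")
    S = rng.standard_normal((4, 6))
    avg = att.averaged_scores(Tensor(S))
    per_head = [A.data for A in att.head_scores(Tensor(S))]
    assert np.allclose(avg, (per_head[0] + per_head[1]) / 2)
    assert np.allclose(avg.sum(axis=1), 1.0)
    for i in range(att.heads):
        att.Wq[i].data[:] = 0.0
        att.Wk[i].data[:] = 0.0
    assert np.allclose(att.averaged_scores(Tensor(S)), 0.25)


# ------------------------------------------------------------------- LSTMs


def test_zero_parameter_lstm_outputs_zeros():
    rng = np.random.default_rng(6)
    lstm = LSTM(3, 4, rng, "l")
    lstm.Wx.data[:] = 0.0
    lstm.Wh.data[:] = 0.0
    lstm.b.data[:] = 0.0
    out = lstm(Tensor(np.random.default_rng(0).standard_normal((5, 3)))).data
    assert np.allclose(out, 0.0)


def test_bilstm_direction_symmetry():
    """Running the reversed sequence through the forward LSTM equals the
    reversed backward-LSTM output of the original under shared weights."""
    rng = np.random.default_rng(7)
    bi = BiLSTM(3, 4, rng, "b")
    bi.bwd.Wx.data = bi.fwd.Wx.data.copy()
    bi.bwd.Wh.data = bi.fwd.Wh.data.copy()
    bi.bwd.b.data = bi.fwd.b.data.copy()
    X = rng.standard_normal((5, 3))
    fwd_rev = bi.fwd(Tensor(X[::-1].copy())).data
    bwd = bi.bwd(Tensor(X)).data
    assert np.allclose(fwd_rev, bwd[::-1], atol=1e-12)


def test_bilstm_output_width_is_twice_hidden():
    rng = np.random.default_rng(8)
    bi = BiLSTM(5, 128, rng, "b")
    out = bi(Tensor(rng.standard_normal((3, 5))))
    assert out.shape == (3, 256)


# ------------------------------------------------------------ hash embedder


def test_hash_embedder_deterministic_across_instances():
    e1 = HashEmbedder(16, seed=3)
    e2 = HashEmbedder(16, seed=3)
    a = e1(["expression", "of", "IL-8"]).data
    b = e2(["expression", "of", "IL-8"]).data
    assert np.array_equal(a, b)
    assert not np.array_equal(a[0], HashEmbedder(16, seed=4)(["expression"]).data[0])


# ------------------------------------------------------------- equivariance


def test_gcn_and_attention_are_permutation_equivariant():
    rng = np.random.default_rng(9)
    n, m = 7, 6
    arcs = [(int(rng.integers(0, i)), i) for i in range(1, n)]
    graph = build_graph([f"w{i}" for i in range(n)], ["NN"] * n, arcs)
    perm = rng.permutation(n)
    inv = np.argsort(perm)
    arcs_p = [(int(inv[h]), int(inv[d])) for h, d in arcs]
    graph_p = build_graph([f"p{i}" for i in range(n)], ["NN"] * n, arcs_p)

    H = rng.standard_normal((n, m))
    layer = GatedGCNLayer(m, rng, "l")
    att = MultiHeadAttention(m, 2, rng, "a")

    out = layer(Tensor(H), graph).data
    out_p = layer(Tensor(H[perm]), graph_p).data
    assert np.allclose(out_p, out[perm], atol=1e-9)

    S = rng.standard_normal((n, m))
    m_out = att(Tensor(S)).data
    m_out_p = att(Tensor(S[perm])).data
    assert np.allclose(m_out_p, m_out[perm], atol=1e-9)
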