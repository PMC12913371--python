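"""Span encoder: enumeration, aggregation, gating, graphs, attention,
classification and pruning."""

import numpy as np
import pytest

from spanccd import _autodiff as ad
from spanccd._autodiff import Tensor
from spanccd.corpus_io import tokenize_and_align
from spanccd.encoder import (
    CapabilityError,
    EncoderConfig,
    SpanBatch,
    aggregate_spans,
    build_span_graph,
    build_vocab,
    classify_spans,
    count_spans,
    encode_tokens,
    encode_tokens_pretrained,
    enumerate_spans,
    forward_spans,
    gate_spans,
    graph_augment_tokens,
    init_params,
    nesting_depths,
    pool_first_subword,
    prune_spans,
    span_self_attention,
    structural_attention,
    token_similarity_graph,
)
from spanccd.schema import schema_from_dict


# ------------------------------------------------------------ enumeration


def test_enumerate_spans_examples():
    assert len(enumerate_spans(5, 2)) == 9
    assert len(enumerate_spans(3, 5)) == 6
    assert enumerate_spans(1, 1) == [(1, 1)]


def test_enumerate_spans_matches_closed_form_exhaustively():
    for T in range(1, 51):
        for L in range(1, 11):
            spans = enumerate_spans(T, L)
            assert len(spans) == count_spans(T, L)
            assert spans == sorted(spans)
            assert all(1 <= s <= t <= T and t - s + 1 <= L for s, t in spans)


def test_enumerate_spans_rejects_nonpositive():
    with pytest.raises(ValueError):
        enumerate_spans(0, 3)
    with pytest.raises(ValueError):
        enumerate_spans(3, 0)


# ------------------------------------------------------------ token encoding


def test_encode_tokens_shape_and_determinism(schema, small_corpus, tiny_config, tiny_params):
    doc = small_corpus[0]
    H1 = encode_tokens(doc, tiny_params, tiny_config)
    H2 = encode_tokens(doc, tiny_params, tiny_config)
    assert H1.shape == (len(doc.tokens), tiny_config.hidden_dim)
    assert np.array_equal(H1.data, H2.data)


def test_encode_single_token_document(schema, small_corpus, tiny_config, tiny_params):
    doc = tokenize_and_align("lupus", doc_id="one")
    H = encode_tokens(doc, tiny_params, tiny_config)
    assert H.shape == (1, tiny_config.hidden_dim)


def test_empty_document_rejected(tiny_params, tiny_config):
    doc = tokenize_and_align("", doc_id="empty")
    with pytest.raises(ValueError, match="empty"):
        encode_tokens(doc, tiny_params, tiny_config)


def test_context_window_zero_localizes_edits(schema, small_corpus):
    cfg = EncoderConfig(hidden_dim=16, dropout=0.0, context_window=0,
                        use_token_graph=False, seed=0)
    doc_a = tokenize_and_align("the IL-2 level rose sharply", doc_id="a")
    doc_b = tokenize_and_align("the IL-2 level fell sharply", doc_id="b")
    vocab = build_vocab([doc_a, doc_b])
    params = init_params(cfg, schema, vocab)
    Ha = encode_tokens(doc_a, params, cfg).data
    Hb = encode_tokens(doc_b, params, cfg).data
    assert np.array_equal(Ha[:3], Hb[:3])  # rows before the edited token
    assert not np.array_equal(Ha[3], Hb[3])


def test_pretrained_backend_requires_provider(tiny_params, tiny_config):
    import dataclasses

    cfg = dataclasses.replace(tiny_config, backend="pretrained")
    doc = tokenize_and_align("a b", doc_id="x")
    with pytest.raises(CapabilityError):
        encode_tokens(doc, tiny_params, cfg)


def test_first_subword_pooling_contract():
    sub = np.arange(12.0).reshape(6, 2)
    # words: [CLS]=-1, w0 -> rows 1, w1 -> rows 2,3, w2 -> row 4, [SEP]=-1
    pooled = pool_first_subword(sub, [-1, 0, 1, 1, 2, -1])
    assert np.array_equal(pooled, sub[[1, 2, 4]])
    doc = tokenize_and_align("a b c", doc_id="p")
    H = encode_tokens_pretrained(
        doc, lambda words: (sub, [-1, 0, 1, 1, 2, -1]), EncoderConfig()
    )
    assert H.shape == (3, 2)


# ------------------------------------------------------------ token graph


def test_token_graph_zero_bilinear_gives_half_similarity(rng):
    H = Tensor(rng.normal(size=(4, 3)))
    g = token_similarity_graph(H, Tensor(np.zeros((3, 3))), threshold=0.6)
    assert np.allclose(g.sim.data, 0.5)
    assert not g.adjacency.any()
    assert np.array_equal(graph_augment_tokens(H, g).data, H.data)  # isolated rule


def test_token_graph_low_threshold_complete(rng):
    H = Tensor(rng.normal(size=(4, 3)))
    g = token_similarity_graph(H, Tensor(np.zeros((3, 3))), threshold=0.1)
    assert g.adjacency.sum() == 12  # complete minus self-loops


def test_graph_augment_singleton_and_equal_neighbors():
    H = Tensor(np.array([[1.0, 0.0], [0.0, 2.0], [3.0, 3.0]]))
    from spanccd.encoder import TokenGraph

    adj = np.array([[False, True, False], [False] * 3, [False] * 3])
    g = TokenGraph(adjacency=adj, sim=Tensor(np.full((3, 3), 0.7)))
    out = graph_augment_tokens(H, g).data
    assert np.allclose(out[0], H.data[0] + H.data[1])  # singleton alpha = 1
    adj2 = np.array([[False, True, True], [False] * 3, [False] * 3])
    g2 = TokenGraph(adjacency=adj2, sim=Tensor(np.full((3, 3), 0.7)))
    out2 = graph_augment_tokens(H, g2).data
    assert np.allclose(out2[0], H.data[0] + 0.5 * H.data[1] + 0.5 * H.data[2])


# ------------------------------------------------------------ aggregation / gating


def test_aggregate_channel_layout(tiny_params, tiny_config, rng):
    d = tiny_config.hidden_dim
    u, v = rng.normal(size=d), rng.normal(size=d)
    H = Tensor(np.stack([u, v]))
    batch = aggregate_spans(H, [(1, 1), (1, 2)], tiny_params, tiny_config)
    r = batch.raw_repr.data
    # single-token span: first four channels all equal h_s
    for c in range(4):
        assert np.allclose(r[0, c * d : (c + 1) * d], u)
    # two-token span: mean and max channels
    assert np.allclose(r[1, 2 * d : 3 * d], (u + v) / 2)
    assert np.allclose(r[1, 3 * d : 4 * d], np.maximum(u, v))
    psi = tiny_params["W_len"].data[1] + tiny_params["b_len"].data
    assert np.allclose(r[1, 4 * d :], psi)


def test_aggregate_constant_rows(tiny_params, tiny_config):
    d = tiny_config.hidden_dim
    v = np.full(d, 2.5)
    H = Tensor(np.tile(v, (3, 1)))
    batch = aggregate_spans(H, [(1, 3), (2, 2)], tiny_params, tiny_config)
    for c in range(4):
        assert np.allclose(batch.raw_repr.data[:, c * d : (c + 1) * d], v)


def test_aggregate_out_of_range_span(tiny_params, tiny_config, rng):
    H = Tensor(rng.normal(size=(2, tiny_config.hidden_dim)))
    with pytest.raises(ValueError, match="out of range"):
        aggregate_spans(H, [(1, 3)], tiny_params, tiny_config)


def test_gate_zero_weights_halve_representation(tiny_params, tiny_config, rng):
    dr = tiny_config.repr_dim
    batch = SpanBatch(spans=[(1, 1)], raw_repr=Tensor(rng.normal(size=(1, dr))))
    import copy

    p = tiny_params.copy()
    p["W_g_gate"].data[:] = 0.0
    p["b_g_gate"].data[:] = 0.0
    out = gate_spans(batch, p)
    assert np.allclose(out.final_repr.data, 0.5 * batch.raw_repr.data)
    assert np.all((out.gate.data > 0) & (out.gate.data < 1))
    # saturated gate passes the representation through
    p["b_g_gate"].data[:] = 50.0
    out2 = gate_spans(SpanBatch(spans=[(1, 1)], raw_repr=batch.raw_repr), p)
    assert np.allclose(out2.final_repr.data, batch.raw_repr.data, atol=1e-8)


# ------------------------------------------------------------ span graph


def test_span_graph_relation_examples():
    g = build_span_graph([(1, 4), (2, 3), (1, 3), (2, 5), (6, 7), (8, 9)])
    i = {sp: k for k, sp in enumerate(g.spans)}
    assert g.relation(i[(1, 4)], i[(2, 3)]) == "nested"
    assert g.relation(i[(1, 3)], i[(2, 5)]) == "overlap"
    assert g.relation(i[(6, 7)], i[(8, 9)]) == "adjacent"
    assert g.relation(i[(1, 4)], i[(6, 7)]) is None  # gap of 1


def test_span_graph_agrees_with_bruteforce_interval_oracle():
    from spanccd.encoder import enumerate_spans

    for T, L in [(5, 3), (8, 4), (6, 2)]:
        spans = enumerate_spans(T, L)
        g = build_span_graph(spans)
        for a in range(len(spans)):
            for b in range(len(spans)):
                (s1, t1), (s2, t2) = spans[a], spans[b]
                if a == b:
                    expected = None
                elif (s1 <= s2 and t2 <= t1) or (s2 <= s1 and t1 <= t2):
                    expected = "nested"
                elif s1 <= t2 and s2 <= t1:
                    expected = "overlap"
                elif t1 + 1 == s2 or t2 + 1 == s1:
                    expected = "adjacent"
                else:
                    expected = None
                assert g.relation(a, b) == expected, (spans[a], spans[b])


def test_span_graph_symmetric_storage():
    g = build_span_graph([(1, 2), (2, 4)])
    assert g.overlap[0, 1] and g.overlap[1, 0]


def test_nesting_depths():
    spans = [(1, 5), (2, 4), (3, 3), (6, 6)]
    assert nesting_depths(spans).tolist() == [0, 1, 2, 0]


# ------------------------------------------------------------ attention stages


def _span_batch(tiny_params, tiny_config, rng, spans):
    H = Tensor(rng.normal(size=(max(t for _, t in spans), tiny_config.hidden_dim)))
    batch = aggregate_spans(H, spans, tiny_params, tiny_config)
    return gate_spans(batch, tiny_params)


def test_structural_attention_rows_normalize(tiny_params, tiny_config, rng):
    spans = [(1, 3), (2, 2), (4, 5), (7, 8)]
    batch = _span_batch(tiny_params, tiny_config, rng, spans)
    graph = build_span_graph(spans)
    out = structural_attention(batch, graph, tiny_params, tiny_config)
    att = graph.attention
    for i in range(len(spans)):
        if graph.neighbors[i].any():
            assert abs(att[i].sum() - 1.0) < 1e-6
        else:
            assert np.allclose(att[i], 0.0)
    assert out.struct_repr.shape == batch.final_repr.shape


def test_structural_attention_isolated_with_zero_bias_ffn(tiny_params, tiny_config, rng):
    spans = [(1, 1), (5, 5)]  # disconnected (gap >= 1)
    batch = _span_batch(tiny_params, tiny_config, rng, spans)
    p = tiny_params.copy()
    p["ffn_b1"].data[:] = 0.0
    p["ffn_b2"].data[:] = 0.0
    graph = build_span_graph(spans)
    out = structural_attention(batch, graph, p, tiny_config)
    expected = ad.layer_norm(batch.final_repr).data
    assert np.allclose(out.struct_repr.data, expected)


def test_structural_attention_single_neighbor_context(tiny_params, tiny_config, rng):
    # spans (1,2) and (2,3) overlap; each is the other's sole neighbor
    spans = [(1, 2), (2, 3)]
    batch = _span_batch(tiny_params, tiny_config, rng, spans)
    graph = build_span_graph(spans)
    structural_attention(batch, graph, tiny_params, tiny_config)
    assert np.allclose(graph.attention[0], [0.0, 1.0])


def test_span_self_attention_singleton(tiny_params, tiny_config, rng):
    batch = _span_batch(tiny_params, tiny_config, rng, [(1, 1)])
    batch.struct_repr = batch.final_repr
    out = span_self_attention(batch, tiny_params, tiny_config)
    r = batch.final_repr
    expected = ad.layer_norm(r + (r @ tiny_params["W_V"])).data
    assert np.allclose(out.struct_repr.data, expected)


def test_phi_bias_saturation_drives_attention(tiny_params, tiny_config, rng):
    spans = [(1, 1), (2, 2), (30, 30)]
    batch = _span_batch(tiny_params, tiny_config, rng, spans)
    batch.struct_repr = batch.final_repr
    p = tiny_params.copy()
    p["phi_table"].data[:] = 0.0
    p["phi_table"].data[5, 2] = 60.0  # distance bucket 9+, equal depth
    import spanccd.encoder as enc

    x = batch.struct_repr
    phi_idx = enc._phi_index_matrix(spans)
    scores = (
        (x.data @ p["W_Q"].data) @ (x.data @ p["W_K"].data).T / np.sqrt(x.shape[1])
        + p["phi_table"].data.reshape(-1)[phi_idx]
    )
    w = np.exp(scores - scores.max(axis=1, keepdims=True))
    w /= w.sum(axis=1, keepdims=True)
    assert w[0, 2] > 0.999  # the boosted far pair dominates row 0


# ------------------------------------------------------------ classification


def test_classifier_uniform_under_zero_params(tiny_params, tiny_config, rng):
    batch = _span_batch(tiny_params, tiny_config, rng, [(1, 2), (3, 3)])
    batch.struct_repr = batch.final_repr
    p = tiny_params.copy()
    p["W_cls"].data[:] = 0.0
    p["b_cls"].data[:] = 0.0
    out = classify_spans(batch, p)
    n = out.type_dist.data.shape[1]
    assert np.allclose(out.type_dist.data, 1.0 / n)
    assert np.allclose(out.type_dist.data.sum(axis=1), 1.0, atol=1e-6)


def test_classifier_none_saturation(tiny_params, tiny_config, rng):
    batch = _span_batch(tiny_params, tiny_config, rng, [(1, 1)])
    batch.struct_repr = batch.final_repr
    p = tiny_params.copy()
    p["b_cls"].data[:] = 0.0
    p["b_cls"].data[-1] = 100.0
    out = classify_spans(batch, p)
    assert out.type_dist.data[0, -1] > 0.999


def test_classifier_permutation_consistency():
    """Permuting classifier columns permutes distributions identically
    (no hidden dependence on label order)."""
    rng = np.random.default_rng(3)
    sch = schema_from_dict({"types": [{"id": y, "name": y} for y in "ABC"]})
    cfg = EncoderConfig(hidden_dim=4, dropout=0.0, seed=1)
    params = init_params(cfg, sch, {"<unk>": 0})
    dr = cfg.repr_dim
    r = Tensor(rng.normal(size=(3, dr)))
    batch = SpanBatch(spans=[(1, 1), (2, 2), (3, 3)], struct_repr=r)
    base = classify_spans(batch, params).type_dist.data.copy()
    perm = np.array([1, 2, 0, 3])
    params2 = params.copy()
    params2["W_cls"].data[:] = params["W_cls"].data[:, perm]
    params2["b_cls"].data[:] = params["b_cls"].data[perm]
    batch2 = SpanBatch(spans=batch.spans, struct_repr=r)
    out = classify_spans(batch2, params2).type_dist.data
    assert np.allclose(out, base[:, perm])


# ------------------------------------------------------------ pruning


def _classified_batch(dists, spans):
    n, k = len(spans), len(dists[0])
    batch = SpanBatch(spans=spans)
    batch.type_dist = Tensor(np.array(dists))
    batch.struct_repr = Tensor(np.zeros((n, 4)))
    batch.labels = [f"Y{i}" for i in range(k - 1)] + ["NONE"]
    return batch


def test_prune_threshold_filter_oracle():
    dists = [[0.9, 0.1], [0.4, 0.6], [0.6, 0.4]]  # alpha = .9, .4, .6
    batch = _classified_batch(dists, [(1, 1), (2, 2), (3, 3)])
    kept = prune_spans(batch, 0.5, 10)
    assert [c.span for c in kept.candidates] == [(1, 1), (3, 3)]
    assert [round(c.entity_score, 6) for c in kept.candidates] == [0.9, 0.6]


def test_prune_keeps_all_at_zero_threshold_and_caps_topk():
    dists = [[0.9, 0.1], [0.4, 0.6], [0.6, 0.4]]
    batch = _classified_batch(dists, [(1, 1), (2, 2), (3, 3)])
    assert len(prune_spans(batch, 0.0, 10).candidates) == 3
    top1 = prune_spans(batch, 0.0, 1)
    assert [c.span for c in top1.candidates] == [(1, 1)]


def test_prune_none_certain_empty():
    dists = [[0.0, 1.0], [0.0, 1.0]]
    batch = _classified_batch(dists, [(1, 1), (2, 2)])
    assert prune_spans(batch, 0.1, 5).candidates == []


def test_prune_rejects_bad_topk():
    batch = _classified_batch([[0.5, 0.5]], [(1, 1)])
    with pytest.raises(ValueError):
        prune_spans(batch, 0.5, 0)


# ------------------------------------------------------------ full forward


def test_forward_pass_bit_reproducible(schema, small_corpus, tiny_config, tiny_params):
    doc = small_corpus[1]
    b1 = forward_spans(doc, tiny_params, tiny_config)
    b2 = forward_spans(doc, tiny_params, tiny_config)
    assert np.array_equal(b1.type_dist.data, b2.type_dist.data)
    assert np.allclose(b1.type_dist.data.sum(axis=1), 1.0, atol=1e-6)
    assert np.all((b1.gate.data > 0) & (b1.gate.data < 1))
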