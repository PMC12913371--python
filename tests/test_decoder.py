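"""CCD decoder: propagation, filtering, penalty terms, the selection
objective, and the beam-vs-exhaustive oracle equivalence."""

import math

import numpy as np
import pytest

from spanccd.candidates import CandidateSet, CandidateSpan
from spanccd.decoder import (
    CapacityError,
    DecodeConfig,
    baseline_config,
    build_decode_graph,
    conflict_penalty,
    context_reward,
    decode_candidates,
    ontology_filter,
    ontology_project,
    overlap_penalty,
    propagate,
    select_spans_beam,
    select_spans_exhaustive,
    selection_objective,
)
from spanccd.schema import schema_from_dict

LABELS = ["CELL", "CYTOKINE", "DISEASE", "ENTITY", "GENE", "T_CELL", "NONE"]


def _cand(span, probs=None, top=None, p=0.8, alpha=None, allowed=None):
    if probs is None:
        probs = np.full(len(LABELS), (1 - p) / (len(LABELS) - 1))
        probs[LABELS.index(top)] = p
    probs = np.asarray(probs, dtype=float)
    return CandidateSpan(
        span=span,
        type_dist=probs,
        entity_score=float(alpha if alpha is not None else 1 - probs[-1]),
        allowed_labels=allowed,
    )


def _cset(cands):
    return CandidateSet(candidates=cands, labels=list(LABELS))


def _random_cset(rng, max_spans=4, alloweds=True):
    cands = []
    used = set()
    for _ in range(rng.integers(2, max_spans + 1)):
        s = int(rng.integers(1, 9))
        t = s + int(rng.integers(0, 4))
        if (s, t) in used:
            continue
        used.add((s, t))
        d = rng.dirichlet(np.ones(len(LABELS)))
        allowed = None
        if alloweds:
            pick = [y for y in LABELS[:-1] if rng.random() < 0.5]
            allowed = set(pick or [LABELS[int(rng.integers(0, 6))]])
        cands.append(
            CandidateSpan(span=(s, t), type_dist=d, entity_score=float(1 - d[-1]),
                          allowed_labels=allowed)
        )
    return _cset(cands)


# ------------------------------------------------------------ propagation


def test_propagation_k0_is_bit_identical(schema, rng):
    cs = _random_cset(rng)
    g = build_decode_graph(cs, None, DecodeConfig())
    before = [c.type_dist.copy() for c in cs.candidates]
    propagate(cs, g, None, 0)
    for c, b in zip(cs.candidates, before):
        assert np.array_equal(c.refined_dist, b)


def test_propagation_rows_sum_to_one(schema, tiny_params, rng):
    cs = _random_cset(rng)
    for c in cs.candidates:  # give reprs so the trained path runs
        c.repr = rng.normal(size=tiny_params["U_prop"].shape[1])
    cs.labels = list(tiny_params.labels) + ["NONE"]
    g = build_decode_graph(cs, tiny_params, DecodeConfig())
    propagate(cs, g, tiny_params, 2)
    for c in cs.candidates:
        assert abs(c.refined_dist.sum() - 1.0) < 1e-6


def test_propagation_edgeless_without_bias_is_uniform(schema, tiny_params):
    # distinct non-overlapping spans, W_sim irrelevant (no reprs -> sim 0.5 < eps)
    cs = _cset([_cand((1, 1), top="CELL"), _cand((5, 5), top="GENE")])
    p = tiny_params.copy()
    p["U_prop"].data[:] = 0.0
    g = build_decode_graph(cs, p, DecodeConfig(sim_threshold=0.7))
    assert not g.adjacency.any()
    propagate(cs, g, p, 1)
    for c in cs.candidates:
        # message and bias are zero -> z = sigmoid(0) = const -> softmax uniform
        assert np.allclose(c.refined_dist, 1.0 / len(LABELS))


def test_decode_graph_overlap_edge_regardless_of_similarity(schema):
    cs = _cset([_cand((1, 3), top="CELL"), _cand((2, 5), top="GENE")])
    g = build_decode_graph(cs, None, DecodeConfig(sim_threshold=0.99))
    assert g.adjacency[0, 1] and g.adjacency[1, 0]
    assert np.allclose(g.A.sum(axis=1), 1.0)  # row-normalized


# ------------------------------------------------------------ filtering / projection


def test_ontology_filter_excludes_on_confident_sibling(schema):
    probs = np.zeros(len(LABELS))
    probs[LABELS.index("CYTOKINE")] = 0.9  # sibling of CELL/DISEASE/GENE
    probs[LABELS.index("CELL")] = 0.05
    probs[-1] = 0.05
    cs = _cset([_cand((1, 1), probs=probs)])
    ontology_filter(cs, schema, 0.5)
    allowed = cs.candidates[0].allowed_labels
    assert "CELL" not in allowed and "DISEASE" not in allowed and "GENE" not in allowed
    assert "CYTOKINE" in allowed
    assert "T_CELL" in allowed  # no siblings -> always allowed


def test_ontology_filter_gamma_one_allows_everything(schema):
    cs = _cset([_cand((1, 1), top="CELL", p=0.9)])
    ontology_filter(cs, schema, 1.0)
    assert cs.candidates[0].allowed_labels == set(LABELS[:-1])


def test_ontology_filter_monotone_in_gamma(schema, rng):
    for _ in range(20):
        cs = _random_cset(rng, alloweds=False)
        gammas = sorted(rng.uniform(0.05, 1.0, size=3))
        prev = None
        for gam in gammas:
            cs2 = _cset([_cand(c.span, probs=c.type_dist) for c in cs.candidates])
            ontology_filter(cs2, schema, float(gam))
            cur = {c.span: set(c.allowed_labels) for c in cs2.candidates}
            if prev is not None:
                for span, allowed in prev.items():
                    assert allowed <= cur.get(span, set())
            prev = cur


def test_ontology_filter_no_siblings_schema_allows_all():
    sch = schema_from_dict({"types": [{"id": "A", "name": "a", "parent": "B"},
                                      {"id": "B", "name": "b"}]})
    labels = ["A", "B", "NONE"]
    cs = CandidateSet(
        [CandidateSpan(span=(1, 1), type_dist=np.array([0.8, 0.1, 0.1]),
                       entity_score=0.9)],
        labels,
    )
    ontology_filter(cs, sch, 0.5)
    assert cs.candidates[0].allowed_labels == {"A", "B"}


def test_ontology_filter_rejects_nonpositive_gamma(schema):
    with pytest.raises(ValueError):
        ontology_filter(_cset([_cand((1, 1), top="CELL")]), schema, 0.0)


def test_ontology_project_identity_and_chain():
    assert np.allclose(
        ontology_project(np.zeros(3), np.eye(3)), np.ones(3) / 3
    )
    sch = schema_from_dict(
        {"types": [{"id": "A", "name": "a", "parent": "B"},
                   {"id": "B", "name": "b", "parent": "C"},
                   {"id": "C", "name": "c"}]}
    )
    omega = sch.projection_matrix()
    v = np.array([2.0, 1.0, 0.5])  # scores for A, B, C
    out = ontology_project(v, omega)
    z = omega @ v  # direct matrix-product oracle
    assert np.allclose(out, np.exp(z - z.max()) / np.exp(z - z.max()).sum())
    assert abs(out.sum() - 1.0) < 1e-9


# ------------------------------------------------------------ penalty terms


def test_overlap_penalty_cases(schema):
    assert overlap_penalty({(1, 2, "CELL"), (4, 5, "GENE")}, schema) == 0
    assert overlap_penalty({(1, 3, "CELL"), (2, 5, "GENE")}, schema) == 1
    crossing = {(1, 3, "CELL"), (2, 4, "GENE"), (3, 5, "DISEASE")}
    assert overlap_penalty(crossing, schema) == 3  # brute-force pair count


def test_overlap_penalty_nesting_exemption(schema):
    nested = {(1, 4, "CELL"), (2, 3, "T_CELL")}  # (T_CELL|CELL) licensed
    assert overlap_penalty(nested, schema) == 0
    assert overlap_penalty(nested, schema, mode="strict") == 1
    unlicensed = {(1, 4, "GENE"), (2, 3, "DISEASE")}
    assert overlap_penalty(unlicensed, schema) == 1


def test_conflict_penalty_gated_by_structural_relation(schema):
    ok = {(1, 2, "CELL"), (3, 4, "CYTOKINE")}
    assert conflict_penalty(ok, schema) == 0  # admissible pair
    far = {(1, 2, "CYTOKINE"), (9, 10, "DISEASE")}
    assert conflict_penalty(far, schema) == 0  # inadmissible but unrelated
    nested = {(1, 4, "CYTOKINE"), (2, 3, "DISEASE")}
    assert conflict_penalty(nested, schema) == 1
    adjacent = {(1, 2, "CYTOKINE"), (3, 4, "DISEASE")}
    assert conflict_penalty(adjacent, schema) == 1


def test_context_reward_values(schema):
    cs = _cset([_cand((1, 1), top="CELL", alpha=0.0)])
    assert context_reward(set(), cs, schema) == 0.0
    val = context_reward({(1, 1, "CELL")}, cs, schema)
    assert abs(val - math.log(2)) < 1e-9  # eta=1, alpha=0 -> log(1+e^0)
    sch0 = schema_from_dict(
        {"types": [{"id": "CELL", "name": "c"}], "frequency_prior": {"CELL": 0.0}}
    )
    assert context_reward({(1, 1, "CELL")}, cs, sch0) == 0.0


# ------------------------------------------------------------ objective


def test_objective_decomposes_into_breakdown(schema, rng):
    cfg = DecodeConfig()
    for _ in range(25):
        cs = _random_cset(rng, alloweds=False)
        sel = set()
        for c in cs.candidates:
            if rng.random() < 0.6:
                sel.add((c.span[0], c.span[1], LABELS[int(rng.integers(0, 6))]))
        value, bd = selection_objective(sel, cs, schema, cfg)
        assert abs(value - sum(bd.values())) < 1e-9
        # independent term-by-term re-evaluation
        margins = 0.0
        for (s, t, y) in sel:
            c = next(c for c in cs.candidates if c.span == (s, t))
            d = np.clip(c.dist(), 1e-12, None)
            margins += math.log(d[LABELS.index(y)]) - math.log(d[-1])
        expected = (
            margins
            - cfg.lambda1 * overlap_penalty(sel, schema)
            - cfg.lambda2 * conflict_penalty(sel, schema)
            + cfg.lambda3 * context_reward(sel, cs, schema)
        )
        from spanccd.decoder import nesting_reward

        expected += nesting_reward(sel, schema)
        assert abs(value - expected) < 1e-9


def test_objective_empty_selection_is_zero(schema):
    cs = _cset([_cand((1, 1), top="CELL")])
    value, _ = selection_objective(set(), cs, schema, DecodeConfig())
    assert value == 0.0


def test_objective_rejects_disallowed_label(schema):
    cs = _cset([_cand((1, 1), top="CELL", allowed={"CELL"})])
    with pytest.raises(ValueError, match="not allowed"):
        selection_objective({(1, 1, "GENE")}, cs, schema, DecodeConfig())


# ------------------------------------------------------------ selection


def test_single_positive_margin_candidate_selected(schema):
    cs = _cset([_cand((1, 1), top="CELL", p=0.8)])
    sel = select_spans_exhaustive(cs, schema, DecodeConfig(lambda3=0.0))
    assert sel.chosen == {(1, 1, "CELL")}


def test_one_label_per_span_keeps_higher_margin(schema):
    probs = np.zeros(len(LABELS))
    probs[LABELS.index("CELL")] = 0.6
    probs[LABELS.index("GENE")] = 0.25
    probs[-1] = 0.15
    cs = _cset([_cand((2, 3), probs=probs, allowed={"CELL", "GENE"})])
    sel = select_spans_exhaustive(cs, schema, DecodeConfig(lambda3=0.0))
    assert sel.chosen == {(2, 3, "CELL")}


def test_heavy_overlap_penalty_drops_weaker_crossing_span(schema):
    a = _cand((1, 3), top="CELL", p=0.62, allowed={"CELL"})
    b = _cand((2, 5), top="GENE", p=0.55, allowed={"GENE"})
    cfg = DecodeConfig(lambda1=10.0, lambda3=0.0)
    sel = select_spans_exhaustive(_cset([a, b]), schema, cfg)
    assert sel.chosen == {(1, 3, "CELL")}


def test_exhaustive_capacity_error(schema, rng):
    cands = [
        _cand((i, i), top="CELL", allowed=set(LABELS[:-1]))
        for i in range(1, 5)
    ]
    with pytest.raises(CapacityError):
        select_spans_exhaustive(_cset(cands), schema, DecodeConfig())


def test_beam_equals_exhaustive_on_seeded_instances(schema):
    """Beam with width 2^n is the exhaustive argmax (oracle equivalence)."""
    rng = np.random.default_rng(123)
    checked = 0
    while checked < 120:
        cs = _random_cset(rng)
        n_atoms = sum(len(c.allowed_labels) for c in cs.candidates)
        if n_atoms > 10:
            continue
        cfg = DecodeConfig(beam_width=1 << n_atoms)
        ex = select_spans_exhaustive(cs, schema, cfg)
        bm = select_spans_beam(cs, schema, cfg)
        assert bm.chosen == ex.chosen
        assert abs(bm.objective_value - ex.objective_value) < 1e-9
        checked += 1


def test_beam_width_monotone_objective(schema):
    rng = np.random.default_rng(7)
    for _ in range(40):
        cs = _random_cset(rng)
        values = []
        for w in (1, 4, 16):
            cfg = DecodeConfig(beam_width=w)
            values.append(select_spans_beam(cs, schema, cfg).objective_value)
        assert values[0] <= values[1] + 1e-12
        assert values[1] <= values[2] + 1e-12


def test_beam_width_one_single_candidate(schema):
    cs = _cset([_cand((1, 1), top="CELL", allowed={"CELL"})])
    ex = select_spans_exhaustive(cs, schema, DecodeConfig(beam_width=1))
    bm = select_spans_beam(cs, schema, DecodeConfig(beam_width=1))
    assert bm.chosen == ex.chosen


# ------------------------------------------------------------ decode pipeline


def test_decode_candidates_no_constraints_is_argmax_threshold(schema):
    cs = _cset(
        [
            _cand((1, 1), top="CELL", p=0.8),
            _cand((3, 3), top="GENE", p=0.3),  # below: NONE wins margin
        ]
    )
    cs.candidates[1].type_dist[-1] = 0.5
    cs.candidates[1].type_dist[:-1] = 0.5 / 6
    mentions = decode_candidates(cs, schema, baseline_config())
    assert [(m.start, m.end, m.label) for m in mentions] == [(1, 1, "CELL")]


def test_decode_output_no_duplicate_spans_or_foreign_labels(schema, rng):
    for _ in range(10):
        cs = _random_cset(rng, max_spans=6, alloweds=False)
        mentions = decode_candidates(cs, schema, DecodeConfig())
        spans = [(m.start, m.end) for m in mentions]
        assert len(spans) == len(set(spans))
        assert all(m.label in schema.labels for m in mentions)


def test_decode_eliminates_injected_crossing_pair(schema):
    """A confident gold-like span plus a crossing false positive: with a
    strong overlap weight the crossing span is never co-selected."""
    gold = _cand((2, 4), top="CELL", p=0.9)
    crossing = _cand((3, 6), top="GENE", p=0.6)
    cs = _cset([gold, crossing])
    mentions = decode_candidates(cs, schema, DecodeConfig(lambda1=10.0))
    spans = [(m.start, m.end) for m in mentions]
    for i, a in enumerate(spans):
        for b in spans[i + 1 :]:
            crossing_pair = a[0] <= b[1] and b[0] <= a[1] and not (
                (a[0] <= b[0] and b[1] <= a[1]) or (b[0] <= a[0] and a[1] <= b[1])
            )
            assert not crossing_pair
    assert (2, 4) in spans  # the strong span survives


def test_decode_empty_candidates(schema):
    assert decode_candidates(_cset([]), schema, DecodeConfig()) == []


def test_decode_empty_document(schema, tiny_params, tiny_config):
    from spanccd.corpus_io import tokenize_and_align
    from spanccd.decoder import decode

    doc = tokenize_and_align("", doc_id="empty")
    assert decode(doc, tiny_params, schema, tiny_config, DecodeConfig()) == []
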