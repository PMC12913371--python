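"""Contextual Constraint Decoding (CCD): global selection of a coherent
span set from pruned candidates.

The decoder refines candidate type distributions by graph-guided message
passing, removes schema-inadmissible labels by ontology filtering, and
then selects the subset of (span, label) atoms maximizing a constrained
objective:

    sum_{(s,t,y) in E} margin(s,t,y)
      - lambda1 * C_overlap(E)  - lambda2 * C_conflict(E)
      + lambda3 * K_context(E)  + R_nest(E)

where ``margin(s,t,y) = log P~(y|s,t) - log P~(NONE|s,t)`` (the
NONE-margin form; the literal sum-of-log-probabilities scoring is
available via ``margin_mode="log_prob"``), ``C_overlap`` counts
conflicting intersecting pairs (schema-licensed nestings exempt by
default), ``C_conflict`` counts structurally related pairs whose labels
are inadmissible under the schema's co-occurrence set C, ``K_context``
rewards type-homogeneous co-occurrence, and ``R_nest`` rewards same-type
nested pairs with the schema's nesting prior.

Selection is solved exactly by subset enumeration (``select_spans_
exhaustive``, small instances, the verification oracle) or approximately
by beam search over include/exclude decisions (``select_spans_beam``);
with ``beam_width >= 2**n_atoms`` the beam is exhaustive.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .candidates import CandidateSet, CandidateSpan
from .corpus_io import AnnotatedDocument, EntityMention
from .encoder import EncoderConfig, ModelParams, forward_spans, prune_spans
from .schema import NONE_LABEL, TypeSchema

__all__ = [
    "DecodeConfig",
    "Selection",
    "CapacityError",
    "build_decode_graph",
    "propagate",
    "ontology_filter",
    "ontology_project",
    "overlap_penalty",
    "conflict_penalty",
    "context_reward",
    "selection_objective",
    "select_spans_exhaustive",
    "select_spans_beam",
    "decode",
    "baseline_config",
]

_EPS = 1e-12


class CapacityError(RuntimeError):
    """Instance too large for exhaustive enumeration; use beam search."""


@dataclass
class DecodeConfig:
    """All CCD weights and thresholds.

    lambda1/2/3 weight the overlap penalty, the conflict penalty and the
    context reward; ``sim_threshold`` (epsilon) gates semantic edges in
    the propagation graph; ``filter_threshold`` (gamma) is the sibling
    confidence bound of ontology filtering; ``propagation_rounds`` is K.
    Defaults are this package's choices (documented in the config
    reference; the method itself prescribes none).
    """

    lambda1: float = 1.0
    lambda2: float = 1.0
    lambda3: float = 0.1
    sim_threshold: float = 0.7
    filter_threshold: float = 0.5
    propagation_rounds: int = 2
    beam_width: int = 16
    use_propagation: bool = True
    use_filtering: bool = True
    use_nesting_prior: bool = True
    # candidate-set formation (threshold + top-k pruning)
    prune_threshold: float = 0.5
    prune_top_k: int = 40
    # variant switches
    margin_mode: str = "none_margin"  # or "log_prob"
    overlap_mode: str = "exempt_nested"  # or "strict"
    strict_conflict: bool = False  # reject inadmissible pairs outright
    max_adjacent_gap: int = 0

    def __post_init__(self) -> None:
        if self.beam_width < 1:
            raise ValueError("beam_width must be >= 1")
        if self.propagation_rounds < 0:
            raise ValueError("propagation_rounds must be >= 0")
        if not (0.0 < self.sim_threshold < 1.0):
            raise ValueError("sim_threshold must be in (0, 1)")
        if not (0.0 < self.filter_threshold <= 1.0):
            raise ValueError("filter_threshold must be in (0, 1]")
        if min(self.lambda1, self.lambda2, self.lambda3) < 0:
            raise ValueError("lambda weights must be nonnegative")


def baseline_config(**overrides) -> DecodeConfig:
    """No-constraint argmax-threshold baseline: all penalties/rewards off."""
    cfg = DecodeConfig(
        lambda1=0.0,
        lambda2=0.0,
        lambda3=0.0,
        use_propagation=False,
        use_filtering=False,
        use_nesting_prior=False,
    )
    return replace(cfg, **overrides)


@dataclass
class Selection:
    """A decoded span set with its objective value and term breakdown.

    Breakdown values are signed and weighted; their sum equals
    ``objective_value``.
    """

    chosen: set[tuple[int, int, str]]
    objective_value: float
    breakdown: dict[str, float] = field(default_factory=dict)


# ----------------------------------------------------------------------
# span geometry helpers


def _intersects(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] <= b[1] and b[0] <= a[1]


def _nested(inner: tuple[int, int], outer: tuple[int, int]) -> bool:
    """Strict containment: outer covers inner and spans differ."""
    return outer[0] <= inner[0] and inner[1] <= outer[1] and inner != outer


def _structurally_related(a, b, max_adjacent_gap: int = 0) -> bool:
    if _intersects(a, b):
        return True
    gap = max(a[0], b[0]) - min(a[1], b[1]) - 1
    return 0 <= gap <= max_adjacent_gap


def _inner_outer(a_span, a_label, b_span, b_label):
    if _nested(a_span, b_span):
        return (a_span, a_label, b_span, b_label)
    if _nested(b_span, a_span):
        return (b_span, b_label, a_span, a_label)
    return None


# ----------------------------------------------------------------------
# graph-guided propagation


@dataclass
class DecodeGraph:
    adjacency: np.ndarray  # (n, n) bool
    A: np.ndarray  # row-normalized weights
    sim: np.ndarray


def build_decode_graph(
    candidates: CandidateSet,
    params: ModelParams | None,
    config: DecodeConfig,
) -> DecodeGraph:
    """Span-level graph for propagation: Sim = sigmoid(r~' W_sim r~');
    an edge exists where Sim >= epsilon or the token intervals overlap.
    The adjacency is row-normalized to A for message passing."""
    cands = candidates.candidates
    n = len(cands)
    reprs = None
    if params is not None and all(c.repr is not None for c in cands) and n > 0:
        reprs = np.stack([c.repr for c in cands])
    if reprs is not None:
        w = params["W_sim"].data
        sim = 1.0 / (1.0 + np.exp(-(reprs @ w @ reprs.T)))
    else:
        sim = np.full((n, n), 0.5)
    overlap = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            if _intersects(cands[i].span, cands[j].span):
                overlap[i, j] = overlap[j, i] = True
    adj = ((sim >= config.sim_threshold) | overlap) & ~np.eye(n, dtype=bool)
    weights = np.where(adj, sim, 0.0)
    row = weights.sum(axis=1, keepdims=True)
    A = np.divide(weights, row, out=np.zeros_like(weights), where=row > 0)
    return DecodeGraph(adjacency=adj, A=A, sim=sim)


def propagate(
    candidates: CandidateSet,
    graph: DecodeGraph,
    params: ModelParams | None,
    K: int,
) -> CandidateSet:
    """K rounds of message passing over the decode graph:
    z^{k+1}_i = sigmoid(sum_j A_ij W_prop z^k_j + U_prop r~_i),
    refined distribution P~ = softmax(z^K).  K = 0 leaves the
    distributions bit-identical.  The update is a trained refinement:
    without model parameters it degrades to the identity (K = 0), since
    running it with placeholder weights would only destroy calibration."""
    cands = candidates.candidates
    if K == 0 or not cands or params is None:
        for c in cands:
            c.refined_dist = c.type_dist.copy()
        return candidates
    W = params["W_prop"].data
    U = params["U_prop"].data
    Z = np.log(np.clip(np.stack([c.type_dist for c in cands]), _EPS, None))
    if all(c.repr is not None for c in cands):
        R = np.stack([c.repr for c in cands])
        bias = R @ U.T
    else:
        bias = np.zeros_like(Z)
    for _ in range(K):
        Z = 1.0 / (1.0 + np.exp(-((graph.A @ Z) @ W.T + bias)))
    e = np.exp(Z - Z.max(axis=1, keepdims=True))
    P = e / e.sum(axis=1, keepdims=True)
    for c, row in zip(cands, P):
        c.refined_dist = row
    return candidates


# ----------------------------------------------------------------------
# ontology-aware filtering / projection


def ontology_filter(
    candidates: CandidateSet, schema: TypeSchema, gamma: float
) -> CandidateSet:
    """Allow label y for a span iff every sibling y' of y has
    P(y'|s,t) < gamma.  Labels with no siblings are always allowed.
    Candidates whose allowed set becomes empty are dropped (logged on
    ``CandidateSet.dropped``)."""
    if gamma <= 0.0:
        raise ValueError("filter threshold gamma must be positive")
    labels = candidates.labels
    kept: list[CandidateSpan] = []
    for c in candidates.candidates:
        dist = c.dist()
        allowed = set()
        for y in candidates.entity_labels:
            sibs = schema.siblings(y)
            if all(dist[labels.index(s)] < gamma for s in sibs if s in labels):
                allowed.add(y)
        if allowed:
            c.allowed_labels = allowed
            kept.append(c)
        else:
            candidates.dropped.append((c.span, "empty allowed_labels"))
    candidates.candidates = kept
    return candidates


def ontology_project(
    struct_repr: np.ndarray,
    projection_matrix: np.ndarray,
    adapter: np.ndarray | None = None,
) -> np.ndarray:
    """Diagnostic ontology projection s_{s,t} = softmax(Omega . a(r~)),
    where a(.) maps the span representation to a |Y|-vector (identity if
    it already has that length, otherwise the supplied adapter matrix)."""
    v = np.asarray(struct_repr, dtype=float)
    n = projection_matrix.shape[0]
    if v.shape[-1] != n:
        if adapter is None:
            raise ValueError(
                f"representation of length {v.shape[-1]} needs an adapter to |Y|={n}"
            )
        v = v @ adapter
    z = projection_matrix @ v
    e = np.exp(z - z.max())
    return e / e.sum()


# ----------------------------------------------------------------------
# objective terms (public, per-selection)


def overlap_penalty(
    selection: set[tuple[int, int, str]],
    schema: TypeSchema | None = None,
    mode: str = "exempt_nested",
) -> int:
    """Number of unordered pairs of distinct selected triples whose token
    intervals intersect with different (s, t).  In ``exempt_nested`` mode
    pairs in a schema-licensed nesting relation — inner strictly nested in
    outer with (inner_label, outer_label) a key of the schema's nesting
    prior — are not counted; ``strict`` counts every intersecting pair."""
    triples = sorted(selection)
    count = 0
    for i, (s1, t1, y1) in enumerate(triples):
        for (s2, t2, y2) in triples[i + 1 :]:
            if (s1, t1) == (s2, t2) or not _intersects((s1, t1), (s2, t2)):
                continue
            if mode == "exempt_nested" and schema is not None:
                io = _inner_outer((s1, t1), y1, (s2, t2), y2)
                if io is not None and (io[1], io[3]) in schema.nesting_prior:
                    continue
            count += 1
    return count


def conflict_penalty(
    selection: set[tuple[int, int, str]],
    schema: TypeSchema,
    max_adjacent_gap: int = 0,
) -> int:
    """Pairs whose labels are inadmissible (compatibility = -inf) and
    which stand in a structural relation (nested, overlapping, or
    adjacent)."""
    triples = sorted(selection)
    count = 0
    for i, (s1, t1, y1) in enumerate(triples):
        for (s2, t2, y2) in triples[i + 1 :]:
            if schema.compatibility(y1, y2) != -np.inf:
                continue
            if _structurally_related((s1, t1), (s2, t2), max_adjacent_gap):
                count += 1
    return count


def context_reward(
    selection: set[tuple[int, int, str]],
    candidates: CandidateSet,
    schema: TypeSchema,
) -> float:
    """K_context = sum_y eta_y log(1 + sum_{(s,t,y) selected} exp(alpha))."""
    alpha = {c.span: c.entity_score for c in candidates.candidates}
    by_type: dict[str, float] = {}
    for (s, t, y) in selection:
        by_type[y] = by_type.get(y, 0.0) + math.exp(alpha.get((s, t), 0.0))
    return sum(schema.eta(y) * math.log1p(v) for y, v in by_type.items())


def nesting_reward(
    selection: set[tuple[int, int, str]], schema: TypeSchema
) -> float:
    """R_nest: for each nested selected pair with equal labels, add the
    schema's gamma prior for that (inner, outer) label pair."""
    triples = sorted(selection)
    total = 0.0
    for i, (s1, t1, y1) in enumerate(triples):
        for (s2, t2, y2) in triples[i + 1 :]:
            io = _inner_outer((s1, t1), y1, (s2, t2), y2)
            if io is not None and y1 == y2:
                total += schema.gamma(io[1], io[3])
    return total


def _margin(c: CandidateSpan, labels: list[str], y: str, mode: str) -> float:
    dist = np.clip(c.dist(), _EPS, None)
    lp = math.log(dist[labels.index(y)])
    if mode == "log_prob":
        return lp
    return lp - math.log(dist[labels.index(NONE_LABEL)])


def selection_objective(
    selection: set[tuple[int, int, str]],
    candidates: CandidateSet,
    schema: TypeSchema,
    config: DecodeConfig,
) -> tuple[float, dict[str, float]]:
    """Evaluate the constrained objective for an explicit selection.

    Returns (value, breakdown); breakdown terms are signed and weighted
    so that their sum equals the value.
    """
    by_span = {c.span: c for c in candidates.candidates}
    score_sum = 0.0
    for (s, t, y) in selection:
        c = by_span.get((s, t))
        if c is None:
            raise ValueError(f"selection references unknown candidate ({s}, {t})")
        if c.allowed_labels is not None and y not in c.allowed_labels:
            raise ValueError(f"label {y!r} not allowed for span ({s}, {t})")
        score_sum += _margin(c, candidates.labels, y, config.margin_mode)
    ov = overlap_penalty(selection, schema, config.overlap_mode)
    cf = conflict_penalty(selection, schema, config.max_adjacent_gap)
    ctx = context_reward(selection, candidates, schema)
    nest = nesting_reward(selection, schema) if config.use_nesting_prior else 0.0
    breakdown = {
        "score_sum": score_sum,
        "overlap_pen": -config.lambda1 * ov,
        "conflict_pen": -config.lambda2 * cf,
        "context_reward": config.lambda3 * ctx,
        "nesting_reward": nest,
    }
    return sum(breakdown.values()), breakdown


# ----------------------------------------------------------------------
# selection instances (shared by the exhaustive oracle and beam search)


class _Instance:
    """Precomputed atom-level view of a selection problem."""

    def __init__(self, candidates: CandidateSet, schema: TypeSchema, config: DecodeConfig):
        self.config = config
        self.schema = schema
        self.labels = candidates.labels
        atoms: list[tuple[tuple[int, int], str, CandidateSpan]] = []
        for c in candidates.candidates:
            allowed = (
                sorted(c.allowed_labels)
                if c.allowed_labels is not None
                else candidates.entity_labels
            )
            for y in allowed:
                atoms.append((c.span, y, c))
        atoms.sort(key=lambda a: (a[0], a[1]))
        self.atoms = atoms
        n = len(atoms)
        self.n = n
        self.margins = np.array(
            [_margin(c, self.labels, y, config.margin_mode) for _, y, c in atoms]
        )
        self.exp_alpha = np.array([math.exp(c.entity_score) for _, _, c in atoms])
        types = sorted({y for _, y, _ in atoms})
        self.type_index = {y: k for k, y in enumerate(types)}
        self.type_onehot = np.zeros((n, len(types)))
        for i, (_, y, _) in enumerate(atoms):
            self.type_onehot[i, self.type_index[y]] = 1.0
        self.eta = np.array([schema.eta(y) for y in types])
        # pairwise weights and validity
        self.invalid = np.zeros((n, n), dtype=bool)
        self.pairw = np.zeros((n, n))
        for i in range(n):
            si, yi, _ = atoms[i]
            for j in range(i + 1, n):
                sj, yj, _ = atoms[j]
                w = 0.0
                if si == sj:
                    self.invalid[i, j] = self.invalid[j, i] = True
                    continue
                if _intersects(si, sj):
                    exempt = False
                    if config.overlap_mode == "exempt_nested":
                        io = _inner_outer(si, yi, sj, yj)
                        exempt = io is not None and (io[1], io[3]) in schema.nesting_prior
                    if not exempt:
                        w -= config.lambda1
                if schema.compatibility(yi, yj) == -np.inf and _structurally_related(
                    si, sj, config.max_adjacent_gap
                ):
                    if config.strict_conflict:
                        self.invalid[i, j] = self.invalid[j, i] = True
                        continue
                    w -= config.lambda2
                if config.use_nesting_prior and yi == yj:
                    io = _inner_outer(si, yi, sj, yj)
                    if io is not None:
                        w += schema.gamma(io[1], io[3])
                self.pairw[i, j] = self.pairw[j, i] = w

    def score_masks(self, bits: np.ndarray) -> np.ndarray:
        """Vectorized exact objective for boolean atom masks (m, n);
        invalid selections score -inf."""
        bits = bits.astype(float)
        base = bits @ self.margins
        pair = 0.5 * np.einsum("mi,ij,mj->m", bits, self.pairw, bits)
        bad = np.einsum("mi,ij,mj->m", bits, self.invalid.astype(float), bits) > 0
        sel_exp = bits @ (self.exp_alpha[:, None] * self.type_onehot)
        ctx = np.log1p(sel_exp) @ self.eta
        value = base + pair + self.config.lambda3 * ctx
        value[bad] = -np.inf
        return value

    def triples(self, mask: int) -> set[tuple[int, int, str]]:
        return {
            (self.atoms[i][0][0], self.atoms[i][0][1], self.atoms[i][1])
            for i in range(self.n)
            if mask >> i & 1
        }

    def tie_key(self, mask: int):
        sel = sorted(self.triples(mask))
        return (len(sel), sel)


def _mask_bits(masks: list[int], n: int) -> np.ndarray:
    if n <= 62:
        arr = np.asarray(masks, dtype=np.int64)
        return ((arr[:, None] >> np.arange(max(n, 1))) & 1).astype(float)[:, :n]
    # arbitrary-precision fallback for wide atom sets
    return np.array([[(m >> i) & 1 for i in range(n)] for m in masks], dtype=float)


def _best_mask(inst: _Instance, masks: list[int]) -> tuple[int, float]:
    values = inst.score_masks(_mask_bits(masks, inst.n))
    best_val = values.max()
    cands = [m for m, v in zip(masks, values) if v >= best_val - 1e-12]
    best = min(cands, key=inst.tie_key)
    return best, float(values[masks.index(best)])


def select_spans_exhaustive(
    candidates: CandidateSet, schema: TypeSchema, config: DecodeConfig
) -> Selection:
    """Exact argmax by enumeration of all label-consistent subsets.

    Verification oracle; limited to 16 (candidate, allowed-label) atoms.
    Ties broken by (fewer spans, then lexicographic triples)."""
    inst = _Instance(candidates, schema, config)
    if inst.n > 16:
        raise CapacityError(
            f"{inst.n} atoms exceed the exhaustive limit of 16; use select_spans_beam"
        )
    masks = list(range(1 << inst.n))
    best, value = _best_mask(inst, masks)
    chosen = inst.triples(best)
    value, breakdown = selection_objective(chosen, candidates, schema, config)
    return Selection(chosen=chosen, objective_value=value, breakdown=breakdown)


def select_spans_beam(
    candidates: CandidateSet, schema: TypeSchema, config: DecodeConfig
) -> Selection:
    """Beam search over include/exclude decisions, atoms visited in
    descending-margin order.  States are scored by the exact partial
    objective plus an optimistic bound (the sum of remaining positive
    margins); states violating one-label-per-span are pruned; the best
    complete state is returned with the same tie-break as the exhaustive
    oracle.  With beam_width >= 2**n_atoms this is exhaustive."""
    inst = _Instance(candidates, schema, config)
    n = inst.n
    if n == 0:
        sel: set[tuple[int, int, str]] = set()
        value, breakdown = selection_objective(sel, candidates, schema, config)
        return Selection(chosen=sel, objective_value=value, breakdown=breakdown)
    order = sorted(
        range(n), key=lambda i: (-inst.margins[i], inst.atoms[i][0], inst.atoms[i][1])
    )
    pos = np.array([max(inst.margins[i], 0.0) for i in order])
    remaining = np.concatenate([np.cumsum(pos[::-1])[::-1][1:], [0.0]])
    n_types = inst.type_onehot.shape[1]
    atom_type = inst.type_onehot.argmax(axis=1)
    # state: (mask, membership bits, incremental score, per-type exp-alpha sums)
    states = [(0, np.zeros(n, dtype=bool), 0.0, np.zeros(n_types))]
    for step, a in enumerate(order):
        bit = 1 << a
        ty = atom_type[a]
        e_a = inst.exp_alpha[a]
        expanded = list(states)
        for (mask, bits, score, tsums) in states:
            if (inst.invalid[a] & bits).any():
                continue
            delta = inst.margins[a] + float(inst.pairw[a] @ bits)
            delta += inst.config.lambda3 * inst.eta[ty] * (
                math.log1p(tsums[ty] + e_a) - math.log1p(tsums[ty])
            )
            new_bits = bits.copy()
            new_bits[a] = True
            new_tsums = tsums.copy()
            new_tsums[ty] += e_a
            expanded.append((mask | bit, new_bits, score + delta, new_tsums))
        # the optimistic bound (remaining positive margins) is the same for
        # every state at a given depth, so it shifts but never reorders
        expanded.sort(key=lambda st: (-(st[2] + remaining[step]), inst.tie_key(st[0])))
        states = expanded[: config.beam_width]
    best, _ = _best_mask(inst, [st[0] for st in states])
    chosen = inst.triples(best)
    value, breakdown = selection_objective(chosen, candidates, schema, config)
    return Selection(chosen=chosen, objective_value=value, breakdown=breakdown)


# ----------------------------------------------------------------------
# full decoding pipeline


def decode(
    doc: AnnotatedDocument,
    params: ModelParams,
    schema: TypeSchema,
    encoder_config: EncoderConfig,
    decode_config: DecodeConfig,
) -> list[EntityMention]:
    """Full pipeline: encode -> enumerate/aggregate/attend -> classify ->
    prune -> (propagate) -> (filter) -> global selection.  Returns
    mentions with confidence P~(y | s, t); stages are toggled by the
    config's ablation switches."""
    if not doc.tokens:
        return []
    batch = forward_spans(doc, params, encoder_config)
    cset = prune_spans(batch, decode_config.prune_threshold, decode_config.prune_top_k)
    return decode_candidates(cset, schema, decode_config, params=params)


def decode_candidates(
    cset: CandidateSet,
    schema: TypeSchema,
    decode_config: DecodeConfig,
    params: ModelParams | None = None,
) -> list[EntityMention]:
    """Decoder-only entry point: run CCD on an explicit candidate set
    (e.g. loaded from JSON), without the encoder."""
    if not cset.candidates:
        return []
    if decode_config.use_propagation:
        graph = build_decode_graph(cset, params, decode_config)
        propagate(cset, graph, params, decode_config.propagation_rounds)
    else:
        for c in cset.candidates:
            c.refined_dist = c.type_dist.copy()
    if decode_config.use_filtering:
        ontology_filter(cset, schema, decode_config.filter_threshold)
    # keep only positive-margin atoms: a negative-margin atom can raise
    # the objective only through the small context term
    pruned_cands = []
    for c in cset.candidates:
        allowed = c.allowed_labels if c.allowed_labels is not None else set(cset.entity_labels)
        positive = {
            y
            for y in allowed
            if _margin(c, cset.labels, y, decode_config.margin_mode) > 0
        }
        if positive:
            pruned_cands.append(replace_allowed(c, positive))
    work = CandidateSet(candidates=pruned_cands, labels=cset.labels)
    selection = select_spans_beam(work, schema, decode_config)
    by_span = {c.span: c for c in cset.candidates}
    mentions = []
    for (s, t, y) in sorted(selection.chosen):
        c = by_span[(s, t)]
        mentions.append(
            EntityMention(s, t, y, confidence=float(c.prob(cset.labels, y)))
        )
    return mentions


def replace_allowed(c: CandidateSpan, allowed: set[str]) -> CandidateSpan:
    return CandidateSpan(
        span=c.span,
        type_dist=c.type_dist,
        entity_score=c.entity_score,
        refined_dist=c.refined_dist,
        allowed_labels=allowed,
        repr=c.repr,
    )
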