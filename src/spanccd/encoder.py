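"""Structured span encoder: token encoding, span enumeration, multi-channel
aggregation with length embeddings and gating, token-graph augmentation,
structural attention over a span graph, span self-attention with a
distance/nesting-depth bias, and span classification.

The trainable "tiny" backend is a small seeded word-embedding +
self-attention stack that runs entirely in-process; it stands behind the
same encoder contract a large pretrained transformer would (the
``"pretrained"`` backend is an adapter contract mapping subword vectors
to word-level rows by first-subword pooling and requires the caller to
supply an embedding provider).

Pipeline order (ablatable): token-graph augmentation -> multi-channel
aggregation -> gating -> structural attention -> span self-attention ->
classification -> pruning.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .candidates import CandidateSet, CandidateSpan
from .corpus_io import AnnotatedDocument
from .schema import NONE_LABEL, TypeSchema

__all__ = [
    "EncoderConfig",
    "ModelParams",
    "SpanBatch",
    "SpanGraph",
    "TokenGraph",
    "CapabilityError",
    "init_params",
    "build_vocab",
    "encode_tokens",
    "enumerate_spans",
    "count_spans",
    "token_similarity_graph",
    "graph_augment_tokens",
    "aggregate_spans",
    "gate_spans",
    "build_span_graph",
    "structural_attention",
    "span_self_attention",
    "classify_spans",
    "prune_spans",
    "forward_spans",
    "nesting_depths",
    "pool_first_subword",
]

# phi bias buckets on |s_i - s_j|: {0, 1, 2, 3-4, 5-8, 9+}
_DIST_BUCKET_EDGES = (0, 1, 2, 4, 8)


class CapabilityError(RuntimeError):
    """A configured backend or feature is unavailable in this process."""


@dataclass
class EncoderConfig:
    """Hyperparameters of the span encoder.

    ``length_embed_dim=None`` means "equal to hidden_dim" (the span-width
    embedding psi then has the same width as a token embedding).
    """

    hidden_dim: int = 64
    max_span_len: int = 5
    length_embed_dim: int | None = None
    token_sim_threshold: float = 0.7
    n_self_attention_layers: int = 1
    n_structural_layers: int = 1
    dropout: float = 0.1
    backend: str = "tiny"
    seed: int = 0
    # tiny-backend internals
    n_encoder_layers: int = 2
    n_encoder_heads: int = 2
    context_window: int | None = None  # None = full bidirectional attention
    max_positions: int = 512
    # ablation switches
    use_token_graph: bool = True
    use_length_embed: bool = True  # False = 4-channel aggregation (no psi)
    max_adjacent_gap: int = 0

    def __post_init__(self) -> None:
        if self.hidden_dim <= 0 or self.max_span_len <= 0:
            raise ValueError("hidden_dim and max_span_len must be positive")
        if not (0.0 <= self.dropout < 1.0):
            raise ValueError("dropout must be in [0, 1)")
        if not (0.0 < self.token_sim_threshold < 1.0):
            raise ValueError("token_sim_threshold must be in (0, 1)")
        if self.backend not in ("tiny", "pretrained"):
            raise ValueError(f"unknown backend {self.backend!r}")

    @property
    def psi_dim(self) -> int:
        return self.hidden_dim if self.length_embed_dim is None else self.length_embed_dim

    @property
    def repr_dim(self) -> int:
        """Dimensionality of the raw multi-channel span representation."""
        return 4 * self.hidden_dim + (self.psi_dim if self.use_length_embed else 0)


@dataclass
class TokenGraph:
    """Token similarity graph: boolean adjacency + differentiable Sim."""

    adjacency: np.ndarray  # (T, T) bool, no self loops
    sim: Tensor  # (T, T) sigmoid similarities


@dataclass
class SpanGraph:
    """Structural span graph with per-relation boolean adjacency."""

    spans: list[tuple[int, int]]
    nested: np.ndarray
    overlap: np.ndarray
    adjacent: np.ndarray
    attention: np.ndarray | None = None  # last structural-attention weights

    @property
    def neighbors(self) -> np.ndarray:
        return self.nested | self.overlap | self.adjacent

    def relation(self, i: int, j: int) -> str | None:
        if self.nested[i, j]:
            return "nested"
        if self.overlap[i, j]:
            return "overlap"
        if self.adjacent[i, j]:
            return "adjacent"
        return None

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(range(len(self.spans)))
        n = len(self.spans)
        for i in range(n):
            for j in range(i + 1, n):
                rel = self.relation(i, j)
                if rel:
                    g.add_edge(i, j, relation=rel)
        return g


@dataclass
class SpanBatch:
    """Candidate spans of one document with staged representations."""

    spans: list[tuple[int, int]]
    raw_repr: Tensor | None = None
    length_embed: Tensor | None = None
    gate: Tensor | None = None
    final_repr: Tensor | None = None
    struct_repr: Tensor | None = None
    logits: Tensor | None = None
    type_dist: Tensor | None = None
    labels: list[str] | None = None  # classifier column order, NONE last

    @property
    def type_dist_array(self) -> np.ndarray:
        return self.type_dist.data


# ----------------------------------------------------------------------
# parameters


class ModelParams:
    """Named parameter tensors plus the vocabulary and config they bind to.

    Serialized as a single ``.npz`` checkpoint embedding the encoder
    config, the label order and a schema fingerprint; loading against a
    different schema is an error.
    """

    def __init__(
        self,
        tensors: dict[str, Tensor],
        vocab: dict[str, int],
        config: EncoderConfig,
        labels: list[str],
        schema_fingerprint: str,
    ):
        self.tensors = tensors
        self.vocab = vocab
        self.config = config
        self.labels = labels  # schema labels (sorted); classifier adds NONE
        self.schema_fingerprint = schema_fingerprint

    def __getitem__(self, name: str) -> Tensor:
        return self.tensors[name]

    def trainable(self) -> dict[str, Tensor]:
        return self.tensors

    def zero_grad(self) -> None:
        for t in self.tensors.values():
            t.zero_grad()

    def copy(self) -> "ModelParams":
        return ModelParams(
            {k: Tensor(v.data.copy(), requires_grad=True) for k, v in self.tensors.items()},
            dict(self.vocab),
            self.config,
            list(self.labels),
            self.schema_fingerprint,
        )

    def save(self, path) -> None:
        header = json.dumps(
            {
                "format": "spanccd-checkpoint-v1",
                "config": asdict(self.config),
                "labels": self.labels,
                "schema_fingerprint": self.schema_fingerprint,
                "vocab": self.vocab,
            },
            sort_keys=True,
        )
        arrays = {f"param/{k}": v.data for k, v in self.tensors.items()}
        np.savez(path, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path, schema: TypeSchema | None = None) -> "ModelParams":
        try:
            with np.load(path) as data:
                header = json.loads(bytes(data["__header__"]).decode())
                if header.get("format") != "spanccd-checkpoint-v1":
                    raise ValueError("not a spanccd checkpoint")
                tensors = {
                    k.removeprefix("param/"): Tensor(data[k].copy(), requires_grad=True)
                    for k in data.files
                    if k.startswith("param/")
                }
        except (OSError, KeyError, ValueError, json.JSONDecodeError) as err:
            raise CheckpointError(f"cannot load checkpoint {path}: {err}") from err
        if schema is not None and header["schema_fingerprint"] != schema.fingerprint():
            raise CheckpointError(
                "checkpoint schema fingerprint does not match the supplied schema"
            )
        return cls(
            tensors,
            header["vocab"],
            EncoderConfig(**header["config"]),
            header["labels"],
            header["schema_fingerprint"],
        )


class CheckpointError(RuntimeError):
    """Checkpoint file unreadable or bound to a different schema."""


def _glorot(rng: np.random.Generator, shape: tuple[int, ...]) -> np.ndarray:
    fan_in = shape[0] if len(shape) > 1 else shape[0]
    return rng.normal(0.0, 1.0 / math.sqrt(fan_in), size=shape)


def init_params(
    config: EncoderConfig, schema: TypeSchema, vocab: dict[str, int]
) -> ModelParams:
    """Seeded initialisation of every trainable tensor."""
    rng = np.random.default_rng(config.seed)
    d = config.hidden_dim
    dr = config.repr_dim
    labels = schema.labels
    n_classes = len(labels) + 1  # + NONE

    t: dict[str, np.ndarray] = {}
    t["E_tok"] = rng.normal(0.0, 0.1, size=(len(vocab), d))
    t["E_pos"] = rng.normal(0.0, 0.1, size=(config.max_positions, d))
    dh = d // config.n_encoder_heads
    for layer in range(config.n_encoder_layers):
        for h in range(config.n_encoder_heads):
            for nm in ("Wq", "Wk", "Wv"):
                t[f"enc{layer}_h{h}_{nm}"] = _glorot(rng, (d, dh))
        t[f"enc{layer}_Wo"] = _glorot(rng, (d, d))
        t[f"enc{layer}_ffn_W1"] = _glorot(rng, (d, 2 * d))
        t[f"enc{layer}_ffn_b1"] = np.zeros(2 * d)
        t[f"enc{layer}_ffn_W2"] = _glorot(rng, (2 * d, d))
        t[f"enc{layer}_ffn_b2"] = np.zeros(d)
    t["W_bilinear_token"] = _glorot(rng, (d, d))
    t["W_len"] = rng.normal(0.0, 0.1, size=(config.max_span_len, config.psi_dim))
    t["b_len"] = np.zeros(config.psi_dim)
    t["W_g_gate"] = _glorot(rng, (dr, dr))
    t["b_g_gate"] = np.zeros(dr)
    t["W_a"] = _glorot(rng, (dr, dr))
    t["ffn_W1"] = _glorot(rng, (dr, dr))
    t["ffn_b1"] = np.zeros(dr)
    t["ffn_W2"] = _glorot(rng, (dr, dr))
    t["ffn_b2"] = np.zeros(dr)
    t["W_Q"] = _glorot(rng, (dr, dr))
    t["W_K"] = _glorot(rng, (dr, dr))
    t["W_V"] = _glorot(rng, (dr, dr))
    t["phi_table"] = np.zeros((len(_DIST_BUCKET_EDGES) + 1, 5))
    t["W_cls"] = _glorot(rng, (dr, n_classes))
    t["b_cls"] = np.zeros(n_classes)
    t["W_sim"] = _glorot(rng, (dr, dr))
    t["W_prop"] = np.eye(n_classes) + rng.normal(0.0, 0.01, size=(n_classes, n_classes))
    t["U_prop"] = rng.normal(0.0, 0.01, size=(n_classes, dr))
    t["W_onto"] = _glorot(rng, (dr, len(labels)))
    tensors = {k: Tensor(v, requires_grad=True) for k, v in t.items()}
    return ModelParams(tensors, vocab, config, labels, schema.fingerprint())


def build_vocab(docs: list[AnnotatedDocument]) -> dict[str, int]:
    """Deterministic vocabulary: sorted unique token strings + <unk>."""
    words = sorted({tok.text for doc in docs for tok in doc.tokens})
    vocab = {"<unk>": 0}
    for w in words:
        vocab[w] = len(vocab)
    return vocab


# ----------------------------------------------------------------------
# token encoding


def _dropout(x: Tensor, p: float, rng: np.random.Generator | None) -> Tensor:
    if rng is None or p <= 0.0:
        return x
    mask = (rng.random(x.shape) >= p) / (1.0 - p)
    return x * mask


def encode_tokens(
    doc: AnnotatedDocument,
    params: ModelParams,
    config: EncoderConfig,
    dropout_rng: np.random.Generator | None = None,
) -> Tensor:
    """Contextual token embeddings h_t, shape (T, d).

    Deterministic given (params, config, input); dropout is applied only
    when a `dropout_rng` is supplied (training mode).
    """
    if not doc.tokens:
        raise ValueError(f"{doc.doc_id}: cannot encode an empty document")
    if config.backend == "pretrained":
        raise CapabilityError(
            "the 'pretrained' backend requires an embedding provider; use "
            "encode_tokens_pretrained(doc, provider, config)"
        )
    T = len(doc.tokens)
    ids = [params.vocab.get(tok.text, 0) for tok in doc.tokens[: config.max_positions]]
    T = len(ids)
    x = ad.take_rows(params["E_tok"], ids) + ad.take_rows(params["E_pos"], list(range(T)))
    if config.context_window is None:
        mask = np.ones((T, T), dtype=bool)
    else:
        idx = np.arange(T)
        mask = np.abs(idx[:, None] - idx[None, :]) <= config.context_window
    dh = config.hidden_dim // config.n_encoder_heads
    scale = 1.0 / math.sqrt(dh)
    for layer in range(config.n_encoder_layers):
        heads = []
        for h in range(config.n_encoder_heads):
            q = x @ params[f"enc{layer}_h{h}_Wq"]
            k = x @ params[f"enc{layer}_h{h}_Wk"]
            v = x @ params[f"enc{layer}_h{h}_Wv"]
            att = ad.masked_softmax(q @ k.T * scale, mask)
            heads.append(att @ v)
        attn_out = ad.concat(heads, axis=1) @ params[f"enc{layer}_Wo"]
        x = ad.layer_norm(x + _dropout(attn_out, config.dropout, dropout_rng))
        ffn = (
            ad.relu(x @ params[f"enc{layer}_ffn_W1"] + params[f"enc{layer}_ffn_b1"])
            @ params[f"enc{layer}_ffn_W2"]
            + params[f"enc{layer}_ffn_b2"]
        )
        x = ad.layer_norm(x + _dropout(ffn, config.dropout, dropout_rng))
    return x


def pool_first_subword(subword_vectors: np.ndarray, word_ids: list[int]) -> np.ndarray:
    """Adapter contract for the 'pretrained' backend: map subword vectors to
    word-level rows by taking each word's first subword vector.

    `word_ids[k]` is the 0-based word index of subword k (monotone
    nondecreasing; -1 marks special tokens to skip).
    """
    rows: list[np.ndarray] = []
    last = -1
    for k, w in enumerate(word_ids):
        if w < 0:
            continue
        if w != last:
            if w != last + 1:
                raise ValueError("word_ids must be monotone without gaps")
            rows.append(subword_vectors[k])
            last = w
    return np.asarray(rows)


def encode_tokens_pretrained(doc: AnnotatedDocument, provider, config: EncoderConfig) -> Tensor:
    """`provider(tokens) -> (subword_matrix, word_ids)`; pooled to word level."""
    if provider is None:
        raise CapabilityError("no pretrained embedding provider supplied")
    sub, word_ids = provider([t.text for t in doc.tokens])
    pooled = pool_first_subword(np.asarray(sub, dtype=np.float64), list(word_ids))
    if pooled.shape[0] != len(doc.tokens):
        raise ValueError("provider alignment does not cover every word")
    return Tensor(pooled)


# ----------------------------------------------------------------------
# span enumeration


def enumerate_spans(T: int, L_max: int) -> list[tuple[int, int]]:
    """All (s, t), 1-based inclusive, with t-s+1 <= L_max, sorted by (s, t)."""
    if T < 1 or L_max < 1:
        raise ValueError("T and L_max must be >= 1")
    return [(s, t) for s in range(1, T + 1) for t in range(s, min(s + L_max - 1, T) + 1)]


def count_spans(T: int, L_max: int) -> int:
    """Closed form: sum over lengths l=1..min(L_max,T) of (T - l + 1)."""
    m = min(L_max, T)
    return m * T - m * (m - 1) // 2


# ----------------------------------------------------------------------
# token graph


def token_similarity_graph(
    H: Tensor, W: Tensor, threshold: float
) -> TokenGraph:
    """Sim(i,j) = sigmoid(h_i' W h_j); edges where Sim >= threshold, i != j."""
    sim = ad.sigmoid(H @ W @ H.T)
    T = H.shape[0]
    adj = (sim.data >= threshold) & ~np.eye(T, dtype=bool)
    return TokenGraph(adjacency=adj, sim=sim)


def graph_augment_tokens(H: Tensor, graph: TokenGraph) -> Tensor:
    """h~_t = h_t + sum_j alpha_tj h_j, alpha = neighborhood softmax of Sim.
    Isolated tokens pass through unchanged."""
    alpha = ad.masked_softmax(graph.sim, graph.adjacency)
    return H + alpha @ H


# ----------------------------------------------------------------------
# span aggregation / gating


def _mean_pool_matrix(spans: list[tuple[int, int]], T: int) -> np.ndarray:
    M = np.zeros((len(spans), T))
    for i, (s, t) in enumerate(spans):
        M[i, s - 1 : t] = 1.0 / (t - s + 1)
    return M


def aggregate_spans(
    H: Tensor,
    spans: list[tuple[int, int]],
    params: ModelParams,
    config: EncoderConfig,
    _pool_cache: dict | None = None,
) -> SpanBatch:
    """Multi-channel span representation
    r_{s,t} = concat(h_s, h_t, mean, max, psi) with the span-width
    embedding psi = W_len[l] + b_len (omitted when use_length_embed is
    off, leaving the 4-channel form)."""
    T = H.shape[0]
    for (s, t) in spans:
        if not (1 <= s <= t <= T):
            raise ValueError(f"span ({s}, {t}) out of range 1..{T}")
    s_idx = [s - 1 for s, _ in spans]
    t_idx = [t - 1 for _, t in spans]
    if _pool_cache is not None and "mean" in _pool_cache:
        M = _pool_cache["mean"]
    else:
        M = _mean_pool_matrix(spans, T)
        if _pool_cache is not None:
            _pool_cache["mean"] = M
    h_s = ad.take_rows(H, s_idx)
    h_t = ad.take_rows(H, t_idx)
    h_mean = Tensor(M) @ H
    h_max = ad.span_max(H, [(s - 1, t - 1) for s, t in spans])
    channels = [h_s, h_t, h_mean, h_max]
    psi = None
    if config.use_length_embed:
        lengths = [t - s for s, t in spans]  # 0-based row l-1
        psi = ad.take_rows(params["W_len"], lengths) + params["b_len"]
        channels.append(psi)
    raw = ad.concat(channels, axis=1)
    return SpanBatch(spans=list(spans), raw_repr=raw, length_embed=psi)


def gate_spans(batch: SpanBatch, params: ModelParams) -> SpanBatch:
    """g = sigmoid(W_g r + b_g); r_final = g (elementwise) r."""
    if batch.raw_repr is None:
        raise ValueError("raw_repr missing; run aggregate_spans first")
    g = ad.sigmoid(batch.raw_repr @ params["W_g_gate"] + params["b_g_gate"])
    batch.gate = g
    batch.final_repr = g * batch.raw_repr
    return batch


# ----------------------------------------------------------------------
# span graph + structural layers


def build_span_graph(
    spans: list[tuple[int, int]], max_adjacent_gap: int = 0
) -> SpanGraph:
    """Relations: nested (strict containment either way), overlap
    (intersecting, neither contains), adjacent (gap <= max_adjacent_gap,
    default strict abutment).  Stored symmetrically."""
    n = len(spans)
    s = np.array([sp[0] for sp in spans])
    t = np.array([sp[1] for sp in spans])
    inter = (s[:, None] <= t[None, :]) & (s[None, :] <= t[:, None])
    contains = (s[:, None] <= s[None, :]) & (t[None, :] <= t[:, None])  # i contains j
    same = (s[:, None] == s[None, :]) & (t[:, None] == t[None, :])
    nested = (contains | contains.T) & ~same
    overlap = inter & ~contains & ~contains.T & ~same
    gap_ij = s[None, :] - t[:, None] - 1  # tokens strictly between t_i and s_j
    adj = (gap_ij >= 0) & (gap_ij <= max_adjacent_gap)
    adjacent = (adj | adj.T) & ~np.eye(n, dtype=bool) & ~inter
    return SpanGraph(spans=list(spans), nested=nested, overlap=overlap, adjacent=adjacent)


def structural_attention(
    batch: SpanBatch,
    graph: SpanGraph,
    params: ModelParams,
    config: EncoderConfig,
    dropout_rng: np.random.Generator | None = None,
) -> SpanBatch:
    """c_i = sum_{j in N(i)} alpha_ij r_j with bilinear attention
    alpha = softmax_j(r_i' W_a r_j); r~_i = LayerNorm(r_i + FFN(c_i)).
    Nodes with no neighbors use c_i = 0.  Applied n_structural_layers
    times (weights shared across rounds)."""
    if batch.final_repr is None:
        raise ValueError("final_repr missing; run gate_spans first")
    r = batch.final_repr
    mask = graph.neighbors
    for _ in range(config.n_structural_layers):
        scores = r @ params["W_a"] @ r.T
        alpha = ad.masked_softmax(scores, mask)
        c = alpha @ r
        ffn = ad.relu(c @ params["ffn_W1"] + params["ffn_b1"]) @ params["ffn_W2"] + params["ffn_b2"]
        r = ad.layer_norm(r + _dropout(ffn, config.dropout, dropout_rng))
        graph.attention = alpha.data
    batch.struct_repr = r
    if config.n_structural_layers == 0:
        batch.struct_repr = batch.final_repr
    return batch


def nesting_depths(spans: list[tuple[int, int]]) -> np.ndarray:
    """Depth of a span = number of candidate spans strictly containing it."""
    s = np.array([sp[0] for sp in spans])
    t = np.array([sp[1] for sp in spans])
    contains = (
        (s[:, None] <= s[None, :])
        & (t[None, :] <= t[:, None])
        & ~((s[:, None] == s[None, :]) & (t[:, None] == t[None, :]))
    )
    return contains.sum(axis=0)


def _phi_index_matrix(spans: list[tuple[int, int]]) -> np.ndarray:
    """Flattened (bucketed start distance, clipped depth difference) index."""
    s = np.array([sp[0] for sp in spans])
    dist = np.abs(s[:, None] - s[None, :])
    bucket = np.digitize(dist, _DIST_BUCKET_EDGES, right=True)
    depth = nesting_depths(spans)
    dd = np.clip(depth[:, None] - depth[None, :], -2, 2) + 2
    return bucket * 5 + dd


def span_self_attention(
    batch: SpanBatch,
    params: ModelParams,
    config: EncoderConfig,
    dropout_rng: np.random.Generator | None = None,
    _phi_cache: dict | None = None,
) -> SpanBatch:
    """Full pairwise span attention with a learned relative bias:
    score(i,j) = (r_i W_Q)(r_j W_K)' / sqrt(d_r) + phi(i,j), where phi is
    a lookup over (bucketed |s_i - s_j|, clipped nesting-depth
    difference).  Single head; residual + LayerNorm output."""
    if batch.struct_repr is None:
        raise ValueError("struct_repr missing; run structural_attention first")
    x = batch.struct_repr
    n = len(batch.spans)
    if _phi_cache is not None and "phi_idx" in _phi_cache:
        phi_idx = _phi_cache["phi_idx"]
    else:
        phi_idx = _phi_index_matrix(batch.spans)
        if _phi_cache is not None:
            _phi_cache["phi_idx"] = phi_idx
    scale = 1.0 / math.sqrt(x.shape[1])
    for _ in range(config.n_self_attention_layers):
        phi = ad.take_rows(params["phi_table"].reshape(-1), phi_idx.ravel()).reshape(n, n)
        scores = (x @ params["W_Q"]) @ (x @ params["W_K"]).T * scale + phi
        att = ad.softmax(scores, axis=-1)
        out = att @ (x @ params["W_V"])
        x = ad.layer_norm(x + _dropout(out, config.dropout, dropout_rng))
    batch.struct_repr = x
    return batch


# ----------------------------------------------------------------------
# classification / pruning


def classify_spans(batch: SpanBatch, params: ModelParams) -> SpanBatch:
    """P(y | s, t, x) = softmax over Y + {NONE} of theta_y' r~ + b_y."""
    if batch.struct_repr is None:
        raise ValueError("struct_repr missing")
    batch.logits = batch.struct_repr @ params["W_cls"] + params["b_cls"]
    batch.type_dist = ad.softmax(batch.logits, axis=-1)
    batch.labels = list(params.labels) + [NONE_LABEL]
    return batch


def prune_spans(batch: SpanBatch, keep_threshold: float, top_k: int) -> CandidateSet:
    """Keep spans with entity-ness alpha = 1 - P(NONE) >= keep_threshold,
    then cap at `top_k` by alpha (ties broken by (s, t) order)."""
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    if batch.type_dist is None:
        raise ValueError("type_dist missing; run classify_spans first")
    probs = batch.type_dist.data
    alpha = 1.0 - probs[:, -1]
    kept = [i for i in range(len(batch.spans)) if alpha[i] >= keep_threshold]
    kept.sort(key=lambda i: (-alpha[i], batch.spans[i]))
    kept = sorted(kept[:top_k], key=lambda i: batch.spans[i])
    reprs = batch.struct_repr.data if batch.struct_repr is not None else None
    cands = [
        CandidateSpan(
            span=batch.spans[i],
            type_dist=probs[i].copy(),
            entity_score=float(alpha[i]),
            repr=None if reprs is None else reprs[i].copy(),
        )
        for i in kept
    ]
    return CandidateSet(candidates=cands, labels=list(batch.labels))


# ----------------------------------------------------------------------
# full encoder forward


def forward_spans(
    doc: AnnotatedDocument,
    params: ModelParams,
    config: EncoderConfig,
    dropout_rng: np.random.Generator | None = None,
    cache: dict | None = None,
) -> SpanBatch:
    """Run the full span-encoder pipeline on one document.

    `cache` (optional, per-document) stores parameter-independent
    structures (span list, pooling matrix, span graph, phi indices) so
    repeated epochs do not recompute them.
    """
    H = encode_tokens(doc, params, config, dropout_rng)
    if config.use_token_graph:
        tg = token_similarity_graph(H, params["W_bilinear_token"], config.token_sim_threshold)
        H = graph_augment_tokens(H, tg)
    T = H.shape[0]
    if cache is not None and "spans" in cache:
        spans = cache["spans"]
        graph = cache["graph"]
    else:
        spans = enumerate_spans(T, config.max_span_len)
        graph = build_span_graph(spans, config.max_adjacent_gap)
        if cache is not None:
            cache["spans"] = spans
            cache["graph"] = graph
    batch = aggregate_spans(H, spans, params, config, _pool_cache=cache)
    batch = gate_spans(batch, params)
    batch = structural_attention(batch, graph, params, config, dropout_rng)
    batch = span_self_attention(batch, params, config, dropout_rng, _phi_cache=cache)
    batch = classify_spans(batch, params)
    return batch
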