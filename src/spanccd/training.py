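"""Training objectives and loop: span cross-entropy, type-centroid center
loss, margin contrastive loss, decoupled-weight-decay Adam, stratified
splits and early stopping on validation F1.

The center and contrastive losses are type-aware coherence regularizers:
spans predicted as the same type are pulled toward their batch centroid
(prototype) and pushed at least a squared-distance margin away from
competing centroids.  They act at training time only; decoding uses the
constrained selection objective exclusively.

The default learning rate (3e-5) and weight decay (0.01) are the
standard fine-tuning settings for a large pretrained encoder backbone.
The from-scratch tiny backend trains with a larger step (1e-3 is used in
tests and examples); pass ``learning_rate`` explicitly for that regime.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from . import _autodiff as ad
from ._autodiff import Tensor
from .corpus_io import AnnotatedDocument, EntityMention
from .decoder import DecodeConfig, decode
from .encoder import (
    EncoderConfig,
    ModelParams,
    SpanBatch,
    build_vocab,
    forward_spans,
    init_params,
)
from .evaluation import evaluate_docs
from .schema import NONE_LABEL, TypeSchema

__all__ = [
    "TrainConfig",
    "CentroidTable",
    "type_centroids",
    "center_loss",
    "contrastive_loss",
    "total_loss",
    "train",
    "split_corpus",
    "AdamW",
    "mean_intra_class_distance",
]


@dataclass
class TrainConfig:
    learning_rate: float = 3e-5
    weight_decay: float = 0.01
    batch_size: int = 16
    max_epochs: int = 30
    patience: int = 5
    # early-stopping burn-in: no stop before this epoch.  From-scratch runs
    # sit at zero validation F1 for several epochs before decoding anything;
    # a floor keeps patience from firing inside that warmup.
    min_epochs: int = 1
    max_seq_len: int = 512
    loss_weight_center: float = 0.01  # beta
    loss_weight_contrast: float = 0.01
    margin: float = 1.0  # delta of the contrastive hinge
    # auxiliary cross-entropy on propagation-refined distributions; this is
    # what trains W_prop / U_prop / W_sim used by the decoder
    loss_weight_prop: float = 1.0
    prop_rounds: int = 2
    prop_sim_threshold: float = 0.7
    grad_clip: float = 1.0
    centroid_ema: float | None = None  # e.g. 0.9; None = per-batch centroids
    seed: int = 0
    split_fractions: tuple[float, float, float] = (0.7, 0.1, 0.2)

    def __post_init__(self) -> None:
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split_fractions must sum to 1")
        if self.max_epochs > 0:
            # patience beyond the epoch budget can never trigger; clamp it
            self.patience = min(self.patience, self.max_epochs)
        if self.margin < 0:
            raise ValueError("margin must be nonnegative")
        if min(self.loss_weight_center, self.loss_weight_contrast) < 0:
            raise ValueError("loss weights must be nonnegative")


@dataclass
class CentroidTable:
    """Per-type prototype vectors mu_y with their support counts."""

    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    support: dict[str, int] = field(default_factory=dict)

    def __contains__(self, y: str) -> bool:
        return y in self.centroids


def type_centroids(
    struct_reprs: np.ndarray, predicted_labels: list[str]
) -> CentroidTable:
    """mu_y = mean representation over spans predicted as y (labels must
    not include NONE); labels without support are absent from the table."""
    table = CentroidTable()
    reprs = np.asarray(struct_reprs, dtype=float)
    groups: dict[str, list[int]] = {}
    for i, y in enumerate(predicted_labels):
        if y == NONE_LABEL:
            raise ValueError("predicted_labels must exclude NONE")
        groups.setdefault(y, []).append(i)
    for y, idx in groups.items():
        table.centroids[y] = reprs[idx].mean(axis=0)
        table.support[y] = len(idx)
    return table


def center_loss(
    struct_reprs: np.ndarray, labels: list[str], centroids: CentroidTable
) -> float:
    """Sum of squared Euclidean distances to the assigned centroid."""
    reprs = np.asarray(struct_reprs, dtype=float)
    total = 0.0
    for r, y in zip(reprs, labels):
        if y not in centroids:
            raise ValueError(f"no centroid for label {y!r}")
        total += float(((r - centroids.centroids[y]) ** 2).sum())
    return total


def contrastive_loss(
    struct_reprs: np.ndarray,
    labels: list[str],
    centroids: CentroidTable,
    margin: float,
) -> float:
    """Margin hinge over competing centroids (squared distances):
    sum_i sum_{y' != y_i} [delta + d2(r_i, mu_{y_i}) - d2(r_i, mu_{y'})]_+.
    Zero by vacuity when fewer than two labels have centroids."""
    if margin < 0:
        raise ValueError("margin must be nonnegative")
    if len(centroids.centroids) < 2:
        return 0.0
    reprs = np.asarray(struct_reprs, dtype=float)
    total = 0.0
    for r, y in zip(reprs, labels):
        if y not in centroids:
            raise ValueError(f"no centroid for label {y!r}")
        d_y = ((r - centroids.centroids[y]) ** 2).sum()
        for y2, mu2 in centroids.centroids.items():
            if y2 == y:
                continue
            d_y2 = ((r - mu2) ** 2).sum()
            total += max(0.0, margin + d_y - d_y2)
    return float(total)


def mean_intra_class_distance(
    params: ModelParams,
    docs: list[AnnotatedDocument],
    encoder_config: EncoderConfig,
    labels_from: str = "gold",
) -> float:
    """Mean Euclidean distance of entity-span representations to their type
    centroid — the compactness the center loss regularizes.

    ``labels_from="gold"`` groups the representations of gold mention spans
    by their gold label (well-defined for any model); ``"predicted"``
    mirrors the loss definition (predicted top-1 labels) but is 0.0 by
    convention when nothing is predicted as an entity.
    """
    reprs: list[np.ndarray] = []
    labels: list[str] = []
    for doc in docs:
        if not doc.tokens:
            continue
        batch = forward_spans(doc, params, encoder_config)
        if labels_from == "gold":
            span_index = {sp: i for i, sp in enumerate(batch.spans)}
            for m in doc.mentions:
                i = span_index.get((m.start, m.end))
                if i is not None:
                    reprs.append(batch.struct_repr.data[i])
                    labels.append(m.label)
        else:
            probs = batch.type_dist.data
            pred = probs.argmax(axis=1)
            none_idx = len(batch.labels) - 1
            for i in np.flatnonzero(pred != none_idx):
                reprs.append(batch.struct_repr.data[i])
                labels.append(batch.labels[pred[i]])
    if not reprs:
        return 0.0
    table = type_centroids(np.asarray(reprs), labels)
    dists = [
        float(np.linalg.norm(r - table.centroids[y])) for r, y in zip(reprs, labels)
    ]
    return float(np.mean(dists))


# ----------------------------------------------------------------------
# differentiable composite loss


def align_gold(
    spans: list[tuple[int, int]], gold: list[EntityMention], labels: list[str]
) -> tuple[np.ndarray, list[EntityMention]]:
    """Map enumerated spans to gold label indices (NONE where unmatched);
    gold mentions absent from the enumeration (e.g. longer than L_max)
    are returned separately for logging."""
    gold_by_span = {(m.start, m.end): m.label for m in gold}
    idx = {y: k for k, y in enumerate(labels)}
    none_idx = idx[NONE_LABEL]
    out = np.full(len(spans), none_idx, dtype=np.intp)
    covered = set()
    for i, sp in enumerate(spans):
        y = gold_by_span.get(sp)
        if y is not None and y in idx:
            out[i] = idx[y]
            covered.add(sp)
    missed = [m for m in gold if (m.start, m.end) not in covered]
    return out, missed


def _regularizer_terms(
    batch: SpanBatch, config: TrainConfig
) -> tuple[Tensor | float, Tensor | float]:
    """Differentiable center/contrast terms from predicted labels (Tensor
    path mirroring the public numpy reference functions)."""
    probs = batch.type_dist.data
    pred_idx = probs.argmax(axis=1)
    none_idx = len(batch.labels) - 1
    sel = np.flatnonzero(pred_idx != none_idx)
    if sel.size == 0:
        return 0.0, 0.0
    R = ad.take_rows(batch.struct_repr, sel)
    plabels = pred_idx[sel]
    uniq = np.unique(plabels)
    # group-mean matrix: (n_groups, n_sel)
    G = np.zeros((uniq.size, sel.size))
    for g, lab in enumerate(uniq):
        members = plabels == lab
        G[g, members] = 1.0 / members.sum()
    M = Tensor(G) @ R  # centroids, differentiable
    onehot = np.zeros((sel.size, uniq.size))
    for i, lab in enumerate(plabels):
        onehot[i, np.searchsorted(uniq, lab)] = 1.0
    r2 = (R * R).sum(axis=1, keepdims=True)
    m2 = (M * M).sum(axis=1, keepdims=True).T
    D2 = r2 - 2.0 * (R @ M.T) + m2  # (n_sel, n_groups) squared distances
    center = (D2 * onehot).sum()
    contrast: Tensor | float = 0.0
    if uniq.size >= 2 and config.loss_weight_contrast > 0:
        d_corr = (D2 * onehot).sum(axis=1, keepdims=True)
        hinge = ad.relu((d_corr - D2 + config.margin) * (1.0 - onehot))
        contrast = hinge.sum()
    return center, contrast


def _propagation_head(
    batch: SpanBatch, params: ModelParams, config: TrainConfig
) -> Tensor:
    """Differentiable mirror of the decoder's graph-guided propagation:
    z^{k+1} = sigmoid(A W_prop z^k + U_prop r~), A row-normalized over
    edges (Sim >= threshold or overlapping spans).  Returns the refined
    distribution tensor; trains W_prop, U_prop and W_sim.  The encoder
    outputs are treated as constants here (stop-gradient) so the
    refinement head cannot perturb the span classifier it refines."""
    R = Tensor(batch.struct_repr.data)
    sim = ad.sigmoid(R @ params["W_sim"] @ R.T)
    s = np.array([sp[0] for sp in batch.spans])
    t = np.array([sp[1] for sp in batch.spans])
    inter = (s[:, None] <= t[None, :]) & (s[None, :] <= t[:, None])
    mask = ((sim.data >= config.prop_sim_threshold) | inter) & ~np.eye(len(s), dtype=bool)
    w = sim * mask
    A = w * (w.sum(axis=1, keepdims=True) + 1e-12) ** -1.0
    Z = Tensor(np.log(batch.type_dist.data + 1e-12))
    bias = R @ params["U_prop"].T
    for _ in range(config.prop_rounds):
        Z = ad.sigmoid((A @ Z) @ params["W_prop"].T + bias)
    return ad.softmax(Z, axis=-1)


def _weighted_ce(dist: Tensor, gold_idx: np.ndarray, n_classes: int) -> Tensor:
    """Cross-entropy with the NONE class down-weighted by the ratio of
    positive to negative spans."""
    none_idx = n_classes - 1
    n_pos = int((gold_idx != none_idx).sum())
    n_neg = len(gold_idx) - n_pos
    w = np.ones(len(gold_idx))
    if n_pos > 0 and n_neg > 0:
        w[gold_idx == none_idx] = n_pos / n_neg
    pick = np.zeros((len(gold_idx), n_classes))
    pick[np.arange(len(gold_idx)), gold_idx] = w
    return -(ad.log(dist + 1e-12) * pick).sum() * (1.0 / w.sum())


def total_loss(
    batch: SpanBatch,
    gold: list[EntityMention],
    config: TrainConfig,
    params: ModelParams | None = None,
) -> tuple[Tensor, dict[str, float]]:
    """Span cross-entropy over all enumerated spans (NONE down-weighted by
    the positive/negative span ratio) + beta * L_center +
    w_contrast * L_contrast (+ the propagation-head cross-entropy when
    model params are supplied).  Returns the scalar loss tensor and a
    float breakdown for logging."""
    gold_idx, missed = align_gold(batch.spans, gold, batch.labels)
    if missed:
        warnings.warn(
            f"{len(missed)} gold mention(s) not covered by span enumeration", stacklevel=2
        )
    ce = _weighted_ce(batch.type_dist, gold_idx, len(batch.labels))
    center, contrast = (
        _regularizer_terms(batch, config)
        if config.loss_weight_center > 0 or config.loss_weight_contrast > 0
        else (0.0, 0.0)
    )
    loss = ce
    prop_ce = 0.0
    if params is not None and config.loss_weight_prop > 0 and config.prop_rounds > 0:
        refined = _propagation_head(batch, params, config)
        prop = _weighted_ce(refined, gold_idx, len(batch.labels))
        loss = loss + config.loss_weight_prop * prop
        prop_ce = float(prop.data)
    if config.loss_weight_center > 0 and not isinstance(center, float):
        loss = loss + config.loss_weight_center * center
    if config.loss_weight_contrast > 0 and not isinstance(contrast, float):
        loss = loss + config.loss_weight_contrast * contrast
    breakdown = {
        "ce": float(ce.data),
        "center": float(center.data) if isinstance(center, Tensor) else center,
        "contrast": float(contrast.data) if isinstance(contrast, Tensor) else contrast,
        "prop_ce": prop_ce,
    }
    return loss, breakdown


# ----------------------------------------------------------------------
# optimizer


class AdamW:
    """Adam with decoupled weight decay and global-norm gradient clipping."""

    def __init__(self, params: ModelParams, lr: float, weight_decay: float = 0.01,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 grad_clip: float = 1.0):
        self.params = params
        self.lr = lr
        self.wd = weight_decay
        self.b1, self.b2 = betas
        self.eps = eps
        self.grad_clip = grad_clip
        self.t = 0
        self.m = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.tensors.items()}

    def step(self) -> None:
        grads = {
            k: (t.grad if t.grad is not None else np.zeros_like(t.data))
            for k, t in self.params.tensors.items()
        }
        if self.grad_clip:
            norm = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
            if norm > self.grad_clip:
                scale = self.grad_clip / norm
                grads = {k: g * scale for k, g in grads.items()}
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, tensor in self.params.tensors.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            update = (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)
            tensor.data -= self.lr * (update + self.wd * tensor.data)


# ----------------------------------------------------------------------
# splits and training loop


def split_corpus(
    docs: list[AnnotatedDocument],
    fractions: tuple[float, float, float],
    seed: int,
) -> tuple[list[AnnotatedDocument], list[AnnotatedDocument], list[AnnotatedDocument]]:
    """Deterministic stratified document split; the stratification key is
    the multiset of labels present in the document."""
    rng = np.random.default_rng(seed)
    strata: dict[tuple, list[int]] = {}
    for i, d in enumerate(docs):
        key = tuple(sorted(Counter(m.label for m in d.mentions).items()))
        strata.setdefault(key, []).append(i)
    targets = [f * len(docs) for f in fractions]
    counts = [0, 0, 0]
    out: tuple[list, list, list] = ([], [], [])
    # greedy deficit allocation: each doc goes to the split farthest below
    # its target, so singleton strata still fill every split proportionally
    for key in sorted(strata):
        idx = strata[key]
        rng.shuffle(idx)
        for i in idx:
            deficits = [targets[j] - counts[j] for j in range(3)]
            j = int(np.argmax(deficits))
            out[j].append(i)
            counts[j] += 1
    return tuple([docs[i] for i in part] for part in out)  # type: ignore[return-value]


def _validate(
    params: ModelParams,
    docs: list[AnnotatedDocument],
    schema: TypeSchema,
    encoder_config: EncoderConfig,
    decode_config: DecodeConfig,
) -> tuple[float, float, float]:
    preds = {
        d.doc_id: decode(d, params, schema, encoder_config, decode_config)
        for d in docs
    }
    rep = evaluate_docs(preds, docs)
    return rep.micro.precision, rep.micro.recall, rep.micro.f1


def train(
    corpus: list[AnnotatedDocument],
    schema: TypeSchema,
    encoder_config: EncoderConfig,
    train_config: TrainConfig,
    decode_config: DecodeConfig | None = None,
) -> tuple[ModelParams, list[dict]]:
    """Train the span encoder on an annotated corpus.

    Stratified 3-way document split; AdamW updates; exact-match F1 on the
    validation split after each epoch; early stopping after
    ``patience`` epochs without improvement; the best-on-validation
    parameters are returned together with the per-epoch training log.
    Fully deterministic given the configs' seeds.
    """
    if not corpus:
        raise ValueError("corpus must be nonempty")
    if sum(len(d.mentions) for d in corpus) == 0:
        warnings.warn("corpus has zero mentions; training degenerates to NONE")
    decode_config = decode_config or DecodeConfig()
    vocab = build_vocab(corpus)
    params = init_params(encoder_config, schema, vocab)
    if train_config.max_epochs == 0:
        return params, []
    train_docs, val_docs, _ = split_corpus(
        corpus, train_config.split_fractions, train_config.seed
    )
    if not train_docs:
        raise ValueError("empty training split")
    opt = AdamW(
        params,
        lr=train_config.learning_rate,
        weight_decay=train_config.weight_decay,
        grad_clip=train_config.grad_clip,
    )
    rng = np.random.default_rng(train_config.seed + 1)
    drop_rng = np.random.default_rng(train_config.seed + 2)
    caches: dict[str, dict] = {d.doc_id: {} for d in train_docs}
    log: list[dict] = []
    best_f1, best_params, since = -1.0, params.copy(), 0
    for epoch in range(1, train_config.max_epochs + 1):
        order = rng.permutation(len(train_docs))
        totals = {"loss": 0.0, "ce": 0.0, "center": 0.0, "contrast": 0.0}
        for b0 in range(0, len(order), train_config.batch_size):
            idx = order[b0 : b0 + train_config.batch_size]
            params.zero_grad()
            for i in idx:
                doc = train_docs[i]
                d_rng = drop_rng if encoder_config.dropout > 0 else None
                batch = forward_spans(
                    doc, params, encoder_config, d_rng, cache=caches[doc.doc_id]
                )
                loss, bd = total_loss(batch, doc.mentions, train_config, params=params)
                loss.backward(np.asarray(1.0 / len(idx)))
                totals["loss"] += float(loss.data)
                for k in ("ce", "center", "contrast"):
                    totals[k] += bd[k]
            opt.step()
        n = len(train_docs)
        val_p, val_r, val_f1 = (0.0, 0.0, 0.0)
        if val_docs:
            val_p, val_r, val_f1 = _validate(
                params, val_docs, schema, encoder_config, decode_config
            )
        log.append(
            {
                "epoch": epoch,
                "train_loss": totals["loss"] / n,
                "ce": totals["ce"] / n,
                "center": totals["center"] / n,
                "contrast": totals["contrast"] / n,
                "val_p": val_p,
                "val_r": val_r,
                "val_f1": val_f1,
            }
        )
        if val_f1 > best_f1:
            best_f1, best_params, since = val_f1, params.copy(), 0
        else:
            since += 1
            if since >= train_config.patience and epoch >= train_config.min_epochs:
                break
    if not val_docs:
        best_params = params
    return best_params, log
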