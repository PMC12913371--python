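"""Span-level exact-match evaluation: micro P/R/F1, per-type breakdown and
a nested-subset view.

Matching is exact on (start, end, label) triples with set semantics
(duplicates collapse).  The 0/0 convention is 0.0 with an explicit
``degenerate`` flag so empty-prediction runs are visible rather than
silently perfect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .corpus_io import AnnotatedDocument, EntityMention

__all__ = ["EvalReport", "Metrics", "match_exact", "report", "evaluate_docs"]


@dataclass
class Metrics:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    precision: float = 0.0
    recall: float = 0.0
    f1: float = 0.0
    degenerate: bool = False

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fp": self.fp,
            "fn": self.fn,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "degenerate": self.degenerate,
        }


@dataclass
class EvalReport:
    micro: Metrics
    per_type: dict[str, Metrics] = field(default_factory=dict)
    nested_subset: Metrics | None = None

    def to_dict(self) -> dict:
        out = {"micro": self.micro.to_dict(),
               "per_type": {y: m.to_dict() for y, m in sorted(self.per_type.items())}}
        if self.nested_subset is not None:
            out["nested_subset"] = self.nested_subset.to_dict()
        return out


def _keys(mentions: list[EntityMention]) -> set[tuple[int, int, str]]:
    return {m.key() for m in mentions}


def match_exact(
    pred: list[EntityMention], gold: list[EntityMention]
) -> tuple[int, int, int]:
    """(tp, fp, fn) under exact (s, t, y) matching, set semantics."""
    p, g = _keys(pred), _keys(gold)
    tp = len(p & g)
    return tp, len(p - g), len(g - p)


def _metrics(tp: int, fp: int, fn: int) -> Metrics:
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be nonnegative")
    degenerate = (tp + fp == 0) or (tp + fn == 0)
    precision = tp / (tp + fp) if tp + fp > 0 else 0.0
    recall = tp / (tp + fn) if tp + fn > 0 else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall > 0 else 0.0
    return Metrics(tp, fp, fn, precision, recall, f1, degenerate)


def report(
    tp: int, fp: int, fn: int, per_type_counts: dict[str, tuple[int, int, int]] | None = None
) -> EvalReport:
    """Build an EvalReport from raw counts (micro counts must equal the
    sums of per-type counts when the latter are supplied)."""
    per_type = {
        y: _metrics(*c) for y, c in (per_type_counts or {}).items()
    }
    if per_type_counts:
        sums = tuple(sum(c[i] for c in per_type_counts.values()) for i in range(3))
        if sums != (tp, fp, fn):
            raise ValueError(f"micro counts {(tp, fp, fn)} != per-type sums {sums}")
    return EvalReport(micro=_metrics(tp, fp, fn), per_type=per_type)


def _nested_gold(gold: list[EntityMention]) -> set[tuple[int, int, str]]:
    keys = set()
    for m in gold:
        for o in gold:
            if o.key() != m.key() and o.start <= m.start and m.end <= o.end:
                keys.add(m.key())
    return keys


def evaluate_docs(
    pred_docs: dict[str, list[EntityMention]],
    gold_docs: list[AnnotatedDocument],
) -> EvalReport:
    """Corpus-level evaluation; predictions keyed by doc_id.

    The nested-subset block restricts gold to mentions strictly contained
    in another gold mention; its fp counts predictions that sit inside
    some gold mention without matching nested gold.
    """
    tp = fp = fn = 0
    per_type: dict[str, list[int]] = {}
    ntp = nfp = nfn = 0
    for doc in gold_docs:
        pred = pred_docs.get(doc.doc_id, [])
        p, g = _keys(pred), _keys(doc.mentions)
        for key in p | g:
            y = key[2]
            cell = per_type.setdefault(y, [0, 0, 0])
            if key in p and key in g:
                cell[0] += 1
            elif key in p:
                cell[1] += 1
            else:
                cell[2] += 1
        d_tp = len(p & g)
        tp += d_tp
        fp += len(p - g)
        fn += len(g - p)
        nested = _nested_gold(doc.mentions)
        ntp += len(p & nested)
        nfn += len(nested - p)
        nfp += sum(
            1
            for k in p - nested
            if any(o.start <= k[0] and k[1] <= o.end and o.key() != k for o in doc.mentions)
        )
    rep = report(tp, fp, fn, {y: tuple(c) for y, c in per_type.items()})
    rep.nested_subset = _metrics(ntp, nfp, nfn)
    return rep
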