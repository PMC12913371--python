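"""Pruned candidate spans passed from the encoder to the global decoder."""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .schema import NONE_LABEL


@dataclass
class CandidateSpan:
    """A high-confidence span entering global decoding.

    `type_dist` rows are ordered like `CandidateSet.labels` (NONE last).
    `refined_dist` is filled by graph-guided propagation; `allowed_labels`
    by ontology filtering.  `entity_score` is the entity-ness
    alpha_{s,t} = 1 - P(NONE) used by the context reward.
    """

    span: tuple[int, int]
    type_dist: np.ndarray
    entity_score: float
    refined_dist: np.ndarray | None = None
    allowed_labels: set[str] | None = None
    repr: np.ndarray | None = None

    def dist(self) -> np.ndarray:
        return self.type_dist if self.refined_dist is None else self.refined_dist

    def prob(self, labels: list[str], y: str) -> float:
        return float(self.dist()[labels.index(y)])


@dataclass
class CandidateSet:
    candidates: list[CandidateSpan]
    labels: list[str]  # column order of the distributions, NONE last
    dropped: list[tuple[tuple[int, int], str]] = field(default_factory=list)

    @property
    def entity_labels(self) -> list[str]:
        return [y for y in self.labels if y != NONE_LABEL]

    def to_json(self, doc_id: str = "doc") -> dict:
        return {
            "doc_id": doc_id,
            "labels": self.labels,
            "candidates": [
                {
                    "start": c.span[0],
                    "end": c.span[1],
                    "dist": {y: float(p) for y, p in zip(self.labels, c.type_dist)},
                }
                | ({"repr": [float(v) for v in c.repr]} if c.repr is not None else {})
                for c in self.candidates
            ],
        }

    @classmethod
    def from_json(cls, data: dict, labels: list[str] | None = None) -> "CandidateSet":
        labels = labels or data.get("labels")
        if labels is None:
            keys = set()
            for c in data["candidates"]:
                keys.update(c["dist"])
            labels = sorted(keys - {NONE_LABEL}) + [NONE_LABEL]
        cands = []
        for c in data["candidates"]:
            dist = np.array([c["dist"].get(y, 0.0) for y in labels])
            cands.append(
                CandidateSpan(
                    span=(int(c["start"]), int(c["end"])),
                    type_dist=dist,
                    entity_score=float(c.get("alpha", 1.0 - dist[-1])),
                    repr=np.asarray(c["repr"], dtype=float) if "repr" in c else None,
                )
            )
        return cls(candidates=cands, labels=list(labels))

    def save(self, path, doc_id: str = "doc") -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_json(doc_id), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "CandidateSet":
        with open(path, encoding="utf-8") as fh:
            return cls.from_json(json.load(fh))
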