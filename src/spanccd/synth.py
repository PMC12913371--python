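"""Seeded generator of synthetic immunology-flavored nested-NER corpora.

The generator emulates the phenomena that make nested biomedical NER
hard, at desk scale and with known ground truth:

* variable-length mentions (1-5 tokens) drawn from per-type template
  lists (immune cells, T-cell subsets, cytokines, diseases, genes);
* nested mentions: some cell templates contain an inner T-cell span
  ("CD4 + T cell" containing "T cell") which is emitted as a second gold
  mention with probability ``nest_rate``;
* ambiguous surface forms listed under two types ("IFNG" as gene or
  cytokine) whose gold type is signalled by a deterministic context cue
  token placed immediately after the mention, so the disambiguation task
  is learnable (near-1.0 Bayes accuracy);
* configurable label noise (sibling flips / mention drops) standing in
  for weak supervision.

Gold mentions never cross (nesting only); crossing spans are a
decode-time phenomenon and are injected only by decoder test fixtures.
All randomness flows from ``GenConfig.seed``; identical configs produce
byte-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corpus_io import AnnotatedDocument, EntityMention, Token
from .schema import TypeSchema, schema_from_dict

__all__ = ["GenConfig", "make_toy_schema", "generate_corpus", "corrupt_labels"]


@dataclass
class GenConfig:
    """Generation parameters.

    ``mention_rate`` is the expected number of top-level mentions per 10
    background tokens; the realized count per document is
    Binomial(L, mention_rate/10) with L the background length drawn from
    ``sent_len_range``.  Documents grow beyond L by the inserted mention
    tokens, mirroring how entity-dense abstracts run longer.
    """

    n_docs: int = 100
    sent_len_range: tuple[int, int] = (8, 20)
    mention_rate: float = 1.5
    nest_rate: float = 0.3
    ambiguity_rate: float = 0.2
    label_noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.sent_len_range
        if lo < 3 or hi < lo:
            raise ValueError("sent_len_range must satisfy 3 <= min <= max")
        for name in ("nest_rate", "ambiguity_rate", "label_noise_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mention_rate < 0:
            raise ValueError("mention_rate must be nonnegative")
        if self.mention_rate / 10.0 > 1.0:
            raise ValueError("mention_rate > 10 per 10 tokens is not realizable")


def make_toy_schema() -> TypeSchema:
    """Fixed immunology-flavoured schema used throughout tests/examples.

    ENTITY is the root; CELL, CYTOKINE, DISEASE and GENE are its
    children; T_CELL is a child of CELL.  All cross-type pairs are
    admissible except {CYTOKINE, DISEASE} (a deliberately inadmissible
    pair for conflict-penalty exercises).  The nesting prior licenses
    (T_CELL inside CELL) and (CELL inside CELL); frequency priors are
    uniform.
    """
    labels = ["CELL", "CYTOKINE", "DISEASE", "ENTITY", "GENE", "T_CELL"]
    pairs = [
        sorted((a, b))
        for i, a in enumerate(labels)
        for b in labels[i + 1 :]
        if {a, b} != {"CYTOKINE", "DISEASE"}
    ]
    return schema_from_dict(
        {
            "types": [
                {"id": "ENTITY", "name": "Entity"},
                {"id": "CELL", "name": "Immune cell", "parent": "ENTITY"},
                {"id": "T_CELL", "name": "T cell", "parent": "CELL"},
                {"id": "CYTOKINE", "name": "Cytokine", "parent": "ENTITY"},
                {"id": "DISEASE", "name": "Disease", "parent": "ENTITY"},
                {"id": "GENE", "name": "Gene", "parent": "ENTITY"},
            ],
            "admissible_pairs": pairs,
            "nesting_prior": {"T_CELL|CELL": 1.0, "CELL|CELL": 0.5},
            "frequency_prior": {y: 1.0 for y in labels},
        }
    )


# template lists; "inner" marks a (start, end, label) sub-span (0-based,
# end-exclusive, in template tokens) emitted as nested gold
_TEMPLATES: dict[str, list[dict]] = {
    "CELL": [
        {"tokens": ["CD4", "+", "T", "cell"], "inner": (2, 4, "T_CELL")},
        {"tokens": ["CD8", "+", "T", "cell"], "inner": (2, 4, "T_CELL")},
        {"tokens": ["regulatory", "T", "cell"], "inner": (1, 3, "T_CELL")},
        {"tokens": ["natural", "killer", "cell"]},
        {"tokens": ["dendritic", "cell"]},
        {"tokens": ["macrophage"]},
        {"tokens": ["B", "cell"]},
        {"tokens": ["memory", "helper", "T", "cell", "subset"], "inner": (2, 4, "T_CELL")},
    ],
    "T_CELL": [
        {"tokens": ["T", "cell"]},
        {"tokens": ["T", "lymphocyte"]},
        {"tokens": ["Th17", "cell"]},
    ],
    "CYTOKINE": [
        {"tokens": ["IL-2"]},
        {"tokens": ["IL-6"]},
        {"tokens": ["IL-10"]},
        {"tokens": ["TNF"]},
        {"tokens": ["interferon", "gamma"]},
        {"tokens": ["TGF", "-", "beta"]},
    ],
    "DISEASE": [
        {"tokens": ["lupus"]},
        {"tokens": ["psoriasis"]},
        {"tokens": ["rheumatoid", "arthritis"]},
        {"tokens": ["multiple", "sclerosis"]},
        {"tokens": ["type", "1", "diabetes"]},
    ],
    "GENE": [
        {"tokens": ["FOXP3"]},
        {"tokens": ["CTLA4"]},
        {"tokens": ["HLA-B"]},
        {"tokens": ["STAT3"]},
    ],
}

# surface forms listed under two types; the gold type is signalled by a cue
_AMBIGUOUS: list[tuple[list[str], tuple[str, str]]] = [
    (["IFNG"], ("GENE", "CYTOKINE")),
    (["APC"], ("GENE", "CELL")),
]

# deterministic context cue emitted right after an ambiguous mention
_CUES = {
    "GENE": "polymorphism",
    "CYTOKINE": "signaling",
    "CELL": "population",
    "DISEASE": "relapse",
    "T_CELL": "subset",
}

_FILLER = [
    "the", "of", "in", "was", "were", "levels", "expression", "observed",
    "increased", "decreased", "patients", "study", "analysis", "response",
    "after", "during", "treatment", "with", "and", "significant", "between",
    "compared", "to", "samples", "measured", "activity", "results",
]

_TOP_LEVEL_TYPES = ["CELL", "T_CELL", "CYTOKINE", "DISEASE", "GENE"]


def _make_document(doc_id: str, cfg: GenConfig, rng: np.random.Generator) -> AnnotatedDocument:
    L = int(rng.integers(cfg.sent_len_range[0], cfg.sent_len_range[1] + 1))
    n_mentions = int(rng.binomial(L, cfg.mention_rate / 10.0))
    # insertion points among the L background tokens (before token k)
    points = sorted(rng.choice(L + 1, size=min(n_mentions, L + 1), replace=False))
    words: list[str] = []
    mentions: list[tuple[int, int, str]] = []  # 0-based token spans, end-exclusive
    fill_idx = rng.integers(0, len(_FILLER), size=L)
    pi = 0
    for k in range(L + 1):
        while pi < len(points) and points[pi] == k:
            pi += 1
            start = len(words)
            if cfg.ambiguity_rate > 0 and rng.random() < cfg.ambiguity_rate:
                tokens, types = _AMBIGUOUS[int(rng.integers(len(_AMBIGUOUS)))]
                label = types[int(rng.integers(2))]
                words.extend(tokens)
                mentions.append((start, len(words), label))
                words.append(_CUES[label])  # cue within 2 tokens of the span
            else:
                label = _TOP_LEVEL_TYPES[int(rng.integers(len(_TOP_LEVEL_TYPES)))]
                tpl = _TEMPLATES[label][int(rng.integers(len(_TEMPLATES[label])))]
                words.extend(tpl["tokens"])
                mentions.append((start, len(words), label))
                if "inner" in tpl and rng.random() < cfg.nest_rate:
                    a, b, inner_label = tpl["inner"]
                    mentions.append((start + a, start + b, inner_label))
        if k < L:
            words.append(_FILLER[fill_idx[k]])
    pos, tokens = 0, []
    for w in words:
        tokens.append(Token(w, pos, pos + len(w)))
        pos += len(w) + 1
    text = " ".join(words)
    ems = [EntityMention(a + 1, b, y) for a, b, y in mentions]
    return AnnotatedDocument(doc_id=doc_id, text=text, tokens=tokens, mentions=ems)


def generate_corpus(
    cfg: GenConfig, schema: TypeSchema
) -> tuple[list[AnnotatedDocument], dict]:
    """Generate a corpus and a manifest of realized counts.

    The manifest records the seed, document count, per-type mention
    counts, the number of top-level insertions and nested gold pairs.
    Label noise, when configured, is applied through
    :func:`corrupt_labels` (seeded from the generator's stream).
    """
    for y in _TOP_LEVEL_TYPES:
        if y not in schema.types:
            raise ValueError(f"schema lacks generator type {y!r}")
    rng = np.random.default_rng(cfg.seed)
    docs = [_make_document(f"synth{i:05d}", cfg, rng) for i in range(cfg.n_docs)]
    n_top = sum(
        1
        for d in docs
        for m in d.mentions
        if not any(
            o.start <= m.start and m.end <= o.end and o.key() != m.key()
            for o in d.mentions
        )
    )
    n_nested = sum(
        1
        for d in docs
        for m in d.mentions
        for o in d.mentions
        if o.key() != m.key() and o.start <= m.start and m.end <= o.end
    )
    noise_log: list[dict] = []
    if cfg.label_noise_rate > 0:
        docs, noise_log = corrupt_labels(
            docs, cfg.label_noise_rate, schema, seed=int(rng.integers(2**31))
        )
    per_type: dict[str, int] = {}
    for d in docs:
        for m in d.mentions:
            per_type[m.label] = per_type.get(m.label, 0) + 1
    manifest = {
        "seed": cfg.seed,
        "n_docs": len(docs),
        "n_mentions": sum(len(d.mentions) for d in docs),
        "n_top_level": n_top,
        "n_nested_pairs": n_nested,
        "mentions_per_type": dict(sorted(per_type.items())),
        "n_corrupted": len(noise_log),
    }
    return docs, manifest


def corrupt_labels(
    corpus: list[AnnotatedDocument],
    noise_rate: float,
    schema: TypeSchema,
    seed: int = 0,
) -> tuple[list[AnnotatedDocument], list[dict]]:
    """Weak-supervision stand-in: each mention independently, with
    probability `noise_rate`, is either flipped to a uniformly random
    sibling type (50%) or dropped (50%).  Labels without siblings fall
    back to a uniformly random other label on the flip branch.  Pure
    function: the input corpus is untouched; a corruption log is
    returned."""
    if not (0.0 <= noise_rate <= 1.0):
        raise ValueError("noise_rate must be in [0, 1]")
    rng = np.random.default_rng(seed)
    out: list[AnnotatedDocument] = []
    log: list[dict] = []
    for doc in corpus:
        new_mentions: list[EntityMention] = []
        for m in doc.mentions:
            if rng.random() >= noise_rate:
                new_mentions.append(m)
                continue
            if rng.random() < 0.5:
                sibs = sorted(schema.siblings(m.label)) or sorted(
                    set(schema.labels) - {m.label}
                )
                new_label = sibs[int(rng.integers(len(sibs)))]
                new_mentions.append(
                    EntityMention(m.start, m.end, new_label, confidence=m.confidence)
                )
                log.append(
                    {
                        "doc_id": doc.doc_id,
                        "span": [m.start, m.end],
                        "action": "flip",
                        "old": m.label,
                        "new": new_label,
                    }
                )
            else:
                log.append(
                    {
                        "doc_id": doc.doc_id,
                        "span": [m.start, m.end],
                        "action": "drop",
                        "old": m.label,
                        "new": None,
                    }
                )
        out.append(
            AnnotatedDocument(
                doc_id=doc.doc_id,
                text=doc.text,
                tokens=list(doc.tokens),
                mentions=new_mentions,
            )
        )
    return out, log
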