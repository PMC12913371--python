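"""Annotated-corpus I/O: PubTator, BRAT standoff, CoNLL and internal JSON.

Coordinate conventions used throughout the package:

* **token spans** are 1-based inclusive ``[s, t]`` (so a single-token
  mention has ``s == t``);
* **character offsets** are 0-based half-open ``[start, end)``, matching
  the PubTator / BRAT convention.

The tokenizer is deterministic and rule-based: split on whitespace, then
split off leading/trailing punctuation, except that ``+``, ``-`` and
``/`` are never split (so biomedical surface forms like ``CD4+`` and
``IL-2`` stay single tokens).  Stripped punctuation characters become
tokens of their own.
"""

from __future__ import annotations

import json
import re
import string
from dataclasses import dataclass, field

from .schema import NONE_LABEL

__all__ = [
    "Token",
    "EntityMention",
    "AnnotatedDocument",
    "CorpusFormatError",
    "AlignmentError",
    "RepresentabilityError",
    "UnsupportedFeatureError",
    "tokenize",
    "tokenize_and_align",
    "read_pubtator",
    "write_pubtator",
    "read_brat",
    "read_conll",
    "write_conll",
    "read_json_corpus",
    "write_json_corpus",
    "spans_to_bioes",
    "bioes_to_spans",
]


class CorpusFormatError(ValueError):
    """Malformed input in one of the supported corpus dialects."""


class AlignmentError(ValueError):
    """Character annotation cannot be mapped onto the token sequence."""


class RepresentabilityError(ValueError):
    """Document structure not expressible in the target encoding."""


class UnsupportedFeatureError(ValueError):
    """Valid input using a feature outside this reader's scope."""


@dataclass(frozen=True)
class Token:
    text: str
    char_start: int
    char_end: int  # exclusive


@dataclass(frozen=True)
class EntityMention:
    """A labeled token span; ``start``/``end`` are 1-based inclusive."""

    start: int
    end: int
    label: str
    confidence: float | None = None
    snapped: bool = False
    metadata: tuple = ()  # opaque key/value pairs, e.g. PubTator concept ids

    def key(self) -> tuple[int, int, str]:
        return (self.start, self.end, self.label)


@dataclass
class AnnotatedDocument:
    doc_id: str
    text: str
    tokens: list[Token]
    mentions: list[EntityMention] = field(default_factory=list)

    def __post_init__(self) -> None:
        T = len(self.tokens)
        seen: set[tuple[int, int, str]] = set()
        deduped = []
        for m in self.mentions:
            if not (1 <= m.start <= m.end <= T):
                raise AlignmentError(
                    f"{self.doc_id}: mention {m.key()} outside 1..{T}"
                )
            if m.label == NONE_LABEL:
                raise ValueError(f"{self.doc_id}: mention labeled {NONE_LABEL}")
            if m.key() not in seen:
                seen.add(m.key())
                deduped.append(m)
        self.mentions = deduped

    def mention_text(self, m: EntityMention) -> str:
        return self.text[self.tokens[m.start - 1].char_start : self.tokens[m.end - 1].char_end]


# ----------------------------------------------------------------------
# tokenizer

_NEVER_SPLIT = set("+-/")
_STRIP = set(string.punctuation) - _NEVER_SPLIT
_CHUNK = re.compile(r"\S+")


def tokenize(text: str) -> list[Token]:
    """Deterministic whitespace+punctuation tokenizer (see module docstring)."""
    tokens: list[Token] = []
    for m in _CHUNK.finditer(text):
        chunk, base = m.group(), m.start()
        lo, hi = 0, len(chunk)
        lead: list[int] = []
        trail: list[int] = []
        while lo < hi and chunk[lo] in _STRIP:
            lead.append(lo)
            lo += 1
        while hi > lo and chunk[hi - 1] in _STRIP:
            trail.append(hi - 1)
            hi -= 1
        for i in lead:
            tokens.append(Token(chunk[i], base + i, base + i + 1))
        if hi > lo:
            tokens.append(Token(chunk[lo:hi], base + lo, base + hi))
        for i in reversed(trail):
            tokens.append(Token(chunk[i], base + i, base + i + 1))
    return tokens


def tokenize_and_align(
    text: str,
    char_annotations: list[tuple[int, int, str]] | None = None,
    doc_id: str = "doc",
) -> AnnotatedDocument:
    """Tokenize `text` and map 0-based half-open char annotations to token
    spans.  Each annotation maps to the minimal covering token span;
    boundaries falling strictly inside a token snap outward to that
    token's boundaries and the resulting mention carries ``snapped=True``.
    """
    tokens = tokenize(text)
    mentions: list[EntityMention] = []
    for ann in char_annotations or []:
        start, end, label = ann[0], ann[1], ann[2]
        meta = tuple(ann[3]) if len(ann) > 3 else ()
        if start >= end:
            raise AlignmentError(f"{doc_id}: zero/negative-length annotation ({start}, {end})")
        if start < 0 or end > len(text):
            raise AlignmentError(
                f"{doc_id}: annotation ({start}, {end}) outside text of length {len(text)}"
            )
        covering = [
            i for i, t in enumerate(tokens) if t.char_end > start and t.char_start < end
        ]
        if not covering:
            raise AlignmentError(
                f"{doc_id}: annotation ({start}, {end}) covers no token"
            )
        first, last = covering[0], covering[-1]
        snapped = tokens[first].char_start != start or tokens[last].char_end != end
        mentions.append(
            EntityMention(first + 1, last + 1, label, snapped=snapped, metadata=meta)
        )
    return AnnotatedDocument(doc_id=doc_id, text=text, tokens=tokens, mentions=mentions)


def mention_char_offsets(doc: AnnotatedDocument, m: EntityMention) -> tuple[int, int]:
    return doc.tokens[m.start - 1].char_start, doc.tokens[m.end - 1].char_end


# ----------------------------------------------------------------------
# PubTator


def read_pubtator(path) -> list[AnnotatedDocument]:
    """Read a PubTator plain-text corpus.

    Blocks are separated by blank lines: ``PMID|t|Title``, optionally
    ``PMID|a|Abstract``, then tab-separated annotation lines
    ``PMID<TAB>start<TAB>end<TAB>text<TAB>type[<TAB>conceptID]``.  Title
    and abstract are joined with a single space and offsets index the
    concatenation (NCBI Disease Corpus convention).  Concept ids are kept
    as opaque mention metadata.
    """
    with open(path, encoding="utf-8") as fh:
        content = fh.read()
    docs: list[AnnotatedDocument] = []
    for block in re.split(r"\n\s*\n", content.strip()):
        if not block.strip():
            continue
        title = abstract = None
        doc_id = None
        anns: list[tuple[int, int, str]] = []
        for lineno, line in enumerate(block.splitlines(), 1):
            if not line.strip():
                continue
            tm = re.match(r"^([^|\t]+)\|t\|(.*)$", line)
            am = re.match(r"^([^|\t]+)\|a\|(.*)$", line)
            if tm:
                doc_id, title = tm.group(1), tm.group(2)
                continue
            if am:
                doc_id, abstract = am.group(1), am.group(2)
                continue
            cols = line.split("\t")
            if len(cols) not in (5, 6):
                raise CorpusFormatError(
                    f"{path}: annotation line {lineno}: expected 5 or 6 tab-separated"
                    f" columns, got {len(cols)}"
                )
            try:
                start, end = int(cols[1]), int(cols[2])
            except ValueError as err:
                raise CorpusFormatError(
                    f"{path}: annotation line {lineno}: non-integer offsets"
                ) from err
            meta = (("concept_id", cols[5]),) if len(cols) == 6 else ()
            anns.append((start, end, cols[4], meta))
        if doc_id is None or title is None:
            raise CorpusFormatError(f"{path}: block without a title line")
        text = title if abstract is None else f"{title} {abstract}"
        for start, end, _label, _meta in anns:
            if not (0 <= start < end <= len(text)):
                raise AlignmentError(
                    f"{doc_id}: annotation offsets ({start}, {end}) outside text"
                )
        docs.append(tokenize_and_align(text, anns, doc_id=doc_id))
    return docs


def write_pubtator(docs: list[AnnotatedDocument], path) -> None:
    """Write documents in PubTator dialect (whole text on the title line)."""
    lines: list[str] = []
    for doc in docs:
        lines.append(f"{doc.doc_id}|t|{doc.text}")
        for m in sorted(doc.mentions, key=EntityMention.key):
            cs, ce = mention_char_offsets(doc, m)
            concept = dict(m.metadata).get("concept_id")
            cols = [doc.doc_id, str(cs), str(ce), doc.text[cs:ce], m.label]
            if concept is not None:
                cols.append(concept)
            lines.append("\t".join(cols))
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


# ----------------------------------------------------------------------
# BRAT standoff

_BRAT_T = re.compile(r"^(T\d+)\t(\S+) (\d+[ ;\d]*\d+)\t(.*)$")


def read_brat(txt_path, ann_path, doc_id: str | None = None) -> AnnotatedDocument:
    """Read a BRAT .txt/.ann pair; only entity (T-) lines are consumed.
    Discontinuous spans (semicolon-separated offsets) are rejected.
    """
    with open(txt_path, encoding="utf-8") as fh:
        text = fh.read()
    anns: list[tuple[int, int, str]] = []
    with open(ann_path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or not line.startswith("T"):
                continue
            m = _BRAT_T.match(line)
            if m is None:
                raise CorpusFormatError(f"{ann_path}: line {lineno}: malformed T-line")
            tid, label, offsets, surface = m.groups()
            if ";" in offsets:
                raise UnsupportedFeatureError(
                    f"{ann_path}: line {lineno}: discontinuous span not supported"
                )
            start_s, end_s = offsets.split()
            start, end = int(start_s), int(end_s)
            if end <= start:
                raise CorpusFormatError(
                    f"{ann_path}: line {lineno}: end offset {end} <= start {start}"
                )
            if text[start:end] != surface:
                raise AlignmentError(
                    f"{ann_path}: line {lineno} ({tid}): surface text does not match .txt"
                )
            anns.append((start, end, label))
    did = doc_id or str(txt_path).rsplit("/", 1)[-1].removesuffix(".txt")
    return tokenize_and_align(text, anns, doc_id=did)


# ----------------------------------------------------------------------
# CoNLL (token TAB tag)

_VALID_PREFIXES = {"B", "I", "O", "E", "S"}


def _runs_from_tags(tags: list[str], strict: bool, where: str) -> list[tuple[int, int, str]]:
    """Convert a BIO/BIOES tag sequence to (start, end, label) 1-based spans.

    Lenient repair (default): an orphan I-/E- tag opens a new span, as if
    it were B-; strict mode raises instead.
    """
    spans: list[tuple[int, int, str]] = []
    cur_start, cur_label = None, None

    def close(end_idx: int) -> None:
        nonlocal cur_start, cur_label
        if cur_start is not None:
            spans.append((cur_start, end_idx, cur_label))
            cur_start = cur_label = None

    for i, tag in enumerate(tags, 1):
        if tag == "O":
            close(i - 1)
            continue
        if len(tag) < 3 or tag[1] != "-" or tag[0] not in _VALID_PREFIXES:
            raise CorpusFormatError(f"{where}: unknown tag {tag!r}")
        prefix, label = tag[0], tag[2:]
        if prefix in ("B", "S"):
            close(i - 1)
            cur_start, cur_label = i, label
        else:  # I or E
            if cur_start is None or cur_label != label:
                if strict:
                    raise CorpusFormatError(
                        f"{where}: orphan {tag!r} at token {i} (strict mode)"
                    )
                close(i - 1)
                cur_start, cur_label = i, label
        if prefix in ("S", "E"):
            close(i)
    close(len(tags))
    return spans


def read_conll(path, strict: bool = False) -> list[AnnotatedDocument]:
    """Read token-per-line CoNLL (``token<TAB>tag``).  Blank lines separate
    sentences; ``-DOCSTART-`` lines (or the file boundary) separate
    documents.  BIO and BIOES dialects are auto-detected; CoNLL cannot
    express nesting, so output is always flat.  Text is reconstructed by
    single-space joining.
    """
    docs: list[AnnotatedDocument] = []
    doc_tokens: list[str] = []
    doc_tags: list[str] = []
    n_doc = 0

    def flush() -> None:
        nonlocal doc_tokens, doc_tags, n_doc
        if not doc_tokens:
            return
        n_doc += 1
        spans = _runs_from_tags(doc_tags, strict, f"{path}: document {n_doc}")
        text = " ".join(doc_tokens)
        doc = tokenize_and_align(text, doc_id=f"doc{n_doc}")
        if [t.text for t in doc.tokens] != doc_tokens:
            # fall back to verbatim tokens when the tokenizer would re-split
            pos, toks = 0, []
            for w in doc_tokens:
                toks.append(Token(w, pos, pos + len(w)))
                pos += len(w) + 1
            doc = AnnotatedDocument(doc_id=f"doc{n_doc}", text=text, tokens=toks)
        doc.mentions = [EntityMention(s, e, lab) for s, e, lab in spans]
        AnnotatedDocument.__post_init__(doc)
        docs.append(doc)
        doc_tokens, doc_tags = [], []

    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("-DOCSTART-"):
                flush()
                continue
            cols = line.split("\t")
            if len(cols) != 2:
                raise CorpusFormatError(
                    f"{path}: line {lineno}: expected 'token<TAB>tag', got {line!r}"
                )
            doc_tokens.append(cols[0])
            doc_tags.append(cols[1])
    flush()
    return docs


def write_conll(docs: list[AnnotatedDocument], path, dialect: str = "BIOES") -> None:
    """Write flat documents in CoNLL form (errors on nested mentions)."""
    lines: list[str] = []
    for doc in docs:
        lines.append("-DOCSTART-")
        tags = spans_to_bioes(doc) if dialect == "BIOES" else _spans_to_bio(doc)
        for tok, tag in zip(doc.tokens, tags):
            lines.append(f"{tok.text}\t{tag}")
        lines.append("")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines))


# ----------------------------------------------------------------------
# BIOES <-> spans


def _check_flat(doc: AnnotatedDocument) -> None:
    ms = sorted(doc.mentions, key=EntityMention.key)
    for i, a in enumerate(ms):
        for b in ms[i + 1 :]:
            if a.start <= b.end and b.start <= a.end:
                raise RepresentabilityError(
                    f"{doc.doc_id}: overlapping mentions {a.key()} and {b.key()}"
                    " cannot be expressed in a flat tagging scheme"
                )


def spans_to_bioes(doc: AnnotatedDocument) -> list[str]:
    """Standard BIOES encoding; raises RepresentabilityError on overlap."""
    _check_flat(doc)
    tags = ["O"] * len(doc.tokens)
    for m in doc.mentions:
        if m.start == m.end:
            tags[m.start - 1] = f"S-{m.label}"
        else:
            tags[m.start - 1] = f"B-{m.label}"
            for i in range(m.start, m.end - 1):
                tags[i] = f"I-{m.label}"
            tags[m.end - 1] = f"E-{m.label}"
    return tags


def _spans_to_bio(doc: AnnotatedDocument) -> list[str]:
    _check_flat(doc)
    tags = ["O"] * len(doc.tokens)
    for m in doc.mentions:
        tags[m.start - 1] = f"B-{m.label}"
        for i in range(m.start, m.end):
            tags[i] = f"I-{m.label}"
    return tags


def bioes_to_spans(tags: list[str], strict: bool = False) -> list[EntityMention]:
    return [
        EntityMention(s, e, lab)
        for s, e, lab in _runs_from_tags(list(tags), strict, "<tags>")
    ]


# ----------------------------------------------------------------------
# internal JSON corpus (canonical interchange format)


def doc_to_dict(doc: AnnotatedDocument) -> dict:
    out = {
        "doc_id": doc.doc_id,
        "text": doc.text,
        "tokens": [
            {"text": t.text, "char_start": t.char_start, "char_end": t.char_end}
            for t in doc.tokens
        ],
        "mentions": [],
    }
    for m in sorted(doc.mentions, key=EntityMention.key):
        md = {"start": m.start, "end": m.end, "label": m.label}
        if m.confidence is not None:
            md["confidence"] = m.confidence
        if m.snapped:
            md["snapped"] = True
        if m.metadata:
            md["metadata"] = dict(m.metadata)
        out["mentions"].append(md)
    return out


def doc_from_dict(data: dict) -> AnnotatedDocument:
    tokens = [Token(t["text"], t["char_start"], t["char_end"]) for t in data["tokens"]]
    mentions = [
        EntityMention(
            m["start"],
            m["end"],
            m["label"],
            confidence=m.get("confidence"),
            snapped=m.get("snapped", False),
            metadata=tuple(sorted(m.get("metadata", {}).items())),
        )
        for m in data["mentions"]
    ]
    return AnnotatedDocument(
        doc_id=data["doc_id"], text=data["text"], tokens=tokens, mentions=mentions
    )


def write_json_corpus(docs: list[AnnotatedDocument], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump([doc_to_dict(d) for d in docs], fh, sort_keys=True, indent=1)
        fh.write("\n")


def read_json_corpus(path) -> list[AnnotatedDocument]:
    with open(path, encoding="utf-8") as fh:
        return [doc_from_dict(d) for d in json.load(fh)]
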