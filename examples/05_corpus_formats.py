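"""Read and write annotated corpora: PubTator, CoNLL/BIOES, internal JSON.

Token spans are 1-based inclusive; character offsets are 0-based
half-open.  CoNLL/BIOES is flat-only: converting a nested document raises
a representability error.
"""

import tempfile
from pathlib import Path

from spanccd import (
    GenConfig,
    generate_corpus,
    make_toy_schema,
    read_pubtator,
    spans_to_bioes,
    write_pubtator,
)
from spanccd.corpus_io import RepresentabilityError

schema = make_toy_schema()
flat, _ = generate_corpus(GenConfig(n_docs=3, seed=2, nest_rate=0.0), schema)
nested, _ = generate_corpus(GenConfig(n_docs=10, seed=8, nest_rate=1.0), schema)

with tempfile.TemporaryDirectory() as tmp:
    path = Path(tmp) / "corpus.pubtator"
    write_pubtator(flat, path)
    print("--- PubTator serialization (first lines) ---")
    print("\n".join(path.read_text().splitlines()[:4]))
    back = read_pubtator(path)
    same = all(
        {m.key() for m in a.mentions} == {m.key() for m in b.mentions}
        for a, b in zip(flat, back)
    )
    print("round trip preserves all mention triples:", same)

print("\n--- BIOES view of a flat document ---")
doc = flat[0]
for tok, tag in zip(doc.tokens, spans_to_bioes(doc)):
    if tag != "O":
        print(f"  {tok.text:12s} {tag}")

nested_doc = next(
    d for d in nested
    if any(
        o.key() != m.key() and o.start <= m.start and m.end <= o.end
        for m in d.mentions for o in d.mentions
    )
)
try:
    spans_to_bioes(nested_doc)
except RepresentabilityError as err:
    print("\nnested document rejected by BIOES, as expected:\n ", err)
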