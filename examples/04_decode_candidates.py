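"""Decoder-only use: run constraint decoding on explicit candidates.

Candidates can come from any scorer as JSON; here we build a small set by
hand containing a confident true mention, a crossing false positive and
an inadmissible neighbor, then compare the argmax baseline with CCD.
"""

import numpy as np

from spanccd import DecodeConfig, baseline_config, make_toy_schema
from spanccd.candidates import CandidateSet, CandidateSpan
from spanccd.decoder import decode_candidates

schema = make_toy_schema()
labels = schema.labels + ["NONE"]


def cand(span, top, p_top, p_none):
    d = np.full(len(labels), (1 - p_top - p_none) / (len(labels) - 2))
    d[labels.index(top)] = p_top
    d[-1] = p_none
    return CandidateSpan(span=span, type_dist=d, entity_score=1 - p_none)


cset = CandidateSet(
    candidates=[
        cand((2, 4), "CELL", 0.85, 0.05),      # confident true mention
        cand((3, 6), "GENE", 0.50, 0.30),      # crossing false positive
        cand((5, 5), "DISEASE", 0.60, 0.20),   # nested in the crossing span
        cand((8, 8), "CYTOKINE", 0.70, 0.10),  # fine on its own
    ],
    labels=labels,
)

for name, cfg in [
    ("argmax baseline", baseline_config()),
    ("CCD (lambda1=10)", DecodeConfig(lambda1=10.0)),
]:
    mentions = decode_candidates(cset, schema, cfg)
    print(name)
    for m in mentions:
        print(f"  ({m.start},{m.end}) {m.label}  confidence={m.confidence:.2f}")
# The baseline keeps every positive-margin candidate, including the
# crossing (3,6) span; CCD's overlap penalty removes it, so the output
# contains no geometrically conflicting pair.
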