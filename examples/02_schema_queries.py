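"""Query a type schema: hierarchy, siblings, admissible pairs, projection.

Schemas are small JSON documents (hand-built subsets of UMLS/MeSH-style
ontologies).  The decoder uses them for conflict penalties (admissible
co-occurrence set C), ontology filtering (sibling masks) and nesting
priors.
"""

import numpy as np

from spanccd import make_toy_schema

schema = make_toy_schema()

print("labels:", schema.labels)
print("T_CELL is a CELL:", schema.is_ancestor("CELL", "T_CELL"))
print("siblings of CYTOKINE:", sorted(schema.siblings("CYTOKINE")))
print("compatibility(CELL, CYTOKINE):", schema.compatibility("CELL", "CYTOKINE"))
print("compatibility(CYTOKINE, DISEASE):", schema.compatibility("CYTOKINE", "DISEASE"))
# -inf marks an inadmissible co-occurrence: selecting both labels on
# structurally related spans costs the conflict penalty at decode time.

omega = schema.projection_matrix()
print("\nprojection matrix Omega (rows/cols in label order):")
with np.printoptions(linewidth=100):
    print(omega.astype(int))
# Row i has a 1 in column j when label i is a (strict) descendant of
# label j; the diagonal keeps each type's own score mass.
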