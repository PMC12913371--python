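"""Entity type schemas: label inventory, hierarchy, co-occurrence and priors.

A schema is a small declarative JSON document describing the label set Y,
a subclass hierarchy (parent links), the set C of admissible label
co-occurrences, a nesting prior gamma over (inner, outer) label pairs and
a frequency prior eta per label.  Hand-built subsets of large medical
ontologies (UMLS/MeSH-style hierarchies) can be expressed in this dialect
without any external download.

JSON dialect (exact keys)::

    {
      "types": [{"id": "CELL", "name": "Cell", "parent": "ENTITY"}, ...],
      "admissible_pairs": [["CELL", "CYTOKINE"], ...],
      "nesting_prior": {"T_CELL|CELL": 1.0, ...},   # "inner|outer" -> weight
      "frequency_prior": {"CELL": 1.0, ...}
    }

The reserved label ``"NONE"`` (non-entity) never appears in a schema.
Labels are ordered lexicographically by id everywhere a fixed ordering is
required (e.g. the projection matrix).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

NONE_LABEL = "NONE"


class SchemaError(ValueError):
    """Base class for schema problems."""


class SchemaFormatError(SchemaError):
    """The file does not parse as the documented schema dialect."""


class SchemaValidationError(SchemaError):
    """The parsed schema violates an invariant (dangling ref, cycle...)."""


class UnknownLabelError(KeyError, SchemaError):
    """A queried label is not part of the schema."""


@dataclass(frozen=True)
class EntityType:
    id: str
    display_name: str
    parent_id: str | None = None


@dataclass
class TypeSchema:
    """Validated type schema; see module docstring for the file dialect."""

    types: dict[str, EntityType]
    admissible_pairs: frozenset[frozenset[str]] = frozenset()
    nesting_prior: dict[tuple[str, str], float] = field(default_factory=dict)
    frequency_prior: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        validate_schema(self)

    # -- queries -------------------------------------------------------
    @property
    def labels(self) -> list[str]:
        """All label ids in the fixed (lexicographic) ordering."""
        return sorted(self.types)

    def _check(self, y: str) -> None:
        if y not in self.types:
            raise UnknownLabelError(f"label {y!r} not in schema")

    def compatibility(self, y: str, y2: str) -> float:
        """Admissible co-occurrence: 1 if {y, y2} in C else -inf.

        Symmetric; a label is always compatible with itself (the JSON
        dialect has no way to exclude a self pair).
        """
        self._check(y)
        self._check(y2)
        if y == y2 or frozenset((y, y2)) in self.admissible_pairs:
            return 1.0
        return -np.inf

    def is_ancestor(self, ancestor: str, descendant: str) -> bool:
        """Strict reachability by parent links (is_ancestor(y, y) is False)."""
        self._check(ancestor)
        self._check(descendant)
        cur = self.types[descendant].parent_id
        while cur is not None:
            if cur == ancestor:
                return True
            cur = self.types[cur].parent_id
        return False

    def siblings(self, y: str) -> set[str]:
        """Labels sharing y's parent (root types share a virtual root)."""
        self._check(y)
        parent = self.types[y].parent_id
        return {t for t in self.types if t != y and self.types[t].parent_id == parent}

    def projection_matrix(self) -> np.ndarray:
        """Binary |Y| x |Y| matrix: (i, j) = 1 iff label_i is a strict
        descendant of label_j; diagonal set to 1 so projection preserves a
        type's own score mass.  Rows/columns follow :attr:`labels`.
        """
        labels = self.labels
        n = len(labels)
        omega = np.eye(n)
        for i, yi in enumerate(labels):
            for j, yj in enumerate(labels):
                if i != j and self.is_ancestor(yj, yi):
                    omega[i, j] = 1.0
        return omega

    def gamma(self, inner: str, outer: str) -> float:
        """Nesting prior for (inner, outer); 0.0 when unspecified."""
        return self.nesting_prior.get((inner, outer), 0.0)

    def eta(self, y: str) -> float:
        """Frequency prior; 1.0 when unspecified."""
        return self.frequency_prior.get(y, 1.0)

    # -- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "types": [
                {"id": t.id, "name": t.display_name}
                | ({"parent": t.parent_id} if t.parent_id else {})
                for t in (self.types[k] for k in self.labels)
            ],
            "admissible_pairs": sorted(sorted(p) for p in self.admissible_pairs),
            "nesting_prior": {f"{i}|{o}": w for (i, o), w in sorted(self.nesting_prior.items())},
            "frequency_prior": dict(sorted(self.frequency_prior.items())),
        }

    def fingerprint(self) -> str:
        import hashlib

        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def validate_schema(schema: TypeSchema) -> None:
    types = schema.types
    if NONE_LABEL in types:
        raise SchemaValidationError(f"reserved label {NONE_LABEL!r} declared as a type")
    for t in types.values():
        if t.parent_id is not None and t.parent_id not in types:
            raise SchemaValidationError(
                f"type {t.id!r} references unknown parent {t.parent_id!r}"
            )
    # cycle detection on parent links
    for start in types:
        seen = [start]
        cur = types[start].parent_id
        while cur is not None:
            if cur in seen:
                cycle = seen[seen.index(cur):] + [cur]
                raise SchemaValidationError(
                    "cycle in type hierarchy: " + " -> ".join(cycle)
                )
            seen.append(cur)
            cur = types[cur].parent_id
    for pair in schema.admissible_pairs:
        for y in pair:
            if y == NONE_LABEL:
                raise SchemaValidationError("NONE may not appear in admissible_pairs")
            if y not in types:
                raise SchemaValidationError(f"admissible_pairs references unknown label {y!r}")
    for (inner, outer) in schema.nesting_prior:
        for y in (inner, outer):
            if y == NONE_LABEL:
                raise SchemaValidationError("NONE may not appear in nesting_prior")
            if y not in types:
                raise SchemaValidationError(f"nesting_prior references unknown label {y!r}")
    for y, w in schema.frequency_prior.items():
        if y == NONE_LABEL:
            raise SchemaValidationError("NONE may not appear in frequency_prior")
        if y not in types:
            raise SchemaValidationError(f"frequency_prior references unknown label {y!r}")
        if w < 0:
            raise SchemaValidationError(f"frequency_prior[{y!r}] = {w} is negative")


def schema_from_dict(data: dict) -> TypeSchema:
    try:
        raw_types = data["types"]
        types: dict[str, EntityType] = {}
        for entry in raw_types:
            tid = entry["id"]
            if tid in types:
                raise SchemaValidationError(f"duplicate type id {tid!r}")
            types[tid] = EntityType(
                id=tid,
                display_name=entry.get("name", tid),
                parent_id=entry.get("parent"),
            )
        pairs = frozenset(
            frozenset(p) for p in data.get("admissible_pairs", [])
        )
        nesting = {}
        for key, w in data.get("nesting_prior", {}).items():
            inner, _, outer = key.partition("|")
            if not outer:
                raise SchemaFormatError(
                    f"nesting_prior key {key!r} is not of the form 'inner|outer'"
                )
            nesting[(inner, outer)] = float(w)
        freq = {y: float(w) for y, w in data.get("frequency_prior", {}).items()}
    except (KeyError, TypeError) as err:
        raise SchemaFormatError(f"malformed schema document: {err}") from err
    return TypeSchema(
        types=types,
        admissible_pairs=pairs,
        nesting_prior=nesting,
        frequency_prior=freq,
    )


def load_schema(path) -> TypeSchema:
    """Load and validate a schema JSON file (see module docstring)."""
    with open(path, encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as err:
            raise SchemaFormatError(f"{path}: line {err.lineno}: {err.msg}") from err
    return schema_from_dict(data)


# module-level function aliases mirroring the method API ----------------


def compatibility(schema: TypeSchema, y: str, y2: str) -> float:
    return schema.compatibility(y, y2)


def is_ancestor(schema: TypeSchema, ancestor: str, descendant: str) -> bool:
    return schema.is_ancestor(ancestor, descendant)


def siblings(schema: TypeSchema, y: str) -> set[str]:
    return schema.siblings(y)


def projection_matrix(schema: TypeSchema) -> np.ndarray:
    return schema.projection_matrix()
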