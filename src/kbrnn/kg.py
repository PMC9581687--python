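"""Symptom/syndrome sub-knowledge-graph: data model, I/O and query primitives.

The graph holds three entity kinds — main symptoms, additional symptoms and
syndromes — and diagnosis links connecting each syndrome to its symptoms.
Symptom ids share one unique, continuous numbering starting from 0 across the
two symptom kinds (display code ``SYM<id>``); syndromes are numbered separately
(``SYN<id>``).  Two query primitives are exposed:

* :meth:`KnowledgeGraph.e_query` — all symptoms of one kind linked to a syndrome;
* :meth:`KnowledgeGraph.e_match` — leftmost-longest dictionary matching of
  symptom aliases in raw record text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field

KIND_MAIN = "main_symptom"
KIND_ADD = "additional_symptom"
KIND_SYN = "syndrome"

_CODE_RE = re.compile(r"^(SYM|SYN)(\d+)$")


class KGValidationError(ValueError):
    """Raised when a graph violates a structural invariant."""


class UnknownSyndromeError(KeyError):
    """Raised when a syndrome id is not present in the graph."""


def format_code(kind: str, entity_id: int) -> str:
    """Display code for an entity: ``SYM<id>`` for symptoms, ``SYN<id>`` for syndromes."""
    return ("SYN" if kind == KIND_SYN else "SYM") + str(entity_id)


def parse_code(code: str) -> tuple[str, int]:
    """Inverse of :func:`format_code`; returns ``("SYM"|"SYN", id)``."""
    m = _CODE_RE.match(code)
    if m is None:
        raise ValueError(f"not an entity code: {code!r}")
    return m.group(1), int(m.group(2))


@dataclass(frozen=True)
class Entity:
    id: int
    kind: str
    canonical_name: str
    aliases: tuple[str, ...]

    def __post_init__(self):
        if self.id < 0:
            raise KGValidationError(f"negative entity id {self.id}")
        if self.kind not in (KIND_MAIN, KIND_ADD, KIND_SYN):
            raise KGValidationError(f"unknown entity kind {self.kind!r}")
        if self.canonical_name not in self.aliases:
            object.__setattr__(self, "aliases", (self.canonical_name,) + tuple(self.aliases))

    @property
    def code(self) -> str:
        return format_code(self.kind, self.id)


@dataclass(frozen=True)
class RelationTriple:
    """A diagnosis link: syndrome --relation_label--> symptom."""

    syndrome: int
    symptom: int
    symptom_kind: str
    relation_label: str = "has_symptom"


@dataclass
class KnowledgeGraph:
    main_symptoms: list[Entity] = field(default_factory=list)
    additional_symptoms: list[Entity] = field(default_factory=list)
    syndromes: list[Entity] = field(default_factory=list)
    triples: list[RelationTriple] = field(default_factory=list)

    def __post_init__(self):
        self.validate()
        self._symptom_by_id = {e.id: e for e in self.main_symptoms + self.additional_symptoms}
        self._syndrome_by_id = {e.id: e for e in self.syndromes}
        self._alias_index: dict[str, int] | None = None

    # ------------------------------------------------------------------ sizes
    @property
    def N(self) -> int:
        """Total entity count."""
        return len(self.main_symptoms) + len(self.additional_symptoms) + len(self.syndromes)

    @property
    def M(self) -> int:
        """Relation (link) count."""
        return len(self.triples)

    @property
    def m(self) -> int:
        """Unified symptom count |E_main ∪ E_add|."""
        return len(self.main_symptoms) + len(self.additional_symptoms)

    @property
    def n_syndromes(self) -> int:
        return len(self.syndromes)

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        sym_ids = sorted(e.id for e in self.main_symptoms + self.additional_symptoms)
        dup = [i for i, j in zip(sym_ids, sym_ids[1:]) if i == j]
        if dup:
            raise KGValidationError(f"duplicate symptom ids: {sorted(set(dup))}")
        if sym_ids and sym_ids != list(range(len(sym_ids))):
            missing = sorted(set(range(len(sym_ids))) - set(sym_ids))
            raise KGValidationError(f"symptom ids not continuous from 0; gaps at {missing}")
        syn_ids = sorted(e.id for e in self.syndromes)
        if len(set(syn_ids)) != len(syn_ids):
            raise KGValidationError("duplicate syndrome ids")
        if syn_ids and syn_ids != list(range(len(syn_ids))):
            missing = sorted(set(range(len(syn_ids))) - set(syn_ids))
            raise KGValidationError(f"syndrome ids not continuous from 0; gaps at {missing}")
        kind_of = {e.id: e.kind for e in self.main_symptoms + self.additional_symptoms}
        syn_set = set(syn_ids)
        bad = []
        for t in self.triples:
            if t.syndrome not in syn_set or t.symptom not in kind_of:
                bad.append(t)
            elif kind_of[t.symptom] != t.symptom_kind:
                bad.append(t)
        if bad:
            raise KGValidationError(f"dangling or mis-kinded link references: {bad}")

    # ---------------------------------------------------------------- lookups
    def symptom(self, symptom_id: int) -> Entity:
        return self._symptom_by_id[symptom_id]

    def syndrome(self, syndrome_id: int) -> Entity:
        if syndrome_id not in self._syndrome_by_id:
            raise UnknownSyndromeError(f"unknown syndrome id {syndrome_id}")
        return self._syndrome_by_id[syndrome_id]

    def symptom_kind(self, symptom_id: int) -> str:
        return self._symptom_by_id[symptom_id].kind

    # ------------------------------------------------------- query primitives
    def e_query(self, syndrome_id: int, pool: str) -> list[int]:
        """Symptom ids of the requested kind linked to a syndrome, sorted by id.

        ``pool`` is ``"main"`` or ``"additional"``.
        """
        self.syndrome(syndrome_id)  # raises UnknownSyndromeError
        kind = {"main": KIND_MAIN, "additional": KIND_ADD}[pool]
        return sorted({t.symptom for t in self.triples
                       if t.syndrome == syndrome_id and t.symptom_kind == kind})

    def _build_alias_index(self) -> dict[str, int]:
        if self._alias_index is None:
            idx: dict[str, int] = {}
            for e in self.main_symptoms + self.additional_symptoms:
                for a in e.aliases:
                    idx[a] = e.id
            self._alias_index = idx
        return self._alias_index

    def e_match(self, text: str) -> list[int]:
        """Scan ``text`` left to right emitting symptom ids in order of appearance.

        At each position the longest matching alias wins; matched spans are
        consumed and never overlap.  Text with no matches yields ``[]``.
        """
        idx = self._build_alias_index()
        if not idx:
            return []
        max_len = max(len(a) for a in idx)
        out: list[int] = []
        i, n = 0, len(text)
        while i < n:
            hit = None
            for j in range(min(n, i + max_len), i, -1):
                if text[i:j] in idx:
                    hit = (j, idx[text[i:j]])
                    break
            if hit is None:
                i += 1
            else:
                out.append(hit[1])
                i = hit[0]
        return out

    # -------------------------------------------------------------------- I/O
    def to_dict(self) -> dict:
        def ents(lst):
            return [{"id": e.id, "name": e.canonical_name, "aliases": list(e.aliases)}
                    for e in sorted(lst, key=lambda e: e.id)]

        return {
            "symptoms_main": ents(self.main_symptoms),
            "symptoms_additional": ents(self.additional_symptoms),
            "syndromes": ents(self.syndromes),
            "links": [{"syndrome": t.syndrome,
                       "symptom_kind": "main" if t.symptom_kind == KIND_MAIN else "additional",
                       "symptom": t.symptom,
                       "relation": t.relation_label}
                      for t in self.triples],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KnowledgeGraph":
        def ents(lst, kind):
            return [Entity(e["id"], kind, e["name"], tuple(e.get("aliases", [e["name"]])))
                    for e in lst]

        kinds = {"main": KIND_MAIN, "additional": KIND_ADD}
        return cls(
            main_symptoms=ents(d.get("symptoms_main", []), KIND_MAIN),
            additional_symptoms=ents(d.get("symptoms_additional", []), KIND_ADD),
            syndromes=ents(d.get("syndromes", []), KIND_SYN),
            triples=[RelationTriple(l["syndrome"], l["symptom"], kinds[l["symptom_kind"]],
                                    l.get("relation", "has_symptom"))
                     for l in d.get("links", [])],
        )

    def __eq__(self, other):
        if not isinstance(other, KnowledgeGraph):
            return NotImplemented
        return (sorted(self.main_symptoms, key=lambda e: e.id) == sorted(other.main_symptoms, key=lambda e: e.id)
                and sorted(self.additional_symptoms, key=lambda e: e.id) == sorted(other.additional_symptoms, key=lambda e: e.id)
                and sorted(self.syndromes, key=lambda e: e.id) == sorted(other.syndromes, key=lambda e: e.id)
                and set(self.triples) == set(other.triples))


def load_kg(path) -> KnowledgeGraph:
    with open(path, "r", encoding="utf-8") as fh:
        return KnowledgeGraph.from_dict(json.load(fh))


def save_kg(kg: KnowledgeGraph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(kg.to_dict(), fh, indent=1, ensure_ascii=False)
        fh.write("\n")
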