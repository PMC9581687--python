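"""Symptom-level sentences, padding, vocabulary and the four-way corpus split.

A record lists main symptoms then additional symptoms plus a syndrome label.
It becomes an ordered token sequence with a main/additional boundary, is framed
with BOS/EOS and padded with PADs to a shared length, and the corpus is split
into pre / train / dev / test parts (defaults 20/50/20/10%), stratified by label.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .kg import KIND_ADD, KIND_MAIN, KnowledgeGraph, format_code, parse_code

BOS, EOS, PAD, UNK = "BOS", "EOS", "PAD", "UNK"
SPECIALS = (BOS, EOS, PAD, UNK)


class StructureError(ValueError):
    """A record's tokens violate the main/additional kind partition."""


class SplitError(ValueError):
    pass


@dataclass
class EMRRecord:
    """Raw record: main/additional parts as text or symptom code lists, plus label."""

    main: list[str] | str
    additional: list[str] | str
    syndrome: int
    truth: int | None = None  # ground-truth label when synthetic label noise applied


@dataclass(frozen=True)
class EMRSentence:
    """Ordered symptom ids; tokens[:boundary] are main, tokens[boundary:] additional."""

    tokens: tuple[int, ...]
    boundary: int
    label: int

    def __post_init__(self):
        if not 0 <= self.boundary <= len(self.tokens):
            raise StructureError(f"boundary {self.boundary} outside [0, {len(self.tokens)}]")

    @property
    def n(self) -> int:
        return len(self.tokens)

    @property
    def main_tokens(self) -> tuple[int, ...]:
        return self.tokens[:self.boundary]

    @property
    def additional_tokens(self) -> tuple[int, ...]:
        return self.tokens[self.boundary:]


@dataclass
class Vocabulary:
    """Token <-> index bijection; BOS, EOS, PAD, UNK occupy indices 0..3."""

    tokens: tuple[str, ...]
    index: dict[str, int] = field(init=False)

    def __post_init__(self):
        if tuple(self.tokens[:4]) != SPECIALS:
            raise ValueError("vocabulary must start with BOS, EOS, PAD, UNK")
        self.index = {t: i for i, t in enumerate(self.tokens)}
        if len(self.index) != len(self.tokens):
            raise ValueError("duplicate vocabulary tokens")

    @classmethod
    def build(cls, symptom_codes) -> "Vocabulary":
        def sort_key(code):
            return parse_code(code)[1]

        return cls(SPECIALS + tuple(sorted(set(symptom_codes), key=sort_key)))

    @classmethod
    def from_kg(cls, kg: KnowledgeGraph) -> "Vocabulary":
        return cls.build([e.code for e in kg.main_symptoms + kg.additional_symptoms])

    @property
    def V(self) -> int:
        return len(self.tokens)

    def encode(self, token: str) -> int:
        """Index of a token; unknown tokens map to UNK."""
        return self.index.get(token, self.index[UNK])


@dataclass(frozen=True)
class PaddedSentence:
    """BOS + symptom codes + EOS + PADs, all sentences sharing one length L."""

    tokens: tuple[str, ...]
    ids: tuple[int, ...]
    label: int

    @property
    def L(self) -> int:
        return len(self.tokens)

    def core_tokens(self) -> tuple[str, ...]:
        """Symptom codes with BOS/EOS/PAD stripped (round-trip to the sentence)."""
        return tuple(t for t in self.tokens if t not in (BOS, EOS, PAD))


def record_to_sentence(record: EMRRecord, kg: KnowledgeGraph) -> EMRSentence:
    """Convert a record to a symptom-level sentence.

    Text fields are routed through dictionary matching; code lists are parsed
    directly.  Duplicate mentions are collapsed keeping the first occurrence
    (rule recognition is set-like).  Main tokens must be main-kind symptoms and
    additional tokens additional-kind, else a :class:`StructureError` is raised.
    """
    def resolve(part) -> list[int]:
        if isinstance(part, str):
            return kg.e_match(part)
        out = []
        for item in part:
            if isinstance(item, int):
                out.append(item)
            else:
                prefix, sid = parse_code(item)
                if prefix != "SYM":
                    raise StructureError(f"{item!r} is not a symptom code")
                out.append(sid)
        return out

    kg.syndrome(record.syndrome)
    main = resolve(record.main)
    add = resolve(record.additional)
    seen: set[int] = set()
    main_d = [t for t in main if not (t in seen or seen.add(t))]
    add_d = [t for t in add if not (t in seen or seen.add(t))]
    for t in main_d:
        if kg.symptom_kind(t) != KIND_MAIN:
            raise StructureError(f"SYM{t} is not a main symptom but appears in the main part")
    for t in add_d:
        if kg.symptom_kind(t) != KIND_ADD:
            raise StructureError(f"SYM{t} is not an additional symptom but appears in the additional part")
    return EMRSentence(tuple(main_d + add_d), len(main_d), record.syndrome)


def pad_sentence(sentence: EMRSentence, vocab: Vocabulary, L: int) -> PaddedSentence:
    codes = [format_code(KIND_MAIN, t) for t in sentence.tokens]  # SYM prefix for both kinds
    if len(codes) + 2 > L:
        raise ValueError(f"padded length {L} < sentence length {len(codes)} + 2")
    toks = (BOS, *codes, EOS) + (PAD,) * (L - len(codes) - 2)
    return PaddedSentence(toks, tuple(vocab.encode(t) for t in toks), sentence.label)


def pad_corpus(sentences, L: int | None = None,
               vocab: Vocabulary | None = None) -> tuple[list[PaddedSentence], Vocabulary]:
    """Frame every sentence with BOS/EOS and pad to a common length L.

    Default L is the longest sentence plus 2 (the frame markers).  The returned
    vocabulary covers every token seen plus the specials, unless one is passed in.
    """
    sentences = list(sentences)
    max_n = max((s.n for s in sentences), default=0)
    if L is None:
        L = max_n + 2
    elif L < max_n + 2:
        raise ValueError(f"L={L} is smaller than longest sentence + 2 = {max_n + 2}")
    if vocab is None:
        codes = {format_code(KIND_MAIN, t) for s in sentences for t in s.tokens}
        vocab = Vocabulary.build(codes)
    return [pad_sentence(s, vocab, L) for s in sentences], vocab


@dataclass
class SplitSpec:
    """Fractions for the pre/train/dev/test parts and the shuffling seed."""

    pre: float = 0.20
    train: float = 0.50
    dev: float = 0.20
    test: float = 0.10
    seed: int = 0
    stratify: bool = True

    @property
    def fractions(self) -> tuple[float, float, float, float]:
        return (self.pre, self.train, self.dev, self.test)

    def __post_init__(self):
        if not math.isclose(sum(self.fractions), 1.0, abs_tol=1e-9):
            raise SplitError(f"fractions {self.fractions} do not sum to 1")


def _largest_remainder(n: int, fractions) -> list[int]:
    ideal = [n * f for f in fractions]
    base = [math.floor(x) for x in ideal]
    rem = n - sum(base)
    order = sorted(range(len(fractions)), key=lambda i: (-(ideal[i] - base[i]), i))
    for i in order[:rem]:
        base[i] += 1
    return base


def split_corpus(sentences, spec: SplitSpec):
    """Partition sentences into (pre, train, dev, test).

    Sizes follow the largest-remainder method on the global fractions; when
    stratified (default) per-label allocations use largest remainder too,
    with leftovers placed in syndrome-id order subject to the global sizes,
    so per-label proportions stay within one sentence of the global fractions.
    Reproducible for a fixed seed; the union of the parts is the input corpus.
    """
    sentences = list(sentences)
    n = len(sentences)
    if n < 4:
        raise SplitError(f"corpus of {n} sentences cannot be split four ways")
    rng = np.random.default_rng(spec.seed)
    targets = _largest_remainder(n, spec.fractions)
    parts: list[list] = [[], [], [], []]
    if not spec.stratify:
        order = rng.permutation(n)
        pos = 0
        for p, size in enumerate(targets):
            parts[p] = [sentences[i] for i in order[pos:pos + size]]
            pos += size
        return tuple(parts)

    labels = sorted({s.label for s in sentences})
    capacity = list(targets)
    floors: dict[int, list[int]] = {}
    remainders: list[tuple[float, int, int]] = []
    leftovers: dict[int, list] = {}
    for lab in labels:
        grp = [s for s in sentences if s.label == lab]
        grp = [grp[i] for i in rng.permutation(len(grp))]
        ideal = [len(grp) * f for f in spec.fractions]
        base = [math.floor(x) for x in ideal]
        floors[lab] = base
        pos = 0
        for p in range(4):
            parts[p].extend(grp[pos:pos + base[p]])
            capacity[p] -= base[p]
            remainders.append((ideal[p] - base[p], lab, p))
            pos += base[p]
        leftovers[lab] = grp[pos:]
    # place each label's leftover sentences so every (label, part) cell gets at
    # most one extra (keeping per-label proportions within one sentence), in
    # descending fractional-remainder order subject to the global part sizes
    remainders.sort(key=lambda t: (-t[0], t[1], t[2]))
    used: set[tuple[int, int]] = set()
    progress = True
    while any(leftovers.values()) and progress:
        progress = False
        for _, lab, p in remainders:
            if leftovers[lab] and capacity[p] > 0 and (lab, p) not in used:
                parts[p].append(leftovers[lab].pop())
                capacity[p] -= 1
                used.add((lab, p))
                progress = True
    for lab in labels:  # rare fallback: any remaining go wherever capacity is left
        while leftovers[lab]:
            p = next(q for q in range(4) if capacity[q] > 0)
            parts[p].append(leftovers[lab].pop())
            capacity[p] -= 1
    return tuple(parts)


# ------------------------------------------------------------------ record I/O

def load_records(path) -> list[EMRRecord]:
    """Read records from JSONL: one {"main", "additional", "syndrome"} per line."""
    out = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            out.append(EMRRecord(d["main"], d["additional"], d["syndrome"], d.get("truth")))
    return out


def save_records(records, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in records:
            d = {"main": r.main, "additional": r.additional, "syndrome": r.syndrome}
            if r.truth is not None:
                d["truth"] = r.truth
            fh.write(json.dumps(d, ensure_ascii=False) + "\n")
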