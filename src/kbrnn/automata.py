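"""Compile knowledge rules to regular expressions, automata and tensors.

A rule ``({m1..}, {a1..})`` becomes the core regex ``(m1|m2|...)+(a1|a2|...)+``
and, for padded sentences, the wildcard-flanked form ``$*(core)$*`` where ``$``
stands for any vocabulary token (including BOS/EOS/PAD/UNK, so framing and
padding are absorbed).  Each regex is turned into a Thompson NFA, determinized
by subset construction, minimized by partition refinement (dead and unreachable
states dropped, so the transition function is partial), and all per-rule
minimal DFAs are merged under one fresh start state.  The merged automaton is
represented by the binary transfer tensor T (V x K x K), the start vector S and
the final vector F; matching a sentence is the matrix product
``S . T[s_1] ... T[s_x] . F`` = the number of component automata accepting it,
with a per-syndrome variant replacing F by the final-state grouping F_syn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import PaddedSentence, Vocabulary
from .kg import KIND_MAIN, format_code
from .rules import KnowledgeRule

WILDCARD = "$"


# ------------------------------------------------------------------ regex AST

class RegexNode:
    def __str__(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError


@dataclass(frozen=True)
class Lit(RegexNode):
    token: str

    def __str__(self):
        return self.token


@dataclass(frozen=True)
class Wildcard(RegexNode):
    def __str__(self):
        return WILDCARD


def _wrap(node: RegexNode) -> str:
    if isinstance(node, (Lit, Wildcard)):
        return str(node)
    return f"({node})"


@dataclass(frozen=True)
class Concat(RegexNode):
    parts: tuple[RegexNode, ...]

    def __str__(self):
        return "".join(_wrap(p) if isinstance(p, Union) else str(p) for p in self.parts)


@dataclass(frozen=True)
class Union(RegexNode):
    parts: tuple[RegexNode, ...]

    def __str__(self):
        return "|".join(str(p) for p in self.parts)


@dataclass(frozen=True)
class Plus(RegexNode):
    child: RegexNode

    def __str__(self):
        return _wrap(self.child) + "+"


@dataclass(frozen=True)
class Star(RegexNode):
    child: RegexNode

    def __str__(self):
        return _wrap(self.child) + "*"


def parse_regex(text: str) -> RegexNode:
    """Recursive-descent parser for the printable regex dialect.

    Grammar: union := concat ('|' concat)* ; concat := factor+ ;
    factor := atom ('+' | '*')* ; atom := token | '$' | '(' union ')'.
    ``str(parse_regex(str(tree)))`` reproduces the printable form.
    """
    import re as _re

    toks = _re.findall(r"[A-Za-z0-9_]+|[()|+*$]", text.replace(" ", ""))
    pos = 0

    def peek():
        return toks[pos] if pos < len(toks) else None

    def take():
        nonlocal pos
        t = toks[pos]
        pos += 1
        return t

    def union():
        parts = [concat()]
        while peek() == "|":
            take()
            parts.append(concat())
        return parts[0] if len(parts) == 1 else Union(tuple(parts))

    def concat():
        parts = []
        while peek() is not None and peek() not in ")|":
            parts.append(factor())
        if not parts:
            raise ValueError("empty concatenation")
        return parts[0] if len(parts) == 1 else Concat(tuple(parts))

    def factor():
        node = atom()
        while peek() in ("+", "*"):
            node = Plus(node) if take() == "+" else Star(node)
        return node

    def atom():
        t = take()
        if t == "(":
            node = union()
            if take() != ")":
                raise ValueError("unbalanced parenthesis")
            return node
        if t == WILDCARD:
            return Wildcard()
        if t in "()|+*":
            raise ValueError(f"unexpected operator {t!r}")
        return Lit(t)

    node = union()
    if pos != len(toks):
        raise ValueError(f"trailing input at token {pos}")
    return node


def rule_to_regex(rule: KnowledgeRule, wildcard: bool = True) -> RegexNode:
    """Core form ``(M1|...)+(A1|...)+``; wildcard-flanked when requested.

    Union members are ordered by ascending symptom id (canonical form).
    """
    if not rule.main_set or not rule.add_set:
        raise ValueError(f"rule for SYN{rule.syndrome} has an empty symptom set")

    def union_of(ids):
        lits = tuple(Lit(format_code(KIND_MAIN, i)) for i in sorted(ids))
        return lits[0] if len(lits) == 1 else Union(lits)

    core = Concat((Plus(union_of(rule.main_set)), Plus(union_of(rule.add_set))))
    if not wildcard:
        return core
    return Concat((Star(Wildcard()), *core.parts, Star(Wildcard())))


# ------------------------------------------------------------------------ NFA

@dataclass
class NFA:
    """Thompson-form NFA: one start, one final, eps edges + single token edges."""

    n_states: int
    start: int
    final: int
    eps: list[list[int]]
    token_edge: dict[int, tuple[str, int]]
    alphabet: tuple[str, ...]

    def eps_closure(self, states) -> frozenset[int]:
        stack = list(states)
        seen = set(stack)
        while stack:
            q = stack.pop()
            for p in self.eps[q]:
                if p not in seen:
                    seen.add(p)
                    stack.append(p)
        return frozenset(seen)

    def accepts(self, tokens) -> bool:
        cur = self.eps_closure([self.start])
        for t in tokens:
            nxt = [tgt for q in cur
                   for tok, tgt in [self.token_edge.get(q, (None, None))] if tok == t]
            if not nxt:
                return False
            cur = self.eps_closure(nxt)
        return self.final in cur


def thompson(regex: RegexNode, vocab: Vocabulary) -> NFA:
    """Thompson construction; the wildcard expands to a union over all
    vocabulary tokens (specials included)."""
    eps: list[list[int]] = []
    token_edge: dict[int, tuple[str, int]] = {}

    def new_state() -> int:
        eps.append([])
        return len(eps) - 1

    vocab_set = set(vocab.tokens)

    def build(node: RegexNode) -> tuple[int, int]:
        if isinstance(node, Lit):
            if node.token not in vocab_set:
                raise ValueError(f"regex token {node.token!r} not in vocabulary")
            s, f = new_state(), new_state()
            token_edge[s] = (node.token, f)
            return s, f
        if isinstance(node, Wildcard):
            return build(Union(tuple(Lit(t) for t in vocab.tokens)))
        if isinstance(node, Concat):
            frags = [build(p) for p in node.parts]
            for (_, f1), (s2, _) in zip(frags, frags[1:]):
                eps[f1].append(s2)
            return frags[0][0], frags[-1][1]
        if isinstance(node, Union):
            s, f = new_state(), new_state()
            for p in node.parts:
                ps, pf = build(p)
                eps[s].append(ps)
                eps[pf].append(f)
            return s, f
        if isinstance(node, Star):
            cs, cf = build(node.child)
            s, f = new_state(), new_state()
            eps[s] += [cs, f]
            eps[cf] += [cs, f]
            return s, f
        if isinstance(node, Plus):
            cs, cf = build(node.child)
            s, f = new_state(), new_state()
            eps[s].append(cs)
            eps[cf] += [cs, f]
            return s, f
        raise TypeError(f"unknown regex node {node!r}")

    start, final = build(regex)
    return NFA(len(eps), start, final, eps, token_edge, tuple(vocab.tokens))


# ------------------------------------------------------------------------ DFA

@dataclass
class DFA:
    """Deterministic automaton with a partial transition function
    (missing edge = reject); carries the owning rule's syndrome."""

    n_states: int
    start: int
    finals: frozenset[int]
    trans: dict[tuple[int, str], int]
    alphabet: tuple[str, ...]
    syndrome: int | None = None
    rule_index: int | None = None

    def accepts(self, tokens) -> bool:
        q = self.start
        for t in tokens:
            q = self.trans.get((q, t))
            if q is None:
                return False
        return q in self.finals


def determinize(nfa: NFA) -> DFA:
    """Subset construction; only non-empty successor sets become states."""
    # group token edges by token for the move step
    by_token: dict[str, dict[int, int]] = {}
    for q, (tok, tgt) in nfa.token_edge.items():
        by_token.setdefault(tok, {})[q] = tgt

    start_set = nfa.eps_closure([nfa.start])
    index = {start_set: 0}
    order = [start_set]
    trans: dict[tuple[int, str], int] = {}
    i = 0
    while i < len(order):
        cur = order[i]
        for tok in nfa.alphabet:
            edges = by_token.get(tok)
            if not edges:
                continue
            moved = [edges[q] for q in cur if q in edges]
            if not moved:
                continue
            nxt = nfa.eps_closure(moved)
            if nxt not in index:
                index[nxt] = len(order)
                order.append(nxt)
            trans[(i, tok)] = index[nxt]
        i += 1
    finals = frozenset(i for s, i in index.items() if nfa.final in s)
    return DFA(len(order), 0, finals, trans, nfa.alphabet)


def minimize(dfa: DFA) -> DFA:
    """Minimum-state equivalent DFA by Moore partition refinement.

    The automaton is completed with a dead state for refinement; the dead
    block and unreachable blocks are dropped afterwards, so the result keeps
    a partial transition function and only live states.
    """
    n = dfa.n_states
    dead = n
    block = [1 if q in dfa.finals else 0 for q in range(n)] + [0]

    def succ(q, tok):
        if q == dead:
            return dead
        return dfa.trans.get((q, tok), dead)

    while True:
        sigs = {}
        new_block = [0] * (n + 1)
        for q in range(n + 1):
            sig = (block[q], tuple(block[succ(q, t)] for t in dfa.alphabet))
            if sig not in sigs:
                sigs[sig] = len(sigs)
            new_block[q] = sigs[sig]
        if new_block == block:
            break
        block = new_block

    dead_block = block[dead]
    # BFS from the start block over non-dead transitions, renumbering on the way
    rep: dict[int, int] = {}  # old block -> representative old state
    for q in range(n):
        rep.setdefault(block[q], q)
    remap: dict[int, int] = {}
    start_b = block[dfa.start]
    if start_b == dead_block:
        return DFA(0, 0, frozenset(), {}, dfa.alphabet, dfa.syndrome, dfa.rule_index)
    queue = [start_b]
    remap[start_b] = 0
    trans: dict[tuple[int, str], int] = {}
    k = 0
    while k < len(queue):
        b = queue[k]
        q = rep[b]
        for tok in dfa.alphabet:
            nb = block[succ(q, tok)]
            if nb == dead_block:
                continue
            if nb not in remap:
                remap[nb] = len(queue)
                queue.append(nb)
            trans[(remap[b], tok)] = remap[nb]
        k += 1
    finals = frozenset(remap[block[q]] for q in dfa.finals if block[q] in remap)
    return DFA(len(queue), 0, finals, trans, dfa.alphabet, dfa.syndrome, dfa.rule_index)


def compile_rule(rule: KnowledgeRule, vocab: Vocabulary, wildcard: bool = True,
                 rule_index: int | None = None) -> DFA:
    """Rule -> regex -> NFA -> DFA -> minimal DFA, tagged with its syndrome."""
    mdfa = minimize(determinize(thompson(rule_to_regex(rule, wildcard), vocab)))
    mdfa.syndrome = rule.syndrome
    mdfa.rule_index = rule_index
    return mdfa


# ------------------------------------------------------------ tensor automaton

@dataclass
class TensorAutomaton:
    """Merged automaton as <T, S, F> with per-syndrome final-state grouping."""

    tokens: tuple[str, ...]
    T: np.ndarray       # (V, K, K) uint8
    S: np.ndarray       # (K,) uint8
    F_syn: np.ndarray   # (K, C) uint8
    components: list[DFA] = field(default_factory=list)
    offsets: list[int] = field(default_factory=list)

    @property
    def K(self) -> int:
        return self.T.shape[1]

    @property
    def V(self) -> int:
        return self.T.shape[0]

    @property
    def C(self) -> int:
        return self.F_syn.shape[1]

    @property
    def F(self) -> np.ndarray:
        """Final vector: row-wise OR of the per-syndrome grouping."""
        return (self.F_syn.sum(axis=1) > 0).astype(np.uint8)

    def token_ids(self, padded: PaddedSentence | list[str]) -> list[int]:
        unk = self.tokens.index("UNK")
        idx = {t: i for i, t in enumerate(self.tokens)}
        toks = padded.tokens if isinstance(padded, PaddedSentence) else padded
        return [idx.get(t, unk) for t in toks]

    def to_dict(self) -> dict:
        sig, i, j = np.nonzero(self.T)
        return {"K": int(self.K), "V": int(self.V), "tokens": list(self.tokens),
                "T": [[int(a), int(b), int(c)] for a, b, c in zip(sig, i, j)],
                "S": self.S.tolist(), "F": self.F.tolist(),
                "F_syn": self.F_syn.tolist()}


def merge(mdfas: list[DFA], vocab: Vocabulary, n_syndromes: int) -> TensorAutomaton:
    """Disjoint union of component automata under one fresh start marker.

    S marks every component start, F_syn groups each component's finals under
    its owning syndrome; T stacks the per-component transition tables.
    """
    if not mdfas:
        raise ValueError("cannot merge an empty automaton list")
    V = vocab.V
    K = sum(d.n_states for d in mdfas)
    T = np.zeros((V, K, K), dtype=np.uint8)
    S = np.zeros(K, dtype=np.uint8)
    F_syn = np.zeros((K, n_syndromes), dtype=np.uint8)
    offsets = []
    off = 0
    for d in mdfas:
        offsets.append(off)
        S[off + d.start] = 1
        for q in d.finals:
            if d.syndrome is None:
                raise ValueError("merged component lacks a syndrome tag")
            F_syn[off + q, d.syndrome] = 1
        for (q, tok), p in d.trans.items():
            T[vocab.encode(tok), off + q, off + p] = 1
        off += d.n_states
    return TensorAutomaton(tuple(vocab.tokens), T, S, F_syn, list(mdfas), offsets)


def match_count(ta: TensorAutomaton, padded: PaddedSentence | list[str]) -> int:
    """Number of component automata accepting the padded sentence:
    ``S . T[s_1] ... T[s_x] . F`` evaluated as integer matrix products."""
    return int(match_count_per_syndrome(ta, padded).sum())


def match_count_per_syndrome(ta: TensorAutomaton, padded) -> np.ndarray:
    """Length-C vector: accepting component count grouped by syndrome."""
    v = ta.S.astype(np.int64)
    for sig in ta.token_ids(padded):
        v = v @ ta.T[sig].astype(np.int64)
    return v @ ta.F_syn.astype(np.int64)


def compile_rules(rules: list[KnowledgeRule], vocab: Vocabulary, n_syndromes: int,
                  wildcard: bool = True) -> TensorAutomaton:
    mdfas = [compile_rule(r, vocab, wildcard, i) for i, r in enumerate(rules)]
    return merge(mdfas, vocab, n_syndromes)
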