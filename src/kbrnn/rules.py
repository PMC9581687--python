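"""Evolutionary extraction of parsimonious symptom-subset diagnostic rules.

For each syndrome the search space is a pair of bit vectors over the unified
symptom index: phi selects main symptoms, psi additional symptoms.  A sentence
is *recognized* by a candidate when every main token lies in phi, every
additional token in psi, and the sentence carries at least one token of each
kind — exactly the strict regular expression ``(m1|m2|...)+(a1|a2|...)+``
applied to a main-then-additional token sequence.

Scoring on the pre-set: v = t_r / c_r when no sentence of another syndrome is
recognized (f_r = 0), else 0.  t_r counts recognized same-syndrome sentences,
c_r the selected symptoms; misrecognition is disqualifying, and among
misrecognition-free candidates with equal support, smaller rules score higher.

The genetic algorithm uses tournament selection, uniform crossover, bit-flip
mutation, elitism, and reinitialization of non-elite members on stagnation.
Candidate evaluation is pure and vectorized, so results are bit-identical for
any nominal worker count.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .corpus import EMRSentence
from .kg import KnowledgeGraph


@dataclass
class CandidateSolution:
    """Triple <phi, psi, v>: main / additional selections and the score."""

    phi: np.ndarray  # bool, length m
    psi: np.ndarray  # bool, length m
    v: float = 0.0

    def copy(self) -> "CandidateSolution":
        return CandidateSolution(self.phi.copy(), self.psi.copy(), self.v)


@dataclass
class EvaluationMatrices:
    """Binary occupancy matrices of the pre-set for one target syndrome.

    ``TP[i][j] = 1`` iff symptom j occurs in the i-th same-syndrome sentence;
    ``FP`` likewise over the other-syndrome sentences.  ``true_nonempty`` /
    ``false_nonempty`` mark rows whose sentence has at least one main and one
    additional token (a structural precondition of recognition).
    """

    TP: np.ndarray
    FP: np.ndarray
    true_nonempty: np.ndarray
    false_nonempty: np.ndarray
    m: int

    @property
    def a(self) -> int:
        return self.TP.shape[0]

    @property
    def b(self) -> int:
        return self.FP.shape[0]

    @classmethod
    def build(cls, sentences, syndrome: int, m: int) -> "EvaluationMatrices":
        def rows(subset):
            mat = np.zeros((len(subset), m), dtype=np.uint8)
            nonempty = np.zeros(len(subset), dtype=bool)
            for i, s in enumerate(subset):
                mat[i, list(s.tokens)] = 1
                nonempty[i] = s.boundary >= 1 and s.n - s.boundary >= 1
            return mat, nonempty

        true_s = [s for s in sentences if s.label == syndrome]
        false_s = [s for s in sentences if s.label != syndrome]
        TP, tn = rows(true_s)
        FP, fn = rows(false_s)
        return cls(TP, FP, tn, fn, m)


@dataclass(frozen=True)
class KnowledgeRule:
    """An extracted rule: two symptom sets with its pre-set score statistics."""

    syndrome: int
    main_set: tuple[int, ...]
    add_set: tuple[int, ...]
    score: float
    support: int      # t_r
    violations: int   # f_r
    size: int         # c_r


@dataclass
class GAConfig:
    population_size: int = 200       # l
    top_k: int = 6                   # k
    max_generations: int = 500
    stagnation_window: int = 20
    mutation_rate: float | None = None   # default 1/m per bit
    crossover_rate: float = 0.9
    crossover_p: float = 0.5             # per-bit uniform-crossover probability
    tournament_size: int = 3
    elite_count: int = 5
    restart_count: int = 3
    outside_pool_prob: float = 0.02      # chance an individual samples beyond KG links
    workers: int = 1
    seed: int = 0
    score_floor: float = 0.05
    min_support: int = 1

    def __post_init__(self):
        if self.population_size <= self.top_k:
            raise ValueError("population size l must exceed top-k")


# ----------------------------------------------------------------- primitives

def seed_from_kg(syndrome: int, kg: KnowledgeGraph) -> CandidateSolution:
    """Indicator vectors of the syndrome's KG-linked main/additional symptoms."""
    m = kg.m
    phi = np.zeros(m, dtype=bool)
    psi = np.zeros(m, dtype=bool)
    mains = kg.e_query(syndrome, "main")
    adds = kg.e_query(syndrome, "additional")
    if not mains and not adds:
        warnings.warn(f"syndrome SYN{syndrome} has no linked symptoms; seeding all-zero")
    phi[mains] = True
    psi[adds] = True
    return CandidateSolution(phi, psi, 0.0)


def recognizes(solution: CandidateSolution, sentence: EMRSentence) -> bool:
    """Strict rule recognition of one sentence (the per-sentence reference path)."""
    main = sentence.main_tokens
    add = sentence.additional_tokens
    if not main or not add:
        return False
    return all(solution.phi[t] for t in main) and all(solution.psi[t] for t in add)


def rule_size(solution: CandidateSolution) -> int:
    """c_r = popcount(phi) + popcount(psi)."""
    return int(solution.phi.sum() + solution.psi.sum())


def _counts_matrix(Phi: np.ndarray, Psi: np.ndarray, mat: EvaluationMatrices):
    """Vectorized (t, f) for a population: rows of Phi/Psi are candidates."""
    sel = (Phi | Psi).astype(np.uint8)           # kind partition keeps phi/psi disjoint
    uncov_t = mat.TP @ (1 - sel).T               # a x l: uncovered symptoms per sentence
    uncov_f = mat.FP @ (1 - sel).T
    t = ((uncov_t == 0) & mat.true_nonempty[:, None]).sum(axis=0)
    f = ((uncov_f == 0) & mat.false_nonempty[:, None]).sum(axis=0)
    return t.astype(np.int64), f.astype(np.int64)


def count_matches(solution: CandidateSolution, matrices: EvaluationMatrices) -> tuple[int, int]:
    """(t_r, f_r): recognized counts over EMR_true and EMR_false via the matrix form."""
    if solution.phi.shape[0] != matrices.m:
        raise ValueError(f"solution over {solution.phi.shape[0]} symptoms, matrices over {matrices.m}")
    t, f = _counts_matrix(solution.phi[None, :], solution.psi[None, :], matrices)
    return int(t[0]), int(f[0])


def score(solution: CandidateSolution, matrices: EvaluationMatrices) -> float:
    """v = t_r / c_r if no misrecognition (f_r = 0), else 0; 0 for empty rules."""
    t_r, f_r = count_matches(solution, matrices)
    c_r = rule_size(solution)
    if f_r > 0 or c_r == 0:
        return 0.0
    return t_r / c_r


def _score_matrix(Phi, Psi, mat: EvaluationMatrices):
    t, f = _counts_matrix(Phi, Psi, mat)
    c = Phi.sum(axis=1) + Psi.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where((f == 0) & (c > 0), t / np.maximum(c, 1), 0.0)
    return v, t, f, c.astype(np.int64)


# ------------------------------------------------------------------ population

def _kind_masks(kg: KnowledgeGraph):
    m = kg.m
    main_mask = np.zeros(m, dtype=bool)
    add_mask = np.zeros(m, dtype=bool)
    main_mask[[e.id for e in kg.main_symptoms]] = True
    add_mask[[e.id for e in kg.additional_symptoms]] = True
    return main_mask, add_mask


def generate_population(syndrome: int, config: GAConfig, kg: KnowledgeGraph,
                        rng: np.random.Generator | None = None) -> list[CandidateSolution]:
    """Initial population: the KG-seeded solution plus random subsets of the
    syndrome's linked symptoms; a small fraction of individuals may also draw
    symptoms outside the KG link set (tolerates incomplete graphs)."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    m = kg.m
    main_mask, add_mask = _kind_masks(kg)
    seed = seed_from_kg(syndrome, kg)
    linked_phi, linked_psi = seed.phi, seed.psi
    pop = [seed]
    for _ in range(config.population_size - 1):
        phi = linked_phi & (rng.random(m) < 0.5)
        psi = linked_psi & (rng.random(m) < 0.5)
        if rng.random() < config.outside_pool_prob:
            phi |= main_mask & (rng.random(m) < 1.0 / m)
            psi |= add_mask & (rng.random(m) < 1.0 / m)
        pop.append(CandidateSolution(phi, psi, 0.0))
    return pop


# ------------------------------------------------------------------- evolution

def _lex_key(phi: np.ndarray, psi: np.ndarray) -> bytes:
    return np.packbits(phi).tobytes() + np.packbits(psi).tobytes()


def evolve(syndrome: int, matrices: EvaluationMatrices, config: GAConfig,
           kg: KnowledgeGraph) -> list[KnowledgeRule]:
    """Run the GA and return the top-k distinct misrecognition-free rules.

    Archive ordering: score desc, then smaller c_r, then fewer symptoms
    outside the syndrome's KG link set (the graph is a prior: between
    otherwise indistinguishable candidates, prefer the one the knowledge
    graph supports), then lexicographic bit order.  On stagnation (best
    score unimproved for the stagnation window) all non-elite members are
    reinitialized, up to ``restart_count`` times; a further stagnation
    terminates the run early.
    """
    if matrices.a == 0:
        warnings.warn(f"no pre-set sentence labeled SYN{syndrome}; returning no rules")
        return []
    rng = np.random.default_rng(config.seed)
    m = kg.m
    mut_rate = config.mutation_rate if config.mutation_rate is not None else 1.0 / m
    main_mask, add_mask = _kind_masks(kg)
    seed = seed_from_kg(syndrome, kg)
    pool_phi = seed.phi | False
    pool_psi = seed.psi | False

    pop = generate_population(syndrome, config, kg, rng)
    Phi = np.array([c.phi for c in pop])
    Psi = np.array([c.psi for c in pop])

    archive: dict[bytes, tuple] = {}
    best_score = -1.0
    stagnant = 0
    restarts = 0

    def reinit(keep: int):
        new = generate_population(syndrome, config, kg, rng)
        NP = np.array([c.phi for c in new])
        NS = np.array([c.psi for c in new])
        Phi[keep:] = NP[keep:]
        Psi[keep:] = NS[keep:]

    for _gen in range(config.max_generations):
        v, t, f, c = _score_matrix(Phi, Psi, matrices)
        # archive misrecognition-free candidates with both parts non-empty
        ok = (f == 0) & Phi.any(axis=1) & Psi.any(axis=1)
        for i in np.flatnonzero(ok):
            key = _lex_key(Phi[i], Psi[i])
            if key not in archive:
                outside = int((Phi[i] & ~pool_phi).sum() + (Psi[i] & ~pool_psi).sum())
                archive[key] = (float(v[i]), int(c[i]), outside, int(t[i]), int(f[i]),
                                Phi[i].copy(), Psi[i].copy())
        gen_best = float(v.max()) if len(v) else 0.0
        if gen_best > best_score + 1e-12:
            best_score = gen_best
            stagnant = 0
        else:
            stagnant += 1
        if stagnant >= config.stagnation_window:
            if restarts < config.restart_count:
                restarts += 1
                stagnant = 0
                order = np.argsort(-v, kind="stable")
                Phi = Phi[order]
                Psi = Psi[order]
                reinit(config.elite_count)
                continue
            break

        # ---- next generation: elitism + tournament/crossover/mutation
        order = np.argsort(-v, kind="stable")
        elite_idx = order[:config.elite_count]
        l = config.population_size
        n_off = l - config.elite_count
        contestants = rng.integers(0, l, size=(2 * n_off, config.tournament_size))
        winners = contestants[np.arange(2 * n_off), np.argmax(v[contestants], axis=1)]
        pa, pb = winners[:n_off], winners[n_off:]
        cross = rng.random(n_off) < config.crossover_rate
        mask = rng.random((n_off, m)) < config.crossover_p
        child_phi = np.where(mask, Phi[pa], Phi[pb])
        child_psi = np.where(mask, Psi[pa], Psi[pb])
        child_phi[~cross] = Phi[pa][~cross]
        child_psi[~cross] = Psi[pa][~cross]
        # mutation restricted to the KG-linked pool, occasionally the full kind pool
        wide = rng.random(n_off) < config.outside_pool_prob
        phi_pool = np.where(wide[:, None], main_mask[None, :], pool_phi[None, :])
        psi_pool = np.where(wide[:, None], add_mask[None, :], pool_psi[None, :])
        flip_phi = (rng.random((n_off, m)) < mut_rate) & phi_pool
        flip_psi = (rng.random((n_off, m)) < mut_rate) & psi_pool
        child_phi ^= flip_phi
        child_psi ^= flip_psi
        Phi = np.concatenate([Phi[elite_idx], child_phi])
        Psi = np.concatenate([Psi[elite_idx], child_psi])

    ranked = sorted(archive.values(),
                    key=lambda e: (-e[0], e[1], e[2], _lex_key(e[5], e[6])))
    rules = []
    for v_, c_, _out, t_, f_, phi, psi in ranked[:config.top_k]:
        rules.append(KnowledgeRule(syndrome,
                                   tuple(np.flatnonzero(phi).tolist()),
                                   tuple(np.flatnonzero(psi).tolist()),
                                   v_, t_, f_, c_))
    return rules


def exhaustive_best(syndrome: int, matrices: EvaluationMatrices,
                    main_pool, add_pool) -> tuple[float, KnowledgeRule | None]:
    """Brute-force optimum over all non-empty subset pairs of the given pools.

    Only tractable for small pools; serves as the GA's independent oracle.
    """
    best_v, best_rule = 0.0, None
    m = matrices.m
    for r_main in range(1, len(main_pool) + 1):
        for mains in itertools.combinations(main_pool, r_main):
            phi = np.zeros(m, dtype=bool)
            phi[list(mains)] = True
            for r_add in range(1, len(add_pool) + 1):
                for adds in itertools.combinations(add_pool, r_add):
                    psi = np.zeros(m, dtype=bool)
                    psi[list(adds)] = True
                    sol = CandidateSolution(phi, psi)
                    v = score(sol, matrices)
                    if v > best_v:
                        t, f = count_matches(sol, matrices)
                        best_v = v
                        best_rule = KnowledgeRule(syndrome, mains, adds, v, t, f,
                                                  rule_size(sol))
    return best_v, best_rule


def prune_rules(rules, config: GAConfig):
    """Drop rules below the score floor or the support minimum, keeping each
    syndrome's single best rule unless it scores 0."""
    by_syn: dict[int, list[KnowledgeRule]] = {}
    for r in rules:
        by_syn.setdefault(r.syndrome, []).append(r)
    kept: list[KnowledgeRule] = []
    for syn, rs in sorted(by_syn.items()):
        rs = sorted(rs, key=lambda r: (-r.score, r.size))
        chosen = [r for r in rs if r.score >= config.score_floor
                  and r.support >= config.min_support]
        if not chosen and rs and rs[0].score > 0:
            chosen = [rs[0]]
        if not chosen:
            warnings.warn(f"all rules for SYN{syn} pruned (insufficient support)")
        kept.extend(chosen)
    return kept


def extract_rules(kg: KnowledgeGraph, pre_sentences, config: GAConfig) -> list[KnowledgeRule]:
    """Evolve top-k rules for every syndrome against the pre-set."""
    rules: list[KnowledgeRule] = []
    for syn in range(kg.n_syndromes):
        mats = EvaluationMatrices.build(pre_sentences, syn, kg.m)
        cfg = GAConfig(**{**config.__dict__, "seed": (config.seed * 1_000_003 + syn) % (2**31)})
        rules.extend(evolve(syn, mats, cfg, kg))
    return rules


# -------------------------------------------------------------------- rule I/O

def save_rules(rules, path) -> None:
    import json
    data = [{"syndrome": r.syndrome, "main": list(r.main_set), "additional": list(r.add_set),
             "score": r.score, "support": r.support, "violations": r.violations,
             "size": r.size} for r in rules]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(data, fh, indent=1)
        fh.write("\n")


def load_rules(path) -> list[KnowledgeRule]:
    import json
    with open(path, "r", encoding="utf-8") as fh:
        data = json.load(fh)
    return [KnowledgeRule(d["syndrome"], tuple(d["main"]), tuple(d["additional"]),
                          d["score"], d.get("support", 0), d.get("violations", 0),
                          d.get("size", len(d["main"]) + len(d["additional"])))
            for d in data]
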