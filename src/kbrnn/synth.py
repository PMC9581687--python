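"""Synthetic knowledge graphs and labeled record corpora with planted rules.

Each syndrome receives a generating rule — a non-empty main and additional
symptom set — and sentences sample subsets of their syndrome's rule, main
part first.  Configurable corruptions emulate real-data blemishes: distractor
symptoms outside the rule, label flips, and knowledge-graph link noise
(missing/extra edges relative to the generating rules).  Two separability
guarantees make noiseless corpora cleanly decodable: planted rules are
pairwise non-subsumed (no rule's two sets are componentwise subsets of
another's), and every emitted sentence is checked against all other planted
rules, resampling (or falling back to the full-rule sentence, which
non-subsumption makes safe) if another rule would cover it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .corpus import EMRRecord
from .kg import KIND_ADD, KIND_MAIN, KIND_SYN, Entity, KnowledgeGraph, RelationTriple
from .rules import KnowledgeRule


@dataclass
class GeneratorConfig:
    n_syndromes: int = 15
    n_main_symptoms: int = 60
    n_add_symptoms: int = 40
    main_rule_size: tuple[int, int] = (3, 6)
    add_rule_size: tuple[int, int] = (2, 4)
    sentences_per_syndrome: int = 40
    sent_main_range: tuple[int, int] = (2, 5)   # short clinical listings
    sent_add_range: tuple[int, int] = (1, 4)
    distractor_prob: float = 0.0
    label_noise: float = 0.0
    link_noise: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for p in (self.distractor_prob, self.label_noise, self.link_noise):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for c in (self.n_syndromes, self.n_main_symptoms, self.n_add_symptoms,
                  self.sentences_per_syndrome):
            if c <= 0:
                raise ValueError("counts must be positive")
        if self.main_rule_size[1] > self.n_main_symptoms or self.add_rule_size[1] > self.n_add_symptoms:
            raise ValueError("rule size range exceeds the symptom pool")


def _subsumed(a: KnowledgeRule, b: KnowledgeRule) -> bool:
    return set(a.main_set) <= set(b.main_set) and set(a.add_set) <= set(b.add_set)


def generate_kg(config: GeneratorConfig) -> tuple[KnowledgeGraph, list[KnowledgeRule]]:
    """Sample planted rules and the (optionally noised) knowledge graph.

    Main symptoms take unified ids ``0 .. n_main-1``, additional symptoms the
    following ids.  Returns the graph and the ground-truth rules.
    """
    rng = np.random.default_rng(config.seed)
    n_main, n_add = config.n_main_symptoms, config.n_add_symptoms
    mains = list(range(n_main))
    adds = list(range(n_main, n_main + n_add))

    rules: list[KnowledgeRule] = []
    for syn in range(config.n_syndromes):
        for attempt in range(200):
            k_m = int(rng.integers(config.main_rule_size[0], config.main_rule_size[1] + 1))
            k_a = int(rng.integers(config.add_rule_size[0], config.add_rule_size[1] + 1))
            cand = KnowledgeRule(syn,
                                 tuple(sorted(rng.choice(mains, size=k_m, replace=False).tolist())),
                                 tuple(sorted(rng.choice(adds, size=k_a, replace=False).tolist())),
                                 0.0, 0, 0, k_m + k_a)
            if not any(_subsumed(cand, r) or _subsumed(r, cand) for r in rules):
                rules.append(cand)
                break
        else:
            raise RuntimeError(f"could not plant a non-subsumed rule for SYN{syn}")

    # repair pass: every rule must keep at least one boundary pair no other
    # rule could match, so noiseless sentences stay separable end to end
    for _round in range(50):
        broken = next((i for i, r in enumerate(rules) if not _safe_pairs(r, rules)), None)
        if broken is None:
            break
        for attempt in range(200):
            r_old = rules[broken]
            k_m = int(rng.integers(config.main_rule_size[0], config.main_rule_size[1] + 1))
            k_a = int(rng.integers(config.add_rule_size[0], config.add_rule_size[1] + 1))
            cand = KnowledgeRule(r_old.syndrome,
                                 tuple(sorted(rng.choice(mains, size=k_m, replace=False).tolist())),
                                 tuple(sorted(rng.choice(adds, size=k_a, replace=False).tolist())),
                                 0.0, 0, 0, k_m + k_a)
            others = [r for r in rules if r.syndrome != r_old.syndrome]
            if (not any(_subsumed(cand, r) or _subsumed(r, cand) for r in others)
                    and _safe_pairs(cand, others + [cand])):
                rules[broken] = cand
                break
        else:
            raise RuntimeError("could not repair planted rules to be pairwise separable")
    else:
        raise RuntimeError("planted rule separability repair did not converge")

    triples: list[RelationTriple] = []
    for r in rules:
        kept_main = [s for s in r.main_set if rng.random() >= config.link_noise]
        kept_add = [s for s in r.add_set if rng.random() >= config.link_noise]
        if not kept_main:
            kept_main = [r.main_set[0]]
        if not kept_add:
            kept_add = [r.add_set[0]]
        for s in kept_main:
            triples.append(RelationTriple(r.syndrome, s, KIND_MAIN, "has_main_symptom"))
        for s in kept_add:
            triples.append(RelationTriple(r.syndrome, s, KIND_ADD, "has_additional_symptom"))
        n_extra = int(rng.binomial(2, config.link_noise))
        for _ in range(n_extra):
            if rng.random() < 0.5:
                pool = [s for s in mains if s not in r.main_set]
                kind, label = KIND_MAIN, "has_main_symptom"
            else:
                pool = [s for s in adds if s not in r.add_set]
                kind, label = KIND_ADD, "has_additional_symptom"
            if pool:
                triples.append(RelationTriple(r.syndrome, int(rng.choice(pool)), kind, label))

    kg = KnowledgeGraph(
        main_symptoms=[Entity(i, KIND_MAIN, f"SYM{i}", (f"SYM{i}",)) for i in mains],
        additional_symptoms=[Entity(i, KIND_ADD, f"SYM{i}", (f"SYM{i}",)) for i in adds],
        syndromes=[Entity(s, KIND_SYN, f"SYN{s}", (f"SYN{s}",))
                   for s in range(config.n_syndromes)],
        triples=triples,
    )
    return kg, rules


def _covered_by_other(main_part, add_part, syn: int, rules) -> bool:
    """True when another planted rule would recognize this sentence.

    Guards both recognition semantics: strict coverage (both parts subsets of
    the foreign rule, the extraction-time notion) and the wildcard-automaton
    notion, which only needs the boundary pair — the last main token adjacent
    to the first additional token — inside the foreign rule's two sets.
    """
    ms, as_ = set(main_part), set(add_part)
    pair = (main_part[-1], add_part[0]) if main_part and add_part else None
    for r in rules:
        if r.syndrome == syn:
            continue
        if ms <= set(r.main_set) and as_ <= set(r.add_set):
            return True
        if pair and pair[0] in r.main_set and pair[1] in r.add_set:
            return True
    return False


def _safe_pairs(rule: KnowledgeRule, rules, mains=None, adds=None):
    """(m, a) boundary pairs of the rule no foreign rule would match."""
    mains = rule.main_set if mains is None else mains
    adds = rule.add_set if adds is None else adds
    return [(m, a) for m in mains for a in adds
            if not any(r.syndrome != rule.syndrome
                       and m in r.main_set and a in r.add_set for r in rules)]


def generate_corpus(config: GeneratorConfig, planted: list[KnowledgeRule]) -> list[EMRRecord]:
    """Emit ``sentences_per_syndrome`` records per syndrome.

    Each record samples >=1 main and >=1 additional symptom from its rule
    (sizes from the configured ranges, clipped to the rule), shuffled within
    each part.  Distractors add one out-of-rule symptom with the configured
    probability; label noise replaces the observed label with a uniformly
    random other syndrome while the truth field keeps the generating label.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_syn = len(planted)
    records: list[EMRRecord] = []
    for r in planted:
        for _ in range(config.sentences_per_syndrome):
            lo_m = min(config.sent_main_range[0], len(r.main_set))
            hi_m = max(lo_m, min(config.sent_main_range[1], len(r.main_set)))
            lo_a = min(config.sent_add_range[0], len(r.add_set))
            hi_a = max(lo_a, min(config.sent_add_range[1], len(r.add_set)))
            for attempt in range(50):
                k_m = int(rng.integers(lo_m, hi_m + 1))
                k_a = int(rng.integers(lo_a, hi_a + 1))
                main = rng.choice(r.main_set, size=k_m, replace=False).tolist()
                add = rng.choice(r.add_set, size=k_a, replace=False).tolist()
                pairs = _safe_pairs(r, planted, main, add)
                if pairs:
                    break
            else:
                # fall back to the full rule; the planting repair pass
                # guarantees it still owns a safe boundary pair
                main, add = list(r.main_set), list(r.add_set)
                pairs = _safe_pairs(r, planted, main, add)
            # a safe pair at the part boundary keeps the sentence unambiguous
            m_b, a_b = pairs[int(rng.integers(0, len(pairs)))]
            main.remove(m_b)
            add.remove(a_b)
            rng.shuffle(main)
            rng.shuffle(add)
            main.append(m_b)
            add.insert(0, a_b)
            if rng.random() < config.distractor_prob:
                if rng.random() < 0.5:
                    pool = [s for s in range(config.n_main_symptoms) if s not in r.main_set]
                    if pool:
                        main.insert(int(rng.integers(0, len(main) + 1)), int(rng.choice(pool)))
                else:
                    lo = config.n_main_symptoms
                    pool = [s for s in range(lo, lo + config.n_add_symptoms)
                            if s not in r.add_set]
                    if pool:
                        add.insert(int(rng.integers(0, len(add) + 1)), int(rng.choice(pool)))
            label = r.syndrome
            if rng.random() < config.label_noise and n_syn > 1:
                others = [s for s in range(n_syn) if s != r.syndrome]
                label = int(rng.choice(others))
            records.append(EMRRecord([f"SYM{s}" for s in main], [f"SYM{s}" for s in add],
                                     label, truth=r.syndrome))
    return records


def generate_dataset(config: GeneratorConfig):
    """Convenience wrapper: (kg, planted rules, records)."""
    kg, planted = generate_kg(config)
    return kg, planted, generate_corpus(config, planted)
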