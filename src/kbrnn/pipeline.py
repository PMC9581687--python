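"""End-to-end pipeline: split -> extract -> prune -> compile -> decompose ->
(optional) fine-tune -> evaluate, with seeded, reproducible stage wiring.

One global seed fans out to per-stage seeds through a fixed stage-name hash,
so any stage can be re-run in isolation with the same randomness.  The report
is a plain dict (JSON-serializable) holding per-syndrome rule scores, the
automaton sizes K/V, the CPD rank and reconstruction error, and untrained /
trained accuracies with the test confusion matrix.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

from .automata import compile_rules
from .corpus import SplitSpec, Vocabulary, pad_corpus, record_to_sentence, split_corpus
from .kg import KnowledgeGraph
from .model import (KBRNNParameters, TrainingConfig, evaluate, fine_tune,
                    tie_order_from_sentences)
from .rules import GAConfig, extract_rules, prune_rules

log = logging.getLogger("kbrnn")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (global_seed * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


@dataclass
class PipelineConfig:
    split: SplitSpec = field(default_factory=SplitSpec)
    ga: GAConfig = field(default_factory=GAConfig)
    wildcard: bool = True
    r: int | None = None
    beta: float = 1.0
    training: TrainingConfig = field(default_factory=TrainingConfig)
    fine_tune: bool = False
    seed: int = 0
    log_level: str = "INFO"


def run_pipeline(kg: KnowledgeGraph, records, config: PipelineConfig,
                 return_params: bool = False):
    """Execute the full construction pipeline and return the report
    (and the final model parameters when ``return_params`` is set)."""
    logging.basicConfig(level=config.log_level)
    log.info("pipeline config: %s", config)

    sentences = [record_to_sentence(r, kg) for r in records]
    split = SplitSpec(**{**config.split.__dict__, "seed": stage_seed(config.seed, "split")})
    pre, train, dev, test = split_corpus(sentences, split)
    log.info("split sizes pre/train/dev/test = %d/%d/%d/%d",
             len(pre), len(train), len(dev), len(test))

    ga = GAConfig(**{**config.ga.__dict__, "seed": stage_seed(config.seed, "extract")})
    rules = extract_rules(kg, pre, ga)
    rules = prune_rules(rules, ga)
    log.info("extracted %d rules after pruning", len(rules))

    vocab = Vocabulary.from_kg(kg)
    padded_all, _ = pad_corpus(sentences, vocab=vocab)
    L = padded_all[0].L if padded_all else 2
    pad = lambda part: pad_corpus(part, L=L, vocab=vocab)[0]
    p_train, p_dev, p_test = pad(train), pad(dev), pad(test)

    ta = compile_rules(rules, vocab, kg.n_syndromes, wildcard=config.wildcard)
    log.info("merged automaton: K=%d states over V=%d tokens", ta.K, ta.V)

    from .model import EmbeddingBlend
    params = KBRNNParameters.from_automaton(
        ta, vocab, r=config.r, seed=stage_seed(config.seed, "cpd"),
        blend=EmbeddingBlend(beta=config.beta),
        tie_order=tie_order_from_sentences(pre, kg.n_syndromes))
    log.info("CPD rank r=%d, max reconstruction error %.3g",
             params.factors.r, params.factors.reconstruction_error)

    acc0, cm0 = evaluate(params, p_test)
    report = {
        "splits": {"pre": len(pre), "train": len(train), "dev": len(dev), "test": len(test)},
        "rules": [{"syndrome": r.syndrome, "main": list(r.main_set),
                   "additional": list(r.add_set), "score": r.score,
                   "support": r.support, "size": r.size} for r in rules],
        "automaton": {"K": ta.K, "V": ta.V},
        "cpd": {"r": params.factors.r,
                "max_error": params.factors.reconstruction_error},
        "accuracy_untrained": acc0,
        "accuracy_trained": None,
        "confusion": cm0.tolist(),
    }
    final_params = params
    if config.fine_tune:
        tc = TrainingConfig(**{**config.training.__dict__,
                               "seed": stage_seed(config.seed, "train")})
        trained, history = fine_tune(params, p_train, p_dev, tc)
        acc1, cm1 = evaluate(trained, p_test)
        report["accuracy_trained"] = acc1
        report["confusion"] = cm1.tolist()
        report["history"] = history
        report["dev_accuracy_untrained"] = history[0]["dev_accuracy"]
        report["dev_accuracy_trained"] = max(h["dev_accuracy"] for h in history)
        final_params = trained
    if return_params:
        return report, final_params
    return report
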