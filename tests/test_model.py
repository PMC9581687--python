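import numpy as np
import pytest

from kbrnn.automata import compile_rules, match_count_per_syndrome
from kbrnn.corpus import PaddedSentence, Vocabulary, pad_corpus, record_to_sentence
from kbrnn.model import (CPDFactors, EmbeddingBlend, KBRNNParameters, TrainingConfig,
                         blend_embeddings, cp_rank_bound, cpd_decompose, cross_entropy,
                         evaluate, fine_tune, forward, load_checkpoint, predict,
                         save_checkpoint, tie_order_from_sentences)
from kbrnn.rules import KnowledgeRule
from kbrnn.synth import GeneratorConfig, generate_corpus, generate_dataset, generate_kg

VOCAB8 = Vocabulary(("BOS", "EOS", "PAD", "UNK", "SYM0", "SYM1", "SYM2", "SYM3"))
RULES8 = [KnowledgeRule(0, (0, 1), (2,), 1, 1, 0, 3),
          KnowledgeRule(1, (1,), (3,), 1, 1, 0, 2)]


class TestCPD:
    def test_rank_one_tensor_exact_at_r1(self):
        T = np.einsum("v,i,j->vij", np.array([1., 0, 1]), np.array([0., 1]), np.array([1., 1]))
        f = cpd_decompose(T, r=1, seed=0)
        assert f.reconstruction_error <= 1e-6

    def test_toy_automaton_exact_at_rank_bound(self):
        ta = compile_rules(RULES8, VOCAB8, 2)
        f = cpd_decompose(ta.T, r=cp_rank_bound(ta.T), seed=1)
        assert f.reconstruction_error <= 1e-6
        That = np.einsum("vr,ir,jr->vij", f.E_R, f.D1, f.D2)
        assert np.abs(That - ta.T).max() <= 1e-6

    def test_rank_deficient_fit_has_error(self):
        # two independent arcs cannot be captured by a single component
        T = np.zeros((2, 2, 2))
        T[0, 0, 0] = 1
        T[1, 1, 1] = 1
        f = cpd_decompose(T, r=1, seed=0)
        assert f.reconstruction_error > 1e-3

    def test_invalid_rank_rejected(self):
        with pytest.raises(ValueError):
            cpd_decompose(np.zeros((2, 2, 2)), r=0)

    def test_deterministic_given_seed(self):
        T = np.zeros((3, 3, 3))
        T[0, 0, 1] = T[1, 1, 2] = T[2, 2, 0] = 1
        a = cpd_decompose(T, r=2, seed=5)
        b = cpd_decompose(T, r=2, seed=5)
        assert np.array_equal(a.E_R, b.E_R) and np.array_equal(a.D1, b.D1)


class TestBlend:
    def _factors(self):
        rng = np.random.default_rng(0)
        return CPDFactors(rng.standard_normal((6, 4)), np.zeros((3, 4)), np.zeros((3, 4)), 4)

    def test_beta_one_returns_factor_rows(self):
        f = self._factors()
        assert blend_embeddings(f, EmbeddingBlend(beta=1.0)) is f.E_R

    def test_beta_zero_projects_external_table(self):
        f = self._factors()
        U = np.eye(6, 5)
        G = np.random.default_rng(1).standard_normal((5, 4))
        out = blend_embeddings(f, EmbeddingBlend(0.0, U, G))
        assert np.allclose(out, U @ G)

    def test_half_blend_with_zero_table(self):
        f = self._factors()
        out = blend_embeddings(f, EmbeddingBlend(0.5, np.zeros((6, 5)), np.zeros((5, 4))))
        assert np.allclose(out, 0.5 * f.E_R)

    def test_missing_table_rejected(self):
        with pytest.raises(ValueError):
            blend_embeddings(self._factors(), EmbeddingBlend(beta=0.5))


def exact_params(rules=RULES8, vocab=VOCAB8, n_syn=2):
    ta = compile_rules(rules, vocab, n_syn)
    return ta, KBRNNParameters.from_automaton(ta, vocab)


def padded(vocab, symptoms, n_pad=1, label=0):
    toks = ("BOS", *symptoms, "EOS") + ("PAD",) * n_pad
    return PaddedSentence(toks, tuple(vocab.encode(t) for t in toks), label)


class TestForward:
    def test_outputs_equal_match_counts_with_exact_factors(self, rng):
        ta, params = exact_params()
        symptoms = ["SYM0", "SYM1", "SYM2", "SYM3"]
        for _ in range(200):
            core = [symptoms[int(rng.integers(0, 4))] for _ in range(int(rng.integers(0, 5)))]
            p = padded(VOCAB8, core, n_pad=int(rng.integers(0, 3)))
            H, out = forward(params, p)
            assert np.abs(out - match_count_per_syndrome(ta, p)).max() <= 1e-6
            assert H.shape == (p.L + 1, ta.K)
            assert np.array_equal(H[0], params.S)

    def test_empty_symptom_sentence_outputs_zero(self):
        _, params = exact_params()
        _, out = forward(params, padded(VOCAB8, [], n_pad=2))
        assert np.abs(out).max() <= 1e-6

    def test_pad_invariance(self):
        _, params = exact_params()
        outs = [forward(params, padded(VOCAB8, ["SYM1", "SYM3"], n_pad=k))[1]
                for k in range(4)]
        for o in outs[1:]:
            assert np.allclose(o, outs[0], atol=1e-9)


class TestPredict:
    def test_argmax(self):
        _, params = exact_params()
        assert predict(params, padded(VOCAB8, ["SYM1", "SYM3"])) == 1
        assert predict(params, padded(VOCAB8, ["SYM0", "SYM1", "SYM2"])) == 0

    def test_all_zero_tie_goes_to_preferred_syndrome(self):
        _, params = exact_params()
        params.tie_order = (1, 0)
        assert predict(params, padded(VOCAB8, [])) == 1
        params.tie_order = (0, 1)
        assert predict(params, padded(VOCAB8, [])) == 0

    def test_tie_order_from_sentence_frequencies(self):
        from kbrnn.corpus import EMRSentence
        sents = [EMRSentence((0,), 1, 1)] * 3 + [EMRSentence((0,), 1, 0)]
        assert tie_order_from_sentences(sents, 3) == (1, 0, 2)


def small_noisy_setup(seed, label_noise=0.1, distractors=0.2):
    cfg = GeneratorConfig(n_syndromes=4, n_main_symptoms=16, n_add_symptoms=12,
                          sentences_per_syndrome=25, label_noise=label_noise,
                          distractor_prob=distractors, seed=seed)
    kg, planted = generate_kg(cfg)
    records = generate_corpus(cfg, planted)
    sentences = [record_to_sentence(r, kg) for r in records]
    vocab = Vocabulary.from_kg(kg)
    corpus_padded, _ = pad_corpus(sentences, vocab=vocab)
    order = np.random.default_rng(seed).permutation(len(corpus_padded))
    corpus_padded = [corpus_padded[i] for i in order]
    ta = compile_rules(planted, vocab, cfg.n_syndromes)
    params = KBRNNParameters.from_automaton(ta, vocab)
    n = len(corpus_padded)
    return params, corpus_padded[: int(0.7 * n)], corpus_padded[int(0.7 * n):]


class TestFineTune:
    def test_zero_epochs_is_identity(self):
        params, train, dev = small_noisy_setup(0)
        trained, history = fine_tune(params, train, dev, TrainingConfig(epochs=0))
        assert len(history) == 1
        assert np.array_equal(trained.factors.E_R, params.factors.E_R)
        assert np.array_equal(trained.factors.D1, params.factors.D1)
        a0, _ = evaluate(params, dev)
        a1, _ = evaluate(trained, dev)
        assert a0 == a1

    def test_first_batch_loss_matches_independent_cross_entropy(self):
        ta, params = exact_params()
        train = [padded(VOCAB8, ["SYM0", "SYM1", "SYM2"], n_pad=1, label=0),
                 padded(VOCAB8, ["SYM1", "SYM3"], n_pad=2, label=1),
                 padded(VOCAB8, ["SYM1", "SYM2"], n_pad=2, label=0)]
        _, history = fine_tune(params, train, train,
                               TrainingConfig(epochs=1, batch_size=16, learning_rate=0.0))
        # oracle: logits from the automaton product, cross-entropy by hand
        logits = np.array([match_count_per_syndrome(ta, p) for p in train], dtype=float)
        z = logits - logits.max(axis=1, keepdims=True)
        logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
        expected = -np.mean([logp[i, p.label] for i, p in enumerate(train)])
        assert history[1]["train_loss"] == pytest.approx(expected, abs=1e-9)

    def test_training_improves_noisy_dev_accuracy_on_average(self):
        accs = []
        for seed in (0, 1, 2):
            params, train, dev = small_noisy_setup(seed)
            trained, history = fine_tune(
                params, train, dev,
                TrainingConfig(epochs=10, learning_rate=0.005, seed=seed))
            accs.append((history[0]["dev_accuracy"],
                         max(h["dev_accuracy"] for h in history)))
        untrained = np.mean([a for a, _ in accs])
        trained_acc = np.mean([b for _, b in accs])
        assert trained_acc >= untrained

    def test_loss_trend_not_increasing_on_toy_fixture(self):
        params, train, dev = small_noisy_setup(3, label_noise=0.0, distractors=0.1)
        _, history = fine_tune(params, train, dev,
                               TrainingConfig(epochs=6, learning_rate=0.001, seed=0))
        losses = [h["train_loss"] for h in history[1:]]
        assert losses[-1] <= losses[0] + 1e-6

    def test_empty_training_corpus_rejected(self):
        params, _, dev = small_noisy_setup(0)
        with pytest.raises(ValueError):
            fine_tune(params, [], dev, TrainingConfig())

    def test_reproducible_given_seed(self):
        outs = []
        for _ in range(2):
            params, train, dev = small_noisy_setup(1)
            trained, history = fine_tune(params, train, dev,
                                         TrainingConfig(epochs=3, seed=9))
            outs.append((trained.factors.E_R.copy(), [h["dev_accuracy"] for h in history]))
        assert np.array_equal(outs[0][0], outs[1][0])
        assert outs[0][1] == outs[1][1]


class TestRecoveryFromCorruptedRules:
    def test_fine_tuning_recovers_dropped_symptoms(self):
        """With one main symptom dropped from each injected rule, training on
        labeled sentences should recover close to the correct-rule accuracy."""
        results = []
        for seed in (0, 1, 2):
            cfg = GeneratorConfig(n_syndromes=4, n_main_symptoms=16, n_add_symptoms=12,
                                  sentences_per_syndrome=25, seed=seed)
            kg, planted = generate_kg(cfg)
            records = generate_corpus(cfg, planted)
            sentences = [record_to_sentence(r, kg) for r in records]
            vocab = Vocabulary.from_kg(kg)
            corpus_padded, _ = pad_corpus(sentences, vocab=vocab)
            order = np.random.default_rng(seed).permutation(len(corpus_padded))
            corpus_padded = [corpus_padded[i] for i in order]
            n = len(corpus_padded)
            train, test = corpus_padded[: int(0.7 * n)], corpus_padded[int(0.7 * n):]

            correct = KBRNNParameters.from_automaton(compile_rules(planted, vocab, 4), vocab)
            acc_correct, _ = evaluate(correct, test)

            corrupted_rules = [KnowledgeRule(r.syndrome, r.main_set[1:], r.add_set,
                                             r.score, r.support, r.violations, r.size - 1)
                               for r in planted]
            corrupted = KBRNNParameters.from_automaton(
                compile_rules(corrupted_rules, vocab, 4), vocab)
            trained, _ = fine_tune(corrupted, train, test,
                                   TrainingConfig(epochs=30, learning_rate=0.01, seed=seed))
            acc_trained, _ = evaluate(trained, test)
            results.append((acc_correct, acc_trained))
        mean_correct = np.mean([a for a, _ in results])
        mean_trained = np.mean([b for _, b in results])
        assert mean_correct >= 0.95
        assert mean_trained >= mean_correct - 0.05


class TestEvaluate:
    def test_perfect_corpus_diagonal_confusion(self):
        _, params = exact_params()
        corpus = [padded(VOCAB8, ["SYM0", "SYM2"], label=0),
                  padded(VOCAB8, ["SYM1", "SYM3"], label=1)]
        acc, cm = evaluate(params, corpus)
        assert acc == 1.0
        assert np.array_equal(cm, np.eye(2, dtype=int))

    def test_single_misclassification_off_diagonal(self):
        _, params = exact_params()
        corpus = [padded(VOCAB8, ["SYM1", "SYM3"], label=0)]  # truly matches SYN1
        acc, cm = evaluate(params, corpus)
        assert acc == 0.0
        assert cm[0, 1] == 1

    def test_accuracy_equals_confusion_diagonal_fraction(self, rng):
        _, params = exact_params()
        symptoms = ["SYM0", "SYM1", "SYM2", "SYM3"]
        corpus = [padded(VOCAB8, [symptoms[int(rng.integers(0, 4))] for _ in range(3)],
                         label=int(rng.integers(0, 2))) for _ in range(40)]
        acc, cm = evaluate(params, corpus)
        assert acc == pytest.approx(np.trace(cm) / cm.sum())

    def test_empty_corpus_rejected(self):
        _, params = exact_params()
        with pytest.raises(ValueError):
            evaluate(params, [])


class TestCheckpointAndPadding:
    def test_checkpoint_round_trip_preserves_predictions(self, tmp_path):
        _, params = exact_params()
        path = tmp_path / "ckpt.json"
        save_checkpoint(params, path, history=[{"epoch": 0}])
        loaded, history = load_checkpoint(path)
        assert history == [{"epoch": 0}]
        p = padded(VOCAB8, ["SYM1", "SYM3"])
        assert predict(loaded, p) == predict(params, p)
        assert np.allclose(forward(loaded, p)[1], forward(params, p)[1])

    def test_inert_state_padding_preserves_outputs(self):
        _, params = exact_params()
        wide = params.pad_states(params.K + 7)
        assert wide.K == params.K + 7
        p = padded(VOCAB8, ["SYM0", "SYM1", "SYM2"])
        assert np.allclose(forward(wide, p)[1], forward(params, p)[1])
        with pytest.raises(ValueError):
            params.pad_states(params.K - 1)
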