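"""Tensor decomposition of the merged automaton and the injected recurrent net.

The transfer tensor T (V x K x K) is CP-decomposed into a per-token factor
E_R (V x r), and state factors D1, D2 (K x r), so that automaton simulation
becomes the recurrence

    h_0 = S,    h_t = ((h_{t-1} . D1) o w_t) . D2^T,    out = h_x . F_syn

where ``o`` is the element-wise product and w_t the effective embedding of the
t-th token: the convex blend ``w = beta * v + (1 - beta) * u G`` of the CPD
token factor v with a projected external embedding u (beta = 1 uses the factor
alone and needs no external table).  With exact factors the outputs equal the
per-syndrome automaton match counts, so the untrained network already encodes
the extracted rules; fine-tuning then treats the outputs as logits and
minimizes cross-entropy with plain SGD (gradients derived by hand through the
recurrence — the factor matrices, and the projection G when beta < 1, train;
S is frozen and F_syn relaxes to real values only behind a flag).
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import confusion_matrix as _sk_confusion

from .automata import TensorAutomaton
from .corpus import PaddedSentence, Vocabulary


# ------------------------------------------------------------------------ CPD

@dataclass
class CPDFactors:
    E_R: np.ndarray   # (V, r) per-token factor ("word embedding of each input word")
    D1: np.ndarray    # (K, r)
    D2: np.ndarray    # (K, r)
    r: int
    reconstruction_error: float = 0.0


def cp_rank_bound(T: np.ndarray) -> int:
    """Number of distinct (i, j) state arcs carrying any token.

    An exact CP decomposition with this many components always exists: one
    component per arc, with the token indicator as its E_R column — so it
    upper-bounds the CP rank of T.
    """
    return int(T.any(axis=0).sum())


def _arc_init(T: np.ndarray, r: int):
    V, K, _ = T.shape
    arcs = np.argwhere(T.any(axis=0))
    E_R = np.zeros((V, r))
    D1 = np.zeros((K, r))
    D2 = np.zeros((K, r))
    for rho, (i, j) in enumerate(arcs[:r]):
        E_R[:, rho] = T[:, i, j]
        D1[i, rho] = 1.0
        D2[j, rho] = 1.0
    return E_R, D1, D2


def _reconstruction_error(T: np.ndarray, E_R, D1, D2) -> float:
    err = 0.0
    for sig in range(T.shape[0]):
        That = (D1 * E_R[sig]) @ D2.T
        err = max(err, float(np.abs(T[sig] - That).max()))
    return err


def cpd_decompose(T: np.ndarray, r: int, seed: int = 0, n_iter: int = 60,
                  tol: float = 1e-9) -> CPDFactors:
    """Canonical polyadic decomposition of the transfer tensor.

    When r reaches the arc rank bound the factors are built exactly (one
    component per transition arc) and the error is zero by construction;
    below the bound, alternating least squares runs from a seeded random
    initialization.  Deterministic for a fixed seed; the max-abs
    reconstruction error is recorded on the result.
    """
    if r <= 0:
        raise ValueError(f"CPD rank must be positive, got {r}")
    T = np.asarray(T, dtype=float)
    V, K, K2 = T.shape
    if K != K2:
        raise ValueError("transfer tensor must be V x K x K")
    if r >= cp_rank_bound(T):
        E_R, D1, D2 = _arc_init(T, r)
        return CPDFactors(E_R, D1, D2, r, _reconstruction_error(T, E_R, D1, D2))

    rng = np.random.default_rng(seed)
    scale = 1.0 / np.sqrt(r)
    E_R = rng.standard_normal((V, r)) * scale
    D1 = rng.standard_normal((K, r)) * scale
    D2 = rng.standard_normal((K, r)) * scale
    T0 = T.reshape(V, K * K)                       # index i*K + j
    T1 = T.transpose(1, 0, 2).reshape(K, V * K)    # index sig*K + j
    T2 = T.transpose(2, 0, 1).reshape(K, V * K)    # index sig*K + i

    def kr(A, B):  # Khatri-Rao with row index a*len(B) + b
        return (A[:, None, :] * B[None, :, :]).reshape(-1, A.shape[1])

    def solve(unfold, Z):
        G = Z.T @ Z
        return unfold @ Z @ np.linalg.pinv(G)

    prev = np.inf
    for _ in range(n_iter):
        E_R = solve(T0, kr(D1, D2))
        D1 = solve(T1, kr(E_R, D2))
        D2 = solve(T2, kr(E_R, D1))
        err = _reconstruction_error(T, E_R, D1, D2)
        if err <= tol or prev - err <= 1e-12:
            break
        prev = err
    return CPDFactors(E_R, D1, D2, r, _reconstruction_error(T, E_R, D1, D2))


# -------------------------------------------------------------- embedding blend

@dataclass
class EmbeddingBlend:
    """Convex combination of the CPD token factor with a projected external
    table; beta = 1 reduces to the factor alone."""

    beta: float = 1.0
    U: np.ndarray | None = None   # (V, D) external per-token embeddings
    G: np.ndarray | None = None   # (D, r) trainable projection

    def __post_init__(self):
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")


def load_embedding_table(path, vocab) -> np.ndarray:
    """Read a per-token embedding table from JSON ({token: [floats], ...}).

    Returns a V x D matrix aligned with the vocabulary; tokens absent from the
    file get zero vectors.  Any provider producing such a file is accepted.
    """
    with open(path, "r", encoding="utf-8") as fh:
        table = json.load(fh)
    dims = {len(v) for v in table.values()}
    if len(dims) != 1:
        raise ValueError("embedding table rows have inconsistent dimensions")
    D = dims.pop()
    U = np.zeros((vocab.V, D))
    for tok, vec in table.items():
        if tok in vocab.index:
            U[vocab.index[tok]] = vec
    return U


def blend_embeddings(factors: CPDFactors, blend: EmbeddingBlend) -> np.ndarray:
    """Effective token embeddings ``w = beta * E_R + (1 - beta) * U G``."""
    if blend.beta == 1.0:
        return factors.E_R
    if blend.U is None or blend.G is None:
        raise ValueError("beta < 1 requires an external embedding table U and projection G")
    if blend.U.shape[0] != factors.E_R.shape[0] or blend.G.shape != (blend.U.shape[1], factors.r):
        raise ValueError("embedding table / projection shapes inconsistent with the factors")
    return blend.beta * factors.E_R + (1.0 - blend.beta) * (blend.U @ blend.G)


# ----------------------------------------------------------------- parameters

@dataclass
class KBRNNParameters:
    factors: CPDFactors
    blend: EmbeddingBlend
    S: np.ndarray                 # (K,) start vector, frozen by default
    F_syn: np.ndarray             # (K, C) readout grouping
    vocab: Vocabulary
    tie_order: tuple[int, ...] = ()   # syndrome preference for argmax ties
    train_S: bool = False
    train_F: bool = False

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=float)
        self.F_syn = np.asarray(self.F_syn, dtype=float)
        if not self.tie_order:
            self.tie_order = tuple(range(self.F_syn.shape[1]))

    @property
    def K(self) -> int:
        return self.S.shape[0]

    @property
    def C(self) -> int:
        return self.F_syn.shape[1]

    def copy(self) -> "KBRNNParameters":
        return copy.deepcopy(self)

    @classmethod
    def from_automaton(cls, ta: TensorAutomaton, vocab: Vocabulary, r: int | None = None,
                       seed: int = 0, blend: EmbeddingBlend | None = None,
                       tie_order: tuple[int, ...] = ()) -> "KBRNNParameters":
        """CP-decompose a compiled automaton into network parameters.

        Default rank: the arc rank bound clamped to 4K (an exact decomposition
        of that rank exists, so larger r would only cost space).
        """
        if r is None:
            r = min(cp_rank_bound(ta.T), 4 * ta.K)
        factors = cpd_decompose(ta.T, r, seed=seed)
        return cls(factors, blend or EmbeddingBlend(), ta.S.astype(float),
                   ta.F_syn.astype(float), vocab, tie_order)

    def pad_states(self, k_target: int) -> "KBRNNParameters":
        """Pad the state dimension with inert states up to ``k_target``
        (honors an external hidden-size budget without changing behavior)."""
        if k_target < self.K:
            raise ValueError(f"target {k_target} below structural state count {self.K}")
        extra = k_target - self.K
        out = self.copy()
        out.factors.D1 = np.vstack([out.factors.D1, np.zeros((extra, self.factors.r))])
        out.factors.D2 = np.vstack([out.factors.D2, np.zeros((extra, self.factors.r))])
        out.S = np.concatenate([out.S, np.zeros(extra)])
        out.F_syn = np.vstack([out.F_syn, np.zeros((extra, self.C))])
        return out


@dataclass
class TrainingConfig:
    learning_rate: float = 0.001
    epochs: int = 30
    batch_size: int = 32
    seed: int = 0
    optimizer: str = "sgd"
    grad_clip: float = 5.0  # global gradient-norm ceiling; keeps the recurrence stable
    lr_grid: tuple[float, ...] = (0.01, 0.005, 0.001, 0.0005, 0.0001)
    hidden_grid: tuple[int, ...] = (50, 100, 150, 200)


# -------------------------------------------------------------------- forward

def _ids_matrix(params: KBRNNParameters, sentences) -> np.ndarray:
    return np.array([s.ids for s in sentences], dtype=np.int64)


def _forward_batch(W, D1, D2, S, F_syn, ids):
    B, L = ids.shape
    h = np.repeat(S[None, :], B, axis=0)
    H = [h]
    cache = []
    for t in range(L):
        p = h @ D1
        wt = W[ids[:, t]]
        a = p * wt
        h = a @ D2.T
        cache.append((p, wt, a))
        H.append(h)
    logits = h @ F_syn
    return H, cache, logits


def forward(params: KBRNNParameters, padded: PaddedSentence):
    """Run the recurrence on one padded sentence.

    Returns the hidden trajectory ``h_0 .. h_x`` (stacked, shape (x+1, K)) and
    the per-syndrome output vector ``h_x . F_syn``.
    """
    W = blend_embeddings(params.factors, params.blend)
    ids = np.array([padded.ids], dtype=np.int64)
    H, _, logits = _forward_batch(W, params.factors.D1, params.factors.D2,
                                  params.S, params.F_syn, ids)
    return np.stack([h[0] for h in H]), logits[0]


def _predict_rows(params: KBRNNParameters, logits: np.ndarray) -> np.ndarray:
    pref = np.empty(params.C, dtype=np.int64)
    pref[list(params.tie_order)] = np.arange(params.C)
    out = np.empty(logits.shape[0], dtype=np.int64)
    for i, row in enumerate(logits):
        best = np.nanmax(row) if np.isfinite(row).any() else None
        cands = np.flatnonzero(row >= best - 1e-12) if best is not None else np.array([], int)
        if cands.size == 0:  # degenerate (non-finite) outputs: fall back to the tie rule
            out[i] = params.tie_order[0]
        else:
            out[i] = cands[np.argmin(pref[cands])]
    return out


def predict(params: KBRNNParameters, padded: PaddedSentence) -> int:
    """Argmax syndrome; ties resolved by the stored preference order
    (most frequent pre-set syndrome first, then lowest id)."""
    _, logits = forward(params, padded)
    return int(_predict_rows(params, logits[None, :])[0])


def tie_order_from_sentences(sentences, n_syndromes: int) -> tuple[int, ...]:
    """Syndromes ordered by descending frequency, then ascending id."""
    counts = np.zeros(n_syndromes, dtype=np.int64)
    for s in sentences:
        counts[s.label] += 1
    return tuple(sorted(range(n_syndromes), key=lambda c: (-counts[c], c)))


# ------------------------------------------------------------------- training

def _softmax(z):
    z = z - z.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def cross_entropy(logits: np.ndarray, labels: np.ndarray) -> float:
    p = _softmax(logits)
    return float(-np.log(np.clip(p[np.arange(len(labels)), labels], 1e-300, None)).mean())


def _batch_grads(params: KBRNNParameters, W, ids, labels):
    D1, D2 = params.factors.D1, params.factors.D2
    H, cache, logits = _forward_batch(W, D1, D2, params.S, params.F_syn, ids)
    B, L = ids.shape
    p_hat = _softmax(logits)
    dlogits = p_hat.copy()
    dlogits[np.arange(B), labels] -= 1.0
    dlogits /= B
    loss = cross_entropy(logits, labels)

    gW = np.zeros_like(W)
    gD1 = np.zeros_like(D1)
    gD2 = np.zeros_like(D2)
    gF = dlogits.T @ H[-1] if params.train_F else None
    dh = dlogits @ params.F_syn.T
    for t in range(L - 1, -1, -1):
        p, wt, a = cache[t]
        da = dh @ D2
        gD2 += dh.T @ a
        dp = da * wt
        dwt = da * p
        np.add.at(gW, ids[:, t], dwt)
        gD1 += H[t].T @ dp
        dh = dp @ D1.T
    return loss, gW, gD1, gD2, (gF.T if gF is not None else None)


def fine_tune(params: KBRNNParameters, train_corpus, dev_corpus,
              config: TrainingConfig):
    """SGD fine-tuning with cross-entropy on the per-syndrome outputs.

    Trains E_R, D1, D2 (and G when beta < 1; F_syn only when relaxed by flag);
    S stays frozen.  Dev accuracy is recorded every epoch, starting with the
    untrained parameters, and the best-dev checkpoint is returned.
    Reproducible for a fixed seed.
    """
    if not train_corpus:
        raise ValueError("empty training corpus")
    rng = np.random.default_rng(config.seed)
    params = params.copy()
    ids = _ids_matrix(params, train_corpus)
    labels = np.array([s.label for s in train_corpus], dtype=np.int64)
    lr = config.learning_rate

    def dev_acc(p):
        acc, _ = evaluate(p, dev_corpus)
        return acc

    history = [{"epoch": 0, "train_loss": None, "dev_accuracy": dev_acc(params)}]
    best = (history[0]["dev_accuracy"], params.copy())
    n = len(train_corpus)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, config.batch_size):
            sel = order[lo:lo + config.batch_size]
            W = blend_embeddings(params.factors, params.blend)
            loss, gW, gD1, gD2, gF = _batch_grads(params, W, ids[sel], labels[sel])
            losses.append(loss)
            if config.grad_clip:
                norm = np.sqrt(sum(float((g ** 2).sum())
                                   for g in (gW, gD1, gD2) if g is not None)
                               + (float((gF ** 2).sum()) if gF is not None else 0.0))
                if norm > config.grad_clip:
                    scale = config.grad_clip / norm
                    gW *= scale
                    gD1 *= scale
                    gD2 *= scale
                    if gF is not None:
                        gF *= scale
            beta = params.blend.beta
            params.factors.E_R -= lr * beta * gW
            if beta < 1.0:
                params.blend.G -= lr * (1.0 - beta) * (params.blend.U.T @ gW)
            params.factors.D1 -= lr * gD1
            params.factors.D2 -= lr * gD2
            if params.train_F and gF is not None:
                params.F_syn -= lr * gF
        acc = dev_acc(params)
        history.append({"epoch": epoch, "train_loss": float(np.mean(losses)),
                        "dev_accuracy": acc})
        if acc > best[0]:
            best = (acc, params.copy())
    return best[1], history


def evaluate(params: KBRNNParameters, corpus):
    """Accuracy and C x C confusion matrix (rows true, columns predicted)."""
    corpus = list(corpus)
    if not corpus:
        raise ValueError("empty evaluation corpus")
    W = blend_embeddings(params.factors, params.blend)
    ids = _ids_matrix(params, corpus)
    _, _, logits = _forward_batch(W, params.factors.D1, params.factors.D2,
                                  params.S, params.F_syn, ids)
    preds = _predict_rows(params, logits)
    truth = np.array([s.label for s in corpus], dtype=np.int64)
    cm = _sk_confusion(truth, preds, labels=list(range(params.C)))
    return float((preds == truth).mean()), cm


# ----------------------------------------------------------------- checkpoints

def save_checkpoint(params: KBRNNParameters, path, history=None) -> None:
    """Text checkpoint: shapes plus row-major float lists, JSON-encoded."""
    def arr(a):
        return None if a is None else {"shape": list(a.shape), "data": np.asarray(a, dtype=float).ravel().tolist()}

    doc = {"E_R": arr(params.factors.E_R), "D1": arr(params.factors.D1),
           "D2": arr(params.factors.D2), "r": params.factors.r,
           "reconstruction_error": params.factors.reconstruction_error,
           "S": arr(params.S), "F_syn": arr(params.F_syn),
           "beta": params.blend.beta, "U": arr(params.blend.U), "G": arr(params.blend.G),
           "vocab": list(params.vocab.tokens), "tie_order": list(params.tie_order),
           "train_S": params.train_S, "train_F": params.train_F,
           "history": history or []}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)
        fh.write("\n")


def load_checkpoint(path) -> tuple[KBRNNParameters, list]:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)

    def arr(d):
        return None if d is None else np.array(d["data"], dtype=float).reshape(d["shape"])

    factors = CPDFactors(arr(doc["E_R"]), arr(doc["D1"]), arr(doc["D2"]), doc["r"],
                         doc.get("reconstruction_error", 0.0))
    blend = EmbeddingBlend(doc["beta"], arr(doc.get("U")), arr(doc.get("G")))
    params = KBRNNParameters(factors, blend, arr(doc["S"]), arr(doc["F_syn"]),
                             Vocabulary(tuple(doc["vocab"])), tuple(doc["tie_order"]),
                             doc.get("train_S", False), doc.get("train_F", False))
    return params, doc.get("history", [])
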