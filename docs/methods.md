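# Methods

`kbrnn` builds a syndrome classifier for symptom-level clinical records in two
steps: it first *extracts* parsimonious diagnostic rules from a
symptom/syndrome knowledge graph, scoring them on held-out records, and then
*injects* those rules into a recurrent network by compiling them to finite
automata, representing the merged automaton as a binary tensor, and factorizing
that tensor into the network's parameters. The untrained network therefore
already implements rule matching exactly; gradient training can only refine it.

## Data model

A record lists **main symptoms** followed by **additional symptoms** plus a
syndrome label. Symptoms carry one unique, continuous id space across both
kinds (`SYM<id>`), syndromes their own (`SYN<id>`); the two symptom kinds are
disjoint, which is what makes the main-then-additional sentence form
unambiguous. Sentences are framed as `BOS <symptoms> EOS PAD...` to a shared
length; the vocabulary reserves indices 0-3 for `BOS, EOS, PAD, UNK` and maps
unknown tokens to `UNK`. Dictionary matching of raw text uses leftmost-longest
alias matching without overlap — the standard convention for entity
dictionaries; matching is exact-substring, with no fuzzy normalization.

Duplicate symptom mentions are collapsed (first occurrence kept): rule
recognition is set-like, so duplicates would only inflate sentence length.

## Rule extraction

For syndrome `i`, a candidate rule is a pair of bit vectors `(phi, psi)` over
the unified symptom index — main and additional selections. A sentence is
recognized when every main token is selected in `phi`, every additional token
in `psi`, and the sentence has at least one token of each kind; this is the
regular expression `(m1|m2|...)+(a1|a2|...)+` applied to the token sequence.
Against a held-out **pre-set** (20% of the corpus), with `t_r` the recognized
same-syndrome sentences, `f_r` the recognized other-syndrome sentences and
`c_r` the selected-symptom count, the score is

    v = t_r / c_r   if f_r = 0,   else 0.

Misrecognition is disqualifying, and among clean rules equal support prefers
fewer symptoms (smaller automata and lower tensor rank downstream). The
recognition counts are computed in matrix form (binary occupancy matrices
`TP`/`FP` times the complement of the selection vector) and are required by
test to equal the per-sentence brute force.

The genetic algorithm uses tournament selection (size 3), uniform crossover
(rate 0.9, per-bit 0.5), per-bit mutation at rate `1/m`, 5 elites, population
200, and at most 500 generations. On stagnation (20 generations without
improvement) all non-elite members are reinitialized, up to 3 times; a further
stagnation ends the run. Candidate bits are restricted to the syndrome's
KG-linked symptoms, with a 2% chance per individual of drawing outside that
pool so incomplete graphs are not a hard ceiling. An archive keeps the k = 6
highest-scoring distinct misrecognition-free solutions (ties: smaller `c_r`,
then fewer symptoms outside the syndrome's KG link set, then lexicographic bit
order). The KG-prior tie level matters when the pre-set is small: a rule
symptom that happens to occur in no pre-set sentence is invisible to the
score, and without the prior the archive fills with equal-score variants
carrying arbitrary unlinked symptoms instead of the graph-supported rule. Candidate evaluation is pure and vectorized, so
results are identical for any nominal worker count. Low-scoring rules are
pruned (score floor 0.05, minimum support 1), but a syndrome's single best
rule is kept unless it scores 0.

## Compilation and tensor form

Each rule becomes the wildcard-flanked regex `$*(m1|...)+(a1|...)+$*`, where
`$` expands to the whole vocabulary **including** `BOS/EOS/PAD/UNK` — that is
what makes the compiled automata indifferent to framing and padding. The regex
is compiled by Thompson construction, subset construction and Moore partition
refinement; dead and unreachable states are dropped, so transition functions
are partial (an absent edge is a zero row in the tensor). For a two-set rule
the minimal wildcarded automaton has exactly three live states (no progress /
inside a selected-main run / accepted).

The per-rule minimal DFAs are merged by disjoint union under a fresh start
marker: `S` flags each component's start state, `F_syn` (K x C) groups final
states by owning syndrome, `F` is its row-wise OR, and `T` (V x K x K) stacks
the transition tables. The product `S . T[s_1] ... T[s_x] . F` counts the
component automata accepting a sentence; replacing `F` with columns of `F_syn`
gives the per-syndrome count vector used as the classification readout, with
argmax prediction. Ties (including the all-zero output) resolve to the most
frequent pre-set syndrome, then the lowest id.

## CP decomposition and the recurrent form

CP decomposition factors `T` into a token factor `E_R` (V x r) and state
factors `D1, D2` (K x r), turning automaton simulation into

    h_0 = S,   h_t = ((h_{t-1} . D1) o w_t) . D2^T,   out = h_x . F_syn.

Because every transition arc `(i, j)` contributes the rank-one term
`T[:, i, j] x e_i x e_j`, an exact decomposition with one component per arc
always exists; the number of distinct arcs is therefore an upper bound on the
CP rank of `T`. `cpd_decompose` builds these factors directly whenever
`r >= arc bound` (error 0 by construction) and otherwise runs alternating
least squares from a seeded random initialization, recording the max-abs
reconstruction error. The default rank is `min(arc bound, 4K)`: oversizing
past the arc bound only costs space. For the default study conditions the arc
bound is 6 per rule (K = 3 states, 6 arcs), e.g. 540 for 90 rules.

Token embeddings may be blended with an external table:
`w = beta * v + (1 - beta) * u G` with `beta` in [0, 1], `u` a per-token
vector (e.g. exported from a pretrained language model) and `G` a trainable
projection. The default `beta = 1` uses the CPD factor alone and needs no
external file; any provider producing V x D vectors is accepted.

## Fine-tuning

The per-syndrome outputs are treated as logits under cross-entropy. Plain SGD
(the learning-rate grid `[0.01, 0.005, 0.001, 0.0005, 0.0001]` is the tuning
range; 0.001 is the default) trains `E_R`, `D1`, `D2` and `G`; `S` is frozen
and `F_syn` only relaxes to real values behind a flag, keeping the readout
interpretable as final-state grouping. Gradients are derived analytically
through the recurrence and clipped to a global norm of 5, which keeps the
multiplicative recurrence stable at the larger grid learning rates. Dev
accuracy is recorded every epoch starting at epoch 0 (the untrained model),
and the best-dev checkpoint — possibly the initial one — is returned: early
stopping from initialization. The hidden size is structurally K; an external
hidden-size budget can be honored by padding with inert (all-zero) states,
which provably leaves outputs unchanged.

## Synthetic data

The generator emulates a diagnosis corpus at reduced scale: 15 syndromes, 60
main + 40 additional symptoms, 40 sentences per syndrome (600 records), rule
sizes 3-6 main / 2-4 additional, per-sentence subsets of 2-5 main / 1-4
additional tokens — short clinical listings. Configurable corruptions:
distractor tokens outside the generating rule, label flips (the ground-truth
label is kept alongside), and KG link noise (missing/extra edges relative to
the generating rules).

Two guarantees make noiseless corpora exactly decodable. Planted rules are
pairwise **non-subsumed** (neither rule's two sets are componentwise subsets
of the other's), and every emitted sentence keeps a **safe boundary pair** — a
(main, additional) token pair adjacent at the part boundary that no foreign
rule contains in its two sets. The second condition matters because the
wildcard-flanked automaton accepts exactly when some selected-main token is
immediately followed by a selected-additional token, and in a main-then-
additional sentence the only such adjacency crosses the boundary. A repair
pass during planting re-samples any rule left without a safe pair. What the
generator does **not** model: symptom co-occurrence beyond rule membership,
realistic surface text (canonical codes are emitted), per-syndrome class
imbalance, and annotation artifacts — so passing tests demonstrate the
machinery is correct and self-consistent, not that real-corpus accuracy would
reach any particular level.

## Numerical and procedural choices

- Scoring indicator: a rule with any misrecognition scores 0 (the intended
  reading of "misrecognition is not allowed"); `c_r = 0` also scores 0.
- Splits use the largest-remainder method; stratification by label is on by
  default (it prevents empty-class pre-sets that would break rule scoring),
  with per-label leftovers placed in descending fractional-remainder order
  subject to the global part sizes, keeping each label within one sentence of
  its global proportion.
- One global seed fans out to per-stage seeds via a stage-name hash (CRC32),
  so stages re-run in isolation reproduce the pipeline's randomness.
- ALS stops on a 1e-9 error tolerance or when progress stalls; pseudo-inverse
  solves guard rank-deficient Gram matrices.
- Prediction with non-finite outputs (a diverged training run) falls back to
  the tie rule rather than crashing.
- Problem sizes in the verification suite — 1000-sentence oracle comparisons,
  50 rules enumerated over all strings of length <= 6 on an 8-token alphabet,
  10 GA fixtures with <= 12 candidate symptoms, a 600-sentence end-to-end
  corpus, 3 seeds x 30 epochs for the noisy-training comparison — were chosen
  as the smallest scales at which the properties are non-trivial.

## Known limitations

- Rule extraction treats the pre-set as ground truth; systematically noisy
  labels in the pre-set bias rules before training can compensate.
- The GA optimality guarantee is empirical and only verified at toy scale;
  at realistic scale the archive is a good local optimum, not a certificate.
- Exact injection needs `r` at the arc bound; memory grows as `(V + 2K) r`,
  so very large rule sets may force `r` below exactness (the reconstruction
  error is always recorded).
- The wildcarded rule language ignores token order beyond one main-additional
  adjacency; corpora whose classes differ only in symptom order are
  indistinguishable to the untrained model.
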