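# Methods

`pathsem` implements path-based relation prediction over a medical knowledge
graph, with textual-semantics enhancements: given an entity pair
(e<sub>s</sub>, e<sub>t</sub>), a query relation δ, and the set of relation
paths P = {π₁ … π_m} connecting the pair, a scoring model estimates
P(δ | e_s, e_t) ∈ (0, 1).  This note records the models, the training and
evaluation protocol, the synthetic data generator, and the numerical and
design choices that were genuinely open.

## Models

**PRA (baseline).**  Each distinct relation sequence between a pair (its
"path type") is a binary feature; the score is σ(w·x + b) over the
path-type indicator vector.  Path types unseen in training contribute
nothing at scoring time (logged).  Features are binary indicators, not
path-constrained random-walk probabilities — the frequency information the
walk probabilities would add is deliberately out of scope here, so PRA acts
as the pure "atomic path feature" baseline.

**RNN path composition (Path-RNN / Single-Model / Att-Model family).**
Each path is folded by a recurrence

    h_t = ReLU(W1 h_{t-1} + W2 r_{t-1} + W3 e_{t-1}),    h_0 = 0

over the path's alternating relation/entity sequence, where r is a learned
d-dimensional relation embedding and e a k-dimensional entity
representation.  An L-hop path unrolls over L+1 steps: the first step
consumes a learned dummy relation together with the source entity (there is
no incoming relation at the source), and each subsequent step consumes one
hop's relation and entity, so every symbol on the path enters the
composition.  The final hidden state is the path vector π.

Entity representations come in three modes: a single shared learned vector
(`none`, the plain Path-RNN/Single-Model setting); the mean of the entity's
type embeddings (`types`, zero vector for typeless entities); or the mean
type embedding concatenated with the encoded entity statement and linearly
projected back to k (`types_plus_text`).

**Pooling.**  Per-path match scores are pooled across the path set either
by LogSumExp over π_i·δ (a smooth maximum — the Single-Model setting), or by
attention:

    z_i = tanh(π_i T) · δ,   α = softmax(z),
    ep  = tanh(Σ_i α_i π_i),  P(δ|e_s,e_t) = σ(ep · δ)

The query relation δ is a learned d-vector from its own table, separate
from the path-relation embeddings.  T ∈ R^{d×d} forces π ∈ R^d, so path
text vectors (width H) are linearly projected to d before pooling.

**Text-enhanced path representation.**  The whole path is verbalized into a
statement (one clause per hop from the hop relation's phrase template,
clauses joined by ", and ", first clause capitalized) and encoded; π is a
linear projection of the statement vector, skipping the RNN.  Two paths
with identical statements necessarily receive identical scores — this is
the mechanism by which textually similar relations share statistical
strength, and it is what the shuffled-phrase ablation (below) switches off.

**Softmax/LogSumExp stability.**  Both are computed with max-subtraction.
Attention weights are validated to be non-negative and sum to 1 (±1e-9).

## Text encoders

The encoder contract: wrap the statement in sequence-start/end markers,
return the start position's final hidden vector of fixed width H, finite
entries, deterministic given fixed encoder state; over-long inputs are
truncated deterministically with a warning; empty input is an error.

The default implementation is a deterministic hashing encoder: character
3-grams plus word unigrams of the marked statement, hashed by seeded
BLAKE2b into H signed buckets, L2-normalized.  It has the single property
downstream reasoning needs — statements sharing surface tokens have higher
cosine similarity than unrelated statements, degrading smoothly as tokens
are corrupted — at a cost of microseconds per statement.  It is a real
encoder in its own right (feature hashing), not a mock: what it lacks,
compared to a pretrained contextual encoder, is word order beyond 3-grams,
synonymy beyond shared surface forms, and any pre-trained world knowledge.
Results obtained with it therefore show that the *architecture* exploits
textual similarity where it exists; they say nothing about the additional
semantics a pretrained encoder would contribute on real clinical text.  An
adapter for HuggingFace transformer encoders implements the same contract
([CLS] final hidden state, frozen by default, optional fine-tune flag) when
the optional `bert` extra is installed; encoder outputs are frozen features
in the NumPy training loop either way.

## Training

The loss is the negative log-likelihood of the labeled instances,

    L = −Σ_pos log p − Σ_neg log(1−p) + λ‖Θ‖₂²,

computed in logit space (softplus form) for numerical stability; λ weighs
the squared L2 norm of the weight matrices (W1, W2, W3, T and the text
projections), not the embedding tables.  The public probability-space loss
clamps degenerate inputs to [1e-12, 1−1e-12] with a logged warning.
Optimization is Adam at a constant learning rate; defaults are learning
rate 1e-3, batch size 64, β₁ = 0.9, β₂ = 0.999, ε = 1e-8, λ = 1e-5, at most
100 epochs.  One model is trained jointly for all query relations.
Gradients come from a small reverse-mode autodiff engine over NumPy arrays
written for this package; per-instance forward passes batch the path
recurrences in equal-length cohorts so each RNN step is one matrix product.
Analytic gradients are verified against central finite differences in the
test suite.

**Negative sampling.**  Negatives are fixed at preparation time (a
`resample_negatives` flag exists but defaults off).  One slot of a true
triple — head, tail, or relation, uniform — is replaced; an entity slot is
refilled, with probability 0.7, from the entities occupying that slot of
the same relation (hard negatives), otherwise uniformly; an empty
same-relation pool falls back to uniform with a logged counter.  Candidates
colliding with any known true triple are rejected and resampled.  The
training split gets ≈0.75 negatives per positive; dev/test get ≈8 per
positive, reflecting the negative-heavy ranking pools of the evaluation
protocol.

**Early stopping and checkpointing.**  Training stops when dev accuracy (at
threshold 0.5) has not improved by ≥0.01 for 10 consecutive epochs, or at
the epoch cap.  The returned checkpoint is the best-dev-MAP epoch — the two
criteria are kept separate deliberately: accuracy is the cheap stopping
signal, MAP the model-selection signal.  With an unattainable improvement
threshold the loop runs exactly patience+1 epochs.  Histories are exactly
reproducible given the config seed.

**Grid search** evaluates a cartesian hyperparameter grid exhaustively by
dev MAP, ties broken toward the first configuration in grid order.

## Evaluation

Per query relation, all test instances (positives plus the fixed negatives)
are ranked together by score; average precision is the mean of precision at
each positive's rank.  Ties are broken by stable instance-id order — AP is
tie-sensitive, so the order must be deterministic.  MAP is the unweighted
(macro) mean of AP over relations with at least one test positive;
relations without positives are excluded with a log message.  Attention
case reports list one pair's verbalized path statements sorted by attention
weight.  A permutation null for MAP is obtained by replacing scores with
uniform noise and recomputing MAP; an observed MAP is compared against the
null's 99th percentile.

## Path extraction

Paths are discovered by uniform random walks: each walk steps uniformly
over the current entity's outgoing edges, ends on dead ends, on reaching
the target, or after `max_len` steps; walked prefixes that revisit an
entity are discarded, so every returned path is simple and a member of the
exhaustive bounded-DFS enumeration (`enumerate_paths`, the test oracle,
backed by networkx).  Walks are batched over integer-indexed adjacency, so
a budget of 10,000 walks per pair costs milliseconds.  The query's own
direct edge (and its inverse) is excluded from every path — the one
label-leakage guard; paths otherwise traverse the full graph, matching a
protocol in which the dataset is built by walks first and split afterwards.
Path sets deduplicate and truncate to `max_paths`, keeping shortest paths
first (shortest paths carry most of the inferential signal in the
path-ranking literature, and short caps keep the rule-bearing 2-hop
evidence salient under attention).  Pairs with zero discovered paths are
dropped with a logged count.  Inverse edges (relation id + `_inv`, phrase
with the name slots swapped) are off by default and enabled in the study
pipeline, where walking both directions roughly doubles pair coverage.

## Synthetic data generator

The generator emulates the statistical structure of a symptom-centered
medical KG at desk scale; it does not attempt to clone any real dataset.

* **Schema.**  Six entity categories (disease, symptom, examination,
  department, drug, body part) and a fixed inventory of 17 relation types
  (disease/symptom/examination crossed with related symptoms, diseases,
  departments, examinations, body parts, drugs).  Category proportions:
  30/30/15/15/5/5%.
* **Long tail over entities.**  Edge endpoints are drawn Zipf-weighted
  within category (exponent 1.1, `edges_per_relation` 150).  At the preset
  scale (2,000 entities) roughly a third of the active entities take part
  in exactly one triple, the long-tail regime of real symptom graphs.  The
  singleton fraction rises with the exponent in the sub-critical range;
  past ≈1.5 the endpoint mass concentrates so hard on hubs that the active
  tail collapses again, so the preset stays sub-critical.
* **Long tail over relations.**  Examination-headed relations are rarer by
  `rare_head_factor` (0.15), and three relations are *synonym variants* —
  a second relation id over an already-occupied category pair (e.g.
  `symptom_consulting_departments` beside `symptom_related_departments`) at
  `variant_factor` (0.2) of the usual frequency.  Duplicated near-synonymous
  relation types are a documented feature of real symptom graphs and are
  the place where textual similarity carries information that graph
  structure alone does not.
* **Planted rules.**  Chain rules (r₁, r₂) ⇒ r_h over composable category
  triads.  The default six rules pair each disease-headed rule with both of
  its body routes — through the common relation and through its rare
  synonym variant (disease→symptom→X via `symptom_related_X` or
  `symptom_…_X`).  After background and planted chains are laid down, a
  closure pass adds the head triple of every body-connected pair with
  probability `rule_precision` (default 1.0, so body presence implies the
  head; at 0 no heads are added).  The gold standard records the rules and
  every entailed head triple.
* **Names and phrases.**  Entity names are a category type-word plus index
  (name words are disjoint from phrase nouns, so phrase tokens are not
  redundant with names); types are the category plus a subtype word.
  Relations sharing a tail category verbalize with near-identical clause
  patterns ("the related department of …" / "the associated department of
  …"), and a synonym-variant relation shares its sibling's phrase
  *exactly*.  The shuffled-phrase ablation deranges phrases across forward
  relations by value (inverse phrases regenerate from the shuffled forward
  ones), destroying exactly this alignment while preserving the phrase
  multiset and everything else.

**What passing tests on this generator do and do not show.**  The generator
provides ground truth (planted rules), controlled sparsity, and textual
similarity aligned with semantics; models that recover the planted signal
demonstrably exploit path evidence, attention selection, and phrase-level
similarity.  Real clinical graphs add everything the generator lacks:
noisy and incomplete rules, entity ambiguity, richer language, and
pretrained-encoder semantics; absolute MAP values here do not transfer.

## Study protocol (desk scale)

The packaged experiments (`pathsem.experiments`, also exercised by
`scripts/acceptance.py`) run on the 2,000-entity preset with inverse edges
enabled, walk budget 10,000 per pair, path cap 8 (shortest first — tight
path sets keep the 2-hop rule evidence salient under attention), path
length cap 4 for extraction, stub encoder, d = k = 50, and training without
early stopping (the dev-accuracy plateau arrives before the dev-MAP optimum
at this scale).  These sizes are the package's chosen study conditions;
they keep a full protocol run in the minutes range on one CPU.

* **Corruption bias audit**: 10,000 corruption draw decisions; the
  same-relation fraction is compared with the configured 0.7 within a 99%
  binomial CI.  Decisions, not accepted corruptions, are counted: same-pool
  candidates collide with existing triples more often, so the accepted
  fraction understates the configured bias.
* **Signal recovery** (250 positives per split, 60 epochs): the attention
  model's test MAP against the permutation null's 99th percentile; mean
  attention advantage of rule-body paths over distractors within
  mixed-evidence positives, with a one-sided sign-flip permutation p-value.
  The longer run matters: attention sharpens onto the discriminative paths
  well after the ranking metric has plateaued.
* **Textual-semantics contrast** (30 epochs, H = 256): the path-text model
  under true phrases versus the shuffled-phrase ablation, paired over 5
  training seeds.  Both arms of a pair share initialization and batch
  order; each pair draws a fresh derangement and a fresh stub hash seed, so
  the comparison marginalizes the ablation's and the encoder's arbitrary
  randomness.  Training uses a deliberately low-data split (10 positives
  per relation — textual parameter-sharing matters most under sparsity);
  dev MAP is measured once per arm, at the final model, on a
  relation-balanced dev pool (80 positives per relation), because the
  macro average over relations with a handful of positives is otherwise a
  lottery.  At this scale the paired mean advantage of true phrases is
  small (of order +0.005 to +0.02 MAP) and varies with the generated
  graph; individual paired comparisons are close to even, so win counts
  are a much noisier summary than the mean paired difference.

## Numerical and degenerate-input choices

* Probabilities are computed through a numerically stable logistic
  (tanh form); losses in logit space; softmax/LSE max-stabilized.
* Degenerate entities (no types) map to the zero type vector; entities and
  relations missing from metadata degrade to name = id and a generic
  "{h} <id> {t}" phrase.
* Duplicate triples collapse silently with a logged count (set semantics).
* Splitting is stratified by relation with largest-remainder rounding, then
  rebalanced deterministically so the global sizes equal the
  largest-remainder allocation of the ratios (1,000 triples at 7:1.5:1.5
  give exactly 700/150/150).
* Parameter init is uniform(−0.1, 0.1), seeded; checkpoints round-trip
  bit-exactly (one `.npy` per named array plus a JSON index).
* All randomness in a workflow flows from one root seed; per-pair walk
  seeds are derived by CRC32 of the seed and the triple identity.

## Known limitations

* The architecture cannot rank relations with zero training positives: δ
  is a learned per-relation embedding, so text transfer helps sparse
  relations, not unseen ones.
* The hashing encoder is surface-level; synonymy beyond shared tokens is
  invisible to it, understating what a pretrained encoder contributes.  In
  particular the desk-scale textual-semantics contrast is positive on
  average but close to the noise floor of individual runs; with a
  contextual encoder and a real vocabulary the alignment between phrase
  similarity and relation semantics would carry far more signal.
* As a bag of features, the hashing encoder cannot distinguish a relation
  phrase from its slot-swapped inverse phrase, so forward and inverse hops
  of the same relation look alike to the text models.
* PRA omits walk-probability features; it is the indicator-feature reading
  of the baseline.
* Whether attention in the entity-representation model should attend over
  intermediate RNN states was an open design point; final states are used.
* Encoder fine-tuning is exposed as a flag on the transformer adapter but
  gradients do not flow into the encoder from the NumPy training loop.
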