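# Methods

`topicscreen` compares document representations for the screening phase of a
systematic review: given citations (title + abstract) with expert relevance
judgements, how well can a classifier rank and flag the relevant minority?
The toolkit implements three representations — TF-IDF bags-of-words (BOW),
LDA topic proportions (TPC), and topic proportions over term-enriched token
streams (TE) — an imbalance-weighted SVM, and a rank-based evaluation
protocol. This note records the models, the numerical choices, and what the
synthetic experiments do and do not establish.

## Preprocessing

Tokens are maximal runs of letters from the lower-cased title + abstract;
punctuation and digits act as delimiters (so hyphenated words split and
embedded digits vanish), stop-words from a fixed ~150-word English list
(package data, overridable) are dropped, and tokens occurring exactly once
in the corpus (hapax legomena) are removed. The operation is idempotent.
The TF-IDF weighting is the plain textbook form: tf(d,w) · ln(N/df(w)) with
raw counts and no row normalisation; a token present in every document gets
weight zero. Hapax removal runs *after* term fusion in TE pipelines so that
fused multi-word tokens are counted as units.

## C-value term recognition

Candidate terms are contiguous windows of 2–4 tokens whose coarse
part-of-speech pattern matches `ADJ*NOUN+` (a richer noun–preposition–noun
filter is available). Both maximal matches and nested sub-windows are
candidates. Termhood is scored by C-value:

    C(a) = log2(|a|) · f(a)                                 (not nested)
    C(a) = log2(|a|) · ( f(a) − (1/|T_a|) Σ_{b∈T_a} f(b) )  (nested)

with T_a the set of extracted candidates strictly containing a; scoring
proceeds longest-first. The default lexicon keeps candidates with C > 0 and
frequency ≥ 2 (the threshold is configurable; unigrams are excluded since
log2(1) = 0). Term location is a greedy left-to-right longest-match scan
(cap four tokens); fused tokens join constituents with underscores, and
splitting on underscores restores the original stream exactly.

Tagging is a pluggable interface. The shipped tagger is a deliberately
small rule/lexicon tagger (closed-class word lists → OTHER/PREP, an
adjective lexicon plus suffix rules → ADJ, default → NOUN). It is adequate
for noun-phrase mining on abstracts and keeps the package dependency-light;
any external tagger can be adapted to the four coarse classes.

## LDA by collapsed Gibbs sampling

Each document mixes K topics (θ_m ~ Dir(α)), each topic is a word
distribution (φ_k ~ Dir(β)); each token draws a topic from θ and a word
from φ_z. With θ and φ integrated out, the full conditional for one token
assignment is

    p(z_i = k | z_−i, w) ∝ (n_dk + α) (n_kw + β) / (n_k + V β)

The sampler sweeps all token positions (inner loop JIT-compiled with
numba); point estimates average the smoothed count ratios
θ = (n_dk+α)/(N_d+Kα), φ = (n_kw+β)/(n_k+Vβ) over thinned post-burn-in
sweeps. Defaults: 1,000 sweeps, 200 burn-in, every 10th sweep averaged;
α = max(1/K, 0.1), β = 0.01, both symmetric (topics are a priori
exchangeable). All randomness flows from a single integer seed; fits are
bit-reproducible.

Held-out documents are folded in by sampling their assignments with φ held
fixed (200 sweeps, 50 burn-in, every 5th averaged); unseen tokens carry no
topic evidence and are skipped; a document left empty gets the uniform
vector — every citation must receive a feature vector. Topic features are
*transductive* by default (the model is fitted on the full unlabelled
corpus before splitting, mirroring how topic features are typically built
for screening experiments); `transductive=False` fits on the training half
only and folds the test half in, for a leak-free comparison.

For diagnostics the sampler can record per-position topic marginals.
These are Rao-Blackwellised — the full conditional of each position is
averaged rather than its sampled one-hot value — which is an unbiased,
strictly lower-variance estimator at the same sweep count. The correctness
test compares these marginals against exhaustive enumeration of all K^N
assignments under the collapsed joint on ≤8-token corpora. Note that a
corpus whose exact marginals are forced to 1/K by label symmetry tests
little beyond mode-switching speed, so the fixtures are asymmetric.

The `log_joint` function evaluates the complete-data log likelihood (token
terms plus Dirichlet priors of every θ_d and φ_k) and returns −inf, rather
than raising, on zero-probability entries; it is invariant under joint
relabelling of topics.

## Classification

The screening imbalance (~1 relevant per 9 irrelevant) is handled by
instance weights w_i = N/(2·N_c): each class carries equal total penalty
mass. The quadratic program is delegated to libsvm (via scikit-learn SVC)
with cost C = 1 and no tuning; kernels are linear, RBF (γ = 1/d, the
classic libsvm default), and cubic polynomial. The polynomial kernel is
inhomogeneous (coef0 = 1): on simplex-valued topic features the
homogeneous cubic (γ x·y)³ has dynamic range ~1e−5, the decision function
collapses onto the bias term, and the predicted class is solver noise —
keeping the lower-order terms makes the kernel usable without tuning.
Decision scores are raw margins (positive ⇒ relevant); predictions
threshold at zero; no probability calibration.

## Evaluation

Precision, recall, F1 and accuracy use the zero-division convention
(no predicted positives ⇒ P = R = F1 = 0), matching how degenerate
all-negative classifiers are conventionally reported on imbalanced
screening corpora. ROC-AUC is the rank formulation (ties count half);
PRC-AUC is step-wise average precision, not trapezoidal interpolation —
the standard choice for rare-positive retrieval.

Representations/kernels are compared across corpora with the Friedman
test: values ranked within each corpus (higher = better, midranks on
ties), mean ranks per group, and the tie-corrected statistic
χ²_F = [12n/(k(k+1))] Σ_j (R̄_j − (k+1)/2)² / C with k−1 degrees of
freedom. Mean ranks are the primary comparison surface; asymptotic
p-values are reported but are unreliable at n = 5 corpora. Reports average
all stochastic cells over ≥3 seeds.

## Synthetic data

Real screening corpora with expert judgements are not redistributable, so
the generators produce corpora with the statistical structure the pipeline
assumes. `generate_lda_corpus` draws φ ~ Dir(β·1_V), θ_m ~ Dir(α·1_K),
Poisson document lengths (truncated ≥ 1) and tokens topic-then-word,
returning the ground truth for recovery experiments.
`generate_screening_corpus` additionally draws Bernoulli(0.1) relevance
labels and centres each document's θ on a class profile
(θ ~ Dir(s·profile), s = 5 by default).

Default conditions emulate the regime real screening corpora occupy: K=10
topics over V=12,000 vocabulary entries, 2,000 documents of ~80 tokens
(β = 0.2 so topics are broad and the observed vocabulary is large —
the bag-of-words space is high-dimensional and sparse relative to the
corpus), prevalence 0.1, and class profiles that are separable in topic
space but share topical mass (the relevant class concentrates 75 % of its
mass on a fifth of the topics, the irrelevant class on the rest, with a
uniform floor). Under these conditions the toolkit reproduces the
qualitative pattern screening studies report: a weighted linear SVM on BOW
is a usable baseline, BOW + RBF/poly degenerates toward all-negative
predictions, and topic features restore high recall under all kernels.

Token symbols are letter-coded ("vaa", "vab", …) so generated documents
survive preprocessing unchanged; a small embedded biomedical vocabulary
with planted multi-word phrases ("logistic regression model", "teen birth
rates", …) exercises the term-recognition path end to end.

What the synthetic experiments do *not* show: real abstracts have bursty
word usage, correlated topics, near-duplicate citations and label noise,
none of which the exchangeable LDA generator produces. Passing tests
establish the correctness of the machinery and the direction of the
BOW-vs-topics contrast under the model's own assumptions, not absolute
performance on any particular review.

## Problem sizes used in tests and the acceptance script

Sampler-vs-enumeration: ≤8 token positions, K=2, 20,000 sweeps. Parameter
recovery: K=5, V=200, 500 documents of ~100 tokens, α=0.1, β=0.01; greedy
topic matching by maximal overlap; mean total-variation distance is
typically ~0.01 (well under the 0.10 tolerance). End-to-end screening runs
are desk-scaled to 1,000 documents with the default generator conditions,
LDA at K=10 with 300 sweeps / 100 burn-in, each cell averaged over three
seeds. These sizes keep the full suite around a minute of CPU while
leaving every statistical margin wide.

## Known limitations

- The C-value implementation scores candidates from a single corpus pass;
  no term-variant normalisation or context weighting (NC-value).
- The rule tagger will mis-tag rare adjectives as nouns; the POS filter is
  permissive enough that this mostly costs candidate precision, not recall.
- Topic-label switching across seeds means φ rows are only comparable
  after matching; the recovery helper does greedy overlap matching, which
  can be suboptimal when topics are highly correlated.
- Friedman p-values use the asymptotic chi-square; with five corpora the
  mean ranks, not the p-values, are the meaningful output.
- The transductive default mirrors common practice for topic-feature
  screening experiments but lets unlabelled test text influence the topic
  basis; use `transductive=False` when that matters.
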