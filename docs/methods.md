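# Methods

This note documents the models, estimators, conventions and limitations
behind `rpcselect`. It is the place where genuinely open design choices are
recorded; the README covers usage.

## The model

Latent Dirichlet allocation with symmetric priors. A corpus has M documents
over a vocabulary of V words; document d has N_d tokens. Each of T topics
is a multinomial φ_t over the vocabulary with φ_t ~ Dirichlet(β); each
document has topic proportions θ_d ~ Dirichlet(α); token n of document d
draws a topic z_n ~ θ_d and then a word w_n ~ φ_{z_n}.

Inference is collapsed Gibbs sampling: θ and φ are integrated out and the
per-token assignments are resampled from

    p(z_i = t | z_-i, w) ∝ (n_dt^-i + α) (n_tw^-i + β) / (n_t^-i + V β),

where n_dt, n_tw, n_t are doc–topic, topic–word and topic-total counts
excluding token i. Point estimates are read off the count tables with
Dirichlet smoothing,

    φ_tw = (n_tw + β) / (n_t + V β),   θ_dt = (n_dt + α) / (N_d + T α),

from the final sweep by default; `sample_every=k` averages the smoothed
estimates over every k-th post-burn-in sweep instead.

The sweep kernel is compiled with numba and consumes pre-generated uniform
variates from a seeded numpy generator, so runs are bit-reproducible and
independent of numba's internal RNG. Correctness is checked against a
brute-force enumeration of the collapsed posterior over all assignment
configurations on a tiny corpus (total-variation distance ≤ 0.02 over
50,000 post-burn-in sweeps).

### Hyperparameter conventions

- α = 50/T, β = 0.01 (the common collapsed-Gibbs convention) unless set
  explicitly. No hyperparameter optimization is performed.
- 1000 sweeps with 500 burn-in by default; the selection experiments in
  the test-suite and acceptance script use 300/150, which at the benchmark
  scale (~20k tokens) is close to, but not fully at, convergence for T near
  the true topic count — see "Known limitations".
- Initialization assigns each token a uniform-random topic. A
  `init="sequential"` option instead samples each token from its collapsed
  conditional as the counts accumulate; both target the same posterior. The
  random default was kept after the sequential variant showed early
  rich-get-richer lock-in at small T under short sweep budgets.

## Held-out perplexity

For a held-out set, perplexity = exp(−Σ_d log p(w_d) / Σ_d N_d). Empty
documents contribute zero to both sums; a held-out set with no tokens has
no defined perplexity and raises.

`fold_in` freezes φ and Gibbs-samples assignments for held-out tokens,
returning smoothed θ estimates and log p(w_d) = Σ_n log Σ_t θ_dt φ_t,w_dn.
Because documents are conditionally independent given φ, fold-in streams
per-document random variates keyed by document id: permuting held-out
documents permutes the results exactly. Vocabularies are built on the full
dataset before splitting, so out-of-vocabulary held-out words cannot occur
and are rejected if presented.

### The cross-validation scorer

Within `cross_validate_perplexity` the default scorer is **document
completion**: θ is inferred from the even-indexed tokens of each test
document and the odd-indexed tokens are scored. Scoring the very tokens θ
was fit to (plain fold-in, available as `scoring="fold_in"`) rewards extra
topics indefinitely — the perplexity curve then decreases monotonically in
T and the change-point rule degenerates. Completion removes that leak and
restores the fall / flatten / slow-rise regime structure the selection
rule relies on.

## Topic-number selection

Candidates t_1 < t_2 < ... < t_r (default 5, 10, 20, ..., 100). Documents
are partitioned once into m folds (balanced ±1, uniform random, shared by
all candidates; a flag re-randomizes per candidate). For each candidate and
fold, train on the other folds, score the fold, and average the m fold
perplexities into P_i. Then

    RPC(i) = | (P_i − P_{i−1}) / (t_i − t_{i−1}) |,   2 ≤ i ≤ r,

and the chosen topic number is t_i for the first i with RPC(i) < RPC(i+1)
(strict; a tie is not a change point). If the series never rises the
result carries an explicit not-found flag with the last candidate as a
fallback suggestion, never a silent answer. The minimum-perplexity
baseline takes argmin P_i, ties to the smallest candidate; the fold mean
is the arithmetic mean.

## Stability and clustering evaluation

`stability_experiment` repeats the whole CV-select pipeline with seeds
base+1..base+repeats, counts the chosen topic numbers per selector, and
scores each frequency distribution by Shannon entropy (bits); lower means
more stable. One curve is computed per repeat and both selectors are
applied to it, comparing the rules on identical evidence.

`cluster_purity` labels each cluster by its dominant true label; overall
purity is size-weighted (Σ_c max-label-count_c / N) and the misclassified
count is its complement. Clustering of θ rows is agglomerative
(average linkage, Euclidean, flat clusters by an explicit cut height —
required, since no universal default height exists) or k-means (seeded,
10 restarts, best inertia kept).

## Synthetic benchmarks

The generators plant ground truth so every stage is testable offline:

- `generate_lda_corpus` runs the generative process forward. Benchmark
  defaults M=200, V=500, 100 tokens/document, α_gen=0.1, β_gen=0.01,
  K=20 — the shape of the real corpora this pipeline targets (hundreds of
  documents, vocabulary in the thousands, 10²–10³ tokens per document)
  shrunk to desk scale.
- `generate_separable_corpus` gives each topic a private uniform word
  block (documents mix 1–2 topics); recovery of φ is unambiguous.
- `generate_snp_alignment` emulates aligned bacterial genomes: group
  consensus sequences differing at planted variant columns with
  within-group noise (default 2% per variant site).
- `generate_binary_profiles` emulates entity×feature incidence data with
  group feature blocks over background noise.

What the synthetic data does *not* emulate: linkage structure along the
genome, burstiness and length variation of real text, correlated
side-effect co-occurrence, or label noise. Passing the planted-truth
benchmarks shows the estimator and the selection rule are implemented
correctly and behave as designed under the model's own assumptions — not
that the RPC rule is superior on any particular real dataset.

## Numerical and procedural choices

- All randomness flows from integer seeds through `numpy.random.SeedSequence`;
  derived sub-seeds are reduced mod 2³¹. Identical inputs and seed give
  bit-identical results, including vocabulary order (first appearance).
- SNP encoding: a column is variant when ≥2 distinct non-gap, non-N
  residues occur; a sequence with a gap/N at a variant column receives the
  token "`<column>-`" so documents stay equal length. This is a convention —
  alignment gap treatment is genuinely underdetermined — and is asserted by
  the encoder's equal-length postcondition.
- Text encoding: lowercase, split on non-alphabetic characters, drop
  tokens shorter than 2, remove words in a fixed ~120-entry English
  function-word list vendored in `_text.py`, then apply the classic Porter
  (1980) stemmer (implemented in-package, validated against the
  algorithm's published example pairs).
- All-zero matrix rows and documents emptied by filtering are retained as
  empty documents with a warning; they contribute nothing to perplexity.
- Top-word tables break probability ties by vocabulary order.

## Known limitations

- At short sweep budgets (300 sweeps), models with T at or just below the
  true topic count mix slowest — merged topics take many sweeps to split —
  so their perplexity estimates sit slightly above their converged values,
  and the perplexity minimum can appear one grid step above the planted K.
  The change-point selection consequently concentrates on {20, 30, 40}
  around a planted K of 20 rather than hitting it exactly; the
  minimum-perplexity baseline drifts further right and varies more. Longer
  chains tighten both.
- The RPC rule reads a first strict rise; on curves made very smooth (for
  example by heavy sample averaging) the rise can migrate into the flat
  region. The default final-sample estimates retain the fold-level
  fluctuation the published rule implicitly rides on.
- Hierarchical cut heights are data- and metric-dependent; no default is
  offered, and purity at a fixed height is not comparable across metrics.
- The collapsed sampler couples documents through the shared topic–word
  counts, so training results depend on document order by construction
  (fold-in does not).
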