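# rpcselect

Choosing the number of topics T is the awkward step of every latent
Dirichlet allocation (LDA) analysis: held-out perplexity keeps improving
(or fluctuates) over a wide range of T, so "pick the least-perplexed
model" is unstable across random seeds and tends to over-select.
`rpcselect` implements a change-point heuristic on the **rate of
perplexity change (RPC)**: with mean cross-validated perplexities P_1..P_r
at increasing candidate topic numbers t_1..t_r,

    RPC(i) = | (P_i − P_{i−1}) / (t_i − t_{i−1}) |,

and the chosen T is t_i for the first i with RPC(i) < RPC(i+1) — the point
where the steep perplexity decline breaks. The package is aimed at
biomedical data-mining settings where documents are not only text:
bacterial strains as bags of SNP words, drugs as bags of side-effect
terms, and ordinary abstracts.

It bundles everything needed to run and evaluate the procedure offline:

- a from-scratch collapsed Gibbs LDA engine (`GibbsLDA`, numba-compiled,
  bit-reproducible under a seed) with held-out fold-in scoring;
- m-fold cross-validated perplexity curves, the RPC series and the
  change-point rule, plus the minimum-perplexity baseline
  (`RPCTopicSelector`);
- stability evaluation by Shannon entropy of repeated-seed selections, and
  cluster-purity evaluation of document–topic matrices (hierarchical and
  k-means);
- document encoders: aligned FASTA → SNP words, binary entity×feature TSV,
  and plain text (tokenize / stopwords / Porter stemming);
- synthetic generators with planted ground truth for every stage.

Estimators follow scikit-learn conventions (`fit`, `transform`,
`get_params`, fitted attributes with trailing underscores) and compose
with sklearn tooling; thin module-level functions mirror each step.

## Worked example

```python
from rpcselect import generate_lda_corpus, RPCTopicSelector, select_min_perplexity

# a corpus drawn from the LDA generative process with 20 planted topics
corpus, truth = generate_lda_corpus(
    n_docs=200, vocab_size=500, n_topics=20, doc_len=100,
    alpha_gen=0.1, beta_gen=0.01, seed=1)

sel = RPCTopicSelector(m_folds=5, n_iter=300, burn_in=150,
                       random_state=1).fit(corpus)
print("mean perplexity:", sel.curve_.mean_perplexity.round(2))
print("RPC:", sel.rpc_.values.round(3))
print("chosen T:", sel.n_topics_, "| change point found:", sel.found_change_point_)
print("min-perplexity baseline:", select_min_perplexity(sel.curve_).chosen)
```

Output:

```
mean perplexity: [105.11  77.87  54.83  54.87  55.53  56.02  56.62  57.3   57.94  58.46
  58.57]
RPC: [5.447e+00 2.304e+00 3.000e-03 6.700e-02 4.900e-02 6.000e-02 6.700e-02
 6.400e-02 5.100e-02 1.100e-02]
chosen T: 30 | change point found: True
min-perplexity baseline: 20
```

The curve falls steeply up to the planted truth (perplexity 105 → 55) and
flattens after it; RPC collapses from 5.4 to ~0.05 across that boundary
and first rises at T=30 — one grid step from the planted 20, which is the
resolution the 5,10,20,...,100 candidate grid can support. Repeating this
with different seeds (`stability_experiment`) shows the RPC choice
concentrating on few values while the minimum-perplexity choice wanders —
the entropy comparison that motivates the rule.

The same protocol runs from the shell:

```sh
rpcselect simulate --kind lda --seed 1 --out sim/
rpcselect select --corpus sim/corpus.txt --m-folds 5 \
    --iterations 300 --burn-in 150 --seed 1 --out run/
rpcselect stability --corpus sim/corpus.txt --repeats 10 --seed 0 --out stab/
```

`prep-msa`, `prep-matrix` and `prep-text` encode aligned FASTA, binary TSV
and raw text into the corpus format; `evaluate` scores cluster purity
against true labels; `topwords` exports ranked per-topic word tables.

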