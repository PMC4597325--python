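"""Latent Dirichlet allocation by collapsed Gibbs sampling.

The model: each topic t is a multinomial phi_t over the vocabulary drawn
from a symmetric Dirichlet(beta); each document d has topic proportions
theta_d drawn from a symmetric Dirichlet(alpha); every token draws a topic
from theta_d and then a word from phi_t. Inference integrates theta and phi
out and samples per-token topic assignments z from the collapsed
conditional

    p(z_i = t | z_-i, w) ∝ (n_dt^-i + alpha) (n_tw^-i + beta) / (n_t^-i + V beta)

Point estimates are read off the count tables with Dirichlet smoothing:
phi_tw = (n_tw + beta) / (n_t + V beta), theta_dt = (n_dt + alpha) / (N_d + T alpha),
either from the final sweep (default) or averaged over every k-th
post-burn-in sweep.
"""

from __future__ import annotations

import json
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import gammaln
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from ._gibbs import _foldin_doc, _init_sequential, _run_chunk_record, run_gibbs
from .corpus import Corpus

__all__ = [
    "GibbsLDA",
    "assignment_distribution",
    "exact_assignment_posterior",
    "fold_in",
    "train_lda",
]

DEFAULT_BETA = 0.01  # Griffiths-Steyvers convention; alpha defaults to 50/T


def _flatten(corpus: Corpus) -> tuple[np.ndarray, np.ndarray]:
    """Token-level (document index, word index) arrays in document order."""
    doc_of = np.concatenate(
        [np.full(len(d), i, dtype=np.int64) for i, d in enumerate(corpus.documents)]
    ) if corpus.n_tokens else np.empty(0, dtype=np.int64)
    word_of = (np.concatenate(corpus.documents).astype(np.int64)
               if corpus.n_tokens else np.empty(0, dtype=np.int64))
    return doc_of, word_of


def _as_corpus(X) -> Corpus:
    if isinstance(X, Corpus):
        return X
    counts = np.asarray(X)
    if counts.ndim != 2:
        raise ValueError("X must be a Corpus or a 2-D document-term count matrix")
    if counts.size and (counts < 0).any():
        raise ValueError("count matrix entries must be nonnegative")
    docs = []
    for row in counts.astype(np.int64):
        docs.append(np.repeat(np.arange(row.shape[0]), row))
    vocab = [f"w{j}" for j in range(counts.shape[1])]
    ids = [f"doc{i}" for i in range(counts.shape[0])]
    return Corpus(documents=docs, vocabulary=vocab, doc_ids=ids)


def _doc_seed(base_seed: int, doc_id: str) -> np.random.Generator:
    """Per-document RNG stream keyed by document identity, not position.

    Used for fold-in, where documents are conditionally independent given
    phi; keying on the id makes fold-in equivariant under permutation of
    the held-out documents.
    """
    ss = np.random.SeedSequence([int(base_seed) % (2**31), zlib.crc32(doc_id.encode())])
    return np.random.default_rng(ss)


class GibbsLDA(BaseEstimator, TransformerMixin):
    """Collapsed-Gibbs LDA with the scikit-learn estimator interface.

    Parameters
    ----------
    n_topics : int
        Number of topics T (>= 1).
    alpha : float or None
        Symmetric document-topic concentration; ``None`` uses 50 / T.
    beta : float
        Symmetric topic-word concentration (default 0.01).
    n_iter, burn_in : int
        Total Gibbs sweeps and how many of them are discarded as burn-in;
        requires ``n_iter > burn_in >= 0``.
    sample_every : int
        0 (default) reads phi/theta off the final sweep's count tables;
        k > 0 averages the smoothed estimates at every k-th post-burn-in
        sweep instead.
    foldin_iter, foldin_burn_in : int
        Gibbs sweeps used by :meth:`transform` / :meth:`score_documents`
        when folding held-out documents into a fitted model.
    init : {"random", "sequential"}
        Token-topic initialization. "random" (default) assigns
        uniform-random topics; "sequential" samples each token's topic
        from its collapsed conditional as counts accumulate. Both target
        the same posterior.
    random_state : int or None
        Seed; identical corpus + parameters + seed give bit-identical
        phi, theta and assignments.

    Attributes
    ----------
    components_ : (T, V) array — topic-word probabilities, rows sum to 1.
    doc_topic_ : (M, T) array — training-document topic proportions.
    assignments_ : (n_tokens,) final token-topic assignments.
    doc_topic_counts_, topic_word_counts_, topic_totals_ : count tables.
    """

    def __init__(self, n_topics: int = 10, alpha: float | None = None,
                 beta: float = DEFAULT_BETA, n_iter: int = 1000, burn_in: int = 500,
                 sample_every: int = 0, foldin_iter: int = 100,
                 foldin_burn_in: int = 50, foldin_average: bool = False,
                 init: str = "random",
                 random_state: int | None = None):
        self.n_topics = n_topics
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.sample_every = sample_every
        self.foldin_iter = foldin_iter
        self.foldin_burn_in = foldin_burn_in
        self.foldin_average = foldin_average
        self.init = init
        self.random_state = random_state

    # -- fitting ------------------------------------------------------------

    def _effective_alpha(self) -> float:
        return 50.0 / self.n_topics if self.alpha is None else float(self.alpha)

    def fit(self, X, y=None) -> "GibbsLDA":
        corpus = _as_corpus(X)
        T = int(self.n_topics)
        if T < 1:
            raise ValueError(f"n_topics must be >= 1, got {T}")
        if not (self.n_iter > self.burn_in >= 0):
            raise ValueError("need n_iter > burn_in >= 0")
        if corpus.n_docs == 0 or corpus.n_tokens == 0:
            raise ValueError("corpus must contain at least one nonempty document")
        alpha = self._effective_alpha()
        beta = float(self.beta)
        M, V = corpus.n_docs, corpus.n_words
        doc_of, word_of = _flatten(corpus)
        seed = 0 if self.random_state is None else int(self.random_state)
        rng = np.random.default_rng(np.random.SeedSequence(seed % (2**31)))

        n = doc_of.shape[0]
        ndt = np.zeros((M, T), dtype=np.int64)
        ntw = np.zeros((T, V), dtype=np.int64)
        u = rng.random(n)
        if self.init == "sequential":
            z = np.empty(n, dtype=np.int64)
            nt = np.zeros(T, dtype=np.int64)
            _init_sequential(z, doc_of, word_of, ndt, ntw, nt, alpha, beta,
                             u, np.empty(T))
        elif self.init == "random":
            z = (u * T).astype(np.int64)
            np.clip(z, 0, T - 1, out=z)
            np.add.at(ndt, (doc_of, z), 1)
            np.add.at(ntw, (z, word_of), 1)
            nt = ntw.sum(axis=1)
        else:
            raise ValueError(f"unknown init {self.init!r}")

        doc_len = corpus.doc_lengths
        phi_sum, theta_sum, n_samples = run_gibbs(
            z, doc_of, word_of, ndt, ntw, nt, alpha, beta,
            int(self.n_iter), int(self.burn_in), int(self.sample_every),
            rng, doc_len,
        )
        if n_samples > 0:
            phi = phi_sum / n_samples
            theta = theta_sum / n_samples
        else:
            phi = (ntw + beta) / (nt[:, None] + V * beta)
            theta = (ndt + alpha) / (doc_len[:, None] + T * alpha)

        self.components_ = phi
        self.doc_topic_ = theta
        self.assignments_ = z
        self.doc_topic_counts_ = ndt
        self.topic_word_counts_ = ntw
        self.topic_totals_ = nt
        self.vocabulary_ = list(corpus.vocabulary)
        self.doc_ids_ = list(corpus.doc_ids)
        self.n_features_in_ = V
        self.alpha_ = alpha
        self.beta_ = beta
        self.random_state_ = seed
        self._doc_of = doc_of
        self._word_of = word_of
        return self

    def check_state_consistency(self) -> None:
        """Assert the incremental count tables equal tallies of assignments."""
        check_is_fitted(self, "assignments_")
        T, V = self.components_.shape
        ndt = np.zeros_like(self.doc_topic_counts_)
        ntw = np.zeros_like(self.topic_word_counts_)
        np.add.at(ndt, (self._doc_of, self.assignments_), 1)
        np.add.at(ntw, (self.assignments_, self._word_of), 1)
        if not (np.array_equal(ndt, self.doc_topic_counts_)
                and np.array_equal(ntw, self.topic_word_counts_)
                and np.array_equal(ntw.sum(axis=1), self.topic_totals_)):
            raise AssertionError("count tables inconsistent with assignments")

    # -- held-out scoring ---------------------------------------------------

    def transform(self, X) -> np.ndarray:
        """Fold held-out documents in and return their theta estimates."""
        theta, _ = self.fold_in(X)
        return theta

    def fold_in(self, X, n_iter: int | None = None,
                seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Infer theta for held-out documents with phi frozen.

        Topic assignments for held-out tokens are Gibbs-sampled against the
        fixed topic-word rows; theta is the smoothed estimate from the final
        sweep's counts (default), or averaged over post-burn-in sweeps when
        ``foldin_average=True``. Returns (theta, per-document log-likelihoods)
        where log p(w_d) = sum_n log sum_t theta_dt phi_t,w_dn. Empty
        documents get theta = uniform and log-likelihood 0.
        """
        check_is_fitted(self, "components_")
        corpus = _as_corpus(X)
        phi = self.components_
        T, V = phi.shape
        for did, doc in zip(corpus.doc_ids, corpus.documents):
            if doc.size and doc.max() >= V:
                raise ValueError(
                    f"held-out document {did!r} uses word index {int(doc.max())} "
                    f"outside the model vocabulary (V={V}); build the vocabulary "
                    "on the full dataset before splitting"
                )
        iters = int(self.foldin_iter if n_iter is None else n_iter)
        base_seed = self.random_state_ if seed is None else int(seed)
        alpha = self.alpha_
        theta = np.empty((corpus.n_docs, T))
        loglik = np.zeros(corpus.n_docs)
        p = np.empty(T)
        for i, (did, words) in enumerate(zip(corpus.doc_ids, corpus.documents)):
            L = len(words)
            if L == 0:
                theta[i] = 1.0 / T
                continue
            if T == 1:
                theta[i] = 1.0
            else:
                rng = _doc_seed(base_seed, did)
                u_init = rng.random(L)
                uniforms = rng.random((iters, L))
                # burn-in >= n_sweeps makes the kernel fall back to the
                # final sample's counts
                burn = int(self.foldin_burn_in) if self.foldin_average else iters
                theta[i] = _foldin_doc(words, phi, alpha, u_init, uniforms,
                                       burn, p)
            loglik[i] = np.log(theta[i] @ phi[:, words]).sum()
        return theta, loglik

    def score_documents(self, X, **kw) -> np.ndarray:
        """Per-document held-out log-likelihoods (convenience wrapper)."""
        return self.fold_in(X, **kw)[1]

    # -- persistence --------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write phi/theta as TSV plus a JSON sidecar of hyperparameters."""
        check_is_fitted(self, "components_")
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(self.components_, columns=self.vocabulary_).to_csv(
            d / "phi.tsv", sep="\t", index_label="topic")
        pd.DataFrame(self.doc_topic_, index=self.doc_ids_).to_csv(
            d / "theta.tsv", sep="\t", index_label="doc_id")
        meta = {
            "n_topics": int(self.components_.shape[0]),
            "alpha": self.alpha_, "beta": self.beta_,
            "n_iter": self.n_iter, "burn_in": self.burn_in,
            "sample_every": self.sample_every, "seed": self.random_state_,
        }
        (d / "model.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "GibbsLDA":
        d = Path(directory)
        meta = json.loads((d / "model.json").read_text())
        phi = pd.read_csv(d / "phi.tsv", sep="\t", index_col="topic")
        theta = pd.read_csv(d / "theta.tsv", sep="\t", index_col="doc_id")
        model = cls(n_topics=meta["n_topics"], alpha=meta["alpha"], beta=meta["beta"],
                    n_iter=meta["n_iter"], burn_in=meta["burn_in"],
                    sample_every=meta["sample_every"], random_state=meta["seed"])
        model.components_ = phi.to_numpy()
        model.doc_topic_ = theta.to_numpy()
        model.vocabulary_ = list(phi.columns)
        model.doc_ids_ = [str(i) for i in theta.index]
        model.alpha_ = meta["alpha"]
        model.beta_ = meta["beta"]
        model.random_state_ = meta["seed"]
        model.n_features_in_ = phi.shape[1]
        return model


def train_lda(corpus: Corpus, n_topics: int, alpha: float | None = None,
              beta: float = DEFAULT_BETA, n_iter: int = 1000, burn_in: int = 500,
              seed: int | None = None, **kw) -> GibbsLDA:
    """Fit collapsed-Gibbs LDA on a corpus; returns the fitted estimator.

    Thin functional wrapper over :class:`GibbsLDA`; the topic-word matrix is
    ``model.components_`` and the document-topic matrix ``model.doc_topic_``.
    """
    return GibbsLDA(n_topics=n_topics, alpha=alpha, beta=beta, n_iter=n_iter,
                    burn_in=burn_in, random_state=seed, **kw).fit(corpus)


def fold_in(model: GibbsLDA, heldout: Corpus, n_iter: int = 100,
            seed: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Functional wrapper over :meth:`GibbsLDA.fold_in`."""
    return model.fold_in(heldout, n_iter=n_iter, seed=seed)


# ---------------------------------------------------------------------------
# Exact collapsed posterior over assignment configurations (validation oracle)
# ---------------------------------------------------------------------------

def exact_assignment_posterior(corpus: Corpus, n_topics: int, alpha: float,
                               beta: float) -> dict[tuple[int, ...], float]:
    """Enumerate p(z | w) for every token-topic configuration.

    Brute force over T ** n_tokens configurations of the collapsed joint

        p(z, w) ∝ prod_d prod_t Γ(n_dt + α) / Γ(α)
                * prod_t [ Γ(V β) / Γ(n_t + V β) * prod_w Γ(n_tw + β) / Γ(β) ]

    Only feasible for tiny corpora; serves as an independent correctness
    oracle for the sweep kernel.
    """
    T = n_topics
    doc_of, word_of = _flatten(corpus)
    n = doc_of.shape[0]
    if T ** n > 2_000_000:
        raise ValueError("configuration space too large to enumerate")
    M, V = corpus.n_docs, corpus.n_words
    configs = []
    logps = []
    for code in range(T ** n):
        z = np.empty(n, dtype=np.int64)
        c = code
        for i in range(n):
            z[i] = c % T
            c //= T
        ndt = np.zeros((M, T))
        ntw = np.zeros((T, V))
        np.add.at(ndt, (doc_of, z), 1)
        np.add.at(ntw, (z, word_of), 1)
        nt = ntw.sum(axis=1)
        lp = gammaln(ndt + alpha).sum() - gammaln(nt + V * beta).sum() \
            + gammaln(ntw + beta).sum()
        configs.append(tuple(int(t) for t in z))
        logps.append(lp)
    logps = np.array(logps)
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    return dict(zip(configs, probs))


def assignment_distribution(corpus: Corpus, n_topics: int, alpha: float,
                            beta: float, n_sweeps: int, burn_in: int,
                            seed: int) -> dict[tuple[int, ...], float]:
    """Empirical post-burn-in distribution of assignment configurations.

    Runs the production sweep kernel on a tiny corpus and tallies the full
    configuration after each post-burn-in sweep; pairs with
    :func:`exact_assignment_posterior` for total-variation checks.
    """
    T = n_topics
    doc_of, word_of = _flatten(corpus)
    n = doc_of.shape[0]
    if T ** n > 2_000_000:
        raise ValueError("configuration space too large to tally")
    M, V = corpus.n_docs, corpus.n_words
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) % (2**31)))
    z = (rng.random(n) * T).astype(np.int64)
    np.clip(z, 0, T - 1, out=z)
    ndt = np.zeros((M, T), dtype=np.int64)
    ntw = np.zeros((T, V), dtype=np.int64)
    np.add.at(ndt, (doc_of, z), 1)
    np.add.at(ntw, (z, word_of), 1)
    nt = ntw.sum(axis=1)
    counts = np.zeros(T ** n, dtype=np.int64)
    p = np.empty(T)
    done = 0
    chunk = 10_000
    while done < n_sweeps:
        k = min(chunk, n_sweeps - done)
        uniforms = rng.random((k, n))
        _run_chunk_record(z, doc_of, word_of, ndt, ntw, nt, alpha, beta,
                          uniforms, done, burn_in, counts, T, p)
        done += k
    total = counts.sum()
    out = {}
    for code in range(T ** n):
        zz = []
        c = code
        for _ in range(n):
            zz.append(c % T)
            c //= T
        out[tuple(zz)] = counts[code] / total
    return out
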