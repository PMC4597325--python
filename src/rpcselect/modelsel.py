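"""Topic-number selection: cross-validated perplexity, RPC, change point.

The protocol: documents are partitioned once into m folds; for each
candidate topic number t and each fold, an LDA model is trained on the
other m-1 folds, the fold is folded in, and its held-out perplexity

    perplexity = exp( - sum_d log p(w_d) / sum_d N_d )

is recorded. The mean over folds gives the perplexity curve P_1..P_r over
the increasing candidates t_1..t_r. The rate of perplexity change

    RPC(i) = | (P_i - P_{i-1}) / (t_i - t_{i-1}) |        (2 <= i <= r)

falls steeply while added topics still improve fit and flattens once they
stop; the first i with RPC(i) < RPC(i+1) — the change point where the
decline breaks — is selected as the appropriate topic number. The
minimum-perplexity rule (argmin P) is provided as the comparison baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .corpus import Corpus
from .lda import GibbsLDA

__all__ = [
    "DEFAULT_CANDIDATES",
    "PerplexityCurve",
    "RPCSeries",
    "RPCTopicSelector",
    "SelectionResult",
    "compute_rpc",
    "cross_validate_perplexity",
    "held_out_perplexity",
    "make_folds",
    "select_change_point",
    "select_min_perplexity",
]

# 5, 10, then increments of 10 up to 100
DEFAULT_CANDIDATES: tuple[int, ...] = (5, 10, 20, 30, 40, 50, 60, 70, 80, 90, 100)


def held_out_perplexity(per_doc_loglik, doc_lengths) -> float:
    """exp(-sum_d log p(w_d) / sum_d N_d) over a held-out document set.

    Empty documents contribute 0 to both sums; a held-out set with zero
    tokens overall has no defined perplexity and raises.
    """
    loglik = np.asarray(per_doc_loglik, dtype=float)
    lengths = np.asarray(doc_lengths, dtype=float)
    if loglik.shape != lengths.shape:
        raise ValueError("log-likelihoods and lengths must align")
    if not np.isfinite(loglik).all():
        raise ValueError("log-likelihoods must be finite")
    total = lengths.sum()
    if total <= 0:
        raise ValueError("held-out set has no tokens: perplexity undefined")
    return float(np.exp(-loglik.sum() / total))


@dataclass
class PerplexityCurve:
    """Mean held-out perplexity at each candidate topic number.

    ``fold_perplexities`` is (r, m): row i holds fold perplexities for
    candidate ``candidates[i]``; ``mean_perplexity`` is its row mean.
    """

    candidates: np.ndarray
    fold_perplexities: np.ndarray
    mean_perplexity: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.candidates = np.asarray(self.candidates, dtype=np.int64)
        self.fold_perplexities = np.atleast_2d(np.asarray(self.fold_perplexities, float))
        if not (np.diff(self.candidates) > 0).all():
            raise ValueError("candidates must be strictly increasing")
        if self.fold_perplexities.shape[0] != self.candidates.shape[0]:
            raise ValueError("one row of fold perplexities per candidate")
        if not (self.fold_perplexities > 0).all():
            raise ValueError("perplexities must be positive")
        self.mean_perplexity = self.fold_perplexities.mean(axis=1)


@dataclass
class RPCSeries:
    """RPC values at candidates t_2..t_r (one fewer than the curve)."""

    topic_numbers: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.topic_numbers = np.asarray(self.topic_numbers, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if self.topic_numbers.shape != self.values.shape:
            raise ValueError("topic numbers and values must align")
        if (self.values < 0).any():
            raise ValueError("RPC values are absolute and must be >= 0")


@dataclass
class SelectionResult:
    """Outcome of a selection rule.

    ``found`` is False when no index satisfied the change-point condition;
    ``chosen`` then carries the last candidate as a fallback suggestion.
    """

    chosen: int
    found: bool
    rule: str


def make_folds(n_docs: int, m_folds: int, seed: int) -> list[np.ndarray]:
    """Random balanced partition of document indices into m folds (±1)."""
    if m_folds < 2:
        raise ValueError("need at least 2 folds")
    if m_folds > n_docs:
        raise ValueError(f"cannot split {n_docs} documents into {m_folds} folds")
    rng = np.random.default_rng(np.random.SeedSequence(int(seed) % (2**31)))
    perm = rng.permutation(n_docs)
    return [np.sort(f) for f in np.array_split(perm, m_folds)]


def _sub_seed(seed: int, *key: int) -> int:
    return int(np.random.SeedSequence([int(seed) % (2**31), *key]).generate_state(1)[0]
               % (2**31))


def cross_validate_perplexity(
    corpus: Corpus,
    candidates=DEFAULT_CANDIDATES,
    m_folds: int = 5,
    seed: int = 0,
    alpha: float | None = None,
    beta: float = 0.01,
    n_iter: int = 1000,
    burn_in: int = 500,
    sample_every: int = 0,
    foldin_iter: int = 100,
    scoring: str = "completion",
    refold_per_candidate: bool = False,
) -> PerplexityCurve:
    """m-fold cross-validated held-out perplexity over candidate topic numbers.

    One random balanced partition is drawn and shared by all candidates
    (``refold_per_candidate=True`` re-randomizes per candidate instead).
    For each candidate and fold, the model is trained on the other folds
    and the fold's perplexity is recorded.

    ``scoring`` picks the held-out likelihood estimator:

    - ``"completion"`` (default): document completion — theta is inferred
      by Gibbs fold-in on the even-indexed tokens of each test document
      and the odd-indexed tokens are scored. Estimating theta on the very
      tokens being scored rewards extra topics indefinitely; completion
      removes that leak, so the curve shows the genuine fall / flatten /
      overfitting-rise shape the change-point rule relies on.
    - ``"fold_in"``: theta inferred from, and scored on, all test tokens.

    Deterministic for fixed seed.
    """
    cand = np.asarray(list(candidates), dtype=np.int64)
    if cand.size < 1 or (cand < 1).any() or not (np.diff(cand) > 0).all():
        raise ValueError("candidates must be strictly increasing integers >= 1")
    if scoring not in ("completion", "fold_in"):
        raise ValueError(f"unknown scoring {scoring!r}")
    folds = make_folds(corpus.n_docs, m_folds, seed)
    fold_perp = np.empty((cand.size, m_folds))
    for ci, t in enumerate(cand):
        if refold_per_candidate:
            folds = make_folds(corpus.n_docs, m_folds, _sub_seed(seed, 7, ci))
        for fi, test_idx in enumerate(folds):
            train_idx = np.setdiff1d(np.arange(corpus.n_docs), test_idx)
            train = corpus.subset(train_idx)
            test = corpus.subset(test_idx)
            model = GibbsLDA(
                n_topics=int(t), alpha=alpha, beta=beta, n_iter=n_iter,
                burn_in=burn_in, sample_every=sample_every,
                foldin_iter=foldin_iter,
                random_state=_sub_seed(seed, ci, fi),
            ).fit(train)
            fi_seed = _sub_seed(seed, ci, fi, 1)
            if scoring == "completion":
                estimation = Corpus([d[0::2] for d in test.documents],
                                    test.vocabulary, test.doc_ids)
                theta, _ = model.fold_in(estimation, seed=fi_seed)
                loglik = np.array([
                    float(np.log(theta[i] @ model.components_[:, d[1::2]]).sum())
                    for i, d in enumerate(test.documents)])
                lengths = np.array([len(d[1::2]) for d in test.documents])
            else:
                _, loglik = model.fold_in(test, seed=fi_seed)
                lengths = test.doc_lengths
            fold_perp[ci, fi] = held_out_perplexity(loglik, lengths)
    return PerplexityCurve(candidates=cand, fold_perplexities=fold_perp)


def compute_rpc(curve: PerplexityCurve) -> RPCSeries:
    """RPC(i) = |(P_i - P_{i-1}) / (t_i - t_{i-1})| for i = 2..r."""
    if curve.candidates.size < 2:
        raise ValueError("need at least 2 candidates to compute RPC")
    dP = np.diff(curve.mean_perplexity)
    dt = np.diff(curve.candidates).astype(float)
    return RPCSeries(topic_numbers=curve.candidates[1:], values=np.abs(dP / dt))


def select_change_point(rpc: RPCSeries) -> SelectionResult:
    """First candidate t_i with RPC(i) < RPC(i+1) (strict inequality).

    A tie is not a change point. When the series is non-increasing
    throughout, ``found`` is False and the last candidate is returned as a
    fallback suggestion.
    """
    if rpc.values.size < 2:
        raise ValueError("need at least 2 RPC values to locate a change point")
    for j in range(rpc.values.size - 1):
        if rpc.values[j] < rpc.values[j + 1]:
            return SelectionResult(chosen=int(rpc.topic_numbers[j]), found=True,
                                   rule="rpc_change_point")
    return SelectionResult(chosen=int(rpc.topic_numbers[-1]), found=False,
                           rule="rpc_change_point")


def select_min_perplexity(curve: PerplexityCurve) -> SelectionResult:
    """Candidate with minimal mean perplexity; ties go to the smallest."""
    if curve.candidates.size < 1:
        raise ValueError("empty curve")
    j = int(np.argmin(curve.mean_perplexity))  # argmin takes first == smallest t
    return SelectionResult(chosen=int(curve.candidates[j]), found=True,
                           rule="min_perplexity")


class RPCTopicSelector(BaseEstimator):
    """Select the number of LDA topics by the RPC change-point rule.

    ``fit(corpus)`` runs the full protocol — m-fold CV perplexity curve,
    RPC series, change-point selection — and exposes:

    - ``curve_`` : :class:`PerplexityCurve`
    - ``rpc_`` : :class:`RPCSeries`
    - ``selection_`` : :class:`SelectionResult` for the configured rule
    - ``n_topics_`` : the chosen topic number
    - ``found_change_point_`` : False when the rule fell back

    Parameters mirror :func:`cross_validate_perplexity`; ``selector`` is
    ``"rpc"`` (default) or ``"min_perplexity"``.
    """

    def __init__(self, candidates=DEFAULT_CANDIDATES, m_folds: int = 5,
                 alpha: float | None = None, beta: float = 0.01,
                 n_iter: int = 1000, burn_in: int = 500, sample_every: int = 0,
                 foldin_iter: int = 100,
                 selector: str = "rpc", scoring: str = "completion",
                 refold_per_candidate: bool = False, random_state: int = 0):
        self.candidates = candidates
        self.m_folds = m_folds
        self.alpha = alpha
        self.beta = beta
        self.n_iter = n_iter
        self.burn_in = burn_in
        self.sample_every = sample_every
        self.foldin_iter = foldin_iter
        self.selector = selector
        self.scoring = scoring
        self.refold_per_candidate = refold_per_candidate
        self.random_state = random_state

    def fit(self, X, y=None) -> "RPCTopicSelector":
        if self.selector not in ("rpc", "min_perplexity"):
            raise ValueError(f"unknown selector {self.selector!r}")
        if not isinstance(X, Corpus):
            raise TypeError("RPCTopicSelector expects a Corpus")
        corpus = X
        self.curve_ = cross_validate_perplexity(
            corpus, candidates=self.candidates, m_folds=self.m_folds,
            seed=self.random_state, alpha=self.alpha, beta=self.beta,
            n_iter=self.n_iter, burn_in=self.burn_in,
            sample_every=self.sample_every,
            foldin_iter=self.foldin_iter, scoring=self.scoring,
            refold_per_candidate=self.refold_per_candidate,
        )
        self.rpc_ = compute_rpc(self.curve_)
        if self.selector == "rpc":
            self.selection_ = select_change_point(self.rpc_)
        else:
            self.selection_ = select_min_perplexity(self.curve_)
        self.n_topics_ = self.selection_.chosen
        self.found_change_point_ = self.selection_.found
        return self
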